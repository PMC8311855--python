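# cognet

Cognitive covariance network analysis: build group-level graphs over a
neuropsychological test battery, quantify their topology with graph-theory
metrics, and contrast groups with nonparametric statistics.

## The problem

Clinical neuropsychology scores patients on batteries of cognitive tests
(memory, semantic processing, abstract reasoning, executive function, ...).
Beyond individual scores, the *correlation structure* among tests carries
information: with aging — and more sharply with conditions such as amnestic
mild cognitive impairment (aMCI) and Alzheimer-type dementia —
performances across unrelated domains become increasingly correlated
("cognitive dedifferentiation"). `cognet` operationalizes that idea as a
network. For each group of subjects:

1. Raw scores are converted to norm-referenced z-scores,
   z = (raw − μ_ref)/σ_ref, oriented so that higher always means better
   (time and error scores are multiplied by −1). Reference norms can come
   from the pooled healthy sample, each group itself, or matched controls.
2. Every pair of tests gets a **partial Spearman correlation** controlling
   for age and education: ranks of both scores and covariates are computed
   (average ranks on ties), each rank vector is residualized on the ranked
   covariates by OLS, and ρ is the Pearson correlation of the residuals,
   with a two-tailed p from t = ρ√((n−2−k)/(1−ρ²)) on n−2−k df.
   Edges with 0.01 < p < 0.1 are re-checked by a seeded permutation test
   (5000 randomizations by default).
3. Thresholding p < 0.05 (and dropping negative coefficients, which have no
   theoretical interpretation here; a flag retains them for sensitivity
   analysis) yields a **binary undirected graph**: nodes are tests, edges
   are significant positive partial correlations.
4. Per node, the package computes betweenness centrality
   BC(v) = Σ_{s<t} σ_st(v)/σ_st (unnormalized), clustering coefficient
   C(v) = 2e_N(v)/(k_v(k_v−1)), local efficiency (global efficiency of the
   neighbor-induced subgraph), nodal global efficiency
   E(v) = ⟨1/d(v,u)⟩_u, and connection density k_v/(N−1); plus Louvain
   communities with Newman modularity Q, and hub flags
   (BC > mean + 1.5 SD). All metrics are implemented from first principles
   and are oracle-tested against brute-force enumeration.
5. Node metrics are averaged into four domain profiles, intra- vs
   inter-domain consistency is assessed on Fisher-z transformed partial
   correlations (controlling age, education and MMSE), and groups are
   contrasted with Mann–Whitney U (node metrics), Kruskal–Wallis H + Dunn
   post hocs (test scores), and chi-square (demographics), all
   Bonferroni-corrected with the family size reported.

Because participant-level clinical data of this kind are rarely shareable,
the package includes a **synthetic cohort generator**: Gaussian-copula
latents with planted within/between-domain Spearman blocks (de-attenuated
via r = 2·sin(πρ_S/6)), additive age/education effects, skewed marginals and
protocol-specific missing tests. The `r_between` parameter is a direct
dedifferentiation dial, so recovery of the construct is testable end to end.

## Worked example

```bash
cognet run --seed 1 --out results/run1
```

builds the default six-group synthetic cohort (three healthy age strata with
n = 75/75/70 — the youngest lacking both Prose Memory measures — plus aMCI,
naMCI and dementia groups, n = 75/60/60) and prints:

```
group young: 14 nodes, 19 edges
group middle: 16 nodes, 37 edges
group older: 16 nodes, 84 edges
group amci: 16 nodes, 115 edges
group namci: 16 nodes, 90 edges
group dementia: 16 nodes, 116 edges
```

The edge counts rise monotonically along the planted dedifferentiation
gradient (whole-network density 0.21 → 0.31 → 0.70 in the healthy strata,
0.75–0.97 in the patient groups): as between-domain correlation grows, more
test pairs clear the p < 0.05 cut. The bundle written to `results/run1`
contains, per group, the edge statistics, the 0/1 adjacency CSV, an edge
list and a GraphML file (Gephi-ready, with community/betweenness/hub node
attributes), the node-metric table, and domain profiles; plus the
cross-group Mann–Whitney table, the consistency table and a `manifest.json`
recording every seed and threshold. For seed 1 the consistency table reads

```
   domain  intra_mean_z  inter_mean_z  n_intra_pairs  n_inter_pairs
   memory         0.562         0.304              6             48
 semantic         0.557         0.295              3             39
 abstract         0.373         0.304              3             39
executive         0.516         0.290              6             48
```

— intra-domain coherence exceeds inter-domain coherence in every domain, as
planted (the generator's within-domain Spearman is 0.5–0.6 against a
0.05–0.45 between-domain gradient), and the pair counts are exactly
C(m,2) and m(T−m) for m domain members among T tests. The node-level
density contrast between the extreme healthy groups is strongly significant
(U = 10, p_adjusted ≈ 0.0003 over a family of 15 group pairs).

Each stage is also available separately (`cognet simulate`, `standardize`,
`build`, `metrics`, `domains`, `consistency`, `compare`, `compare-scores`)
or as plain library calls (`cognet.generate_cohort`,
`cognet.build_edge_stats`, `cognet.node_metrics`, ...).

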