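# Methods

This note documents the models, numerical choices and limitations behind
`cognet`, in the order the pipeline runs.

## Synthetic cohorts

The generator emulates a multi-group neuropsychological study in which only
the correlation structure and covariate effects matter downstream — it makes
no attempt to mimic real tests' score ranges, ceilings or medians.

**Model.** For a group of n subjects scored on T tests, latent performance
is multivariate normal, L ~ N(0, R), where R has unit diagonal, r_within
for pairs of tests sharing a primary domain and r_between elsewhere.
Covariate effects enter additively, performance = L + β_age·age +
β_edu·education, with age and education drawn uniformly (integer years)
from group-specific ranges. Reverse-oriented tests (Stroop time and errors)
emit raw = −performance, so the orientation flip downstream is exercised.
An optional strictly monotone transform, x ↦ expm1(x/2), right-skews the
marginals without touching ranks.

**Spearman targets.** Because bivariate-normal latents attenuate rank
correlation (ρ_S = (6/π)·arcsin(r/2)), targets are specified on the
Spearman scale and de-attenuated with r = 2·sin(πρ_S/6) before the
Cholesky draw. Tests confirm the planted Spearman block means are recovered
to Monte-Carlo accuracy (±0.05 over 100–200 replicate seeds at n = 75).

**Positive semi-definiteness.** The block target is PSD whenever
0 ≤ r_between ≤ r_within < 1 (it decomposes as (1−r_w)·I + (r_w−r_b)·block-J
+ r_b·J), but both the Spearman target and its de-attenuated Pearson image
are verified by eigendecomposition anyway (tolerance −1e−10), with the
offending eigenvalue named on failure; a 1e−10 diagonal jitter guards the
Cholesky factorization at the PSD boundary.

**Defaults.** The default cohort mirrors a six-group aging/impairment
study: healthy strata aged 18–39 / 40–64 / 65–85 (n = 75/75/70, the
youngest missing both Prose Memory measures, which are emitted as empty
fields, never zeros), and aMCI / naMCI / dementia groups (n = 75/60/60)
with lower education and MMSE ranges. Within-domain correlation is
0.5–0.6; between-domain correlation rises 0.05 → 0.15 → 0.30 across the
healthy strata and 0.35–0.45 in patient groups, expressing the
dedifferentiation construct the pipeline is meant to detect. Covariate
slopes default to −0.01 SD per year of age and +0.05 SD per year of
education for every test — mild, plausible values chosen once; no published
per-test effect sizes exist for this battery, so they are configuration,
not constants. Every group draws from an independent `SeedSequence` stream
spawned from the master seed, so edits to one group never perturb another.

**What the generator does not emulate:** item-level structure, practice and
floor/ceiling effects, informative missingness (missingness is
protocol-level only), measurement error heteroscedasticity, and
age-dependent covariance changes within a group. Passing recovery tests on
these cohorts therefore shows the pipeline detects planted rank-correlation
structure under realistic marginals and covariates — not that it would
survive every pathology of real clinical data.

## Standardization

z = (raw − μ_ref)/σ_ref per test, sample SD (n−1 denominator, the
normative-study convention; the source procedure is silent on this).
Three referencing schemes are exposed as one `norm_source` option: pooled
healthy sample (between-group score tables), own group (network formation
for healthy groups), and matched controls (network formation for patient
groups). Orientation (−1 for reverse-scored tests) is applied after
z-scoring and is an involution. Missing values propagate; nothing is
imputed. Since z-scoring is affine with positive slope and the network
stage is rank-based, self-normed networks equal raw-score networks with the
same covariates — a tested invariant. The canonical battery file makes
orientation explicit and editable; the Stroop time/error measures are the
only reverse-oriented scores.

## Network formation

Partial Spearman correlation is computed as rank-then-residualize: average
ranks for scores and covariates, OLS residuals of each rank vector on
[1, ranked covariates], Pearson correlation of residuals. This standard
construction admits an exact independent oracle (tests agree to 1e−12).
Analytic p uses t = ρ√((n−2−k)/(1−ρ²)) on n−2−k df, two-tailed; its type-I
rate calibrates to 0.05 ± 0.015 over 2000 null replicates at n = 70.

Complete cases are determined per pair (pairwise-listwise deletion over x,
y and the covariates), maximizing n per edge; pairs that cannot be computed
(constant scores, n < k+3) are skipped with a logged reason, never silently.
Tests with no data in a group drop out of the node set entirely, so a
protocol missing both Prose Memory measures yields 14 nodes and C(14,2)=91
candidate edges.

The permutation check permutes the y rank-residual vector (a
Freedman–Lane-style scheme on ranks, preserving the covariate structure of
the unpermuted variable), two-sided, with the add-one correction
p = (1+#exceed)/(n_perm+1), so p = 0 is unattainable and determinism is
guaranteed by per-pair `SeedSequence` streams (results do not depend on
pair order or on which other pairs exist). Permutation p is computed only
for edges with analytic p strictly inside (0.01, 0.1) — the band where a
threshold decision is fragile. By default it is a *check*; the
`use_permutation_in_band` flag makes it the deciding p instead, since the
source procedure is ambiguous on this point. At 5000 permutations the
Monte-Carlo SD of a permutation p near 0.05 is ≈ 0.003, so the maximum
|p_perm − p_analytic| over a band of 25–40 edges sits naturally near 0.01.

Thresholding is an absolute cut, strictly p < α (α = 0.05 default): no
proportional thresholding, and no Gaussian graphical model / regularized
precision estimation — scores are non-normal by design and density
differences between groups are themselves the signal. Negative coefficients
are removed by default (graph metrics here are validated on positively
connected networks; negative cross-domain correlations lack a theoretical
reading); `drop_negative=False` retains them as ordinary unsigned edges for
sensitivity analysis. A second sensitivity hook rebuilds the graph with age
only as covariate and reports the symmetric-difference edge set; with no
planted education effect the changed fraction is ≈ 0.

Under a global null the expected density is ≈ α/2 with the positivity
filter (a true-null significant edge is positive with probability 1/2) and
≈ α without it; both calibrations are asserted over 500 synthetic null
groups.

## Graph metrics

All metrics operate on the binary adjacency and are written from their
definitions; a brute-force path-enumeration oracle (and networkx) verifies
them exactly on hundreds of random graphs.

- **Betweenness**: Brandes accumulation; unordered-pair convention (ordered
  sum halved), unnormalized — matching the verbal definition and reference
  toolbox convention. Whether the original analysis counted ordered pairs
  is unverifiable; unordered is documented here and differs only by a
  global factor of 2, which cancels in hub detection and rank-based
  contrasts.
- **Clustering**: C(v) = 2e_N(v)/(k_v(k_v−1)), 0 for k_v < 2.
- **Global efficiency** (nodal): mean of 1/d(v,u); unreachable pairs
  contribute 0; the whole-network value is the nodal mean.
- **Local efficiency**: whole-network global efficiency of the subgraph
  induced by v's neighbors (v excluded), 0 for k_v < 2. The one-line verbal
  definition is ambiguous between this (the reference-toolbox definition,
  adopted) and pairwise-only paths.
- **Density**: k_v/(N−1) per node, 2|E|/(N(N−1)) whole-network; their
  equality in the mean is a tested identity.
- **Hubs**: BC > mean + 1.5·SD, sample SD (n−1); zero spread ⇒ no hubs.
- **Louvain**: standard two-phase greedy modularity optimization with
  seeded sweep order; gain threshold 1e−12 breaks ties toward staying, so
  runs are deterministic under a seed. Run-once by default; `restarts=R`
  keeps the best-Q of R independent seeded runs. The reported Q is always
  recomputed from the final node mapping by the standalone `modularity`
  function, making it independently checkable. Edgeless graphs return the
  all-singleton partition with Q defined as 0. On random graphs with
  N ≤ 10 the run-once partition attains the exhaustive-search optimum in
  well over 80% of runs and never exceeds it.

## Domain profiles and consistency

Domain means are arithmetic means of each metric over the member nodes
present in the graph; Similarities and Category Fluency belong to both the
semantic and abstract domains and are counted in each (never deduplicated);
a domain with no present members is reported as absent, not zero. Domains
are fixed theoretical groupings — Louvain communities are reported
separately and never substituted for them.

Consistency uses whole-cohort partial Spearman correlations controlling
age, education and MMSE, mapped through Fisher z = atanh(ρ). For domain d
with m members among T tests, the intra mean averages C(m,2) within-domain
z values and the inter mean averages the m(T−m) member-vs-nonmember values
(the member×nonmember reading of the ambiguous verbal definition, which its
own worked pair counts support: 6 and 48 for a 4-member domain among 16
tests). Means are taken on the z scale and reported both as z and as
tanh(mean z), since the two scales are easily conflated. |ρ| ≥ 1−1e−12
raises (infinite z), naming the pair.

## Group contrasts

Mann–Whitney U is two-tailed with scipy's policy: exact enumeration for
small untied samples, tie-corrected normal approximation otherwise.
The samples being compared are node-level metric vectors of two group
graphs — not independent observations, since they derive from one estimated
network. The test is provided exactly as practiced in this literature, with
this caveat, and `metric_permutation_test` offers a subject-relabelling
alternative (re-split subjects at observed group sizes, rebuild both
graphs, compare mean metric differences) whose null respects the
construction. Kruskal–Wallis H is tie-corrected, df = G−1; an all-tied
pooled sample returns H = 0, p = 1. Dunn's post hoc z uses pooled
mid-ranks with tie term Σ(t³−t)/(12(N−1)). Chi-square is Pearson's without
continuity correction; zero marginals raise. The Bonferroni family for
network metrics defaults to the number of group pairs per metric
(per-metric families — the most defensible reading of an unstated
convention) and is always recorded in the output, so any convention is
auditable.

## Orchestration

`run_pipeline` composes the stages per group and writes the bundle
(edge stats, adjacency CSV — the inter-stage interchange format — edge
list, GraphML with community/betweenness/hub attributes, node metrics,
partition, domain profiles, comparison and consistency tables) plus a
manifest with every seed, threshold and option; identical config ⇒
byte-identical numeric outputs (tested). Per-group edge and Louvain seeds
derive deterministically from the master seed by group index and are
recorded in the manifest. 2-D layout is intentionally out of scope: exports
target external tools (Gephi/ForceAtlas2).

## Problem sizes in the automated checks

The test and acceptance studies use group sizes matching the emulated study
(n = 60–75), 500 null groups for density calibration, 2000 replicates for
type-I calibration, 50 replicates for gradient/community-recovery studies,
200 random graphs (N ≤ 8) for metric oracles and 100 (N ≤ 10) for the
exhaustive modularity comparison — sizes at which the Monte-Carlo error of
each assertion is small relative to its tolerance.

## Known limitations

- The U test on node metrics inherits the dependence caveat above.
- Analytic p for partial Spearman is a t approximation; at n ≈ 70 its gap
  to the permutation p is within ~0.01 for band edges, but it is not exact.
- Community recovery on thresholded graphs is limited by the modularity
  landscape itself: planted between-domain correlation produces real
  cross-block edges, and beyond a modest rate the maximum-modularity
  partition genuinely merges blocks — no optimizer can then recover the
  planted split exactly. The clustering coefficient is likewise a noisy
  dedifferentiation readout at low graph density; density and global
  efficiency separate the planted gradient far more reliably.
- Graphs are strictly binary and unweighted; no weighted metrics, no
  small-world σ/ω statistics.
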