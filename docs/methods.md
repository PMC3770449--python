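# Methods

## Model and procedure

`intomics` tests, for each of *n* biomarkers measured on *Q* platforms,
the conjunction of analogous null hypotheses "biomarker *i* is
undifferentiated between disease and control on platform *q*". The
procedure is:

1. **Per-platform statistics.** For each biomarker and platform a
   two-group statistic is computed, oriented disease-minus-control:
   Welch (unpooled-variance) Student *t*, the unstandardized difference
   of group means, or a Wilcoxon rank-sum *Z* (normal approximation
   with tie correction, no continuity correction). The side adjustment
   maps the raw statistic to the scale where larger positive values
   support the alternative: right keeps *t*, left negates it, two-sided
   takes |*t*|. Because calibration is by permutation, the marginal
   distribution of the statistic is irrelevant; only its ordering and
   scale matter, which is what permits mixing statistic types across
   platforms.
2. **Simultaneous permutation null.** Group labels are permuted *B*
   times, uniformly over balanced assignments (group sizes preserved;
   the identity is not excluded). A permutation moves whole sample
   columns, never individual biomarker values, so within-sample
   dependence across biomarkers survives. Platforms whose samples are
   linked by `subject_id` receive one common relabeling per round;
   unlinked platforms are permuted independently. Each round recomputes
   the full n × Q statistic matrix, and all B·n vectors are pooled
   across biomarkers. Pooling is justified when biomarkers are
   independent or exchangeably correlated within a platform; see
   "Limitations".
3. **Weighted aggregation and threshold.** σ̂_q is the sample standard
   deviation of platform *q*'s pooled permuted statistics and Σ̂ their
   sample covariance. The linear aggregated statistic is
   t_A = Σ_q t_q/σ̂_q — platforms with noisier statistics get
   proportionally less weight — and the threshold C_α is the empirical
   100(1−α)% percentile of t_A over the pooled null (the same σ̂ weights
   applied to the null rows, so the weighting is self-consistent).
   Selection uses the strict inequality t_A > C_α.
4. **Error control.** The per-biomarker level α can be set directly,
   via Bonferroni α = α*/n, or by targeting at most *f* expected false
   discoveries through α = f/(n·π̂). Estimated quantities reported:
   F̂P = nπ̂α, T̂P (selected count), FD̂R = F̂P/T̂P (capped at 1, zero
   when nothing is selected).

The quadratic alternative t_Q = v′Σ̂⁻¹v consumes the signed statistic
vector (sign information would be destroyed by side adjustment and is
already irrelevant to a quadratic form); it is appropriate only for
two-sided alternatives, whereas the linear statistic handles one- and
two-sided ones.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `B` | 100 | permutation rounds; the pooled null has B·n rows, so even B = 100 yields 10⁵ null draws at n = 1000, enough to estimate a 95th percentile stably |
| `alpha` | 0.05 | per-biomarker level; the selection proportion under the global null calibrates to it |
| `pi_hat` | 1 | non-differential proportion used in F̂P and f-mode α; 1 is conservative. An optional plug-in (`estimate_pi_hat`: twice the fraction of observed t_A below the null median, clamped) is provided but never applied implicitly |
| `cap` | 1e6 | finite stand-in for an infinite *t* when both group variances vanish with unequal means, keeping null percentiles finite |
| `scale_basis` | `"raw"` | σ̂/Σ̂ estimated from signed permuted statistics. For two-sided platforms one could instead use the side-adjusted |t| values (`"adjusted"`); raw is the default because σ̂ is defined as the sd of the statistics themselves, and the absolute value enters only the aggregation numerator. The switch exists because either reading is defensible; since the same σ̂ weights observed and null rows, the choice shifts relative platform weights only mildly |
| `method` | `"linear"` | `"quadratic"` switches to t_Q |

Percentile convention: C_α is the k-th order statistic of the M pooled
null aggregates with k = ceil((1−α)·M), clamped to [1, M] — an attained,
slightly conservative value (α = 1 gives the minimum). Ties at the
threshold are excluded by the strict inequality.

## Synthetic-data generator

`intomics.simulate` emulates two-group multi-platform experiments.
Continuous platforms draw each biomarker's 2m measurements from a
multivariate normal with unit variances and exchangeable correlation
ρ_within (Σ = (1−ρ)I + ρJ), control mean 0 and disease mean *e*; count
platforms draw independent Poisson counts with control mean λ (default
5) and disease mean λ + e. The differential biomarkers are the first
g₁ + g₂ indices, two subgroups with separate effect sizes per platform.
Cross-platform sample dependence, when requested, couples matched
samples of continuous platforms through a shared Gaussian factor with
correlation ρ_across (a Gaussian-copula exchangeable coupling; disease
and control groups stay independent), and marks those samples as linked
so the permutation is simultaneous. The benchmark defaults are n = 1000
biomarkers, g₁ = g₂ = 100, m = 5 samples per group, B = 100, α = 0.05,
100 replicate datasets per scenario.

The scenario catalog fixes the benchmark settings: two-platform
continuous designs at ρ ∈ {0, 0.5} with right-, left- and two-sided
effect patterns ((0.5, 2)/(1.5, 1) and sign-flipped/mixed variants),
five-platform designs with effects (1.5, 1.5), (1.5, 1), (−0.5, −2),
(−1, 1.5), (2, −1), a mixed continuous/Poisson design (λ = 5, e = 3 for
all 200 differential markers), a tiny-sample design (m = 2), a
cross-platform-correlation design (ρ_across = 0.5), a mean-difference
variant, the quadratic-statistic comparison, and expected-false-positive
control at α = f/(nπ) = 4/(1000·0.8) = 0.005. Where a table setting does
not print per-platform sides, sides are inferred from the effect signs
(all positive → right, all negative → left, mixed → two-sided). The
tiny-sample scenario does not print its effect sizes either; it runs
with the standard two-platform right-sided effects.

What the generator does **not** emulate: heavy-tailed or heteroscedastic
expression noise, platform-specific normalization artifacts, batch
effects, missingness (real inputs must be imputed upstream), non-
exchangeable (e.g. block or autoregressive) within-platform covariance,
and count overdispersion beyond Poisson. Passing simulation benchmarks
therefore demonstrates correctness of the machinery and its operating
characteristics under the stated generative conditions, not robustness
to those real-data features.

## Numerical choices and degenerate inputs

- Welch t is computed from row-centered data via sum/sum-of-squares
  updates; variances are clipped at zero against cancellation noise.
  A zero pooled variance yields 0 when the group means agree (to within
  1e−8 of the data scale) and ±`cap` otherwise, with a logged warning.
- Wilcoxon uses the exact relabeling mean and variance of the rank-sum
  (Var W = n_d·n_c/(S−1) · population-variance of the within-row
  ranks), which reduces to the classical t³−t tie formula; an all-tied
  row scores 0.
- All-constant platforms make every permuted statistic identical; the
  null scale is then degenerate and the fit raises rather than divide
  by zero.
- Σ̂ must be invertible for t_Q; a condition number above 1e12 raises
  with a suggestion to drop a redundant platform.
- Platforms sharing only part of their subject sets cannot be permuted
  both simultaneously and with exact group-size preservation; such
  partial overlap is rejected. Contradictory group labels for a linked
  subject are rejected.
- Biomarker panels must match across platforms exactly; intersection is
  deliberately an error, not a silent inner join, so that panel
  alignment is an explicit upstream step.

## Design decisions

- **Orientation.** Raw statistics are disease-minus-control on every
  platform, so "right" uniformly means up-regulation in disease. The
  convention is fixed here once and documented rather than configurable
  per platform; flipping a platform is equivalent to choosing the other
  side.
- **Single null, shared permutations.** The simulation harness derives
  each individual-platform analysis from the same pooled null as the
  integrated analysis (one statistic column and its own σ̂ and
  percentile), which is statistically identical to running the Q = 1
  pipeline and avoids recomputing permutations.
- **Model/Results surface.** The library exposes a statsmodels-style
  pair — `MultiPlatformIntegration` holding data and specification,
  `fit()` returning `IntegrationResults` with estimates, diagnostics
  and `summary()` — with the lower-level operations (statistics,
  permutation, aggregation, thresholding, error control) as plain
  functions underneath and a thin `click` CLI on top.
- **Replicate counts.** Benchmark comparisons use 100 replicates (SE of
  a PSR mean ≈ 0.003); invariant-style comparative checks in the test
  suite use 25 replicates, which keeps the whole suite under a minute
  while leaving comparative margins many standard errors wide.

## Known limitations

- Exchangeability across biomarkers is assumed by the pooling step;
  strongly structured cross-biomarker correlation can distort the
  pooled percentile.
- Permutation requires the group labels to be exchangeable under the
  null within each platform; confounded or stratified designs are not
  supported (no stratified permutation).
- The f-mode level controls the *expected* false-positive count, not a
  tail probability; FD̂R is an estimate, accurate insofar as π̂ is.
- Count platforms with very small λ can produce all-tied permuted
  statistics for some biomarkers (capped/zero statistics are handled
  but reduce resolution).
- F-statistics for multi-factor designs, moderated/shrinkage t
  statistics, Benjamini–Hochberg-style procedures, and rank-aggregation
  comparators are out of scope.
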