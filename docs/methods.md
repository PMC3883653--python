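# Methods

## Mortality models

Ages at death are measured in months from treatment start (animals enter the
study at 4 months of age), so the time origin is x = 0 at enrolment and no
left-truncation term is needed.  Four nested hazard models are supported:

| family            | hazard u(x)                                | parameters |
|-------------------|--------------------------------------------|------------|
| gompertz          | a·e^{bx}                                   | a, b       |
| gompertz_makeham  | c + a·e^{bx}                               | a, b, c    |
| logistic          | a·e^{bx} / (1 + (as/b)(e^{bx} − 1))        | a, b, s    |
| logistic_makeham  | c + logistic                               | a, b, c, s |

*a* (1/month) is the initial mortality rate at the time origin, *b* (1/month)
the exponential rate of increase of the hazard — the demographic rate of
aging — *c* (1/month) an age-independent extrinsic hazard, and *s*
(dimensionless) a late-life deceleration that makes the hazard plateau at
b/s.  The logistic parameterization is the one used by the classic
mortality-model-selection software lineage; as s → 0 it reduces continuously
to the Gompertz model.  Cumulative hazards are closed form for every family,
so survivorship S(x) = exp(−H(x)) needs no quadrature; quadrature appears
only as an independent oracle in tests.

The censored log-likelihood is Σ_deaths [ln u(x) − H(x)] − Σ_censored H(x).
The study design this package emulates is essentially uncensored (deaths from
natural causes; an event flag is supported and defaults to 1 for every
record).

**Fitting.**  The two-parameter Gompertz model is fitted by exact profile
likelihood: given b, the MLE of a is closed form (â = n_d·b / Σᵢ(e^{bxᵢ}−1)),
leaving a 1-D bounded search on log b (Brent, |log b| ∈ [log 1e−6, log 10]).
This is exact, fast, and has no multi-start fragility.  The 3- and
4-parameter families use Nelder–Mead in log-parameter space (positivity by
construction) with deterministic multi-starts; the first start places the
extra parameters at 1e−8 on top of the Gompertz MLE, which pins the
extension's likelihood at or above the base model's and keeps every LRT
statistic non-negative.  Remaining starts jitter the log-parameters with a
seeded Gaussian (SD 0.7).  The convergence flag is honest: a search that ends
below its own starting likelihood is reported non-converged.

**Model selection** walks up the nesting lattice (gompertz ⊂ {makeham,
logistic} ⊂ logistic_makeham) from the bottom: an extension replaces the
current model only when 2·ΔlogL exceeds the χ² critical value at α (df =
parameter difference), so the least-parameterized unrejected model is
retained.

**Group comparisons** (two-parameter Gompertz): the free model fits separate
(a, b) per group; the constrained model shares the tested parameter — shared
b profiles each group's a in closed form (1-D search), shared a profiles the
common a in closed form (2-D Nelder–Mead over the two b's), shared both is a
pooled fit.  The statistic 2·(logL_free − logL_constrained) is referred to
χ² with 1 df (a or b) or 2 df (both).  Sex pooling is done by concatenating
cohorts before calling, mirroring the usual combine-the-sexes-for-power
analysis.  The null rejection rate of the b test is calibrated to 3–7% at
nominal 5% in the acceptance suite (2,000 replicates, 200 animals/arm).

## Survival summaries

Kaplan–Meier estimation and Cox proportional hazards (Breslow ties) are
delegated to lifelines.  Conventions:

- **Quantile ages** at survival level q: the smallest observed event time
  where the KM curve has fallen to q or below — deterministic under ties.
  Quantiles the curve never reaches (heavy censoring) are NaN and flagged.
- **Mean** survival: area under the KM step function up to the largest event
  time (restricted mean).
- **Maximum survival** is reported under both circulating conventions — the
  single longest-lived animal and the mean of the top decile (k = max(1,
  ⌊n/10⌋) longest lives) — because aging studies use either.
- **Quantile comparisons** use the Wang–Allison construction: a 2×2 Fisher
  exact test of animals above vs at/below the pooled KM quantile threshold.
  This is a documented stand-in: published lifespan tables often do not state
  the quantile test used.
- **Cox** monotone likelihoods (complete separation of the death order) raise
  a dedicated error instead of returning an arbitrarily large coefficient.

**Weibull AFT.**  Both groups share the Weibull shape k; the binary covariate
multiplies event times by the time ratio TR = scale₂/scale₁, so percent
lifespan extension is (TR − 1)·100.  The fit is by profile likelihood: for
fixed shape the per-group scale MLE is closed form, λ̂ᵍ = (Σᵢ tᵢᵏ / d_g)^{1/k}
(events d_g; the sum includes censored times), collapsing the problem to a
1-D search over log k.  A consequence worth having: if one group's times are
exactly a constant multiple of the other's, the estimated TR equals that
constant for *every* k, hence to machine precision — a generic quasi-Newton
fit only achieves optimizer tolerance.  The p-value is a 1-df LRT of a shared
scale; the Wald SE of log TR comes from the finite-difference observed
information, and the resulting 95% interval shows ~93–95% coverage in
simulation.  lifelines' generic Weibull AFT fit serves as an independent
cross-check in the tests, never as the implementation.

## Transcriptome workflow

- **Normalization**: per-column log2, then quantile normalization — each
  column's values are replaced by the row means of the column-sorted matrix
  at the value's within-column rank; ties receive the mean of their tied rank
  positions.  All columns then share an identical multiset of values and the
  operation is idempotent.
- **Differential testing**: per-probe two-sample Student's t with pooled
  variance (Welch available by flag — the pooled form matches the default of
  the numerical environments these analyses were historically run in), B-H
  step-up adjustment (statsmodels), fold change as the difference of group
  means on the log2 scale, and percent change = 100·(2^{log2FC} − 1).
  Constant probes get p = 1 and a flag.
- **DE filter**: strict inequalities on both criteria; the default is
  adjusted p < 0.05 and |percent change| > 15 on the linear scale.  The
  sex-gene filter used for dimorphic transcripts (adjusted p < 0.01 and
  |log2FC| > 1) is the same object in log2-threshold mode.
- **Overlap**: direction-consistent intersections (up∩up, down∩down) with
  percentages against the first list's denominators, matching how shared
  responses between responder males and treated females are quoted.
- **Relative matrices** subtract the reference group's per-probe mean,
  producing the log2-relative heatmaps used to compare treatment durations.

A caveat established by the calibration tests: when a very large fraction of
probes genuinely changes, quantile normalization itself slightly perturbs
null probes, inflating the realized FDR above the B-H target.  At the
generator's study-like proportions (~18% of probes responsive) the effect is
small; the FDR-calibration test therefore evaluates the testing machinery on
the log2 signal directly.

## Ordination and subgroups

Classical (Torgerson) MDS is implemented directly: B = −½·J·D²·J,
eigendecomposition, coordinates = top-k eigenvectors scaled by √eigenvalue.
Signs are fixed by making each axis's largest-magnitude loading positive, so
results are byte-reproducible.  (The common SMACOF-style MDS in scikit-learn
is a different, stochastic estimator and is not used.)  k is reduced with a
warning if positive eigenvalues run out.

Responder assignment formalizes a call usually made by eye: each treated male
is labelled by the nearer of the control-male and treated-female centroids in
the retained MDS space — Rapa-1 (control-like) vs Rapa-2 (responder).  Exact
ties go conservatively to Rapa-1 and are flagged.  The rule is invariant to
rigid transformations of the embedding and achieves ≥ 99% accuracy at 5σ
centroid separation.

Heatmap row orders come from scipy's agglomerative clustering (average
linkage, Euclidean metric by default — the linkage is configurable since
published figure legends rarely name it) with scipy's deterministic leaf
ordering.

## Enrichment

One-sided (over-representation) Fisher exact test per gene set: p = P(X ≥ k)
for the hypergeometric overlap of the DE list with the set in the background
universe.  The background is the detected probes of the contrast, not the
whole catalog.  B-H runs across all tested sets; significance is adjusted
p < 0.05; output is ranked by adjusted p.  Direction composition reports the
percent of each set's members up / down / unchanged under the DE filter.

## Synthetic data

The generator's defaults are the emulated study's conditions:

- **Cohort**: 40 control males, 45 animals in each of treated males, control
  females, treated females.  Hazards are Gompertz with control a = 0.003/mo,
  b = 0.15/mo (males; females a = 0.0025, b = 0.155), putting median age at
  death near 28 months of age; treatment lowers b to 0.13 (males) and 0.128
  (females), ~11%/15% median-lifespan extension — the headline effect
  size and its direction (a rate-of-aging effect, not an initial-mortality
  effect) of the study design emulated.  The published per-group parameter
  estimates themselves are not available, so these values were chosen once
  for realism and are not tuned.  Gompertz sampling is closed-form
  inverse-CDF, x = (1/b)·ln(1 − (b/a)·ln U); Makeham/logistic variants use
  bisection on S(x) − U with bracket doubling (exactness over speed).
  Censoring, when requested, removes a fixed fraction per group at
  Uniform(0, t_death) times.
- **Expression**: log2 signal = baseline (Uniform(6, 12)) + effects +
  Gaussian noise (SD 0.25); intensities are 2^signal, hence positive.
  12–13 samples per group.  Sex-specific probes (1.5% of the array, ±1.5
  log2) separate the sexes; treatment-responsive probes (18.5%, ±1.0 log2)
  shift in treated females; each treated male is independently a responder
  with probability 6/13 — the simplest mechanism consistent with an observed
  6-vs-7 split — and responders echo 80% of the female-response genes.
  Non-responder males have the control-male expectation.  The generator does
  not mimic bead-level noise, probe sequences or spatial artifacts, so
  passing tests demonstrate correctness of the statistical machinery on
  idealized arrays, not robustness to platform artifacts.
- **Gene sets**: planted sets draw members with selection weight equal to the
  target odds ratio on DE genes (weighted sampling without replacement);
  decoys are uniform.  Odds ratio 1 plants nothing.

## Pipeline determinism

One global seed is expanded per stage via numpy's
`SeedSequence(seed, spawn_key=(stage_index,))` with fixed stage indices, so
appending a stage never perturbs earlier stages' streams.  The run report
echoes the config and lists every output with its SHA-256; identical
config + seed reproduces every byte.  All thresholds (0.05, 15%, 0.01,
|log2| > 1, B-H 0.05) are config fields with the conventional values as
defaults.

## Problem sizes

The test suite and acceptance script use reduced but structure-preserving
sizes chosen as sensible defaults for a desk-scale reanalysis: arrays of
~1–2k probes at the study's effect proportions, cohorts of 175 animals for
study-design runs, and simulation sizes of 100 × 5,000 (parameter recovery),
2,000 × 200/arm (LRT calibration), 200 × 2,000 (model selection) and 500 ×
100/arm (AFT coverage).

## Known limitations

- No frailty/heterogeneity mortality models, interval censoring, stratified
  Cox, time-varying covariates or competing risks.
- No moderated-variance (empirical-Bayes) testing, background correction or
  probe-to-gene collapsing beyond a user-supplied mapping.
- Nonmetric MDS is out of scope; exact replication of published ordination
  geometry is not claimed, nor are pathway counts that depend on a
  proprietary knowledge base.
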