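# Methods

## Cox proportional-hazards engine

The statistical core is a from-scratch maximizer of the Cox partial
likelihood. For event times `t_(1) < t_(2) < …` with risk sets `R_i`, the
log partial likelihood is maximized by Newton–Raphson starting from β = 0,
with step-halving whenever a full step would decrease the likelihood.
Convergence is declared when the largest component of the Newton step falls
below 1e-8, with a cap of 50 iterations. Standard errors come from the
inverse observed information at the maximum; 95% confidence intervals are
Wald-type on the log-hazard scale, `exp(β̂ ± 1.96·se)`.

Tied event times use the Efron approximation by default (Breslow is
selectable); the two coincide exactly when no ties exist. A subject
censored at an event time remains in that event's risk set (the standard
convention). When no two events share a time, the risk-set sums reduce to
reverse cumulative sums over the time-sorted data; this vectorized path is
taken automatically (≈ 0.5 ms per fit at n = 200, p = 4, which is what
makes 10⁴–10⁵-fit permutation and calibration experiments practical), and
tied data fall back to an explicit per-event-time loop. Both paths
reproduce lifelines' `CoxPHFitter` estimates to ≈ 1e-6, which the test
suite checks.

Degenerate fits are flagged rather than raised: a coefficient escaping
beyond |β| = 50 (complete separation), hitting the iteration cap, a
singular information matrix, or a converged step criterion with an absurd
standard error (> 100 on the log-hazard scale, the signature of a flat
quasi-separated plateau) all yield `converged=False` with a named flag.
Constant or exactly duplicated design columns are hard errors, since no
reparameterization can rescue them.

The global Wald test over a term subset S is the quadratic form
`β_S' [Cov_SS]⁻¹ β_S` against χ²(|S|), using the corresponding block of the
inverse information — the form that reduces exactly to the squared
per-term z for |S| = 1. The score test at β = 0 equals the log-rank
statistic for a single binary covariate without ties, which serves as an
independent correctness anchor.

VIF diagnostics regress each column on the others (with intercept) via
least squares: `VIF_j = 1/(1−R²_j)`, reported with a pass/fail flag at the
threshold of 5; exact collinearity reports +inf and fails.

## Screening and panel selection

Each present candidate is fitted crude (gene alone) and adjusted
(gene + grade + age); absent candidates go to a side report. Both p-values
are kept so the two-stage funnel (crude α, then adjusted α) is auditable
from one pass. Selection thresholds the adjusted p at α = 0.05 with **no**
multiple-testing correction — the discovery convention this pipeline
mirrors, which deliberately trades false positives for sensitivity and
defers robustness to external validation and the random-model null. An
optional BH switch (off by default) is exposed. Consequence worth stating
plainly: with 48 null candidates an uncorrected screen admits ≈ 2.4 false
positives per run, so the *selected set* is expected to be a superset of
the true signal genes; what is stable is that true signals rank first. Panel
gene order is ascending adjusted p. Selected genes are vetted jointly by
VIF; any VIF ≥ 5 rejects the panel with a named error.

## Stratified evaluation

Strata: Gleason low = {3+3, 3+4} versus everything else; age ≤ cutoff
versus > cutoff with presets 60 (prostate) and 56 (AML), semantics exactly
"≤" / ">"; cytogenetic risk favorable versus unfavorable (intermediate and
poor collapsed into unfavorable). Grade is encoded for adjustment as the
numeric Gleason sum (major + minor) treated as continuous, or the binary
risk indicator. Within-stratum panel fits are **unadjusted** by default —
the stratified models take only the panel genes as inputs — with a flag to
re-enable adjustment for sensitivity analysis. Strata with zero samples or
zero events are marked not-analyzable and skipped without aborting the
other strata; an axis that collapses to a single populated stratum (e.g. an
all-young cohort) is analyzed as that single stratum.

## Integration

A subgroup's per-cohort p-values are combined with the plain harmonic mean
`n / Σ(1/p_i)`; the BH step-up adjustment is then applied across the
subgroup family, m = number of subgroups (4 for one cancer analysis — the
only family size consistent with the published adjusted values). The
harmonic mean is implemented in its standard constant-n form; a literal
"as-printed" variant with constant 2 in the three-value case is selectable
for audit, but it is not a mean (it violates idempotence and the min/max
bounds) and is never used by the pipeline. No cohort weighting is applied.
BH is the hand-written step-up definition (sort, `p(i)·m/i`, enforce
monotonicity from the largest rank down, cap at 1), cross-checked in tests
against statsmodels and against a brute-force implementation. The
asymptotically calibrated harmonic-mean-p procedure with Landau-distribution
thresholds is intentionally out of scope; the plain harmonic mean + BH is
what this analysis design uses.

## Random-gene-set null

Each repetition samples k distinct genes uniformly from *all* genes in the
expression matrix (panel genes not excluded), without replacement within a
repetition and independently across repetitions, fits the crude additive
k-gene model, and records its global Wald p. Crude fits are the default to
match how the random-model comparison is described; an adjusted mode exists
and then expects an adjusted observed p for a like-with-like comparison.
The nominal p is `#{random p ≤ observed p} / R` — exactly the
"reached-or-outperformed" count over the requested R, so it can be 0; an
add-one `(count+1)/(R+1)` estimator is available behind a flag.
Non-converged repetitions are excluded from the sample and counted.

## Synthetic cohorts

The simulator draws the data structure the analysis assumes, with the study
regimes as presets:

- **Expression**: block-equicorrelated Gaussian (blocks of 4, correlation ρ;
  marginal N(0,1)), a gene universe of 1000 containing the 52-gene
  candidate list.
- **Covariates**: grade categorical over Gleason pairs with the published
  training-cohort frequencies (or favorable/unfavorable 53:74 for the AML
  regime); age Gaussian (mean 59, SD 8 for prostate; mean 54, SD 16,
  clipped at 1, for AML — chosen to match the published medians of 60
  and 56 and the reported age ranges).
- **Hazard**: `T ~ Exponential(λ0 · exp(η))` with
  `η = Σ β_g x_g + γ_grade (grade − E[grade]) + γ_age (age − mean)/SD`;
  grade is centered at its theoretical mean so λ0 keeps its baseline
  interpretation. A Weibull shape option generalizes the baseline; the
  default shape 1 is the exponential, the simplest PH-compatible choice
  since no survival-time distribution is published. Default γ_grade > 0
  makes covariate adjustment non-vacuous, mirroring grade's known
  prognostic role.
- **Censoring**: independent, same family; its rate is tuned by a 1-D root
  find so the expected censored fraction `mean_i λc/(λc+λ_i)` hits the
  target — 0.75 for the prostate regime (≈ 25% events at n = 138) and
  0.638 for the AML regime (≈ 36% events at n = 127). Event/censoring ties
  are impossible under the continuous generator; a round-to-whole-months
  flag exists specifically to exercise tie handling.
- **Planted effects**: the presets plant log-hazard effects at the
  published per-gene hazard ratios (e.g. 0.49, 0.55, 0.66, 1.30 for the
  prostate regime) on the named candidate genes; the `null` preset has no
  gene effects and drops the expression correlation (ρ = 0) so per-gene
  calibration checks are effectively independent.

Everything is driven by one `numpy` Generator seeded from the config, so a
config reproduces its cohort bit-identically.

What the simulator does **not** emulate: realistic gene–gene covariance
beyond equicorrelated blocks, batch or platform effects, non-proportional
hazards, informative censoring, measurement error in clinical covariates,
or missingness patterns. Passing calibration and recovery tests therefore
demonstrate correctness of the estimation and selection machinery under the
model's own assumptions, not robustness to their violation in real cohorts.

## Problem sizes in the test suite

Stochastic checks run at sizes chosen to keep Monte-Carlo error well inside
the asserted bands: screening calibration pools 20 null cohorts (1040
adjusted fits); the random-null uniformity check uses 200 repeats of
R = 200; panel recovery uses 100 replicates at n = 300 and the
beats-the-null check 50 replicates at R = 1000; single-gene recovery/CI
coverage uses 500 replicates at n = 500. The whole suite runs in ≈ 2.5
minutes on one CPU.

## Other design choices and limitations

- Missing clinical fields are removed listwise before modelling, with
  counts logged; no imputation. Records with non-positive follow-up time
  are rejected outright rather than silently shifted.
- Cohort assembly inner-joins expression and clinical tables on sample id
  and orders samples lexicographically, making every downstream computation
  order-deterministic.
- z-scoring standardizes each gene row with the sample SD (ddof = 1);
  zero-variance rows are left unscaled and logged.
- Per-patient risk scores are the panel linear predictor, reported without
  any cut-point: no thresholding or risk-group dichotomization claims are
  made.
- The pipeline report is a single JSON document; the human-readable summary
  is rendered from report fields only (no recomputation), and a fixed
  config + seed reproduces the report byte-identically.
- No time-varying covariates, stratified-baseline Cox, penalized
  estimation, or proportional-hazards diagnostics; stratification here
  always means subgroup refitting.
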