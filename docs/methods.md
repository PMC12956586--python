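# Methods

This note documents the statistical models implemented in `mamsnet`, the
choices made where the design was genuinely open, and what the tests do and
do not demonstrate.

## Outcome model and effect sizes

The design treats the (transformed) primary behavioral endpoint as
independent normal with **known** variance: control mean μ₀ = 0.55 and s.d.
σ = 1.048 by default. The 1.048 value is a conservative inflation of a
literature-based estimate (0.262) intended to absorb between-laboratory
variability; the generator therefore keeps all of that variability inside σ
by default rather than in an explicit site effect. Because the transformation
applied to the raw behavioral index is a study-specific preprocessing step,
all modules operate directly on the transformed scale; the transformation
itself is deliberately abstract here.

Effects are decreases from the control mean. The interesting effect is
δ = μ₀ · 50% = 0.275 (standardized 0.2624) and the uninteresting effect
δ₀ = μ₀ · 6% = 0.033 (standardized 0.0315). Both percentages are tunable
(`eff_pct`, `fut_pct` on `DesignSpec`).

## Statistics and boundaries

At stage j the statistic for arm k is the many-to-one z statistic
Z_kj = (X̄₀ⱼ − X̄ₖⱼ) / (σ√(1/n₀ⱼ + 1/nₖⱼ)), positive when the arm improves on
control. With equal allocation, statistics for two arms sharing the control
are correlated 0.5 — the generalized Dunnett structure, verified empirically
in the tests. Variance is never estimated: the known-variance assumption is
part of the design model, so the engine uses z rather than t statistics.

Stopping boundaries are triangular on the score–information plane: efficacy
e(I) = a + cI, futility f(I) = −a + 3cI, meeting at I = a/c with common score
2a. On the z scale, u_j = e(I_j)/√I_j and l_j = f(I_j)/√I_j. Decision rules
per stage: Z below l_j drops the arm for futility and stops its enrollment;
Z above u_j declares it effective and stops its enrollment (the rest of the
trial continues); otherwise the arm continues. The control keeps recruiting
while any arm is active. Ties exactly on a boundary resolve to "continue" — a
measure-zero event fixed purely for determinism. Final analyses pool data
cumulatively across stages (the cumulative statistic at I_J), the standard
reading of a MAMS final look.

## Calibration

Discrete-look triangular designs have no exact closed-form constants, so
calibration is operational. The triangle's apex is pinned at the final
information level (a = c·I_J), which closes the continuation region at the
last look and leaves a single free scale parameter θ = c·√I_J. On the z
scale the bounds become

    u_j = θ(1 + f_j)/√f_j,   l_j = θ(3f_j − 1)/√f_j,

functions of θ and the information fractions f_j alone — so under the global
null the FWER depends only on θ. The search is therefore two-level and fully
deterministic given a seed:

- **inner:** for a candidate per-arm final group size n (per-stage sizes
  ⌈f_j·n⌉), bisect θ until the simulated FWER under the global null equals α,
  reusing one fixed matrix of standard-normal increments (the null statistics
  do not depend on θ, so the same draws serve every bisection step);
- **outer:** bracket and integer-bisect the smallest n whose recalibrated
  design attains the power target under the least favorable configuration,
  using a second fixed draw (common random numbers make power monotone in n
  up to recalibration noise).

Futility stops are binding during FWER calibration, because the protocol
mandates dropping futile arms. Defaults: 100,000 replicates, absolute
tolerance 0.005 on FWER and power (the bisection resolves θ to 1e−7, so the
attained FWER sits within one Monte Carlo jump of α). Simulation operates on
sufficient statistics (stage-wise group means), never on subject-level loops,
so a full calibration takes seconds on one CPU.

The two control routes (IP and IV) are pooled into a single control group of
one arm's size, reflecting the design assumption that the two vehicle
controls do not differ on the primary endpoint. A single-arm trial (e.g. a
mechanical intervention needing its own control) uses the same machinery with
K = 1. With K = 1, J = 1 and futility disabled, the calibrated bound reduces
to the one-sided fixed-sample normal quantile (1.6449 at α = 0.05), which the
tests verify — a useful end-to-end check that the simulation calibration is
unbiased.

Attrition inflation is ⌈n/(1−rate)⌉ with a 1e−9 guard against float rounding
on exact quotients. FWER accounting counts a false claim whenever any
null-true arm crosses u_j at any stage, even after another arm has already
graduated.

## Synthetic cohorts

`generate_cohort` emulates the study conditions the design assumes: subjects
in every laboratory × sex × model cell (6 × 2 × 5 by default), outcomes
N(μ₀ − decreaseₖ + lab shift, σ²), deaths Bernoulli(0.10) with death day
uniform on 1..30 and no day-30 outcome, and a six-dose intraperitoneal
schedule (surgery day plus twice daily through day 3) for the disposition
milestones. Attrition is missing completely at random — the design's power
adjustment implies no informative-missingness model, and none is implemented.
The per-laboratory shift defaults to 0 because no between-site variance
estimate is available to anchor it; it exists as a heterogeneity knob for
sensitivity analyses. What passing tests show is therefore that the pipeline
is correct *under its own assumptions* (normality, known variance, MCAR
attrition); they cannot show robustness to real-data features such as
informative dropout, floor/ceiling effects of behavioral scores, or
site-by-treatment interactions.

## Randomization and populations

Tables are permuted blocks within each laboratory × sex × model cell: block
size must be a multiple of the arm count, every completed block is exactly
balanced, and assignment consumes the lowest-index unconsumed row of the
subject's stratum (the "next available row" contract a coordinating center
operates). The default block size is the least multiple of the arm count at
or above the weekly enrollment of 8; blocks are per-sex because sex is a
stratification variable (the block-size narrative in the source protocol is
not a formula, so this is a configuration default, not a derivation).
Concealment workflows (emails, vial logistics) are out of machine scope.

CONSORT flags are nested by construction: ITT = randomized; mITT = ITT ∧
surgery completed ∧ first dose given; PP = mITT ∧ all prescribed doses ∧
survived ≥ 5 days after surgery. Milestone inconsistencies (dosing without
surgery, surgery without randomization) raise rather than silently classify.

## Process control and concordance

The EWMA chart uses the standard recursion M_i = λx_i + (1−λ)M_{i−1} started
at the certification target M₀, with time-varying limits
M₀ ± L·σ₀·√((1−(1−λ)^{2i})·λ/(2−λ)) and defaults λ = 0.15, L = 3. At i = 1
the half-width is exactly L·λ·σ₀ and it grows monotonically to the asymptote
L·σ₀·√(λ/(2−λ)) (in float64 it saturates exactly at the asymptote near
i ≈ 110). The chart is per-observation; reporting cadence (e.g. fortnightly)
is a workflow concern, not a computational one. Whether M₀ and σ₀ are
recomputed per stage or per laboratory is left to the caller: both are plain
arguments.

Rater concordance is ICC(A,1) — two-way random effects, absolute agreement,
single rater — computed from the two-way ANOVA mean squares with
F-distribution confidence bounds using a Satterthwaite denominator df
(McGraw & Wong). Perfect-agreement grids return ICC = 1 with a degenerate
interval. A covariate adjustment (`adjust_for=`) residualizes scores on
factor means (e.g. time point, intervention) before the ICC; this changes the
estimand to "agreement net of those factors" and is off by default.

## Numerical and testing choices

- All Monte Carlo work uses `numpy.random.default_rng` seeded explicitly;
  identical seeds give bit-identical designs, cohorts and reports.
- Unit tests calibrate a small 2-arm, 2-stage design at 20,000 replicates;
  the full-resolution checks (100,000 replicates, the default five-arm
  design) live in the end-to-end suite and in `scripts/acceptance.py`. These
  sizes keep the whole suite under a minute while leaving Monte Carlo
  standard errors (~0.07 percentage points on the FWER at 100k) an order of
  magnitude below the tolerances being asserted.
- The degenerate cases are pinned by tests: σ = 0 cohorts, λ = 1 charts,
  zero-variance rating grids, empty observation series, exhausted
  randomization strata and outcome streams.

## Known limitations

- No unknown-variance (t-statistic) variant and no exact multivariate-normal
  integration backend; calibration is simulation-only by design.
- No sequentially-adjusted p-values or confidence intervals are reported for
  trial results, and no optimal-boundary search (e.g. minimizing expected N).
- The cohort generator produces only the day-30 primary endpoint and
  disposition milestones — no longitudinal trajectories, imaging or video
  simulation.
- Real rater data are not bundled, so the concordance module is validated
  against simulated variance components and a reference implementation, not
  against the motivating study's ratings.
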