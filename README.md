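# mamsnet

Statistical and operational machinery for running a **multi-laboratory,
randomized, blinded preclinical assessment network**: several candidate
interventions are tested against one shared control across sequential stages,
with interventions dropped at interim analyses for futility or graduated for
efficacy. The package is aimed at biostatisticians and coordinating centers
planning such networks — its proof-of-concept configuration is a rodent
stroke network testing five drug arms plus a pooled control over four stages,
but every parameter is a plain config value.

## What it computes

**Design.** A multi-arm multi-stage (MAMS) design with *K* intervention arms,
one shared control and *J* analyses at recruitment fractions
*f₁ < … < f_J = 1*. The primary endpoint is assumed normal with known
variance: control mean μ₀, s.d. σ. Effects are expressed as decreases from
the control mean — interesting effect δ = μ₀·eff% (declare effective) and
uninteresting effect δ₀ = μ₀·fut% (declare futile). At each stage the
generalized Dunnett statistic

    Z_kj = (X̄₀ⱼ − X̄ₖⱼ) / (σ √(1/n₀ⱼ + 1/nₖⱼ))

is compared against **triangular boundaries**: on the (score, information)
plane the efficacy line is *a + cI* and the futility line *−a + 3cI*; they
meet at *I = a/c*, closing the continuation region at the final look. Because
discrete-look triangular designs have no closed-form constants, the boundary
scale and per-arm group sizes are calibrated by Monte Carlo search so that

- the familywise error rate (any false efficacy claim under the global null)
  equals α, and
- power under the least favorable configuration (one arm at δ, the other
  K−1 at δ₀) reaches the target,

with futility stops binding, common random numbers, and bit-identical results
for identical seeds. Planned totals are inflated for attrition by
⌈n/(1−rate)⌉.

**Execution & operating characteristics.** Stage decision rules, whole-trial
execution on subject-level outcome streams with arm dropping, and Monte Carlo
operating characteristics (FWER, per-arm rejection probabilities, expected
sample size, stopping-stage distributions).

**Cohorts.** A synthetic subject-level generator (stratified by laboratory,
sex and animal model) with normal outcomes, optional per-laboratory mean
shifts, and missing-completely-at-random attrition — so the whole pipeline is
testable without any animal data.

**Randomization & CONSORT.** Stratified permuted-block randomization tables
with next-available-row assignment, balance and medication-error audits, and
nested ITT / modified-ITT / per-protocol population classification.

**Quality monitoring.** EWMA control charts
(M_i = λx_i + (1−λ)M_{i−1}, limits M₀ ± L·σ₀√((1−(1−λ)^{2i})λ/(2−λ)),
defaults λ = 0.15, L = 3) and two-way random-effects absolute-agreement
single-rater ICC with F-based confidence intervals for blinded-rater
concordance.

## Worked example

```python
from mamsnet import DesignSpec, calibrate_design, operating_characteristics

spec = DesignSpec()          # 5 arms + control, 4 stages, mu0=0.55, sigma=1.048
design = calibrate_design(spec, mc_reps=100_000, seed=1)
print(design.n_per_stage, design.total_planned_n, design.total_inflated_n)
print(round(design.attained_fwer, 4), round(design.attained_power, 4))

null = {f"arm_{k}": 0.0 for k in range(1, 6)}
report = operating_characteristics(design, null, reps=100_000, seed=2)
print(round(report.fwer, 4), round(report.expected_n, 1))
```

prints

```
[107 213 320 426] 2556 2840
0.05 0.9001
0.0491 1301.0
```

meaning: cumulative per-arm group sizes of 107/213/320/426 across the four
looks, a maximum of 2556 subjects (2840 after 10% attrition inflation), a
calibrated familywise error rate of 5.0% with 90.0% power on the calibration
draws, an independently re-simulated FWER of 4.91%, and an expected total of
about 1301 subjects under the global null (early futility stops save roughly
half the maximum).

The same objects drive the CLI, e.g.

```bash
mamsnet design calibrate --config design.yml --reps 100000 --seed 1 --out out/
mamsnet chart ewma --observations lesions.csv --center 48 --sigma0 12 --out chart.csv
mamsnet concordance icc --ratings ratings.csv
```

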