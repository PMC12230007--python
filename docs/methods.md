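# Methods

## The composite intrinsic-capacity score

Intrinsic capacity (IC) is the WHO construct for the composite of an
individual's physical and mental capacities. This package operationalises
it as five domains, each worth up to 2 points, summed without weighting to
a 0–10 composite:

```
IC = locomotion (2) + vitality (2) + cognition (2) + psychological (2) + sensory (2)
```

| Domain        | Items (points each)                                           |
|---------------|---------------------------------------------------------------|
| Vitality      | handgrip, BMI band, 3-month weight loss, appetite (0.5 each)  |
| Locomotion    | TUG, chair stand, sit-and-reach, one-leg stance (0.5 each)    |
| Sensory       | vision, hearing self-report (1 each)                          |
| Psychological | GDS-15 banded 0–5 → 2, 6–10 → 1, 11–15 → 0                    |
| Cognitive     | MoCA vs education-adjusted cutoff, all-or-nothing (0 or 2)    |

Pass rules and defaults: handgrip ≥ 27 kgf (men) / ≥ 16 kgf (women); BMI in
[22, 27] kg/m² inclusive; weight loss < 3 kg in 3 months; no appetite loss;
TUG < 10 s; chair-stand repetitions at or above the age/sex norm;
sit-and-reach inside the age/sex range (inclusive); one-leg stance > 20 s;
a sensory item scores only with neither reported difficulty nor a
corrective device. The composite classifies as low (< 5), moderate
(5 to < 9) or high (≥ 9) capacity.

### Boundary conventions

The rules are printed on discrete grids (whole seconds, integer scores);
applying them to continuous measurements requires conventions, which are
applied uniformly and tested as a partition:

- TUG exactly 10 s fails (tie-to-fail, consistent with the "over 10 s"
  zero rule).
- One-leg stance passes strictly above 20 s, so 20.4 s passes even though
  the printed pass rule starts at 21 whole seconds.
- Handgrip and MoCA at their cutoffs pass (single-threshold step
  functions).
- A device without reported difficulty (or vice versa) scores 0 on that
  sensory item: any impairment indicator ends the item.
- Half-point composites in the printed bands' gaps resolve downward:
  4.5 is low, 8.5 is moderate.

Sub-scores are exact binary fractions (multiples of 0.5) and are
accumulated as integer half-points, so grid-equality tests are exact.

### Cutoff configuration

Scalar cutoffs ship as defaults and are overridable from YAML/JSON. The
chair-stand and sit-and-reach norms (age band × sex) and the MoCA
education cutoffs are population-specific tables with no defensible
universal default; they are pure configuration. The packaged
`synthetic_example_thresholds.yaml` is a clearly labelled illustrative
stand-in, not a published norm edition. Age bands are closed integer
intervals, required to be non-overlapping, so exactly one band matches
any covered (sex, age).

## Pre/post analysis

Baseline vs follow-up comparison uses generalized estimating equations:
a marginal regression of the outcome on a time indicator, clustered by
participant, with robust (sandwich) variance. All enrolled participants
contribute every row they have (intention-to-treat); dropouts contribute
baseline only. Families are declared per variable in the analysis plan
(no automatic skewness detection): `linear` (Gaussian), `log-linear`
(Gaussian on logs, positive variables), `ordinal-logistic` (cumulative
logit on declared ordered levels), `binary-logistic`. The linear and
binary families use an exchangeable working correlation; the ordinal
family uses an independence working structure because the global-odds-ratio
association model is undefined whenever a level is empty at one
timepoint — routine at n ≈ 40 — and with two timepoints the working
correlation does not affect the point estimate on balanced data, while the
sandwich variance still accounts for clustering.

On complete balanced data the linear time effect reduces to the paired
mean difference exactly; this closed form is the independent oracle in the
tests (agreement to 1e-8 relative over 200 simulated cohorts).

### Standardized effect size

The SES quantifies change in baseline standard-deviation units:

```
SES = mean(post − pre over complete pairs) / sd(pre over those pairs)
```

with `pooled` (average of the two timepoint variances) and `change`
(sd of difference scores) denominators available as alternatives, since
no single convention is universal. Ordinal variables enter via their
integer level codes. The 95% CI is a seeded percentile bootstrap over
participants (default 2000 resamples). Banding follows Cohen-style
thresholds on the magnitude: |SES| < 0.5 small, 0.5–0.8 moderate,
> 0.8 large.

The percentile bootstrap is first-order accurate: at n = 200 pairs the
null CI covers 0 in ~94% of replicates; at n ≈ 40 coverage drops to
~92%, a known small-sample property users should weigh when reading CIs
from small cohorts. Degenerate inputs (zero baseline variance, fewer than
2 complete pairs, a constant outcome, an empty binary cell at a timepoint)
raise named errors rather than producing numbers; in batch analysis the
error is recorded on that variable's row and the batch continues. When the
sandwich variance is exactly zero (post identical to pre for every
participant) the p-value is reported as 1 for a zero estimate.

## Synthetic cohorts

The generator emulates a small community exercise cohort measured twice.
Per variable, a participant's two measurements come from a bivariate
standard-normal latent pair with correlation `rho` (default 0.7 — the true
pre/post correlation of such cohorts is rarely reported; this is a free
parameter, not an estimate). The latent draw maps to the measurement
scale by location–scale for continuous measures, exponentiation for
log-normal ones, and quantile thresholding for binary flags (the threshold
set so baseline prevalence matches the configured value). The configured
true effect is an additive latent shift at follow-up; a null cohort has
every effect 0. Dropout is completely at random: `dropout_n` participants
(default 3 of 43) lack the follow-up row.

Defaults mirror a published community cohort's descriptive profile:
n = 43, 86% women, age 67.7 ± 4.3 y, and baseline moments 37.5 ± 9.5
(body fat %), 26.6 ± 4.5 (muscle mass %), 93.1 ± 10.9 cm (abdominal
circumference), 0.84 ± 0.08 (SF-6D utility), 73.2 ± 12.4 bpm (heart
rate). Raw-battery defaults (TUG 9.5 ± 1.8 s, chair stand 13 ± 3,
handgrip 24/34 kgf for women/men, GDS-15 2.5 ± 2.5, MoCA 24 ± 3, etc.)
were chosen once as realistic for active community-dwelling, predominantly
female older adults, with the TUG mean deliberately near the 10 s cutoff
so intervention effects propagate visibly through the locomotion scorer.

Draws are truncated into each measure's valid range and rounded where the
instrument is integer-valued (GDS-15 to 0–15, MoCA to 0–30, repetitions
to non-negative integers, age to ≥ 60). Truncation slightly distorts
moments for variables near their bounds; calibration and effect-recovery
tests therefore use the unbounded sit-and-reach measure. What the
generator does **not** emulate: the real joint correlation structure
across variables (latents are independent across measures), informative
dropout, practice/learning effects, or measurement error models — so
passing tests demonstrate the pipeline's statistical correctness under
its stated assumptions, not agreement with any real cohort's numbers.

## Problem sizes and numerical choices

Simulation-based checks use: 200 cohorts for the GEE closed-form limit,
500 replicates for type-I calibration (rejection 5% ± 3 points), 100
replicates at n = 500 for SES recovery and CI coverage, 2000 bootstrap
resamples for reported CIs (500 in high-replicate checks). All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; the simulate → score → analyze pipeline is
byte-reproducible under a fixed seed, and every CLI run writes a JSON
manifest (command, seed, paths, version, timestamp) beside its output.

## Known limitations

- Partial records are rejected, never imputed; partial scoring is out of
  scope by design.
- The shipped norm/MoCA tables are stand-ins; substantive use requires
  the norm edition appropriate to the studied population.
- SES conventions differ across the literature; the baseline-sd default
  is one defensible choice, selectable among three.
- GEE sandwich inference is asymptotic in the number of participants;
  at n ≈ 40 its type-I error is only approximately nominal (observed
  4.6% at the 5% level in the calibration check).
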