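# icscore

Composite intrinsic-capacity scoring and pre/post cohort analysis for
geriatric functional assessment.

Intrinsic capacity (IC) — the WHO composite of an individual's physical
and mental capacities — is increasingly used as the primary outcome of
healthy-ageing interventions, but published scoring systems are scattered
across papers and rarely ship as testable code. `icscore` implements a
five-domain IC score for community-dwelling older adults and the
longitudinal analysis that goes with it, for researchers and program
evaluators running two-timepoint (baseline / follow-up) studies.

## The score

Each domain contributes up to 2 points, summed without weighting:

```
IC = locomotion (2) + vitality (2) + cognition (2) + psychological (2) + sensory (2)   ∈ [0, 10]
```

- **Vitality** — handgrip (≥ 27 kgf men / ≥ 16 kgf women), BMI in
  [22, 27] kg/m², 3-month weight loss < 3 kg, no appetite loss; 0.5 each.
- **Locomotion** — Timed Up and Go < 10 s, chair-stand repetitions at or
  above the age/sex norm, sit-and-reach within the age/sex range,
  one-leg stance > 20 s; 0.5 each.
- **Sensory** — vision and hearing self-report, 1 point each; any
  reported difficulty or corrective device zeroes the item.
- **Psychological** — GDS-15: 0–5 → 2, 6–10 → 1, 11–15 → 0.
- **Cognitive** — MoCA at or above the education-adjusted cutoff → 2, else 0.

The composite classifies as **low** (< 5), **moderate** (5 to < 9) or
**high** (≥ 9) capacity. Baseline vs follow-up change is assessed per
variable with GEE marginal models (linear, log-linear, ordinal- or
binary-logistic; robust clustered variance, intention-to-treat) and a
standardized effect size SES = mean(Δ)/sd(baseline) with a bootstrap 95%
CI, banded |SES| < 0.5 / ≤ 0.8 / > 0.8 as small / moderate / large.
A synthetic-cohort generator (correlated pre/post latents, configurable
true effects, random dropout) makes the whole pipeline testable without
participant data. See `docs/methods.md` for the full model description.

## Worked example

Simulate a reference-style cohort (n = 43, 86% women, 3 dropouts) with a
modest configured intervention effect on mobility and cognition, score
it, and compare timepoints:

```bash
cat > effects.yaml <<'YAML'
seed: 7
effects:
  tug: -1.5     # 1.5 s faster Timed Up and Go at follow-up
  balance: 6.0  # 6 s longer one-leg stance
  moca: 1.5     # 1.5-point MoCA shift
YAML
icscore simulate --config effects.yaml --output cohort.csv
icscore score    --input cohort.csv  --output scored.csv
icscore analyze  --input scored.csv  --seed 7 --output-dir report
```

`report/comparisons.txt` (also written as `comparisons.csv`):

```
Variable       Baseline          Follow-up         p-value  Effect size (95% CI)
-------------  ----------------  ----------------  -------  ---------------------
sensory        1.00 (1.00-1.00)  1.00 (1.00-1.00)  0.877    0.00 (-0.30 to 0.26)
psychological  2.00 (2.00-2.00)  2.00 (2.00-2.00)  0.065    -0.25 (-0.68 to 0.00)
cognitive      2.00 (0.00-2.00)  2.00 (2.00-2.00)  0.025    0.35 (0.05 to 0.65)
vitality       1.50 (1.50-2.00)  1.50 (1.50-1.62)  0.412    -0.12 (-0.46 to 0.17)
locomotion     1.50 (1.00-1.50)  1.50 (1.00-1.50)  0.079    0.34 (-0.06 to 0.77)
composite      7.00 (6.00-8.00)  7.50 (6.88-8.00)  0.052    0.31 (0.01 to 0.64)
category       n=43              n=40              1.000    0.00 (-0.47 to 0.45)
  low          1 (2.3)           2 (5.0)
  moderate     41 (95.3)         36 (90.0)
  high         1 (2.3)           2 (5.0)
```

Each row is one variable: median (P25–P75) summaries per timepoint, the
GEE time-effect p-value, and the standardized effect size with its
bootstrap CI. Here the configured cognitive shift surfaces as a small
significant improvement (p = 0.025, SES 0.35), the locomotion shift as a
small-to-moderate SES of 0.34, and the untouched sensory domain sits at
SES 0.00 — while the three-level composite classification, a coarse
ordinal summary, shows no detectable shift at this sample size. Every
run writes a `*.manifest.json` recording command, seed, paths and
package version.

Scoring uses the packaged **synthetic example** norm table
(`--thresholds` to supply your own; the chair-stand / sit-and-reach norms
and MoCA education cutoffs are population-specific configuration, and
the shipped values are illustrative stand-ins — see
`docs/column_dictionary.md` for schemas).

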