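# Cohort CSV column dictionary

Interchange dialect: UTF-8, comma-separated, header row, `.` decimal
separator, empty string = missing. One row per participant × timepoint.

## Core columns (required)

| Column              | Type    | Coding / units                                  |
|---------------------|---------|-------------------------------------------------|
| `participant_id`    | string  | opaque identifier                                |
| `timepoint`         | integer | 0 = baseline, 1 = follow-up                      |
| `age`               | float   | years, ≥ 60                                      |
| `sex`               | string  | `F` / `M`                                        |
| `education`         | string  | free-form band label matching the MoCA config    |
| `hgs`               | float   | handgrip strength, kgf                           |
| `bmi`               | float   | kg/m²                                            |
| `weight_loss_3mo`   | float   | kg lost in the last 3 months, ≥ 0                |
| `appetite_loss`     | 0/1     | reported loss of appetite                        |
| `wears_glasses`     | 0/1     | uses prescription glasses                        |
| `vision_difficulty` | 0/1     | difficulty seeing far or near                    |
| `uses_hearing_aid`  | 0/1     | uses a hearing aid                               |
| `hearing_difficulty`| 0/1     | difficulty hearing whispers                      |
| `tug`               | float   | Timed Up and Go, seconds                         |
| `chair_stand`       | integer | sit-to-stand repetitions                         |
| `sit_reach`         | float   | sit-and-reach, cm (may be negative)              |
| `balance`           | float   | one-leg stance hold, seconds                     |
| `gds15`             | integer | GDS-15 total, 0–15                               |
| `moca`              | integer | MoCA total, 0–30                                 |

Invariants: (`participant_id`, `timepoint`) unique; every participant has
a baseline row; follow-up rows optional (dropout).

## Secondary outcome columns (optional)

Declared through `VariableSpec(name, vtype, levels)` with
`vtype ∈ {continuous, continuous-skewed, ordinal, binary}`; ordinal
variables carry an ordered level list covering every observed value.
In analysis plans (YAML), the same declaration is
`{variable, family, type, levels}`.

## Score columns (appended by `icscore score`)

`sensory`, `psychological`, `cognitive`, `vitality`, `locomotion`
(domain points), `composite` (0–10), `category`
(`low` / `moderate` / `high`).

## Threshold configuration schema

A single YAML/JSON document:

```yaml
fixed:            # scalar cutoffs; omitted keys take the defaults
  hgs_male_min: 27
  hgs_female_min: 16
  bmi_low: 22
  bmi_high: 27
  tug_max: 10
  balance_min: 20
  weight_loss_kg: 3
  gds_band_edges: [5, 10]
  composite_low_max: 4
  composite_moderate_max: 8
norms:            # chair-stand / sit-and-reach norms; no defaults
  - {sex: F, age_min: 60, age_max: 64, chair_stand_min: 12,
     sit_reach_min: -0.5, sit_reach_max: 12.5}
moca:             # education band -> cutoff; no defaults
  low: 22
  high: 26
```
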