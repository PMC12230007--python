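# SYNTHETIC EXAMPLE threshold configuration.
#
# The `fixed` block carries the literature defaults used by the scoring
# rules.  The `norms` rows (chair-stand repetitions and sit-and-reach range
# by age band and sex) and the `moca` education cutoffs are ILLUSTRATIVE
# STAND-INS chosen to be plausible for community-dwelling older adults;
# they are NOT published norm values.  Replace them with the norm edition
# appropriate to your population before any substantive use.
fixed:
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

norms:
  - {sex: F, age_min: 60, age_max: 64, chair_stand_min: 12, sit_reach_min: -0.5, sit_reach_max: 12.5}
  - {sex: F, age_min: 65, age_max: 69, chair_stand_min: 11, sit_reach_min: -1.5, sit_reach_max: 11.5}
  - {sex: F, age_min: 70, age_max: 74, chair_stand_min: 10, sit_reach_min: -2.5, sit_reach_max: 10.5}
  - {sex: F, age_min: 75, age_max: 79, chair_stand_min: 10, sit_reach_min: -3.5, sit_reach_max: 9.5}
  - {sex: F, age_min: 80, age_max: 84, chair_stand_min: 9,  sit_reach_min: -4.5, sit_reach_max: 9.0}
  - {sex: F, age_min: 85, age_max: 89, chair_stand_min: 8,  sit_reach_min: -6.0, sit_reach_max: 7.5}
  - {sex: F, age_min: 90, age_max: 94, chair_stand_min: 4,  sit_reach_min: -11.5, sit_reach_max: 2.5}
  - {sex: M, age_min: 60, age_max: 64, chair_stand_min: 14, sit_reach_min: -6.5, sit_reach_max: 10.0}
  - {sex: M, age_min: 65, age_max: 69, chair_stand_min: 12, sit_reach_min: -7.5, sit_reach_max: 9.5}
  - {sex: M, age_min: 70, age_max: 74, chair_stand_min: 12, sit_reach_min: -8.5, sit_reach_max: 8.5}
  - {sex: M, age_min: 75, age_max: 79, chair_stand_min: 11, sit_reach_min: -10.0, sit_reach_max: 7.5}
  - {sex: M, age_min: 80, age_max: 84, chair_stand_min: 10, sit_reach_min: -14.0, sit_reach_max: 6.0}
  - {sex: M, age_min: 85, age_max: 89, chair_stand_min: 8,  sit_reach_min: -14.5, sit_reach_max: 4.0}
  - {sex: M, age_min: 90, age_max: 94, chair_stand_min: 7,  sit_reach_min: -16.5, sit_reach_max: 2.5}

moca:
  low: 22
  medium: 24
  high: 26
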