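# Synthetic-cohort specification matching the published participant table of
# the 3-year Swedish primary-care lifestyle trial for metabolic syndrome:
# group-wise means (SDs) of the continuous risk factors and proportions of the
# binary ones at baseline, year 1 and year 3.  Duration of diabetes was
# published as median (SD); the median is used as the location parameter of a
# truncated normal.  Overall attrition by year 3 was 17%, with most dropouts
# already missing at year 1 (122/145 ≈ observed at year 1, 120/145 at year 3).
dropout_fraction: 0.17
early_dropout_share: 0.88
groups:
  control:
    n: 74
    age_mean: 53.1
    age_sd: 8.2
    waves:
      baseline:
        means: {sbp: 144.7, bmi: 29.4, hba1c: 6.62, fpg: 5.20, hdl: 1.46, tc: 5.4}
        sds:   {sbp: 17.6,  bmi: 5.1,  hba1c: 2.05, fpg: 0.05, hdl: 0.4,  tc: 0.9}
        male_frac: 0.365
        diabetes_frac: 0.23
        smoker_frac: 0.176
        diabetes_duration_loc: 5.0
        diabetes_duration_sd: 4.3
      year1:
        means: {sbp: 143.8, bmi: 28.3, hba1c: 6.3, fpg: 5.3, hdl: 1.5, tc: 5.5}
        sds:   {sbp: 15.5,  bmi: 4.7,  hba1c: 1.1, fpg: 0.6, hdl: 0.4, tc: 0.8}
        male_frac: 0.317
        diabetes_frac: 0.206
        smoker_frac: 0.143
        diabetes_duration_loc: 5.0
        diabetes_duration_sd: 3.5
      year3:
        means: {sbp: 147.3, bmi: 28.5, hba1c: 6.9, fpg: 5.5, hdl: 1.4, tc: 5.3}
        sds:   {sbp: 14.8,  bmi: 5.0,  hba1c: 1.5, fpg: 0.8, hdl: 0.4, tc: 1.0}
        male_frac: 0.323
        diabetes_frac: 0.21
        smoker_frac: 0.113
        diabetes_duration_loc: 8.0
        diabetes_duration_sd: 3.5
  intervention:
    n: 71
    age_mean: 55.7
    age_sd: 6.6
    waves:
      baseline:
        means: {sbp: 145.6, bmi: 30.1, hba1c: 6.30, fpg: 5.24, hdl: 1.39, tc: 5.4}
        sds:   {sbp: 15.5,  bmi: 5.2,  hba1c: 1.35, fpg: 0.05, hdl: 0.3,  tc: 1.0}
        male_frac: 0.493
        diabetes_frac: 0.32
        smoker_frac: 0.24
        diabetes_duration_loc: 7.0
        diabetes_duration_sd: 5.8
      year1:
        means: {sbp: 141.0, bmi: 29.2, hba1c: 5.9, fpg: 5.2, hdl: 1.3, tc: 5.7}
        sds:   {sbp: 13.2,  bmi: 4.7,  hba1c: 1.7, fpg: 0.9, hdl: 0.3, tc: 1.1}
        male_frac: 0.533
        diabetes_frac: 0.333
        smoker_frac: 0.183
        diabetes_duration_loc: 6.5
        diabetes_duration_sd: 5.6
      year3:
        means: {sbp: 141.6, bmi: 29.5, hba1c: 6.4, fpg: 5.4, hdl: 1.3, tc: 5.4}
        sds:   {sbp: 14.0,  bmi: 4.8,  hba1c: 1.9, fpg: 0.9, hdl: 0.3, tc: 1.0}
        male_frac: 0.534
        diabetes_frac: 0.345
        smoker_frac: 0.103
        diabetes_duration_loc: 9.5
        diabetes_duration_sd: 5.6
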