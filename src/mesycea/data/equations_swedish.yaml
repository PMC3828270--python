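# Alternative "Swedish data sources" risk-equation battery, used by the
# multivariate sensitivity analysis: diabetes incidence in the style of a
# Swedish prevention-programme cohort (native 10-year logistic risk) and
# myocardial-infarction/stroke risks in the style of a Nordic register study.
#
# SYNTHETIC DEFAULTS: coefficients are plausible-magnitude synthetic values,
# deliberately differing from the default battery (lower diabetes incidence,
# steeper age gradients for events) so the sensitivity analysis exercises a
# genuinely different parameterisation.  Not transcriptions of any
# publication; replace for substantive use.
name: swedish
equations:
  diabetes:
    form: logistic
    horizon: 10
    terms:
      intercept: -12.8
      age: 0.025
      female: 0.50
      fpg_mgdl: 0.075
      bmi: 0.065
  mi:
    form: weibull_hazard
    horizon: 1
    shape: 1.0
    terms:
      intercept: -11.6
      age: 0.070
      male: 0.50
      sbp: 0.011
      hdl_mgdl: -0.012
      smoker: 0.60
      diabetes: 0.60
  stroke:
    form: weibull_hazard
    horizon: 1
    shape: 1.0
    terms:
      intercept: -13.4
      age: 0.090
      male: 0.25
      sbp: 0.015
      smoker: 0.45
      diabetes: 0.70
  chd:
    form: weibull_hazard
    horizon: 1
    shape: 1.0
    terms:
      intercept: -11.0
      age: 0.062
      male: 0.48
      sbp: 0.008
      hdl_mgdl: -0.011
      tc_mgdl: 0.0045
      smoker: 0.42
      diabetes: 0.52
  chf:
    form: weibull_hazard
    horizon: 1
    shape: 1.0
    terms:
      intercept: -13.7
      age: 0.092
      male: 0.28
      sbp: 0.008
      bmi: 0.042
      diabetes: 0.72
  diabetes_micro:
    form: weibull_hazard
    horizon: 1
    shape: 1.0
    terms:
      intercept: -6.5
      diabetes_duration: 0.068
      hba1c: 0.175
  diabetes_macro:
    form: weibull_hazard
    horizon: 1
    shape: 1.0
    terms:
      intercept: -7.0
      diabetes_duration: 0.052
      hba1c: 0.135
      sbp: 0.008
excess_mortality:
  diabetes: 0.004
  diabetes_micro: 0.012
  diabetes_macro: 0.030
  mi: 0.028
  stroke: 0.048
  chd: 0.012
  chf: 0.078
mortality_table:
  - {age: 0,   male: 0.0005, female: 0.0004}
  - {age: 30,  male: 0.0008, female: 0.0004}
  - {age: 35,  male: 0.0010, female: 0.0005}
  - {age: 40,  male: 0.0014, female: 0.0008}
  - {age: 45,  male: 0.0021, female: 0.0013}
  - {age: 50,  male: 0.0032, female: 0.0021}
  - {age: 55,  male: 0.0050, female: 0.0032}
  - {age: 60,  male: 0.0080, female: 0.0051}
  - {age: 65,  male: 0.0128, female: 0.0082}
  - {age: 70,  male: 0.0210, female: 0.0135}
  - {age: 75,  male: 0.0360, female: 0.0230}
  - {age: 80,  male: 0.0640, female: 0.0430}
  - {age: 85,  male: 0.1150, female: 0.0840}
  - {age: 90,  male: 0.1950, female: 0.1560}
  - {age: 95,  male: 0.3000, female: 0.2600}
  - {age: 100, male: 0.4000, female: 0.3600}
  - {age: 110, male: 0.5500, female: 0.5500}
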