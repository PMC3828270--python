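# Default risk-equation battery.
#
# Functional forms follow the style of the published sources the model family
# draws on — a logistic diabetes-incidence equation (San Antonio style, native
# 7.5-year risk), proportional-hazards annual equations for cardiovascular
# events (Framingham style) and diabetic complications (UKPDS outcome style).
#
# SYNTHETIC DEFAULTS: the coefficients below are plausible-magnitude synthetic
# values calibrated to produce realistic event rates for a middle-aged
# metabolic-syndrome population (annual CVD event risks of order 0.2–1%,
# diabetes onset of order 3%/year).  They are NOT transcriptions of the
# original publications; replace them with the published coefficients for any
# substantive use.  Covariate units: sbp mmHg; fpg_mgdl, hdl_mgdl, tc_mgdl
# mg/dL; bmi kg/m²; age and diabetes_duration years; male/female/smoker/
# diabetes indicators.
name: default
equations:
  diabetes:
    form: logistic
    horizon: 7.5
    terms:
      intercept: -13.415
      age: 0.028
      female: 0.661
      fpg_mgdl: 0.079
      sbp: 0.018
      hdl_mgdl: -0.039
      bmi: 0.070
  mi:
    form: weibull_hazard
    horizon: 1
    shape: 1.0
    terms:
      intercept: -11.2
      age: 0.065
      male: 0.45
      sbp: 0.012
      hdl_mgdl: -0.014
      tc_mgdl: 0.004
      smoker: 0.55
      diabetes: 0.55
  stroke:
    form: weibull_hazard
    horizon: 1
    shape: 1.0
    terms:
      intercept: -13.0
      age: 0.085
      male: 0.30
      sbp: 0.016
      smoker: 0.50
      diabetes: 0.65
  chd:
    form: weibull_hazard
    horizon: 1
    shape: 1.0
    terms:
      intercept: -10.8
      age: 0.060
      male: 0.50
      sbp: 0.008
      hdl_mgdl: -0.012
      tc_mgdl: 0.005
      smoker: 0.40
      diabetes: 0.50
  chf:
    form: weibull_hazard
    horizon: 1
    shape: 1.0
    terms:
      intercept: -13.5
      age: 0.090
      male: 0.30
      sbp: 0.008
      bmi: 0.045
      diabetes: 0.70
  diabetes_micro:
    form: weibull_hazard
    horizon: 1
    shape: 1.0
    terms:
      intercept: -6.3
      diabetes_duration: 0.070
      hba1c: 0.180
  diabetes_macro:
    form: weibull_hazard
    horizon: 1
    shape: 1.0
    terms:
      intercept: -6.9
      diabetes_duration: 0.055
      hba1c: 0.140
      sbp: 0.008
# Constant annual excess death probability while occupying a disease state,
# added to the life-table floor (synthetic defaults).
excess_mortality:
  diabetes: 0.004
  diabetes_micro: 0.012
  diabetes_macro: 0.030
  mi: 0.030
  stroke: 0.050
  chd: 0.012
  chf: 0.080
# Abridged all-cause life table (annual death probability by age band and sex;
# synthetic, Nordic-like level and shape; editable).
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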