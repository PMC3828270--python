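# Per-state annual cost components (SEK, 2012 price year) and utility weights.
#
# SYNTHETIC DEFAULTS: the Swedish register-based cost and utility tables the
# original evaluation used are not publicly printed; the values below are
# synthetic placeholders at clinically plausible magnitudes (disease states
# several-fold costlier than the at-risk state, severe states with higher
# informal-care and productivity components, utilities ordered by severity).
# Replace with sourced values for any substantive analysis.
price_year: 2012
discount_rate: 0.03
usd_per_sek_divisor: 6.57
# Swedish consumer price index (1980 = 100); approximate, editable.
cpi_index:
  2003: 278.1
  2004: 279.2
  2005: 280.4
  2006: 284.2
  2007: 290.5
  2008: 300.6
  2009: 299.7
  2010: 303.5
  2011: 311.4
  2012: 314.2
state_costs_sek:
  at_risk:
    medical_treatment: 3000
    institutional_care: 0
    pharmaceuticals: 1500
    community_care: 500
    informal_care: 1000
    patient_relative_other: 0
    productivity_loss: 5000
  diabetes:
    medical_treatment: 9000
    institutional_care: 500
    pharmaceuticals: 5000
    community_care: 1500
    informal_care: 2000
    patient_relative_other: 0
    productivity_loss: 15000
  diabetes_micro:
    medical_treatment: 20000
    institutional_care: 3000
    pharmaceuticals: 8000
    community_care: 4000
    informal_care: 6000
    patient_relative_other: 0
    productivity_loss: 30000
  diabetes_macro:
    medical_treatment: 30000
    institutional_care: 6000
    pharmaceuticals: 9000
    community_care: 6000
    informal_care: 9000
    patient_relative_other: 0
    productivity_loss: 40000
  mi:
    medical_treatment: 28000
    institutional_care: 8000
    pharmaceuticals: 7000
    community_care: 5000
    informal_care: 8000
    patient_relative_other: 0
    productivity_loss: 45000
  stroke:
    medical_treatment: 35000
    institutional_care: 20000
    pharmaceuticals: 6000
    community_care: 12000
    informal_care: 15000
    patient_relative_other: 0
    productivity_loss: 50000
  chd:
    medical_treatment: 18000
    institutional_care: 2000
    pharmaceuticals: 6000
    community_care: 3000
    informal_care: 4000
    patient_relative_other: 0
    productivity_loss: 25000
  chf:
    medical_treatment: 30000
    institutional_care: 10000
    pharmaceuticals: 8000
    community_care: 8000
    informal_care: 10000
    patient_relative_other: 0
    productivity_loss: 35000
  dead:
    medical_treatment: 0
    institutional_care: 0
    pharmaceuticals: 0
    community_care: 0
    informal_care: 0
    patient_relative_other: 0
    productivity_loss: 0
utilities:
  at_risk: 0.85
  diabetes: 0.78
  diabetes_micro: 0.68
  diabetes_macro: 0.62
  mi: 0.70
  stroke: 0.55
  chd: 0.72
  chf: 0.60
  dead: 0.0
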