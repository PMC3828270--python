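"""Published results of the trial's economic evaluation, used as inputs.

The original evaluation printed its group-level outputs — per-arm
within-group cost/QALY differences for the base case, and per-analysis
DD cost and QALY columns for the sensitivity battery — but the
underlying participant records and the exact cost/utility/risk tables
are not public.  These printed numbers therefore serve as *inputs* to
the package's desk-scale arithmetic (DD recomposition, ICER
classification); they are transcribed here once so every consumer reads
the same values.

All costs in 2012 US$; QALYs discounted at 3% unless the analysis says
otherwise.
"""

from __future__ import annotations

#: Base-case within-group differences (with study − reference), per horizon
#: and perspective, and the corresponding QALY differences.
BASE_CASE_WITHIN_DIFFS = {
    "short_term": {
        "societal": {"intervention": 50.0, "control": 750.0},
        "healthcare": {"intervention": 60.0, "control": 560.0},
        "qaly": {"intervention": 0.00, "control": 0.00},
    },
    "long_term": {
        "societal": {"intervention": 300.0, "control": 7600.0},
        "healthcare": {"intervention": 400.0, "control": 1900.0},
        "qaly": {"intervention": 0.03, "control": -0.43},
    },
}

#: Published base-case DD estimates the within-group differences recompose to.
BASE_CASE_DD = {
    "short_term": {"societal": -700.0, "healthcare": -500.0, "qaly": 0.00},
    "long_term": {"societal": -7300.0, "healthcare": -1500.0, "qaly": 0.46},
}

#: Long-term sensitivity battery: DD cost per perspective (US$) and DD QALYs.
#: Keys follow the published analysis numbering.
SENSITIVITY_ROWS = {
    "base": {"societal": -7300.0, "healthcare": -1500.0, "qaly": 0.46},
    "1a": {"societal": -930.0, "healthcare": 250.0, "qaly": 0.40},
    "1b": {"societal": -850.0, "healthcare": 880.0, "qaly": 0.31},
    "1c": {"societal": 4800.0, "healthcare": 1540.0, "qaly": 0.23},
    "1d": {"societal": -1230.0, "healthcare": 90.0, "qaly": 0.12},
    "2a": {"societal": -11300.0, "healthcare": -6100.0, "qaly": 0.47},
    "2b": {"societal": -10300.0, "healthcare": -1400.0, "qaly": 0.33},
    "3a": {"societal": 9800.0, "healthcare": 1580.0, "qaly": 0.95},
    "3b": {"societal": -12900.0, "healthcare": -2260.0, "qaly": 0.30},
    "4": {"societal": -11300.0, "healthcare": -2370.0, "qaly": 0.27},
    "5": {"societal": -780.0, "healthcare": -160.0, "qaly": 0.04},
    "6": {"societal": -940.0, "healthcare": -1700.0, "qaly": 0.39},
    "7a": {"societal": -14900.0, "healthcare": -3100.0, "qaly": 0.48},
    "7b": {"societal": -8270.0, "healthcare": -1900.0, "qaly": 0.06},
}

#: Published ICERs (US$/QALY, truncated to whole dollars) for the analyses
#: reported as cost-effective rather than cost-saving.
PUBLISHED_ICERS = {
    ("1a", "healthcare"): 1152,
    ("1b", "healthcare"): 3519,
    ("1c", "societal"): 21_786,
    ("1c", "healthcare"): 7_613,
    ("3a", "societal"): 10_537,
    ("3a", "healthcare"): 1_885,
    ("5", "healthcare"): 1_275,
}

#: trial arm sizes (intervention, control)
N_INTERVENTION = 71
N_CONTROL = 74
N_TOTAL = N_INTERVENTION + N_CONTROL
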