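"""DD estimation, bootstrap CIs, ICER classification and orchestration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mesycea.cohort import CONTINUOUS_FIELDS, generate_cohort
from mesycea.ddcea import (
    bootstrap_dd,
    dd_estimate,
    icer,
    run_base_case,
    run_sensitivity_battery,
)
from mesycea.markov import SimulationSettings
from conftest import make_null_cohort, make_small_spec

finite = st.floats(-1e6, 1e6, allow_nan=False)


class TestDDEstimate:
    @pytest.mark.parametrize(
        "i_diff, c_diff, expected",
        [
            (50.0, 750.0, -700.0),     # short-term societal
            (60.0, 560.0, -500.0),     # short-term health care
            (300.0, 7600.0, -7300.0),  # long-term societal
            (400.0, 1900.0, -1500.0),  # long-term health care
            (0.03, -0.43, 0.46),       # long-term QALYs
        ],
    )
    def test_published_within_group_differences_recompose(
        self, i_diff, c_diff, expected
    ):
        dd = dd_estimate(i_diff, 0.0, c_diff, 0.0)
        assert dd.dd == pytest.approx(expected)

    @settings(derandomize=True, max_examples=100)
    @given(finite, finite, finite, finite, finite)
    def test_group_level_shifts_cancel(self, iw, ir, cw, cr, shift):
        base = dd_estimate(iw, ir, cw, cr).dd
        shifted = dd_estimate(iw + shift, ir + shift, cw, cr).dd
        assert shifted == pytest.approx(base, abs=1e-6)

    @settings(derandomize=True, max_examples=100)
    @given(finite, finite, finite, finite)
    def test_swapping_arms_negates_dd(self, iw, ir, cw, cr):
        assert dd_estimate(iw, ir, cw, cr).dd == pytest.approx(
            -dd_estimate(cw, cr, iw, ir).dd
        )


class TestICER:
    @pytest.mark.parametrize(
        "dd_cost, dd_qaly, expected",
        [
            (1540.0, 0.23, 7_613),   # immediate-reversion, health care
            (4800.0, 0.23, 21_786),  # immediate-reversion, societal
            (1580.0, 0.95, 1_885),   # diabetic subgroup, health care
            (9800.0, 0.95, 10_537),  # diabetic subgroup, societal
            (250.0, 0.40, 1_152),    # 10-year reversion, health care
            (880.0, 0.31, 3_519),    # 5-year reversion, health care
            (-160.0, 0.04, 1_275),   # alternative equation set, health care
        ],
    )
    def test_published_ratios_reproduced_with_truncation(
        self, dd_cost, dd_qaly, expected
    ):
        res = icer(dd_cost, dd_qaly, programme_cost=211.0)
        assert res.icer == expected
        assert res.label == "icer"
        assert res.cost_effective_swedish and res.cost_effective_who

    def test_cost_saving_when_programme_cost_absorbed(self):
        res = icer(-7300.0, 0.46, 211.0)
        assert res.label == "cost_saving"
        assert res.icer is None
        assert res.incremental_cost == pytest.approx(-7089.0)

    def test_dominated_quadrant(self):
        res = icer(500.0, -0.2, 211.0)
        assert res.label == "dominated"

    def test_zero_qaly_gain_with_net_cost_is_undefined_ratio(self):
        assert icer(100.0, 0.0, 211.0).label == "ratio_undefined"
        assert icer(-500.0, 0.0, 211.0).label == "cost_saving"

    def test_threshold_classification_boundaries(self):
        # 60,000 US$/QALY: under the Swedish threshold, over the WHO one
        res = icer(59_999.0 * 1.0 - 211.0, 1.0, 211.0)
        assert res.cost_effective_swedish and not res.cost_effective_who

    def test_negative_programme_cost_rejected(self):
        with pytest.raises(ValueError):
            icer(0.0, 0.1, programme_cost=-1.0)


class TestBootstrap:
    def test_degenerate_cohort_gives_point_ci(self):
        i = np.full(10, 3.0)
        c = np.full(12, 1.0)
        lo, hi = bootstrap_dd(i, c, B=200, seed=0)
        assert lo == hi == pytest.approx(2.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        i, c = rng.normal(5, 2, 40), rng.normal(3, 2, 40)
        assert bootstrap_dd(i, c, seed=9) == bootstrap_dd(i, c, seed=9)

    def test_percentile_bounds_converge_in_B(self):
        rng = np.random.default_rng(2)
        i, c = rng.normal(5, 2, 60), rng.normal(3, 2, 60)
        lo1, hi1 = bootstrap_dd(i, c, B=1000, seed=3)
        lo2, hi2 = bootstrap_dd(i, c, B=10_000, seed=4)
        mc_tol = 4 * 2.0 * np.sqrt(2 / 60) / np.sqrt(10)  # ~SE of a percentile
        assert abs(lo1 - lo2) < mc_tol and abs(hi1 - hi2) < mc_tol

    def test_small_group_and_small_B_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_dd(np.array([1.0]), np.ones(5))
        with pytest.raises(ValueError):
            bootstrap_dd(np.ones(5), np.ones(5), B=50)


@pytest.fixture(scope="module")
def null_base_case():
    cohort = make_null_cohort(n=6, seed=2)
    return run_base_case(
        cohort,
        settings=SimulationSettings(termination_age=75.0),
        bootstrap_B=100,
        seed=0,
    )


class TestBaseCase:
    def test_null_intervention_dd_is_zero_everywhere(self, null_base_case):
        for horizon in ("short_term", "long_term"):
            for m in ("cost_societal", "cost_healthcare", "qaly"):
                cell = null_base_case[horizon]["dd"][m]
                assert cell["dd"] == 0.0
                assert cell["ci"] == (0.0, 0.0)

    def test_report_table_covers_all_cells(self, null_base_case):
        t = null_base_case["table"]
        assert len(t) == 4
        assert set(t["horizon"]) == {"short_term", "long_term"}
        assert set(t["perspective"]) == {"societal", "healthcare"}
        assert t["dd_cost_ci_lo"].notna().all()

    def test_ci_brackets_point_estimate(self):
        cohort = generate_cohort(make_small_spec(n=10, dropout=0.2, seed=4))
        res = run_base_case(
            cohort,
            settings=SimulationSettings(termination_age=75.0),
            bootstrap_B=200,
            seed=1,
        )
        for horizon in ("short_term", "long_term"):
            for m in ("cost_societal", "cost_healthcare", "qaly"):
                cell = res[horizon]["dd"][m]
                assert cell["ci"][0] <= cell["dd"] <= cell["ci"][1]


@pytest.fixture(scope="module")
def degenerate_battery():
    """Battery on a cohort of identical participants with no dropout: the
    complete-case and mean-value variants must then equal the base case."""
    spec = make_small_spec(n=4, dropout=0.0, seed=5)
    for g in spec.groups.values():
        g.age_sd = 0.0
        for w in g.waves.values():
            w.sds = {f: 0.0 for f in CONTINUOUS_FIELDS}
            w.male_frac = 1.0
            w.diabetes_frac = 1.0
            w.smoker_frac = 0.0
            w.diabetes_duration_sd = 0.0
    cohort = generate_cohort(spec)
    return run_sensitivity_battery(
        cohort,
        settings=SimulationSettings(termination_age=72.0),
        seed=0,
        mi_m=2,
        mi_bootstrap_B=100,
    )


EXPECTED_ROWS = [
    "base", "1a", "1b", "1c", "1d", "2a", "2b",
    "3a", "3b", "4", "5", "6", "7a", "7b",
]


class TestSensitivityBattery:
    def test_all_published_analysis_rows_present(self, degenerate_battery):
        assert list(degenerate_battery["analysis"]) == EXPECTED_ROWS
        assert {
            "dd_cost_societal", "dd_cost_healthcare", "dd_qaly",
            "interpretation_societal", "interpretation_healthcare",
        } <= set(degenerate_battery.columns)

    def test_complete_cases_equal_base_without_dropout(self, degenerate_battery):
        b = degenerate_battery.set_index("analysis")
        for col in ("dd_cost_societal", "dd_cost_healthcare", "dd_qaly"):
            assert b.loc["2b", col] == pytest.approx(b.loc["base", col], abs=1e-9)

    def test_mean_value_equals_base_for_identical_participants(
        self, degenerate_battery
    ):
        b = degenerate_battery.set_index("analysis")
        for col in ("dd_cost_societal", "dd_cost_healthcare", "dd_qaly"):
            assert b.loc["6", col] == pytest.approx(b.loc["base", col], abs=1e-6)

    def test_all_diabetic_cohort_marks_nondiabetic_subgroup_undefined(
        self, degenerate_battery
    ):
        b = degenerate_battery.set_index("analysis")
        assert np.isnan(b.loc["3b", "dd_cost_societal"])
        assert b.loc["3b", "interpretation_societal"] == "Undefined"

    def test_effect_reversion_shrinks_the_effect(self, degenerate_battery):
        # the sooner risk factors revert to baseline, the smaller |DD|
        b = degenerate_battery.set_index("analysis")
        base = abs(b.loc["base", "dd_qaly"])
        assert abs(b.loc["1a", "dd_qaly"]) <= base + 1e-12
        assert abs(b.loc["1c", "dd_qaly"]) <= abs(b.loc["1a", "dd_qaly"]) + 1e-12


def test_no_discounting_amplifies_a_sign_stable_effect():
    """When the intervention uniformly lowers year-3 blood pressure in one
    arm only, the per-cycle effect has constant sign, so removing
    discounting can only grow the DD magnitude."""
    cohort = make_null_cohort(n=5, seed=7)
    mask = (cohort["group"] == "intervention") & (cohort["wave"] == "year3")
    cohort.loc[mask, "sbp"] -= 15.0
    settings = SimulationSettings(termination_age=75.0)
    res = {}
    for code, rate in (("base", 0.03), ("7a", 0.0)):
        from mesycea.econ import default_economics

        r = run_base_case(
            cohort,
            econ=default_economics().with_rate(rate),
            settings=settings,
            bootstrap_B=100,
            seed=0,
        )
        res[code] = r["long_term"]["dd"]
    for m in ("cost_societal", "cost_healthcare", "qaly"):
        assert abs(res["7a"][m]["dd"]) >= abs(res["base"][m]["dd"])
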