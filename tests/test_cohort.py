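"""Synthetic cohort generation, LOCF, multiple imputation, Rubin pooling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mesycea.cohort import (
    CONTINUOUS_FIELDS,
    MEASURED_FIELDS,
    CohortSpecError,
    default_cohort_spec,
    generate_cohort,
    locf_complete,
    mi_complete,
    pool_rubin,
    read_cohort_csv,
    write_cohort_csv,
)
from conftest import make_small_spec


class TestGenerate:
    def test_group_sizes_match_trial(self):
        df = generate_cohort(default_cohort_spec(seed=0))
        base = df[df["wave"] == "baseline"]
        assert len(base) == 145
        assert (base["group"] == "intervention").sum() == 71
        assert (base["group"] == "control").sum() == 74

    def test_degenerate_spec_reproduces_wave_means_exactly(self):
        spec = make_small_spec(n=5, dropout=0.0, seed=0)
        for g in spec.groups.values():
            for w in g.waves.values():
                w.sds = {f: 0.0 for f in CONTINUOUS_FIELDS}
        df = generate_cohort(spec)
        assert not df[list(MEASURED_FIELDS)].isna().any().any()
        for gname, g in spec.groups.items():
            for wname, w in g.waves.items():
                sub = df[(df["group"] == gname) & (df["wave"] == wname)]
                for f in CONTINUOUS_FIELDS:
                    assert np.allclose(sub[f], w.means[f])

    def test_dropout_fraction_converges(self):
        spec = make_small_spec(n=10_000, dropout=0.17, seed=1)
        df = generate_cohort(spec)
        frac = df[df["wave"] == "year3"]["sbp"].isna().mean()
        assert abs(frac - 0.17) < 0.01

    def test_dropout_is_monotone(self):
        df = generate_cohort(make_small_spec(n=200, dropout=0.3, seed=2))
        wide = df.pivot(index="id", columns="wave", values="sbp")
        missing_y1 = wide["year1"].isna()
        assert wide.loc[missing_y1, "year3"].isna().all()

    def test_marginals_converge_to_spec(self):
        spec = make_small_spec(n=4000, dropout=0.0, seed=3)
        df = generate_cohort(spec)
        for gname, g in spec.groups.items():
            sub = df[(df["group"] == gname) & (df["wave"] == "baseline")]
            w = g.waves["baseline"]
            for f in ("sbp", "bmi", "tc"):
                se = w.sds[f] / np.sqrt(len(sub))
                assert abs(sub[f].mean() - w.means[f]) < 4 * se
            assert abs((sub["sex"] == "male").mean() - w.male_frac) < 0.03
            assert abs(sub["diabetes"].mean() - w.diabetes_frac) < 0.03

    def test_deterministic_given_seed(self):
        a = generate_cohort(make_small_spec(n=20, dropout=0.2, seed=7))
        b = generate_cohort(make_small_spec(n=20, dropout=0.2, seed=7))
        pd.testing.assert_frame_equal(a, b)

    def test_nondiabetic_duration_zero_and_positivity(self):
        df = generate_cohort(make_small_spec(n=300, dropout=0.0, seed=4))
        assert (df.loc[df["diabetes"] == 0.0, "diabetes_duration"] == 0.0).all()
        for f in CONTINUOUS_FIELDS:
            assert (df[f] > 0).all()

    @pytest.mark.parametrize(
        "mutate, field",
        [
            (lambda s: setattr(s, "dropout_fraction", 1.3), "dropout_fraction"),
            (
                lambda s: s.groups["control"].waves["baseline"].sds.update(sbp=-1),
                "sds.sbp",
            ),
            (
                lambda s: setattr(
                    s.groups["control"].waves["baseline"], "smoker_frac", 1.2
                ),
                "smoker_frac",
            ),
        ],
    )
    def test_invalid_spec_names_field(self, mutate, field):
        spec = make_small_spec()
        mutate(spec)
        with pytest.raises(CohortSpecError, match=field.split(".")[-1]):
            generate_cohort(spec)

    def test_ages_advance_with_waves(self):
        df = generate_cohort(make_small_spec(n=10, dropout=0.2, seed=5))
        wide = df.pivot(index="id", columns="wave", values="age")
        assert np.allclose(wide["year1"] - wide["baseline"], 1.0)
        assert np.allclose(wide["year3"] - wide["baseline"], 3.0)


class TestLOCF:
    def test_carries_baseline_through_both_waves(self, small_cohort):
        out = locf_complete(small_cohort)
        assert not out[list(MEASURED_FIELDS)].isna().any().any()
        wide_in = small_cohort.pivot(index="id", columns="wave", values="sbp")
        wide_out = out.pivot(index="id", columns="wave", values="sbp")
        lost_all = wide_in["year1"].isna() & wide_in["year3"].isna()
        assert np.allclose(
            wide_out.loc[lost_all, "year3"], wide_out.loc[lost_all, "baseline"]
        )

    def test_observed_values_untouched_and_idempotent(self, small_cohort):
        once = locf_complete(small_cohort)
        obs = small_cohort["sbp"].notna()
        assert np.allclose(
            once.loc[obs.index[obs], "sbp"], small_cohort.loc[obs.index[obs], "sbp"]
        )
        pd.testing.assert_frame_equal(locf_complete(once), once)

    def test_age_not_carried(self, small_cohort):
        out = locf_complete(small_cohort)
        wide = out.pivot(index="id", columns="wave", values="age")
        assert np.allclose(wide["year3"] - wide["baseline"], 3.0)

    def test_missing_baseline_errors(self, small_cohort):
        broken = small_cohort.copy()
        idx = broken[broken["wave"] == "baseline"].index[0]
        broken.loc[idx, "sbp"] = np.nan
        with pytest.raises(ValueError, match="baseline"):
            locf_complete(broken)


class TestMI:
    def test_complete_data_returns_identical_copies(self):
        df = generate_cohort(make_small_spec(n=10, dropout=0.0, seed=6))
        out = mi_complete(df, m=3, seed=0)
        for ds in out:
            pd.testing.assert_frame_equal(
                ds[df.columns], df, check_dtype=False, check_categorical=False
            )

    def test_observed_entries_identical_across_datasets(self, small_cohort):
        out = mi_complete(small_cohort, m=3, seed=1)
        obs = small_cohort["bmi"].notna()
        for ds in out:
            assert not ds[list(MEASURED_FIELDS)].isna().any().any()
            assert np.array_equal(
                ds.loc[obs.index[obs], "bmi"].to_numpy(),
                small_cohort.loc[obs.index[obs], "bmi"].to_numpy(),
            )

    def test_mcar_recovery_of_withheld_means(self):
        # withhold follow-ups completely at random, impute, compare to truth
        truth = generate_cohort(make_small_spec(n=120, dropout=0.0, seed=8))
        rng = np.random.default_rng(8)
        df = truth.copy()
        followup = df.index[df["wave"] != "baseline"]
        holes = rng.choice(followup, size=int(0.2 * len(followup)), replace=False)
        df.loc[holes, list(MEASURED_FIELDS)] = np.nan
        out = mi_complete(df, m=5, seed=8)
        for f in ("sbp", "bmi"):
            true_mean = truth.loc[followup, f].mean()
            se = truth.loc[followup, f].std() / np.sqrt(len(followup))
            imp_means = [ds.loc[followup, f].mean() for ds in out]
            assert abs(np.mean(imp_means) - true_mean) < 2 * se

    def test_m_and_complete_record_preconditions(self, small_cohort):
        with pytest.raises(ValueError, match="m must be"):
            mi_complete(small_cohort, m=1)
        all_missing = small_cohort.copy()
        mask = all_missing["wave"] != "baseline"
        all_missing.loc[mask, list(MEASURED_FIELDS)] = np.nan
        with pytest.raises(ValueError, match="fully observed"):
            mi_complete(all_missing, m=2)

    def test_deterministic_given_seed(self, small_cohort):
        a = mi_complete(small_cohort, m=2, seed=5)
        b = mi_complete(small_cohort, m=2, seed=5)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)


class TestRubin:
    def test_identical_estimates_pool_to_themselves(self):
        assert pool_rubin([(5.0, 1.0)] * 3) == (5.0, 1.0)

    def test_hand_computed_two_imputation_case(self):
        point, var = pool_rubin([(1.0, 2.0), (3.0, 2.0)])
        assert point == 2.0
        assert var == pytest.approx(2.0 + 1.5 * 2.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(
                st.floats(-50, 50), st.floats(0, 10, allow_nan=False)
            ),
            min_size=2,
            max_size=10,
        ),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariance_and_hull(self, ests, rnd):
        point, var = pool_rubin(ests)
        shuffled = list(ests)
        rnd.shuffle(shuffled)
        point2, var2 = pool_rubin(shuffled)
        assert point == pytest.approx(point2)
        assert var == pytest.approx(var2)
        pts = [e[0] for e in ests]
        assert min(pts) - 1e-9 <= point <= max(pts) + 1e-9
        assert var >= 0

    def test_too_few_estimates(self):
        with pytest.raises(ValueError):
            pool_rubin([(1.0, 1.0)])


class TestCSV:
    def test_round_trip_preserves_values_and_missingness(self, small_cohort, tmp_path):
        p = tmp_path / "cohort.csv"
        write_cohort_csv(small_cohort, p)
        back = read_cohort_csv(p)
        pd.testing.assert_frame_equal(
            back, small_cohort, check_dtype=False, check_categorical=False
        )
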