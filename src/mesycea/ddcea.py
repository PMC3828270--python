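"""Differences-in-differences cost-effectiveness analysis.

The causal contrast is built from four scenario runs: each arm is
simulated under its observed post-intervention ("with study") risk-factor
levels and under its baseline ("reference") counterfactual.  The first
difference (with study − reference, within arm) removes person-level
levels; the second difference (intervention − control) removes secular
trends, yielding the DD estimate of the intervention's effect on
discounted costs and QALYs.  Uncertainty comes from a non-parametric
bootstrap over participants within each arm; the incremental
cost-effectiveness ratio adds the per-participant programme cost and is
classified against the Swedish willingness-to-pay threshold
(US$76,000/QALY) and the WHO GDP-per-capita threshold (US$57,114/QALY).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import locf_complete, mi_complete, pool_rubin
from .econ import EconomicParameters, default_economics
from .markov import (
    ScenarioSpec,
    SimulationSettings,
    cohort_to_persons,
    run_group,
)
from .risk import RiskEquationSet, load_equation_set
from .statespace import HealthStateModel, default_state_model

__all__ = [
    "PROGRAMME_COST_USD",
    "SWEDISH_THRESHOLD_USD",
    "WHO_THRESHOLD_USD",
    "DDPoint",
    "CEAResult",
    "dd_estimate",
    "bootstrap_dd",
    "icer",
    "run_base_case",
    "run_sensitivity_battery",
]

log = logging.getLogger(__name__)

PROGRAMME_COST_USD = 211.0
SWEDISH_THRESHOLD_USD = 76_000.0
WHO_THRESHOLD_USD = 57_114.0

METRICS = ("cost_societal", "cost_healthcare", "qaly")

#: cycles from baseline at which the 3-year intervention's effect reverts
#: under the "return to baseline after k years" sensitivity analyses
INTERVENTION_YEARS = 3


@dataclass(frozen=True)
class DDPoint:
    """The two within-group differences and their difference."""

    intervention_diff: float
    control_diff: float

    @property
    def dd(self) -> float:
        return self.intervention_diff - self.control_diff


def dd_estimate(
    i_with: float, i_ref: float, c_with: float, c_ref: float
) -> DDPoint:
    """Differences-in-differences from four group means (pure arithmetic)."""
    return DDPoint(i_with - i_ref, c_with - c_ref)


def bootstrap_dd(
    i_diff: np.ndarray,
    c_diff: np.ndarray,
    B: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile 95% CI for the DD from per-participant paired differences.

    Participants are resampled with replacement independently within each
    arm (arm sizes preserved); each replicate's DD is the difference of
    resampled arm means.  Deterministic given ``seed``.
    """
    i_diff = np.asarray(i_diff, dtype=float)
    c_diff = np.asarray(c_diff, dtype=float)
    if len(i_diff) < 2 or len(c_diff) < 2:
        raise ValueError("each group needs at least 2 participants to bootstrap")
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    bi = i_diff[rng.integers(0, len(i_diff), size=(B, len(i_diff)))].mean(axis=1)
    bc = c_diff[rng.integers(0, len(c_diff), size=(B, len(c_diff)))].mean(axis=1)
    reps = bi - bc
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass(frozen=True)
class CEAResult:
    """Incremental cost (programme cost included), incremental QALYs, the
    ICER (truncated to whole dollars) and its classification."""

    incremental_cost: float
    incremental_qaly: float
    icer: int | None
    label: str
    cost_effective_swedish: bool | None = None
    cost_effective_who: bool | None = None

    def interpretation(self) -> str:
        if self.label == "cost_saving":
            return "Cost-saving"
        if self.label == "icer":
            tag = "Cost-effective" if self.cost_effective_swedish else "Not cost-effective"
            return f"{tag} (US${self.icer:,}/QALY)"
        return self.label.replace("_", " ").capitalize()


def icer(
    dd_cost: float,
    dd_qaly: float,
    programme_cost: float = PROGRAMME_COST_USD,
    swedish_threshold: float = SWEDISH_THRESHOLD_USD,
    who_threshold: float = WHO_THRESHOLD_USD,
) -> CEAResult:
    """Classify the DD estimate as cost-saving, cost-effective or dominated.

    The incremental cost adds the per-participant programme cost to the DD
    cost.  A negative incremental cost with no QALY loss is cost-saving
    (no ratio).  Positive ratios are reported truncated (floored) to whole
    dollars and compared with both thresholds.  A zero QALY difference
    with a positive incremental cost yields the ``ratio_undefined``
    signal.
    """
    if programme_cost < 0:
        raise ValueError("programme cost must be >= 0")
    if math.isnan(dd_cost) or math.isnan(dd_qaly):
        return CEAResult(float("nan"), float("nan"), None, "undefined", None, None)
    inc = dd_cost + programme_cost
    if dd_qaly >= 0 and inc < 0:
        return CEAResult(inc, dd_qaly, None, "cost_saving", True, True)
    if dd_qaly > 0 and inc >= 0:
        ratio = int(math.floor(inc / dd_qaly))
        return CEAResult(
            inc, dd_qaly, ratio, "icer",
            ratio < swedish_threshold, ratio < who_threshold,
        )
    if dd_qaly == 0:
        label = "ratio_undefined" if inc > 0 else "equivalent"
        return CEAResult(inc, dd_qaly, None, label, None, None)
    if inc > 0:
        return CEAResult(inc, dd_qaly, None, "dominated", False, False)
    return CEAResult(inc, dd_qaly, None, "less_costly_less_effective", None, None)


# ---------------------------------------------------------------------------
# orchestration


def _paired_diffs(with_df: pd.DataFrame, ref_df: pd.DataFrame) -> pd.DataFrame:
    merged = with_df.merge(ref_df, on=["id", "group"], suffixes=("_with", "_ref"))
    for m in METRICS:
        merged[m] = merged[f"{m}_with"] - merged[f"{m}_ref"]
    return merged[["id", "group", *METRICS]]


def _run_dd(
    persons_i,
    persons_c,
    with_scenario: ScenarioSpec,
    ref_scenario: ScenarioSpec,
    model,
    eqset,
    econ,
    settings,
    weights_i=None,
    weights_c=None,
):
    """Four scenario runs → group means, per-participant paired diffs, DD."""
    runs = {}
    for gname, persons, w in (
        ("intervention", persons_i, weights_i),
        ("control", persons_c, weights_c),
    ):
        for scen in (with_scenario, ref_scenario):
            df, means = run_group(persons, scen, model, eqset, econ, settings, w)
            runs[(gname, scen.label)] = (df, means)
    diffs = {
        g: _paired_diffs(runs[(g, with_scenario.label)][0],
                         runs[(g, ref_scenario.label)][0])
        for g in ("intervention", "control")
    }
    dd = {}
    for m in METRICS:
        dd[m] = dd_estimate(
            runs[("intervention", with_scenario.label)][1][m],
            runs[("intervention", ref_scenario.label)][1][m],
            runs[("control", with_scenario.label)][1][m],
            runs[("control", ref_scenario.label)][1][m],
        )
    return runs, diffs, dd


def _split_groups(persons: list[dict]):
    pi = [p for p in persons if p["group"] == "intervention"]
    pc = [p for p in persons if p["group"] == "control"]
    if not pi or not pc:
        raise ValueError("cohort must contain both intervention and control arms")
    return pi, pc


def run_base_case(
    cohort: pd.DataFrame,
    model: HealthStateModel | None = None,
    eqset: RiskEquationSet | None = None,
    econ: EconomicParameters | None = None,
    settings: SimulationSettings | None = None,
    programme_cost: float = PROGRAMME_COST_USD,
    bootstrap_B: int = 1000,
    seed: int = 0,
    apply_locf: bool = True,
) -> dict:
    """Intention-to-treat base case: with-study (year-3 factors) vs reference
    (baseline factors) over the 3-year and lifelong horizons, both
    perspectives, with bootstrap CIs and ICER classification.

    Returns a nested dict keyed ``short_term`` / ``long_term``, each with
    group means, within-group differences, DD points and CIs per metric,
    and a ``CEAResult`` per perspective, plus a tidy report table.
    """
    model = model or default_state_model()
    eqset = eqset or load_equation_set("default")
    econ = econ or default_economics()
    settings = settings or SimulationSettings(seed=seed)
    completed = locf_complete(cohort) if apply_locf else cohort
    persons = cohort_to_persons(completed)
    pi, pc = _split_groups(persons)

    out: dict = {}
    rows = []
    for horizon_key, horizon in (("short_term", 3), ("long_term", "lifelong")):
        with_s = ScenarioSpec("with_study", "year3", None, horizon)
        ref_s = ScenarioSpec("reference", "baseline", None, horizon)
        runs, diffs, dd = _run_dd(pi, pc, with_s, ref_s, model, eqset, econ, settings)
        res: dict = {"means": {k: v[1] for k, v in runs.items()}, "dd": {}, "cea": {}}
        for m in METRICS:
            ci = bootstrap_dd(
                diffs["intervention"][m].to_numpy(),
                diffs["control"][m].to_numpy(),
                B=bootstrap_B,
                seed=seed,
            )
            res["dd"][m] = {
                "intervention_diff": dd[m].intervention_diff,
                "control_diff": dd[m].control_diff,
                "dd": dd[m].dd,
                "ci": ci,
            }
        for persp, m in (("societal", "cost_societal"), ("healthcare", "cost_healthcare")):
            res["cea"][persp] = icer(dd[m].dd, dd["qaly"].dd, programme_cost)
            rows.append(
                {
                    "horizon": horizon_key,
                    "perspective": persp,
                    "dd_cost": res["dd"][m]["dd"],
                    "dd_cost_ci_lo": res["dd"][m]["ci"][0],
                    "dd_cost_ci_hi": res["dd"][m]["ci"][1],
                    "dd_qaly": res["dd"]["qaly"]["dd"],
                    "dd_qaly_ci_lo": res["dd"]["qaly"]["ci"][0],
                    "dd_qaly_ci_hi": res["dd"]["qaly"]["ci"][1],
                    "interpretation": res["cea"][persp].interpretation(),
                }
            )
        out[horizon_key] = res
        log.info(
            "%s: DD societal %.0f, healthcare %.0f, QALY %.3f",
            horizon_key,
            res["dd"]["cost_societal"]["dd"],
            res["dd"]["cost_healthcare"]["dd"],
            res["dd"]["qaly"]["dd"],
        )
    out["table"] = pd.DataFrame(rows)
    return out


def _mean_value_persons(completed: pd.DataFrame, group: str):
    """Pseudo-participants carrying the group's mean characteristics.

    Diabetes and sex are categorical in the simulation (they set the start
    state and the life-table column), so the group mean is represented as
    four pseudo-participants — {male, female} × {diabetic, non-diabetic} —
    weighted by the group's baseline prevalences; smoking enters as its
    fractional prevalence.
    """
    g = completed[completed["group"] == group]
    base = g[g["wave"] == "baseline"]
    p_male = float((base["sex"] == "male").mean())
    p_diab = float(base["diabetes"].mean())
    diab_dur = {
        w: float(
            g[(g["wave"] == w) & (g["diabetes"] > 0.5)]["diabetes_duration"].mean()
        )
        if (g[(g["wave"] == w)]["diabetes"] > 0.5).any()
        else 0.0
        for w in ("baseline", "year1", "year3")
    }
    waves_mean = {}
    for w in ("baseline", "year1", "year3"):
        gw = g[g["wave"] == w]
        waves_mean[w] = {
            f: float(gw[f].mean())
            for f in ("sbp", "bmi", "hba1c", "fpg", "hdl", "tc")
        }
        waves_mean[w]["smoker"] = float(gw["smoker"].mean())
    persons, weights = [], []
    for male, w_sex in ((1.0, p_male), (0.0, 1.0 - p_male)):
        for diab, w_diab in ((1.0, p_diab), (0.0, 1.0 - p_diab)):
            waves = {}
            for w, means in waves_mean.items():
                prof = dict(means)
                prof["diabetes"] = diab
                prof["diabetes_duration"] = diab_dur[w] if diab else 0.0
                waves[w] = prof
            persons.append(
                {
                    "id": f"{group}_mean_m{int(male)}_d{int(diab)}",
                    "group": group,
                    "male": male,
                    "baseline_age": float(base["age"].mean()),
                    "waves": waves,
                }
            )
            weights.append(w_sex * w_diab)
    return persons, np.array(weights)


def run_sensitivity_battery(
    cohort: pd.DataFrame,
    model: HealthStateModel | None = None,
    eqset: RiskEquationSet | None = None,
    econ: EconomicParameters | None = None,
    settings: SimulationSettings | None = None,
    programme_cost: float = PROGRAMME_COST_USD,
    seed: int = 0,
    mi_m: int = 10,
    mi_bootstrap_B: int = 200,
) -> pd.DataFrame:
    """Long-horizon sensitivity battery over effect duration, missing-data
    handling, diabetes subgroups, time horizon, the alternative equation
    set, mean-value cohorts and discount rates.

    Takes the raw (incomplete) cohort; each row re-runs the four-scenario
    DD pipeline under one varied assumption and reports DD cost (both
    perspectives), DD QALYs, and the ICER classification per perspective.
    """
    model = model or default_state_model()
    eqset = eqset or load_equation_set("default")
    econ = econ or default_economics()
    settings = settings or SimulationSettings(seed=seed)
    completed = locf_complete(cohort)
    persons = cohort_to_persons(completed)
    pi, pc = _split_groups(persons)

    def dd_points(
        pi_, pc_, wave="year3", revert=None, eqset_=None, econ_=None,
        settings_=None, wi=None, wc=None,
    ):
        if not pi_ or not pc_:  # empty subgroup: row reported as undefined
            return {m: float("nan") for m in METRICS}
        with_s = ScenarioSpec("with_study", wave, revert, "lifelong")
        ref_s = ScenarioSpec("reference", "baseline", None, "lifelong")
        _, _, dd = _run_dd(
            pi_, pc_, with_s, ref_s, model,
            eqset_ or eqset, econ_ or econ, settings_ or settings,
            wi, wc,
        )
        return {m: dd[m].dd for m in METRICS}

    rows = []

    def emit(code: str, label: str, dd: dict):
        rows.append(
            {
                "analysis": code,
                "label": label,
                "dd_cost_societal": dd["cost_societal"],
                "dd_cost_healthcare": dd["cost_healthcare"],
                "dd_qaly": dd["qaly"],
                "interpretation_societal": icer(
                    dd["cost_societal"], dd["qaly"], programme_cost
                ).interpretation(),
                "interpretation_healthcare": icer(
                    dd["cost_healthcare"], dd["qaly"], programme_cost
                ).interpretation(),
            }
        )
        log.info("sensitivity %s (%s): %s", code, label, rows[-1])

    emit("base", "3rd-year risk factors remain until death", dd_points(pi, pc))
    emit(
        "1a", "Risk factors return to baseline after 10 years",
        dd_points(pi, pc, revert=INTERVENTION_YEARS + 10),
    )
    emit(
        "1b", "Risk factors return to baseline after 5 years",
        dd_points(pi, pc, revert=INTERVENTION_YEARS + 5),
    )
    emit(
        "1c", "Risk factors return to baseline immediately after the intervention",
        dd_points(pi, pc, revert=INTERVENTION_YEARS),
    )
    emit("1d", "1st-year risk factors remain until death", dd_points(pi, pc, wave="year1"))

    # 2a: multiple imputation with Rubin pooling across m completed cohorts
    imputed = mi_complete(cohort, m=mi_m, seed=seed)
    per_metric: dict[str, list[tuple[float, float]]] = {m: [] for m in METRICS}
    for ds in imputed:
        persons_m = cohort_to_persons(ds)
        pim, pcm = _split_groups(persons_m)
        with_s = ScenarioSpec("with_study", "year3", None, "lifelong")
        ref_s = ScenarioSpec("reference", "baseline", None, "lifelong")
        _, diffs_m, dd_m = _run_dd(pim, pcm, with_s, ref_s, model, eqset, econ, settings)
        for m in METRICS:
            lo, hi = bootstrap_dd(
                diffs_m["intervention"][m].to_numpy(),
                diffs_m["control"][m].to_numpy(),
                B=mi_bootstrap_B,
                seed=seed,
            )
            var = ((hi - lo) / (2 * 1.96)) ** 2
            per_metric[m].append((dd_m[m].dd, var))
    emit(
        "2a", "With multiple imputations for missing cases",
        {m: pool_rubin(per_metric[m])[0] for m in METRICS},
    )

    # 2b: complete cases — participants observed through year 3
    observed_y3 = cohort[
        (cohort["wave"] == "year3") & cohort["sbp"].notna()
    ]["id"]
    cc = cohort[cohort["id"].isin(observed_y3)]
    pic, pcc = _split_groups(cohort_to_persons(locf_complete(cc)))
    emit("2b", "Complete cases only", dd_points(pic, pcc))

    # 3a/3b: diabetes-at-baseline subgroups
    base_rows = completed[completed["wave"] == "baseline"]
    diab_ids = set(base_rows[base_rows["diabetes"] > 0.5]["id"])
    pi_d = [p for p in pi if p["id"] in diab_ids]
    pc_d = [p for p in pc if p["id"] in diab_ids]
    pi_n = [p for p in pi if p["id"] not in diab_ids]
    pc_n = [p for p in pc if p["id"] not in diab_ids]
    emit("3a", "Only persons with diabetes", dd_points(pi_d, pc_d))
    emit("3b", "Only persons without diabetes", dd_points(pi_n, pc_n))

    emit(
        "4", "Extended time horizon (max age 120 years)",
        dd_points(
            pi, pc,
            settings_=SimulationSettings(
                termination_age=120.0,
                repetitions=settings.repetitions,
                seed=settings.seed,
                mode=settings.mode,
                common_random_numbers=settings.common_random_numbers,
            ),
        ),
    )
    emit("5", "Swedish data sources", dd_points(pi, pc, eqset_=load_equation_set("swedish")))

    mv_i, w_i = _mean_value_persons(completed, "intervention")
    mv_c, w_c = _mean_value_persons(completed, "control")
    emit("6", "Study group, mean value", dd_points(mv_i, mv_c, wi=w_i, wc=w_c))

    emit("7a", "No discounting", dd_points(pi, pc, econ_=econ.with_rate(0.0)))
    emit("7b", "5% discount rate", dd_points(pi, pc, econ_=econ.with_rate(0.05)))

    return pd.DataFrame(rows)
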