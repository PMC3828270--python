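"""Annual-cycle state-transition micro-simulation.

Each participant walks the health-state graph one year at a time, with
person-specific transition probabilities from the risk engine, accruing
the occupied state's discounted cost (both perspectives) and utility
each cycle until death or the termination age.  Two modes compute the
same estimand:

``montecarlo``
    repeats the walk (default 10,000 repetitions) and averages;
``cohort_expectation``
    propagates the state-occupancy distribution forward and returns the
    exact expectation on the same transition structure (no Monte-Carlo
    error), tracking years-since-diabetes-onset alongside the state so
    duration-dependent equations stay exact.

Scenario risk factors are piecewise constant: the scenario wave's levels
hold until an optional reversion cycle, after which baseline levels
hold; age and diabetes duration always advance with simulated time, and
age stays at its baseline value when the scenario wave's factors are
adopted (the counterfactual pair differ only in risk-factor levels).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .econ import EconomicParameters
from .risk import RiskEquationSet, transition_probabilities
from .statespace import DIABETIC_STATES, HealthStateModel, default_state_model

__all__ = [
    "ScenarioSpec",
    "SimulationSettings",
    "SimulationResult",
    "cohort_to_persons",
    "initial_state",
    "simulate_participant",
    "run_group",
]

PROFILE_FIELDS = (
    "sbp", "bmi", "hba1c", "fpg", "hdl", "tc",
    "diabetes", "diabetes_duration", "smoker",
)


@dataclass(frozen=True)
class ScenarioSpec:
    """Which risk-factor wave drives the simulation, and for how long.

    ``revert_after`` is the cycle index (years since baseline) at which
    risk factors fall back to baseline levels; ``None`` means the effect
    is lifelong.  ``horizon`` is a cycle count or ``"lifelong"`` (run to
    the termination age).
    """

    label: str
    risk_factor_wave: str = "baseline"
    revert_after: int | None = None
    horizon: int | str = "lifelong"

    def active_wave(self, cycle: int) -> str:
        if self.revert_after is not None and cycle >= self.revert_after:
            return "baseline"
        return self.risk_factor_wave


@dataclass(frozen=True)
class SimulationSettings:
    termination_age: float = 85.0
    repetitions: int = 10_000
    seed: int = 0
    mode: str = "cohort_expectation"  # or "montecarlo"
    common_random_numbers: bool = True

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.mode not in ("cohort_expectation", "montecarlo"):
            raise ValueError(f"unknown mode: {self.mode!r}")


@dataclass(frozen=True)
class SimulationResult:
    """Discounted expectations per participant (means over repetitions in
    Monte-Carlo mode; exact in cohort-expectation mode)."""

    cost_societal: float
    cost_healthcare: float
    qaly: float
    se_cost_societal: float = 0.0
    se_cost_healthcare: float = 0.0
    se_qaly: float = 0.0


def cohort_to_persons(df: pd.DataFrame) -> list[dict]:
    """Convert a long-format cohort frame into simulation person records."""
    persons: list[dict] = []
    for pid, rows in df.groupby("id", sort=True, observed=True):
        waves = {}
        base = rows[rows["wave"] == "baseline"]
        if base.empty:
            raise ValueError(f"participant {pid!r} has no baseline record")
        for _, r in rows.iterrows():
            prof = {f: r[f] for f in PROFILE_FIELDS}
            if not any(pd.isna(v) for v in prof.values()):
                waves[str(r["wave"])] = {k: float(v) for k, v in prof.items()}
        persons.append(
            {
                "id": str(pid),
                "group": str(base["group"].iloc[0]),
                "male": 1.0 if base["sex"].iloc[0] == "male" else 0.0,
                "baseline_age": float(base["age"].iloc[0]),
                "waves": waves,
            }
        )
    return persons


def initial_state(profile: dict) -> tuple[str, float]:
    """Start state for a risk-factor profile: diabetics start in the
    diabetes state with their recorded duration, everyone else at risk."""
    if profile["diabetes"] > 0.5:
        return "diabetes", float(profile["diabetes_duration"])
    return "at_risk", 0.0


def _stream_seed(master_seed: int, participant_id: str, scenario_key: str) -> int:
    """Stable per-(participant, scenario) RNG seed: adding participants to a
    cohort never perturbs the draws of the others."""
    digest = hashlib.sha256(
        f"{master_seed}|{participant_id}|{scenario_key}".encode()
    ).digest()
    return int.from_bytes(digest[:4], "little")


def _n_cycles(scenario: ScenarioSpec, baseline_age: float, termination_age: float) -> int:
    if scenario.horizon == "lifelong":
        if termination_age <= baseline_age:
            raise ValueError(
                f"termination age {termination_age} must exceed baseline age "
                f"{baseline_age}"
            )
        return int(math.ceil(termination_age - baseline_age))
    return int(scenario.horizon)


class _TransitionCache:
    """Memoised annual transition rows for one participant-scenario run."""

    def __init__(self, person, scenario, model, eqset):
        self.person = person
        self.scenario = scenario
        self.model = model
        self.eqset = eqset
        self.state_index = {s: i for i, s in enumerate(model.states)}
        self._rows: dict[tuple, np.ndarray] = {}
        for w in ("baseline", scenario.risk_factor_wave):
            if w not in person["waves"]:
                raise ValueError(
                    f"participant {person['id']!r}: scenario references wave "
                    f"{w!r} with no complete data"
                )

    def profile(self, cycle: int, state: str, dur: float) -> dict:
        base = self.person["waves"][self.scenario.active_wave(cycle)]
        prof = dict(base)
        prof["age"] = self.person["baseline_age"] + cycle
        prof["male"] = self.person["male"]
        if state in DIABETIC_STATES:
            prof["diabetes"] = 1.0
            prof["diabetes_duration"] = dur
        elif state == "at_risk":
            prof["diabetes"] = 0.0
            prof["diabetes_duration"] = 0.0
        return prof

    def row(self, cycle: int, state: str, dur: float) -> np.ndarray:
        wave = self.scenario.active_wave(cycle)
        key = (wave, cycle, state, dur)
        cached = self._rows.get(key)
        if cached is not None:
            return cached
        probs = transition_probabilities(
            self.profile(cycle, state, dur), state, self.eqset, self.model
        )
        vec = np.array([probs[s] for s in self.model.states])
        self._rows[key] = vec
        return vec


def _next_dur(succ: str, state: str, dur: float) -> float:
    if succ in DIABETIC_STATES:
        return dur + 1.0 if state in DIABETIC_STATES else 0.0
    return 0.0


def _expectation(person, scenario, model, eqset, cost_soc, cost_hc, util,
                 rate, n_cycles) -> SimulationResult:
    cache = _TransitionCache(person, scenario, model, eqset)
    s0, d0 = initial_state(person["waves"][scenario.risk_factor_wave])
    masses: dict[tuple[str, float], float] = {(s0, d0): 1.0}
    idx = cache.state_index
    tot_soc = tot_hc = tot_q = 0.0
    for t in range(n_cycles):
        df_t = 1.0 / (1.0 + rate) ** t
        total_mass = 0.0
        for (s, d), m in masses.items():
            total_mass += m
            i = idx[s]
            tot_soc += m * cost_soc[i] * df_t
            tot_hc += m * cost_hc[i] * df_t
            tot_q += m * util[i] * df_t
        if abs(total_mass - 1.0) > 1e-9:
            raise AssertionError(f"occupancy mass {total_mass} != 1 at cycle {t}")
        nxt: dict[tuple[str, float], float] = {}
        for (s, d), m in masses.items():
            if s in model.absorbing:
                nxt[(s, 0.0)] = nxt.get((s, 0.0), 0.0) + m
                continue
            row = cache.row(t, s, d)
            for j, p in enumerate(row):
                if p == 0.0:
                    continue
                succ = model.states[j]
                key = (succ, _next_dur(succ, s, d))
                nxt[key] = nxt.get(key, 0.0) + m * p
        masses = nxt
    return SimulationResult(tot_soc, tot_hc, tot_q)


def _montecarlo(person, scenario, model, eqset, cost_soc, cost_hc, util,
                rate, n_cycles, settings) -> SimulationResult:
    cache = _TransitionCache(person, scenario, model, eqset)
    scen_key = "" if settings.common_random_numbers else scenario.label
    rng = np.random.default_rng(
        _stream_seed(settings.seed, person["id"], scen_key)
    )
    R = settings.repetitions
    idx = cache.state_index
    dead_i = idx["dead"]
    s0, d0 = initial_state(person["waves"][scenario.risk_factor_wave])
    states = np.full(R, idx[s0], dtype=np.int64)
    durs = np.full(R, d0, dtype=float)
    acc_soc = np.zeros(R)
    acc_hc = np.zeros(R)
    acc_q = np.zeros(R)
    diabetic_idx = np.array(
        [idx[s] for s in DIABETIC_STATES if s in idx], dtype=np.int64
    )
    for t in range(n_cycles):
        # one uniform per repetition per cycle, drawn unconditionally so the
        # with-study and reference runs consume identical streams (CRN)
        u = rng.random(R)
        df_t = 1.0 / (1.0 + rate) ** t
        acc_soc += cost_soc[states] * df_t
        acc_hc += cost_hc[states] * df_t
        acc_q += util[states] * df_t
        alive = states != dead_i
        if not alive.any():
            continue
        new_states = states.copy()
        pairs = np.unique(np.stack([states[alive], durs[alive]]), axis=1)
        for s_i, d in pairs.T:
            s_i = int(s_i)
            mask = alive & (states == s_i) & (durs == d)
            row = cache.row(t, model.states[s_i], float(d))
            cum = np.cumsum(row)
            succ = np.searchsorted(cum, u[mask] * cum[-1], side="right")
            new_states[mask] = np.minimum(succ, len(row) - 1)
        was_diab = np.isin(states, diabetic_idx)
        now_diab = np.isin(new_states, diabetic_idx)
        durs = np.where(now_diab, np.where(was_diab, durs + 1.0, 0.0), 0.0)
        states = new_states
    mean = lambda a: float(a.mean())
    se = lambda a: float(a.std(ddof=1) / math.sqrt(R)) if R > 1 else 0.0
    return SimulationResult(
        mean(acc_soc), mean(acc_hc), mean(acc_q),
        se(acc_soc), se(acc_hc), se(acc_q),
    )


def simulate_participant(
    person: dict,
    scenario: ScenarioSpec,
    model: HealthStateModel | None = None,
    eqset: RiskEquationSet | None = None,
    econ: EconomicParameters | None = None,
    settings: SimulationSettings | None = None,
) -> SimulationResult:
    """Discounted expected costs (both perspectives) and QALYs for one
    participant under one scenario.  Deterministic given the settings seed."""
    from .econ import default_economics
    from .risk import load_equation_set

    model = model or default_state_model()
    eqset = eqset or load_equation_set("default")
    econ = econ or default_economics()
    settings = settings or SimulationSettings()

    cost_soc = np.array([econ.perspective_cost(s, "societal") for s in model.states])
    cost_hc = np.array([econ.perspective_cost(s, "healthcare") for s in model.states])
    util = np.array([econ.utility(s) for s in model.states])
    n_cycles = _n_cycles(scenario, person["baseline_age"], settings.termination_age)
    args = (person, scenario, model, eqset, cost_soc, cost_hc, util,
            econ.discount_rate, n_cycles)
    if settings.mode == "cohort_expectation":
        return _expectation(*args)
    return _montecarlo(*args, settings)


def run_group(
    persons: list[dict],
    scenario: ScenarioSpec,
    model: HealthStateModel | None = None,
    eqset: RiskEquationSet | None = None,
    econ: EconomicParameters | None = None,
    settings: SimulationSettings | None = None,
    weights: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-participant results plus (optionally weighted) group means."""
    if not persons:
        raise ValueError("empty group")
    rows = []
    for p in persons:
        r = simulate_participant(p, scenario, model, eqset, econ, settings)
        rows.append(
            {
                "id": p["id"],
                "group": p["group"],
                "scenario": scenario.label,
                "cost_societal": r.cost_societal,
                "cost_healthcare": r.cost_healthcare,
                "qaly": r.qaly,
            }
        )
    df = pd.DataFrame(rows)
    w = None if weights is None else np.asarray(weights, dtype=float)
    means = {
        k: float(np.average(df[k].to_numpy(), weights=w))
        for k in ("cost_societal", "cost_healthcare", "qaly")
    }
    return df, means
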