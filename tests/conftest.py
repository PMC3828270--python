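"""Shared fixtures: toy state spaces, equation sets and economics."""

from __future__ import annotations

import numpy as np
import pytest

from mesycea.cohort import default_cohort_spec, generate_cohort
from mesycea.econ import EconomicParameters
from mesycea.risk import RiskEquationSet, load_equation_set
from mesycea.statespace import HealthStateModel


def make_small_spec(n: int = 12, dropout: float = 0.0, seed: int = 0):
    """Default (published-table) cohort spec scaled down to ``n`` per arm."""
    spec = default_cohort_spec(seed=seed)
    for g in spec.groups.values():
        g.n = n
    spec.dropout_fraction = dropout
    return spec


def make_null_cohort(n: int = 8, seed: int = 0):
    """Cohort whose follow-up values equal baseline for every participant
    (a null intervention), with ages still advancing."""
    spec = make_small_spec(n=n, dropout=0.0, seed=seed)
    for g in spec.groups.values():
        for wname in ("year1", "year3"):
            g.waves[wname] = g.waves["baseline"]
    df = generate_cohort(spec)
    base = df[df["wave"] == "baseline"].set_index("id")
    fields = ["sbp", "bmi", "hba1c", "fpg", "hdl", "tc",
              "diabetes", "diabetes_duration", "smoker"]
    for f in fields:
        df[f] = base.loc[df["id"], f].to_numpy()
    return df


@pytest.fixture
def two_state_model() -> HealthStateModel:
    return HealthStateModel(
        states=("at_risk", "dead"),
        transitions={"at_risk": frozenset({"at_risk", "dead"}), "dead": frozenset()},
    )


def make_const_death_eqset(q: float, name: str = "toy") -> RiskEquationSet:
    """No event equations; flat all-cause annual death probability ``q``."""
    return RiskEquationSet(
        name=name,
        event_equations={},
        mortality_table=((0.0, q, q),),
    )


def make_toy_econ(
    states,
    utility: float = 0.8,
    cost: float = 0.0,
    rate: float = 0.03,
) -> EconomicParameters:
    """Uniform living-state utility/cost; 1:1 currency so costs read as US$."""
    e = EconomicParameters(
        state_costs_sek={
            s: {"medical_treatment": 0.0 if s == "dead" else cost} for s in states
        },
        utilities={s: 0.0 if s == "dead" else utility for s in states},
        price_year=2012,
        discount_rate=rate,
        cpi_index={2012: 100.0},
        usd_per_sek_divisor=1.0,
    )
    e.validate()
    return e


@pytest.fixture(scope="session")
def default_eqset():
    return load_equation_set("default")


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(make_small_spec(n=12, dropout=0.25, seed=3))
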