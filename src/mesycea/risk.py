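"""Risk equations: individual risk-factor profiles → annual transition probabilities.

A pluggable equation set maps a participant's current covariates (age,
sex, systolic blood pressure, BMI, lipids, glycaemia, diabetes presence
and duration, smoking) to probabilities of diabetes onset, cardiovascular
events (myocardial infarction, stroke, other coronary heart disease,
congestive heart failure) and diabetic micro-/macro-vascular
complications, plus all-cause background mortality from an abridged life
table.  Equations whose published forms report multi-year risks are
converted to the model's annual cycle by inverting the compounding
identity.

Two sets ship with the package, ``default`` (Framingham / San Antonio /
UKPDS style functional forms) and ``swedish`` (an alternative-source
battery); their coefficients are synthetic plausible-magnitude defaults,
clearly labelled in the config files, intended to be overwritten with
transcriptions of the original publications by anyone who needs them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import product

from .statespace import HealthStateModel, default_state_model

__all__ = [
    "RiskEquationError",
    "Equation",
    "RiskEquationSet",
    "annual_probability",
    "compound_probability",
    "transition_probabilities",
    "load_equation_set",
    "profile_covariates",
]

log = logging.getLogger(__name__)

#: base covariates every profile must carry
BASE_COVARIATES = (
    "age", "male", "sbp", "bmi", "hba1c", "fpg", "hdl", "tc",
    "diabetes", "diabetes_duration", "smoker",
)

MGDL_PER_MMOL_GLUCOSE = 18.016
MGDL_PER_MMOL_CHOLESTEROL = 38.67


class RiskEquationError(ValueError):
    """A risk equation produced or would produce an invalid probability."""


def profile_covariates(profile: dict) -> dict:
    """Expand a base profile with the derived covariates equations may use."""
    cov = dict(profile)
    cov["female"] = 1.0 - float(profile["male"])
    cov["fpg_mgdl"] = profile["fpg"] * MGDL_PER_MMOL_GLUCOSE
    cov["hdl_mgdl"] = profile["hdl"] * MGDL_PER_MMOL_CHOLESTEROL
    cov["tc_mgdl"] = profile["tc"] * MGDL_PER_MMOL_CHOLESTEROL
    cov["log_age"] = math.log(profile["age"])
    cov["age_sq"] = profile["age"] ** 2
    cov["intercept"] = 1.0
    return cov


def annual_probability(multi_year_risk: float, horizon: float) -> float:
    """Convert a ``horizon``-year cumulative risk to an annual probability.

    Assumes a constant hazard within the native horizon:
    ``1 - (1 - risk)**(1/horizon)``.
    """
    if not 0.0 <= multi_year_risk <= 1.0:
        raise RiskEquationError(f"risk outside [0, 1]: {multi_year_risk}")
    if horizon < 1:
        raise RiskEquationError(f"horizon must be >= 1 year, got {horizon}")
    if multi_year_risk == 1.0:
        return 1.0
    return 1.0 - (1.0 - multi_year_risk) ** (1.0 / horizon)


def compound_probability(annual: float, horizon: float) -> float:
    """Inverse of :func:`annual_probability`: compound an annual probability."""
    if not 0.0 <= annual <= 1.0:
        raise RiskEquationError(f"probability outside [0, 1]: {annual}")
    return 1.0 - (1.0 - annual) ** horizon


@dataclass(frozen=True)
class Equation:
    """One outcome equation: functional form + coefficients + native horizon.

    Forms
    -----
    logistic
        ``p = expit(lp)`` over the native horizon.
    weibull_hazard
        ``p = 1 - exp(-exp(lp) * horizon**shape)`` — a proportional-hazards
        Weibull cumulative risk (UKPDS-outcome style).
    framingham_accumulator
        Accelerated-failure-time form: ``u = (ln(horizon) - lp) / sigma``
        with ``sigma = exp(sigma_const + sigma_mu * lp)``;
        ``p = 1 - exp(-exp(u))`` (Anderson-1991 style).
    linear
        ``p = lp`` directly; only sensible for hand-built test sets, and
        the form the load-time grid validation exists to police.
    """

    name: str
    form: str
    horizon: float
    terms: dict[str, float]
    shape: float = 1.0
    sigma_const: float = 0.0
    sigma_mu: float = 0.0

    def linear_predictor(self, cov: dict) -> float:
        lp = 0.0
        for term, coef in self.terms.items():
            try:
                lp += coef * cov[term]
            except KeyError:
                raise RiskEquationError(
                    f"equation {self.name!r}: unknown covariate {term!r}"
                ) from None
        return lp

    def native_risk(self, cov: dict) -> float:
        lp = self.linear_predictor(cov)
        if self.form == "logistic":
            return 1.0 / (1.0 + math.exp(-lp))
        if self.form == "weibull_hazard":
            return 1.0 - math.exp(-math.exp(lp) * self.horizon**self.shape)
        if self.form == "framingham_accumulator":
            sigma = math.exp(self.sigma_const + self.sigma_mu * lp)
            u = (math.log(self.horizon) - lp) / sigma
            return 1.0 - math.exp(-math.exp(u))
        if self.form == "linear":
            return lp
        raise RiskEquationError(f"equation {self.name!r}: unknown form {self.form!r}")

    def annual_risk(self, cov: dict) -> float:
        p = self.native_risk(cov)
        if not 0.0 <= p <= 1.0:
            raise RiskEquationError(
                f"equation {self.name!r} produced probability {p} outside [0, 1]"
            )
        return annual_probability(p, self.horizon)

    def to_dict(self) -> dict:
        d = {"form": self.form, "horizon": self.horizon, "terms": dict(self.terms)}
        if self.form == "weibull_hazard":
            d["shape"] = self.shape
        if self.form == "framingham_accumulator":
            d["sigma_const"] = self.sigma_const
            d["sigma_mu"] = self.sigma_mu
        return d


@dataclass(frozen=True)
class RiskEquationSet:
    """Named battery of outcome equations plus a background life table.

    ``event_equations`` maps destination health states to equations;
    ``excess_mortality`` holds constant annual excess death probabilities
    added to the life-table floor while occupying a disease state.
    """

    name: str
    event_equations: dict[str, Equation]
    mortality_table: tuple[tuple[float, float, float], ...]  # (age_from, male, female)
    excess_mortality: dict[str, float] = field(default_factory=dict)

    def mortality(self, age: float, male) -> float:
        """All-cause annual death probability from the abridged life table."""
        qx = 0.0
        col = 1 if male else 2
        for row in self.mortality_table:
            if age >= row[0]:
                qx = row[col]
            else:
                break
        return qx

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "equations": {s: eq.to_dict() for s, eq in self.event_equations.items()},
            "excess_mortality": dict(self.excess_mortality),
            "mortality_table": [
                {"age": a, "male": m, "female": f} for a, m, f in self.mortality_table
            ],
        }


def transition_probabilities(
    profile: dict,
    current_state: str,
    eqset: RiskEquationSet,
    model: HealthStateModel | None = None,
) -> dict[str, float]:
    """Annual transition distribution out of ``current_state``.

    Permitted successors get their equation's annual probability; death
    gets at least the life-table floor for the profile's age and sex plus
    any state excess; the residual mass stays.  If cause-specific
    probabilities sum beyond 1 the whole outgoing distribution is
    normalised jointly (with a logged warning), preserving the
    distribution invariant.  Impermissible transitions are exactly 0.
    """
    if model is None:
        model = default_state_model()
    if current_state in model.absorbing:
        raise ValueError(f"no transitions out of absorbing state {current_state!r}")
    successors = model.successors(current_state)
    cov = profile_covariates(profile)

    p_dead = min(
        eqset.mortality(cov["age"], cov["male"])
        + eqset.excess_mortality.get(current_state, 0.0),
        1.0,
    )
    probs = {s: 0.0 for s in model.states}
    total_events = 0.0
    for succ in successors:
        if succ in (current_state,) or succ in model.absorbing:
            continue
        eq = eqset.event_equations.get(succ)
        if eq is None:
            continue
        p = eq.annual_risk(cov)
        probs[succ] = p
        total_events += p
    probs["dead"] = p_dead

    stay = 1.0 - total_events - p_dead
    if stay < 0.0:
        total = total_events + p_dead
        log.warning(
            "outgoing probabilities from %s sum to %.4f > 1; normalising jointly",
            current_state, total,
        )
        for s in probs:
            probs[s] /= total
        stay = 0.0
    probs[current_state] = stay
    return probs


_VALIDATION_GRID = {
    "age": (30.0, 84.0),
    "male": (0.0, 1.0),
    "sbp": (100.0, 200.0),
    "bmi": (20.0, 45.0),
    "hba1c": (4.5, 12.0),
    "fpg": (4.0, 15.0),
    "hdl": (0.6, 2.5),
    "tc": (3.0, 9.0),
    "diabetes": (0.0, 1.0),
    "diabetes_duration": (0.0, 30.0),
    "smoker": (0.0, 1.0),
}


def _validate_on_grid(eqset: RiskEquationSet) -> None:
    keys = list(_VALIDATION_GRID)
    for corner in product(*(_VALIDATION_GRID[k] for k in keys)):
        cov = profile_covariates(dict(zip(keys, corner)))
        for state, eq in eqset.event_equations.items():
            p = eq.native_risk(cov)
            if not 0.0 <= p <= 1.0:
                raise RiskEquationError(
                    f"equation {eq.name!r} (→ {state}) produced probability "
                    f"{p:.4g} outside [0, 1] on the validation grid"
                )


def _set_from_dict(d: dict) -> RiskEquationSet:
    eqs = {}
    for state, e in d.get("equations", {}).items():
        if "form" not in e or "terms" not in e or "horizon" not in e:
            raise RiskEquationError(
                f"equation for {state!r}: needs form, horizon and terms"
            )
        for term, coef in e["terms"].items():
            if coef is None:
                raise RiskEquationError(
                    f"equation for {state!r}: missing coefficient for term {term!r}"
                )
        eqs[state] = Equation(
            name=state,
            form=str(e["form"]),
            horizon=float(e["horizon"]),
            terms={k: float(v) for k, v in e["terms"].items()},
            shape=float(e.get("shape", 1.0)),
            sigma_const=float(e.get("sigma_const", 0.0)),
            sigma_mu=float(e.get("sigma_mu", 0.0)),
        )
    table = tuple(
        sorted(
            (float(r["age"]), float(r["male"]), float(r["female"]))
            for r in d["mortality_table"]
        )
    )
    return RiskEquationSet(
        name=str(d.get("name", "unnamed")),
        event_equations=eqs,
        mortality_table=table,
        excess_mortality={k: float(v) for k, v in d.get("excess_mortality", {}).items()},
    )


def load_equation_set(source) -> RiskEquationSet:
    """Load and validate an equation set.

    ``source`` may be a packaged set name (``"default"`` or ``"swedish"``),
    a path to a YAML file, or an already-parsed dict (as produced by
    :meth:`RiskEquationSet.to_dict`, so serialisation round-trips).
    Validation evaluates every equation on a grid of extreme-but-plausible
    profiles and rejects any probability outside [0, 1], naming the
    equation.
    """
    if isinstance(source, dict):
        d = source
    elif isinstance(source, str) and source in ("default", "swedish"):
        from ._resources import load_packaged_yaml

        d = load_packaged_yaml(f"equations_{source}.yaml")
    else:
        import yaml

        with open(source, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
    eqset = _set_from_dict(d)
    _validate_on_grid(eqset)
    return eqset
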