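"""Per-state costs and utilities, perspectives, discounting, currency.

Costs are stated per health state and year in SEK at a declared price
year, broken into the components the evaluation distinguishes: medical
treatment, institutional care, pharmaceuticals, community care, informal
care, other costs for patients and relatives, and productivity loss.
The societal perspective sums all components; the health-care
perspective counts only medical treatment, pharmaceuticals and community
care.  Everything is inflated to 2012 prices with a consumer-price-index
table and converted to US dollars at the 2012 rate of 6.57 SEK per US$.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._resources import load_packaged_yaml

__all__ = [
    "COST_COMPONENTS",
    "HEALTHCARE_COMPONENTS",
    "EconomicParameters",
    "default_economics",
    "discount",
    "sek_to_usd_2012",
]

COST_COMPONENTS = (
    "medical_treatment",
    "institutional_care",
    "pharmaceuticals",
    "community_care",
    "informal_care",
    "patient_relative_other",
    "productivity_loss",
)
#: component subset counted under the health-care perspective
HEALTHCARE_COMPONENTS = ("medical_treatment", "pharmaceuticals", "community_care")

USD_PER_SEK_DIVISOR_2012 = 6.57


def discount(amount: float, cycle_index: int, rate: float) -> float:
    """Discount ``amount`` accrued in annual cycle ``cycle_index``.

    The first cycle (t = 0) is undiscounted: ``amount / (1 + rate)**t``.
    """
    if cycle_index < 0:
        raise ValueError(f"cycle index must be >= 0, got {cycle_index}")
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    return amount / (1.0 + rate) ** cycle_index


def sek_to_usd_2012(
    amount_sek: float,
    price_year: int,
    cpi_index: dict[int, float],
    divisor: float = USD_PER_SEK_DIVISOR_2012,
) -> float:
    """Inflate SEK from ``price_year`` to 2012 prices, then convert to US$."""
    if price_year not in cpi_index:
        raise KeyError(f"price year {price_year} not in CPI table")
    if 2012 not in cpi_index:
        raise KeyError("CPI table lacks the 2012 reference year")
    return amount_sek * cpi_index[2012] / cpi_index[price_year] / divisor


@dataclass
class EconomicParameters:
    """Costs, utilities and discounting settings for the simulation.

    ``state_costs_sek`` maps state → component → annual SEK at
    ``price_year``; ``utilities`` maps state → QALY weight per year.
    """

    state_costs_sek: dict[str, dict[str, float]]
    utilities: dict[str, float]
    price_year: int = 2012
    discount_rate: float = 0.03
    cpi_index: dict[int, float] = field(default_factory=lambda: {2012: 100.0})
    usd_per_sek_divisor: float = USD_PER_SEK_DIVISOR_2012

    def validate(self) -> None:
        for state, comps in self.state_costs_sek.items():
            for comp, v in comps.items():
                if comp not in COST_COMPONENTS:
                    raise ValueError(f"{state}: unknown cost component {comp!r}")
                if v < 0:
                    raise ValueError(f"{state}.{comp}: cost must be >= 0")
        for state, u in self.utilities.items():
            if u > 1.0:
                raise ValueError(f"{state}: utility {u} exceeds 1")
        dead_cost = sum(self.state_costs_sek.get("dead", {}).values())
        if dead_cost != 0.0 or self.utilities.get("dead", 0.0) != 0.0:
            raise ValueError("dead state must have zero cost and utility")
        if self.discount_rate < 0:
            raise ValueError("discount rate must be >= 0")

    def perspective_cost(self, state: str, perspective: str) -> float:
        """Annual cost of occupying ``state``, in 2012 US$, by perspective."""
        if state not in self.state_costs_sek:
            raise KeyError(f"unknown state: {state!r}")
        comps = self.state_costs_sek[state]
        if perspective == "societal":
            sek = sum(comps.get(c, 0.0) for c in COST_COMPONENTS)
        elif perspective == "healthcare":
            sek = sum(comps.get(c, 0.0) for c in HEALTHCARE_COMPONENTS)
        else:
            raise ValueError(f"unknown perspective: {perspective!r}")
        return sek_to_usd_2012(
            sek, self.price_year, self.cpi_index, self.usd_per_sek_divisor
        )

    def utility(self, state: str) -> float:
        if state not in self.utilities:
            raise KeyError(f"unknown state: {state!r}")
        return self.utilities[state]

    def with_rate(self, rate: float) -> "EconomicParameters":
        return EconomicParameters(
            state_costs_sek=self.state_costs_sek,
            utilities=self.utilities,
            price_year=self.price_year,
            discount_rate=rate,
            cpi_index=self.cpi_index,
            usd_per_sek_divisor=self.usd_per_sek_divisor,
        )


def default_economics() -> EconomicParameters:
    """Packaged per-state cost/utility tables (synthetic defaults)."""
    d = load_packaged_yaml("economics_default.yaml")
    params = EconomicParameters(
        state_costs_sek={
            s: {c: float(v) for c, v in comps.items()}
            for s, comps in d["state_costs_sek"].items()
        },
        utilities={s: float(u) for s, u in d["utilities"].items()},
        price_year=int(d["price_year"]),
        discount_rate=float(d["discount_rate"]),
        cpi_index={int(y): float(v) for y, v in d["cpi_index"].items()},
        usd_per_sek_divisor=float(d["usd_per_sek_divisor"]),
    )
    params.validate()
    return params
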