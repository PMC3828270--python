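"""Health-state topology for the metabolic-syndrome progression model."""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["STATES", "DIABETIC_STATES", "HealthStateModel", "default_state_model"]

STATES = (
    "at_risk",
    "diabetes",
    "diabetes_micro",
    "diabetes_macro",
    "mi",
    "stroke",
    "chd",
    "chf",
    "dead",
)

#: states in which the years-with-diabetes counter advances
DIABETIC_STATES = frozenset({"diabetes", "diabetes_micro", "diabetes_macro"})


@dataclass(frozen=True)
class HealthStateModel:
    """Directed state-transition graph with a single absorbing death state.

    Invariants enforced at construction: the absorbing state has no
    outgoing edges, every non-absorbing state has a self-edge, and every
    state reaches the absorbing state.
    """

    states: tuple[str, ...]
    transitions: dict[str, frozenset[str]]
    absorbing: frozenset[str] = field(default_factory=lambda: frozenset({"dead"}))

    def __post_init__(self) -> None:
        for s, succs in self.transitions.items():
            if s not in self.states:
                raise ValueError(f"unknown state in topology: {s!r}")
            for t in succs:
                if t not in self.states:
                    raise ValueError(f"unknown successor {t!r} of {s!r}")
        for a in self.absorbing:
            if self.transitions.get(a):
                raise ValueError(f"absorbing state {a!r} has outgoing edges")
        for s in self.states:
            if s in self.absorbing:
                continue
            if s not in self.transitions.get(s, frozenset()):
                raise ValueError(f"non-absorbing state {s!r} lacks a self-edge")
        # every state must reach an absorbing state
        for s in self.states:
            if s in self.absorbing:
                continue
            seen, stack = {s}, [s]
            while stack:
                cur = stack.pop()
                for t in self.transitions.get(cur, frozenset()):
                    if t in self.absorbing:
                        stack = []
                        seen.add("__dead_reachable__")
                        break
                    if t not in seen:
                        seen.add(t)
                        stack.append(t)
            if "__dead_reachable__" not in seen:
                raise ValueError(f"state {s!r} cannot reach an absorbing state")

    def successors(self, state: str) -> frozenset[str]:
        if state not in self.states:
            raise KeyError(f"unknown state: {state!r}")
        return self.transitions.get(state, frozenset())


def default_state_model() -> HealthStateModel:
    """Nine-state topology: at-risk → diabetes and cardiovascular events,
    diabetes → micro-/macro-vascular complications and events, events and
    complications chronic (self-loop) until death."""
    edges = {
        "at_risk": {"at_risk", "diabetes", "mi", "stroke", "chd", "chf", "dead"},
        "diabetes": {
            "diabetes", "diabetes_micro", "diabetes_macro",
            "mi", "stroke", "chd", "chf", "dead",
        },
        "diabetes_micro": {"diabetes_micro", "dead"},
        "diabetes_macro": {"diabetes_macro", "dead"},
        "mi": {"mi", "dead"},
        "stroke": {"stroke", "dead"},
        "chd": {"chd", "dead"},
        "chf": {"chf", "dead"},
        "dead": set(),
    }
    return HealthStateModel(
        states=STATES,
        transitions={s: frozenset(t) for s, t in edges.items()},
    )
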