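"""Health-state enumeration and transition-matrix construction.

The model tracks survivors of an acute myocardial infarction (MI) through
mutually exclusive health states over annual cycles.  Acute event states
("Non-fatal MI", "Non-fatal stroke" and their 2+ recurrence variants) are
tunnel states occupied for exactly one cycle; afterwards the cohort settles
into post-event maintenance states.  Composite states preserve the memory of
both an MI and a stroke history.  Revascularization is a costed procedure,
not a health state.  Death is split into cardiovascular and
non-cardiovascular causes; both are absorbing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np

__all__ = [
    "HealthState",
    "StateSpace",
    "TransitionMatrix",
    "build_state_space",
    "compose_state",
    "build_transition_matrix",
    "MI",
    "STROKE",
]

# Event labels used throughout the risk and economics layers.
MI = "MI"
STROKE = "stroke"

# Primitive event-history labels a composite can be built from.
_PRIMITIVE_HISTORIES = {
    "post_MI",
    "post_stroke",
    "acute_MI",
    "acute_MI_2plus",
    "acute_stroke",
    "acute_stroke_2plus",
}
_DEATH_HISTORIES = {"CV_death", "nonCV_death"}

CATEGORIES = {
    "acute_MI",
    "acute_MI_2plus",
    "acute_stroke",
    "acute_stroke_2plus",
    "post_MI",
    "post_stroke",
    "composite",
    "CV_death",
    "nonCV_death",
}


@dataclass(frozen=True)
class HealthState:
    """One mutually exclusive health state.

    ``components`` is non-empty only for composite states and holds the
    unordered primitive histories the composite is built from.  ``mi_history``
    / ``stroke_history`` record whether the cohort member carries that event
    in their past (including the event of the current acute tunnel), which is
    what routes recurrent events to the 2+ variants.
    """

    name: str
    category: str
    components: frozenset = frozenset()
    tunnel: bool = False
    mi_history: bool = False
    stroke_history: bool = False
    acute_event: str | None = None  # MI / stroke while in an acute tunnel
    recurrent: bool = False  # acute tunnel is a 2+ (second or later) event

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown state category {self.category!r}")
        if self.components and len(self.components) < 2:
            raise ValueError("composite component set must have >= 2 histories")

    @property
    def alive(self) -> bool:
        return self.category not in ("CV_death", "nonCV_death")

    @property
    def is_death(self) -> bool:
        return not self.alive

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "category": self.category,
            "tunnel": self.tunnel,
            "components": sorted(self.components),
        }


def _state(name, category, *, components=(), tunnel=False, mi=False,
           stroke=False, acute=None, recurrent=False) -> HealthState:
    return HealthState(
        name=name,
        category=category,
        components=frozenset(components),
        tunnel=tunnel,
        mi_history=mi,
        stroke_history=stroke,
        acute_event=acute,
        recurrent=recurrent,
    )


@dataclass(frozen=True)
class StateSpace:
    """Ordered collection of states plus name-based lookup."""

    states: tuple

    def __post_init__(self) -> None:
        names = [s.name for s in self.states]
        if len(names) != len(set(names)):
            raise ValueError("duplicate state names")

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(self.states)

    @property
    def names(self) -> list:
        return [s.name for s in self.states]

    def index(self, name: str) -> int:
        for i, s in enumerate(self.states):
            if s.name == name:
                return i
        raise KeyError(f"no state named {name!r}")

    def __getitem__(self, name: str) -> HealthState:
        return self.states[self.index(name)]

    @property
    def living(self) -> list:
        return [s for s in self.states if s.alive]

    def to_json(self, indent: int = 2) -> str:
        return json.dumps([s.to_dict() for s in self.states], indent=indent)


# Canonical state names (field vocabulary, used as CSV/JSON keys everywhere).
NONFATAL_MI = "Non-fatal MI"
NONFATAL_MI_2P = "Non-fatal MI 2+"
NONFATAL_STROKE = "Non-fatal stroke"
NONFATAL_STROKE_2P = "Non-fatal stroke 2+"
POST_MI = "Post-MI"
POST_STROKE = "Post-stroke"
POST_MI_POST_STROKE = "Post-MI + Post-stroke"
NONFATAL_MI_POST_STROKE = "Non-fatal MI + Post-stroke"
NONFATAL_MI_2P_POST_STROKE = "Non-fatal MI 2+ + Post-stroke"
NONFATAL_STROKE_POST_MI = "Non-fatal stroke + Post-MI"
NONFATAL_STROKE_2P_POST_MI = "Non-fatal stroke 2+ + Post-MI"
CV_DEATH = "CV death"
NONCV_DEATH = "Non-CV death"


def build_state_space() -> StateSpace:
    """Return the fixed model state space.

    Four pure acute tunnels, two post-event states, the post-event composite,
    four acute-over-post composites (an acute event striking someone who
    already carries the other event's history), and two absorbing death
    states.  Deeper histories collapse onto the 2+ variants.
    """
    states = (
        _state(NONFATAL_MI, "acute_MI", tunnel=True, mi=True, acute=MI),
        _state(NONFATAL_MI_2P, "acute_MI_2plus", tunnel=True, mi=True,
               acute=MI, recurrent=True),
        _state(NONFATAL_STROKE, "acute_stroke", tunnel=True, stroke=True,
               acute=STROKE),
        _state(NONFATAL_STROKE_2P, "acute_stroke_2plus", tunnel=True,
               stroke=True, acute=STROKE, recurrent=True),
        _state(POST_MI, "post_MI", mi=True),
        _state(POST_STROKE, "post_stroke", stroke=True),
        _state(POST_MI_POST_STROKE, "composite",
               components=("post_MI", "post_stroke"), mi=True, stroke=True),
        _state(NONFATAL_MI_POST_STROKE, "composite",
               components=("acute_MI", "post_stroke"), tunnel=True, mi=True,
               stroke=True, acute=MI),
        _state(NONFATAL_MI_2P_POST_STROKE, "composite",
               components=("acute_MI_2plus", "post_stroke"), tunnel=True,
               mi=True, stroke=True, acute=MI, recurrent=True),
        _state(NONFATAL_STROKE_POST_MI, "composite",
               components=("acute_stroke", "post_MI"), tunnel=True, mi=True,
               stroke=True, acute=STROKE),
        _state(NONFATAL_STROKE_2P_POST_MI, "composite",
               components=("acute_stroke_2plus", "post_MI"), tunnel=True,
               mi=True, stroke=True, acute=STROKE, recurrent=True),
        _state(CV_DEATH, "CV_death"),
        _state(NONCV_DEATH, "nonCV_death"),
    )
    return StateSpace(states=states)


def compose_state(history_a: str, history_b: str,
                  space: StateSpace | None = None) -> HealthState:
    """Combine two primitive event histories into their composite state.

    Commutative; composing with a death history is an error because death is
    absorbing and never combined with anything.
    """
    for h in (history_a, history_b):
        if h in _DEATH_HISTORIES:
            raise ValueError(f"cannot compose with absorbing state {h!r}")
        if h not in _PRIMITIVE_HISTORIES:
            raise ValueError(f"unknown primitive history {h!r}")
    if history_a == history_b:
        raise ValueError("composite histories must be distinct")
    if space is None:
        space = build_state_space()
    key = frozenset((history_a, history_b))
    for s in space:
        if s.components == key:
            return s
    raise ValueError(
        f"no composite state for histories {sorted(key)}; the packaged "
        "topology combines an acute or post event with the other event's "
        "post history only"
    )


# ---------------------------------------------------------------------------
# Transition routing
# ---------------------------------------------------------------------------

def _event_destination(space: StateSpace, state: HealthState, event: str) -> str:
    """Name of the acute tunnel a new MI/stroke routes to from ``state``."""
    if event == MI:
        recurrent = state.mi_history
        other = state.stroke_history
        if recurrent and other:
            return NONFATAL_MI_2P_POST_STROKE
        if recurrent:
            return NONFATAL_MI_2P
        if other:
            return NONFATAL_MI_POST_STROKE
        return NONFATAL_MI
    if event == STROKE:
        recurrent = state.stroke_history
        other = state.mi_history
        if recurrent and other:
            return NONFATAL_STROKE_2P_POST_MI
        if recurrent:
            return NONFATAL_STROKE_2P
        if other:
            return NONFATAL_STROKE_POST_MI
        return NONFATAL_STROKE
    raise ValueError(f"unknown event {event!r}")


def _residual_destination(state: HealthState) -> str:
    """Where a cohort member goes when nothing happens during the cycle.

    Acute tunnels advance to the post state carrying their full history;
    post states stay put.
    """
    if not state.tunnel:
        return state.name
    if state.mi_history and state.stroke_history:
        return POST_MI_POST_STROKE
    if state.acute_event == MI:
        return POST_MI
    return POST_STROKE


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic annual transition matrix for one cycle."""

    cycle_index: int
    space: StateSpace
    matrix: np.ndarray

    _ROW_TOL = 1e-12

    def __post_init__(self) -> None:
        m = self.matrix
        n = len(self.space)
        if m.shape != (n, n):
            raise ValueError(f"matrix shape {m.shape} != ({n}, {n})")
        if (m < 0).any():
            i, j = np.argwhere(m < 0)[0]
            raise ValueError(
                f"negative transition probability from "
                f"{self.space.names[i]!r} to {self.space.names[j]!r}"
            )
        rows = m.sum(axis=1)
        bad = np.abs(rows - 1.0) > self._ROW_TOL
        if bad.any():
            name = self.space.names[int(np.argmax(bad))]
            raise ValueError(f"row for state {name!r} sums to "
                             f"{rows[bad][0]!r}, not 1")

    def prob(self, frm: str, to: str) -> float:
        return float(self.matrix[self.space.index(frm), self.space.index(to)])


def _per_state(value, state_name: str, keys) -> dict:
    """Resolve flat-vs-per-state mapping inputs."""
    if not isinstance(value, Mapping):
        raise TypeError("expected a mapping")
    if set(value) & set(keys):  # flat mapping applied to every state
        return dict(value)
    return dict(value.get(state_name, {}))


def build_transition_matrix(
    space: StateSpace,
    event_probs: Mapping,
    mortality: Mapping,
    cycle_index: int = 0,
) -> TransitionMatrix:
    """Assemble one cycle's row-stochastic matrix.

    Parameters
    ----------
    event_probs
        Either ``{"MI": p, "stroke": p}`` applied to every living state, or a
        per-state mapping ``{state_name: {"MI": p, "stroke": p}}``.
    mortality
        Either ``{"cv": p, "noncv": p}`` applied to every living state, or a
        per-state mapping of the same shape.

    Death claims its probability first; if the competing event probabilities
    plus death exceed 1, the event probabilities are rescaled proportionally
    so the row sums to 1.  Residual mass advances acute tunnels to their post
    states and keeps post states in place.  Death rows are absorbing.
    """
    n = len(space)
    m = np.zeros((n, n))
    for i, s in enumerate(space):
        if s.is_death:
            m[i, i] = 1.0
            continue
        ev = _per_state(event_probs, s.name, (MI, STROKE))
        mort = _per_state(mortality, s.name, ("cv", "noncv"))
        p_cv = float(mort.get("cv", 0.0))
        p_noncv = float(mort.get("noncv", 0.0))
        probs = {e: float(ev.get(e, 0.0)) for e in (MI, STROKE)}
        for label, p in [("cv", p_cv), ("noncv", p_noncv), *probs.items()]:
            if p < 0:
                raise ValueError(
                    f"negative probability {p!r} for {label!r} in state "
                    f"{s.name!r}"
                )
            if p > 1:
                raise ValueError(
                    f"probability {p!r} for {label!r} in state {s.name!r} "
                    "exceeds 1"
                )
        p_death = p_cv + p_noncv
        if p_death > 1:
            raise ValueError(
                f"total death probability {p_death!r} exceeds 1 in state "
                f"{s.name!r}"
            )
        p_events = sum(probs.values())
        if p_death + p_events > 1 and p_events > 0:
            scale = (1.0 - p_death) / p_events
            probs = {e: p * scale for e, p in probs.items()}
            p_events = 1.0 - p_death
        m[i, space.index(CV_DEATH)] += p_cv
        m[i, space.index(NONCV_DEATH)] += p_noncv
        residual = 1.0 - p_death - p_events
        for e, p in probs.items():
            dest = _event_destination(space, s, e)
            if dest == s.name:
                # A same-type recurrence struck while already in that 2+
                # acute tunnel: acute states never self-transition, so the
                # mass advances with the tunnel (memory is unchanged).
                residual += p
            else:
                m[i, space.index(dest)] += p
        m[i, space.index(_residual_destination(s))] += max(residual, 0.0)
    return TransitionMatrix(cycle_index=cycle_index, space=space, matrix=m)
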