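"""Costs and utilities: states, events, drugs, perspectives.

Two payer perspectives are supported: ``healthcare`` counts direct medical
costs only; ``private_payer`` adds indirect costs (caregiver wage loss during
hospitalization and informal home care).  Combined health states take the
lowest utility and the highest cost of their components, except where an
explicit cost is configured for a composite.  Non-cardiovascular death is
costless; death from MI or stroke carries a one-time terminal cost charged on
the transition into cardiovascular death.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .state_space import MI, STROKE, HealthState, StateSpace

__all__ = [
    "HEALTHCARE",
    "PRIVATE_PAYER",
    "PERSPECTIVES",
    "Q2W_140",
    "QM_420",
    "REGIMENS",
    "CostSet",
    "UtilitySet",
    "composite_utility",
    "composite_cost",
    "perspective_cost",
    "annual_drug_cost",
    "convert_currency",
]

HEALTHCARE = "healthcare"
PRIVATE_PAYER = "private_payer"
PERSPECTIVES = (HEALTHCARE, PRIVATE_PAYER)

Q2W_140 = "Q2W_140"
QM_420 = "QM_420"
REGIMENS = (Q2W_140, QM_420)

#: Doses per year under each regimen's default calendar and 140 mg vials per
#: dose.  Q2W: one vial every 14 days; QM: three vials every month.
_DOSING = {Q2W_140: (365.25 / 14.0, 1), QM_420: (12.0, 3)}


def composite_utility(components: Iterable[float]) -> float:
    """Utility of a combined state: the lowest component utility."""
    values = list(components)
    if not values:
        raise ValueError("composite_utility requires a non-empty set")
    return min(values)


def composite_cost(components: Iterable[float]) -> float:
    """Cost of a combined state: the highest component cost."""
    values = list(components)
    if not values:
        raise ValueError("composite_cost requires a non-empty set")
    return max(values)


def perspective_cost(direct: float, indirect: float, perspective: str) -> float:
    """Collapse a (direct, indirect) cost pair under a payer perspective."""
    if direct < 0 or indirect < 0:
        raise ValueError("costs must be >= 0")
    if perspective == HEALTHCARE:
        return direct
    if perspective == PRIVATE_PAYER:
        return direct + indirect
    raise ValueError(f"unknown perspective {perspective!r}")


def annual_drug_cost(regimen: str, unit_price: float) -> float:
    """Annual acquisition cost from the per-140 mg unit price.

    Uses the default dosing calendar (26.09 doses/year for 140 mg Q2W, 12
    triple-vial doses/year for 420 mg QM).  The packaged parameter set carries
    the published annual costs directly; this calculator exists for price
    sweeps and is linear in the unit price.
    """
    if unit_price <= 0:
        raise ValueError("unit_price must be > 0")
    try:
        doses_per_year, units_per_dose = _DOSING[regimen]
    except KeyError:
        raise ValueError(f"unknown regimen {regimen!r}") from None
    return doses_per_year * units_per_dose * unit_price


def convert_currency(amount_cny: float, rate: float,
                     round_to_int: bool = True) -> float:
    """Convert CNY to USD at ``rate`` CNY per USD; headline values round to
    the nearest integer."""
    if rate <= 0:
        raise ValueError("exchange rate must be > 0")
    usd = amount_cny / rate
    return float(round(usd)) if round_to_int else usd


@dataclass(frozen=True)
class UtilitySet:
    """Per-state utilities in [0, 1] plus the adverse-event disutility.

    ``state_utilities`` maps state name -> utility.  Composite states not
    listed explicitly fall back to the minimum over ``component_utilities``
    of their primitive histories.
    """

    state_utilities: Mapping[str, float]
    component_utilities: Mapping[str, float] = field(default_factory=dict)
    ae_disutility: float = 0.0

    def __post_init__(self) -> None:
        for name, u in {**self.state_utilities,
                        **self.component_utilities}.items():
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"utility for {name!r} is {u!r}, outside "
                                 "[0, 1]")
        if self.ae_disutility > 0:
            raise ValueError("ae_disutility must be <= 0")

    def utility(self, state: HealthState) -> float:
        if state.is_death:
            return 0.0
        if state.name in self.state_utilities:
            return self.state_utilities[state.name]
        if state.components:
            try:
                return composite_utility(
                    self.component_utilities[c] for c in state.components
                )
            except KeyError as exc:
                raise KeyError(
                    f"no utility for component {exc.args[0]!r} of composite "
                    f"state {state.name!r}"
                ) from None
        raise KeyError(f"no utility configured for state {state.name!r}")


@dataclass(frozen=True)
class CostSet:
    """Annual state costs, per-event costs, and drug costs, all in CNY.

    ``state_direct`` / ``state_indirect`` map state name -> annual cost;
    composites without an explicit entry take the maximum over
    ``component_direct`` / ``component_indirect``.  ``event_direct`` /
    ``event_indirect`` hold per-occurrence costs for revascularization and
    the terminal cardiovascular-death costs keyed ``death_MI`` /
    ``death_stroke``.
    """

    state_direct: Mapping[str, float]
    state_indirect: Mapping[str, float]
    component_direct: Mapping[str, float] = field(default_factory=dict)
    component_indirect: Mapping[str, float] = field(default_factory=dict)
    event_direct: Mapping[str, float] = field(default_factory=dict)
    event_indirect: Mapping[str, float] = field(default_factory=dict)
    statin_annual: float = 0.0
    evolocumab_annual: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for table in (self.state_direct, self.state_indirect,
                      self.component_direct, self.component_indirect,
                      self.event_direct, self.event_indirect):
            for k, v in table.items():
                if v < 0:
                    raise ValueError(f"cost for {k!r} is negative")
        if self.statin_annual < 0:
            raise ValueError("statin_annual is negative")

    def _lookup(self, state: HealthState, explicit: Mapping,
                by_component: Mapping) -> float:
        if state.is_death:
            return 0.0  # ongoing death-state cost is zero by construction
        if state.name in explicit:
            return explicit[state.name]
        if state.components:
            values = [by_component[c] for c in state.components
                      if c in by_component]
            if not values:
                raise KeyError(f"no cost for composite state {state.name!r}")
            return composite_cost(values)
        raise KeyError(f"no cost configured for state {state.name!r}")

    def state_cost(self, state: HealthState, perspective: str) -> float:
        """Annual cost of occupying ``state`` under a perspective."""
        direct = self._lookup(state, self.state_direct, self.component_direct)
        indirect = self._lookup(state, self.state_indirect,
                                self.component_indirect)
        return perspective_cost(direct, indirect, perspective)

    def event_cost(self, event: str, perspective: str) -> float:
        direct = self.event_direct.get(event, 0.0)
        indirect = self.event_indirect.get(event, 0.0)
        return perspective_cost(direct, indirect, perspective)

    def cv_death_cost(self, from_state: HealthState, perspective: str) -> float:
        """One-time terminal cost of a cardiovascular death out of
        ``from_state``, attributed by the causing event history.

        States carrying both histories take the more expensive terminal
        event, consistent with the max-cost rule for combined states.
        """
        candidates = []
        if from_state.mi_history or from_state.acute_event == MI:
            candidates.append(self.event_cost("death_MI", perspective))
        if from_state.stroke_history or from_state.acute_event == STROKE:
            candidates.append(self.event_cost("death_stroke", perspective))
        if not candidates:
            return 0.0
        return composite_cost(candidates)
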