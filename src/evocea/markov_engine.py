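"""Cohort simulation: advance occupancy, accrue discounted rewards.

The cohort enters in a configurable state (default "Post-MI": survivors of
an acute MI starting therapy) and is pushed through annual cycles.  Each
cycle rebuilds the transition matrix at the attained age because mortality
is age-dependent, advances the occupancy vector, and accrues costs and
QALYs with a half-cycle correction (the average of beginning- and
end-of-cycle occupancy).  Rewards of cycle t are discounted by
``1/(1+d)**t``.

Mortality composition: cycle 0 uses the cohort's published death rates
(non-cardiovascular = all-cause minus cardiovascular when the cohort
publishes an all-cause rate); later cycles take non-cardiovascular mortality
from the life table at attained age and scale the cohort's cardiovascular
hazard by the life table's cardiovascular age gradient, anchored to 1 at the
starting age.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .economics import CostSet, UtilitySet, PERSPECTIVES, REGIMENS
from .risk_engine import (
    EffectSpec,
    EventRates,
    LifeTable,
    annual_ae_prob,
    apply_effects,
    mortality_at_age,
    prob_to_rate,
    rate_to_prob,
)
from .state_space import CV_DEATH, MI, POST_MI, STROKE, StateSpace, \
    build_transition_matrix

__all__ = [
    "STATINS",
    "COMBO",
    "ARMS",
    "RunConfig",
    "RiskModel",
    "EconModel",
    "CohortTrace",
    "run_cohort",
    "half_cycle_correct",
    "discount_factor",
]

STATINS = "statins"
COMBO = "statins_plus_evolocumab"
ARMS = (STATINS, COMBO)


def discount_factor(rate: float, cycle_index: int) -> float:
    """Annual-start discounting: ``1/(1+rate)**cycle_index``."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    return 1.0 / (1.0 + rate) ** cycle_index


def half_cycle_correct(start_occupancy: np.ndarray,
                       end_occupancy: np.ndarray) -> np.ndarray:
    """Element-wise mean of start- and end-of-cycle occupancy, the
    trapezoidal approximation to mid-cycle membership."""
    start = np.asarray(start_occupancy, dtype=float)
    end = np.asarray(end_occupancy, dtype=float)
    if start.shape != end.shape:
        raise ValueError("occupancy vectors have mismatched lengths")
    return 0.5 * (start + end)


@dataclass(frozen=True)
class RunConfig:
    """Everything that selects one model run."""

    start_age: float
    horizon: int = 25
    discount_rate_cost: float = 0.05
    discount_rate_qaly: float = 0.05
    perspective: str = "healthcare"
    arm: str = STATINS
    regimen: str = "Q2W_140"
    entry_state: str = POST_MI
    drug_half_cycle: bool = True

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        for name in ("discount_rate_cost", "discount_rate_qaly"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.perspective not in PERSPECTIVES:
            raise ValueError(f"unknown perspective {self.perspective!r}")
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.regimen not in REGIMENS:
            raise ValueError(f"unknown regimen {self.regimen!r}")


@dataclass(frozen=True)
class RiskModel:
    """Bundle of risk-engine outputs the cohort engine consumes."""

    baseline: EventRates
    effect: EffectSpec | None
    life_table: LifeTable


@dataclass(frozen=True)
class EconModel:
    """Bundle of economics inputs the cohort engine consumes."""

    costs: CostSet
    utilities: UtilitySet


@dataclass
class CohortTrace:
    """Per-cycle state occupancy and accumulated discounted rewards."""

    space: StateSpace
    start_age: float
    occupancy: np.ndarray  # (horizon+1, n_states)
    cost_increments: np.ndarray  # discounted CNY per cycle
    qaly_increments: np.ndarray  # discounted QALYs per cycle
    rv_events: np.ndarray  # expected revascularizations per cycle
    ae_events: np.ndarray  # expected injection-site reactions per cycle

    _SUM_TOL = 1e-10

    @property
    def discounted_cost(self) -> float:
        return float(self.cost_increments.sum())

    @property
    def discounted_qalys(self) -> float:
        return float(self.qaly_increments.sum())

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def validate(self) -> None:
        sums = self.occupancy.sum(axis=1)
        bad = np.abs(sums - 1.0) > self._SUM_TOL
        if bad.any():
            t = int(np.argmax(bad))
            raise AssertionError(
                f"occupancy at cycle {t} sums to {sums[t]!r}, not 1"
            )

    def to_frame(self) -> pd.DataFrame:
        """Trace export: cycle, age, per-state occupancy, discounted
        increments."""
        horizon = self.horizon
        df = pd.DataFrame(self.occupancy[:-1], columns=self.space.names)
        df.insert(0, "cycle", np.arange(horizon))
        df.insert(1, "age", self.start_age + np.arange(horizon))
        df["discounted_cost"] = self.cost_increments
        df["discounted_qalys"] = self.qaly_increments
        df["expected_rv"] = self.rv_events
        df["expected_ae"] = self.ae_events
        return df


def _check_support(config: RunConfig, table: LifeTable) -> None:
    last_age = config.start_age + config.horizon - 1
    if config.start_age < table.min_age or last_age > table.max_age:
        raise ValueError(
            f"horizon {config.horizon} from age {config.start_age} exceeds "
            f"life-table support [{table.min_age}, {table.max_age}]"
        )


def cycle_risk(config: RunConfig, space: StateSpace, risks: RiskModel,
               cycle_index: int):
    """Transition matrix and per-state revascularization probabilities for
    one cycle of one arm.

    Exposed separately from :func:`run_cohort` so the same matrices can be
    replayed by an external check (e.g. an individual-level simulation).
    """
    t = cycle_index
    table = risks.life_table
    baseline = risks.baseline
    effect = risks.effect if config.arm == COMBO else None
    age = config.start_age + t
    treated = apply_effects(baseline, effect, t)

    cv0_prob, _ = mortality_at_age(table, config.start_age)
    cv0_rate = prob_to_rate(cv0_prob) if cv0_prob > 0 else None
    if t == 0 or cv0_rate is None:
        cv_scale = 1.0
    else:
        cv_prob_t, _ = mortality_at_age(table, age)
        cv_scale = prob_to_rate(cv_prob_t) / cv0_rate

    if t == 0 and baseline.all_cause_death is not None:
        noncv_rate = baseline.all_cause_death - baseline.cv_death
        p_noncv = rate_to_prob(noncv_rate)
    else:
        _, p_noncv = mortality_at_age(table, age)

    event_probs = {}
    mortality = {}
    rv_prob = np.zeros(len(space))
    for s in space:
        if not s.alive:
            continue
        mult = baseline.state_multiplier(s)
        event_probs[s.name] = {
            MI: rate_to_prob(treated.nonfatal_mi * mult),
            STROKE: rate_to_prob(treated.nonfatal_stroke * mult),
        }
        mortality[s.name] = {
            "cv": rate_to_prob(treated.cv_death * mult * cv_scale),
            "noncv": p_noncv,
        }
        rv_prob[space.index(s.name)] = rate_to_prob(
            treated.revascularization * mult
        )
    matrix = build_transition_matrix(space, event_probs, mortality,
                                     cycle_index=t)
    return matrix, rv_prob


def cycle_matrices(config: RunConfig, space: StateSpace,
                   risks: RiskModel) -> list:
    """The per-cycle transition matrices a run would use."""
    _check_support(config, risks.life_table)
    return [cycle_risk(config, space, risks, t)[0]
            for t in range(config.horizon)]


def run_cohort(config: RunConfig, space: StateSpace, risks: RiskModel,
               econ: EconModel) -> CohortTrace:
    """Simulate the cohort for ``config.horizon`` annual cycles."""
    n = len(space)
    horizon = config.horizon
    _check_support(config, risks.life_table)

    entry = space.index(config.entry_state)
    occupancy = np.zeros((horizon + 1, n))
    occupancy[0, entry] = 1.0
    cost_inc = np.zeros(horizon)
    qaly_inc = np.zeros(horizon)
    rv_events = np.zeros(horizon)
    ae_events = np.zeros(horizon)
    utilities = np.array([econ.utilities.utility(s) for s in space])
    state_costs = np.array([
        0.0 if s.is_death else econ.costs.state_cost(s, config.perspective)
        for s in space
    ])
    rv_cost = econ.costs.event_cost("revascularization", config.perspective)
    death_costs = np.array([
        0.0 if s.is_death else
        econ.costs.cv_death_cost(s, config.perspective)
        for s in space
    ])
    cv_col = space.index(CV_DEATH)

    drug_annual = econ.costs.statin_annual
    ae_p = 0.0
    ae_disutility = 0.0
    if config.arm == COMBO:
        drug_annual += econ.costs.evolocumab_annual[config.regimen]
        if risks.effect is not None:
            ae_p = annual_ae_prob(risks.effect.ae_prob_26mo)
            ae_disutility = risks.effect.ae_disutility

    alive_mask = np.array([s.alive for s in space], dtype=float)

    for t in range(horizon):
        matrix, rv_prob = cycle_risk(config, space, risks, t)
        start = occupancy[t]
        end = start @ matrix.matrix
        occupancy[t + 1] = end
        if abs(end.sum() - 1.0) > 1e-10:
            raise AssertionError(
                f"occupancy lost mass at cycle {t}: sum {end.sum()!r}"
            )

        mid = half_cycle_correct(start, end)
        living_mass = float((mid * alive_mask).sum())
        drug_mass = living_mass if config.drug_half_cycle \
            else float((start * alive_mask).sum())

        exp_rv = float((mid * rv_prob).sum())
        exp_ae = living_mass * ae_p
        rv_events[t] = exp_rv
        ae_events[t] = exp_ae

        # One-time terminal costs on the inflow into cardiovascular death.
        cv_inflow_cost = float(
            (start * matrix.matrix[:, cv_col] * death_costs).sum()
        )

        cost = (
            float((mid * state_costs).sum())
            + exp_rv * rv_cost
            + drug_mass * drug_annual
            + cv_inflow_cost
        )
        qaly = float((mid * utilities).sum()) + exp_ae * ae_disutility

        cost_inc[t] = cost * discount_factor(config.discount_rate_cost, t)
        qaly_inc[t] = qaly * discount_factor(config.discount_rate_qaly, t)

    trace = CohortTrace(
        space=space,
        start_age=config.start_age,
        occupancy=occupancy,
        cost_increments=cost_inc,
        qaly_increments=qaly_inc,
        rv_events=rv_events,
        ae_events=ae_events,
    )
    trace.validate()
    return trace
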