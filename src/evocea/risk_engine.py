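"""Baseline risks, treatment effects, and mortality.

Baseline cardiovascular event rates are expressed per 100 patient-years, as
published for the source cohorts.  Two treatment-effect engines turn them
into treated rates:

* ``endpoint_HR`` — multiply each event rate by a trial hazard ratio, with
  separate year-1 and beyond-year-1 values.
* ``ldl_RR`` — surrogate modelling: the treated rate is
  ``r0 * RR ** dLDL`` where RR is the rate ratio per 1 mmol/l of LDL-C
  reduction and dLDL the absolute reduction achieved (mmol/l).

Mortality is competing: cardiovascular death (treatable in the ldl_RR
engine, RR 0.86 per mmol/l) versus non-cardiovascular death from an
age-indexed life table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .state_space import MI, STROKE, HealthState

__all__ = [
    "EventRates",
    "EffectSpec",
    "LifeTable",
    "rate_to_prob",
    "prob_to_rate",
    "split_mortality",
    "apply_endpoint_hr",
    "apply_ldl_rr",
    "apply_effects",
    "annual_ae_prob",
    "mortality_at_age",
]

ENDPOINT_HR = "endpoint_HR"
LDL_RR = "ldl_RR"

# Events a treatment effect can act on.
RV = "revascularization"
CV_DEATH_EVENT = "cv_death"


@dataclass(frozen=True)
class EventRates:
    """Annual event rates per 100 patient-years for one cohort.

    ``history_multipliers`` are hazard multipliers applied to every event
    rate for cohort members carrying the given prior event ("prior_MI",
    "prior_stroke").  Multipliers for two distinct histories stack
    multiplicatively.  Defaults are 1 (no adjustment); the published
    adjustment factors live in a supplement and enter as configuration.
    """

    nonfatal_mi: float
    nonfatal_stroke: float
    cv_death: float
    revascularization: float
    all_cause_death: float | None = None
    history_multipliers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("nonfatal_mi", "nonfatal_stroke", "cv_death",
                     "revascularization"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name!r} is negative")
        if self.all_cause_death is not None:
            if self.all_cause_death < 0:
                raise ValueError("all_cause_death rate is negative")
            if self.all_cause_death < self.cv_death:
                raise ValueError(
                    "all_cause_death rate below cv_death rate: inconsistent"
                )
        for k, v in self.history_multipliers.items():
            if v < 0:
                raise ValueError(f"history multiplier {k!r} is negative")

    def state_multiplier(self, state: HealthState) -> float:
        """Combined hazard multiplier for a state's prior-event history."""
        m = 1.0
        if state.mi_history:
            m *= self.history_multipliers.get("prior_MI", 1.0)
        if state.stroke_history:
            m *= self.history_multipliers.get("prior_stroke", 1.0)
        return m


@dataclass(frozen=True)
class EffectSpec:
    """One treatment-effect model for the add-on arm.

    ``effects`` maps event -> (year-1 value, beyond-year-1 value); values are
    hazard ratios in ``endpoint_HR`` mode and rate ratios per 1 mmol/l of
    LDL-C reduction in ``ldl_RR`` mode.  ``cv_death_effect`` follows the same
    convention (the surrogate engine's published value is 0.86 in both
    periods; the endpoint engine defaults to 1.0 because no combined
    cardiovascular-death HR is published, and that default should be treated
    as a conservative placeholder).
    """

    mode: str
    effects: Mapping[str, tuple]  # event -> (year1, beyond1)
    cv_death_effect: tuple = (1.0, 1.0)
    delta_ldl: float | None = None
    ae_prob_26mo: float = 0.0
    ae_disutility: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in (ENDPOINT_HR, LDL_RR):
            raise ValueError(f"unknown effect mode {self.mode!r}")
        for ev, pair in self.effects.items():
            if len(pair) != 2 or any(v <= 0 for v in pair):
                raise ValueError(f"effect for {ev!r} must be two positive "
                                 "values (year 1, beyond year 1)")
        if any(v <= 0 for v in self.cv_death_effect):
            raise ValueError("cv_death_effect values must be positive")
        if self.mode == LDL_RR:
            if self.delta_ldl is None or self.delta_ldl < 0:
                raise ValueError("ldl_RR mode requires delta_ldl >= 0")
        if not 0.0 <= self.ae_prob_26mo < 1.0:
            raise ValueError("ae_prob_26mo must be in [0, 1)")
        if self.ae_disutility > 0:
            raise ValueError("ae_disutility must be <= 0")

    def multiplier(self, event: str, cycle_index: int) -> float:
        """Rate multiplier for ``event`` during model cycle ``cycle_index``.

        Year-1 values apply to cycle 0 (time since treatment start).
        """
        if event == CV_DEATH_EVENT:
            pair = self.cv_death_effect
        else:
            pair = self.effects.get(event, (1.0, 1.0))
        base = pair[0] if cycle_index == 0 else pair[1]
        if self.mode == LDL_RR:
            return float(base) ** float(self.delta_ldl)
        return float(base)


def rate_to_prob(rate: float, cycle_years: float = 1.0) -> float:
    """Constant-hazard conversion of a per-100-patient-year rate to a
    per-cycle probability: ``1 - exp(-(rate/100) * cycle_years)``."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if cycle_years <= 0:
        raise ValueError("cycle_years must be > 0")
    p = 1.0 - math.exp(-(rate / 100.0) * cycle_years)
    return min(p, math.nextafter(1.0, 0.0))  # strictly below 1


def prob_to_rate(prob: float, cycle_years: float = 1.0) -> float:
    """Inverse of :func:`rate_to_prob` (per 100 patient-years)."""
    if not 0.0 <= prob < 1.0:
        raise ValueError("probability must be in [0, 1)")
    return -math.log(1.0 - prob) / cycle_years * 100.0


def split_mortality(all_cause: float, cv: float) -> float:
    """Non-cardiovascular probability = all-cause minus cardiovascular."""
    if cv > all_cause:
        raise ValueError(
            f"cardiovascular mortality {cv!r} exceeds all-cause "
            f"{all_cause!r}: inconsistent life table"
        )
    return max(all_cause - cv, 0.0)


def _apply(baseline: EventRates, spec: EffectSpec, cycle_index: int) -> EventRates:
    return replace(
        baseline,
        nonfatal_mi=baseline.nonfatal_mi * spec.multiplier(MI, cycle_index),
        nonfatal_stroke=(baseline.nonfatal_stroke
                         * spec.multiplier(STROKE, cycle_index)),
        revascularization=(baseline.revascularization
                           * spec.multiplier(RV, cycle_index)),
        cv_death=baseline.cv_death * spec.multiplier(CV_DEATH_EVENT, cycle_index),
        all_cause_death=None,  # no longer meaningful once CV death is scaled
    )


def apply_endpoint_hr(baseline: EventRates, spec: EffectSpec,
                      cycle_index: int) -> EventRates:
    """Treated rates under the clinical-endpoint hazard-ratio engine."""
    if spec.mode != ENDPOINT_HR:
        raise ValueError(f"spec mode is {spec.mode!r}, expected 'endpoint_HR'")
    return _apply(baseline, spec, cycle_index)


def apply_ldl_rr(baseline: EventRates, spec: EffectSpec,
                 cycle_index: int) -> EventRates:
    """Treated rates under the LDL-C surrogate engine (``r0 * RR**dLDL``)."""
    if spec.mode != LDL_RR:
        raise ValueError(f"spec mode is {spec.mode!r}, expected 'ldl_RR'")
    if spec.delta_ldl is None:
        raise ValueError("ldl_RR mode requires delta_ldl")
    return _apply(baseline, spec, cycle_index)


def apply_effects(baseline: EventRates, spec: EffectSpec | None,
                  cycle_index: int) -> EventRates:
    """Dispatch on the spec's mode; ``None`` means the comparator arm."""
    if spec is None:
        return baseline
    if spec.mode == ENDPOINT_HR:
        return apply_endpoint_hr(baseline, spec, cycle_index)
    return apply_ldl_rr(baseline, spec, cycle_index)


def annual_ae_prob(p_26mo: float) -> float:
    """Annualize a 26-month injection-site-reaction probability under a
    constant hazard: ``1 - (1 - p)**(12/26)``."""
    if not 0.0 <= p_26mo < 1.0:
        raise ValueError("p_26mo must be in [0, 1)")
    return 1.0 - (1.0 - p_26mo) ** (12.0 / 26.0)


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed all-cause annual death probability and the fraction of
    those deaths that are cardiovascular."""

    ages: np.ndarray
    all_cause: np.ndarray
    cv_fraction: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        ac = np.asarray(self.all_cause, dtype=float)
        cf = np.asarray(self.cv_fraction, dtype=float)
        if not (len(ages) == len(ac) == len(cf)):
            raise ValueError("life-table columns have unequal lengths")
        if ((ac < 0) | (ac > 1)).any():
            raise ValueError("all-cause probabilities must be in [0, 1]")
        if ((cf < 0) | (cf > 1)).any():
            raise ValueError("cv fractions must be in [0, 1]")
        beyond40 = ac[ages >= 40]
        if (np.diff(beyond40) < -1e-12).any():
            raise ValueError("all-cause mortality must be non-decreasing "
                             "beyond age 40")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "all_cause", ac)
        object.__setattr__(self, "cv_fraction", cf)

    @property
    def min_age(self) -> float:
        return float(self.ages[0])

    @property
    def max_age(self) -> float:
        return float(self.ages[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "age": self.ages.astype(int),
            "all_cause_prob": self.all_cause,
            "cv_fraction": self.cv_fraction,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LifeTable":
        required = {"age", "all_cause_prob", "cv_fraction"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"life table missing columns {sorted(missing)}")
        df = df.sort_values("age")
        return cls(
            ages=df["age"].to_numpy(dtype=float),
            all_cause=df["all_cause_prob"].to_numpy(dtype=float),
            cv_fraction=df["cv_fraction"].to_numpy(dtype=float),
        )


def mortality_at_age(table: LifeTable, age: float) -> tuple:
    """Age-specific (cardiovascular, non-cardiovascular) annual death
    probabilities; their sum is the table's all-cause value.  Ages outside
    the table's support raise rather than extrapolate."""
    if age < table.min_age or age > table.max_age:
        raise ValueError(
            f"age {age!r} outside life-table support "
            f"[{table.min_age}, {table.max_age}]"
        )
    i = int(np.searchsorted(table.ages, age, side="right") - 1)
    all_cause = float(table.all_cause[i])
    cv = all_cause * float(table.cv_fraction[i])
    return cv, split_mortality(all_cause, cv)
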