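"""Cost-effectiveness statistics and sensitivity analyses.

Assembles model inputs from a parameter set and population profile, runs
both arms, and summarizes: ICER and net monetary benefit against the
willingness-to-pay threshold (3x GDP per capita), one-way deterministic
sensitivity analysis (tornado), probabilistic sensitivity analysis with
cost-effectiveness acceptability curves, scenario sweeps, and a head-to-head
comparison of the two treatment-effect engines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .economics import (
    CostSet,
    HEALTHCARE,
    PERSPECTIVES,
    Q2W_140,
    QM_420,
    REGIMENS,
    UtilitySet,
)
from .markov_engine import (
    COMBO,
    EconModel,
    RiskModel,
    RunConfig,
    STATINS,
    run_cohort,
)
from .risk_engine import ENDPOINT_HR, LDL_RR, EffectSpec, EventRates, LifeTable
from .state_space import (
    MI,
    NONFATAL_MI,
    NONFATAL_MI_2P,
    NONFATAL_STROKE,
    NONFATAL_STROKE_2P,
    POST_MI,
    POST_MI_POST_STROKE,
    POST_STROKE,
    STROKE,
    StateSpace,
    build_state_space,
)
from .synthetic_data import Parameter, ParameterSet, PopulationProfile

__all__ = [
    "CEAResult",
    "PSAConfig",
    "PSAResult",
    "ScenarioSpec",
    "icer",
    "classify",
    "nmb",
    "assemble_event_rates",
    "assemble_effect_spec",
    "assemble_cost_set",
    "assemble_utility_set",
    "run_cea",
    "make_runner",
    "one_way_dsa",
    "default_dsa_ranges",
    "ParameterSampler",
    "sample_parameters",
    "run_psa",
    "run_scenarios",
    "compare_effect_engines",
    "HOSPITAL_TIERS",
]

# ICER flags.
ICER_OK = "icer"
DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"

HIGHLY_CE = "highly_cost_effective"
COST_EFFECTIVE = "cost_effective"
NOT_CE = "not_cost_effective"

DISCOUNT_KEY = "discount_rate"  # pseudo-parameter for DSA sweeps

#: Hospital-tier multipliers on direct event costs.  Synthetic stand-ins for
#: the yearbook's tiered hospitalization costs (roughly a 2.4x span from
#: county hospitals to those directly under the Health Commission), scaled
#: relative to the packaged national-average values.
HOSPITAL_TIERS = {
    "County hospitals": 0.60,
    "County-level municipal hospitals": 0.70,
    "Prefecture-level municipal hospitals": 0.95,
    "Provincial hospitals": 1.05,
    "Hospitals directly under the Health Commission": 1.45,
}


# ---------------------------------------------------------------------------
# ICER / NMB / classification
# ---------------------------------------------------------------------------

def icer(delta_cost: float, delta_qalys: float) -> tuple:
    """(flag, value).  The ratio is reported only when the incremental
    effect is non-zero; strict improvement at no extra cost is ``dominant``,
    strict worsening at no saving is ``dominated``, and a zero effect
    difference is flagged ``undefined`` rather than returned as infinity."""
    if delta_qalys == 0:
        return UNDEFINED, None
    if delta_qalys > 0 and delta_cost <= 0:
        return DOMINANT, None
    if delta_qalys < 0 and delta_cost >= 0:
        return DOMINATED, None
    return ICER_OK, delta_cost / delta_qalys


def classify(icer_value: float, gdp_per_capita: float) -> str:
    """WTP banding: below 1x GDP per capita is highly cost-effective,
    between 1x and 3x (boundary-inclusive) is cost-effective, above 3x is
    not cost-effective."""
    if gdp_per_capita <= 0:
        raise ValueError("gdp_per_capita must be > 0")
    if icer_value < gdp_per_capita:
        return HIGHLY_CE
    if icer_value <= 3.0 * gdp_per_capita:
        return COST_EFFECTIVE
    return NOT_CE


def nmb(delta_cost: float, delta_qalys: float, wtp: float) -> float:
    """Net monetary benefit ``wtp * dE - dC``; positive iff the ICER is
    below the threshold whenever dE > 0."""
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    return wtp * delta_qalys - delta_cost


@dataclass(frozen=True)
class CEAResult:
    """Base-case comparison of the two arms under one configuration."""

    population: str
    regimen: str
    perspective: str
    cost_statins: float
    cost_combo: float
    qalys_statins: float
    qalys_combo: float
    gdp_per_capita: float
    wtp: float

    @property
    def incremental_cost(self) -> float:
        return self.cost_combo - self.cost_statins

    @property
    def incremental_qalys(self) -> float:
        return self.qalys_combo - self.qalys_statins

    @property
    def icer_flag(self) -> str:
        return icer(self.incremental_cost, self.incremental_qalys)[0]

    @property
    def icer(self) -> float | None:
        return icer(self.incremental_cost, self.incremental_qalys)[1]

    @property
    def classification(self) -> str:
        flag, value = icer(self.incremental_cost, self.incremental_qalys)
        if flag == DOMINANT:
            return "dominant"
        if flag == DOMINATED:
            return "dominated"
        if flag == UNDEFINED:
            return UNDEFINED
        return classify(value, self.gdp_per_capita)

    def nmb(self, wtp: float | None = None) -> float:
        return nmb(self.incremental_cost, self.incremental_qalys,
                   self.wtp if wtp is None else wtp)

    def to_dict(self) -> dict:
        return {
            "population": self.population,
            "regimen": self.regimen,
            "perspective": self.perspective,
            "cost_statins": self.cost_statins,
            "cost_combo": self.cost_combo,
            "qalys_statins": self.qalys_statins,
            "qalys_combo": self.qalys_combo,
            "incremental_cost": self.incremental_cost,
            "incremental_qalys": self.incremental_qalys,
            "icer": self.icer,
            "icer_flag": self.icer_flag,
            "classification": self.classification,
            "nmb_at_wtp": self.nmb(),
        }


# ---------------------------------------------------------------------------
# Assembling model inputs from a parameter set
# ---------------------------------------------------------------------------

_RATE_LABELS = {
    "nonfatal_mi": "Nonfatal MI",
    "nonfatal_stroke": "Nonfatal stroke",
    "cv_death": "Cardiovascular-related death",
    "revascularization": "Coronary revascularization",
}


def assemble_event_rates(params: ParameterSet,
                         profile: PopulationProfile) -> EventRates:
    """Baseline event rates for a profile from its rate block."""
    group = f"event_rate_{profile.rates_source}"
    kwargs = {fieldname: params.value(group, label)
              for fieldname, label in _RATE_LABELS.items()}
    all_cause_key = f"{group}/All-cause mortality"
    all_cause = params[all_cause_key].value if all_cause_key in params \
        else None
    multipliers = {
        "prior_MI": params.value("adjustment", "Prior MI hazard multiplier"),
        "prior_stroke": params.value("adjustment",
                                     "Prior stroke hazard multiplier"),
    }
    return EventRates(all_cause_death=all_cause,
                      history_multipliers=multipliers, **kwargs)


_EFFECT_LABELS = {
    MI: ("Nonfatal MI (year 1)", "Nonfatal MI (beyond 1y)"),
    STROKE: ("Nonfatal stroke (year 1)", "Nonfatal stroke (beyond 1y)"),
    "revascularization": ("Coronary revascularization (year 1)",
                          "Coronary revascularization (beyond 1y)"),
}


def assemble_effect_spec(params: ParameterSet, profile: PopulationProfile,
                         regimen: str,
                         mode: str | None = None) -> EffectSpec:
    """Treatment-effect specification for the add-on arm.

    ``mode`` overrides the profile's engine (used by the engine
    comparison); otherwise the profile decides.
    """
    mode = mode or profile.effect_mode
    group = "hazard_ratio" if mode == ENDPOINT_HR else "rate_ratio"
    effects = {
        event: (params.value(group, y1), params.value(group, b1))
        for event, (y1, b1) in _EFFECT_LABELS.items()
    }
    if mode == ENDPOINT_HR:
        effects.update(profile.hr_overrides)
        cv_hr = params.value(
            "constant", "Cardiovascular death hazard ratio (endpoint engine)"
        )
        cv_effect = (cv_hr, cv_hr)
        delta = None
    else:
        cv_rr = params.value("rate_ratio", "Vascular causes of death")
        cv_effect = (cv_rr, cv_rr)
        delta = profile.delta(regimen)
        if delta is None:
            raise ValueError(
                f"profile {profile.name!r} has no LDL-C reduction for "
                f"regimen {regimen!r}"
            )
    return EffectSpec(
        mode=mode,
        effects=effects,
        cv_death_effect=cv_effect,
        delta_ldl=delta,
        ae_prob_26mo=params.value(
            "constant", "Injection site reaction, 26-month probability"),
        ae_disutility=params.value(
            "disutility", "Injection site reaction, disutility"),
    )


def assemble_cost_set(params: ParameterSet) -> CostSet:
    """Map the cost rows onto states and events.

    Acute 2+ tunnels reuse the first-event acute costs (no separate rows are
    published).  The post-MI + post-stroke composite takes its explicitly
    published cost rows; acute-over-post composites fall back to the
    max-of-components rule.
    """
    d = lambda label: params.value("direct_cost", label)  # noqa: E731
    i = lambda label: params.value("indirect_cost", label)  # noqa: E731
    mi_y1_d, mi_b_d = d("Nonfatal MI (year 1)"), d("Nonfatal MI (beyond 1y)")
    st_y1_d = d("Nonfatal stroke (year 1)")
    st_b_d = d("Nonfatal stroke (beyond 1y)")
    mi_y1_i = i("Nonfatal MI (year 1)")
    st_y1_i = i("Nonfatal stroke (year 1)")
    st_b_i = i("Nonfatal stroke (beyond 1y)")
    return CostSet(
        state_direct={
            NONFATAL_MI: mi_y1_d,
            NONFATAL_MI_2P: mi_y1_d,
            NONFATAL_STROKE: st_y1_d,
            NONFATAL_STROKE_2P: st_y1_d,
            POST_MI: mi_b_d,
            POST_STROKE: st_b_d,
            POST_MI_POST_STROKE: d("Stroke + Post MI"),
        },
        state_indirect={
            NONFATAL_MI: mi_y1_i,
            NONFATAL_MI_2P: mi_y1_i,
            NONFATAL_STROKE: st_y1_i,
            NONFATAL_STROKE_2P: st_y1_i,
            POST_MI: 0.0,  # no published indirect follow-up cost for MI
            POST_STROKE: st_b_i,
            POST_MI_POST_STROKE: i("Stroke + Post MI"),
        },
        component_direct={
            "acute_MI": mi_y1_d, "acute_MI_2plus": mi_y1_d,
            "acute_stroke": st_y1_d, "acute_stroke_2plus": st_y1_d,
            "post_MI": mi_b_d, "post_stroke": st_b_d,
        },
        component_indirect={
            "acute_MI": mi_y1_i, "acute_MI_2plus": mi_y1_i,
            "acute_stroke": st_y1_i, "acute_stroke_2plus": st_y1_i,
            "post_MI": 0.0, "post_stroke": st_b_i,
        },
        event_direct={
            "revascularization": d("Coronary revascularization"),
            "death_MI": d("Death due to MI"),
            "death_stroke": d("Death due to stroke"),
        },
        event_indirect={
            "revascularization": i("Coronary revascularization"),
            "death_MI": i("Death due to MI"),
            "death_stroke": i("Death due to stroke"),
        },
        statin_annual=params.value("drug_cost", "Statins"),
        evolocumab_annual={
            Q2W_140: params.value("drug_cost", "Evolocumab (140 mg/2W)"),
            QM_420: params.value("drug_cost", "Evolocumab (420 mg/M)"),
        },
    )


def assemble_utility_set(params: ParameterSet) -> UtilitySet:
    """Map the utility rows onto states; composites take the minimum of
    their components.  The acute 2+ tunnels use the published 2+ year-1
    values; post states use the beyond-1y first-event values (the packaged
    topology does not distinguish recurrence count in post states)."""
    u = lambda label: params.value("utility", label)  # noqa: E731
    comp = {
        "acute_MI": u("Nonfatal MI (year 1)"),
        "acute_MI_2plus": u("MI 2+ (year 1)"),
        "acute_stroke": u("Nonfatal stroke (year 1)"),
        "acute_stroke_2plus": u("Stroke 2+ (year 1)"),
        "post_MI": u("Nonfatal MI (beyond 1y)"),
        "post_stroke": u("Nonfatal stroke (beyond 1y)"),
    }
    return UtilitySet(
        state_utilities={
            NONFATAL_MI: comp["acute_MI"],
            NONFATAL_MI_2P: comp["acute_MI_2plus"],
            NONFATAL_STROKE: comp["acute_stroke"],
            NONFATAL_STROKE_2P: comp["acute_stroke_2plus"],
            POST_MI: comp["post_MI"],
            POST_STROKE: comp["post_stroke"],
        },
        component_utilities=comp,
        ae_disutility=params.value(
            "disutility", "Injection site reaction, disutility"),
    )


# ---------------------------------------------------------------------------
# Running a full CEA
# ---------------------------------------------------------------------------

def run_cea(
    params: ParameterSet,
    profile: PopulationProfile,
    life_table: LifeTable,
    regimen: str = Q2W_140,
    perspective: str = HEALTHCARE,
    *,
    space: StateSpace | None = None,
    horizon: int = 25,
    start_age: float | None = None,
    discount_rate: float | None = None,
    discount_rate_qaly: float | None = None,
    mode: str | None = None,
    entry_state: str = POST_MI,
    drug_half_cycle: bool = True,
) -> CEAResult:
    """Run both arms and summarize the incremental comparison."""
    space = space or build_state_space()
    baseline = assemble_event_rates(params, profile)
    effect = assemble_effect_spec(params, profile, regimen, mode=mode)
    econ = EconModel(costs=assemble_cost_set(params),
                     utilities=assemble_utility_set(params))
    d = params.value("constant", "Annual discount rate") \
        if discount_rate is None else discount_rate
    dq = d if discount_rate_qaly is None else discount_rate_qaly
    age = profile.start_age if start_age is None else start_age

    totals = {}
    for arm in (STATINS, COMBO):
        config = RunConfig(
            start_age=age, horizon=horizon, discount_rate_cost=d,
            discount_rate_qaly=dq, perspective=perspective, arm=arm,
            regimen=regimen, entry_state=entry_state,
            drug_half_cycle=drug_half_cycle,
        )
        risks = RiskModel(baseline=baseline, effect=effect,
                          life_table=life_table)
        trace = run_cohort(config, space, risks, econ)
        totals[arm] = (trace.discounted_cost, trace.discounted_qalys)

    return CEAResult(
        population=profile.name,
        regimen=regimen,
        perspective=perspective,
        cost_statins=totals[STATINS][0],
        cost_combo=totals[COMBO][0],
        qalys_statins=totals[STATINS][1],
        qalys_combo=totals[COMBO][1],
        gdp_per_capita=params.value("constant", "GDP per capita, CNY"),
        wtp=params.value("constant", "Willingness to pay per QALY, CNY"),
    )


def make_runner(
    params: ParameterSet,
    profile: PopulationProfile,
    life_table: LifeTable,
    regimen: str = Q2W_140,
    perspective: str = HEALTHCARE,
    **fixed,
) -> Callable:
    """Closure re-running the base case under parameter/config overrides.

    The returned callable accepts either a full replacement
    :class:`ParameterSet` (PSA) or a ``{key: value}`` override mapping whose
    keys are parameter keys plus the pseudo-key ``"discount_rate"`` (DSA).
    """

    def runner(overrides=None, **config) -> CEAResult:
        p = params
        cfg = dict(fixed)
        cfg.update(config)
        if isinstance(overrides, ParameterSet):
            p = overrides
        elif overrides:
            overrides = dict(overrides)
            if DISCOUNT_KEY in overrides:
                cfg["discount_rate"] = overrides.pop(DISCOUNT_KEY)
            if overrides:
                p = params.with_values(overrides)
        return run_cea(p, profile, life_table, regimen, perspective, **cfg)

    return runner


# ---------------------------------------------------------------------------
# One-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------

def default_dsa_ranges(params: ParameterSet,
                       profile: PopulationProfile) -> dict:
    """Parameters a one-way analysis varies for a given profile: every
    ranged row in the groups the profile actually uses, plus the discount
    rate swept over 0-8%."""
    groups = {"drug_cost", "direct_cost", "indirect_cost", "utility",
              "disutility", "adjustment"}
    groups.add("hazard_ratio" if profile.effect_mode == ENDPOINT_HR
               else "rate_ratio")
    groups.add(f"event_rate_{profile.rates_source}")
    ranges = {
        p.key: (p.low, p.high)
        for p in params
        if p.group in groups and p.low is not None and p.low != p.high
    }
    ranges[DISCOUNT_KEY] = (0.0, 0.08)
    return ranges


def one_way_dsa(model_runner: Callable, parameter_ranges: Mapping,
                wtp: float | None = None) -> pd.DataFrame:
    """Tornado table: re-run the base case at each parameter's low and high
    bound, holding the others fixed.

    Returns a frame with columns (parameter, low, high, icer_low, icer_high,
    spread) sorted by |spread| descending, ties broken by parameter name.
    Dominant/dominated runs contribute their net-monetary-benefit-equivalent
    ICER bound of 0 (dominant) so the spread stays finite; ``undefined``
    runs raise.
    """

    def _icer_of(result: CEAResult) -> float:
        flag, value = icer(result.incremental_cost, result.incremental_qalys)
        if flag == ICER_OK:
            return value
        if flag == DOMINANT:
            return 0.0
        raise ValueError(
            f"one-way run produced a {flag} comparison; ICER spread is "
            "not defined"
        )

    rows = []
    for name in sorted(parameter_ranges):
        low, high = parameter_ranges[name]
        try:
            r_low = _icer_of(model_runner({name: low}))
            r_high = _icer_of(model_runner({name: high}))
        except (ValueError, KeyError) as exc:
            raise ValueError(
                f"one-way bound for parameter {name!r} is outside its "
                f"domain: {exc}"
            ) from exc
        rows.append({
            "parameter": name,
            "low": low,
            "high": high,
            "icer_low": r_low,
            "icer_high": r_high,
            "spread": r_high - r_low,
        })
    df = pd.DataFrame(rows)
    df["abs_spread"] = df["spread"].abs()
    df = df.sort_values(["abs_spread", "parameter"],
                        ascending=[False, True], kind="mergesort")
    return df.drop(columns="abs_spread").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

_Z95 = 3.919927969080108  # width of a 95% interval in standard deviations


@dataclass(frozen=True)
class PSAConfig:
    """Monte Carlo settings: number of replications and the seed."""

    params: ParameterSet
    n_draws: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


def _sampler_for(p: Parameter) -> Callable:
    """Per-parameter sampling callable ``rng -> float``.

    Lognormal: median matched to the point value, sigma from the log-width
    of the 95% interval.  Gamma and beta: moment matching with
    sd = (high - low) / 3.92.  Negative-valued beta rows (disutilities) are
    sampled on their magnitude and negated.  Fixed or unranged rows return
    the point value.
    """
    if p.distribution == "fixed" or p.low is None or p.low == p.high:
        value = p.value
        return lambda rng: value

    if p.distribution == "lognormal":
        if p.value <= 0 or p.low <= 0:
            raise ValueError(f"lognormal parameter {p.key!r} needs positive "
                             "value and bounds")
        mu = math.log(p.value)
        sigma = (math.log(p.high) - math.log(p.low)) / _Z95
        return lambda rng: rng.lognormal(mu, sigma)

    if p.distribution == "gamma":
        sd = (p.high - p.low) / _Z95
        var = sd * sd
        if p.value <= 0 or var <= 0:
            raise ValueError(f"gamma parameter {p.key!r} needs positive "
                             "mean and variance")
        shape = p.value ** 2 / var
        scale = var / p.value
        return lambda rng: rng.gamma(shape, scale)

    if p.distribution == "beta":
        sign = -1.0 if p.value < 0 else 1.0
        mean = abs(p.value)
        sd = abs(p.high - p.low) / _Z95
        var = sd * sd
        if not 0.0 < mean < 1.0:
            raise ValueError(
                f"beta parameter {p.key!r} has mean {mean} outside (0, 1)"
            )
        if var >= mean * (1.0 - mean):
            raise ValueError(
                f"beta parameter {p.key!r}: interval too wide for a beta "
                "fit"
            )
        nu = mean * (1.0 - mean) / var - 1.0
        a, b = mean * nu, (1.0 - mean) * nu
        return lambda rng: sign * rng.beta(a, b)

    raise ValueError(f"unknown distribution {p.distribution!r}")


class ParameterSampler:
    """Draws full parameter-set realizations, independently per parameter,
    in deterministic (sorted-key) order so a seed fixes the sequence."""

    def __init__(self, params: ParameterSet, seed: int) -> None:
        self._params = params
        self._keys = sorted(params.keys())
        self._samplers = {k: _sampler_for(params[k]) for k in self._keys}
        self._rng = np.random.default_rng(seed)

    def draw(self) -> ParameterSet:
        values = {k: float(self._samplers[k](self._rng)) for k in self._keys}
        return self._params.with_values(values)


def sample_parameters(config: PSAConfig) -> ParameterSet:
    """One reproducible parameter draw (the first of the seeded sequence)."""
    return ParameterSampler(config.params, config.seed).draw()


@dataclass
class PSAResult:
    """Scatter of incremental (cost, QALY) pairs plus the CEAC."""

    scatter: pd.DataFrame  # draw, delta_cost, delta_qalys
    ceac: pd.DataFrame  # wtp, prob_cost_effective
    n_failures: int

    def prob_cost_effective(self, wtp: float) -> float:
        dc = self.scatter["delta_cost"].to_numpy()
        de = self.scatter["delta_qalys"].to_numpy()
        return float(np.mean(wtp * de - dc > 0))


def default_wtp_grid(wtp: float, n: int = 101) -> np.ndarray:
    """0 to 3x the threshold in ``n`` steps, always containing the
    threshold itself."""
    grid = np.linspace(0.0, 3.0 * wtp, n)
    if wtp not in grid:
        grid = np.sort(np.append(grid, wtp))
    return grid


def run_psa(model_runner: Callable, config: PSAConfig,
            wtp_grid: Sequence[float] | None = None) -> PSAResult:
    """Monte Carlo over the parameter distributions.

    Each replication draws one parameter set, reruns both arms, and records
    the incremental cost and QALYs; the CEAC is the fraction of draws with
    positive net monetary benefit at each willingness-to-pay value.  Draws
    on which the model fails are recorded and skipped.
    """
    if wtp_grid is None:
        wtp = config.params.value("constant",
                                  "Willingness to pay per QALY, CNY")
        wtp_grid = default_wtp_grid(wtp)
    wtp_grid = np.asarray(wtp_grid, dtype=float)

    sampler = ParameterSampler(config.params, config.seed)
    rows = []
    failures = 0
    for k in range(config.n_draws):
        draw = sampler.draw()
        try:
            result = model_runner(draw)
        except (ValueError, KeyError):
            failures += 1
            continue
        rows.append({
            "draw": k,
            "delta_cost": result.incremental_cost,
            "delta_qalys": result.incremental_qalys,
        })
    scatter = pd.DataFrame(rows,
                           columns=["draw", "delta_cost", "delta_qalys"])
    dc = scatter["delta_cost"].to_numpy()
    de = scatter["delta_qalys"].to_numpy()
    probs = [float(np.mean(lam * de - dc > 0)) for lam in wtp_grid]
    ceac = pd.DataFrame({"wtp": wtp_grid, "prob_cost_effective": probs})
    return PSAResult(scatter=scatter, ceac=ceac, n_failures=failures)


# ---------------------------------------------------------------------------
# Scenario analyses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioSpec:
    """Axes of the one-at-a-time scenario sweep."""

    horizons: Sequence[int] = (5, 10, 15, 20, 25, 30, 35)
    start_ages: Sequence[float | None] = (None, 65, 70, 75)  # None = base
    discount_rates: Sequence[float] = (0.03, 0.05, 0.06)
    statin_costs: Sequence[float] = (118.86, 2855.0, 5470.28)
    hospital_tiers: Mapping[str, float] = field(
        default_factory=lambda: dict(HOSPITAL_TIERS))


def run_scenarios(
    params: ParameterSet,
    profile: PopulationProfile,
    life_table: LifeTable,
    spec: ScenarioSpec | None = None,
    regimens: Sequence[str] = REGIMENS,
    perspectives: Sequence[str] = PERSPECTIVES,
    **base_config,
) -> pd.DataFrame:
    """One-at-a-time scenario grid over both regimens and perspectives.

    Each row varies a single axis from the base case and reports the ICER
    (or dominance flag) with its WTP classification.
    """
    spec = spec or ScenarioSpec()
    rows = []

    def record(axis, level, regimen, perspective, result: CEAResult) -> None:
        rows.append({
            "axis": axis,
            "level": level,
            "regimen": regimen,
            "perspective": perspective,
            "incremental_cost": result.incremental_cost,
            "incremental_qalys": result.incremental_qalys,
            "icer": result.icer,
            "icer_flag": result.icer_flag,
            "classification": result.classification,
        })

    for regimen in regimens:
        for perspective in perspectives:
            base = make_runner(params, profile, life_table, regimen,
                               perspective, **base_config)
            for h in spec.horizons:
                record("time_horizon", h, regimen, perspective,
                       base(horizon=h))
            for age in spec.start_ages:
                label = "base" if age is None else age
                record("starting_age", label, regimen, perspective,
                       base(start_age=age) if age is not None else base())
            for d in spec.discount_rates:
                record("discount_rate", d, regimen, perspective,
                       base(discount_rate=d))
            for c in spec.statin_costs:
                record("statin_annual_cost", c, regimen, perspective,
                       base({"drug_cost/Statins": c}))
            for tier, mult in spec.hospital_tiers.items():
                tier_params = params.scaled("direct_cost", mult)
                tier_runner = make_runner(tier_params, profile, life_table,
                                          regimen, perspective, **base_config)
                record("hospital_tier", tier, regimen, perspective,
                       tier_runner())
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Engine comparison
# ---------------------------------------------------------------------------

def compare_effect_engines(
    params: ParameterSet,
    profile: PopulationProfile,
    life_table: LifeTable,
    regimen: str = Q2W_140,
    perspective: str = HEALTHCARE,
    **config,
) -> dict:
    """Run the full CEA under both effect engines on the same baseline
    population and report the ratio of ICERs (endpoint / surrogate).

    The ratio is flagged non-computable when either engine yields a
    dominant, dominated, or undefined comparison.
    """
    results = {}
    for mode in (ENDPOINT_HR, LDL_RR):
        results[mode] = run_cea(params, profile, life_table, regimen,
                                perspective, mode=mode, **config)
    flag_hr, icer_hr = icer(results[ENDPOINT_HR].incremental_cost,
                            results[ENDPOINT_HR].incremental_qalys)
    flag_rr, icer_rr = icer(results[LDL_RR].incremental_cost,
                            results[LDL_RR].incremental_qalys)
    computable = flag_hr == ICER_OK and flag_rr == ICER_OK and icer_rr != 0
    return {
        "population": profile.name,
        "regimen": regimen,
        "perspective": perspective,
        "icer_endpoint_hr": icer_hr,
        "icer_ldl_rr": icer_rr,
        "flag_endpoint_hr": flag_hr,
        "flag_ldl_rr": flag_rr,
        "ratio": (icer_hr / icer_rr) if computable else None,
        "computable": computable,
        "result_endpoint_hr": results[ENDPOINT_HR],
        "result_ldl_rr": results[LDL_RR],
    }
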