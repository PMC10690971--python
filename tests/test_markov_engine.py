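"""Cohort engine: conservation, half-cycle correction, discounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evocea.economics import CostSet, UtilitySet
from evocea.markov_engine import (
    COMBO,
    EconModel,
    RiskModel,
    RunConfig,
    STATINS,
    discount_factor,
    half_cycle_correct,
    run_cohort,
)
from evocea.risk_engine import EventRates, LifeTable
from evocea.state_space import build_state_space
from evocea.synthetic_data import gen_life_table


def flat_life_table(all_cause=0.0):
    ages = np.arange(40.0, 111.0)
    return LifeTable(ages=ages,
                     all_cause=np.full(ages.shape, all_cause),
                     cv_fraction=np.full(ages.shape, 0.4))


def unit_econ(space, utility=1.0, state_cost=0.0):
    names = [s.name for s in space.living]
    return EconModel(
        costs=CostSet(
            state_direct={n: state_cost for n in names},
            state_indirect={n: 0.0 for n in names},
            evolocumab_annual={"Q2W_140": 0.0, "QM_420": 0.0},
        ),
        utilities=UtilitySet(state_utilities={n: utility for n in names}),
    )


def make_risks(mi=0.0, stroke=0.0, cv=0.0, rv=0.0, table=None):
    return RiskModel(
        baseline=EventRates(nonfatal_mi=mi, nonfatal_stroke=stroke,
                            cv_death=cv, revascularization=rv),
        effect=None,
        life_table=table if table is not None else flat_life_table(),
    )


class TestHalfCycle:
    def test_steady_state_is_fixed_point(self):
        v = np.array([0.2, 0.3, 0.5])
        np.testing.assert_array_equal(half_cycle_correct(v, v), v)

    def test_forced_average(self):
        np.testing.assert_allclose(
            half_cycle_correct([1.0, 0.0], [0.0, 1.0]), [0.5, 0.5])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            half_cycle_correct([1.0, 0.0], [1.0, 0.0, 0.0])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=3, max_size=3),
           st.lists(st.floats(0, 1), min_size=3, max_size=3))
    def test_preserves_total_mass(self, a, b):
        a, b = np.array(a), np.array(b)
        out = half_cycle_correct(a, b)
        assert out.sum() == pytest.approx((a.sum() + b.sum()) / 2)


class TestDiscounting:
    @pytest.mark.parametrize("rate, t, expected", [
        (0.0, 7, 1.0),
        (0.05, 0, 1.0),
        (0.05, 1, 1.0 / 1.05),
    ])
    def test_closed_form(self, rate, t, expected):
        assert discount_factor(rate, t) == pytest.approx(expected)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(-0.01, 1)


class TestRunCohort:
    def test_degenerate_cohort_earns_exactly_one_qaly(self, space):
        """No events, no deaths, utility 1, no cost, one undiscounted
        year: exactly 1.0 QALY and 0 cost."""
        config = RunConfig(start_age=61, horizon=1, discount_rate_cost=0.0,
                           discount_rate_qaly=0.0)
        trace = run_cohort(config, space, make_risks(), unit_econ(space))
        assert trace.discounted_qalys == pytest.approx(1.0, abs=1e-15)
        assert trace.discounted_cost == 0.0

    def test_null_treatment_symmetry(self, space):
        """With a null effect specification, both arms except for drug
        costs are identical."""
        risks = make_risks(mi=1.7, stroke=0.9, cv=2.2, rv=6.4,
                           table=gen_life_table(1))
        econ = unit_econ(space, utility=0.9, state_cost=100.0)
        traces = {}
        for arm in (STATINS, COMBO):
            config = RunConfig(start_age=61, horizon=10, arm=arm)
            traces[arm] = run_cohort(config, space, risks, econ)
        np.testing.assert_array_equal(traces[STATINS].occupancy,
                                      traces[COMBO].occupancy)
        assert traces[STATINS].discounted_qalys == \
            traces[COMBO].discounted_qalys

    def test_entry_state_holds_full_cohort(self, space):
        config = RunConfig(start_age=61, horizon=2)
        trace = run_cohort(config, space, make_risks(), unit_econ(space))
        assert trace.occupancy[0, space.index("Post-MI")] == 1.0
        assert trace.occupancy[0].sum() == 1.0

    @settings(max_examples=25, deadline=None)
    @given(mi=st.floats(0, 30), stroke=st.floats(0, 30),
           cv=st.floats(0, 30), rv=st.floats(0, 30),
           horizon=st.integers(1, 12))
    def test_occupancy_conserved_every_cycle(self, mi, stroke, cv, rv,
                                             horizon):
        space = build_state_space()
        risks = make_risks(mi=mi, stroke=stroke, cv=cv, rv=rv,
                           table=gen_life_table(2))
        config = RunConfig(start_age=65, horizon=horizon)
        trace = run_cohort(config, space, risks, unit_econ(space))
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0,
                                   atol=1e-10)

    def test_death_occupancy_non_decreasing(self, space):
        risks = make_risks(mi=2.0, stroke=1.0, cv=3.0, table=gen_life_table(3))
        config = RunConfig(start_age=61, horizon=25)
        trace = run_cohort(config, space, risks, unit_econ(space))
        for name in ("CV death", "Non-CV death"):
            col = trace.occupancy[:, space.index(name)]
            assert (np.diff(col) >= -1e-15).all()

    def test_qalys_non_increasing_in_discount_rate(self, space):
        risks = make_risks(mi=1.7, stroke=0.9, cv=2.2, table=gen_life_table(1))
        econ = unit_econ(space, utility=0.9)
        prev = np.inf
        for d in np.linspace(0.0, 0.08, 9):
            config = RunConfig(start_age=61, horizon=25,
                               discount_rate_cost=d, discount_rate_qaly=d)
            q = run_cohort(config, space, risks, econ).discounted_qalys
            assert q <= prev + 1e-12
            prev = q

    def test_longer_horizon_never_loses_undiscounted_qalys(self, space):
        risks = make_risks(mi=1.7, stroke=0.9, cv=2.2, table=gen_life_table(1))
        econ = unit_econ(space, utility=0.9)
        prev = 0.0
        for h in (1, 5, 10, 20, 30):
            config = RunConfig(start_age=61, horizon=h,
                               discount_rate_cost=0.0, discount_rate_qaly=0.0)
            q = run_cohort(config, space, risks, econ).discounted_qalys
            assert q >= prev - 1e-12
            prev = q

    def test_drug_costs_accrue_for_living_only(self, space):
        """With certain death in the first cycle the treated arm pays at
        most half a year of drug cost (half-cycle on a dying cohort)."""
        risks = RiskModel(
            baseline=EventRates(nonfatal_mi=0, nonfatal_stroke=0,
                                cv_death=1e9, revascularization=0),
            effect=None,
            life_table=flat_life_table(),
        )
        econ = EconModel(
            costs=CostSet(
                state_direct={s.name: 0.0 for s in space.living},
                state_indirect={s.name: 0.0 for s in space.living},
                statin_annual=1000.0,
            ),
            utilities=UtilitySet(
                state_utilities={s.name: 1.0 for s in space.living}),
        )
        config = RunConfig(start_age=61, horizon=3, discount_rate_cost=0.0)
        trace = run_cohort(config, space, risks, econ)
        assert trace.discounted_cost == pytest.approx(500.0, rel=1e-6)

    def test_horizon_beyond_life_table_rejected(self, space):
        config = RunConfig(start_age=100, horizon=30)
        with pytest.raises(ValueError, match="life-table support"):
            run_cohort(config, space, make_risks(table=gen_life_table(1)),
                       unit_econ(space))

    def test_trace_export_shape(self, space):
        config = RunConfig(start_age=61, horizon=4)
        trace = run_cohort(config, space, make_risks(mi=1.0, cv=1.0,
                                                     table=gen_life_table(1)),
                           unit_econ(space))
        df = trace.to_frame()
        assert len(df) == 4
        assert {"cycle", "age", "discounted_cost",
                "discounted_qalys"} <= set(df.columns)
        assert set(space.names) <= set(df.columns)


class TestMicrosimAgreement:
    def test_small_cohort_matches_microsimulation(self, space):
        """10,000-patient individual simulation agrees with the cohort
        trace within Monte Carlo error on a short run."""
        from conftest import microsimulate
        risks = make_risks(mi=5.0, stroke=3.0, cv=4.0, table=gen_life_table(1))
        config = RunConfig(start_age=61, horizon=8)
        trace = run_cohort(config, space, risks, unit_econ(space))
        n = 10_000
        occ = microsimulate(config, space, risks, n_patients=n, seed=42)
        se = np.sqrt(trace.occupancy * (1 - trace.occupancy) / n)
        assert (np.abs(occ - trace.occupancy) <= 3 * se + 1e-9).all()
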