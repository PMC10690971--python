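"""ICER/NMB statistics, tornado, PSA sampling, scenarios, engines."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evocea.cea_stats import (
    COST_EFFECTIVE,
    DOMINANT,
    DOMINATED,
    HIGHLY_CE,
    ICER_OK,
    NOT_CE,
    PSAConfig,
    ParameterSampler,
    UNDEFINED,
    assemble_cost_set,
    assemble_effect_spec,
    assemble_utility_set,
    classify,
    compare_effect_engines,
    default_dsa_ranges,
    icer,
    make_runner,
    nmb,
    one_way_dsa,
    run_cea,
    run_psa,
    sample_parameters,
)
from evocea.risk_engine import ENDPOINT_HR, LDL_RR
from evocea.synthetic_data import Parameter, ParameterSet, gen_population


class TestIcer:
    def test_ratio(self):
        assert icer(100.0, 1.0) == (ICER_OK, 100.0)

    def test_dominant_when_cheaper_and_better(self):
        assert icer(-5.0, 0.2) == (DOMINANT, None)

    def test_dominated_when_costlier_and_worse(self):
        assert icer(5.0, -0.2) == (DOMINATED, None)

    def test_zero_effect_is_undefined_not_infinite(self):
        assert icer(50.0, 0.0) == (UNDEFINED, None)


class TestClassify:
    @pytest.mark.parametrize("value, expected", [
        (137755.18, COST_EFFECTIVE),
        (40905.80, HIGHLY_CE),
        (3 * 85698 + 1, NOT_CE),
        (3 * 85698, COST_EFFECTIVE),  # boundary-inclusive
        (85698, COST_EFFECTIVE),
    ])
    def test_gdp_banding(self, value, expected):
        assert classify(value, 85698) == expected


class TestNmb:
    def test_zero_increments(self):
        assert nmb(0.0, 0.0, 257094) == 0.0

    def test_published_base_case_increments(self):
        assert nmb(48732.96, 0.35, 257094) == pytest.approx(41249.94)

    @settings(max_examples=100, deadline=None)
    @given(dc=st.floats(-1e5, 1e5), de=st.floats(1e-6, 2.0),
           wtp=st.floats(0, 1e6))
    def test_sign_agrees_with_icer_threshold_comparison(self, dc, de, wtp):
        value = icer(dc, de)[1]
        benefit = nmb(dc, de, wtp)
        if value is not None:
            assert (benefit > 0) == (value < wtp) or benefit == 0
        else:  # dominant: positive benefit at any positive threshold
            assert benefit >= 0


class TestAssembly:
    def test_effect_spec_follows_profile_mode(self, params, peace, berson):
        hr = assemble_effect_spec(params, peace, "Q2W_140")
        assert hr.mode == ENDPOINT_HR
        assert hr.effects["MI"] == (0.79, 0.64)
        rr = assemble_effect_spec(params, berson, "QM_420")
        assert rr.mode == LDL_RR
        assert rr.delta_ldl == 1.69
        assert rr.cv_death_effect == (0.86, 0.86)

    def test_composite_state_costs_and_utilities(self, params, space):
        costs = assemble_cost_set(params)
        utils = assemble_utility_set(params)
        both_post = space["Post-MI + Post-stroke"]
        # Explicitly published composite cost row wins over the max rule.
        assert costs.state_cost(both_post, "healthcare") == 13637.40
        # No published utility row: minimum of components.
        assert utils.utility(both_post) == 0.750
        # Acute-over-post composite: max cost / min utility of components.
        acute_over_post = space["Non-fatal stroke + Post-MI"]
        assert costs.state_cost(acute_over_post, "healthcare") == 13377.54
        assert utils.utility(acute_over_post) == 0.510

    def test_death_states_cost_and_utility_zero(self, params, space):
        costs = assemble_cost_set(params)
        utils = assemble_utility_set(params)
        for name in ("CV death", "Non-CV death"):
            assert costs.state_cost(space[name], "private_payer") == 0.0
            assert utils.utility(space[name]) == 0.0

    def test_private_payer_state_costs_dominate(self, params, space):
        costs = assemble_cost_set(params)
        for s in space.living:
            assert costs.state_cost(s, "private_payer") >= \
                costs.state_cost(s, "healthcare")


class TestBaseCase:
    def test_q2w_cheaper_than_qm_with_same_benefit_mechanism(
            self, params, peace, life_table):
        q2w = run_cea(params, peace, life_table, "Q2W_140")
        qm = run_cea(params, peace, life_table, "QM_420")
        assert q2w.icer < qm.icer
        assert q2w.incremental_qalys == pytest.approx(qm.incremental_qalys)

    def test_private_payer_never_cheaper_in_totals(self, params, peace,
                                                   life_table):
        hc = run_cea(params, peace, life_table, perspective="healthcare")
        pp = run_cea(params, peace, life_table, perspective="private_payer")
        assert pp.cost_statins >= hc.cost_statins
        assert pp.cost_combo >= hc.cost_combo


class TestTornado:
    def test_statin_cost_bounds_follow_quarter_rule(self, params):
        p = params["drug_cost/Statins"]
        assert (p.low, p.high) == (2141.25, 3568.75)

    def test_tornado_sorted_by_spread_with_zero_spread_last(
            self, params, peace, life_table):
        runner = make_runner(params, peace, life_table)
        ranges = {
            "drug_cost/Statins": (2141.25, 3568.75),
            "utility/Nonfatal stroke (beyond 1y)": (0.710, 0.800),
            "utility/MI 2+ (beyond 1y)": (0.940, 0.940),  # inert by design
        }
        table = one_way_dsa(runner, ranges)
        spreads = table["spread"].abs().to_numpy()
        assert (np.diff(spreads) <= 1e-9).all()
        assert table.iloc[-1]["spread"] == pytest.approx(0.0, abs=1e-9)

    def test_discount_sweep_increases_icer(self, params, peace, life_table):
        runner = make_runner(params, peace, life_table)
        low = runner({"discount_rate": 0.0}).icer
        high = runner({"discount_rate": 0.08}).icer
        assert low <= high

    def test_default_ranges_cover_engine_of_profile(self, params, peace,
                                                    berson):
        hr_keys = default_dsa_ranges(params, peace)
        assert any(k.startswith("hazard_ratio/") for k in hr_keys)
        assert not any(k.startswith("rate_ratio/") for k in hr_keys)
        rr_keys = default_dsa_ranges(params, berson)
        assert any(k.startswith("rate_ratio/") for k in rr_keys)

    def test_bad_bound_names_parameter(self, params, peace, life_table):
        runner = make_runner(params, peace, life_table)
        with pytest.raises((ValueError, KeyError),
                           match="Nonfatal stroke"):
            one_way_dsa(runner,
                        {"utility/Nonfatal stroke (beyond 1y)": (0.5, 1.2)})


class TestSampling:
    def test_fixed_parameters_always_at_point_value(self, params):
        draw = sample_parameters(PSAConfig(params=params, seed=5))
        assert draw.value("event_rate_peace", "Nonfatal MI") == 1.7
        assert draw.value("constant", "GDP per capita, CNY") == 85698

    def test_same_seed_identical_sequences(self, params):
        a = ParameterSampler(params, seed=11)
        b = ParameterSampler(params, seed=11)
        for _ in range(3):
            da, db = a.draw(), b.draw()
            for key in da.keys():
                assert da[key].value == db[key].value

    def test_lognormal_fit_matches_interval(self, params):
        """Draws of a lognormal effect match the published median and 95%
        interval by quantile."""
        rng_params = ParameterSet([
            Parameter("rate_ratio", "Nonfatal MI (beyond 1y)", 0.74,
                      0.70, 0.78, "lognormal"),
        ])
        sampler = ParameterSampler(rng_params, seed=123)
        draws = np.array([
            sampler.draw().value("rate_ratio", "Nonfatal MI (beyond 1y)")
            for _ in range(10_000)
        ])
        assert 0.70 <= np.median(draws) <= 0.78
        coverage = np.mean((draws >= 0.70) & (draws <= 0.78))
        assert coverage == pytest.approx(0.95, abs=0.01)

    def test_disutility_draws_stay_nonpositive(self, params):
        sampler = ParameterSampler(params, seed=2)
        key = "disutility/Injection site reaction, disutility"
        for _ in range(50):
            assert sampler.draw()[key].value <= 0.0

    def test_infeasible_beta_named(self):
        bad = ParameterSet([
            Parameter("utility", "implausible", 0.5, 0.0, 3.5, "beta"),
        ])
        with pytest.raises(ValueError, match="implausible"):
            ParameterSampler(bad, seed=0)


class TestPSA:
    def test_ceac_at_zero_wtp_is_fraction_of_cost_saving_draws(
            self, params, peace, life_table):
        runner = make_runner(params, peace, life_table)
        res = run_psa(runner, PSAConfig(params=params, n_draws=100, seed=9),
                      wtp_grid=[0.0, 257094.0])
        frac = float((res.scatter["delta_cost"] < 0).mean())
        at_zero = res.ceac.loc[res.ceac["wtp"] == 0.0,
                               "prob_cost_effective"].iloc[0]
        assert at_zero == pytest.approx(frac)

    def test_degenerate_psa_collapses_to_base_case(self, params, peace,
                                                   life_table):
        fixed = ParameterSet([
            Parameter(p.group, p.label, p.value) for p in params
        ])
        runner = make_runner(fixed, peace, life_table)
        base = runner()
        res = run_psa(runner, PSAConfig(params=fixed, n_draws=20, seed=1),
                      wtp_grid=np.linspace(0, 3 * 257094, 31))
        assert res.scatter["delta_cost"].nunique() == 1
        assert res.scatter["delta_cost"].iloc[0] == \
            pytest.approx(base.incremental_cost)
        # CEAC is the 0/1 step function around the base-case ICER.
        probs = res.ceac["prob_cost_effective"]
        assert set(probs.unique()) <= {0.0, 1.0}
        crossings = (res.ceac["wtp"] > base.icer) == (probs == 1.0)
        assert crossings.all()

    def test_ceac_monotone_when_all_draws_gain_qalys(self, params, peace,
                                                     life_table):
        runner = make_runner(params, peace, life_table)
        res = run_psa(runner, PSAConfig(params=params, n_draws=100, seed=4))
        if (res.scatter["delta_qalys"] > 0).all():
            probs = res.ceac["prob_cost_effective"].to_numpy()
            assert (np.diff(probs) >= 0).all()


class TestEngineComparison:
    def test_identical_multipliers_give_unit_ratio(self, params, life_table):
        """Forcing both engines to the same per-cycle multipliers (HRs set
        to the RRs, 1 mmol/l reduction, matching death effect) makes the
        ICERs coincide."""
        profile = gen_population("FOURIER")
        rr = {k.split("/")[1]: params[k]
              for k in params.keys() if k.startswith("rate_ratio/")}
        overrides = {}
        for label, p in rr.items():
            if label == "Vascular causes of death":
                overrides["constant/Cardiovascular death hazard ratio "
                          "(endpoint engine)"] = p.value
            else:
                overrides[f"hazard_ratio/{label}"] = p.value
        forced = params.with_values(overrides)
        profile = type(profile)(
            name=profile.name, start_age=profile.start_age,
            baseline_ldl=profile.baseline_ldl,
            effect_mode=profile.effect_mode,
            rates_source=profile.rates_source,
            delta_ldl={"Q2W_140": 1.0, "QM_420": 1.0},
            hr_overrides={},  # drop the overall-trial stroke substitution
        )
        rep = compare_effect_engines(forced, profile, life_table)
        assert rep["computable"]
        assert rep["ratio"] == pytest.approx(1.0, abs=1e-12)

    def test_packaged_trial_set_gives_ratio_above_one(self, params,
                                                      life_table):
        rep = compare_effect_engines(params, gen_population("FOURIER"),
                                     life_table)
        assert rep["computable"] and rep["ratio"] > 1.0

    def test_null_treatment_flagged_non_computable(self, params, life_table):
        profile = gen_population("FOURIER")
        null = params.with_values({
            f"hazard_ratio/{lbl}": 1.0
            for lbl in ("Nonfatal MI (year 1)", "Nonfatal MI (beyond 1y)",
                        "Nonfatal stroke (year 1)",
                        "Nonfatal stroke (beyond 1y)",
                        "Coronary revascularization (year 1)",
                        "Coronary revascularization (beyond 1y)")
        })
        null = null.with_values({
            f"rate_ratio/{lbl}": 1.0
            for lbl in ("Nonfatal MI (year 1)", "Nonfatal MI (beyond 1y)",
                        "Nonfatal stroke (year 1)",
                        "Nonfatal stroke (beyond 1y)",
                        "Coronary revascularization (year 1)",
                        "Coronary revascularization (beyond 1y)",
                        "Vascular causes of death")
        })
        rep = compare_effect_engines(null, profile, life_table)
        assert not rep["computable"]
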