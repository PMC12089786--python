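"""Rice-paddy CH4 simulator: substrate pool, redox dynamics, transport,
carbon conservation and the two-variant ensemble."""

import numpy as np
import pytest

from agghg import rice as rc


@pytest.fixture(scope="module")
def params_a() -> rc.RiceModelParams:
    return rc.load_variant("A")


@pytest.fixture(scope="module")
def params_b() -> rc.RiceModelParams:
    return rc.load_variant("B")


def _custom(**kw) -> rc.RiceModelParams:
    base = dict(variant_id="T", vi=0.27, q10=3.0, t_ref=30.0,
                eh_flood_min=-250.0, eh_oxic_max=300.0, eh_rate_flood=0.16,
                eh_rate_drain=0.25, eh_gate="linear", eh_full=-150.0,
                eh_zero=0.0, exudate_coeff=0.45, om_decay_rate=0.02,
                ox_frac_plant=0.55, ox_frac_diffusion=0.8,
                ebullition_threshold=0.2, k_b=120.0)
    base.update(kw)
    return rc.RiceModelParams(**base)


class TestSubstrate:
    def test_no_growth_no_amendment_no_substrate(self, params_a):
        n = 30
        s = rc.substrate_supply(np.full(n, 100.0), np.full(n, 30.0), params_a)
        np.testing.assert_array_equal(s, 0.0)

    def test_amended_pool_decays_exponentially(self):
        p = _custom(exudate_coeff=0.0, om_decay_rate=0.02)
        n = 3
        s = rc.substrate_supply(np.zeros(n), np.full(n, p.t_ref), p,
                                amendment_c=100.0, amendment_day=0)
        assert s[0] == pytest.approx(2.0)          # 100 x 0.02
        assert s[1] == pytest.approx(98.0 * 0.02)  # pool 98 after day 1

    def test_mass_closure_over_long_season(self):
        p = _custom(exudate_coeff=0.0)
        n = 500
        s = rc.substrate_supply(np.zeros(n), np.full(n, p.t_ref), p,
                                amendment_c=100.0)
        assert s.sum() == pytest.approx(100.0, rel=1e-3)

    def test_senescence_contributes_no_exudate(self):
        p = _custom(om_decay_rate=0.0)
        biomass = np.array([0.0, 10.0, 5.0, 5.0])
        with pytest.raises(ValueError):
            # SeasonInputs rejects decreasing biomass outright
            rc.SeasonInputs(np.full(4, 30.0), np.ones(4, bool), biomass)
        # the substrate operation itself clips the negative increment
        s = rc.substrate_supply(biomass, np.full(4, p.t_ref), p)
        assert s[2] == 0.0


class TestEhDynamics:
    def test_permanent_flooding_monotone_approach_to_floor(self, params_a):
        eh = rc.eh_dynamics(np.ones(120, bool), params_a, eh0=0.0)
        assert (np.diff(eh) < 1e-12).all()
        assert eh[-1] == pytest.approx(-250.0, abs=1.0)

    def test_bounded_under_alternating_regimes(self, params_a):
        flooded = (np.arange(200) % 14) < 7
        eh = rc.eh_dynamics(flooded, params_a)
        assert eh.min() >= -250.0 - 1e-9
        assert eh.max() <= 300.0 + 1e-9

    def test_daily_stepping_matches_analytic_solution(self):
        p = _custom(eh_rate_flood=0.3)
        t = np.arange(1, 61)
        eh = rc.eh_dynamics(np.ones(60, bool), p, eh0=0.0)
        analytic = -250.0 + (0.0 - (-250.0)) * np.exp(-0.3 * t)
        assert np.abs(eh - analytic).max() < 1.0


class TestProduction:
    def test_oxic_soil_shuts_production_off(self, params_a):
        prod = rc.daily_production(np.array([5.0]), np.array([30.0]),
                                   np.array([100.0]), params_a)
        assert prod[0] == 0.0

    def test_direct_evaluation_at_reference_conditions(self):
        p = _custom(vi=0.27)
        prod = rc.daily_production(np.array([1.0]), np.array([30.0]),
                                   np.array([-200.0]), p)
        assert prod[0] == pytest.approx(0.27)

    def test_q10_scaling_is_exact(self):
        p = _custom(q10=3.0)
        args = (np.array([1.0]), np.array([-200.0]))
        cold = rc.daily_production(np.array([1.0]), np.array([30.0]),
                                   args[1], p)
        warm = rc.daily_production(np.array([1.0]), np.array([40.0]),
                                   args[1], p)
        assert warm[0] == pytest.approx(3.0 * cold[0])

    def test_step_gate_variant_is_all_or_nothing(self, params_b):
        ehs = np.array([-200.0, -150.0, -149.0, 0.0])
        prod = rc.daily_production(np.ones(4), np.full(4, params_b.t_ref),
                                   ehs, params_b)
        assert prod[0] == prod[1] > 0
        assert prod[2] == prod[3] == 0.0


class TestTransport:
    def test_zero_biomass_means_no_plant_flux(self, params_a):
        parts = rc.partition_transport(np.array([1.0]), np.array([0.0]),
                                       params_a)
        assert parts["plant"][0] == 0.0

    def test_limiting_case_all_plant_transport(self):
        p = _custom(ox_frac_plant=0.5, ebullition_threshold=10.0)
        production = np.array([0.8])
        parts = rc.partition_transport(production, np.array([1e12]), p)
        emitted = parts["plant"] + parts["ebullition"] + parts["diffusion"]
        assert emitted[0] == pytest.approx(0.4, rel=1e-6)
        assert parts["ebullition"][0] == pytest.approx(0.0, abs=1e-9)

    def test_pathways_conserve_production(self, rng, params_a):
        production = rng.uniform(0, 2, 200)
        biomass = rng.uniform(0, 900, 200)
        parts = rc.partition_transport(production, biomass, params_a)
        total = sum(parts.values())
        np.testing.assert_allclose(total, production, atol=1e-12)
        for v in parts.values():
            assert (v >= 0).all()


def _season(params, flooded=None, amendment=150.0, n=100, temp=28.0):
    if flooded is None:
        flooded = np.ones(n, bool)
    inputs = rc.SeasonInputs(
        temperature=np.full(len(flooded), float(temp)),
        flooded=flooded,
        biomass=rc.logistic_biomass(len(flooded)),
        amendment_c=amendment, amendment_day=0)
    return rc.simulate_season(inputs, params)


class TestSeason:
    def test_fully_drained_season_emits_nothing(self, params_a):
        res = _season(params_a, flooded=np.zeros(100, bool))
        assert res.season_total == 0.0

    def test_carbon_closure(self, params_a, params_b):
        for p in (params_a, params_b):
            assert _season(p).carbon_closure_error() < 1e-12

    def test_midseason_drainage_lowers_the_season_total(self, params_a):
        flooded = np.ones(100, bool)
        drained = flooded.copy()
        drained[45:55] = False
        assert (_season(params_a, drained).season_total
                < _season(params_a, flooded).season_total)

    def test_monotone_in_amendment_and_flooded_days(self, params_a):
        totals = [_season(params_a, amendment=a).season_total
                  for a in (0.0, 50.0, 150.0, 300.0)]
        assert all(a <= b for a, b in zip(totals, totals[1:]))
        by_days = []
        for wet_until in (40, 60, 80, 100):
            fl = np.zeros(100, bool)
            fl[:wet_until] = True
            by_days.append(_season(params_a, fl).season_total)
        assert all(a <= b for a, b in zip(by_days, by_days[1:]))

    def test_half_step_integration_agrees_within_two_percent(self, params_a):
        daily = _season(params_a)
        n = 100
        # the same season advanced in half-day steps: drivers repeated,
        # per-day rates and thresholds halved, biomass interpolated
        half_params = rc.RiceModelParams(**{
            **params_a.__dict__,
            "eh_rate_flood": params_a.eh_rate_flood / 2,
            "eh_rate_drain": params_a.eh_rate_drain / 2,
            "om_decay_rate": params_a.om_decay_rate / 2,
            "ebullition_threshold": params_a.ebullition_threshold / 2,
        })
        biomass = rc.logistic_biomass(n)
        half_biomass = np.interp(np.arange(2 * n) / 2.0,
                                 np.arange(n, dtype=float), biomass)
        inputs = rc.SeasonInputs(
            temperature=np.full(2 * n, 28.0),
            flooded=np.ones(2 * n, bool),
            biomass=half_biomass, amendment_c=150.0, amendment_day=0)
        half = rc.simulate_season(inputs, half_params)
        assert half.season_total == pytest.approx(daily.season_total,
                                                  rel=0.02)


class TestEnsemble:
    def test_two_point_mean_and_relative_sd(self):
        mean, rel = rc.multi_model_mean([10.0, 14.0])
        assert mean == pytest.approx(12.0)
        assert rel == pytest.approx(np.sqrt(8.0) / 12.0, rel=1e-6)

    def test_identical_variants_have_zero_spread(self):
        _, rel = rc.multi_model_mean([np.ones(5) * 3, np.ones(5) * 3])
        np.testing.assert_array_equal(rel, 0.0)

    def test_scale_invariance_of_relative_sd(self, rng):
        a, b = rng.uniform(1, 5, 10), rng.uniform(1, 5, 10)
        _, rel1 = rc.multi_model_mean([a, b])
        _, rel2 = rc.multi_model_mean([7 * a, 7 * b])
        np.testing.assert_allclose(rel1, rel2, rtol=1e-12)

    def test_zero_mean_cells_defined_as_zero(self):
        _, rel = rc.multi_model_mean([np.array([0.0]), np.array([0.0])])
        assert rel == 0.0

    def test_single_variant_errors(self):
        with pytest.raises(ValueError):
            rc.multi_model_mean([np.ones(3)])

    def test_variants_differ_structurally(self, params_a, params_b):
        assert params_a.eh_gate != params_b.eh_gate
        assert _season(params_a).season_total != \
            _season(params_b).season_total
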