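"""Energy-balance livestock emissions and the manure-nitrogen ledger."""

import numpy as np
import pandas as pd
import pytest

from agghg import livestock as lv
from agghg.activity import ActivityDataset
from agghg.config import LIVESTOCK_CATEGORIES, RUMINANT_CATEGORIES
from agghg.synthetic import generate_activity_series
from agghg.config import SyntheticConfig


@pytest.fixture(scope="module")
def params() -> lv.LivestockParams:
    return lv.load_params()


class TestYmLookup:
    def test_default_table_values(self, params):
        table = params.ym_table_default
        assert lv.ym_from_de(55, table) == 7.0
        assert lv.ym_from_de(80, table) == 6.0
        assert lv.ym_from_de(62, table) == 7.0  # boundary belongs below

    def test_monotone_nonincreasing_in_digestibility(self, params):
        table = params.ym_table_default
        des = np.linspace(45, 85, 41)
        yms = [lv.ym_from_de(d, table) for d in des]
        assert all(a >= b for a, b in zip(yms, yms[1:]))

    @pytest.mark.parametrize("de", [40, 90])
    def test_out_of_range_digestibility_errors(self, de, params):
        with pytest.raises(ValueError):
            lv.ym_from_de(de, params.ym_table_default)


class TestPerHeadFactors:
    def test_enteric_ef_hand_arithmetic(self):
        assert lv.enteric_ch4_ef(250, 6.5) == pytest.approx(106.58, abs=0.01)

    def test_enteric_zero_ym_and_linearity_in_ge(self):
        assert lv.enteric_ch4_ef(250, 0.0) == 0.0
        assert lv.enteric_ch4_ef(500, 6.5) == pytest.approx(
            2 * lv.enteric_ch4_ef(250, 6.5))

    def test_volatile_solids_hand_arithmetic(self):
        assert lv.volatile_solids(250, 60, 0.04, 0.08) == pytest.approx(
            5.485, abs=1e-3)

    def test_volatile_solids_fully_digestible_limit(self):
        assert lv.volatile_solids(250, 100, 0.0, 0.08) == 0.0

    def test_volatile_solids_decreasing_in_digestibility(self):
        vs = [lv.volatile_solids(250, de, 0.04, 0.08)
              for de in (50, 60, 70, 80)]
        assert all(a > b for a, b in zip(vs, vs[1:]))

    def test_manure_ch4_ef_hand_arithmetic(self):
        ef = lv.manure_ch4_ef(5.485, 0.18, {"s": 1.0}, {"s": 20.0})
        assert ef == pytest.approx(48.28, abs=0.02)

    def test_manure_ch4_zero_mcf_and_share_split_invariance(self):
        assert lv.manure_ch4_ef(5.0, 0.2, {"s": 1.0}, {"s": 0.0}) == 0.0
        one = lv.manure_ch4_ef(5.0, 0.2, {"a": 1.0}, {"a": 15.0})
        split = lv.manure_ch4_ef(5.0, 0.2, {"a": 0.5, "b": 0.5},
                                 {"a": 15.0, "b": 15.0})
        assert one == pytest.approx(split)

    def test_manure_ch4_bad_shares_error(self):
        with pytest.raises(ValueError):
            lv.manure_ch4_ef(5.0, 0.2, {"a": 0.6, "b": 0.6},
                             {"a": 10.0, "b": 10.0})

    def test_n_excretion_hand_arithmetic(self):
        assert lv.n_excretion(250, 0.14, 0.10) == pytest.approx(99.7, abs=0.1)

    def test_n_excretion_full_retention_and_linearity_in_protein(self):
        assert lv.n_excretion(250, 0.14, 1.0) == 0.0
        assert lv.n_excretion(250, 0.28, 0.1) == pytest.approx(
            2 * lv.n_excretion(250, 0.14, 0.1))


class TestManureN2O:
    SYSTEMS = {"s1": {"ef3": 0.005, "frac_gas": 0.2, "frac_leach": 0.05},
               "s2": {"ef3": 0.02, "frac_gas": 0.1, "frac_leach": 0.0}}

    def test_single_system_direct_hand_arithmetic(self):
        out = lv.manure_n2o(100.0, {"s1": 1.0},
                            {"s1": {"ef3": 0.005, "frac_gas": 0.0,
                                    "frac_leach": 0.0}},
                            ef4=0.01, ef5=0.011)
        assert out["direct_n2o"] == pytest.approx(0.786, abs=1e-3)

    def test_all_zero_factors_give_zero_emissions(self):
        zero = {"s": {"ef3": 0.0, "frac_gas": 0.0, "frac_leach": 0.0}}
        out = lv.manure_n2o(100.0, {"s": 1.0}, zero, 0.0, 0.0)
        assert all(v == 0.0 for k, v in out.items() if "n2o" in k)

    def test_matches_per_system_loop_oracle(self, rng):
        for _ in range(20):
            shares_raw = rng.random(2)
            shares = dict(zip(self.SYSTEMS, shares_raw / shares_raw.sum()))
            nex = float(rng.uniform(1, 500))
            ef4, ef5 = rng.uniform(0, 0.05, 2)
            out = lv.manure_n2o(nex, shares, self.SYSTEMS, ef4, ef5)
            direct = sum(nex * shares[s] * self.SYSTEMS[s]["ef3"]
                         for s in shares) * lv.N_TO_N2O
            vol = sum(nex * shares[s] * self.SYSTEMS[s]["frac_gas"]
                      for s in shares) * ef4 * lv.N_TO_N2O
            assert out["direct_n2o"] == pytest.approx(direct, rel=1e-12)
            assert out["indirect_vol_n2o"] == pytest.approx(vol, rel=1e-12)

    def test_loss_fractions_exceeding_one_error(self):
        bad = {"s": {"ef3": 0.5, "frac_gas": 0.4, "frac_leach": 0.2}}
        with pytest.raises(ValueError):
            lv.manure_n2o(10.0, {"s": 1.0}, bad, 0.01, 0.011)


class TestManureExport:
    def _ledger(self, nex=100.0, direct=4.0, vol=5.0, leach=1.0):
        return pd.DataFrame({
            "year": [2000], "region": ["R1"], "category": ["swine"],
            "n_excreted": [nex], "n_direct_n2o_n": [direct],
            "n_volatilized": [vol], "n_leached": [leach]})

    def test_zero_application_fraction(self):
        out = lv.manure_n_for_cropland(self._ledger(), 0.0, {"R1": 0.5})
        assert out["n_applied_cropland"].iloc[0] == 0.0
        assert out["n_residual"].iloc[0] == pytest.approx(90.0)

    def test_half_of_residual_applied(self):
        out = lv.manure_n_for_cropland(self._ledger(), 0.5, {"R1": 0.5})
        assert out["n_applied_cropland"].iloc[0] == pytest.approx(45.0)

    def test_no_application_without_mixed_cells(self):
        out = lv.manure_n_for_cropland(self._ledger(), 0.5, {"R1": 0.0})
        assert out["n_applied_cropland"].iloc[0] == 0.0

    def test_ledger_closes_for_random_inputs(self, rng):
        n = 50
        nex = rng.uniform(10, 1000, n)
        frac = rng.uniform(0, 0.3, (3, n))
        ledger = pd.DataFrame({
            "year": 2000, "region": "R1", "category": "swine",
            "n_excreted": nex,
            "n_direct_n2o_n": nex * frac[0],
            "n_volatilized": nex * frac[1],
            "n_leached": nex * frac[2]})
        out = lv.manure_n_for_cropland(ledger, 0.7, {"R1": 1.0})
        assert lv.ledger_closure_error(out) < 1e-9


@pytest.fixture(scope="module")
def activity() -> ActivityDataset:
    cfg = SyntheticConfig(seed=21, grid_shape=(4, 6),
                          years=(1990, 1999), breakpoints=[1994, 1997],
                          n_regions=2)
    return generate_activity_series(cfg)


class TestVectorizedPipeline:

    def test_matches_naive_triple_loop_oracle(self, activity, params):
        emis, _ = lv.compute_livestock_emissions(activity, params)
        cat_ef = lv.category_emission_factors(params).set_index("category")
        heads = activity.livestock
        mms = activity.mms_shares
        check = emis.sample(60, random_state=0)
        for _, row in check.iterrows():
            y, r, c = row["year"], row["region"], row["category"]
            h = float(heads.query(
                "year == @y and region == @r and category == @c")
                ["value"].iloc[0])
            shares = mms.query("region == @r and category == @c")
            assert row["enteric_ch4"] == pytest.approx(
                h * cat_ef.loc[c, "enteric_ch4_ef"], rel=1e-12)
            if cat_ef.loc[c, "route"] == "tier2":
                mcf = sum(s["share"] * params.systems[s["system"]]["mcf"]
                          / 100.0 for _, s in shares.iterrows())
                manure = (h * cat_ef.loc[c, "vs_daily"] * 365.0
                          * cat_ef.loc[c, "b0"]
                          * params.constants["ch4_density"] * mcf)
            else:
                manure = h * cat_ef.loc[c, "manure_ch4_ef_fixed"]
            assert row["manure_ch4"] == pytest.approx(manure, rel=1e-12)
            ef3 = sum(s["share"] * params.systems[s["system"]]["ef3"]
                      for _, s in shares.iterrows())
            assert row["direct_n2o"] == pytest.approx(
                h * cat_ef.loc[c, "nex"] * ef3 * lv.N_TO_N2O, rel=1e-12)

    def test_homogeneous_degree_one_in_heads(self, activity, params):
        emis1, _ = lv.compute_livestock_emissions(activity, params)
        doubled = ActivityDataset(
            livestock=activity.livestock.assign(
                value=activity.livestock["value"] * 2),
            crop_area=activity.crop_area, n_rate=activity.n_rate,
            rice_area=activity.rice_area, mms_shares=activity.mms_shares)
        emis2, _ = lv.compute_livestock_emissions(doubled, params)
        for col in ("enteric_ch4", "manure_ch4", "direct_n2o"):
            np.testing.assert_allclose(emis2[col], 2 * emis1[col], rtol=1e-12)

    def test_nitrogen_ledger_closes(self, activity, params):
        _, ledger = lv.compute_livestock_emissions(activity, params)
        assert lv.ledger_closure_error(ledger) < 1e-9

    def test_enteric_dominates_manure_for_ruminants(self, activity, params):
        emis, _ = lv.compute_livestock_emissions(activity, params)
        rum = emis[emis["category"].isin(RUMINANT_CATEGORIES)]
        by_cat = rum.groupby("category")[["enteric_ch4", "manure_ch4"]].sum()
        assert (by_cat["enteric_ch4"] > by_cat["manure_ch4"]).all()

    def test_param_pack_validation_rejects_bad_loss_fractions(self, params):
        bad = lv.LivestockParams(
            constants=params.constants,
            ym_table_default=params.ym_table_default,
            categories=params.categories,
            systems={"s": {"mcf": 10.0, "ef3": 0.6, "frac_gas": 0.5,
                           "frac_leach": 0.0}},
            ef4=0.01, ef5=0.011)
        with pytest.raises(ValueError):
            bad.validate()
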