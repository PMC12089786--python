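"""End-to-end orchestration: synthesize, harmonize, estimate, aggregate.

Stage order: synthetic inputs -> activity harmonization (census anchoring,
final-year extrapolation) -> four subsector estimates (livestock CH4,
livestock N2O, cropland N2O, rice CH4) with the manure-N ledger linking
livestock to cropland -> CO2-eq aggregation and regional rollup ->
Monte-Carlo / structural uncertainty -> trend segmentation.  Every artifact
carries the configuration hash for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import aggregate as agg
from . import cropland as cl
from . import livestock as lv
from . import rice as rc
from . import synthetic as syn
from . import trends as tr
from .activity import (ActivityDataset, GeoLayers, apply_census_correction,
                       disaggregate_to_grid, extrapolate_recent,
                       interpolate_weight_maps)
from .config import (RICE_SEASONS, SUBSECTORS, RunConfig, SyntheticConfig,
                     child_seed)

CENSUS_YEARS = (1996, 2006, 2016)
KG_TO_TG = 1e-9

#: synthetic magnitudes of the minor N sources, as fractions of synthetic
#: fertilizer N (stand-ins for deposition/mineralization/residue/pasture maps)
MINOR_N_SOURCE_FRACTIONS = {
    "n_deposition": 0.15,
    "n_mineralization": 0.20,
    "n_residue": 0.10,
    "n_pasture_fert": 0.05,
}


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {"seed": config.seed, "synthetic": config.synthetic.to_dict(),
         "gwp": [config.gwp_ch4, config.gwp_n2o],
         "mc_draws": config.mc_draws,
         "bootstrap": [config.bootstrap_reps, config.bootstrap_k]},
        sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunArtifacts:
    """Everything a pipeline run produces."""

    config: RunConfig
    config_hash: str
    activity: ActivityDataset
    geography: GeoLayers
    livestock_emissions: pd.DataFrame
    n_ledger: pd.DataFrame
    cropland: cl.CroplandN2OResult
    ef_report: dict
    rice_regional: pd.DataFrame          # per (year, region, season, variant)
    national_gas: pd.DataFrame           # Tg gas, columns = subsectors
    national_co2eq: pd.DataFrame         # Tg CO2-eq, columns = subsectors
    total_co2eq: pd.Series               # Tg CO2-eq per year
    regional_co2eq: pd.DataFrame         # (year, region) totals, Tg CO2-eq
    trend: tr.TrendReport
    envelopes: Dict[str, agg.UncertaintyEnvelope]
    rice_relative_sd: float

    def subsector_means(self) -> pd.Series:
        return self.national_co2eq.mean(axis=0)

    #: totals below this (Tg CO2-eq, i.e. ~1 mg nationally) count as zero
    _ZERO_TG = 1e-12

    def shares_percent(self) -> Optional[Dict[str, int]]:
        """Integer subsector shares; None when the total is zero (undefined)."""
        means = self.subsector_means()
        if means.sum() <= self._ZERO_TG:
            return None
        return agg.rollup_shares(means.to_dict())

    def ch4_share_percent(self) -> Optional[int]:
        means = self.subsector_means()
        if means.sum() <= self._ZERO_TG:
            return None
        ch4 = means["livestock_ch4"] + means["cropland_ch4"]
        return agg.round_half_up(100.0 * ch4 / means.sum())

    def increase_percent(self) -> float:
        first, last = self.total_co2eq.iloc[0], self.total_co2eq.iloc[-1]
        if first <= self._ZERO_TG:
            return float("nan")
        return 100.0 * (last - first) / first


def _harmonize_livestock(activity: ActivityDataset, config: RunConfig
                         ) -> ActivityDataset:
    """Census-anchor each regional livestock series, then extrapolate the
    final year from the previous 5 years' OLS trend."""
    rng = np.random.default_rng(child_seed(config.seed, "census"))
    years = activity.years
    census_in_range = [y for y in CENSUS_YEARS if years[0] <= y <= years[-1]]
    heads = activity.livestock
    out = []
    for (region, cat), sub in heads.groupby(["region", "category"]):
        s = sub.set_index("year")["value"].sort_index()
        if census_in_range:
            anchors = {y: float(s.loc[y]) * rng.uniform(0.97, 1.03)
                       for y in census_in_range}
            s = apply_census_correction(s, anchors)
        if len(s) > config.extrapolate_n_back:
            s.iloc[-1] = extrapolate_recent(s.iloc[:-1],
                                            config.extrapolate_n_back)
        df = s.rename("value").reset_index()
        df["region"], df["category"] = region, cat
        out.append(df)
    corrected = pd.concat(out, ignore_index=True)[
        ["year", "region", "category", "value"]]
    return ActivityDataset(
        livestock=corrected, crop_area=activity.crop_area,
        n_rate=activity.n_rate, rice_area=activity.rice_area,
        mms_shares=activity.mms_shares)


def _productivity_scale(years: List[int], drift: float = 0.002) -> pd.Series:
    """Per-year livestock EF multiplier encoding slow productivity change.

    The final year is frozen at the penultimate year's value (static EFs
    alongside extrapolated activity).
    """
    scale = pd.Series(
        [1.0 + drift * (y - years[0]) for y in years], index=years)
    if len(years) >= 2:
        scale.iloc[-1] = scale.iloc[-2]
    return scale


def _regional_covariates(config: RunConfig, geo: GeoLayers,
                         regional_temp: pd.Series) -> pd.DataFrame:
    """Static per-region site covariates for the EF model (climate + soil)."""
    rng = np.random.default_rng(child_seed(config.seed, "site_covariates"))
    rows = []
    for region in geo.regions:
        rows.append({
            "region": region,
            "mat": float(regional_temp[region]),
            "map_": float(rng.uniform(400, 1600)),
            "soil_ph": float(rng.uniform(5.0, 8.0)),
            "soc": float(rng.uniform(8, 35)),
            "clay_frac": float(rng.uniform(0.1, 0.5)),
        })
    return pd.DataFrame(rows)


def _cropland_stage(config: RunConfig, activity: ActivityDataset,
                    ledger: pd.DataFrame, geo: GeoLayers,
                    regional_temp: pd.Series,
                    ef_surface=None) -> Tuple[cl.CroplandN2OResult, dict]:
    obs = syn.generate_ef_observations(config.synthetic, ef_surface)
    model = cl.train_ef_model(obs, seed=child_seed(config.seed, "ef_model"))

    area = activity.crop_area.rename(columns={"value": "area_ha"})
    rate = activity.n_rate.rename(columns={"value": "n_rate"})
    loads = area.merge(rate, on=["year", "region", "crop"])
    loads["n_fert_synthetic"] = loads["area_ha"] * loads["n_rate"]

    # manure N allocated to crops proportional to synthetic fertilizer N
    applied = ledger.groupby(["year", "region"])["n_applied_cropland"].sum()
    group_tot = loads.groupby(["year", "region"])["n_fert_synthetic"]\
        .transform("sum")
    frac = (loads["n_fert_synthetic"] / group_tot).to_numpy()
    keys = pd.MultiIndex.from_frame(loads[["year", "region"]])
    loads["n_fert_manure"] = frac * keys.map(applied).to_numpy()
    mixed = geo.mixed_share()
    no_mixed = loads["region"].map(lambda r: mixed[r] == 0)
    loads.loc[no_mixed, "n_fert_manure"] = 0.0
    for comp, f in MINOR_N_SOURCE_FRACTIONS.items():
        loads[comp] = f * loads["n_fert_synthetic"]

    cov_static = _regional_covariates(config, geo, regional_temp)
    covariates = loads.merge(cov_static, on="region", how="left")
    # EF model covariate n_rate is the per-ha application rate
    covariates["n_rate"] = loads["n_rate"]

    # static EFs for the extrapolated final year: predict the last year's
    # rows with the penultimate year's covariates
    years = sorted(loads["year"].unique())
    efs = np.empty(len(loads))
    for crop in loads["crop"].unique():
        sel = (loads["crop"] == crop).to_numpy()
        efs[sel] = model.predict(crop, covariates.loc[sel])
    if len(years) >= 2:
        last, prev = years[-1], years[-2]
        key = ["region", "crop"]
        idx_last = loads.index[loads["year"] == last]
        prev_map = pd.Series(
            efs[(loads["year"] == prev).to_numpy()],
            index=pd.MultiIndex.from_frame(
                loads.loc[loads["year"] == prev, key]))
        efs[idx_last] = prev_map.loc[
            pd.MultiIndex.from_frame(loads.loc[idx_last, key])].to_numpy()

    result = cl.compute_cropland_n2o(
        loads, model, covariates, frac_leach=config.frac_leach,
        ef5=config.ef5, ef_override=efs)
    return result, model.training_report()


def _rice_stage(config: RunConfig, activity: ActivityDataset,
                regional_daily_temp: pd.DataFrame,
                variants: Optional[List[rc.RiceModelParams]] = None
                ) -> pd.DataFrame:
    """Simulate both variants per (year, region, season); returns long frame
    with season totals (g CH4 m-2) and emissions (Tg CH4)."""
    if variants is None:
        variants = [rc.load_variant("A"), rc.load_variant("B")]
    area = activity.rice_area.set_index(["year", "region", "season"])["value"]
    temp_by = {k: g for k, g in regional_daily_temp.groupby(["year", "region"])}
    rows = []
    for (year, region), tdf in temp_by.items():
        temp_year = tdf.sort_values("day")["temp"].to_numpy()
        for season in RICE_SEASONS:
            start, end, _, _ = syn.SEASON_CALENDARS[season]
            flooded = syn.season_water_calendar(season)
            temp = temp_year[start - 1:end]
            inputs = rc.make_season_inputs(season, flooded, temp)
            a_ha = float(area.loc[(year, region, season)])
            for params in variants:
                res = rc.simulate_season(inputs, params)
                rows.append({
                    "year": year, "region": region, "season": season,
                    "variant": params.variant_id,
                    "season_total_g_m2": res.season_total,
                    # g/m2 x ha x 1e4 m2/ha -> g; x 1e-12 -> Tg
                    "emission_tg": res.season_total * a_ha * 1e4 * 1e-12,
                })
    return pd.DataFrame(rows)


def run_pipeline(config: Optional[RunConfig] = None,
                 seed: Optional[int] = None,
                 livestock_params: Optional[lv.LivestockParams] = None,
                 rice_variants: Optional[List[rc.RiceModelParams]] = None,
                 ef_surface=None) -> RunArtifacts:
    """Execute all stages in dependency order and return the artifacts.

    ``livestock_params``, ``rice_variants`` and ``ef_surface`` override the
    default parameter packs / true observation surface (used for alternative
    scenarios such as a zero-emission null run).
    """
    if config is None:
        config = RunConfig(seed=seed if seed is not None else 0)
    chash = config_hash(config)
    scfg = config.synthetic

    raw_activity = syn.generate_activity_series(scfg)
    geo = syn.generate_geography(scfg)
    climate = syn.generate_climate(scfg)
    activity = _harmonize_livestock(raw_activity, config)

    regional_daily = climate.regional_mean(geo.region_mask)
    regional_temp = regional_daily.groupby("region")["temp"].mean()

    # --- livestock CH4 + N2O with the manure-N ledger
    ef_scale = _productivity_scale(activity.years)
    mixed = geo.mixed_share().to_dict()
    lv_params = livestock_params or lv.load_params()
    lv_emis, ledger = lv.compute_livestock_emissions(
        activity, lv_params, application_frac=0.5, mixed_share=mixed,
        ef_scale=ef_scale)

    # --- cropland N2O (consumes the ledger's applied manure N)
    crop_res, ef_report = _cropland_stage(
        config, activity, ledger, geo, regional_temp, ef_surface)

    # --- rice CH4, two structural variants
    rice_reg = _rice_stage(config, activity, regional_daily, rice_variants)

    # --- national series per subsector, Tg gas
    lv_year = lv_emis.groupby("year")
    livestock_ch4 = (lv_year["enteric_ch4"].sum()
                     + lv_year["manure_ch4"].sum()) * KG_TO_TG
    livestock_n2o = (lv_year["direct_n2o"].sum()
                     + lv_year["indirect_vol_n2o"].sum()
                     + lv_year["indirect_leach_n2o"].sum()) * KG_TO_TG
    cropland_n2o = crop_res.by_year() * KG_TO_TG
    rice_variant_year = rice_reg.pivot_table(
        index="year", columns="variant", values="emission_tg", aggfunc="sum")
    rice_mean, rice_rel = rc.multi_model_mean(
        [rice_variant_year[c].to_numpy() for c in rice_variant_year.columns])
    cropland_ch4 = pd.Series(rice_mean, index=rice_variant_year.index)

    national_gas = pd.DataFrame({
        "livestock_ch4": livestock_ch4,
        "cropland_ch4": cropland_ch4,
        "cropland_n2o": cropland_n2o,
        "livestock_n2o": livestock_n2o,
    })
    national_co2eq = agg.to_co2eq(national_gas, config.gwp_ch4,
                                  config.gwp_n2o)
    total = national_co2eq.sum(axis=1)

    # --- regional totals (CO2-eq) for the rollup outputs
    def _by_region(df, cols, kg=True):
        g = df.groupby(["year", "region"])[cols].sum().sum(axis=1)
        return g * (KG_TO_TG if kg else 1.0)

    reg = pd.DataFrame({
        "livestock_ch4": _by_region(
            lv_emis, ["enteric_ch4", "manure_ch4"]) * config.gwp_ch4,
        "livestock_n2o": _by_region(
            lv_emis, ["direct_n2o", "indirect_vol_n2o",
                      "indirect_leach_n2o"]) * config.gwp_n2o,
    })
    crop_region = crop_res.loads[["year", "region"]].copy()
    crop_region["n2o"] = crop_res.total_kg()
    reg["cropland_n2o"] = (crop_region.groupby(["year", "region"])["n2o"]
                           .sum() * KG_TO_TG * config.gwp_n2o)
    rice_region = (rice_reg.groupby(["year", "region", "variant"])
                   ["emission_tg"].sum().groupby(["year", "region"]).mean())
    reg["cropland_ch4"] = rice_region * config.gwp_ch4
    regional_co2eq = reg.fillna(0.0)

    # --- trends on the national total
    trend = tr.analyze_series(
        total, n_rep=config.bootstrap_reps, k=config.bootstrap_k,
        seed=child_seed(config.seed, "bootstrap"))

    # --- uncertainty: MC for the EF-approach subsectors, structural for rice
    envelopes: Dict[str, agg.UncertaintyEnvelope] = {}
    for sub in ("livestock_ch4", "cropland_n2o", "livestock_n2o"):
        base = national_co2eq[sub].to_numpy()
        envelopes[sub] = agg.monte_carlo(
            lambda a, e, b=base: b * a * e,
            activity_cv=config.activity_cv[sub],
            ef_rel_sd=config.ef_rel_sd[sub],
            n=config.mc_draws,
            seed=child_seed(config.seed, f"mc_{sub}"),
        )
    rice_relative_sd = float(np.mean(rice_rel))

    return RunArtifacts(
        config=config, config_hash=chash, activity=activity, geography=geo,
        livestock_emissions=lv_emis, n_ledger=ledger, cropland=crop_res,
        ef_report=ef_report, rice_regional=rice_reg,
        national_gas=national_gas, national_co2eq=national_co2eq,
        total_co2eq=total, regional_co2eq=regional_co2eq, trend=trend,
        envelopes=envelopes, rice_relative_sd=rice_relative_sd)


def report(artifacts: RunArtifacts) -> dict:
    """Summary tables: subsector shares, stage slopes, ledger closure."""
    closure = lv.ledger_closure_error(artifacts.n_ledger)
    shares = artifacts.shares_percent()
    return {
        "config_hash": artifacts.config_hash,
        "subsector_mean_tg_co2eq":
            artifacts.subsector_means().round(3).to_dict(),
        "total_mean_tg_co2eq": float(artifacts.total_co2eq.mean()),
        "shares_percent": shares,
        "shares_undefined": shares is None,
        "ch4_share_percent": artifacts.ch4_share_percent(),
        "increase_percent": artifacts.increase_percent(),
        "peaks": artifacts.trend.peaks,
        "stage_slopes": artifacts.trend.stage_slopes.to_dict(orient="records"),
        "ledger_closure_max_rel_error": closure,
        "rice_relative_sd": artifacts.rice_relative_sd,
    }


def save_artifacts(artifacts: RunArtifacts, outdir,
                   fmt: str = "csv") -> None:
    """Write CSV/JSON (and optional NetCDF grids) with the config hash."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": artifacts.config_hash}
    artifacts.national_gas.assign(**meta).to_csv(
        out / "national_gas_tg.csv")
    artifacts.national_co2eq.assign(**meta).to_csv(
        out / "national_co2eq_tg.csv")
    artifacts.regional_co2eq.reset_index().assign(**meta).to_csv(
        out / "regional_co2eq_tg.csv", index=False)
    artifacts.n_ledger.assign(**meta).to_csv(
        out / "nitrogen_ledger.csv", index=False)
    (out / "trend_report.json").write_text(json.dumps(
        {**meta, **artifacts.trend.to_dict()}, indent=2, default=str))
    (out / "run_report.json").write_text(json.dumps(
        {**meta, **report(artifacts)}, indent=2, default=str))
    env = {
        sub: {"mean": e.mean.tolist(), "sd": e.sd.tolist(),
              "p2_5": e.p2_5.tolist(), "p97_5": e.p97_5.tolist(),
              "n_draws": e.n_draws, "inputs": e.inputs}
        for sub, e in artifacts.envelopes.items()}
    env["cropland_ch4"] = {"relative_sd": artifacts.rice_relative_sd,
                           "method": "structural (ensemble sd / mean)"}
    (out / "uncertainty.json").write_text(
        json.dumps({**meta, **env}, indent=2))
    if fmt == "netcdf":
        _save_grids(artifacts, out)


def _save_grids(artifacts: RunArtifacts, out: Path) -> None:
    """Period-mean gridded CO2-eq per subsector, via weight interpolation."""
    import xarray as xr

    geo = artifacts.geography
    years = artifacts.national_co2eq.index
    mid_year = int(np.median(years))
    group_of = {"livestock_ch4": "livestock", "livestock_n2o": "livestock",
                "cropland_n2o": "cropland", "cropland_ch4": "rice"}
    by = artifacts.regional_co2eq.groupby("region").mean()
    data = {}
    for sub in SUBSECTORS:
        g = group_of[sub]
        w = interpolate_weight_maps(
            geo.weights[2010][g], geo.weights[2015][g], mid_year,
            2010, 2015, geo.region_mask)
        totals = by[sub].to_dict()
        data[sub] = (("row", "col"), disaggregate_to_grid(
            totals, w, geo.region_mask, geo.regions))
    ds = xr.Dataset(data, attrs={"config_hash": artifacts.config_hash,
                                 "units": "Tg CO2-eq yr-1 per cell"})
    ds.to_netcdf(out / "gridded_mean_co2eq.nc", engine="scipy")
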