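"""Synthetic activity world with known ground truth.

The real inventory draws on agricultural yearbooks, livestock censuses and
global gridded livestock maps.  None of those can ship with the package, so
this module generates structurally equivalent inputs — a 44-year annual
record of livestock numbers, crop sown areas, fertilizer-N rates and rice
areas for a handful of block regions on a toy raster, two base-year spatial
weight maps, a production-system classification, daily climate drivers and a
table of N2O emission-factor field observations drawn from a known response
surface.  Every generator is seeded through a per-output child stream, so the
ground truth behind each component is reproducible and independently
regenerable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import xarray as xr

from .activity import ActivityDataset, GeoLayers
from .config import (
    ACTIVITY_GROUPS,
    CROP_TYPES,
    LIVESTOCK_CATEGORIES,
    RICE_SEASONS,
    SyntheticConfig,
    child_seed,
)

MANURE_SYSTEMS: Tuple[str, ...] = (
    "pasture_range",
    "solid_storage",
    "liquid_slurry",
    "anaerobic_lagoon",
    "daily_spread",
)

WEIGHT_BASE_YEARS: Tuple[int, int] = (2010, 2015)

# Base national levels in the first year (order of magnitude only; the toy
# world is not a census).  Heads for livestock, kha for areas, kg N/ha rates.
_BASE_LEVELS: Dict[str, Dict[str, float]] = {
    "livestock": {
        "dairy_cattle": 2.0e6,
        "non_dairy_cattle": 5.0e7,
        "buffalo": 2.0e7,
        "sheep": 1.0e8,
        "goats": 8.0e7,
        "swine": 3.0e8,
        "camel": 4.0e5,
        "mules": 4.0e6,
        "donkeys": 8.0e6,
        "horses": 1.0e7,
        "poultry": 2.0e9,
        "rabbit": 1.0e8,
    },
    "crop_area": {
        "rice": 3.2e7,
        "wheat": 2.8e7,
        "maize": 2.2e7,
        "soybean": 8.0e6,
        "cotton": 5.0e6,
        "rapeseed": 5.5e6,
        "vegetables": 1.0e7,
        "fruits": 4.0e6,
        "potato": 4.5e6,
        "sugarcane": 1.5e6,
    },
    "n_rate": {c: r for c, r in zip(
        CROP_TYPES, (150, 180, 170, 60, 200, 140, 260, 240, 110, 190))},
    "rice_area": {"early": 7.0e6, "middle": 1.8e7, "late": 7.0e6},
}

_GROUP_ITEMS: Dict[str, Tuple[str, ...]] = {
    "livestock": LIVESTOCK_CATEGORIES,
    "crop_area": CROP_TYPES,
    "n_rate": CROP_TYPES,
    "rice_area": RICE_SEASONS,
}


def _region_shares(n_regions: int, rng: np.random.Generator) -> np.ndarray:
    """Fixed regional split of national totals, denser in 'eastern' regions."""
    base = np.linspace(2.0, 1.0, n_regions)
    jitter = rng.uniform(0.85, 1.15, n_regions)
    s = base * jitter
    return s / s.sum()


def _piecewise_log_trend(config: SyntheticConfig, rates: List[float]) -> np.ndarray:
    """Cumulative log-level relative to the first year.

    The increment from year y to y+1 uses the rate of the stage containing
    [y, y+1]; within each stage the log series is exactly linear with the
    configured rate, so stage-wise OLS log-slopes recover the config exactly
    when the breakpoint overshoot is switched off.  A positive
    ``breakpoint_overshoot`` adds a one-year log bump at each breakpoint
    where growth slows, proportional to the drop in growth rate — the
    boom-bust / statistical-revision spike that makes regime-transition
    years genuine local maxima of aggregate series.
    """
    years = np.asarray(config.year_index)
    edges = [config.years[0], *config.breakpoints, config.years[1]]
    inc = np.zeros(len(years))
    for i, y in enumerate(years[:-1]):
        stage = np.searchsorted(edges[1:-1], y, side="right")
        inc[i + 1] = rates[stage]
    trend = np.cumsum(inc)
    if config.breakpoint_overshoot > 0:
        for s, b in enumerate(config.breakpoints):
            drop = rates[s] - rates[s + 1]
            if drop > 0:
                trend = trend + np.where(
                    years == b, config.breakpoint_overshoot * drop, 0.0)
    return trend


def generate_activity_series(config: SyntheticConfig) -> ActivityDataset:
    """Generate the annual, region-resolved activity record.

    Noise-free expectations are piecewise-exponential per stage; multiplicative
    lognormal noise (mean 1, CV ``config.noise_cv``) is applied on top, keeping
    every quantity strictly positive.
    """
    rng = np.random.default_rng(child_seed(config.seed, "activity"))
    shares = _region_shares(config.n_regions, rng)
    years = config.year_index
    regions = [f"R{i+1}" for i in range(config.n_regions)]

    sigma = float(np.sqrt(np.log1p(config.noise_cv**2)))
    frames: Dict[str, pd.DataFrame] = {}
    for group in ACTIVITY_GROUPS:
        items = _GROUP_ITEMS[group]
        rates = config.stage_growth[group]
        trend = np.exp(_piecewise_log_trend(config, rates))  # (n_years,)
        rows = []
        for item in items:
            base = _BASE_LEVELS[group][item]
            for r_i, region in enumerate(regions):
                level = base * trend
                if group != "n_rate":  # rates are intensive, not apportioned
                    level = level * shares[r_i]
                else:
                    level = level * rng.uniform(0.9, 1.1)
                if sigma > 0:
                    noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, len(years)))
                else:
                    noise = 1.0
                vals = level * noise
                rows.append(pd.DataFrame(
                    {"year": years, "region": region, "item": item, "value": vals}))
        frames[group] = pd.concat(rows, ignore_index=True)

    mms_rows = []
    for region in regions:
        for cat in LIVESTOCK_CATEGORIES:
            alpha = rng.uniform(0.5, 2.0, len(MANURE_SYSTEMS))
            sh = rng.dirichlet(alpha)
            for sys_name, s in zip(MANURE_SYSTEMS, sh):
                mms_rows.append(
                    {"region": region, "category": cat, "system": sys_name,
                     "share": float(s)})
    mms = pd.DataFrame(mms_rows)

    ds = ActivityDataset(
        livestock=frames["livestock"].rename(columns={"item": "category"}),
        crop_area=frames["crop_area"].rename(columns={"item": "crop"}),
        n_rate=frames["n_rate"].rename(columns={"item": "crop"}),
        rice_area=frames["rice_area"].rename(columns={"item": "season"}),
        mms_shares=mms,
    )
    ds.validate()
    return ds


def generate_geography(config: SyntheticConfig) -> GeoLayers:
    """Toy raster geography: block regions, base-year weights, system classes.

    The region mask partitions the grid into ``n_regions`` contiguous bands
    (row-major).  For each base year (2010, 2015) and activity weight group a
    positive random field is normalized to sum to 1 within every region.  The
    production-system raster labels each cell cropland-based/mixed or
    livestock-only, mixed farming being more common in the low-index
    ('eastern') regions; every region keeps at least one mixed cell so manure
    always has somewhere to go.
    """
    rng = np.random.default_rng(child_seed(config.seed, "geography"))
    rows, cols = config.grid_shape
    n_cells = rows * cols
    bounds = np.linspace(0, n_cells, config.n_regions + 1).astype(int)
    mask = np.empty(n_cells, dtype=np.int64)
    for r in range(config.n_regions):
        mask[bounds[r]:bounds[r + 1]] = r
    region_mask = mask.reshape(rows, cols)

    weights: Dict[int, Dict[str, np.ndarray]] = {}
    for base_year in WEIGHT_BASE_YEARS:
        weights[base_year] = {}
        for group in ("livestock", "cropland", "rice"):
            raw = rng.lognormal(mean=0.0, sigma=0.8, size=(rows, cols))
            w = np.empty_like(raw)
            for r in range(config.n_regions):
                sel = region_mask == r
                w[sel] = raw[sel] / raw[sel].sum()
            weights[base_year][group] = w

    p_mixed = np.linspace(0.85, 0.35, config.n_regions)
    system_class = np.empty((rows, cols), dtype="U14")
    draw = rng.uniform(size=(rows, cols))
    for r in range(config.n_regions):
        sel = region_mask == r
        system_class[sel] = np.where(
            draw[sel] < p_mixed[r], "cropland_mixed", "livestock_only")
        first = tuple(np.argwhere(sel)[0])
        system_class[first] = "cropland_mixed"

    return GeoLayers(
        region_mask=region_mask,
        regions=[f"R{i+1}" for i in range(config.n_regions)],
        weights=weights,
        system_class=system_class,
        cell_area_km2=100.0,
    )


# ---------------------------------------------------------------------------
# Emission-factor observations


_CROP_EF_MULT: Dict[str, float] = {c: m for c, m in zip(
    CROP_TYPES, (1.5, 0.5, 1.0, 0.25, 3.0, 0.4, 7.0, 5.0, 0.3, 0.15))}

COVARIATE_RANGES: Dict[str, Tuple[float, float]] = {
    "n_rate": (0.0, 400.0),      # kg N / ha
    "mat": (2.0, 28.0),          # mean annual temperature, deg C
    "map_": (200.0, 2000.0),     # mean annual precipitation, mm
    "soil_ph": (4.5, 8.5),
    "soc": (5.0, 40.0),          # soil organic carbon, g/kg
    "clay_frac": (0.05, 0.60),
}


def default_ef_surface(crop: str, n_rate, mat, map_, soil_ph, soc, clay_frac):
    """Smooth true emission-factor surface (fraction of applied N).

    Saturating in the N application rate, modulated by a per-crop multiplier
    and climate/soil terms; bounded inside [0, 0.1] over the covariate ranges
    by construction.
    """
    base = 0.0002 + 0.0060 * n_rate / (n_rate + 150.0)
    clim = (1.0 + 0.60 * np.tanh((mat - 15.0) / 8.0)) * (
        1.0 + 0.35 * np.tanh((map_ - 900.0) / 500.0))
    soil = (1.0 + 0.20 * np.tanh((soil_ph - 6.5) / 1.5)) * (
        1.0 + 0.10 * np.tanh((soc - 20.0) / 10.0))
    return base * _CROP_EF_MULT[crop] * clim * soil


@dataclass
class EFObservationTable:
    """Field-observation table for the N2O emission-factor model."""

    data: pd.DataFrame
    true_surface: Callable = default_ef_surface

    def __post_init__(self) -> None:
        required = {"crop_type", "n_rate", "mat", "map_", "soil_ph", "soc",
                    "clay_frac", "ef_observed"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        ef = self.data["ef_observed"]
        if (ef < 0).any() or (ef > 0.1).any():
            raise ValueError("ef_observed outside [0, 0.1]")
        if (self.data["n_rate"] < 0).any():
            raise ValueError("negative n_rate")


def generate_ef_observations(
    config: SyntheticConfig,
    true_ef_surface: Optional[Callable] = None,
) -> EFObservationTable:
    """Draw EF observations from a known surface with lognormal noise.

    Covariates are sampled uniformly from :data:`COVARIATE_RANGES`, crop types
    are balanced across the ten labels, and observed EFs are the true surface
    value times mean-1 lognormal noise (CV ``config.ef_obs_noise_cv``),
    clipped to [0, 0.1].
    """
    surface = true_ef_surface or default_ef_surface
    rng = np.random.default_rng(child_seed(config.seed, "ef_observations"))
    n = config.ef_obs_n
    crops = np.array([CROP_TYPES[i % len(CROP_TYPES)] for i in range(n)])
    cov = {k: rng.uniform(lo, hi, n) for k, (lo, hi) in COVARIATE_RANGES.items()}
    truth = np.array([
        surface(c, cov["n_rate"][i], cov["mat"][i], cov["map_"][i],
                cov["soil_ph"][i], cov["soc"][i], cov["clay_frac"][i])
        for i, c in enumerate(crops)
    ])
    if (truth < 0).any() or (truth > 0.1).any():
        raise ValueError("true_ef_surface leaves [0, 0.1] on sampled covariates")
    cv = config.ef_obs_noise_cv
    if cv > 0:
        sigma = float(np.sqrt(np.log1p(cv**2)))
        noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, n))
    else:
        noise = np.ones(n)
    obs = np.clip(truth * noise, 0.0, 0.1)
    df = pd.DataFrame({"crop_type": crops, **cov, "ef_true": truth,
                       "ef_observed": obs})
    return EFObservationTable(data=df, true_surface=surface)


# ---------------------------------------------------------------------------
# Climate and water management


#: rice season calendars: (first flooded day, last season day,
#: midseason drainage start, drainage length in days)
SEASON_CALENDARS: Dict[str, Tuple[int, int, int, int]] = {
    "early": (105, 195, 150, 7),
    "middle": (150, 255, 200, 7),
    "late": (200, 295, 250, 7),
}


def season_water_calendar(season: str, drained_final_days: int = 7) -> np.ndarray:
    """Boolean flooded-state vector over the season's days.

    Flooded from transplanting to harvest except a midseason aeration window
    and final pre-harvest drainage.
    """
    start, end, drain_start, drain_len = SEASON_CALENDARS[season]
    n_days = end - start + 1
    flooded = np.ones(n_days, dtype=bool)
    d0 = drain_start - start
    flooded[d0:d0 + drain_len] = False
    flooded[n_days - drained_final_days:] = False
    return flooded


@dataclass
class ClimateFields:
    """Daily temperature fields plus per-season water calendars."""

    temperature: xr.DataArray  # (year, day, row, col), deg C
    calendars: Dict[str, np.ndarray] = field(default_factory=dict)

    def regional_mean(self, region_mask: np.ndarray) -> pd.DataFrame:
        """Mean daily temperature per region: columns (year, day, region, temp)."""
        t = self.temperature
        out = []
        for r in np.unique(region_mask):
            sel = xr.DataArray(region_mask == r, dims=("row", "col"))
            series = t.where(sel).mean(dim=("row", "col"))
            df = series.to_dataframe(name="temp").reset_index()
            df["region"] = f"R{int(r)+1}"
            out.append(df)
        return pd.concat(out, ignore_index=True)

    def payload_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.temperature.values).tobytes())
        for season in sorted(self.calendars):
            h.update(season.encode())
            h.update(self.calendars[season].tobytes())
        return h.hexdigest()

    def to_netcdf(self, path) -> None:
        ds = xr.Dataset({"temperature": self.temperature})
        ds.to_netcdf(path, engine="scipy")


def generate_climate(
    config: SyntheticConfig,
    mean_temp: float = 18.0,
    amplitude: float = 10.0,
    noise_sd: float = 1.5,
    years: Optional[List[int]] = None,
) -> ClimateFields:
    """Daily near-surface/soil temperature as a sinusoidal annual cycle + noise.

    A north-south gradient is imposed across rows; each cell carries a small
    static offset.  Stored as float32 to keep the full (year, day, row, col)
    cube light.
    """
    rng = np.random.default_rng(child_seed(config.seed, "climate"))
    yrs = years if years is not None else config.year_index
    rows, cols = config.grid_shape
    days = np.arange(1, 366)
    cycle = mean_temp + amplitude * np.sin(2 * np.pi * (days - 120) / 365.0)
    lat_gradient = np.linspace(-3.0, 3.0, rows)[:, None] * np.ones((1, cols))
    cell_offset = rng.normal(0.0, 0.5, (rows, cols))
    base = (cycle[None, :, None, None]
            + (lat_gradient + cell_offset)[None, None, :, :])
    noise = rng.normal(0.0, noise_sd, (len(yrs), len(days), rows, cols))
    temp = (np.broadcast_to(base, (len(yrs), len(days), rows, cols)) + noise
            ).astype(np.float32)
    da = xr.DataArray(
        temp,
        dims=("year", "day", "row", "col"),
        coords={"year": yrs, "day": days},
        name="temperature",
        attrs={"units": "degC"},
    )
    calendars = {s: season_water_calendar(s) for s in RICE_SEASONS}
    for a, b in zip(RICE_SEASONS[:-1], RICE_SEASONS[1:]):
        assert SEASON_CALENDARS[a][0] < SEASON_CALENDARS[b][0]
    return ClimateFields(temperature=da, calendars=calendars)


def save_synthetic_inputs(config: SyntheticConfig, outdir) -> None:
    """Write activity CSVs, geography/climate NetCDF and a config sidecar."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ds = generate_activity_series(config)
    ds.to_csv(out)
    geo = generate_geography(config)
    geo.to_netcdf(out / "geography.nc")
    clim = generate_climate(config)
    clim.to_netcdf(out / "climate.nc")
    obs = generate_ef_observations(config)
    obs.data.to_csv(out / "ef_observations.csv", index=False)
    sidecar = {"config": config.to_dict(),
               "climate_hash": clim.payload_hash()}
    (out / "synthetic_inputs.json").write_text(json.dumps(sidecar, indent=2))
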