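"""Activity-data harmonization and spatial disaggregation.

Annual regional activity series are corrected against sparse census anchors
(multiplicative ratio factors interpolated linearly in time), the most recent
year can be extrapolated from a trailing OLS trend, and regional totals are
spread onto the toy raster with base-year weight maps interpolated linearly
between their two reference years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd
import xarray as xr

from .config import LIVESTOCK_CATEGORIES

__all__ = [
    "ActivityDataset",
    "GeoLayers",
    "apply_census_correction",
    "extrapolate_recent",
    "interpolate_weight_maps",
    "disaggregate_to_grid",
]


@dataclass
class ActivityDataset:
    """Annual, region-resolved activity quantities in long format.

    Each table has columns (year, region, <item>, value):
    ``livestock`` heads by category, ``crop_area`` ha by crop, ``n_rate``
    kg N/ha by crop, ``rice_area`` ha by season type, plus static
    manure-management-system shares per (region, category).
    """

    livestock: pd.DataFrame
    crop_area: pd.DataFrame
    n_rate: pd.DataFrame
    rice_area: pd.DataFrame
    mms_shares: pd.DataFrame

    def validate(self) -> None:
        for name in ("livestock", "crop_area", "n_rate", "rice_area"):
            df = getattr(self, name)
            if (df["value"] < 0).any():
                raise ValueError(f"negative values in {name}")
        cats = set(self.livestock["category"].unique())
        if cats != set(LIVESTOCK_CATEGORIES):
            raise ValueError(
                f"livestock categories must be the fixed 12-category set, "
                f"got {sorted(cats)}")
        sums = self.mms_shares.groupby(["region", "category"])["share"].sum()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("manure-system shares must sum to 1 per "
                             "(region, category)")

    @property
    def years(self) -> List[int]:
        return sorted(self.livestock["year"].unique())

    @property
    def regions(self) -> List[str]:
        return sorted(self.livestock["region"].unique())

    def national(self, table: str) -> pd.DataFrame:
        """Sum a table over regions -> wide frame indexed by year."""
        df = getattr(self, table)
        item_col = [c for c in df.columns
                    if c not in ("year", "region", "value")][0]
        return df.pivot_table(index="year", columns=item_col, values="value",
                              aggfunc="sum")

    def to_csv(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("livestock", "crop_area", "n_rate", "rice_area",
                     "mms_shares"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)


@dataclass
class GeoLayers:
    """Raster geography: region mask, base-year weights, system classes."""

    region_mask: np.ndarray            # int region index per cell
    regions: List[str]                 # label for each region index
    weights: Dict[int, Dict[str, np.ndarray]]  # base_year -> group -> raster
    system_class: np.ndarray           # 'cropland_mixed' | 'livestock_only'
    cell_area_km2: float = 100.0

    def region_index(self, region: str) -> int:
        return self.regions.index(region)

    def mixed_share(self) -> pd.Series:
        """Fraction of cells classified cropland-based/mixed, per region."""
        out = {}
        for i, r in enumerate(self.regions):
            sel = self.region_mask == i
            out[r] = float(np.mean(self.system_class[sel] == "cropland_mixed"))
        return pd.Series(out, name="mixed_share")

    def to_netcdf(self, path) -> None:
        rows, cols = self.region_mask.shape
        data = {"region_mask": (("row", "col"), self.region_mask),
                "system_is_mixed": (("row", "col"),
                                    (self.system_class == "cropland_mixed")
                                    .astype(np.int8))}
        for year, groups in self.weights.items():
            for g, w in groups.items():
                data[f"weight_{g}_{year}"] = (("row", "col"), w)
        xr.Dataset(data).to_netcdf(path, engine="scipy")


def apply_census_correction(
    series: pd.Series,
    census_points: Mapping[int, float],
) -> pd.Series:
    """Anchor an annual series to sparse census values.

    At each census year the ratio census/raw defines a correction factor; the
    factor is interpolated linearly in time between consecutive anchors,
    held constant outside the anchor span, and applied multiplicatively.  The
    corrected series passes exactly through the anchors, and a series already
    matching them is returned unchanged.
    """
    if not census_points:
        return series.copy()
    years = np.asarray(series.index, dtype=float)
    anchors = sorted(census_points.items())
    a_years = np.array([y for y, _ in anchors], dtype=float)
    if a_years.min() < years.min() or a_years.max() > years.max():
        raise ValueError("census years must lie within the series range")
    factors = []
    for y, v in anchors:
        raw = series.loc[y]
        if raw == 0:
            raise ValueError(f"census anchor at year {y} hits raw value 0; "
                             "correction ratio undefined")
        if v <= 0:
            raise ValueError("census values must be > 0")
        factors.append(v / raw)
    f = np.interp(years, a_years, np.asarray(factors))
    return series * pd.Series(f, index=series.index)


def extrapolate_recent(series: pd.Series, n_back: int = 5) -> float:
    """One-step-ahead OLS linear-trend forecast from the trailing window.

    Fits value ~ year on the last ``n_back`` observations and evaluates at the
    next year; negative forecasts are floored at zero.
    """
    if n_back < 2:
        raise ValueError("need at least 2 points to fit a trend")
    if len(series) < n_back:
        raise ValueError(f"series has {len(series)} points, need {n_back}")
    tail = series.iloc[-n_back:]
    x = np.asarray(tail.index, dtype=float)
    y = tail.to_numpy(dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    forecast = slope * (x[-1] + 1) + intercept
    return float(max(forecast, 0.0))


def _renormalize(w: np.ndarray, region_mask: np.ndarray) -> np.ndarray:
    out = np.clip(w, 0.0, None)
    for r in np.unique(region_mask):
        sel = region_mask == r
        s = out[sel].sum()
        if s > 0:
            out[sel] = out[sel] / s
    return out


def interpolate_weight_maps(
    w_a: np.ndarray,
    w_b: np.ndarray,
    year: int,
    year_a: int,
    year_b: int,
    region_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Cellwise linear interpolation of base-year weight maps in time.

    Outside [year_a, year_b] the nearer base map is used unchanged (constant
    extrapolation).  The result is re-normalized per region to guard against
    floating-point drift; with no mask the whole grid is one region.
    """
    if w_a.shape != w_b.shape:
        raise ValueError(f"raster shapes differ: {w_a.shape} vs {w_b.shape}")
    if year_a >= year_b:
        raise ValueError("base years must satisfy year_a < year_b")
    if year <= year_a:
        w = w_a.copy()
    elif year >= year_b:
        w = w_b.copy()
    else:
        t = (year - year_a) / (year_b - year_a)
        w = (1 - t) * w_a + t * w_b
    if region_mask is None:
        region_mask = np.zeros_like(w, dtype=int)
    return _renormalize(w, region_mask)


def disaggregate_to_grid(
    regional_totals: Mapping[str, float],
    weights: np.ndarray,
    region_mask: np.ndarray,
    regions: List[str],
) -> np.ndarray:
    """Spread regional totals onto the grid: cell = total x cell weight.

    Weights must be normalized within each region, so per-region raster sums
    reproduce the inputs exactly (conservation).
    """
    if weights.shape != region_mask.shape:
        raise ValueError("weights and region_mask shapes differ")
    out = np.zeros_like(weights, dtype=float)
    for region, total in regional_totals.items():
        if region not in regions:
            raise KeyError(f"region {region!r} not present in the mask")
        sel = region_mask == regions.index(region)
        out[sel] = total * weights[sel]
    return out
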