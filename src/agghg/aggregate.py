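"""CO2-equivalent aggregation, regional rollup and Monte-Carlo uncertainty.

Gas masses are weighted by 100-year global warming potentials (27 for CH4,
273 for N2O); grids roll up to regions and the nation conservatively; and
uncertainty propagates by Monte Carlo with uniform activity multipliers and
truncated-normal emission-factor draws.  The rice subsector's uncertainty is
structural — the two-variant spread — and bypasses the Monte Carlo.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from typing import Callable, Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import SUBSECTORS
from .rice import multi_model_mean

GWP_CH4 = 27.0
GWP_N2O = 273.0

#: gas carried by each subsector
SUBSECTOR_GAS: Dict[str, str] = {
    "livestock_ch4": "CH4",
    "cropland_ch4": "CH4",
    "cropland_n2o": "N2O",
    "livestock_n2o": "N2O",
}

__all__ = [
    "to_co2eq",
    "rollup_shares",
    "round_half_up",
    "monte_carlo",
    "rice_structural_uncertainty",
    "UncertaintyEnvelope",
]


def to_co2eq(masses: Mapping[str, float] | pd.DataFrame,
             gwp_ch4: float = GWP_CH4,
             gwp_n2o: float = GWP_N2O):
    """Convert subsector gas masses (Tg gas) to Tg CO2-eq.

    Accepts a mapping subsector -> mass or a DataFrame with subsector
    columns; attribution by subsector is retained.
    """
    def _factor(subsector: str) -> float:
        gas = SUBSECTOR_GAS.get(subsector)
        if gas == "CH4":
            return gwp_ch4
        if gas == "N2O":
            return gwp_n2o
        raise KeyError(f"unknown subsector/gas label {subsector!r}")

    if isinstance(masses, pd.DataFrame):
        out = masses.copy()
        for col in out.columns:
            out[col] = out[col] * _factor(col)
        return out
    return {k: v * _factor(k) for k, v in masses.items()}


def round_half_up(x: float) -> int:
    """Integer rounding with ties away from the floor (0.5 -> 1)."""
    return int(decimal.Decimal(repr(float(x))).quantize(
        0, rounding=decimal.ROUND_HALF_UP))


def rollup_shares(values: Mapping[str, float]) -> Dict[str, int]:
    """Percentage shares of a total, half-up rounded to integer percent."""
    total = sum(values.values())
    if total == 0:
        raise ValueError("total is zero; shares undefined")
    return {k: round_half_up(100.0 * v / total) for k, v in values.items()}


def rollup(field: np.ndarray, region_mask: np.ndarray,
           regions: Sequence[str], level: str = "region"):
    """Sum a gridded field to regions or the nation (exactly conservative)."""
    if field.shape != region_mask.shape:
        raise ValueError("field and region mask are misaligned")
    if level == "cell":
        return field
    totals = {r: float(field[region_mask == i].sum())
              for i, r in enumerate(regions)}
    if level == "region":
        return pd.Series(totals)
    if level == "nation":
        return float(sum(totals.values()))
    raise ValueError(f"unknown level {level!r}")


@dataclass
class UncertaintyEnvelope:
    """Monte-Carlo summary of a scalar or annual series."""

    mean: np.ndarray
    sd: np.ndarray
    p2_5: np.ndarray
    p97_5: np.ndarray
    n_draws: int
    seed: int
    inputs: dict = field(default_factory=dict)

    def relative_sd(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.mean != 0, self.sd / self.mean, 0.0)


def monte_carlo(
    emission_fn: Callable[[float, float], np.ndarray | float],
    activity_cv: float,
    ef_rel_sd: float,
    n: int = 10_000,
    seed: int = 0,
) -> UncertaintyEnvelope:
    """Propagate input uncertainty through a deterministic emission function.

    Activity multipliers are uniform on 1 +/- sqrt(3) x cv (so the stated CV
    is the distribution's actual CV), truncated at 0 if the lower bound would
    go negative; EF multipliers are normal(1, rel sd) truncated at 0.
    ``emission_fn(activity_mult, ef_mult)`` is re-evaluated per draw.
    """
    if activity_cv < 0 or ef_rel_sd < 0:
        raise ValueError("cv and sd must be >= 0")
    rng = np.random.default_rng(seed)
    half = np.sqrt(3.0) * activity_cv
    lo, hi = 1.0 - half, 1.0 + half
    truncated_uniform = lo < 0
    a_mult = np.clip(rng.uniform(lo, hi, n), 0.0, None)
    e_mult = np.clip(rng.normal(1.0, ef_rel_sd, n) if ef_rel_sd > 0
                     else np.ones(n), 0.0, None)
    draws = np.stack([np.asarray(emission_fn(a, e), dtype=float)
                      for a, e in zip(a_mult, e_mult)])
    return UncertaintyEnvelope(
        mean=draws.mean(axis=0),
        sd=draws.std(axis=0, ddof=1),
        p2_5=np.percentile(draws, 2.5, axis=0),
        p97_5=np.percentile(draws, 97.5, axis=0),
        n_draws=n,
        seed=seed,
        inputs={"activity_cv": activity_cv, "ef_rel_sd": ef_rel_sd,
                "activity_distribution": "uniform(1-sqrt3*cv, 1+sqrt3*cv)",
                "ef_distribution": "normal(1, sd) truncated at 0",
                "uniform_truncated_at_zero": bool(truncated_uniform)},
    )


def rice_structural_uncertainty(variant_fields: Sequence[np.ndarray]
                                ) -> np.ndarray:
    """Relative uncertainty of the rice subsector: ensemble sd / mean."""
    _, rel = multi_model_mean(variant_fields)
    return rel
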