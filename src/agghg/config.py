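"""Configuration objects shared across the inventory pipeline.

The package works on a toy rectangular domain split into contiguous block
regions (a stand-in for a national 0.1-degree grid split into six
administrative regions either side of a density divide).  All defaults encode
the study conditions: an annual 1980-2023 record with trend breaks near 1997
and 2015, six regions, 12 livestock categories, 10 crop types and three rice
season types.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Sequence, Tuple

LIVESTOCK_CATEGORIES: Tuple[str, ...] = (
    "dairy_cattle",
    "non_dairy_cattle",
    "buffalo",
    "sheep",
    "goats",
    "swine",
    "camel",
    "mules",
    "donkeys",
    "horses",
    "poultry",
    "rabbit",
)

RUMINANT_CATEGORIES: Tuple[str, ...] = (
    "dairy_cattle",
    "non_dairy_cattle",
    "buffalo",
    "sheep",
    "goats",
)

CROP_TYPES: Tuple[str, ...] = (
    "rice",
    "wheat",
    "maize",
    "soybean",
    "cotton",
    "rapeseed",
    "vegetables",
    "fruits",
    "potato",
    "sugarcane",
)

RICE_SEASONS: Tuple[str, ...] = ("early", "middle", "late")

SUBSECTORS: Tuple[str, ...] = (
    "livestock_ch4",
    "cropland_ch4",
    "cropland_n2o",
    "livestock_n2o",
)

#: Activity variable groups produced by the synthetic generator.
ACTIVITY_GROUPS: Tuple[str, ...] = ("livestock", "crop_area", "n_rate", "rice_area")

# Default per-stage relative annual growth rates per activity group.  The
# groups deliberately peak at different breakpoints: livestock numbers crest at
# the first break and decline thereafter, while fertilizer-driven cropland
# activity keeps growing until the second break.  The aggregate CO2-eq series
# then shows two local maxima at the configured breaks, mirroring a rapid
# growth / slow growth / stabilization staging.
DEFAULT_STAGE_GROWTH: Dict[str, List[float]] = {
    "livestock": [0.050, -0.040, -0.001],
    "crop_area": [0.010, 0.005, 0.000],
    "n_rate": [0.035, 0.050, -0.002],
    "rice_area": [0.000, 0.010, -0.001],
}


@dataclass
class SyntheticConfig:
    """Ground-truth parameters of the synthetic activity world.

    Parameters
    ----------
    years : (int, int)
        Inclusive calendar-year range of the annual record.
    n_regions : int
        Number of contiguous block regions on the toy grid.
    grid_shape : (int, int)
        Rows and columns of the toy raster domain.
    breakpoints : list of int
        Years at which the piecewise growth rate changes; strictly increasing
        and strictly inside the year range.
    stage_growth : mapping group -> list of float
        Relative annual growth rate per stage for each activity group; each
        list has exactly ``len(breakpoints) + 1`` entries.
    noise_cv : float
        Coefficient of variation of multiplicative lognormal noise applied to
        every activity series.
    ef_obs_n : int
        Number of rows in the synthetic emission-factor observation table.
    ef_obs_noise_cv : float
        CV of the multiplicative lognormal noise on observed emission factors.
    seed : int
        Master seed; per-output child streams are split from it.
    """

    years: Tuple[int, int] = (1980, 2023)
    n_regions: int = 6
    grid_shape: Tuple[int, int] = (40, 60)
    breakpoints: List[int] = field(default_factory=lambda: [1997, 2015])
    stage_growth: Dict[str, List[float]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_STAGE_GROWTH.items()}
    )
    noise_cv: float = 0.02
    #: one-year log-level bump at each breakpoint, as a fraction of the drop
    #: in growth rate across the break — emulates the boom-bust overshoot /
    #: statistical-revision spikes real series show at regime transitions
    breakpoint_overshoot: float = 1.0
    ef_obs_n: int = 1705
    ef_obs_noise_cv: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        y0, y1 = self.years
        if y1 <= y0:
            raise ValueError(f"year range must be increasing, got {self.years}")
        bps = list(self.breakpoints)
        if sorted(set(bps)) != bps:
            raise ValueError(f"breakpoints must be strictly increasing, got {bps}")
        for b in bps:
            if not (y0 < b < y1):
                raise ValueError(f"breakpoint {b} not strictly inside {self.years}")
        n_stages = len(bps) + 1
        for group, rates in self.stage_growth.items():
            if len(rates) != n_stages:
                raise ValueError(
                    f"stage_growth[{group!r}] needs {n_stages} entries, "
                    f"got {len(rates)}"
                )
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.ef_obs_noise_cv < 0:
            raise ValueError("ef_obs_noise_cv must be >= 0")
        r, c = self.grid_shape
        if r <= 0 or c <= 0:
            raise ValueError(f"grid_shape must be positive, got {self.grid_shape}")
        if self.n_regions <= 0 or self.n_regions > r * c:
            raise ValueError("n_regions must be in [1, n_cells]")

    @property
    def year_index(self) -> List[int]:
        return list(range(self.years[0], self.years[1] + 1))

    @property
    def n_stages(self) -> int:
        return len(self.breakpoints) + 1

    def stages(self) -> List[Tuple[int, int]]:
        """Inclusive (start, end) year pairs tiling the record at breakpoints.

        Each breakpoint year closes one stage and opens the next, so
        breakpoints [1997, 2015] on 1980-2023 give (1980, 1997),
        (1997, 2015), (2015, 2023).
        """
        edges = [self.years[0], *self.breakpoints, self.years[1]]
        return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunConfig:
    """End-to-end pipeline settings (seed, sizes, constants, output formats)."""

    seed: int = 0
    synthetic: SyntheticConfig = None  # type: ignore[assignment]
    gwp_ch4: float = 27.0
    gwp_n2o: float = 273.0
    mc_draws: int = 10_000
    bootstrap_reps: int = 1000
    bootstrap_k: int = 10
    #: the final year's activity is extrapolated from this many prior years
    #: while emission factors stay frozen at the penultimate year
    extrapolate_n_back: int = 5
    #: cropland N-leaching pathway (fraction of total N leached; EF5 on it)
    frac_leach: float = 0.2
    ef5: float = 0.011
    activity_cv: Dict[str, float] = field(
        default_factory=lambda: {
            "livestock_ch4": 0.10,
            "cropland_n2o": 0.05,
            "livestock_n2o": 0.10,
        }
    )
    ef_rel_sd: Dict[str, float] = field(
        default_factory=lambda: {
            "livestock_ch4": 0.15,
            "cropland_n2o": 0.20,
            "livestock_n2o": 0.20,
        }
    )
    output_format: str = "csv"

    def __post_init__(self) -> None:
        if self.synthetic is None:
            self.synthetic = SyntheticConfig(seed=self.seed)
        if self.mc_draws < 1 or self.bootstrap_reps < 1:
            raise ValueError("mc_draws and bootstrap_reps must be positive")
        if self.output_format not in ("csv", "netcdf"):
            raise ValueError("output_format must be 'csv' or 'netcdf'")


def child_seed(master: int, stream: str) -> int:
    """Deterministic per-stream child seed below 2**31.

    Splitting per output means regenerating one component never perturbs the
    random stream of another.
    """
    h = 2166136261
    for ch in f"{master}/{stream}".encode():
        h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
    return h % (2**31 - 1)
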