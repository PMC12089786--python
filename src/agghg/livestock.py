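"""Livestock CH4 (enteric + manure) and manure N2O via energy-balance Tier 2.

Enteric CH4 scales gross energy intake by the methane conversion factor Ym;
manure CH4 follows volatile solids through management-system methane
conversion factors; nitrogen excretion is N intake minus retention, routed
through management systems into direct N2O, volatilization and leaching
losses, with the residual available for field application — the manure-N link
the cropland module consumes.  A per-(year, region, category) nitrogen ledger
closes exactly: excreted = direct N2O-N + volatilized + leached + applied +
residual.

All emission-relevant numbers (energy densities, Ym lookup, B0, MCF, EF3/4/5)
live in YAML parameter packs, not in code.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .activity import ActivityDataset

N_TO_N2O = 44.0 / 28.0

__all__ = [
    "LivestockParams",
    "load_params",
    "ym_from_de",
    "enteric_ch4_ef",
    "volatile_solids",
    "manure_ch4_ef",
    "n_excretion",
    "manure_n2o",
    "manure_n_for_cropland",
    "compute_livestock_emissions",
]


@dataclass
class LivestockParams:
    """Parsed parameter pack: per-category profiles plus system EFs."""

    constants: Dict[str, float]
    ym_table_default: list
    categories: Dict[str, dict]
    systems: Dict[str, dict]
    ef4: float
    ef5: float

    def validate(self) -> None:
        for name, prof in self.categories.items():
            if prof["route"] == "tier2":
                if not (0 < prof["de"] < 100):
                    raise ValueError(f"{name}: de out of (0, 100)")
                ym = prof["ym"]
                if ym != "from_de" and not (0 <= ym < 15):
                    raise ValueError(f"{name}: ym out of [0, 15)")
                for frac in ("ue_frac", "ash_frac", "cp_frac",
                             "n_retention_frac"):
                    if not (0 <= prof[frac] <= 1):
                        raise ValueError(f"{name}: {frac} out of [0, 1]")
        for sname, s in self.systems.items():
            if not (0 <= s["mcf"] <= 100):
                raise ValueError(f"{sname}: mcf out of [0, 100]")
            loss = s["ef3"] + s["frac_gas"] + s["frac_leach"]
            if loss > 1:
                raise ValueError(
                    f"{sname}: ef3 + frac_gas + frac_leach = {loss} > 1; "
                    "the nitrogen ledger would go negative")


def load_params(
    profiles_path=None, systems_path=None
) -> LivestockParams:
    """Load the default (or user-supplied) YAML parameter packs."""
    pkg = resources.files("agghg") / "params"
    prof_text = (open(profiles_path).read() if profiles_path
                 else (pkg / "livestock_profiles.yaml").read_text())
    sys_text = (open(systems_path).read() if systems_path
                else (pkg / "manure_systems.yaml").read_text())
    prof = yaml.safe_load(prof_text)
    sysd = yaml.safe_load(sys_text)
    params = LivestockParams(
        constants=prof["constants"],
        ym_table_default=prof["ym_table_default"],
        categories=prof["categories"],
        systems=sysd["systems"],
        ef4=sysd["ef4"],
        ef5=sysd["ef5"],
    )
    params.validate()
    return params


def ym_from_de(de: float, table: Optional[list] = None) -> float:
    """Methane conversion factor (% of GE) from feed digestibility (%).

    ``table`` is a list of [de_upper_bound, ym] rows with an open-tail row
    (null bound) last; the default encodes the ruminant convention of lower
    conversion at higher digestibility.  Monotone non-increasing in DE.
    """
    if not (45.0 <= de <= 85.0):
        raise ValueError(f"de={de} outside the supported range [45, 85]")
    if table is None:
        table = load_params().ym_table_default
    for bound, ym in table:
        if bound is None or de <= bound:
            return float(ym)
    raise ValueError("ym table has no open tail row")


def enteric_ch4_ef(ge: float, ym: float,
                   ch4_energy_content: float = 55.65) -> float:
    """Enteric CH4 emission factor, kg head-1 yr-1.

    EF = GE x (Ym/100) x 365 / energy content of CH4.
    """
    if np.any(np.asarray(ge) <= 0):
        raise ValueError("ge must be > 0")
    return ge * (ym / 100.0) * 365.0 / ch4_energy_content


def volatile_solids(ge, de, ue_frac, ash_frac,
                    energy_density_dm: float = 18.45):
    """Volatile solids excreted, kg dry matter head-1 d-1.

    VS = [GE x (1 - DE/100) + UE x GE] x (1 - ASH) / energy density of DM.
    """
    return (ge * (1.0 - de / 100.0) + ue_frac * ge) * (
        1.0 - ash_frac) / energy_density_dm


def manure_ch4_ef(vs, b0, system_shares: Mapping[str, float],
                  mcfs: Mapping[str, float],
                  ch4_density: float = 0.67):
    """Manure CH4 emission factor, kg head-1 yr-1.

    EF = VS x 365 x B0 x rho_CH4 x sum_s(MCF_s/100 x share_s).
    """
    total_share = sum(system_shares.values())
    if abs(total_share - 1.0) > 1e-6:
        raise ValueError(f"system shares sum to {total_share}, expected 1")
    weighted_mcf = sum(system_shares[s] * mcfs[s] / 100.0
                       for s in system_shares)
    return vs * 365.0 * b0 * ch4_density * weighted_mcf


def n_excretion(ge, cp_frac, n_retention_frac,
                energy_density_dm: float = 18.45,
                protein_to_n: float = 6.25):
    """Annual nitrogen excretion, kg N head-1 yr-1.

    Daily N intake = (GE / energy density) x (CP / 6.25); excretion is the
    non-retained fraction scaled to a year.
    """
    n_intake_daily = (ge / energy_density_dm) * (cp_frac / protein_to_n)
    return n_intake_daily * (1.0 - n_retention_frac) * 365.0


def manure_n2o(
    nex: float,
    system_shares: Mapping[str, float],
    systems: Mapping[str, Mapping[str, float]],
    ef4: float,
    ef5: float,
) -> Dict[str, float]:
    """Manure N2O pathways for one animal-year's excretion.

    Returns a dict with direct / indirect (volatilization, leaching) N2O in
    kg N2O plus the underlying N flows (kg N) for the ledger.
    """
    total_share = sum(system_shares.values())
    if abs(total_share - 1.0) > 1e-6:
        raise ValueError(f"system shares sum to {total_share}, expected 1")
    direct_n = vol_n = leach_n = 0.0
    for s, share in system_shares.items():
        p = systems[s]
        loss = p["ef3"] + p["frac_gas"] + p["frac_leach"]
        if loss > 1:
            raise ValueError(f"system {s}: N loss fractions sum to {loss} > 1")
        handled = nex * share
        direct_n += handled * p["ef3"]
        vol_n += handled * p["frac_gas"]
        leach_n += handled * p["frac_leach"]
    return {
        "direct_n2o": direct_n * N_TO_N2O,
        "indirect_vol_n2o": vol_n * ef4 * N_TO_N2O,
        "indirect_leach_n2o": leach_n * ef5 * N_TO_N2O,
        "n_direct_n2o_n": direct_n,
        "n_volatilized": vol_n,
        "n_leached": leach_n,
    }


def manure_n_for_cropland(
    ledger: pd.DataFrame,
    application_frac: Mapping[str, float] | float,
    mixed_share: Mapping[str, float],
) -> pd.DataFrame:
    """Resolve applied-to-cropland manure N and close the ledger.

    applied = (excreted - direct N2O-N - volatilized - leached) x
    application fraction, credited only to regions that contain
    cropland-based/mixed production cells.  Returns the ledger with
    ``n_applied_cropland`` and ``n_residual`` filled so that the row sum
    identity holds exactly.
    """
    out = ledger.copy()
    avail = (out["n_excreted"] - out["n_direct_n2o_n"]
             - out["n_volatilized"] - out["n_leached"])
    if (avail < -1e-9).any():
        raise ValueError("nitrogen losses exceed excretion")
    fracs = out["region"].map(
        (lambda r: application_frac) if np.isscalar(application_frac)
        else (lambda r: application_frac[r]))
    fr = fracs.to_numpy(dtype=float)
    if ((fr < 0) | (fr > 1)).any():
        raise ValueError("application_frac must be in [0, 1]")
    has_mixed = out["region"].map(lambda r: mixed_share[r] > 0).to_numpy()
    out["n_applied_cropland"] = np.where(has_mixed, avail * fr, 0.0)
    out["n_residual"] = avail - out["n_applied_cropland"]
    return out


def _resolve_ym(prof: dict, ym_table_default: list) -> float:
    ym = prof["ym"]
    if ym == "from_de":
        return ym_from_de(prof["de"], prof.get("ym_table", ym_table_default))
    return float(ym)


def category_emission_factors(params: LivestockParams) -> pd.DataFrame:
    """Per-category EFs (kg head-1 yr-1 except N flows) before system mixing.

    Columns: enteric_ch4_ef, vs_daily, nex (system-dependent terms are mixed
    in later using per-region shares).  Simplified-route categories carry
    their fixed per-head factors.
    """
    const = params.constants
    rows = []
    for cat, prof in params.categories.items():
        if prof["route"] == "tier2":
            ym = _resolve_ym(prof, params.ym_table_default)
            rows.append({
                "category": cat,
                "route": "tier2",
                "enteric_ch4_ef": enteric_ch4_ef(
                    prof["ge"], ym, const["ch4_energy_content"]),
                "vs_daily": volatile_solids(
                    prof["ge"], prof["de"], prof["ue_frac"],
                    prof["ash_frac"], const["energy_density_dm"]),
                "b0": prof["b0"],
                "nex": n_excretion(
                    prof["ge"], prof["cp_frac"], prof["n_retention_frac"],
                    const["energy_density_dm"], const["protein_to_n"]),
                "manure_ch4_ef_fixed": np.nan,
            })
        else:
            rows.append({
                "category": cat,
                "route": "simplified",
                "enteric_ch4_ef": prof["enteric_ef"],
                "vs_daily": np.nan,
                "b0": np.nan,
                "nex": prof["nex_rate"],
                "manure_ch4_ef_fixed": prof["manure_ch4_ef"],
            })
    return pd.DataFrame(rows)


def compute_livestock_emissions(
    activity: ActivityDataset,
    params: Optional[LivestockParams] = None,
    application_frac: Mapping[str, float] | float = 0.5,
    mixed_share: Optional[Mapping[str, float]] = None,
    ef_scale: pd.Series | float = 1.0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorized livestock emissions per (year, region, category).

    Returns ``(emissions, ledger)``: emissions in kg gas with columns
    enteric_ch4, manure_ch4, direct_n2o, indirect_vol_n2o,
    indirect_leach_n2o; the nitrogen ledger in kg N with the closure columns.

    ``ef_scale`` optionally scales all per-head EFs per year (index = year),
    used to freeze the final year's factors at the penultimate year when the
    last year's activity is extrapolated.
    """
    params = params or load_params()
    cat_ef = category_emission_factors(params).set_index("category")
    heads = activity.livestock
    if mixed_share is None:
        mixed_share = {r: 1.0 for r in activity.regions}

    # per-(region, category) system-weighted MCF and N-loss fractions
    mms = activity.mms_shares.copy()
    mms["mcf"] = mms["system"].map(lambda s: params.systems[s]["mcf"] / 100.0)
    mms["ef3"] = mms["system"].map(lambda s: params.systems[s]["ef3"])
    mms["fgas"] = mms["system"].map(lambda s: params.systems[s]["frac_gas"])
    mms["fleach"] = mms["system"].map(lambda s: params.systems[s]["frac_leach"])
    for col in ("mcf", "ef3", "fgas", "fleach"):
        mms[f"w_{col}"] = mms["share"] * mms[col]
    wsys = mms.groupby(["region", "category"])[
        ["w_mcf", "w_ef3", "w_fgas", "w_fleach"]].sum().reset_index()

    df = heads.merge(wsys, on=["region", "category"], how="left")
    for col, src in (("enteric_ef", "enteric_ch4_ef"), ("vs", "vs_daily"),
                     ("b0", "b0"), ("nex", "nex"),
                     ("manure_fixed", "manure_ch4_ef_fixed")):
        df[col] = df["category"].map(cat_ef[src])
    df["route_tier2"] = df["category"].map(cat_ef["route"]) == "tier2"

    if np.isscalar(ef_scale):
        scale = float(ef_scale)
    else:
        scale = df["year"].map(ef_scale).to_numpy(dtype=float)

    const = params.constants
    heads_n = df["value"].to_numpy()
    manure_ef = np.where(
        df["route_tier2"],
        df["vs"].fillna(0) * 365.0 * df["b0"].fillna(0)
        * const["ch4_density"] * df["w_mcf"],
        df["manure_fixed"].fillna(0),
    )
    emis = pd.DataFrame({
        "year": df["year"], "region": df["region"],
        "category": df["category"],
        "heads": heads_n,
        "enteric_ch4": heads_n * df["enteric_ef"].to_numpy() * scale,
        "manure_ch4": heads_n * manure_ef * scale,
    })
    nex_total = heads_n * df["nex"].to_numpy() * scale
    n_direct = nex_total * df["w_ef3"].to_numpy()
    n_vol = nex_total * df["w_fgas"].to_numpy()
    n_leach = nex_total * df["w_fleach"].to_numpy()
    emis["direct_n2o"] = n_direct * N_TO_N2O
    emis["indirect_vol_n2o"] = n_vol * params.ef4 * N_TO_N2O
    emis["indirect_leach_n2o"] = n_leach * params.ef5 * N_TO_N2O

    ledger = pd.DataFrame({
        "year": df["year"], "region": df["region"],
        "category": df["category"],
        "n_excreted": nex_total,
        "n_direct_n2o_n": n_direct,
        "n_volatilized": n_vol,
        "n_leached": n_leach,
    })
    ledger = manure_n_for_cropland(ledger, application_frac, mixed_share)
    return emis, ledger


def ledger_closure_error(ledger: pd.DataFrame) -> float:
    """Max relative closure residual of the nitrogen ledger."""
    lhs = ledger["n_excreted"]
    rhs = (ledger["n_direct_n2o_n"] + ledger["n_volatilized"]
           + ledger["n_leached"] + ledger["n_applied_cropland"]
           + ledger["n_residual"])
    denom = np.maximum(lhs.abs(), 1e-30)
    return float(((lhs - rhs).abs() / denom).max())
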