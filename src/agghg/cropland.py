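"""Cropland N2O: data-driven emission factors times nitrogen loads.

Direct emissions are EF x N load for each nitrogen source (synthetic
fertilizer, manure, deposition, mineralization, crop residues, pasture
fertilization), with a crop-specific tree-ensemble EF model trained on field
observations; the indirect pathway routes a leached fraction of total N
through the leaching emission factor.  Manure N enters only where production
systems are cropland-based/mixed, and its magnitude comes from the livestock
module's nitrogen ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import train_test_split

from .config import CROP_TYPES

N_TO_N2O = 44.0 / 28.0
EF_MIN, EF_MAX = 0.0, 0.1

#: nitrogen-load component columns, kg N
LOAD_COMPONENTS = (
    "n_fert_synthetic",
    "n_fert_manure",
    "n_deposition",
    "n_mineralization",
    "n_residue",
    "n_pasture_fert",
)

COVARIATES = ("n_rate", "mat", "map_", "soil_ph", "soc", "clay_frac")


class EFModel:
    """Crop-specific emission-factor regressor (scikit-learn style).

    Each crop type gets its own random-forest sub-model mapping site
    covariates to the fraction of applied N emitted as N2O-N.  Because EF
    measurement error is multiplicative, forests are fit on log(EF) and
    back-transformed with a smearing correction.  A crop's sub-model blends
    its own forest with a shared climate/soil backbone — a forest trained on
    all crops' log-EFs after removing each crop's level — since the
    environmental response is largely common across crops while per-crop
    samples are sparse (a standard multi-task trick).  ``fit`` holds out
    ``1 - train_frac`` of each crop's observations and records holdout R^2
    and RMSE per crop and pooled.  Predictions are clipped to [0, 0.1]: an
    EF of 10% of applied N is beyond any plausible cropland value, so
    anything larger is treated as extrapolation error.

    Attributes set by ``fit`` (trailing underscore): ``models_``,
    ``backbone_``, ``metrics_``, ``pooled_r2_``, ``pooled_rmse_``.
    """

    def __init__(self, n_estimators: int = 500, max_depth: Optional[int] = None,
                 train_frac: float = 0.7, min_obs_per_crop: int = 30,
                 log_target: bool = True, backbone_weight: float = 0.5,
                 min_samples_leaf: int = 3, seed: int = 0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.train_frac = train_frac
        self.min_obs_per_crop = min_obs_per_crop
        #: fit forests on log(EF) (multiplicative measurement error) and
        #: back-transform with a smearing (half-residual-variance) correction
        self.log_target = log_target
        #: blend weight of the shared climate/soil backbone in each crop's
        #: log-space prediction (0 disables the backbone)
        self.backbone_weight = backbone_weight
        self.min_samples_leaf = min_samples_leaf
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"n_estimators": self.n_estimators, "max_depth": self.max_depth,
                "train_frac": self.train_frac,
                "min_obs_per_crop": self.min_obs_per_crop,
                "log_target": self.log_target,
                "backbone_weight": self.backbone_weight,
                "min_samples_leaf": self.min_samples_leaf, "seed": self.seed}

    def set_params(self, **kw) -> "EFModel":
        for k, v in kw.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    _LOG_EPS = 1e-5

    def _predict_raw(self, crop: str, X: np.ndarray) -> np.ndarray:
        rf = self.models_[crop]
        if not self.log_target:
            return rf.predict(X)
        z = rf.predict(X)
        if self.backbone_weight > 0:
            z_shared = self.backbone_.predict(X) + self._crop_level_[crop]
            w = self.backbone_weight
            z = (1.0 - w) * z + w * z_shared
        return np.exp(z) * self._smearing_[crop] - self._LOG_EPS

    def fit(self, obs: pd.DataFrame) -> "EFModel":
        """Train per-crop sub-models on a 70/30 split of the observations."""
        crops = sorted(obs["crop_type"].unique())
        splits = {}
        for i, crop in enumerate(crops):
            sub = obs[obs["crop_type"] == crop]
            if len(sub) < self.min_obs_per_crop:
                raise ValueError(
                    f"crop {crop!r} has only {len(sub)} observations "
                    f"(need >= {self.min_obs_per_crop})")
            X = sub[list(COVARIATES)].to_numpy()
            y = sub["ef_observed"].to_numpy()
            splits[crop] = train_test_split(
                X, y, train_size=self.train_frac,
                random_state=(self.seed + i) % (2**31 - 1))

        self.models_: Dict[str, RandomForestRegressor] = {}
        self._smearing_: Dict[str, float] = {}
        self._crop_level_: Dict[str, float] = {}
        self.backbone_ = None
        if self.log_target and self.backbone_weight > 0:
            # shared environmental-response forest on all crops' train rows,
            # each crop's mean log level removed
            Xs, zs = [], []
            for crop in crops:
                X_tr, _, y_tr, _ = splits[crop]
                z = np.log(y_tr + self._LOG_EPS)
                self._crop_level_[crop] = float(z.mean())
                Xs.append(X_tr)
                zs.append(z - z.mean())
            self.backbone_ = RandomForestRegressor(
                n_estimators=self.n_estimators, max_depth=self.max_depth,
                min_samples_leaf=self.min_samples_leaf,
                random_state=self.seed % (2**31 - 1), n_jobs=1)
            self.backbone_.fit(np.vstack(Xs), np.concatenate(zs))

        metrics = []
        pooled_true, pooled_pred = [], []
        for i, crop in enumerate(crops):
            X_tr, X_te, y_tr, y_te = splits[crop]
            rf = RandomForestRegressor(
                n_estimators=self.n_estimators, max_depth=self.max_depth,
                min_samples_leaf=self.min_samples_leaf,
                random_state=(self.seed + i) % (2**31 - 1), n_jobs=1)
            self.models_[crop] = rf
            self._smearing_[crop] = 1.0
            if self.log_target:
                z_tr = np.log(y_tr + self._LOG_EPS)
                rf.fit(X_tr, z_tr)
                # smearing factor from in-sample residuals of the blend
                z_hat = np.log(np.maximum(
                    self._predict_raw(crop, X_tr), self._LOG_EPS)
                    + self._LOG_EPS)
                self._smearing_[crop] = float(
                    np.exp(np.var(z_tr - z_hat) / 2.0))
            else:
                rf.fit(X_tr, y_tr)
            pred = np.clip(self._predict_raw(crop, X_te), EF_MIN, EF_MAX)
            constant_target = np.ptp(y_te) == 0
            metrics.append({
                "crop": crop,
                "n_train": len(y_tr),
                "n_test": len(y_te),
                "r2": (np.nan if constant_target else
                       float(r2_score(y_te, pred))),
                "rmse": float(np.sqrt(mean_squared_error(y_te, pred))),
                "constant_target": bool(constant_target),
            })
            pooled_true.append(y_te)
            pooled_pred.append(pred)
        self.metrics_ = pd.DataFrame(metrics)
        yt = np.concatenate(pooled_true)
        yp = np.concatenate(pooled_pred)
        self.pooled_r2_ = (np.nan if np.ptp(yt) == 0
                           else float(r2_score(yt, yp)))
        self.pooled_rmse_ = float(np.sqrt(mean_squared_error(yt, yp)))
        return self

    def predict(self, crop: str, covariates: pd.DataFrame) -> np.ndarray:
        """Predicted EFs for one crop, clipped to [0, 0.1].

        Rows with any missing covariate yield NaN (crop absent there).
        """
        if crop not in self.models_:
            raise KeyError(f"no sub-model for crop {crop!r}")
        X = covariates[list(COVARIATES)].to_numpy(dtype=float)
        valid = ~np.isnan(X).any(axis=1)
        out = np.full(len(X), np.nan)
        if valid.any():
            out[valid] = np.clip(
                self._predict_raw(crop, X[valid]), EF_MIN, EF_MAX)
        return out

    def training_report(self) -> dict:
        return {
            "pooled_r2": self.pooled_r2_,
            "pooled_rmse": self.pooled_rmse_,
            "per_crop": self.metrics_.to_dict(orient="records"),
            "params": self.get_params(),
        }


def train_ef_model(obs, train_frac: float = 0.7, seed: int = 0,
                   **kw) -> EFModel:
    """Convenience wrapper: fit an :class:`EFModel` on an observation table."""
    data = obs.data if hasattr(obs, "data") else obs
    return EFModel(train_frac=train_frac, seed=seed, **kw).fit(data)


def predict_ef(model: EFModel, crop: str, covariates: pd.DataFrame
               ) -> np.ndarray:
    return model.predict(crop, covariates)


def direct_n2o(loads: pd.DataFrame, efs: np.ndarray | pd.Series
               ) -> pd.DataFrame:
    """Direct N2O per source: load x EF x 44/28, kg N2O.

    ``loads`` has the :data:`LOAD_COMPONENTS` columns minus leaching; every
    source present is emitted at the row's EF and attributed separately, so
    the per-source columns sum exactly to ``total``.
    """
    ef = np.asarray(efs, dtype=float)
    out = pd.DataFrame(index=loads.index)
    total = np.zeros(len(loads))
    for comp in LOAD_COMPONENTS:
        if comp not in loads.columns:
            continue
        load = loads[comp].to_numpy(dtype=float)
        if (load < 0).any():
            raise ValueError(f"negative load in {comp}")
        e = load * ef * N_TO_N2O
        out[comp] = e
        total = total + e
    out["total"] = total
    return out


def leaching_n2o(loads: pd.DataFrame,
                 frac_leach: float | Mapping[str, float] = 0.2,
                 ef5: float = 0.011) -> pd.Series:
    """Indirect N2O from leached N: total N x frac_leach x EF5 x 44/28.

    ``frac_leach`` may be a single coefficient or a per-region mapping
    (``loads`` then needs a 'region' column).
    """
    comps = [c for c in LOAD_COMPONENTS if c in loads.columns]
    total_n = loads[comps].sum(axis=1).to_numpy(dtype=float)
    if np.isscalar(frac_leach):
        fl = np.full(len(loads), float(frac_leach))
    else:
        fl = loads["region"].map(frac_leach).to_numpy(dtype=float)
    if ((fl < 0) | (fl > 1)).any():
        raise ValueError("frac_leach must be in [0, 1]")
    return pd.Series(total_n * fl * ef5 * N_TO_N2O, index=loads.index,
                     name="leach_n2o")


@dataclass
class CroplandN2OResult:
    """Per (year, region, crop) N2O emissions and the loads behind them."""

    loads: pd.DataFrame
    direct: pd.DataFrame
    leach: pd.Series

    def total_kg(self) -> pd.Series:
        return self.direct["total"] + self.leach

    def by_year(self) -> pd.Series:
        df = self.loads[["year"]].copy()
        df["n2o"] = self.total_kg()
        return df.groupby("year")["n2o"].sum()


def compute_cropland_n2o(
    loads: pd.DataFrame,
    model: EFModel,
    covariates: pd.DataFrame,
    frac_leach: float | Mapping[str, float] = 0.2,
    ef5: float = 0.011,
    ef_override: Optional[np.ndarray] = None,
) -> CroplandN2OResult:
    """Predict per-row EFs by crop and evaluate both N2O pathways.

    ``loads`` and ``covariates`` are row-aligned with 'year', 'region' and
    'crop' columns; ``ef_override`` replaces model predictions (used to
    freeze EFs for the extrapolated final year).
    """
    if ef_override is not None:
        efs = np.asarray(ef_override, dtype=float)
    else:
        efs = np.empty(len(loads))
        for crop in loads["crop"].unique():
            sel = (loads["crop"] == crop).to_numpy()
            efs[sel] = model.predict(crop, covariates.loc[sel])
    direct = direct_n2o(loads, efs)
    leach = leaching_n2o(loads, frac_leach, ef5)
    result = CroplandN2OResult(loads=loads, direct=direct, leach=leach)
    result.efs = efs  # type: ignore[attr-defined]
    return result
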