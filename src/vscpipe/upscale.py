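"""Upscaling plot-level structure metrics to gridded maps.

Two geostatistical/ML pieces:

* **ordinary kriging** fills predictor layers that are only observed at
  plot locations (soil pH, organic carbon, nitrogen, partial pressures).
  A semivariogram is estimated from the sample pairs, a parametric model
  (spherical by default) is fitted by weighted least squares, and the
  ordinary-kriging system with a Lagrange multiplier is solved per cell.
  Predictions at sampled locations reproduce the observations exactly.

* a **random-forest regression** links the three structure metrics to the
  13 environmental predictors, validated on a 25% hold-out, and is then
  applied cell-by-cell to a predictor raster stack.  Maximum height is
  modelled on the log10 scale and back-transformed for mapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import train_test_split

from .raster import RasterStack
from .registry import ALL_VARS

__all__ = [
    "Variogram",
    "fit_variogram",
    "krige_layer",
    "UpscaleReport",
    "fit_rf",
    "predict_map",
    "observed_vs_predicted",
]

RESPONSES = ("height_max", "height_var", "height_even")


# ---------------------------------------------------------------------------
# ordinary kriging

def _spherical(h, nugget, psill, rng):
    h = np.asarray(h, dtype=float)
    g = np.where(
        h <= 0,
        0.0,
        np.where(
            h >= rng,
            nugget + psill,
            nugget + psill * (1.5 * h / rng - 0.5 * (h / rng) ** 3),
        ),
    )
    return g


def _exponential(h, nugget, psill, rng):
    h = np.asarray(h, dtype=float)
    return np.where(h <= 0, 0.0, nugget + psill * (1.0 - np.exp(-3.0 * h / rng)))


def _linear(h, nugget, slope):
    h = np.asarray(h, dtype=float)
    return np.where(h <= 0, 0.0, nugget + slope * h)


_MODELS = {"spherical": _spherical, "exponential": _exponential, "linear": _linear}


@dataclass
class Variogram:
    """A fitted semivariogram model gamma(h)."""

    model: str
    params: tuple[float, ...]
    lags: np.ndarray | None = None
    gamma_hat: np.ndarray | None = None

    def __call__(self, h: np.ndarray | float) -> np.ndarray:
        return _MODELS[self.model](h, *self.params)


def fit_variogram(
    coords: np.ndarray,
    values: np.ndarray,
    model: str = "spherical",
    n_lags: int = 12,
) -> Variogram:
    """Fit a parametric semivariogram by weighted least squares.

    The empirical semivariance ``0.5 * mean((z_i - z_j)^2)`` is computed in
    equal-width distance bins up to half the maximum pair distance, then the
    chosen model is fitted with bin pair counts as weights.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown variogram model {model!r}")
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    d = cdist(coords, coords)
    iu = np.triu_indices(len(values), k=1)
    dist = d[iu]
    semi = 0.5 * (values[iu[0]] - values[iu[1]]) ** 2
    dmax = dist.max()

    def _bin(cutoff: float):
        edges = np.linspace(0.0, max(cutoff, 1e-9), n_lags + 1)
        mids, gammas, cnts = [], [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = (dist > lo) & (dist <= hi)
            if sel.sum() > 0:
                mids.append(dist[sel].mean())
                gammas.append(semi[sel].mean())
                cnts.append(sel.sum())
        return (np.array(mids), np.array(gammas),
                np.array(cnts, dtype=float))

    lag_mid, gamma_hat, counts = _bin(dmax * 0.55)
    if len(lag_mid) < 2:
        # too few samples for the usual half-range cutoff: use all pairs
        lag_mid, gamma_hat, counts = _bin(dmax * (1.0 + 1e-9))

    var = values.var(ddof=1) if len(values) > 1 else 0.0
    if model == "linear":
        p0 = [0.0, max(gamma_hat[-1] / max(lag_mid[-1], 1e-9), 1e-12)]
        bounds = ([0.0, 0.0], [np.inf, np.inf])
    else:
        p0 = [0.0, max(var, 1e-12), max(dmax / 2.0, 1e-9)]
        bounds = ([0.0, 1e-12, 1e-9], [np.inf, np.inf, np.inf])
    if len(lag_mid) <= len(p0):
        # fewer bins than parameters: keep the moment-based estimate
        return Variogram(model=model, params=tuple(p0), lags=lag_mid,
                         gamma_hat=gamma_hat)
    try:
        popt, _ = curve_fit(
            _MODELS[model],
            lag_mid,
            gamma_hat,
            p0=p0,
            sigma=1.0 / np.sqrt(counts),
            bounds=bounds,
            maxfev=20000,
        )
    except (RuntimeError, TypeError):
        # no convergence, or fewer bins than parameters: keep the initial
        # moment-based estimate
        popt = np.array(p0)
    return Variogram(model=model, params=tuple(popt), lags=lag_mid,
                     gamma_hat=gamma_hat)


def krige_layer(
    coords: np.ndarray,
    values: np.ndarray,
    grid_coords: np.ndarray,
    variogram: str | Variogram = "spherical",
    n_lags: int = 12,
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary kriging of point samples onto target locations.

    Parameters
    ----------
    coords : (n, 2) sample locations.
    values : (n,) sample values.
    grid_coords : (m, 2) prediction locations.
    variogram : model name to fit, or an already fitted :class:`Variogram`.

    Returns
    -------
    (predictions, kriging_variance), both of length m.  The zero-distance
    semivariance is taken as 0 (even with a fitted nugget), which makes the
    interpolator exact at sampled locations.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    grid_coords = np.asarray(grid_coords, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 samples to krige")

    d = cdist(coords, coords)
    dup = np.argwhere(np.triu(d < 1e-12, k=1))
    if dup.size:
        pairs = [tuple(map(int, p)) for p in dup[:5]]
        raise ValueError(
            f"duplicate sample locations make the kriging system singular: "
            f"sample index pairs {pairs}"
        )

    # constant field: kriging degenerates to the constant with zero variance
    if np.ptp(values) < 1e-15 * max(1.0, abs(values[0])):
        return (
            np.full(len(grid_coords), values[0]),
            np.zeros(len(grid_coords)),
        )

    vg = variogram if isinstance(variogram, Variogram) else fit_variogram(
        coords, values, model=variogram, n_lags=n_lags
    )

    gamma = vg(d)
    np.fill_diagonal(gamma, 0.0)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = gamma
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    try:
        A_inv = np.linalg.inv(A)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"singular kriging system: {e}") from e

    d0 = cdist(grid_coords, coords)
    g0 = vg(d0)
    g0[d0 < 1e-12] = 0.0  # exactness at sample locations
    B = np.hstack([g0, np.ones((len(grid_coords), 1))])
    sol = B @ A_inv.T
    lam, mu = sol[:, :n], sol[:, n]
    pred = lam @ values
    var = np.einsum("ij,ij->i", lam, g0) + mu
    return pred, np.maximum(var, 0.0)


# ---------------------------------------------------------------------------
# random-forest upscaling

@dataclass
class UpscaleReport:
    """Hold-out validation summary of the random-forest upscaling."""

    validation_r2: dict[str, float]
    importance: dict[str, pd.Series]
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int
    predictors: list[str]
    log_height_max: bool
    r2_mode: str
    observed: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    predicted: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    models: dict[str, RandomForestRegressor] = field(
        default_factory=dict, repr=False
    )

    def to_dict(self) -> dict:
        return {
            "validation_r2": self.validation_r2,
            "importance": {k: v.to_dict() for k, v in self.importance.items()},
            "n_train": int(len(self.train_idx)),
            "n_test": int(len(self.test_idx)),
            "seed": self.seed,
            "predictors": self.predictors,
            "log_height_max": self.log_height_max,
            "r2_mode": self.r2_mode,
        }


def _r2(obs: np.ndarray, pred: np.ndarray, mode: str) -> float:
    if mode == "pearson":
        if np.std(pred) < 1e-300 or np.std(obs) < 1e-300:
            return 0.0
        return float(np.corrcoef(obs, pred)[0, 1] ** 2)
    if mode == "ssr":
        sst = float(((obs - obs.mean()) ** 2).sum())
        sse = float(((obs - pred) ** 2).sum())
        return 1.0 - sse / sst
    raise ValueError(f"unknown r2 mode {mode!r}")


def fit_rf(
    vsc: pd.DataFrame,
    env: pd.DataFrame,
    split_seed: int = 0,
    responses: Sequence[str] = RESPONSES,
    predictors: Sequence[str] = ALL_VARS,
    train_frac: float = 0.75,
    n_estimators: int = 500,
    max_features: float | str | None = None,
    min_train: int = 20,
    log_height_max: bool = True,
    r2_mode: Literal["pearson", "ssr"] = "pearson",
) -> UpscaleReport:
    """Train and validate random forests linking metrics to the environment.

    The plot table is split 75/25 (one shared split for all responses);
    validation R² is the squared Pearson correlation between observed and
    held-out predictions (a 1:1-line comparison) by default.  Variable
    importance is the forest's accumulated node-impurity (variance)
    reduction per predictor.
    """
    missing = [p for p in predictors if p not in env.columns]
    if missing:
        raise ValueError(f"environment table is missing predictor(s): {missing}")
    data = vsc.merge(env[["plot_id", *predictors]], on="plot_id", how="inner")
    # canonical ordering: the split depends on the seed, not on row order
    data = data.sort_values("plot_id", kind="stable").reset_index(drop=True)
    n = len(data)
    idx = np.arange(n)
    train_idx, test_idx = train_test_split(
        idx, train_size=train_frac, random_state=split_seed, shuffle=True
    )
    if len(train_idx) < min_train:
        raise ValueError(
            f"training set has {len(train_idx)} plots (< min_train={min_train})"
        )
    X = data[list(predictors)].to_numpy(dtype=float)
    if max_features is None:
        max_features = max(1, math.ceil(len(predictors) / 3)) / len(predictors)

    report = UpscaleReport(
        validation_r2={},
        importance={},
        train_idx=np.sort(train_idx),
        test_idx=np.sort(test_idx),
        seed=split_seed,
        predictors=list(predictors),
        log_height_max=log_height_max,
        r2_mode=r2_mode,
    )
    for resp in responses:
        y = data[resp].to_numpy(dtype=float)
        if resp == "height_max" and log_height_max:
            y = np.log10(y)
        rf = RandomForestRegressor(
            n_estimators=n_estimators,
            max_features=max_features,
            random_state=split_seed,
            n_jobs=1,
        )
        rf.fit(X[report.train_idx], y[report.train_idx])
        pred = rf.predict(X[report.test_idx])
        obs = y[report.test_idx]
        report.validation_r2[resp] = _r2(obs, pred, r2_mode)
        report.importance[resp] = pd.Series(
            rf.feature_importances_, index=list(predictors)
        ).sort_values(ascending=False)
        report.observed[resp] = obs
        report.predicted[resp] = pred
        report.models[resp] = rf
    return report


def predict_map(
    report: UpscaleReport, raster: RasterStack, response: str
) -> np.ndarray:
    """Apply a fitted forest cell-by-cell to a predictor raster stack.

    Masked or missing cells propagate as NaN; log-modelled maximum height is
    back-transformed to metres.
    """
    if response not in report.models:
        raise ValueError(f"no fitted model for response {response!r}")
    X, valid = raster.table(report.predictors)
    out = np.full(X.shape[0], np.nan)
    if valid.any():
        out[valid] = report.models[response].predict(X[valid])
    if response == "height_max" and report.log_height_max:
        out = 10.0**out
    return out.reshape(raster.shape)


def observed_vs_predicted(
    report: UpscaleReport, response: str
) -> tuple[pd.DataFrame, float]:
    """Held-out observed/predicted pairs and their squared correlation."""
    if response not in report.observed:
        raise ValueError(f"no validation predictions for {response!r}")
    df = pd.DataFrame(
        {"observed": report.observed[response],
         "predicted": report.predicted[response]}
    )
    return df, _r2(df["observed"].to_numpy(), df["predicted"].to_numpy(),
                   report.r2_mode)
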