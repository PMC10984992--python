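"""Attribution of vertical-structure variation to environmental drivers.

The inferential chain, per vegetation type and response metric:

1. **screening** of the 13 candidate variables by pairwise Pearson
   correlation, to remove near-duplicate drivers before any model fit;
2. **stepwise model selection** — a bidirectional AIC search over ordinary
   least-squares models, starting from the full model;
3. **relative importance** of the surviving variables by the LMG
   decomposition: each predictor's share of the model R² is its average
   incremental R² over all orders of predictor entry;
4. aggregation of those shares into **resource vs non-resource** percentages
   of the model R²;
5. diagnostics: variance inflation factors and Moran's I of the residuals;
6. **bootstrap size-matching** so that vegetation types with very different
   plot counts are compared at a common sample size;
7. a **partial correlation** check that controls for species diversity
   (Shannon–Wiener of importance values).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .registry import ALL_VARS, classify

__all__ = [
    "ScreenReport",
    "DriverModel",
    "screen_variables",
    "stepwise_select",
    "relative_importance",
    "vif",
    "resource_split",
    "bootstrap_match",
    "partial_correlation",
    "morans_i",
]


# ---------------------------------------------------------------------------
# screening

@dataclass
class ScreenReport:
    """Outcome of the collinearity screen over the 13 candidate variables."""

    kept: list[str]
    dropped: dict[str, str]  # variable -> rule that removed it
    correlation_matrix: pd.DataFrame


_TEMP_TRIO = ("T_coldest", "T_diurnal", "T_annual")


def screen_variables(
    env: pd.DataFrame,
    collinear_threshold: float = 0.9,
    trio_threshold: float = 0.5,
) -> ScreenReport:
    """Pearson screen of the 13 explanatory variables.

    Ordered rules:

    (i)   drop PCO2 when |r(PO2, PCO2)| >= ``collinear_threshold`` — the two
          partial pressures are near-duplicates by construction;
    (ii)  among the three cold/temperature-range variables, when any pair is
          inter-correlated at |r| >= ``trio_threshold``, keep only the member
          least correlated with MAT and drop the members redundant with it;
    (iii) drop MAP when AI is present and |r(AI, MAP)| >= ``collinear_threshold``
          (the aridity index already carries the precipitation signal).

    With the default thresholds on a table exhibiting the survey's observed
    correlation structure this retains 9 of the 13 variables.
    """
    missing = [v for v in ALL_VARS if v not in env.columns]
    if missing:
        raise ValueError(f"environment table is missing column(s): {missing}")
    if len(env) < 3:
        raise ValueError("need at least 3 plots to screen variables")
    for v in ALL_VARS:
        if np.isclose(env[v].std(ddof=0), 0.0):
            raise ValueError(f"column {v!r} is constant; correlation undefined")

    corr = env[list(ALL_VARS)].corr(method="pearson")
    dropped: dict[str, str] = {}

    if abs(corr.at["PO2", "PCO2"]) >= collinear_threshold:
        dropped["PCO2"] = (
            f"|r(PO2,PCO2)|={abs(corr.at['PO2', 'PCO2']):.3f} "
            f">= {collinear_threshold}"
        )

    trio = [v for v in _TEMP_TRIO if v not in dropped]
    pair_r = {
        (a, b): abs(corr.at[a, b]) for a, b in itertools.combinations(trio, 2)
    }
    if pair_r and max(pair_r.values()) >= trio_threshold:
        keep = min(trio, key=lambda v: abs(corr.at[v, "MAT"]))
        for v in trio:
            if v != keep and abs(corr.at[v, keep]) >= trio_threshold:
                dropped[v] = (
                    f"redundant with {keep} (|r|={abs(corr.at[v, keep]):.3f}); "
                    f"{keep} least correlated with MAT"
                )

    if "MAP" not in dropped and abs(corr.at["AI", "MAP"]) >= collinear_threshold:
        dropped["MAP"] = (
            f"|r(AI,MAP)|={abs(corr.at['AI', 'MAP']):.3f} >= {collinear_threshold}"
        )

    kept = [v for v in ALL_VARS if v not in dropped]
    return ScreenReport(kept=kept, dropped=dropped, correlation_matrix=corr)


# ---------------------------------------------------------------------------
# subset-R2 machinery shared by stepwise search and the LMG decomposition

class _R2Cache:
    """R² of OLS-with-intercept for arbitrary predictor subsets.

    Precomputes centered cross-products once; each subset then costs one
    small positive-definite solve.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.n, self.p = X.shape
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        self.sxx = Xc.T @ Xc
        self.sxy = Xc.T @ yc
        self.syy = float(yc @ yc)
        self._cache: dict[frozenset[int], float] = {frozenset(): 0.0}

    def r2(self, subset: Sequence[int]) -> float:
        key = frozenset(subset)
        if key in self._cache:
            return self._cache[key]
        idx = sorted(key)
        A = self.sxx[np.ix_(idx, idx)]
        b = self.sxy[idx]
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(A, b, rcond=None)[0]
        val = float(b @ beta) / self.syy if self.syy > 0 else 0.0
        val = min(max(val, 0.0), 1.0)
        self._cache[key] = val
        return val

    def aic(self, subset: Sequence[int]) -> float:
        """R-style AIC for lm: n*log(RSS/n) + 2*edf (edf = #coefficients)."""
        rss = self.syy * (1.0 - self.r2(subset))
        rss = max(rss, 1e-300)
        return self.n * math.log(rss / self.n) + 2 * (len(subset) + 1)


# ---------------------------------------------------------------------------
# model container

@dataclass
class DriverModel:
    """A selected OLS model with its relative-importance decomposition."""

    response: str
    selected_vars: list[str]
    coefficients: dict[str, float]
    pvalues: dict[str, float]
    vif: dict[str, float]
    r2_total: float
    r2_by_var: dict[str, float]
    resource_share: float
    nonresource_share: float
    residual_moran_i: float | None = None
    n_obs: int = 0
    aic: float = float("nan")
    residuals: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {
            "response": self.response,
            "selected_vars": self.selected_vars,
            "coefficients": self.coefficients,
            "pvalues": self.pvalues,
            "vif": self.vif,
            "r2_total": self.r2_total,
            "r2_by_var": self.r2_by_var,
            "resource_share": self.resource_share,
            "nonresource_share": self.nonresource_share,
            "residual_moran_i": self.residual_moran_i,
            "n_obs": self.n_obs,
            "aic": self.aic,
        }
        return d


def _check_design(X: pd.DataFrame) -> None:
    Xv = X.to_numpy(dtype=float)
    if np.isnan(Xv).any():
        raise ValueError("design matrix contains missing values")
    rank = np.linalg.matrix_rank(Xv - Xv.mean(axis=0))
    if rank < X.shape[1]:
        # name the aliased columns for the error message
        aliased = []
        cols = list(X.columns)
        kept: list[int] = []
        Xc = Xv - Xv.mean(axis=0)
        for j in range(X.shape[1]):
            trial = kept + [j]
            if np.linalg.matrix_rank(Xc[:, trial]) == len(trial):
                kept.append(j)
            else:
                aliased.append(cols[j])
        raise ValueError(f"rank-deficient design; aliased column(s): {aliased}")


def stepwise_select(
    y: pd.Series | np.ndarray,
    X: pd.DataFrame,
    response: str = "response",
    direction: str = "both",
    coords: np.ndarray | None = None,
    max_lmg_predictors: int = 12,
) -> DriverModel:
    """Bidirectional AIC search over OLS models, starting from the full model.

    At each step the single add or drop move with the lowest AIC is taken;
    ties are broken toward fewer predictors.  The surviving model is refit
    with statsmodels for coefficients and p-values, decomposed with the LMG
    method, and diagnosed with VIFs (and residual Moran's I when plot
    coordinates are supplied).
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("response contains missing values")
    n, p = len(y), X.shape[1]
    if n <= p + 2:
        raise ValueError(f"need n > p + 2 (n={n}, p={p})")
    _check_design(X)
    cols = list(X.columns)
    cache = _R2Cache(X.to_numpy(dtype=float), y)

    current: set[int] = set(range(p))
    current_aic = cache.aic(current)
    while True:
        moves: list[tuple[float, int, frozenset[int]]] = []
        if direction in ("both", "backward"):
            for j in current:
                cand = frozenset(current - {j})
                moves.append((cache.aic(cand), len(cand), cand))
        if direction in ("both", "forward"):
            for j in set(range(p)) - current:
                cand = frozenset(current | {j})
                moves.append((cache.aic(cand), len(cand), cand))
        if not moves:
            break
        moves.sort(key=lambda t: (t[0], t[1]))
        best_aic, _, best = moves[0]
        if best_aic < current_aic - 1e-10:
            current, current_aic = set(best), best_aic
        else:
            break

    selected = [cols[j] for j in sorted(current)]
    return _fit_driver_model(
        y, X, selected, response, coords, max_lmg_predictors, aic=current_aic
    )


def _fit_driver_model(
    y: np.ndarray,
    X: pd.DataFrame,
    selected: list[str],
    response: str,
    coords: np.ndarray | None,
    max_lmg_predictors: int = 12,
    aic: float = float("nan"),
) -> DriverModel:
    Xs = X[selected]
    design = sm.add_constant(Xs.to_numpy(dtype=float)) if selected else np.ones(
        (len(y), 1)
    )
    fit = sm.OLS(y, design).fit()
    names = ["const"] + selected
    coeffs = dict(zip(names, map(float, fit.params)))
    pvals = dict(zip(names, map(float, fit.pvalues)))
    r2_total = float(fit.rsquared) if selected else 0.0

    if selected:
        r2_by_var = relative_importance(
            Xs, y, max_predictors=max_lmg_predictors
        )
        vifs = vif(Xs)
        if all(var in ALL_VARS for var in selected):
            res_share, nonres_share = resource_split(r2_by_var)
        else:
            # generic predictors carry no resource classification
            res_share = nonres_share = float("nan")
    else:
        r2_by_var, vifs = {}, {}
        res_share = nonres_share = float("nan")

    moran = None
    if coords is not None:
        moran = morans_i(fit.resid, coords)

    return DriverModel(
        response=response,
        selected_vars=selected,
        coefficients=coeffs,
        pvalues=pvals,
        vif=vifs,
        r2_total=r2_total,
        r2_by_var=r2_by_var,
        resource_share=res_share,
        nonresource_share=nonres_share,
        residual_moran_i=moran,
        n_obs=len(y),
        aic=aic,
        residuals=np.asarray(fit.resid),
    )


# ---------------------------------------------------------------------------
# relative importance (LMG)

def relative_importance(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    max_predictors: int = 12,
) -> dict[str, float]:
    """LMG decomposition of the model R² over the predictors in X.

    For each predictor the incremental R² of adding it to a preceding set S
    is averaged over all orderings; equivalently, a Shapley value over
    subsets with weights |S|! (p-1-|S|)! / p!.  Shares are non-negative and
    sum to the full-model R².
    """
    p = X.shape[1]
    if p == 0:
        return {}
    if p > max_predictors:
        raise ValueError(
            f"{p} predictors exceeds the exact-enumeration limit "
            f"({max_predictors}); sampling of orderings is not implemented"
        )
    y = np.asarray(y, dtype=float)
    cache = _R2Cache(X.to_numpy(dtype=float), y)
    fact = [math.factorial(k) for k in range(p + 1)]
    shares = np.zeros(p)
    others = list(range(p))
    for j in range(p):
        rest = [k for k in others if k != j]
        for r in range(p):
            w = fact[r] * fact[p - 1 - r] / fact[p]
            for S in itertools.combinations(rest, r):
                shares[j] += w * (cache.r2(S + (j,)) - cache.r2(S))
    return {col: float(s) for col, s in zip(X.columns, shares)}


# ---------------------------------------------------------------------------
# diagnostics

def vif(X: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factor of each predictor: 1/(1-R²) of the
    auxiliary regression of that predictor on all the others.

    A single predictor has no auxiliary regression; its VIF is NaN.  Exact
    collinearity yields ``inf``.
    """
    cols = list(X.columns)
    if len(cols) == 1:
        return {cols[0]: float("nan")}
    out = {}
    Xv = X.to_numpy(dtype=float)
    for j, col in enumerate(cols):
        others = np.delete(np.arange(len(cols)), j)
        cache = _R2Cache(Xv[:, others], Xv[:, j])
        r2 = cache.r2(tuple(range(len(others))))
        out[col] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def resource_split(
    r2_by_var: Mapping[str, float],
) -> tuple[float, float]:
    """Resource and non-resource percentages of the model R².

    Sums LMG shares within each variable class; the two percentages sum
    to 100.  Undefined (NaN, NaN) for an empty model.
    """
    if not r2_by_var:
        return float("nan"), float("nan")
    res = nonres = 0.0
    for var, share in r2_by_var.items():
        cls = classify(var)  # raises KeyError for unregistered variables
        if cls == "resource":
            res += share
        else:
            nonres += share
    total = res + nonres
    if total <= 0:
        return float("nan"), float("nan")
    return 100.0 * res / total, 100.0 * nonres / total


# ---------------------------------------------------------------------------
# bootstrap size-matching

def bootstrap_match(
    data: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    n_target: int = 237,
    n_reps: int = 100,
    seed: int = 0,
    group_col: str = "veg_type",
    exclude: Sequence[str] = ("shrubland",),
) -> pd.DataFrame:
    """Size-matched resampling of the driver attribution across groups.

    For each vegetation type (minus ``exclude``) and each replicate,
    ``n_target`` plots are drawn without replacement, the stepwise
    selection and LMG split are rerun, and the resource/non-resource
    shares recorded.  Types with fewer than ``n_target`` plots raise.
    """
    rng = np.random.default_rng(seed)
    groups = [g for g in data[group_col].unique() if g not in set(exclude)]
    rows = []
    for g in groups:
        sub = data[data[group_col] == g].reset_index(drop=True)
        if len(sub) < n_target:
            raise ValueError(
                f"group {g!r} has {len(sub)} plots < n_target={n_target}"
            )
        for rep in range(n_reps):
            idx = rng.choice(len(sub), size=n_target, replace=False)
            samp = sub.iloc[idx]
            model = stepwise_select(
                samp[response], samp[list(predictors)], response=response
            )
            rows.append(
                {
                    "replicate": rep,
                    group_col: g,
                    "r2_total": model.r2_total,
                    "resource_share": model.resource_share,
                    "nonresource_share": model.nonresource_share,
                    "n_selected": len(model.selected_vars),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# partial correlation

def partial_correlation(
    x: Sequence[float], y: Sequence[float], control: Sequence[float]
) -> tuple[float, float]:
    """Zero-order Pearson r(x, y) and first-order partial r(x, y | control).

    The partial coefficient is the correlation of the residuals of x and y
    after regressing each on the control; it is NaN when either residual
    vector is (numerically) zero, e.g. when y equals the control.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(control, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    for name, v in (("x", x), ("y", y), ("control", z)):
        if np.isclose(v.std(ddof=0), 0.0):
            raise ValueError(f"{name} is constant")

    def _corr(a: np.ndarray, b: np.ndarray) -> float:
        return float(np.corrcoef(a, b)[0, 1])

    r_xy = _corr(x, y)

    def _resid(a: np.ndarray) -> np.ndarray:
        zc = z - z.mean()
        beta = float(zc @ (a - a.mean())) / float(zc @ zc)
        return a - a.mean() - beta * zc

    rx, ry = _resid(x), _resid(y)
    scale = max(np.abs(y).max(), np.abs(x).max(), 1.0)
    if np.abs(rx).max() < 1e-12 * scale or np.abs(ry).max() < 1e-12 * scale:
        return r_xy, float("nan")
    return r_xy, _corr(rx, ry)


# ---------------------------------------------------------------------------
# spatial autocorrelation

def _haversine_matrix(coords: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances (km) for (lat, lon) degree coordinates."""
    lat = np.radians(coords[:, 0])[:, None]
    lon = np.radians(coords[:, 1])[:, None]
    dlat = lat - lat.T
    dlon = lon - lon.T
    a = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
    return 2 * 6371.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def morans_i(
    values: Sequence[float],
    coords: np.ndarray | None = None,
    weight_scheme: str = "inverse_distance",
    weights: np.ndarray | None = None,
    row_standardize: bool = True,
    geographic: bool = True,
    k: int = 8,
) -> float:
    """Moran's I spatial autocorrelation statistic.

    ``I = (n / sum(w)) * (z' W z) / (z' z)`` with z the centered values and
    zero diagonal weights.  The null expectation is -1/(n-1).  Weight
    schemes: row-standardized inverse distance (default, great-circle
    distances for lat/lon coordinates), k-nearest-neighbour, or an explicit
    weight matrix via ``weights``.
    """
    z = np.asarray(values, dtype=float)
    n = len(z)
    if n < 3:
        raise ValueError("need at least 3 locations")
    if np.isclose(z.std(ddof=0), 0.0):
        raise ValueError("values are constant; Moran's I undefined")

    if weights is not None:
        W = np.asarray(weights, dtype=float).copy()
        if W.shape != (n, n):
            raise ValueError("weight matrix shape does not match values")
    else:
        if coords is None:
            raise ValueError("coords required when no weight matrix is given")
        coords = np.asarray(coords, dtype=float)
        d = _haversine_matrix(coords) if geographic else _euclidean_matrix(coords)
        np.fill_diagonal(d, np.inf)
        pos = d[np.isfinite(d) & (d > 0)]
        if pos.size == 0:
            raise ValueError("all points are coincident")
        dmin = pos.min()
        coincident = np.isfinite(d) & (d <= 0)
        if coincident.any():
            warnings.warn(
                "coincident points: capping their weight at the nearest "
                "positive distance",
                stacklevel=2,
            )
            d[coincident] = dmin
        if weight_scheme == "inverse_distance":
            W = 1.0 / d
        elif weight_scheme == "knn":
            W = np.zeros((n, n))
            order = np.argsort(d, axis=1)
            for i in range(n):
                W[i, order[i, :k]] = 1.0
        else:
            raise ValueError(f"unknown weight_scheme {weight_scheme!r}")
        W[~np.isfinite(W)] = 0.0

    np.fill_diagonal(W, 0.0)
    if row_standardize and weights is None:
        rows = W.sum(axis=1, keepdims=True)
        rows[rows == 0] = 1.0
        W = W / rows

    zc = z - z.mean()
    s0 = W.sum()
    if s0 <= 0:
        raise ValueError("weight matrix sums to zero")
    return float((n / s0) * (zc @ W @ zc) / (zc @ zc))


def _euclidean_matrix(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))
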