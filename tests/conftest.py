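"""Shared fixtures: small synthetic surveys and correlation-structured tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import vscpipe as v
from vscpipe.registry import ALL_VARS


@pytest.fixture(scope="session")
def small_survey():
    """A reduced survey (same regimes, fewer plots) shared across tests."""
    cfg = v.SyntheticConfig(
        n_plots_per_type={
            "forest": 60, "shrubland": 20, "meadow": 80, "steppe": 70,
            "desert": 50,
        },
        seed=11,
        grid_shape=(10, 10),
    )
    plots = v.generate_plots(cfg)
    vsc = v.vsc_table(plots)
    env = v.generate_env_table(plots)
    return cfg, plots, vsc, env


def gaussian_env_table(n: int = 4000, seed: int = 0) -> pd.DataFrame:
    """Synthetic Gaussian 13-variable table with the survey-style pooled
    correlation structure that drives variable screening.

    Built structurally (factor loadings on a temperature axis and a
    wetness axis) so the target matrix is positive definite by
    construction.  Pinned pairwise correlations: r(AI,MAP)=0.95,
    r(MAT,MAP)=0.62, r(MAT,AI)=0.45, r(MAT,T_diurnal)=-0.46,
    r(T_diurnal,T_annual)=-0.71, r(T_diurnal,T_coldest)=-0.60,
    r(T_coldest,T_annual)=0.65, and PCO2 exactly proportional to PO2
    (r=1).  The MAT correlations of T_coldest / T_annual (0.85 / 0.55)
    are larger in magnitude than T_diurnal's, so T_diurnal is the trio
    member least aligned with mean annual temperature.  The remaining
    six variables are independent noise.  Realised correlations match
    the pins to a few hundredths at large n.
    """
    r_mat_map, r_mat_ai, r_ai_map = 0.62, 0.45, 0.95
    lam = {"T_diurnal": -0.46, "T_coldest": 0.85, "T_annual": 0.55}
    trio_target = {
        ("T_diurnal", "T_coldest"): -0.60,
        ("T_diurnal", "T_annual"): -0.71,
        ("T_coldest", "T_annual"): 0.65,
    }

    rng = np.random.default_rng(seed)
    mat = rng.normal(size=n)
    wet = rng.normal(size=n)

    b_map = np.sqrt(1.0 - r_mat_map**2)
    map_ = r_mat_map * mat + b_map * wet
    b_ai = (r_ai_map - r_mat_map * r_mat_ai) / b_map
    g_ai = np.sqrt(1.0 - r_mat_ai**2 - b_ai**2)
    ai = r_mat_ai * mat + b_ai * wet + g_ai * rng.normal(size=n)

    # temperature trio: MAT loading + correlated residuals that make the
    # pairwise correlations land on the pinned targets
    trio = ("T_diurnal", "T_coldest", "T_annual")
    resid_sd = {t: np.sqrt(1.0 - lam[t] ** 2) for t in trio}
    S = np.eye(3)
    for (a, b), r_ab in trio_target.items():
        i, j = trio.index(a), trio.index(b)
        S[i, j] = S[j, i] = (r_ab - lam[a] * lam[b]) / (resid_sd[a] * resid_sd[b])
    L = np.linalg.cholesky(S)  # raises if the pins were inconsistent
    resid = rng.normal(size=(n, 3)) @ L.T
    temps = {
        t: lam[t] * mat + resid_sd[t] * resid[:, i] for i, t in enumerate(trio)
    }

    df = pd.DataFrame({"MAT": mat, "MAP": map_, "AI": ai, **temps})
    for name in ("pH", "SOC", "TN", "PO2", "UR", "Wind"):
        df[name] = rng.normal(size=n)
    df["PCO2"] = 0.0019 * df["PO2"]  # exact proportionality: r = 1
    return df[list(ALL_VARS)]
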