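"""Synthetic plot surveys and predictor rasters for a high-plateau gradient.

The generator emulates a field campaign across five vegetation types that
span the favorable-to-extreme climate gradient of a high cold plateau:
subtropical forests (canopies near 23 m) through shrublands, alpine
meadows and steppes, down to alpine desert grasslands (communities a few
centimetres tall).  Each plot receives

1. a geographic position and an environment vector consistent with its
   type's regime (forests wet and warm with high aridity index; deserts
   dry, windy, with wide diurnal temperature swings and low oxygen
   pressure at altitude),
2. latent plot-level structure targets (maximum height, height CV,
   height evenness) that follow a configurable linear model on the
   standardized environmental drivers, and
3. individual plant records (heights, plus coverage for grasslands or
   stem diameters for woody plots) realising those targets.

The default effect sizes encode the regime contrast under study: a
resource variable (aridity index) dominates vertical structure in the
forest/shrubland regime, while non-resource limiting variables (diurnal
temperature range, wind, oxygen partial pressure) dominate in the alpine
regimes, with the non-resource share growing monotonically toward the
desert end of the gradient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics import PlantRecord, Plot
from .raster import RasterStack
from .registry import (
    ALL_VARS,
    CO2_MIXING_RATIO,
    GRASSLAND_TYPES,
    O2_MIXING_RATIO,
    VEG_TYPES,
    validate_registry_names,
)

__all__ = [
    "SyntheticConfig",
    "generate_plots",
    "generate_env_table",
    "generate_raster",
    "compute_po2",
    "compute_pco2",
    "standardize_env",
    "default_effect_sizes",
    "default_noise_sd",
]

SEA_LEVEL_PRESSURE_KPA = 101.325
DEFAULT_SCALE_HEIGHT_M = 8000.0

#: Plot counts per vegetation type in the emulated survey (2013 in total).
DEFAULT_N_PLOTS = {
    "forest": 456,
    "shrubland": 30,
    "meadow": 669,
    "steppe": 621,
    "desert": 237,
}

#: Baseline (regime-mean) value of each structure metric per type.
METRIC_BASE = {
    "forest": {"height_max": 23.48, "height_var": 0.38, "height_even": 0.74},
    "shrubland": {"height_max": 1.23, "height_var": 0.79, "height_even": 0.75},
    "meadow": {"height_max": 0.17, "height_var": 0.75, "height_even": 0.69},
    "steppe": {"height_max": 0.16, "height_var": 0.67, "height_even": 0.75},
    "desert": {"height_max": 0.17, "height_var": 0.64, "height_even": 0.78},
}

#: Total spread (SD) of each metric per type, partitioned between the
#: configured driver effects and residual noise.
METRIC_SD = {
    "forest": {"height_max": 8.11, "height_var": 0.13, "height_even": 0.13},
    "shrubland": {"height_max": 0.51, "height_var": 0.18, "height_even": 0.11},
    "meadow": {"height_max": 0.11, "height_var": 0.35, "height_even": 0.10},
    "steppe": {"height_max": 0.08, "height_var": 0.31, "height_even": 0.12},
    "desert": {"height_max": 0.10, "height_var": 0.32, "height_even": 0.13},
}

#: Fraction of each metric's variance attributed to each driver, with sign.
#: Rows encode the regime contrast: aridity index (resource) dominates the
#: woody types; diurnal range / wind / oxygen pressure (non-resource)
#: dominate the alpine grassland types, increasingly so toward deserts.
_VARIANCE_SHARES: dict[str, dict[str, dict[str, float]]] = {
    "forest": {
        "height_max": {"AI": 0.352, "Wind": -0.051, "MAT": 0.027},
        "height_var": {"AI": 0.398, "MAT": 0.099, "pH": -0.021, "Wind": -0.074},
        "height_even": {"AI": 0.104, "UR": -0.032, "T_diurnal": -0.019, "PO2": 0.059},
    },
    "shrubland": {
        "height_max": {"AI": 0.603, "Wind": -0.180, "pH": -0.078},
        "height_var": {"AI": 0.403, "Wind": -0.135},
        "height_even": {"AI": 0.669, "T_diurnal": -0.151, "SOC": 0.034},
    },
    "meadow": {
        # the meadow regime keeps a moderate resource component (MAT, AI) so
        # the non-resource share steps up clearly from meadow to steppe
        "height_max": {
            "PO2": 0.151, "Wind": -0.110, "T_diurnal": -0.074,
            "MAT": 0.080, "AI": 0.040,
        },
        "height_var": {"MAT": 0.350, "Wind": -0.231, "PO2": 0.065, "AI": 0.018},
        "height_even": {"Wind": -0.110, "SOC": 0.007, "TN": 0.006, "pH": 0.004},
    },
    "steppe": {
        "height_max": {"T_diurnal": -0.390, "AI": 0.058, "Wind": -0.029},
        "height_var": {"MAT": 0.233, "Wind": -0.186, "PO2": 0.044, "SOC": 0.019},
        "height_even": {"TN": 0.083, "MAT": 0.071, "UR": -0.040},
    },
    "desert": {
        "height_max": {"T_diurnal": -0.205, "Wind": -0.111},
        "height_var": {
            "Wind": -0.174, "UR": -0.151, "T_diurnal": -0.091, "MAT": 0.029,
        },
        "height_even": {"Wind": -0.046},
    },
}

#: Directly sampled environment variables: (mean, sd) per vegetation type.
#: MAP, PO2 and PCO2 are derived (MAP = AI*PET; partial pressures from
#: elevation), so they carry no sampling entry here.
ENV_REGIMES: dict[str, dict[str, tuple[float, float]]] = {
    #           MAT(degC)    PET(mm)     AI          pH         SOC(g/kg)
    "forest": {
        "MAT": (8.0, 4.0), "PET": (900.0, 150.0), "AI": (1.10, 0.30),
        "pH": (6.0, 0.6), "SOC": (45.0, 15.0), "TN": (3.5, 1.2),
        "T_coldest": (-4.0, 4.0), "T_diurnal": (12.0, 2.0),
        "T_annual": (26.0, 3.0), "UR": (180.0, 25.0), "Wind": (1.8, 0.5),
    },
    "shrubland": {
        "MAT": (4.0, 3.0), "PET": (850.0, 120.0), "AI": (0.70, 0.20),
        "pH": (6.5, 0.6), "SOC": (35.0, 12.0), "TN": (2.8, 1.0),
        "T_coldest": (-10.0, 4.0), "T_diurnal": (13.0, 2.0),
        "T_annual": (28.0, 3.0), "UR": (200.0, 25.0), "Wind": (2.2, 0.6),
    },
    "meadow": {
        "MAT": (0.0, 2.5), "PET": (800.0, 100.0), "AI": (0.55, 0.15),
        "pH": (6.8, 0.5), "SOC": (30.0, 10.0), "TN": (2.5, 0.9),
        "T_coldest": (-15.0, 4.0), "T_diurnal": (14.0, 2.0),
        "T_annual": (30.0, 3.0), "UR": (220.0, 25.0), "Wind": (2.8, 0.7),
    },
    "steppe": {
        "MAT": (-2.0, 2.5), "PET": (750.0, 100.0), "AI": (0.30, 0.10),
        "pH": (7.6, 0.5), "SOC": (15.0, 6.0), "TN": (1.2, 0.5),
        "T_coldest": (-18.0, 4.0), "T_diurnal": (15.5, 2.0),
        "T_annual": (32.0, 3.0), "UR": (240.0, 25.0), "Wind": (3.5, 0.8),
    },
    "desert": {
        "MAT": (-4.0, 2.5), "PET": (800.0, 100.0), "AI": (0.12, 0.05),
        "pH": (8.2, 0.4), "SOC": (6.0, 3.0), "TN": (0.5, 0.25),
        "T_coldest": (-22.0, 4.0), "T_diurnal": (17.0, 2.0),
        "T_annual": (34.0, 3.0), "UR": (260.0, 25.0), "Wind": (4.5, 1.0),
    },
}

#: Geographic boxes per type: (lat_lo, lat_hi, lon_lo, lon_hi, elev_lo, elev_hi).
GEO_BOXES: dict[str, tuple[float, float, float, float, float, float]] = {
    "forest": (27.0, 32.0, 92.0, 102.0, 1000.0, 4000.0),
    "shrubland": (28.0, 34.0, 90.0, 102.0, 2500.0, 4300.0),
    "meadow": (29.0, 36.0, 88.0, 102.0, 3200.0, 5200.0),
    "steppe": (30.0, 37.0, 82.0, 95.0, 4200.0, 5200.0),
    "desert": (32.0, 39.0, 78.0, 92.0, 4300.0, 5500.0),
}

#: Expected number of species (grasslands) or stems (woody plots) per plot.
PLOT_RICHNESS = {
    "forest": 28,
    "shrubland": 8,
    "meadow": 8,
    "steppe": 6,
    "desert": 4,
}


def compute_po2(
    elevation: float | np.ndarray,
    sea_level_pressure: float = SEA_LEVEL_PRESSURE_KPA,
    scale_height: float = DEFAULT_SCALE_HEIGHT_M,
    mixing_ratio: float = O2_MIXING_RATIO,
) -> float | np.ndarray:
    """Oxygen partial pressure from elevation (isothermal barometric decay).

    ``PO2 = P0 * exp(-z / H) * x_O2`` with scale height H (default 8000 m)
    and the O2 volume mixing ratio of dry air.  Strictly decreasing in
    elevation.
    """
    if sea_level_pressure <= 0:
        raise ValueError("sea_level_pressure must be positive")
    z = np.asarray(elevation, dtype=float)
    out = sea_level_pressure * np.exp(-z / scale_height) * mixing_ratio
    return float(out) if np.isscalar(elevation) else out


def compute_pco2(
    elevation: float | np.ndarray,
    sea_level_pressure: float = SEA_LEVEL_PRESSURE_KPA,
    scale_height: float = DEFAULT_SCALE_HEIGHT_M,
) -> float | np.ndarray:
    """Carbon-dioxide partial pressure from elevation (same decay as PO2)."""
    return compute_po2(
        elevation, sea_level_pressure, scale_height, mixing_ratio=CO2_MIXING_RATIO
    )


def default_effect_sizes() -> dict[str, dict[str, dict[str, float]]]:
    """Driver effect sizes (metric units per SD of driver) per type & metric.

    Derived from the variance-share table: a driver carrying a signed
    fraction f of a metric's variance gets slope sign(f)*sqrt(|f|)*SD_metric.
    """
    out: dict[str, dict[str, dict[str, float]]] = {}
    for vt, metrics in _VARIANCE_SHARES.items():
        out[vt] = {}
        for metric, shares in metrics.items():
            sd = METRIC_SD[vt][metric]
            out[vt][metric] = {
                var: math.copysign(math.sqrt(abs(f)) * sd, f)
                for var, f in shares.items()
            }
    return out


def default_noise_sd() -> dict[str, dict[str, float]]:
    """Residual SD per type & metric: the variance not carried by drivers."""
    out: dict[str, dict[str, float]] = {}
    for vt, metrics in _VARIANCE_SHARES.items():
        out[vt] = {}
        for metric, shares in metrics.items():
            sd = METRIC_SD[vt][metric]
            resid_var = sd**2 * max(0.0, 1.0 - sum(abs(f) for f in shares.values()))
            out[vt][metric] = math.sqrt(resid_var)
    return out


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic survey scenario.

    ``effect_sizes[veg_type][metric][var]`` is the slope of the metric on
    the standardized driver; ``noise_sd[veg_type][metric]`` the residual SD
    on the metric's own scale.  Identical seeds yield bit-identical output.
    """

    n_plots_per_type: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PLOTS)
    )
    seed: int = 0
    effect_sizes: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=default_effect_sizes
    )
    noise_sd: dict[str, dict[str, float]] = field(default_factory=default_noise_sd)
    metric_base: dict[str, dict[str, float]] = field(
        default_factory=lambda: {vt: dict(m) for vt, m in METRIC_BASE.items()}
    )
    grid_shape: tuple[int, int] = (40, 40)
    richness: dict[str, int] = field(default_factory=lambda: dict(PLOT_RICHNESS))
    sea_level_pressure: float = SEA_LEVEL_PRESSURE_KPA
    scale_height: float = DEFAULT_SCALE_HEIGHT_M

    def __post_init__(self) -> None:
        for vt, n in self.n_plots_per_type.items():
            if vt not in VEG_TYPES:
                raise ValueError(f"unknown vegetation type {vt!r}")
            if n <= 0:
                raise ValueError(f"plot count for {vt} must be > 0, got {n}")
        for vt, metrics in self.effect_sizes.items():
            if vt not in VEG_TYPES:
                raise ValueError(f"unknown vegetation type {vt!r} in effect_sizes")
            for metric, eff in metrics.items():
                validate_registry_names(eff)
        for metrics in self.noise_sd.values():
            for metric, sd in metrics.items():
                if sd < 0:
                    raise ValueError(f"noise_sd must be >= 0, got {sd} for {metric}")
        r, c = self.grid_shape
        if r <= 0 or c <= 0:
            raise ValueError("grid_shape must be positive")

    def regime_stats(self, veg_type: str, var: str) -> tuple[float, float]:
        """(mean, sd) used to standardize *var* within *veg_type*.

        Derived variables (MAP, PO2, PCO2) get moments computed from their
        generating transforms so standardization is deterministic.
        """
        reg = ENV_REGIMES[veg_type]
        if var in reg:
            return reg[var]
        if var == "MAP":
            ai_m, ai_s = reg["AI"]
            pet_m, pet_s = reg["PET"]
            mean = ai_m * pet_m
            sd = math.sqrt(
                ai_m**2 * pet_s**2 + pet_m**2 * ai_s**2 + ai_s**2 * pet_s**2
            )
            return mean, sd
        if var in ("PO2", "PCO2"):
            lo, hi = GEO_BOXES[veg_type][4], GEO_BOXES[veg_type][5]
            z = np.linspace(lo, hi, 2001)
            fn = compute_po2 if var == "PO2" else compute_pco2
            vals = fn(z, self.sea_level_pressure, self.scale_height)
            return float(vals.mean()), float(vals.std())
        raise KeyError(f"no regime statistics for variable {var!r}")


def standardize_env(
    env: pd.DataFrame, veg_type: str, config: SyntheticConfig
) -> pd.DataFrame:
    """Z-score environment columns with the configured regime constants.

    Uses the generating (population) moments, not sample statistics, so the
    transform is independent of which plots were drawn.
    """
    out = {}
    for var in env.columns:
        if var in ALL_VARS:
            m, s = config.regime_stats(veg_type, var)
            out[var] = (env[var] - m) / s
    return pd.DataFrame(out, index=env.index)


def _sample_environment(
    vt: str, n: int, rng: np.random.Generator, config: SyntheticConfig
) -> pd.DataFrame:
    """Environment vectors for n plots of one vegetation type."""
    lat_lo, lat_hi, lon_lo, lon_hi, elev_lo, elev_hi = GEO_BOXES[vt]
    reg = ENV_REGIMES[vt]
    df = pd.DataFrame(
        {
            "lat": rng.uniform(lat_lo, lat_hi, n),
            "lon": rng.uniform(lon_lo, lon_hi, n),
            "elev": rng.uniform(elev_lo, elev_hi, n),
        }
    )
    for var, (m, s) in reg.items():
        df[var] = rng.normal(m, s, n)
    # the three cold/temperature-range variables track mean annual
    # temperature to different degrees: the coldest-month minimum and the
    # annual range are tightly coupled to MAT, the diurnal range only
    # weakly, so the collinearity screen retains the diurnal range
    zmat = (df["MAT"] - reg["MAT"][0]) / reg["MAT"][1]
    for var, r_mat in (("T_coldest", 0.80), ("T_annual", -0.75),
                       ("T_diurnal", -0.30)):
        m, s = reg[var]
        eps = rng.normal(0.0, 1.0, n)
        df[var] = m + s * (r_mat * zmat + math.sqrt(1.0 - r_mat**2) * eps)
    # physical floors
    df["PET"] = df["PET"].clip(lower=50.0)
    df["AI"] = df["AI"].clip(lower=0.01)
    df["SOC"] = df["SOC"].clip(lower=0.1)
    df["TN"] = df["TN"].clip(lower=0.02)
    df["Wind"] = df["Wind"].clip(lower=0.1)
    df["UR"] = df["UR"].clip(lower=1.0)
    # derived variables: the aridity index is MAP/PET by definition, and the
    # partial pressures follow barometric decay of total pressure
    df["MAP"] = df["AI"] * df["PET"]
    df["PO2"] = compute_po2(
        df["elev"].to_numpy(), config.sea_level_pressure, config.scale_height
    )
    df["PCO2"] = compute_pco2(
        df["elev"].to_numpy(), config.sea_level_pressure, config.scale_height
    )
    return df


def _metric_targets(
    vt: str, env: pd.DataFrame, rng: np.random.Generator, config: SyntheticConfig
) -> pd.DataFrame:
    """Latent plot-level metric targets from the configured linear models."""
    z = standardize_env(env, vt, config)
    n = len(env)
    out = {}
    for metric in ("height_max", "height_var", "height_even"):
        base = config.metric_base[vt][metric]
        val = np.full(n, base)
        for var, slope in config.effect_sizes.get(vt, {}).get(metric, {}).items():
            val = val + slope * z[var].to_numpy()
        sd = config.noise_sd.get(vt, {}).get(metric, 0.0)
        if sd > 0:
            val = val + rng.normal(0.0, sd, n)
        out[metric] = val
    df = pd.DataFrame(out)
    # floor at the 1 cm measurement precision of the grassland survey
    df["height_max"] = df["height_max"].clip(lower=0.01)
    df["height_var"] = df["height_var"].clip(lower=0.02, upper=2.5)
    df["height_even"] = df["height_even"].clip(lower=0.05, upper=1.0)
    return df


def _draw_heights(
    n: int, hmax: float, cv: float, rng: np.random.Generator
) -> np.ndarray:
    """n positive heights with max pinned to hmax and CV near cv.

    Heights are log-normal; rescaling so the maximum equals the target
    leaves the coefficient of variation unchanged (scale invariance), so
    the maximum is exact and the CV is the sampled realization of the
    target.
    """
    if n == 1:
        return np.array([hmax])
    sigma = math.sqrt(math.log(1.0 + cv**2))
    g = rng.normal(0.0, sigma, n)
    h = np.exp(g)
    return h * (hmax / h.max())


def _grassland_records(
    vt: str,
    hmax: float,
    cv: float,
    even: float,
    rng: np.random.Generator,
    config: SyntheticConfig,
) -> list[PlantRecord]:
    """Survey records for one grassland plot: 3 measured plants per species.

    Species coverages come from a Dirichlet whose concentration grows with
    the evenness target, so more even latent structure yields more uniform
    importance values (a monotone, not exactly linear, link).
    """
    n_species = max(1, int(rng.poisson(config.richness[vt])))
    # within-species height spread is small relative to between-species
    sig_within = 0.08
    sigma_total = math.sqrt(math.log(1.0 + cv**2))
    sig_between = math.sqrt(max(sigma_total**2 - sig_within**2, 1e-6))
    sp_log_mu = rng.normal(0.0, sig_between, n_species)
    heights = np.exp(
        sp_log_mu[:, None] + rng.normal(0.0, sig_within, (n_species, 3))
    )
    heights = heights * (hmax / heights.max())
    conc = 0.2 + 6.0 * even**3
    total_cover = rng.uniform(0.3, 0.95)
    shares = rng.dirichlet(np.full(n_species, conc))
    coverage = np.clip(shares * total_cover, 1e-4, 1.0)
    records = []
    for s in range(n_species):
        for j in range(3):
            records.append(
                PlantRecord(
                    species=f"sp{s:03d}",
                    height=float(heights[s, j]),
                    coverage=float(coverage[s]),
                )
            )
    return records


def _woody_records(
    vt: str,
    hmax: float,
    cv: float,
    rng: np.random.Generator,
    config: SyntheticConfig,
) -> list[PlantRecord]:
    """Stems for one forest or shrubland plot, with allometric diameters."""
    n = max(2, int(rng.poisson(config.richness[vt])))
    heights = _draw_heights(n, hmax, cv, rng)
    noise = np.exp(rng.normal(0.0, 0.15, n))
    if vt == "forest":
        # trees: DBH > 3 cm by survey convention
        dbh = 3.05 + 1.4 * heights**1.05 * noise
    else:
        dbh = 0.3 + 2.2 * heights**1.1 * noise
    n_sp = max(1, n // 3)
    sp = rng.integers(0, n_sp, n)
    return [
        PlantRecord(species=f"sp{sp[i]:03d}", height=float(heights[i]),
                    dbh=float(dbh[i]))
        for i in range(n)
    ]


def generate_plots(config: SyntheticConfig) -> list[Plot]:
    """Generate the full synthetic survey: one Plot per sampled community."""
    rng = np.random.default_rng(config.seed)
    plots: list[Plot] = []
    for vt in VEG_TYPES:
        if vt not in config.n_plots_per_type:
            continue
        n = config.n_plots_per_type[vt]
        env = _sample_environment(vt, n, rng, config)
        targets = _metric_targets(vt, env, rng, config)
        for i in range(n):
            hmax = float(targets.at[i, "height_max"])
            cv = float(targets.at[i, "height_var"])
            even = float(targets.at[i, "height_even"])
            if vt in GRASSLAND_TYPES:
                records = _grassland_records(vt, hmax, cv, even, rng, config)
            else:
                records = _woody_records(vt, hmax, cv, rng, config)
            env_row = {
                var: float(env.at[i, var]) for var in ALL_VARS
            }
            env_row["PET"] = float(env.at[i, "PET"])
            plots.append(
                Plot(
                    plot_id=f"{vt[:2]}{i:04d}",
                    veg_type=vt,
                    records=records,
                    lat=float(env.at[i, "lat"]),
                    lon=float(env.at[i, "lon"]),
                    elev=float(env.at[i, "elev"]),
                    env=env_row,
                )
            )
    return plots


def generate_env_table(plots: list[Plot]) -> pd.DataFrame:
    """One row per plot with the 13 explanatory variables plus coordinates."""
    rows = []
    for p in plots:
        row = {"plot_id": p.plot_id, "veg_type": p.veg_type,
               "lat": p.lat, "lon": p.lon, "elev": p.elev}
        row.update({v: p.env.get(v, np.nan) for v in ALL_VARS})
        rows.append(row)
    return pd.DataFrame(rows)


def _smooth_field(
    shape: tuple[int, int], lo: float, hi: float, rng: np.random.Generator
) -> np.ndarray:
    """A smooth gradient field in [lo, hi]: tilted plane + one long sinusoid."""
    r, c = shape
    v = np.linspace(0.0, 1.0, r)[:, None]
    u = np.linspace(0.0, 1.0, c)[None, :]
    a, b = rng.uniform(0.3, 0.7, 2)
    phase = rng.uniform(0.0, 2 * np.pi)
    s = 0.5 * (a * u + b * v) / (a + b) * 2.0
    s = 0.6 * s + 0.4 * (0.5 + 0.5 * np.sin(np.pi * (u + v) + phase))
    s = (s - s.min()) / max(s.max() - s.min(), 1e-12)
    return lo + (hi - lo) * s


def generate_raster(config: SyntheticConfig) -> RasterStack:
    """Smooth gridded layers for the 13 predictors plus an exclusion mask.

    Each directly sampled variable spans its pooled plot-level regime range;
    MAP, PO2 and PCO2 honour their defining transforms cell-by-cell.  A
    small blob of cells is masked, standing in for glaciers and lakes.
    """
    rng = np.random.default_rng(config.seed + 1)
    shape = config.grid_shape
    layers: dict[str, np.ndarray] = {}

    def pooled_range(var: str) -> tuple[float, float]:
        los, his = [], []
        for vt in VEG_TYPES:
            m, s = ENV_REGIMES[vt][var]
            los.append(m - 2 * s)
            his.append(m + 2 * s)
        return min(los), max(his)

    for var in ("MAT", "pH", "SOC", "TN", "T_coldest", "T_diurnal",
                "T_annual", "UR", "Wind"):
        lo, hi = pooled_range(var)
        layers[var] = _smooth_field(shape, lo, hi, rng)
    layers["SOC"] = np.clip(layers["SOC"], 0.1, None)
    layers["TN"] = np.clip(layers["TN"], 0.02, None)
    layers["Wind"] = np.clip(layers["Wind"], 0.1, None)

    pet = np.clip(_smooth_field(shape, *pooled_range("PET"), rng), 50.0, None)
    ai = np.clip(_smooth_field(shape, *pooled_range("AI"), rng), 0.01, None)
    layers["AI"] = ai
    layers["MAP"] = ai * pet

    elev_lo = min(b[4] for b in GEO_BOXES.values())
    elev_hi = max(b[5] for b in GEO_BOXES.values())
    elev = _smooth_field(shape, elev_lo, elev_hi, rng)
    layers["PO2"] = compute_po2(elev, config.sea_level_pressure, config.scale_height)
    layers["PCO2"] = compute_pco2(elev, config.sea_level_pressure, config.scale_height)

    mask = np.zeros(shape, dtype=bool)
    r, c = shape
    if r >= 4 and c >= 4:
        i0, j0 = rng.integers(0, r - 2), rng.integers(0, c - 2)
        mask[i0 : i0 + 2, j0 : j0 + 2] = True
    return RasterStack(layers=layers, mask=mask, cell_size=1.0)
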