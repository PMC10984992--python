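"""Plot-level vertical structural complexity (VSC) metrics.

Three metrics summarise how a plant community occupies vertical space:

* ``height_max`` — the tallest plant recorded in the plot (m);
* ``height_var`` — the coefficient of variation of plant heights,
  ``SD_H / Mean_H`` (dimensionless);
* ``height_even`` — Shannon evenness of weight shares across fixed-width
  height classes, ``[-sum(Pk ln Pk)] / ln(Nh)``, in [0, 1].

The class weight ``Pk`` depends on the growth form: in woody plots
(forests, shrublands) it is the basal-area share of the k-th height class;
in grassland plots each species contributes an importance value
``(relative height + relative coverage) / 2`` to the class of its mean
height.  Class widths are 1 m (forest), 10 cm (shrubland) and 1 cm
(grassland); classes are half-open intervals ``[k*w, (k+1)*w)`` anchored
at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .registry import CLASS_WIDTHS, GRASSLAND_TYPES, VEG_TYPES, WOODY_TYPES

__all__ = [
    "PlantRecord",
    "Plot",
    "VSCResult",
    "height_max",
    "height_var",
    "class_proportions",
    "evenness_from_proportions",
    "height_even",
    "importance_value",
    "shannon_wiener",
    "compute_vsc",
    "vsc_table",
    "gradient_bins",
    "bin_ratio",
]


@dataclass(frozen=True)
class PlantRecord:
    """One measured plant: species label, height, and a weight measurement.

    Grassland records carry fractional ``coverage``; woody records carry a
    stem diameter ``dbh`` in cm (diameter at breast height for trees, basal
    diameter for shrubs).
    """

    species: str
    height: float
    coverage: float | None = None
    dbh: float | None = None

    def __post_init__(self) -> None:
        if not self.height > 0:
            raise ValueError(f"height must be > 0, got {self.height}")
        if self.coverage is not None and not (0 < self.coverage <= 1):
            raise ValueError(f"coverage must be in (0, 1], got {self.coverage}")
        if self.dbh is not None and not self.dbh > 0:
            raise ValueError(f"dbh must be > 0, got {self.dbh}")


@dataclass
class Plot:
    """A surveyed plant community with its location and environment."""

    plot_id: str
    veg_type: str
    records: list[PlantRecord] = field(default_factory=list)
    lat: float = float("nan")
    lon: float = float("nan")
    elev: float = float("nan")
    env: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.veg_type not in VEG_TYPES:
            raise ValueError(
                f"unknown veg_type {self.veg_type!r}; expected one of {VEG_TYPES}"
            )

    @property
    def heights(self) -> np.ndarray:
        return np.array([r.height for r in self.records], dtype=float)

    @property
    def is_woody(self) -> bool:
        return self.veg_type in WOODY_TYPES


@dataclass(frozen=True)
class VSCResult:
    """The three VSC metrics of one plot plus bookkeeping counts."""

    plot_id: str
    veg_type: str
    height_max: float
    height_var: float
    height_even: float
    n_plants: int
    n_classes: int


def height_max(heights: Sequence[float] | np.ndarray) -> float:
    """Maximum plant height in a plot (m)."""
    h = np.asarray(heights, dtype=float)
    if h.size == 0:
        raise ValueError("height_max undefined for an empty plot")
    return float(h.max())


def height_var(
    heights: Sequence[float] | np.ndarray,
    sd_mode: Literal["sample", "population"] = "sample",
) -> float:
    """Coefficient of variation of plant heights, SD/mean.

    The sample (n-1 denominator) standard deviation is the default, since a
    plot is a sample of the surrounding community; the population form is
    available via ``sd_mode``.
    """
    h = np.asarray(heights, dtype=float)
    if h.size < 2:
        raise ValueError("height_var (CV) undefined for fewer than 2 plants")
    mean = h.mean()
    if mean <= 0:
        raise ValueError("mean height must be positive")
    ddof = 1 if sd_mode == "sample" else 0
    return float(h.std(ddof=ddof) / mean)


def _basal_area(dbh_cm: np.ndarray) -> np.ndarray:
    """Circular stem cross-section area from diameter (units cancel in shares)."""
    return np.pi * (dbh_cm / 2.0) ** 2


def class_proportions(
    heights: np.ndarray,
    weights: np.ndarray,
    class_width: float,
) -> pd.Series:
    """Weight share per occupied height class.

    Heights are binned into half-open classes ``[k*w, (k+1)*w)`` anchored at
    zero; the weights falling in each class are summed and normalised so the
    shares sum to one.  Returns a Series indexed by class index k.
    """
    if class_width <= 0:
        raise ValueError("class_width must be > 0")
    heights = np.asarray(heights, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if heights.size == 0:
        raise ValueError("empty plot")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    k = np.floor(heights / class_width).astype(int)
    shares = pd.Series(weights).groupby(k).sum() / total
    return shares[shares > 0]


def evenness_from_proportions(pk: Iterable[float]) -> float:
    """Normalised Shannon entropy of class shares; 1 for a single class.

    A single occupied class is the maximally uniform degenerate case and
    scores 1 by convention, consistent with a CV of 0 for equal heights.
    """
    p = np.asarray(list(pk), dtype=float)
    p = p[p > 0]
    if p.size == 0:
        raise ValueError("no occupied classes")
    if p.size == 1:
        return 1.0
    return float(-(p * np.log(p)).sum() / math.log(p.size))


def height_even(
    plot: Plot,
    class_width: float | None = None,
    nh_mode: Literal["occupied", "span"] = "occupied",
) -> tuple[float, int]:
    """Shannon evenness of height-class weight shares for one plot.

    Returns ``(evenness, n_classes)``.  ``nh_mode="occupied"`` (default)
    normalises by the number of occupied classes; ``"span"`` normalises by
    the number of classes spanned from the lowest to the highest occupied
    class, counting empty intermediate classes.
    """
    if class_width is None:
        class_width = CLASS_WIDTHS[plot.veg_type]
    if not plot.records:
        raise ValueError(f"plot {plot.plot_id}: empty plot")

    if plot.is_woody:
        dbh = np.array(
            [r.dbh if r.dbh is not None else np.nan for r in plot.records]
        )
        if np.isnan(dbh).any():
            raise ValueError(
                f"plot {plot.plot_id}: woody plot has records without dbh"
            )
        shares = class_proportions(plot.heights, _basal_area(dbh), class_width)
    else:
        shares = _grassland_class_proportions(plot, class_width)

    nh = len(shares)
    if nh_mode == "span":
        nh = int(shares.index.max() - shares.index.min()) + 1
    if nh <= 1:
        return 1.0, len(shares)
    p = shares.to_numpy()
    return float(-(p * np.log(p)).sum() / math.log(nh)), len(shares)


def _grassland_class_proportions(plot: Plot, class_width: float) -> pd.Series:
    """Per-class importance-value shares for a grassland plot.

    Each species is summarised by its mean height and total coverage; its
    weight is the importance value (relative mean height + relative
    coverage)/2 and it is assigned to the height class of its mean height.
    """
    rows = []
    for r in plot.records:
        if r.coverage is None:
            raise ValueError(
                f"plot {plot.plot_id}: grassland record without coverage"
            )
        rows.append((r.species, r.height, r.coverage))
    df = pd.DataFrame(rows, columns=["species", "height", "coverage"])
    # coverage is recorded once per species; averaging tolerates repeats
    sp = df.groupby("species").agg(
        mean_height=("height", "mean"), coverage=("coverage", "mean")
    )
    rel_h = sp["mean_height"] / sp["mean_height"].sum()
    rel_c = sp["coverage"] / sp["coverage"].sum()
    iv = (rel_h + rel_c) / 2.0
    return class_proportions(
        sp["mean_height"].to_numpy(), iv.to_numpy(), class_width
    )


def importance_value(relative_height: float, relative_coverage: float) -> float:
    """Species importance value: mean of relative height and relative coverage."""
    for name, v in (
        ("relative_height", relative_height),
        ("relative_coverage", relative_coverage),
    ):
        if not (0 <= v <= 1):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return (relative_height + relative_coverage) / 2.0


def shannon_wiener(iv: Sequence[float] | np.ndarray, rtol: float = 1e-6) -> float:
    """Shannon–Wiener diversity of species importance values, ``-sum(IV ln IV)``.

    Importance values must be non-negative and sum to ~1; they are
    renormalised when within ``rtol`` of 1.
    """
    p = np.asarray(iv, dtype=float)
    if p.size == 0 or p.sum() <= 0:
        raise ValueError("importance values must be positive")
    if np.any(p < 0):
        raise ValueError("importance values must be non-negative")
    if abs(p.sum() - 1.0) > max(rtol, 1e-12) and abs(p.sum() - 1.0) > 0.01:
        raise ValueError(f"importance values sum to {p.sum():.4f}, expected 1")
    p = p / p.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def compute_vsc(
    plot: Plot,
    sd_mode: Literal["sample", "population"] = "sample",
    nh_mode: Literal["occupied", "span"] = "occupied",
) -> VSCResult:
    """All three VSC metrics for a single plot."""
    h = plot.heights
    hmax = height_max(h)
    hvar = height_var(h, sd_mode=sd_mode) if h.size >= 2 else 0.0
    heven, n_classes = height_even(plot, nh_mode=nh_mode)
    return VSCResult(
        plot_id=plot.plot_id,
        veg_type=plot.veg_type,
        height_max=hmax,
        height_var=hvar,
        height_even=heven,
        n_plants=len(plot.records),
        n_classes=n_classes,
    )


def vsc_table(
    plots: Iterable[Plot],
    sd_mode: Literal["sample", "population"] = "sample",
    nh_mode: Literal["occupied", "span"] = "occupied",
) -> pd.DataFrame:
    """VSC metrics for a collection of plots, one row per plot.

    Carries coordinates through so downstream spatial diagnostics and
    gradient binning can join on them.
    """
    rows = []
    for p in plots:
        r = compute_vsc(p, sd_mode=sd_mode, nh_mode=nh_mode)
        rows.append(
            {
                "plot_id": r.plot_id,
                "veg_type": r.veg_type,
                "height_max": r.height_max,
                "height_var": r.height_var,
                "height_even": r.height_even,
                "n_plants": r.n_plants,
                "n_classes": r.n_classes,
                "lat": p.lat,
                "lon": p.lon,
                "elev": p.elev,
            }
        )
    return pd.DataFrame(rows)


_BIN_SPECS = {"latitude": ("lat", 3.0), "elevation": ("elev", 1000.0)}


def gradient_bins(
    vsc: pd.DataFrame,
    axis: Literal["latitude", "elevation"],
    metrics: Sequence[str] = ("height_max", "height_var", "height_even"),
) -> pd.DataFrame:
    """Mean VSC within fixed bands of latitude (3 deg) or elevation (1000 m).

    Returns one row per band with the band bounds, plot count and per-metric
    means; empty bands between occupied ones are reported with count 0 and
    NaN means.
    """
    col, width = _BIN_SPECS[axis]
    k = np.floor(vsc[col] / width).astype(int)
    grouped = vsc.groupby(k)
    out = grouped[list(metrics)].mean()
    out.insert(0, "n", grouped.size())
    full = pd.RangeIndex(k.min(), k.max() + 1)
    out = out.reindex(full)
    out["n"] = out["n"].fillna(0).astype(int)
    out.insert(0, "bin_low", out.index * width)
    out.insert(1, "bin_high", (out.index + 1) * width)
    out.index.name = f"{axis}_bin"
    return out.reset_index()


def bin_ratio(
    bins: pd.DataFrame, metric: str, low_a: float, low_b: float
) -> float:
    """Ratio of a metric's mean between the band starting at ``low_a`` and
    the band starting at ``low_b`` (e.g. how many times taller)."""
    a = bins.loc[bins["bin_low"] == low_a, metric]
    b = bins.loc[bins["bin_low"] == low_b, metric]
    if a.empty or b.empty:
        raise ValueError("requested band not present in the binned table")
    return float(a.iloc[0] / b.iloc[0])
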