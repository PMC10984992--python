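"""Gridded layers: an in-memory stack plus ESRI ASCII grid text I/O.

Grids are row-major, north-up 2-D arrays (row 0 is the northernmost row).
Each predictor layer in a :class:`RasterStack` shares one shape, origin and
cell size.  Masked cells (e.g. glaciers and lakes) carry the nodata
sentinel and propagate as missing through any prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA = -9999.0


def write_ascii_grid(
    path: str | Path,
    grid: np.ndarray,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    cellsize: float = 1.0,
    nodata: float = NODATA,
) -> None:
    """Write one layer as an ESRI ASCII grid (plain text)."""
    grid = np.asarray(grid, dtype=float)
    nrows, ncols = grid.shape
    out = grid.copy()
    out[~np.isfinite(out)] = nodata
    header = (
        f"ncols {ncols}\nnrows {nrows}\n"
        f"xllcorner {xllcorner!r}\nyllcorner {yllcorner!r}\n"
        f"cellsize {cellsize!r}\nNODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.8g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; nodata cells become NaN.

    Returns ``(grid, meta)`` with meta keys xllcorner, yllcorner, cellsize,
    nodata.
    """
    meta: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines[:6]:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            meta[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    grid = np.loadtxt(lines[n_header:])
    grid = np.atleast_2d(grid)
    nodata = meta.get("nodata_value", NODATA)
    grid[grid == nodata] = np.nan
    if "ncols" in meta and grid.shape != (int(meta["nrows"]), int(meta["ncols"])):
        raise ValueError(
            f"{path}: grid shape {grid.shape} does not match header "
            f"({int(meta['nrows'])}, {int(meta['ncols'])})"
        )
    return grid, {
        "xllcorner": meta.get("xllcorner", 0.0),
        "yllcorner": meta.get("yllcorner", 0.0),
        "cellsize": meta.get("cellsize", 1.0),
        "nodata": nodata,
    }


@dataclass
class RasterStack:
    """Named gridded layers sharing one grid geometry.

    ``mask`` is True where a cell is excluded from analysis; excluded cells
    hold NaN in every layer view returned by :meth:`get`.
    """

    layers: dict[str, np.ndarray]
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {name: lyr.shape for name, lyr in self.layers.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"layers have inconsistent shapes: {shapes}")
        if self.mask is not None and self.layers:
            if self.mask.shape != self.shape:
                raise ValueError("mask shape does not match layers")

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.layers.values()))
        return first.shape

    @property
    def names(self) -> list[str]:
        return sorted(self.layers)

    def get(self, name: str) -> np.ndarray:
        """Layer with the exclusion mask applied (masked cells = NaN)."""
        if name not in self.layers:
            raise KeyError(f"raster stack has no layer {name!r}")
        lyr = self.layers[name].astype(float).copy()
        if self.mask is not None:
            lyr[self.mask] = np.nan
        return lyr

    def table(self, names: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """Flatten the requested layers to an (n_cells, n_layers) matrix.

        Returns ``(X, valid)`` where ``valid`` marks rows with no missing
        value in any requested layer and outside the mask.
        """
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"raster stack is missing layer(s): {missing}")
        cols = [self.get(n).ravel() for n in names]
        X = np.column_stack(cols)
        valid = np.all(np.isfinite(X), axis=1)
        return X, valid

    def to_dir(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, lyr in self.layers.items():
            write_ascii_grid(
                directory / f"{name}.asc",
                lyr,
                xllcorner=self.origin[0],
                yllcorner=self.origin[1],
                cellsize=self.cell_size,
            )
        if self.mask is not None:
            write_ascii_grid(
                directory / "mask.asc",
                self.mask.astype(float),
                xllcorner=self.origin[0],
                yllcorner=self.origin[1],
                cellsize=self.cell_size,
            )

    @classmethod
    def from_dir(cls, directory: str | Path) -> "RasterStack":
        directory = Path(directory)
        paths = sorted(directory.glob("*.asc"))
        if not paths:
            raise FileNotFoundError(f"no .asc layers found in {directory}")
        layers: dict[str, np.ndarray] = {}
        mask = None
        meta: dict = {}
        for p in paths:
            grid, m = read_ascii_grid(p)
            if p.stem == "mask":
                mask = ~np.isfinite(grid) | (grid > 0.5)
            else:
                layers[p.stem] = grid
                meta = m
        return cls(
            layers=layers,
            cell_size=meta.get("cellsize", 1.0),
            origin=(meta.get("xllcorner", 0.0), meta.get("yllcorner", 0.0)),
            mask=mask,
            meta=meta,
        )
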