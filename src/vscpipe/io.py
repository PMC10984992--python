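"""Readers, writers and the pipeline driver.

Tables are UTF-8 comma-delimited text with '.' decimals.  The plot table
has one row per measured plant::

    plot_id, veg_type, species, height_m, coverage_frac, dbh_cm, lat, lon, elev_m

grassland rows carry ``coverage_frac`` (``dbh_cm`` empty), woody rows carry
``dbh_cm`` (``coverage_frac`` empty).  The environment table has one row
per plot with the 13 predictor columns under their registry names.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import drivers as drv
from . import metrics as met
from . import synthetic as syn
from . import upscale as ups
from .raster import RasterStack
from .registry import ALL_VARS, GRASSLAND_TYPES, VEG_TYPES, WOODY_TYPES

logger = logging.getLogger("vscpipe")

PLOT_COLUMNS = [
    "plot_id", "veg_type", "species", "height_m", "coverage_frac",
    "dbh_cm", "lat", "lon", "elev_m",
]


def write_plot_table(plots: list[met.Plot], path: str | Path) -> None:
    rows = []
    for p in plots:
        for r in p.records:
            rows.append(
                {
                    "plot_id": p.plot_id,
                    "veg_type": p.veg_type,
                    "species": r.species,
                    "height_m": r.height,
                    "coverage_frac": r.coverage if r.coverage is not None else "",
                    "dbh_cm": r.dbh if r.dbh is not None else "",
                    "lat": p.lat,
                    "lon": p.lon,
                    "elev_m": p.elev,
                }
            )
    pd.DataFrame(rows, columns=PLOT_COLUMNS).to_csv(path, index=False)


def read_plot_table(path: str | Path) -> list[met.Plot]:
    """Read and validate a plant-record table into plots.

    Row numbers (1-based, counting the header as row 1) are carried into
    every validation error.
    """
    df = pd.read_csv(
        path,
        dtype={"plot_id": str, "veg_type": str, "species": str},
        float_precision="round_trip",
    )
    missing = [c for c in PLOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {missing}")

    plots: dict[str, met.Plot] = {}
    for i, row in df.iterrows():
        rownum = int(i) + 2  # header is row 1
        vt = row["veg_type"]
        if vt not in VEG_TYPES:
            raise ValueError(f"{path}, row {rownum}: unknown veg_type {vt!r}")
        h = float(row["height_m"])
        if not h > 0:
            raise ValueError(f"{path}, row {rownum}: non-positive height {h}")
        cov = row["coverage_frac"]
        dbh = row["dbh_cm"]
        cov = None if pd.isna(cov) or cov == "" else float(cov)
        dbh = None if pd.isna(dbh) or dbh == "" else float(dbh)
        if vt in GRASSLAND_TYPES and cov is None:
            raise ValueError(
                f"{path}, row {rownum}: grassland record without coverage_frac"
            )
        if vt in WOODY_TYPES and dbh is None:
            raise ValueError(f"{path}, row {rownum}: woody record without dbh_cm")
        try:
            rec = met.PlantRecord(
                species=str(row["species"]), height=h, coverage=cov, dbh=dbh
            )
        except ValueError as e:
            raise ValueError(f"{path}, row {rownum}: {e}") from e
        pid = str(row["plot_id"])
        if pid not in plots:
            plots[pid] = met.Plot(
                plot_id=pid,
                veg_type=vt,
                lat=float(row["lat"]),
                lon=float(row["lon"]),
                elev=float(row["elev_m"]),
            )
        elif plots[pid].veg_type != vt:
            raise ValueError(
                f"{path}, row {rownum}: plot {pid} mixes vegetation types "
                f"({plots[pid].veg_type} vs {vt})"
            )
        plots[pid].records.append(rec)
    return list(plots.values())


def write_env_table(env: pd.DataFrame, path: str | Path) -> None:
    env.to_csv(path, index=False)


def read_env_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"plot_id": str, "veg_type": str},
        float_precision="round_trip",
    )
    missing = [v for v in ALL_VARS if v not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing predictor column(s): {missing}")
    return df


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class PipelineConfig:
    """End-to-end run configuration; stage toggles default to all-on."""

    out_dir: str = "vsc_output"
    seed: int = 0
    synthetic: syn.SyntheticConfig | None = None
    run_simulate: bool = True
    run_metrics: bool = True
    run_drivers: bool = True
    run_upscale: bool = True
    run_report: bool = True
    plots_path: str | None = None  # read instead of simulating
    env_path: str | None = None
    bootstrap_reps: int = 100
    bootstrap_n_target: int = 237
    responses: tuple[str, ...] = ("height_max", "height_var", "height_even")
    sd_mode: str = "sample"
    nh_mode: str = "occupied"

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        syn_cfg = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn_cfg is not None:
            if "grid_shape" in syn_cfg:
                syn_cfg["grid_shape"] = tuple(syn_cfg["grid_shape"])
            cfg.synthetic = syn.SyntheticConfig(**syn_cfg)
        return cfg


def summarize_by_type(vsc: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD and N of each metric per vegetation type."""
    g = vsc.groupby("veg_type")
    out = pd.DataFrame(
        {
            "height_max_mean": g["height_max"].mean(),
            "height_max_sd": g["height_max"].std(ddof=1),
            "height_var_mean": g["height_var"].mean(),
            "height_var_sd": g["height_var"].std(ddof=1),
            "height_even_mean": g["height_even"].mean(),
            "height_even_sd": g["height_even"].std(ddof=1),
            "N": g.size(),
        }
    )
    order = [v for v in VEG_TYPES if v in out.index]
    return out.loc[order].reset_index()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate -> metrics -> drivers -> upscale -> report.

    Every stochastic stage logs its seed; fixed seeds make the whole output
    bundle bit-identical across runs.  Returns the report bundle dict.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"seed": config.seed, "stages": []}
    plots: list[met.Plot] | None = None
    env: pd.DataFrame | None = None
    vsc: pd.DataFrame | None = None
    raster: RasterStack | None = None

    def stage(name: str):
        logger.info("stage %s (seed=%d)", name, config.seed)
        bundle["stages"].append(name)

    if config.run_simulate:
        stage("simulate")
        try:
            syn_cfg = config.synthetic or syn.SyntheticConfig(seed=config.seed)
            plots = syn.generate_plots(syn_cfg)
            env = syn.generate_env_table(plots)
            raster = syn.generate_raster(syn_cfg)
            write_plot_table(plots, out_dir / "plots.csv")
            write_env_table(env, out_dir / "env.csv")
            raster.to_dir(out_dir / "rasters")
            logger.info("simulated %d plots", len(plots))
        except Exception as e:
            raise RuntimeError(f"stage simulate failed: {e}") from e
    elif config.plots_path:
        plots = read_plot_table(config.plots_path)
        env = read_env_table(config.env_path) if config.env_path else None

    if config.run_metrics:
        stage("metrics")
        try:
            if plots is None:
                raise ValueError("no plots available (simulate off, no plots_path)")
            vsc = met.vsc_table(plots, sd_mode=config.sd_mode, nh_mode=config.nh_mode)
            vsc.to_csv(out_dir / "vsc.csv", index=False)
        except Exception as e:
            raise RuntimeError(f"stage metrics failed: {e}") from e

    if config.run_drivers:
        stage("drivers")
        try:
            if vsc is None or env is None:
                raise ValueError("drivers stage needs metrics and environment")
            screen = drv.screen_variables(env)
            data = vsc.merge(
                env[["plot_id", *ALL_VARS]], on="plot_id", how="inner"
            )
            models: dict[str, dict] = {"screening": {
                "kept": screen.kept, "dropped": screen.dropped}}
            for vt in data["veg_type"].unique():
                sub = data[data["veg_type"] == vt]
                coords = sub[["lat", "lon"]].to_numpy()
                models[vt] = {}
                for resp in config.responses:
                    m = drv.stepwise_select(
                        sub[resp], sub[screen.kept], response=resp, coords=coords
                    )
                    models[vt][resp] = m.to_dict()
            with open(out_dir / "models.json", "w") as fh:
                json.dump(models, fh, indent=1)
            bundle["models"] = models

            counts = data["veg_type"].value_counts()
            eligible = counts[counts >= config.bootstrap_n_target].index
            boot = drv.bootstrap_match(
                data[data["veg_type"].isin(eligible)],
                response="height_max",
                predictors=screen.kept,
                n_target=config.bootstrap_n_target,
                n_reps=config.bootstrap_reps,
                seed=config.seed,
            )
            boot.to_csv(out_dir / "bootstrap.csv", index=False)
            bundle["bootstrap_mean_shares"] = (
                boot.groupby("veg_type")[["resource_share", "nonresource_share"]]
                .mean()
                .to_dict("index")
            )
        except Exception as e:
            raise RuntimeError(f"stage drivers failed: {e}") from e

    if config.run_upscale:
        stage("upscale")
        try:
            if vsc is None or env is None:
                raise ValueError("upscale stage needs metrics and environment")
            report = ups.fit_rf(vsc, env, split_seed=config.seed)
            bundle["upscale"] = report.to_dict()
            with open(out_dir / "upscale_report.json", "w") as fh:
                json.dump(report.to_dict(), fh, indent=1)
            if raster is not None:
                maps_dir = out_dir / "maps"
                maps_dir.mkdir(exist_ok=True)
                map_layers = {}
                for resp in config.responses:
                    map_layers[resp] = ups.predict_map(report, raster, resp)
                RasterStack(
                    layers=map_layers,
                    cell_size=raster.cell_size,
                    origin=raster.origin,
                    mask=raster.mask,
                ).to_dir(maps_dir)
        except Exception as e:
            raise RuntimeError(f"stage upscale failed: {e}") from e

    if config.run_report:
        stage("report")
        try:
            if vsc is not None:
                summary = summarize_by_type(vsc)
                summary.to_csv(out_dir / "summary_table.csv", index=False)
                bundle["summary"] = summary.to_dict("records")
            with open(out_dir / "report.json", "w") as fh:
                json.dump(_jsonable(bundle), fh, indent=1)
        except Exception as e:
            raise RuntimeError(f"stage report failed: {e}") from e

    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj
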