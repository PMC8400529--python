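"""Run configuration and end-to-end orchestration.

A run is: enumerate scenarios -> generate radiance fields -> integrate
irradiance profiles -> regress attenuation coefficients -> assemble the
assessment tables. Everything is deterministic for a fixed configuration and
base seed (the default pipeline is noise free; noise uses per-scenario seeds
derived from the base seed by a fixed counter). Output tables are CSV with a
provenance header comment (config hash + seed); radiance fields can be
persisted as NetCDF.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .assessment import (
    RATIO_DEPTHS_M,
    AssessmentTables,
    error_heatmap,
    lighting_heatmaps,
    mean_cell_slope,
    ratio_analysis,
    scatter_stats,
    slope_and_error_tables,
    water_type_error_maps,
)
from .attenuation import DEPTH_RANGES_M, k_profiles, k_regression
from .bio_optics import water_classes
from .quad_grid import build_grid
from .radiance_synth import (
    CLOUD_GRID,
    ZENITH_GRID_DEG,
    Scenario,
    generate_field,
    par_wavelengths,
    scenario_grid,
    table1_depths,
)
from .radiometry import irradiance_profile

__all__ = ["RunConfig", "load_config", "save_config", "compute_k_table",
           "assess_from_tables", "run_pipeline"]

logger = logging.getLogger("annkd")

_ALL_CLASSES = tuple(w.name for w in water_classes())


@dataclass
class RunConfig:
    """Validated pipeline configuration (defaults = the full study grid)."""

    base_seed: int = 12345
    water_classes: Sequence[str] = _ALL_CLASSES
    zeniths: Sequence[float] = ZENITH_GRID_DEG
    clouds: Sequence[float] = CLOUD_GRID
    spectral_resolution_nm: float = 5.0
    noise_sd: float = 0.0
    depth_ranges: Sequence[float] = DEPTH_RANGES_M
    ratio_depths: Sequence[float] = RATIO_DEPTHS_M
    assessment_bands: Sequence[str] = ("Ea40", "Ea50")
    heatmap_depth: float = 1.5
    out_dir: str = "annkd_out"
    log_level: str = "INFO"

    def __post_init__(self):
        for name in self.water_classes:
            if name not in _ALL_CLASSES:
                raise ValueError(f"unknown water class {name!r} in config")
        for z in self.zeniths:
            if float(z) not in ZENITH_GRID_DEG:
                raise ValueError(
                    f"illegal zenith value {z}; legal values: {ZENITH_GRID_DEG}"
                )
        for c in self.clouds:
            if not any(np.isclose(float(c), g) for g in CLOUD_GRID):
                raise ValueError(
                    f"illegal cloud value {c}; legal values: {CLOUD_GRID}"
                )
        if self.spectral_resolution_nm not in (5.0, 10.0):
            raise ValueError("spectral_resolution_nm must be 5 or 10")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for z in self.depth_ranges:
            if z <= 0:
                raise ValueError("depth ranges must be positive")

    @property
    def max_depth(self) -> float:
        return float(max(max(self.depth_ranges), max(self.ratio_depths)))

    def scenarios(self) -> list[Scenario]:
        return scenario_grid(
            zeniths=self.zeniths,
            clouds=self.clouds,
            classes=list(self.water_classes),
            base_seed=self.base_seed,
            wavelengths=par_wavelengths(self.spectral_resolution_nm),
            depths=table1_depths(self.max_depth),
            noise_sd=self.noise_sd,
        )

    def config_hash(self) -> str:
        # hash of the scientific parameters only (where the run is written
        # and how verbosely it logs do not change the results)
        d = _as_plain_dict(self)
        d.pop("out_dir"), d.pop("log_level")
        blob = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _as_plain_dict(config: RunConfig) -> dict:
    d = asdict(config)
    return {
        k: list(v) if isinstance(v, (tuple, list)) else v for k, v in d.items()
    }


def load_config(path) -> RunConfig:
    """Load a YAML config; unknown keys or illegal values raise ValueError."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    legal = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - legal
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_as_plain_dict(config), sort_keys=True))


def compute_k_table(
    scenarios: Sequence[Scenario],
    grid=None,
    depth_ranges=DEPTH_RANGES_M,
    ratio_depths=RATIO_DEPTHS_M,
    progress_every: int = 500,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One pass over a scenario set: attenuation table + log-ratio table.

    Returns ``(k_df, ratio_df)``: ``k_df`` has one row per scenario x band x
    depth range with scenario metadata; ``ratio_df`` one row per scenario x
    annular band x ratio depth with ``log_ratio`` = log10(Ea_par/Ed_par).
    """
    if grid is None:
        grid = build_grid()
    if not scenarios:
        raise ValueError("empty scenario set")
    ratio_depths = [z for z in ratio_depths if z <= scenarios[0].depths[-1] + 1e-9]
    k_rows, ratio_rows = [], []
    t0 = time.perf_counter()
    for i, sc in enumerate(scenarios):
        prof = irradiance_profile(generate_field(sc, grid), grid)
        kp = k_profiles(prof, depth_ranges)
        kp["water_class"] = sc.water_class
        kp["chl"] = sc.chl
        kp["cdom380"] = sc.cdom380
        kp["mineral"] = sc.mineral
        kp["solar_zenith_deg"] = sc.solar_zenith_deg
        kp["cloud_fraction"] = sc.cloud_fraction
        k_rows.append(kp)
        for z in ratio_depths:
            iz = prof.depth_row(z)
            for j, th in enumerate(prof.annular_centers_deg):
                ratio_rows.append(
                    {
                        "scenario_id": sc.scenario_id,
                        "water_class": sc.water_class,
                        "solar_zenith_deg": sc.solar_zenith_deg,
                        "cloud_fraction": sc.cloud_fraction,
                        "theta_deg": float(th),
                        "depth_m": float(z),
                        "log_ratio": float(
                            np.log10(prof.ea_par[iz, j] / prof.ed_par[iz])
                        ),
                    }
                )
        if progress_every and (i + 1) % progress_every == 0:
            logger.info(
                "processed %d/%d scenarios (%.1f s)",
                i + 1, len(scenarios), time.perf_counter() - t0,
            )
    return pd.concat(k_rows, ignore_index=True), pd.DataFrame(ratio_rows)


def _ratio_stats(ratio_df: pd.DataFrame) -> pd.DataFrame:
    return (
        ratio_df.groupby(["theta_deg", "depth_m"])["log_ratio"]
        .agg(mean="mean", sd=lambda v: float(np.std(v)), n="count")
        .reset_index()
    )


def assess_from_tables(
    k_df: pd.DataFrame,
    ratio_df: pd.DataFrame | None = None,
    bands=("Ea40", "Ea50"),
    depth_ranges=DEPTH_RANGES_M,
    heatmap_depth: float = 1.5,
) -> AssessmentTables:
    """Assemble every assessment product from precomputed tables.

    Running this on a persisted attenuation table gives results identical to
    a full pipeline run (the tables are the only state the assessment uses).
    """
    scatter_rows = []
    for band in bands:
        for z_max in depth_ranges:
            sel = k_df[np.isclose(k_df["z_max"], z_max)]
            kd = sel[sel["band"] == "Ed"].set_index("scenario_id")["K"]
            ka = sel[sel["band"] == band].set_index("scenario_id")["K"]
            common = kd.index.intersection(ka.index)
            r, m = scatter_stats(kd.loc[common], ka.loc[common])
            scatter_rows.append(
                {"band": band, "z_max": float(z_max), "r": r, "m": m,
                 "n": len(common)}
            )
    slope_df, error_df = slope_and_error_tables(k_df, bands, depth_ranges)
    tables = AssessmentTables(
        ratio_stats=_ratio_stats(ratio_df) if ratio_df is not None else pd.DataFrame(),
        scatter=pd.DataFrame(scatter_rows),
        slope_table=slope_df,
        error_table=error_df,
    )
    for band in bands:
        tables.heatmaps[band] = lighting_heatmaps(k_df, band, heatmap_depth)
        m = mean_cell_slope(k_df, band, heatmap_depth)
        tables.error_heatmaps[band] = error_heatmap(k_df, band, heatmap_depth, m=m)
        tables.water_type_errors[band] = water_type_error_maps(
            k_df, band, heatmap_depth, m=m
        )
    return tables


def _write_csv(df: pd.DataFrame, path: Path, header: str, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=index)


def run_pipeline(config: RunConfig) -> AssessmentTables:
    """Execute the full pipeline and persist every table under ``out_dir``."""
    logging.basicConfig(level=config.log_level)
    grid = build_grid()
    scenarios = config.scenarios()
    logger.info("scenario grid: %d scenarios", len(scenarios))
    t0 = time.perf_counter()
    try:
        k_df, ratio_df = compute_k_table(
            scenarios, grid, config.depth_ranges, config.ratio_depths
        )
    except Exception as err:  # surface the failing stage for operators
        raise RuntimeError(f"pipeline stage 'attenuation' failed: {err}") from err
    tables = assess_from_tables(
        k_df,
        ratio_df,
        bands=config.assessment_bands,
        depth_ranges=config.depth_ranges,
        heatmap_depth=config.heatmap_depth,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# annkd config_hash={config.config_hash()} seed={config.base_seed}\n"
    _write_csv(k_df, out / "k_table.csv", header)
    _write_csv(ratio_df, out / "ratio_table.csv", header)
    _write_csv(tables.ratio_stats, out / "ratio_stats.csv", header)
    _write_csv(tables.scatter, out / "scatter_stats.csv", header)
    _write_csv(tables.slope_table, out / "slope_table.csv", header, index=True)
    _write_csv(tables.error_table, out / "error_table.csv", header, index=True)
    for band, df in tables.heatmaps.items():
        _write_csv(df, out / f"heatmap_{band}.csv", header)
    for band, df in tables.error_heatmaps.items():
        _write_csv(df, out / f"error_heatmap_{band}.csv", header)
    for band, df in tables.water_type_errors.items():
        _write_csv(df, out / f"water_type_errors_{band}.csv", header)
    logger.info(
        "pipeline complete: %d scenarios in %.1f s -> %s",
        len(scenarios), time.perf_counter() - t0, out,
    )
    return tables
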