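"""Assessment of the annular attenuation Ka as a proxy for planar Kd.

Given a long-format attenuation table (one row per scenario x band x depth
range, with scenario metadata), this module reproduces the study analyses:

* optimal-angle statistics: mean and standard deviation of
  ``log10(Ea(theta_i)/Ed)`` per band and analysis depth across a scenario set;
* Kd-Ka scatter statistics: Pearson r and the slope m of the least-squares
  regression of Ka (response) on Kd (predictor) - this orientation makes the
  reconstruction ``Kd_hat = Ka/m`` exact when the relation is;
* lighting heat-maps: r and m per (solar zenith x cloud cover) cell, each
  cell pooling all water classes and concentration corners (56 points);
* slope and error tables: the average slope m per (band, depth range), the
  reconstruction ``Kd_hat = Ka/m`` and the relative error
  ``eps_K = (Kd_hat - Kd)/Kd * 100`` (%), summarized as the mean absolute
  relative error (reported as a fraction in the table layout), per lighting
  cell, and per water type.

Correlation significance (p-value at the 0.05 level) is computed and
reported; no cell filtering is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .attenuation import DEPTH_RANGES_M
from .radiometry import IrradianceProfile, log_ratio_ea_ed

__all__ = [
    "AssessmentTables",
    "RATIO_DEPTHS_M",
    "ratio_analysis",
    "scatter_stats",
    "lighting_heatmaps",
    "mean_cell_slope",
    "relative_errors",
    "error_heatmap",
    "water_type_error_maps",
    "slope_and_error_tables",
    "render_heatmap",
]

#: Analysis depths (m) for the Ea/Ed ratio diagnostics.
RATIO_DEPTHS_M = (0.2, 0.5, 1.0, 1.5, 5.0, 10.0)


def ratio_analysis(
    profiles: Iterable[IrradianceProfile], depths=RATIO_DEPTHS_M
) -> pd.DataFrame:
    """Mean and standard deviation of log10(Ea/Ed) per band and depth.

    ``profiles`` may be any iterable (a generator is fine; it is consumed
    once). Standard deviation is the population value (0 for one scenario).
    """
    records = []
    n_profiles = 0
    for prof in profiles:
        n_profiles += 1
        for z in depths:
            for th in prof.annular_centers_deg:
                records.append(
                    {
                        "theta_deg": float(th),
                        "depth_m": float(z),
                        "log_ratio": log_ratio_ea_ed(prof, th, z),
                    }
                )
    if n_profiles == 0:
        raise ValueError("empty scenario set")
    df = pd.DataFrame(records)
    out = (
        df.groupby(["theta_deg", "depth_m"])["log_ratio"]
        .agg(mean="mean", sd=lambda v: float(np.std(v)), n="count")
        .reset_index()
    )
    return out


def scatter_stats(kd, ka) -> tuple[float, float]:
    """Pearson r and slope m of the regression of Ka on Kd."""
    kd = np.asarray(kd, dtype=float)
    ka = np.asarray(ka, dtype=float)
    if kd.size != ka.size:
        raise ValueError("Kd and Ka vectors must have equal length")
    if kd.size < 3:
        raise ValueError(f"need at least 3 points, got {kd.size}")
    if np.allclose(kd, kd[0]):
        raise ValueError("Kd has zero variance; the regression is undefined")
    if np.allclose(ka, ka[0]):
        return 0.0, 0.0  # constant response: flat line, no association
    fit = stats.linregress(kd, ka)
    return float(fit.rvalue), float(fit.slope)


def _pivot(k_df: pd.DataFrame, band: str, z_max: float) -> pd.DataFrame:
    """Per-scenario (Kd, Ka) pairs with lighting/water metadata."""
    sel = k_df[np.isclose(k_df["z_max"], z_max)]
    if sel.empty:
        raise ValueError(f"no results for depth range 0-{z_max} m")
    kd = sel[sel["band"] == "Ed"]
    ka = sel[sel["band"] == band]
    if ka.empty:
        raise ValueError(f"no results for band {band!r}")
    meta = ["scenario_id", "water_class", "solar_zenith_deg", "cloud_fraction"]
    merged = kd[meta + ["K"]].merge(
        ka[["scenario_id", "K"]], on="scenario_id", suffixes=("_d", "_a")
    )
    return merged.rename(columns={"K_d": "kd", "K_a": "ka"})


def lighting_heatmaps(
    k_df: pd.DataFrame, band: str, z_max: float = 1.5
) -> pd.DataFrame:
    """r and m of Ka-on-Kd per (solar zenith, cloud cover) lattice cell.

    Each cell pools every water class and concentration corner present for
    that lighting condition. Returns a long table (zenith, cloud, r, m,
    p_value, n); an empty or degenerate cell raises.
    """
    pairs = _pivot(k_df, band, z_max)
    rows = []
    for (zen, cloud), cell in pairs.groupby(["solar_zenith_deg", "cloud_fraction"]):
        if len(cell) < 3:
            raise ValueError(
                f"lighting cell (zenith={zen}, cloud={cloud}) has only "
                f"{len(cell)} scenarios"
            )
        r, m = scatter_stats(cell["kd"], cell["ka"])
        p = float(stats.linregress(cell["kd"], cell["ka"]).pvalue)
        rows.append(
            {
                "solar_zenith_deg": zen,
                "cloud_fraction": cloud,
                "r": r,
                "m": m,
                "p_value": p,
                "n": len(cell),
            }
        )
    return pd.DataFrame(rows)


def mean_cell_slope(k_df: pd.DataFrame, band: str, z_max: float) -> float:
    """Average over lighting cells of the per-cell Ka-on-Kd slope."""
    return float(lighting_heatmaps(k_df, band, z_max)["m"].mean())


def relative_errors(
    k_df: pd.DataFrame, band: str, z_max: float, m: float | None = None
) -> pd.DataFrame:
    """Per-scenario reconstruction error of Kd from Ka via the average slope.

    ``Kd_hat = Ka/m`` with ``m`` the cell-averaged slope for this (band,
    depth range) unless given; ``eps_pct = (Kd_hat - Kd)/Kd * 100``.
    """
    if m is None:
        m = mean_cell_slope(k_df, band, z_max)
    pairs = _pivot(k_df, band, z_max)
    pairs = pairs.assign(
        m=m,
        kd_hat=pairs["ka"] / m,
        eps_pct=(pairs["ka"] / m - pairs["kd"]) / pairs["kd"] * 100.0,
    )
    return pairs


def error_heatmap(
    k_df: pd.DataFrame, band: str, z_max: float = 1.5, m: float | None = None
) -> pd.DataFrame:
    """Mean absolute relative error (%) per (zenith, cloud) lattice cell."""
    errs = relative_errors(k_df, band, z_max, m=m)
    out = (
        errs.assign(abs_eps_pct=errs["eps_pct"].abs())
        .groupby(["solar_zenith_deg", "cloud_fraction"])["abs_eps_pct"]
        .agg(mean_abs_eps_pct="mean", n="count")
        .reset_index()
    )
    return out


def water_type_error_maps(
    k_df: pd.DataFrame, band: str, z_max: float = 1.5, m: float | None = None
) -> pd.DataFrame:
    """Mean absolute relative error (%) per water class and lighting cell."""
    errs = relative_errors(k_df, band, z_max, m=m)
    return (
        errs.assign(abs_eps_pct=errs["eps_pct"].abs())
        .groupby(["water_class", "solar_zenith_deg", "cloud_fraction"])["abs_eps_pct"]
        .agg(mean_abs_eps_pct="mean", n="count")
        .reset_index()
    )


def slope_and_error_tables(
    k_df: pd.DataFrame,
    bands=("Ea40", "Ea50"),
    depth_ranges=DEPTH_RANGES_M,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average-slope and mean-relative-error tables per band and depth range.

    The slope table holds the cell-averaged slope m; the error table holds
    the mean absolute relative error of ``Kd_hat = Ka/m`` expressed as a
    fraction. Rows are bands, columns the "0-z" depth ranges.
    """
    slope = {}
    error = {}
    for band in bands:
        srow, erow = {}, {}
        for z_max in depth_ranges:
            m = mean_cell_slope(k_df, band, z_max)
            errs = relative_errors(k_df, band, z_max, m=m)
            srow[z_max] = m
            erow[z_max] = float(errs["eps_pct"].abs().mean() / 100.0)
        slope[band] = srow
        error[band] = erow
    cols = [float(z) for z in depth_ranges]
    slope_df = pd.DataFrame(slope).T[cols]
    error_df = pd.DataFrame(error).T[cols]
    slope_df.index.name = error_df.index.name = "band"
    return slope_df, error_df


@dataclass
class AssessmentTables:
    """Bundle of every assessment product for one pipeline run."""

    ratio_stats: pd.DataFrame
    scatter: pd.DataFrame                       # band, z_max, r, m, n
    heatmaps: dict[str, pd.DataFrame] = field(default_factory=dict)
    slope_table: pd.DataFrame | None = None
    error_table: pd.DataFrame | None = None
    error_heatmaps: dict[str, pd.DataFrame] = field(default_factory=dict)
    water_type_errors: dict[str, pd.DataFrame] = field(default_factory=dict)


def render_heatmap(heatmap: pd.DataFrame, value: str, path, title: str = "") -> None:
    """Render a (zenith x cloud) heat-map table to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = heatmap.pivot(
        index="cloud_fraction", columns="solar_zenith_deg", values=value
    )
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.pcolormesh(pivot.columns, pivot.index * 100.0, pivot.values, shading="nearest")
    fig.colorbar(im, ax=ax, label=value)
    ax.set_xlabel("solar zenith angle (deg)")
    ax.set_ylabel("cloud coverage (%)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
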