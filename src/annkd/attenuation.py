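"""Diffuse attenuation coefficients from irradiance profiles.

Two estimators of the (depth-averaged) attenuation coefficient K, in m^-1:

* the two-depth formula ``K = ln(E(z1)/E(z2)) / (z2 - z1)``;
* ordinary least squares on ``ln E(z)`` versus ``z`` (K = -slope), the
  standard profile method. Both agree exactly on a pure exponential and are
  invariant under rescaling E by a positive constant.

Broadband (PAR) coefficients are computed from PAR-integrated irradiances,
not by averaging spectral coefficients. Depth ranges are open at the surface:
"0-1.5 m" means every grid depth <= 1.5 m (the grid starts at 0.02 m).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .radiometry import IrradianceProfile

__all__ = [
    "AttenuationResult",
    "k_two_depth",
    "k_regression",
    "k_profiles",
    "DEPTH_RANGES_M",
    "BAND_LABELS",
]

#: Standard analysis depth ranges (upper bound of "0 - z" in metres).
DEPTH_RANGES_M = (0.2, 0.5, 1.0, 1.5, 5.0, 10.0)

#: Band labels used in attenuation tables: planar Ed plus the 8 annular bands.
BAND_LABELS = ("Ed", "Ea10", "Ea20", "Ea30", "Ea40", "Ea50", "Ea60", "Ea70", "Ea80")


@dataclass(frozen=True)
class AttenuationResult:
    depth_range: tuple[float, float]  # (z1, z2), m
    K: float                          # m^-1
    method: str                       # "two-depth" | "regression"
    band: str = "Ed"
    r_squared: float | None = None
    n_points: int | None = None

    def __post_init__(self):
        if self.depth_range[1] <= self.depth_range[0]:
            raise ValueError("depth_range must have z2 > z1")
        if not np.isfinite(self.K):
            raise ValueError("K must be finite")


def k_two_depth(e1: float, e2: float, z1: float, z2: float) -> float:
    """Two-depth attenuation ``(1/(z2-z1)) * ln(E(z1)/E(z2))``, m^-1."""
    if e1 <= 0 or e2 <= 0:
        raise ValueError("irradiances must be strictly positive")
    if z2 <= z1:
        raise ValueError(f"z2 ({z2}) must exceed z1 ({z1})")
    return float(np.log(e1 / e2) / (z2 - z1))


def k_regression(depths, e, band: str = "Ed") -> AttenuationResult:
    """Attenuation as the negative OLS slope of ln E versus depth.

    Requires at least 3 depths with strictly positive irradiance. For a
    constant profile the slope is exactly 0 and r_squared is reported as
    None (the fit is degenerate).
    """
    z = np.asarray(depths, dtype=float)
    e = np.asarray(e, dtype=float)
    if z.size != e.size:
        raise ValueError("depths and irradiances must have equal length")
    if z.size < 3:
        raise ValueError(f"need at least 3 depths for a regression, got {z.size}")
    if np.any(e <= 0):
        raise ValueError("all irradiances must be strictly positive")
    ln_e = np.log(e)
    if np.allclose(ln_e, ln_e[0]):
        return AttenuationResult(
            depth_range=(float(z[0]), float(z[-1])), K=0.0,
            method="regression", band=band, r_squared=None, n_points=int(z.size),
        )
    fit = stats.linregress(z, ln_e)
    return AttenuationResult(
        depth_range=(float(z[0]), float(z[-1])),
        K=float(-fit.slope),
        method="regression",
        band=band,
        r_squared=float(fit.rvalue**2),
        n_points=int(z.size),
    )


def k_profiles(
    profile: IrradianceProfile, depth_ranges=DEPTH_RANGES_M
) -> pd.DataFrame:
    """Regression K for PAR-band Ed and each Ea over each depth range.

    Returns one row per (band, range): columns ``band``, ``z_max``, ``K``,
    ``r_squared``, ``n``; rows number (#ranges) x 9.
    """
    rows = []
    for z_max in depth_ranges:
        mask = profile.depths <= z_max + 1e-9
        if mask.sum() < 3:
            raise ValueError(f"depth range 0-{z_max} m holds fewer than 3 grid depths")
        z = profile.depths[mask]
        for band, e in [("Ed", profile.ed_par[mask])] + [
            (f"Ea{int(th)}", profile.ea_par[mask, j])
            for j, th in enumerate(profile.annular_centers_deg)
        ]:
            res = k_regression(z, e, band=band)
            rows.append(
                {
                    "scenario_id": profile.scenario_id,
                    "band": band,
                    "z_max": float(z_max),
                    "K": res.K,
                    "r_squared": res.r_squared,
                    "n": res.n_points,
                }
            )
    return pd.DataFrame(rows)
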