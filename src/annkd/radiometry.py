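"""Irradiance integrals over the quad grid: planar Ed, annular Ea, PAR.

Planar downward irradiance weights each quad's radiance by the band's exact
mean cosine and the quad solid angle (isotropic L = 1 gives Ed = pi exactly).
Annular irradiance Ea(theta_i) sums one band's radiances over all 24 azimuth
bins times their solid angles with *no* cosine factor - the sensor ring is
normal to the theta direction - so its units follow radiance x solid angle:
W m^-2 nm^-1 per band (isotropic L = 1 gives Ea = 2*pi*dtheta_i).

PAR converts band irradiances to quantum flux with rectangle-rule band sums:
``sum E * dlambda * lambda / (h c N_A)``, in mol quanta s^-1 m^-2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quad_grid import ANNULAR_CENTERS_DEG, QuadGrid
from .radiance_synth import RadianceField

__all__ = [
    "IrradianceProfile",
    "planar_ed",
    "annular_ea",
    "par_integrate",
    "irradiance_profile",
    "log_ratio_ea_ed",
    "H_PLANCK",
    "C_LIGHT",
    "N_AVOGADRO",
]

H_PLANCK = 6.62607015e-34   # J s
C_LIGHT = 2.99792458e8      # m s^-1
N_AVOGADRO = 6.02214076e23  # mol^-1


def _check_shapes(field: RadianceField, grid: QuadGrid) -> None:
    if field.L.shape[1] != grid.n_bands:
        raise ValueError(
            f"field has {field.L.shape[1]} theta bands, grid has {grid.n_bands}"
        )


def planar_ed(field: RadianceField, grid: QuadGrid) -> np.ndarray:
    """Planar downward irradiance Ed(z, lambda), W m^-2 nm^-1.

    Cosine-weighted sum over every downward quad (cap and equator band
    included) using the exact band mean-cosine weights.
    """
    _check_shapes(field, grid)
    weights = grid.band_mean_cosine[:, None] * grid.quad_weights()
    return np.einsum("zbpw,bp->zw", field.L, weights)


def annular_ea(field: RadianceField, grid: QuadGrid, theta_center_deg: float) -> np.ndarray:
    """Annular irradiance Ea(theta_i)(z, lambda) for one measurement band.

    Sum of the 24 azimuth quads of the band centered at ``theta_center_deg``
    (10..80 degrees only) of L * dtheta_i * dphi_j, without cosine weighting.
    """
    _check_shapes(field, grid)
    b = grid.annular_band_index(theta_center_deg)
    return field.L[:, b, :, :].sum(axis=1) * grid.dtheta[b] * grid.dphi


def par_integrate(e, wavelengths, band_width: float | None = None) -> np.ndarray:
    """PAR quantum flux from band irradiances, mol quanta s^-1 m^-2.

    ``e`` holds band-average spectral irradiance (W m^-2 nm^-1) along its last
    axis; ``wavelengths`` are the band centers in nm, all within 400-700 nm.
    ``band_width`` defaults to the grid spacing (required for a single band).
    """
    lam = np.atleast_1d(np.asarray(wavelengths, dtype=float))
    e = np.asarray(e, dtype=float)
    if np.any(lam < 400.0) or np.any(lam > 700.0):
        raise ValueError("wavelengths must lie within the PAR range 400-700 nm")
    if band_width is None:
        if lam.size < 2:
            raise ValueError("band_width is required for a single wavelength band")
        spacing = np.diff(lam)
        if not np.allclose(spacing, spacing[0]):
            raise ValueError("wavelength grid must be uniform")
        band_width = float(spacing[0])
    quanta = lam * 1e-9 / (H_PLANCK * C_LIGHT * N_AVOGADRO)  # mol J^-1
    return np.sum(e * band_width * quanta, axis=-1)


@dataclass(frozen=True)
class IrradianceProfile:
    """Ed, Ea(theta_i) and their PAR integrals versus depth for one scenario.

    ``ea`` has shape (depth, 8, wavelength) over the annular bands 10..80
    degrees; ``ed_par``/``ea_par`` are the corresponding PAR quantum fluxes.
    """

    depths: np.ndarray
    wavelengths: np.ndarray
    annular_centers_deg: np.ndarray
    ed: np.ndarray       # (nz, nw)
    ea: np.ndarray       # (nz, 8, nw)
    ed_par: np.ndarray   # (nz,)
    ea_par: np.ndarray   # (nz, 8)
    scenario_id: str = ""

    def __post_init__(self):
        if self.ea.shape[1] != 8:
            raise ValueError("Ea must cover exactly 8 annular bands")
        for name in ("ed", "ea", "ed_par", "ea_par"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} contains negative values")

    def band_column(self, theta_center_deg: float) -> int:
        match = np.nonzero(np.isclose(self.annular_centers_deg, theta_center_deg))[0]
        if match.size == 0:
            raise ValueError(f"no annular band centered at {theta_center_deg} deg")
        return int(match[0])

    def depth_row(self, z: float) -> int:
        match = np.nonzero(np.isclose(self.depths, z))[0]
        if match.size == 0:
            raise ValueError(f"depth {z} m is not on the profile grid")
        return int(match[0])

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-depth PAR table (band Ed plus the eight Ea bands)."""
        rows = {"scenario_id": self.scenario_id, "depth_m": self.depths,
                "Ed_par": self.ed_par}
        for j, th in enumerate(self.annular_centers_deg):
            rows[f"Ea{int(th)}_par"] = self.ea_par[:, j]
        return pd.DataFrame(rows)


def irradiance_profile(field: RadianceField, grid: QuadGrid) -> IrradianceProfile:
    """Integrate a radiance field into a full irradiance profile."""
    sc = field.scenario
    ed = planar_ed(field, grid)
    ea = np.stack(
        [annular_ea(field, grid, th) for th in ANNULAR_CENTERS_DEG], axis=1
    )
    return IrradianceProfile(
        depths=np.asarray(sc.depths, dtype=float),
        wavelengths=np.asarray(sc.wavelengths, dtype=float),
        annular_centers_deg=np.asarray(ANNULAR_CENTERS_DEG),
        ed=ed,
        ea=ea,
        ed_par=par_integrate(ed, sc.wavelengths),
        ea_par=par_integrate(ea, sc.wavelengths),
        scenario_id=sc.scenario_id,
    )


def log_ratio_ea_ed(profile: IrradianceProfile, theta_center_deg: float, z: float) -> float:
    """log10 of the PAR-band Ea(theta_i)/Ed ratio at depth ``z``."""
    i = profile.depth_row(z)
    j = profile.band_column(theta_center_deg)
    ed = profile.ed_par[i]
    if ed <= 0:
        raise ValueError(f"Ed is zero at depth {z} m; the ratio is undefined")
    return float(np.log10(profile.ea_par[i, j] / ed))
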