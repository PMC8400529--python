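"""Angular discretization of the downward hemisphere into quads.

The in-water light field is averaged over a fixed set of (theta, phi) quads:
polar-angle bands of 10 degrees between 5 and 85 degrees, a polar cap
(0-5 degrees, a single quad spanning all azimuths), an equator band
(85-90 degrees), and 24 azimuth bins of 15 degrees for every ordinary band.
Theta is measured from the downward-pointing polar axis, so the downward
hemisphere is theta in [0, 90] degrees.

Per-band weights:

* ``dtheta_i = cos(theta_lower) - cos(theta_upper)`` so that a quad's solid
  angle is ``dtheta_i * dphi_j`` steradians.
* The band mean cosine is the exact band integral
  ``(cos(theta_lower) + cos(theta_upper)) / 2``, which makes the isotropic
  planar-irradiance closed form ``Ed = pi * L`` hold to machine precision.

Angles are degrees at the interface; solid angles are steradians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["QuadGrid", "build_grid", "quad_solid_angle", "N_PHI", "ANNULAR_CENTERS_DEG"]

#: Number of azimuth bins for every band except the polar cap.
N_PHI = 24

#: Band centers (degrees) at which annular irradiance is defined.
ANNULAR_CENTERS_DEG = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0)

_THETA_EDGES_DEG = (0.0, 5.0, 15.0, 25.0, 35.0, 45.0, 55.0, 65.0, 75.0, 85.0, 90.0)
# Cap labelled ~0, ordinary bands at their centers, equator band labelled 87.5.
_THETA_CENTERS_DEG = (0.0,) + ANNULAR_CENTERS_DEG + (87.5,)


@dataclass(frozen=True)
class QuadGrid:
    """The fixed (theta, phi) quad layout plus precomputed per-band weights.

    Attributes
    ----------
    theta_edges_deg : (11,) band edges in degrees, 0 to 90.
    theta_centers_deg : (10,) band center labels in degrees (cap -> 0.0,
        equator band -> 87.5).
    phi_edges_deg : (25,) azimuth bin edges in degrees, 0 to 360 step 15.
    dtheta : (10,) per-band cos(lower) - cos(upper), all positive.
    dphi : azimuth bin width in radians, 2*pi/24.
    band_solid_angle : (10,) total solid angle of each band (cap included),
        2*pi*dtheta_i steradians.
    band_mean_cosine : (10,) exact cosine weight of each band.
    """

    theta_edges_deg: np.ndarray
    theta_centers_deg: np.ndarray
    phi_edges_deg: np.ndarray
    dtheta: np.ndarray
    dphi: float
    band_solid_angle: np.ndarray
    band_mean_cosine: np.ndarray

    @property
    def n_bands(self) -> int:
        return self.theta_centers_deg.size

    @property
    def cap_index(self) -> int:
        return 0

    @property
    def equator_index(self) -> int:
        return self.n_bands - 1

    @property
    def phi_centers_deg(self) -> np.ndarray:
        return 0.5 * (self.phi_edges_deg[:-1] + self.phi_edges_deg[1:])

    def annular_band_index(self, theta_center_deg: float) -> int:
        """Index of the annular measurement band centered at ``theta_center_deg``.

        Only the eight ordinary bands (10..80 degrees) are legal annular
        measurement bands; the polar cap and the equator band are not.
        """
        centers = np.asarray(ANNULAR_CENTERS_DEG)
        match = np.nonzero(np.isclose(centers, theta_center_deg))[0]
        if match.size == 0:
            raise ValueError(
                f"theta_center={theta_center_deg!r} deg is not an annular band "
                f"center; expected one of {ANNULAR_CENTERS_DEG}"
            )
        return int(match[0]) + 1  # offset past the cap

    def quad_weights(self) -> np.ndarray:
        """Per-quad solid angles as a dense (n_bands, N_PHI) array.

        The cap is a single quad; for array-shaped integrations its solid
        angle is spread uniformly over the 24 pseudo-azimuth slots (the cap
        radiance is azimuth-independent by construction, so this is exact).
        """
        w = np.outer(self.dtheta, np.full(N_PHI, self.dphi))
        w[self.cap_index, :] = self.band_solid_angle[self.cap_index] / N_PHI
        return w

    def to_frame(self) -> pd.DataFrame:
        """Tabular view of the band layout for inspection / CSV export."""
        return pd.DataFrame(
            {
                "band": np.arange(self.n_bands),
                "theta_lower_deg": self.theta_edges_deg[:-1],
                "theta_upper_deg": self.theta_edges_deg[1:],
                "theta_center_deg": self.theta_centers_deg,
                "dtheta": self.dtheta,
                "n_phi": [1] + [N_PHI] * (self.n_bands - 1),
                "band_solid_angle_sr": self.band_solid_angle,
                "band_mean_cosine": self.band_mean_cosine,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_grid() -> QuadGrid:
    """Build the fixed hemisphere quad layout.

    Bands are {0-5 (cap), 5-15, 15-25, ..., 75-85, 85-90} degrees; all bands
    except the cap carry 24 azimuth bins of 15 degrees.
    """
    edges = np.asarray(_THETA_EDGES_DEG)
    lo = np.cos(np.radians(edges[:-1]))
    hi = np.cos(np.radians(edges[1:]))
    dtheta = lo - hi
    return QuadGrid(
        theta_edges_deg=edges,
        theta_centers_deg=np.asarray(_THETA_CENTERS_DEG),
        phi_edges_deg=np.arange(0.0, 361.0, 15.0),
        dtheta=dtheta,
        dphi=2.0 * np.pi / N_PHI,
        band_solid_angle=2.0 * np.pi * dtheta,
        band_mean_cosine=0.5 * (lo + hi),
    )


def quad_solid_angle(grid: QuadGrid, band_index: int, phi_index: int) -> float:
    """Solid angle of one quad in steradians.

    Ordinary quads have ``dtheta_i * dphi_j``; the polar cap is a single quad
    of ``2*pi*(1 - cos 5 deg)`` with no azimuthal subdivision (``phi_index``
    must be 0 for the cap).
    """
    if not 0 <= band_index < grid.n_bands:
        raise IndexError(f"band_index {band_index} out of range [0, {grid.n_bands})")
    if band_index == grid.cap_index:
        if phi_index != 0:
            raise IndexError("the polar cap has a single quad; phi_index must be 0")
        return float(grid.band_solid_angle[grid.cap_index])
    if not 0 <= phi_index < N_PHI:
        raise IndexError(f"phi_index {phi_index} out of range [0, {N_PHI})")
    return float(grid.dtheta[band_index] * grid.dphi)
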