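"""Bio-optical model: constituent concentrations -> inherent optical properties.

Maps chlorophyll (mg m^-3), CDOM absorption at 380 nm (m^-1) and suspended
mineral concentration (g m^-3) to spectral absorption ``a``, scattering ``b``
and backscattering ``b_b`` over the visible range, plus the reference
("ground truth") downwelling attenuation used to drive and validate the
synthetic radiance generator.

The constituent model is a standard-magnitude case-2 parameterization:

* phytoplankton absorption: double-Gaussian specific spectrum peaking at
  440 and 675 nm;
* CDOM: exponential with slope ``S_g`` referenced to 380 nm;
* mineral absorption: exponential with slope ``S_m`` referenced to 443 nm;
* particle scattering: (550/lambda) shape for both phytoplankton and mineral;
* backscattering: fixed particulate backscatter ratio plus half the (near
  isotropic) pure-water scattering.

Pure-water absorption follows the standard published visible-range table
(Pope & Fry style, 10 nm resolution, linearly interpolated), and pure-water
scattering a lambda^-4.32 law anchored at 500 nm.

Seven reference water classes (ultra clear ... brown) give the constituent
concentration ranges of optically classified Estonian / south-Finnish lakes
and coastal waters; within a class only the {low, high} corner values are
used by the scenario grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WaterClass",
    "IOPSpectrum",
    "water_classes",
    "water_class_by_name",
    "water_class_table",
    "iops",
    "snell_refract",
    "diffuse_fraction",
    "ground_truth_kd",
    "N_WATER",
    "MU_DIFFUSE",
]

# ---------------------------------------------------------------------------
# Fixed model constants (documented package choices)
# ---------------------------------------------------------------------------

#: Refractive index of water used for Snell refraction.
N_WATER = 1.34
#: Mean cosine of the transmitted diffuse (sky + cloud) light field.
MU_DIFFUSE = 0.83
#: Clear-sky skylight fraction: diffuse fraction is cloud + 0.15 * (1 - cloud).
CLEAR_SKY_DIFFUSE = 0.15

#: Chlorophyll-specific absorption peak magnitude, m^2 mg^-1.
A_PH_PEAK = 0.05
#: CDOM spectral slope, nm^-1, referenced to 380 nm.
S_CDOM = 0.014
#: Mineral-specific absorption at 443 nm, m^2 g^-1, and its spectral slope.
A_MINERAL_443 = 0.03
S_MINERAL = 0.011
#: Particle specific scattering at 550 nm: phytoplankton m^2 mg^-1, mineral m^2 g^-1.
B_PH_550 = 0.30
B_MINERAL_550 = 0.50
#: Particulate backscatter ratio.
BB_RATIO = 0.018

# Pure-water absorption (m^-1), 400-700 nm at 10 nm; standard published values.
_AW_WAVELENGTH = np.arange(400.0, 701.0, 10.0)
_AW = np.array(
    [
        0.00663, 0.00473, 0.00454, 0.00495, 0.00635, 0.00922, 0.00979, 0.0106,
        0.0127, 0.0150, 0.0204, 0.0325, 0.0409, 0.0434, 0.0474, 0.0565,
        0.0619, 0.0695, 0.0896, 0.1351, 0.2224, 0.2644, 0.2755, 0.2916,
        0.3108, 0.340, 0.410, 0.439, 0.465, 0.516, 0.624,
    ]
)
# Pure-water scattering anchor: b_w(500 nm) = 0.00288 m^-1, lambda^-4.32 law.
_BW_500 = 0.00288
_BW_EXP = 4.32


@dataclass(frozen=True)
class WaterClass:
    """One optical water class with {low, high} constituent concentration ranges."""

    name: str
    chl_range: tuple[float, float]      # mg m^-3
    cdom_range: tuple[float, float]     # a_CDOM(380), m^-1
    mineral_range: tuple[float, float]  # g m^-3

    def __post_init__(self):
        for rng in (self.chl_range, self.cdom_range, self.mineral_range):
            if rng[0] > rng[1]:
                raise ValueError(f"range {rng} has min > max in class {self.name!r}")

    def corners(self) -> list[tuple[float, float, float]]:
        """The 8 (chl, cdom, mineral) low/high combinations, in fixed order."""
        return [
            (c, g, m)
            for c in self.chl_range
            for g in self.cdom_range
            for m in self.mineral_range
        ]


# The published table prints the columns as Max/Min, with the "ultra clear" row
# having Max < Min throughout (a typo in the source); each pair is therefore
# treated as an unordered {low, high} set.
_WATER_CLASSES = (
    WaterClass("ultra clear", (0.0, 1.0), (0.0, 0.6), (0.0, 0.8)),
    WaterClass("very clear", (1.0, 3.0), (0.5, 1.5), (0.5, 1.5)),
    WaterClass("clear", (2.1, 7.5), (1.3, 3.3), (1.2, 2.4)),
    WaterClass("moderate", (3.9, 17.1), (5.0, 12.0), (1.0, 6.6)),
    WaterClass("turbid", (19.7, 41.3), (5.5, 9.7), (10.8, 18.6)),
    WaterClass("very turbid", (65.2, 67.6), (6.1, 6.7), (30.3, 38.7)),
    WaterClass("brown", (3.3, 20.3), (18.1, 22.5), (2.2, 7.8)),
)


def water_classes() -> list[WaterClass]:
    """The seven reference water classes, from ultra clear to brown."""
    return list(_WATER_CLASSES)


def water_class_by_name(name: str) -> WaterClass:
    for wc in _WATER_CLASSES:
        if wc.name == name:
            return wc
    raise KeyError(f"unknown water class {name!r}; known: "
                   f"{[w.name for w in _WATER_CLASSES]}")


def water_class_table() -> pd.DataFrame:
    """Water-class ranges as a table (class, chl/cdom/mineral min and max)."""
    return pd.DataFrame(
        {
            "class": [w.name for w in _WATER_CLASSES],
            "chl_min": [w.chl_range[0] for w in _WATER_CLASSES],
            "chl_max": [w.chl_range[1] for w in _WATER_CLASSES],
            "cdom_min": [w.cdom_range[0] for w in _WATER_CLASSES],
            "cdom_max": [w.cdom_range[1] for w in _WATER_CLASSES],
            "mineral_min": [w.mineral_range[0] for w in _WATER_CLASSES],
            "mineral_max": [w.mineral_range[1] for w in _WATER_CLASSES],
        }
    )


@dataclass(frozen=True)
class IOPSpectrum:
    """Spectral inherent optical properties on a wavelength grid (all m^-1)."""

    wavelengths: np.ndarray  # nm
    a: np.ndarray            # absorption
    b: np.ndarray            # total scattering
    bb: np.ndarray           # backscattering

    def __post_init__(self):
        for name in ("a", "b", "bb"):
            v = getattr(self, name)
            if v.shape != self.wavelengths.shape:
                raise ValueError(f"{name} shape {v.shape} does not match wavelengths")
            if np.any(v < 0):
                raise ValueError(f"{name} contains negative values")

    @property
    def beam_c(self) -> np.ndarray:
        return self.a + self.b


def water_absorption(wavelengths) -> np.ndarray:
    """Pure-water absorption a_w(lambda), m^-1, interpolated to ``wavelengths``."""
    lam = np.asarray(wavelengths, dtype=float)
    return np.interp(lam, _AW_WAVELENGTH, _AW)


def water_scattering(wavelengths) -> np.ndarray:
    """Pure-water scattering b_w(lambda) = 0.00288 * (lambda/500)^-4.32, m^-1."""
    lam = np.asarray(wavelengths, dtype=float)
    return _BW_500 * (lam / 500.0) ** (-_BW_EXP)


def phytoplankton_specific_absorption(wavelengths) -> np.ndarray:
    """Chlorophyll-specific absorption a*_ph(lambda), m^2 mg^-1 (double Gaussian)."""
    lam = np.asarray(wavelengths, dtype=float)
    return A_PH_PEAK * (
        np.exp(-((lam - 440.0) ** 2) / (2.0 * 30.0**2))
        + 0.6 * np.exp(-((lam - 675.0) ** 2) / (2.0 * 20.0**2))
    )


def iops(chl: float, cdom380: float, mineral: float, wavelengths) -> IOPSpectrum:
    """Spectral IOPs for the given constituent concentrations.

    Parameters
    ----------
    chl : chlorophyll-a concentration, mg m^-3.
    cdom380 : CDOM absorption at 380 nm, m^-1.
    mineral : mineral / detritus concentration, g m^-3.
    wavelengths : wavelength grid in nm.
    """
    for name, v in (("chl", chl), ("cdom380", cdom380), ("mineral", mineral)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    lam = np.asarray(wavelengths, dtype=float)
    a_w = water_absorption(lam)
    b_w = water_scattering(lam)
    a = (
        a_w
        + chl * phytoplankton_specific_absorption(lam)
        + cdom380 * np.exp(-S_CDOM * (lam - 380.0))
        + mineral * A_MINERAL_443 * np.exp(-S_MINERAL * (lam - 443.0))
    )
    b = b_w + (chl * B_PH_550 + mineral * B_MINERAL_550) * (550.0 / lam)
    bb = BB_RATIO * (b - b_w) + 0.5 * b_w
    return IOPSpectrum(wavelengths=lam, a=a, b=b, bb=bb)


def snell_refract(theta_air_deg: float) -> float:
    """In-water polar angle (degrees) of a ray incident at ``theta_air_deg``.

    ``asin(sin(theta)/n)`` with n = 1.34; maps [0, 90] into [0, ~48.27]
    (the edge of Snell's window).
    """
    theta = np.asarray(theta_air_deg, dtype=float)
    if np.any(theta < 0) or np.any(theta > 90):
        raise ValueError("theta_air must be within [0, 90] degrees")
    out = np.degrees(np.arcsin(np.sin(np.radians(theta)) / N_WATER))
    return float(out) if np.isscalar(theta_air_deg) else out


def diffuse_fraction(cloud_fraction: float) -> float:
    """Fraction of surface irradiance that is diffuse sky/cloud light.

    ``min(1, cloud + 0.15 * (1 - cloud))``: monotone in cloud cover with a
    nonzero clear-sky skylight floor.
    """
    if not 0.0 <= cloud_fraction <= 1.0:
        raise ValueError(f"cloud_fraction must be in [0, 1], got {cloud_fraction}")
    return min(1.0, cloud_fraction + CLEAR_SKY_DIFFUSE * (1.0 - cloud_fraction))


def ground_truth_kd(
    iop: IOPSpectrum, theta_air_deg: float, cloud_fraction: float
) -> np.ndarray:
    """Reference per-wavelength attenuation Kd of the synthetic generator, m^-1.

    Two-stream form ``(a + b_b) / mu_eff`` with
    ``mu_eff = (1 - f_dif) * cos(theta_sw) + f_dif * mu_dif``, where
    ``theta_sw`` is the refracted solar zenith angle, ``f_dif`` the diffuse
    fraction and ``mu_dif`` = 0.83 the diffuse mean cosine. Strictly positive
    whenever absorption is.
    """
    f_dif = diffuse_fraction(cloud_fraction)
    theta_sw = snell_refract(theta_air_deg)
    mu_eff = (1.0 - f_dif) * np.cos(np.radians(theta_sw)) + f_dif * MU_DIFFUSE
    return (iop.a + iop.bb) / mu_eff
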