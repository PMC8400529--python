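import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from annkd.pipeline import compute_k_table
from annkd.quad_grid import build_grid
from annkd.radiance_synth import (
    RadianceField,
    Scenario,
    par_wavelengths,
    scenario_grid,
    table1_depths,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def grid():
    return build_grid()


def make_field(L_band_phi, depths=(0.5, 1.0), wavelengths=(500.0, 505.0)):
    """Field with the same (band, phi) radiance pattern at every depth/wavelength.

    ``L_band_phi`` has shape (10, 24); handy for analytic closed-form checks.
    """
    depths = np.asarray(depths, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    sc = Scenario(
        "clear", 2.1, 1.3, 1.2, 0.0, 0.0,
        wavelengths=wavelengths, depths=depths, seed=0,
    )
    L = np.broadcast_to(
        np.asarray(L_band_phi, dtype=float)[None, :, :, None],
        (depths.size, 10, 24, wavelengths.size),
    ).copy()
    kd = np.ones(wavelengths.size)
    return RadianceField(scenario=sc, L=L, kd_true=kd)


@pytest.fixture(scope="session")
def study_tables(grid):
    """Attenuation and log-ratio tables for the full 3024-scenario grid.

    Computed once per session at 10 nm spectral resolution over the standard
    depth grid truncated at 1.5 m (the focal analysis depth); drives the
    scenario-set assessments.
    """
    scenarios = scenario_grid(
        wavelengths=par_wavelengths(10.0),
        depths=table1_depths(1.5),
        base_seed=12345,
    )
    k_df, ratio_df = compute_k_table(
        scenarios, grid, depth_ranges=(1.5,), ratio_depths=(1.5,), progress_every=0
    )
    return k_df, ratio_df


@pytest.fixture(scope="session")
def case_study_1(study_tables):
    """Restriction of the grid tables to solar zenith <= 60 deg (2352 scenarios)."""
    k_df, ratio_df = study_tables
    return (
        k_df[k_df["solar_zenith_deg"] <= 60.0],
        ratio_df[ratio_df["solar_zenith_deg"] <= 60.0],
    )
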