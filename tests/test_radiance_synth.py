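import numpy as np
import pytest

from annkd.bio_optics import diffuse_fraction, water_class_by_name, water_classes
from annkd.quad_grid import build_grid
from annkd.radiance_synth import (
    Scenario,
    field_roundtrip,
    generate_field,
    par_wavelengths,
    read_field,
    scenario_grid,
    table1_depths,
    write_field,
)
from annkd.radiometry import planar_ed

WL10 = par_wavelengths(10.0)


def ols_slope(z, ln_e):
    zz = z - z.mean()
    return (zz[:, None] * (ln_e - ln_e.mean(axis=0))).sum(axis=0) / (zz**2).sum()


class TestDepthAndWavelengthGrids:
    def test_depth_grid_structure(self):
        z = table1_depths()
        assert z[0] == 0.02
        assert z[-1] == 20.0
        assert z.size == 88
        for expected in (0.5, 0.55, 2.0, 2.1, 3.0, 3.2, 4.0, 4.5, 10.0, 11.0, 15.0):
            assert np.any(np.isclose(z, expected))
        assert np.all(np.diff(z) > 0)

    def test_depth_grid_truncation(self):
        z = table1_depths(1.5)
        assert z[-1] == 1.5 and z.size == 45

    def test_wavelength_band_centers(self):
        wl5 = par_wavelengths(5.0)
        assert wl5.size == 60 and wl5[0] == 402.5 and wl5[-1] == 697.5
        assert WL10.size == 30 and WL10[0] == 405.0
        with pytest.raises(ValueError):
            par_wavelengths(2.0)


class TestScenarioGrid:
    def test_full_grid_count(self):
        assert len(scenario_grid()) == 3024

    def test_case_study_1_count(self):
        assert len(scenario_grid(zeniths=range(0, 61, 10))) == 2352

    def test_singleton(self):
        scen = scenario_grid(zeniths=[30.0], clouds=[0.2], classes=["clear"])
        assert len(scen) == 8  # one class still has 8 concentration corners
        one = [s for s in scen if (s.chl, s.cdom380, s.mineral) == (2.1, 1.3, 1.2)]
        assert len(one) == 1

    def test_off_grid_values_rejected(self):
        with pytest.raises(ValueError, match="zenith"):
            scenario_grid(zeniths=[45.0])
        with pytest.raises(ValueError, match="cloud"):
            scenario_grid(clouds=[0.3])
        with pytest.raises(ValueError, match="empty"):
            scenario_grid(classes=[])

    def test_seeds_distinct_and_deterministic(self):
        a = scenario_grid(zeniths=[0.0, 10.0], clouds=[0.0], classes=["clear"])
        b = scenario_grid(zeniths=[0.0, 10.0], clouds=[0.0], classes=["clear"])
        assert [s.seed for s in a] == [s.seed for s in b]
        assert len({s.seed for s in a}) == len(a)

    def test_scenario_validation(self):
        with pytest.raises(ValueError, match="depths"):
            Scenario("clear", 1, 1, 1, 0.0, 0.0, depths=np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="cloud"):
            Scenario("clear", 1, 1, 1, 0.0, 1.5)


class TestGeneratedFields:
    def test_determinism(self, grid):
        sc = Scenario("moderate", 3.9, 5.0, 1.0, 30.0, 0.2,
                      wavelengths=WL10, depths=table1_depths(1.0), seed=7,
                      noise_sd=0.05)
        f1, f2 = generate_field(sc, grid), generate_field(sc, grid)
        np.testing.assert_array_equal(f1.L, f2.L)

    def test_noise_perturbs_with_distinct_seeds(self, grid):
        base = dict(wavelengths=WL10, depths=table1_depths(0.5), noise_sd=0.05)
        f1 = generate_field(Scenario("clear", 2.1, 1.3, 1.2, 30.0, 0.2, seed=1, **base), grid)
        f2 = generate_field(Scenario("clear", 2.1, 1.3, 1.2, 30.0, 0.2, seed=2, **base), grid)
        assert not np.array_equal(f1.L, f2.L)

    def test_overcast_is_azimuthally_uniform_diffuse(self, grid):
        sc = Scenario("clear", 2.1, 1.3, 1.2, 50.0, 1.0,
                      wavelengths=WL10, depths=table1_depths(0.5))
        f = generate_field(sc, grid)
        # no direct lobe: identical radiance in every azimuth bin
        assert np.all(f.L == f.L[:, :, :1, :])

    def test_refracted_sun_band_holds_the_radiance_maximum(self, grid):
        # sun at 30 deg in air refracts to ~22 deg: band 15-25 dominates
        sc = Scenario("clear", 2.1, 1.3, 1.2, 30.0, 0.0,
                      wavelengths=WL10, depths=np.array([0.1, 0.2]))
        f = generate_field(sc, grid)
        band_sums = f.L[1].sum(axis=(1, 2))
        assert int(np.argmax(band_sums)) == grid.annular_band_index(20.0)

    def test_log_linear_decay(self, grid):
        # ln Ed versus z is linear (R^2 > 0.999) at every wavelength over 0-10 m
        sc = Scenario("clear", 7.5, 3.3, 2.4, 40.0, 0.4,
                      wavelengths=WL10, depths=table1_depths(10.0))
        f = generate_field(sc, grid)
        z = np.asarray(sc.depths)
        ln_e = np.log(planar_ed(f, grid))
        slope = ols_slope(z, ln_e)
        fit = ln_e.mean(axis=0) + slope * (z[:, None] - z.mean())
        ss_res = ((ln_e - fit) ** 2).sum(axis=0)
        ss_tot = ((ln_e - ln_e.mean(axis=0)) ** 2).sum(axis=0)
        assert np.all(1.0 - ss_res / ss_tot > 0.999)

    def test_snell_window_containment(self, grid):
        # clear sky, any solar zenith: <5% of direct-beam planar energy lies
        # in bands with lower edge >= 55 deg at 0.2 m depth
        wc = water_class_by_name("clear")
        corner = wc.corners()[0]
        depths = np.array([0.1, 0.2])
        weights = grid.band_mean_cosine[:, None] * grid.quad_weights()
        f_sky = diffuse_fraction(0.0)
        for zenith in np.arange(0.0, 81.0, 10.0):
            clear = generate_field(
                Scenario("clear", *corner, zenith, 0.0, wavelengths=WL10, depths=depths),
                grid,
            )
            overcast = generate_field(
                Scenario("clear", *corner, zenith, 1.0, wavelengths=WL10, depths=depths),
                grid,
            )
            direct = clear.L[1] - f_sky * overcast.L[1]
            total = np.einsum("bpw,bp->w", direct, weights).sum()
            deep = np.einsum("bpw,bp->w", direct[7:], weights[7:]).sum()
            assert deep / total < 0.05

    def test_parameter_recovery_against_ground_truth(self, grid):
        # regression Kd per wavelength over 0-10 m matches the generator's
        # reference attenuation within 3% (overcast exact by construction;
        # clear sky exercises the direct lobe)
        z = table1_depths(10.0)
        wl = par_wavelengths(10.0)
        for wc in water_classes():
            chl, cdom, mineral = wc.corners()[-1]
            for zenith in (0.0, 30.0):
                for cloud in (0.0, 1.0):
                    sc = Scenario(wc.name, chl, cdom, mineral, zenith, cloud,
                                  wavelengths=wl, depths=z)
                    f = generate_field(sc, grid)
                    k = -ols_slope(z, np.log(planar_ed(f, grid)))
                    np.testing.assert_allclose(k, f.kd_true, rtol=0.03)


class TestPersistence:
    def test_roundtrip_bitwise(self, grid, tmp_path):
        sc = Scenario("brown", 3.3, 18.1, 2.2, 20.0, 0.6,
                      wavelengths=WL10, depths=table1_depths(0.5), seed=11)
        f = generate_field(sc, grid)
        back = field_roundtrip(f, tmp_path / "field.nc")
        np.testing.assert_array_equal(back.L, f.L)
        np.testing.assert_array_equal(back.kd_true, f.kd_true)
        assert back.scenario.water_class == "brown"
        np.testing.assert_array_equal(back.scenario.depths, sc.depths)
        np.testing.assert_array_equal(back.scenario.wavelengths, sc.wavelengths)
        assert back.scenario.seed == 11
        assert back.scenario.cloud_fraction == 0.6

    def test_malformed_container_names_dimension(self, grid, tmp_path):
        import xarray as xr

        sc = Scenario("clear", 2.1, 1.3, 1.2, 0.0, 0.0,
                      wavelengths=WL10, depths=table1_depths(0.5))
        path = tmp_path / "field.nc"
        write_field(generate_field(sc, grid), path)
        with xr.open_dataset(path, engine="scipy") as ds:
            broken = ds.load().isel(theta_band=slice(0, 5))
        bad = tmp_path / "broken.nc"
        broken.to_netcdf(bad, engine="scipy")
        with pytest.raises(ValueError, match="theta_band"):
            read_field(bad)
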