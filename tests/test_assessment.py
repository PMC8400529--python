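import numpy as np
import pandas as pd
import pytest

from annkd.assessment import (
    error_heatmap,
    lighting_heatmaps,
    mean_cell_slope,
    ratio_analysis,
    relative_errors,
    scatter_stats,
    slope_and_error_tables,
    water_type_error_maps,
)
from annkd.quad_grid import build_grid
from annkd.radiance_synth import Scenario, generate_field, par_wavelengths, table1_depths
from annkd.radiometry import irradiance_profile


def fake_k_table(slope_by_band, n_waters=8, zeniths=(0.0, 30.0), clouds=(0.0, 1.0)):
    """Attenuation table where every Ka band is an exact multiple of Kd."""
    rng = np.random.default_rng(0)
    rows = []
    for zen in zeniths:
        for cloud in clouds:
            kd = rng.uniform(0.1, 2.0, size=n_waters)
            for i, k in enumerate(kd):
                sid = f"w{i}_z{zen}_c{cloud}"
                rows.append(dict(scenario_id=sid, water_class=f"w{i}",
                                 solar_zenith_deg=zen, cloud_fraction=cloud,
                                 band="Ed", z_max=1.5, K=k))
                for band, m0 in slope_by_band.items():
                    rows.append(dict(scenario_id=sid, water_class=f"w{i}",
                                     solar_zenith_deg=zen, cloud_fraction=cloud,
                                     band=band, z_max=1.5, K=m0 * k))
    return pd.DataFrame(rows)


class TestScatterStats:
    def test_exact_linear_relation(self):
        kd = np.linspace(0.1, 2.0, 20)
        r, m = scatter_stats(kd, 1.1 * kd)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert m == pytest.approx(1.1, rel=1e-12)

    def test_constant_response_flagged(self):
        r, m = scatter_stats(np.linspace(0.1, 1.0, 5), np.full(5, 0.7))
        assert (r, m) == (0.0, 0.0)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            scatter_stats(np.full(5, 0.7), np.linspace(0.1, 1.0, 5))

    def test_noisy_relation(self):
        rng = np.random.default_rng(7)
        kd = np.linspace(0.2, 2.0, 200)
        ka = kd + rng.normal(0.0, 0.01 * kd.mean(), kd.size)
        r, m = scatter_stats(kd, ka)
        assert r > 0.99
        assert abs(m - 1.0) < 0.05


@pytest.fixture(scope="module")
def one_profile():
    grid = build_grid()
    sc = Scenario("clear", 2.1, 1.3, 1.2, 30.0, 0.2,
                  wavelengths=par_wavelengths(10.0), depths=table1_depths(1.5))
    return irradiance_profile(generate_field(sc, grid), grid)


class TestRatioAnalysis:
    def test_single_scenario_has_zero_spread(self, one_profile):
        stats = ratio_analysis([one_profile], depths=(0.5, 1.5))
        assert len(stats) == 8 * 2
        assert np.all(stats["sd"] == 0.0)
        assert np.all(stats["n"] == 1)

    def test_duplicated_set_is_idempotent(self, one_profile):
        a = ratio_analysis([one_profile], depths=(1.5,))
        b = ratio_analysis([one_profile, one_profile], depths=(1.5,))
        np.testing.assert_allclose(a["mean"], b["mean"])
        np.testing.assert_allclose(a["sd"], b["sd"])

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ratio_analysis([])


class TestSlopeAndErrorTables:
    def test_exact_multiple_recovers_slope_and_zero_error(self):
        k_df = fake_k_table({"Ea40": 1.25, "Ea50": 0.9})
        slope, error = slope_and_error_tables(k_df, depth_ranges=(1.5,))
        assert slope.loc["Ea40", 1.5] == pytest.approx(1.25, rel=1e-12)
        assert slope.loc["Ea50", 1.5] == pytest.approx(0.9, rel=1e-12)
        assert error.loc["Ea40", 1.5] == pytest.approx(0.0, abs=1e-12)
        assert error.loc["Ea50", 1.5] == pytest.approx(0.0, abs=1e-12)

    def test_table_layout(self, study_tables):
        k_df, _ = study_tables
        slope, error = slope_and_error_tables(k_df, depth_ranges=(1.5,))
        assert list(slope.index) == ["Ea40", "Ea50"]
        assert slope.shape == (2, 1) and error.shape == (2, 1)

    def test_relative_error_is_scale_free(self):
        k_df = fake_k_table({"Ea40": 1.1})
        scaled = k_df.assign(K=3.0 * k_df["K"])
        e1 = relative_errors(k_df, "Ea40", 1.5)["eps_pct"]
        e2 = relative_errors(scaled, "Ea40", 1.5)["eps_pct"]
        np.testing.assert_allclose(e1, e2, atol=1e-10)


class TestLightingHeatmaps:
    def test_single_cell_matches_pooled_scatter(self):
        k_df = fake_k_table({"Ea40": 1.2}, zeniths=(30.0,), clouds=(0.2,))
        hm = lighting_heatmaps(k_df, "Ea40", 1.5)
        assert len(hm) == 1
        kd = k_df[k_df.band == "Ed"]["K"]
        ka = k_df[k_df.band == "Ea40"]["K"]
        r, m = scatter_stats(kd, ka)
        assert hm["r"].iloc[0] == pytest.approx(r, rel=1e-12)
        assert hm["m"].iloc[0] == pytest.approx(m, rel=1e-12)

    def test_sparse_cell_rejected(self):
        k_df = fake_k_table({"Ea40": 1.2}, n_waters=2, zeniths=(0.0,), clouds=(0.0,))
        with pytest.raises(ValueError, match="cell"):
            lighting_heatmaps(k_df, "Ea40", 1.5)

    def test_full_grid_lattice(self, study_tables):
        k_df, _ = study_tables
        hm = lighting_heatmaps(k_df, "Ea40", 1.5)
        assert len(hm) == 9 * 6
        assert set(hm["n"]) == {56}  # 7 classes x 8 corners per cell
        assert np.all((hm["r"] >= -1.0) & (hm["r"] <= 1.0))


class TestScenarioGridBehaviour:
    """Scenario-set statistics of the synthetic study grid."""

    def test_ratio_curve_peaks_mid_band_and_collapses_beyond_window(self, case_study_1):
        _, ratio_df = case_study_1
        curve = ratio_df.groupby("theta_deg")["log_ratio"].mean()
        assert curve.idxmax() in (30.0, 40.0)
        for theta in (60.0, 70.0, 80.0):
            assert curve[theta] < curve[10.0]

    def test_correlation_ordering_and_floor(self, case_study_1):
        k_df, _ = case_study_1
        r = {}
        for band in ("Ea40", "Ea50"):
            kd = k_df[k_df.band == "Ed"].set_index("scenario_id")["K"]
            ka = k_df[k_df.band == band].set_index("scenario_id")["K"]
            r[band], _ = scatter_stats(kd, ka.loc[kd.index])
        assert r["Ea40"] >= r["Ea50"]
        assert r["Ea50"] > 0.9

    def test_all_k_positive(self, study_tables):
        k_df, _ = study_tables
        sel = k_df[k_df.band.isin(["Ed", "Ea40"])]
        assert np.all(sel["K"] > 0)

    def test_errors_peak_in_clear_sky_columns(self, study_tables):
        # the least-diffuse lighting shows the largest Kd-reconstruction
        # errors; clear water classes peak right at zenith 0
        k_df, _ = study_tables
        m = mean_cell_slope(k_df, "Ea40", 1.5)
        wt = water_type_error_maps(k_df, "Ea40", 1.5, m=m)
        for wc, sub in wt.groupby("water_class"):
            worst = sub.loc[sub["mean_abs_eps_pct"].idxmax()]
            assert worst["cloud_fraction"] == 0.0
            if "clear" in wc:
                assert worst["solar_zenith_deg"] == 0.0

    def test_cell_mean_error_bounded(self, study_tables):
        k_df, _ = study_tables
        eh = error_heatmap(k_df, "Ea40", 1.5)
        assert np.all(np.isfinite(eh["mean_abs_eps_pct"]))
        assert len(eh) == 9 * 6


def test_render_heatmap_writes_image(tmp_path):
    from annkd.assessment import render_heatmap

    k_df = fake_k_table({"Ea40": 1.1})
    hm = lighting_heatmaps(k_df, "Ea40", 1.5)
    path = tmp_path / "hm.png"
    render_heatmap(hm, "m", path, title="slope")
    assert path.exists() and path.stat().st_size > 0
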