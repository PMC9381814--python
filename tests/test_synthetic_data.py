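"""Generator contract: calibration, planted optics, cubes, determinism."""

import numpy as np
import pandas as pd
import pytest

from leafchem.exceptions import ConfigurationError, DegenerateOpticsError
from leafchem.imaging import ndvi_map
from leafchem.synthetic_data import (
    DEFAULT_SIGNATURE_CENTERS,
    REFERENCE_PANEL,
    AnalytePanelConfig,
    OpticsConfig,
    StudyConfig,
    coupling_strengths,
    default_baseline,
    generate_concentrations,
    generate_cube,
    generate_reflectance,
    generate_study,
)


class TestConcentrations:
    def test_default_panel_has_24_analytes(self, default_panel):
        assert len(default_panel.names) == 24
        assert np.all(default_panel.mean > 0)

    def test_heavy_tailed_analyte_cv_is_reproduced(self, default_panel):
        # Gln: mean 20.93, SD 31.58 -> CV 150.88%; the sampled column's CV
        # must land within 10% of that at large n
        df = generate_concentrations(10_000, default_panel, seed=0)
        gln = df["Gln"]
        cv = gln.std(ddof=1) / gln.mean() * 100.0
        assert abs(cv / 150.88 - 1.0) < 0.10

    def test_moment_calibration_at_large_n(self, default_panel):
        df = generate_concentrations(10_000, default_panel, seed=1)
        mean_dev = np.abs(df.mean().to_numpy() / default_panel.mean - 1.0)
        sd_dev = np.abs(df.std(ddof=1).to_numpy() / default_panel.sd - 1.0)
        assert mean_dev.max() < 0.10
        assert sd_dev.max() < 0.10

    def test_zero_sd_gives_constant_columns(self):
        panel = AnalytePanelConfig(names=("A", "B"), mean=[5.0, 2.0], sd=[0.0, 0.0])
        df = generate_concentrations(5, panel, seed=0)
        assert np.all(df["A"] == 5.0) and np.all(df["B"] == 2.0)

    def test_determinism(self, default_panel):
        a = generate_concentrations(50, default_panel, seed=9)
        b = generate_concentrations(50, default_panel, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ConfigurationError):
            AnalytePanelConfig(names=("A",), mean=[0.0], sd=[1.0])

    def test_min_clip_enforced(self):
        panel = AnalytePanelConfig(names=("A",), mean=[1.0], sd=[5.0], min_clip=0.5)
        df = generate_concentrations(500, panel, seed=2)
        assert df["A"].min() >= 0.5


class TestReflectance:
    wl = np.linspace(400.0, 1000.0, 120)

    def test_zero_coupling_reproduces_baseline(self):
        optics = OpticsConfig(coupling=np.zeros((2, 8)), noise_sd=0.0,
                              multiplicative_sd=0.0)
        conc = pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [4.0, 5.0, 6.0]})
        spectra = generate_reflectance(conc, optics, self.wl, seed=0)
        expected = np.broadcast_to(default_baseline(self.wl), spectra.shape)
        np.testing.assert_allclose(spectra, expected, atol=1e-12)

    def test_single_feature_monotone_in_concentration(self):
        optics = OpticsConfig(signature_centers=(550.0,), signature_widths=(8.0,),
                              coupling=np.array([[1.5]]), noise_sd=0.0,
                              multiplicative_sd=0.0)
        conc = pd.DataFrame({"A": [1.0, 5.0, 9.0]})
        spectra = generate_reflectance(conc, optics, self.wl, seed=0)
        band = np.argmin(np.abs(self.wl - 550.0))
        r = spectra[:, band]
        assert r[0] > r[1] > r[2]

    def test_visible_band_varies_more_than_nir(self, default_panel):
        conc = generate_concentrations(200, default_panel, seed=3)
        spectra = generate_reflectance(conc, OpticsConfig(), self.wl, seed=4)
        cv = spectra.std(0, ddof=1) / spectra.mean(0)
        b550 = np.argmin(np.abs(self.wl - 550.0))
        b900 = np.argmin(np.abs(self.wl - 900.0))
        assert cv[b550] > cv[b900]

    def test_nir_plateau_above_red_for_every_leaf(self, default_panel):
        conc = generate_concentrations(100, default_panel, seed=5)
        spectra = generate_reflectance(conc, OpticsConfig(), self.wl, seed=6)
        nir = spectra[:, self.wl > 750.0].min(axis=1)
        red = spectra[:, (self.wl > 620.0) & (self.wl < 710.0)].max(axis=1)
        assert np.all(nir > red)

    def test_fully_clipped_optics_rejected(self):
        # one grid-wide absorption feature driven far beyond the baseline
        optics = OpticsConfig(signature_centers=(700.0,), signature_widths=(500.0,),
                              coupling=np.full((1, 1), 50.0), depth_scale=5.0,
                              noise_sd=0.0, multiplicative_sd=0.0,
                              baseline_spectrum=np.full(self.wl.size, 0.005))
        conc = pd.DataFrame({"A": np.linspace(1, 30, 12)})
        with pytest.raises(DegenerateOpticsError):
            generate_reflectance(conc, optics, self.wl, seed=0)

    def test_default_centers_sit_in_pigment_windows(self):
        for c in DEFAULT_SIGNATURE_CENTERS:
            assert 505.39 <= c <= 604.95 or 651.21 <= c <= 714.10


class TestCube:
    wl = np.linspace(400.0, 1000.0, 40)

    def test_noise_free_mask_mean_equals_spectrum(self):
        spectrum = default_baseline(self.wl)
        cube, mask = generate_cube(spectrum, self.wl, shape=(16, 16), noise_sd=0.0)
        leaf_mean = cube.reflectance[mask].mean(axis=0)
        np.testing.assert_allclose(leaf_mean, spectrum, atol=1e-12)

    def test_background_ndvi_is_negative(self):
        cube, mask = generate_cube(default_baseline(self.wl), self.wl,
                                   shape=(16, 16), noise_sd=0.002, seed=1)
        ndvi = ndvi_map(cube)
        assert np.all(ndvi.values[~mask] < 0)

    def test_same_seed_identical_cube(self):
        a, _ = generate_cube(default_baseline(self.wl), self.wl, (12, 12),
                             noise_sd=0.01, seed=5)
        b, _ = generate_cube(default_baseline(self.wl), self.wl, (12, 12),
                             noise_sd=0.01, seed=5)
        np.testing.assert_array_equal(a.reflectance, b.reflectance)

    def test_too_small_shape_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_cube(default_baseline(self.wl), self.wl, shape=(4, 20))


class TestStudy:
    def test_default_study_has_290_rows(self, study_table):
        assert study_table.n_samples == 290
        assert list(study_table.frame["experiment"].value_counts().sort_index()) == [144, 146]

    def test_small_study_experiment_labels(self):
        table = generate_study(StudyConfig(n_exp1=6, n_exp2=4, n_bands=20, seed=0))
        assert table.n_samples == 10
        assert list(table.frame["experiment"]) == [1] * 6 + [2] * 4

    def test_same_seed_identical_table(self):
        cfg = StudyConfig(n_exp1=8, n_exp2=7, n_bands=25, seed=42)
        a = generate_study(cfg)
        b = generate_study(cfg)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_visible_cv_exceeds_nir_cv(self, study_table):
        X = study_table.spectra()
        wl = study_table.wavelengths
        cv = X.std(0, ddof=1) / X.mean(0) * 100.0
        assert cv[wl <= 717.08].mean() > cv[wl > 717.08].mean()

    def test_coupling_strengths_cover_strong_and_weak(self):
        s = coupling_strengths()
        assert s.max() == pytest.approx(2.0)
        assert s.min() < 0.2

    def test_csv_round_trip(self, tmp_path, study_table):
        path = tmp_path / "samples.csv"
        study_table.to_csv(path)
        from leafchem.tables import SampleTable

        back = SampleTable.from_csv(path)
        assert back.analytes == study_table.analytes
        # wavelength column names carry 0.01 nm precision
        np.testing.assert_allclose(back.wavelengths, study_table.wavelengths,
                                   atol=5e-3)
        np.testing.assert_allclose(back.spectra(), study_table.spectra(), atol=1e-6)
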