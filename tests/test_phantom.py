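"""Synthetic-data generator: expectations, noise statistics, determinism."""

import numpy as np
import pytest
from scipy import stats

from cellxrf import phantom
from cellxrf.phantom import (CellGeometry, Hotspot, PhantomConfig,
                             apply_radiation_damage, build_truth,
                             expected_line_maps, expected_stack,
                             generate_image_series, generate_phantom,
                             generate_standard_spectrum)
from cellxrf.spectral import KALPHA_KEV, LineDefinition, net_line_area


def _quiet(**kw):
    """Config with no background so only cell-borne lines remain."""
    defaults = dict(background_rates={}, continuum_rate=0.0, scatter_rate=0.0,
                    apply_absorption=False)
    defaults.update(kw)
    return PhantomConfig(**defaults)


class TestGeneratePhantom:
    def test_empty_phantom_is_noise_only(self):
        cfg = _quiet(true_areal_density={}, saxs_contrast=0.0, seed=5)
        truth, stack, saxs = generate_phantom(cfg)
        assert stack.counts.sum() == 0
        # SAXS is baseline plus Gaussian noise only
        assert saxs.values.mean() == pytest.approx(cfg.saxs_baseline, abs=1.0)
        assert saxs.values.std() == pytest.approx(cfg.saxs_noise_sd, rel=0.1)

    def test_poisson_mean_matches_analytic_expectation(self):
        """density * sensitivity * dwell = 1 * 100 * 0.5 -> 50 counts/px,
        averaged over >= 1e4 in-cell pixels."""
        cfg = _quiet(grid_shape=(100, 100), step_y_um=1.0, step_z_um=1.0,
                     cell=CellGeometry((49.5, 49.5), 45.0, 45.0, 30.0),
                     true_areal_density={"Cu": 1.0},
                     sensitivity_true={"Cu": 100.0}, seed=9)
        truth, stack, _ = generate_phantom(cfg)
        # interior pixels only: uniform density over the whole footprint
        m = truth.mask_true
        assert m.sum() >= 1e4 * 0.6
        second = generate_phantom(phantom.replace(cfg, seed=10))[1]
        counts = np.concatenate([stack.counts[m].sum(axis=-1),
                                 second.counts[m].sum(axis=-1)])
        assert counts.size >= 1e4
        sem = np.sqrt(50.0 / counts.size)
        assert counts.mean() == pytest.approx(50.0, abs=3 * sem)

    def test_identical_seed_is_bitwise_reproducible(self):
        cfg = PhantomConfig(seed=17)
        t1, s1, x1 = generate_phantom(cfg)
        t2, s2, x2 = generate_phantom(cfg)
        np.testing.assert_array_equal(s1.counts, s2.counts)
        np.testing.assert_array_equal(x1.values, x2.values)

    def test_poisson_variance_matches_mean(self):
        """Chi-square test of var/mean over >= 1e3 equal-rate pixels."""
        cfg = _quiet(true_areal_density={}, background_rates={"K": 80.0},
                     seed=3)
        _, stack, _ = generate_phantom(cfg)
        line = LineDefinition.kalpha("K")
        e = stack.energy_keV
        sel = (e > line.energy_keV - 0.1) & (e < line.energy_keV + 0.1)
        counts = stack.counts[..., sel].sum(axis=-1).ravel()
        n = counts.size
        assert n >= 1000
        # expected rate: 80 counts/s * 0.5 s times the window's line coverage
        lam = counts.mean()
        assert lam == pytest.approx(40.0, rel=0.1)
        chi2 = (n - 1) * counts.var(ddof=1) / lam  # dispersion test
        lo, hi = stats.chi2.ppf([0.005, 0.995], df=n - 1)
        assert lo < chi2 < hi

    def test_mass_map_consistency(self):
        cfg = _quiet(true_areal_density={"Zn": 0.7})
        truth = build_truth(cfg)
        expected = 0.7 * truth.mask_true.sum() * truth.pixel_area_um2
        assert truth.total_mass_fg("Zn") == pytest.approx(expected, rel=1e-12)

    def test_density_zero_outside_mask(self):
        truth = build_truth(_quiet(true_areal_density={"Cu": 1.0}))
        assert np.all(truth.density_maps["Cu"][~truth.mask_true] == 0)

    def test_hotspot_multiplies_density_locally(self):
        hs = Hotspot("Cu", (24.5, 24.5), radius_um=6.0, multiplier=3.0)
        cfg = _quiet(true_areal_density={"Cu": 1.0}, hotspots=(hs,))
        truth = build_truth(cfg)
        assert truth.density_maps["Cu"].max() == pytest.approx(3.0)
        assert truth.density_maps["Cu"][truth.mask_true].min() == pytest.approx(1.0)

    def test_zero_area_cell_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(cell=CellGeometry((24.5, 24.5), 0.0, 15.0, 30.0))

    def test_grid_smaller_than_cell_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            PhantomConfig(grid_shape=(8, 8),
                          cell=CellGeometry((3.5, 3.5), 15.0, 15.0, 30.0))

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(true_areal_density={"Cu": -1.0})


class TestStandardSpectrum:
    def test_line_area_linear_in_certified_value(self):
        cfg = _quiet()
        kw = dict(live_time_s=250.0, sensitivity_true={"Cu": 100.0},
                  config=cfg, seed=4)
        s1 = generate_standard_spectrum({"Cu": 100.0}, **kw)
        s2 = generate_standard_spectrum({"Cu": 200.0}, **kw)
        line = LineDefinition.kalpha("Cu")
        a1 = net_line_area(s1, line)
        a2 = net_line_area(s2, line)
        assert a2 / a1 == pytest.approx(2.0, rel=0.01)

    def test_zero_live_time_gives_empty_spectrum(self):
        s = generate_standard_spectrum({"Cu": 100.0}, live_time_s=0.0,
                                       config=_quiet())
        assert s.counts.sum() == 0

    def test_peak_area_matches_analytic_expectation(self):
        cfg = _quiet()
        s = generate_standard_spectrum({"Zn": 181.1}, live_time_s=250.0,
                                       pellet_areal_mass_mg_cm2=50.0,
                                       sensitivity_true={"Zn": 120.0},
                                       config=cfg, seed=11)
        expected = 181.1 * 50.0 * 0.01 * 120.0 * 250.0
        got = net_line_area(s, LineDefinition.kalpha("Zn"))
        assert got == pytest.approx(expected, abs=3 * np.sqrt(expected))

    def test_missing_sensitivity_raises(self):
        with pytest.raises(KeyError):
            generate_standard_spectrum({"Cu": 100.0}, sensitivity_true={},
                                       config=_quiet())

    def test_nonpositive_certified_rejected(self):
        with pytest.raises(ValueError):
            generate_standard_spectrum({"Cu": 0.0}, config=_quiet())


class TestRadiationDamage:
    def _expectation(self):
        cfg = _quiet(true_areal_density={"Mn": 1.0, "Cu": 1.0})
        return cfg, expected_stack(cfg, include_background=False)

    def test_zero_damage_is_identity(self):
        _, exp = self._expectation()
        out = apply_radiation_damage(exp, {"Mn": 0.0}, pass_index=3)
        np.testing.assert_allclose(out.counts, exp.counts)

    def test_forty_percent_loss_scales_line_exactly(self):
        """Maximum elemental signal loss: one pass at 0.4 -> x0.6."""
        _, exp = self._expectation()
        out = apply_radiation_damage(exp, {"Mn": 0.4}, pass_index=1)
        e = exp.energy_keV
        mn = (e > KALPHA_KEV["Mn"] - 0.2) & (e < KALPHA_KEV["Mn"] + 0.2)
        cu = (e > KALPHA_KEV["Cu"] - 0.2) & (e < KALPHA_KEV["Cu"] + 0.2)
        ratio = out.counts[..., mn].sum() / exp.counts[..., mn].sum()
        assert ratio == pytest.approx(0.6, rel=1e-9)
        # untouched element unaffected
        assert out.counts[..., cu].sum() == pytest.approx(
            exp.counts[..., cu].sum(), rel=1e-12)

    def test_negative_damage_concentrates(self):
        _, exp = self._expectation()
        out = apply_radiation_damage(exp, {"Cu": -0.1}, pass_index=1)
        e = exp.energy_keV
        cu = (e > KALPHA_KEV["Cu"] - 0.2) & (e < KALPHA_KEV["Cu"] + 0.2)
        ratio = out.counts[..., cu].sum() / exp.counts[..., cu].sum()
        assert ratio == pytest.approx(1.1, rel=1e-9)

    def test_compounds_over_passes(self):
        _, exp = self._expectation()
        two = apply_radiation_damage(exp, {"Mn": 0.2}, pass_index=2)
        e = exp.energy_keV
        mn = (e > KALPHA_KEV["Mn"] - 0.2) & (e < KALPHA_KEV["Mn"] + 0.2)
        ratio = two.counts[..., mn].sum() / exp.counts[..., mn].sum()
        assert ratio == pytest.approx(0.8 ** 2, rel=1e-9)

    def test_invalid_inputs_rejected(self):
        _, exp = self._expectation()
        with pytest.raises(ValueError):
            apply_radiation_damage(exp, {"Mn": 0.5}, pass_index=1)
        with pytest.raises(ValueError):
            apply_radiation_damage(exp, {"Mn": 0.1}, pass_index=-1)
        with pytest.raises(ValueError):
            PhantomConfig(damage={"Mn": 0.41})


class TestImageSeries:
    def test_static_series_has_identical_frames(self):
        s = generate_image_series(n_frames=3, jitter_sd_um=(0.0, 0.0), seed=1)
        np.testing.assert_array_equal(s.frames[0], s.frames[1])
        np.testing.assert_array_equal(s.frames[0], s.frames[2])

    def test_injected_jitter_sd_matches_draws(self):
        """Sample sd of the generated trajectory reproduces the requested
        0.23 um (Y) / 0.84 um (Z) within 10%."""
        s = generate_image_series(n_frames=9000, jitter_sd_um=(0.23, 0.84),
                                  seed=2)
        sd_zy = s.truth_px["cell"].std(axis=0, ddof=1) * s.um_per_px
        assert sd_zy[0] == pytest.approx(0.84, rel=0.10)
        assert sd_zy[1] == pytest.approx(0.23, rel=0.10)

    def test_linear_drift_shifts_one_px_per_frame(self):
        s = generate_image_series(n_frames=5, drift_model="linear",
                                  jitter_sd_um=(0.0, 0.0),
                                  drift_px_per_frame=(1.0, 0.0), seed=3)
        steps = np.diff(s.truth_px["cell"], axis=0)
        np.testing.assert_allclose(steps[:, 0], 1.0)
        np.testing.assert_allclose(steps[:, 1], 0.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            generate_image_series(n_frames=1)
        with pytest.raises(ValueError):
            generate_image_series(n_frames=5, jitter_sd_um=(-0.1, 0.2))
        with pytest.raises(ValueError):
            generate_image_series(n_frames=5, drift_model="brownian")
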