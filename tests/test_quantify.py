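"""External-standard calibration, absorption corrections, LOD, aggregation."""

import math

import numpy as np
import pytest

from cellxrf import quantify, xray
from cellxrf.phantom import (PhantomConfig, generate_phantom,
                             generate_standard_spectrum)
from cellxrf.quantify import (CorrectionGeometry, absorption_correction,
                              accumulation_ranking, aggregate_cells,
                              areal_concentration, calibrate_sensitivity,
                              lod_threshold)
from cellxrf.spectral import KALPHA_KEV


class TestCalibrateSensitivity:
    def test_round_trip_recovers_true_sensitivity(self):
        """Standard built with known S_true; recovered within 3% at
        >= 1e5 counts per line."""
        s_true = {"Mn": 1300.0, "Fe": 1500.0, "Cu": 2000.0, "Zn": 2200.0}
        certified = {"Mn": 10.46, "Fe": 197.94, "Cu": 275.2, "Zn": 181.1}
        cfg = PhantomConfig()
        spec = generate_standard_spectrum(certified, live_time_s=250.0,
                                          sensitivity_true=s_true,
                                          config=cfg, seed=6)
        calib = calibrate_sensitivity(spec, certified)
        for el, s in s_true.items():
            assert calib.sensitivity[el] == pytest.approx(s, rel=0.03)

    def test_sensitivity_inverse_in_certified_value(self):
        s_true = {"Cu": 2000.0}
        spec = generate_standard_spectrum({"Cu": 275.2}, live_time_s=250.0,
                                          sensitivity_true=s_true,
                                          config=PhantomConfig(), seed=6)
        c1 = calibrate_sensitivity(spec, {"Cu": 275.2})
        c2 = calibrate_sensitivity(spec, {"Cu": 550.4})
        assert c2.sensitivity["Cu"] == pytest.approx(
            c1.sensitivity["Cu"] / 2, rel=1e-9)

    def test_sensitivity_inverse_in_live_time(self):
        s_true = {"Cu": 2000.0}
        spec = generate_standard_spectrum({"Cu": 275.2}, live_time_s=250.0,
                                          sensitivity_true=s_true,
                                          config=PhantomConfig(), seed=6)
        c1 = calibrate_sensitivity(spec, {"Cu": 275.2}, live_time_s=250.0)
        c2 = calibrate_sensitivity(spec, {"Cu": 275.2}, live_time_s=500.0)
        assert c2.sensitivity["Cu"] == pytest.approx(
            c1.sensitivity["Cu"] / 2, rel=1e-9)

    def test_interpolated_sensitivity_between_neighbours(self):
        calib = quantify.SensitivityCalibration(
            {"Fe": 1500.0, "Cu": 2000.0}, 250.0, {}, 50.0)
        s_ni = calib.sensitivity_for("Ni")  # Z=28, between Fe(26), Cu(29)
        assert 1500.0 < s_ni < 2000.0

    def test_absent_line_rejected(self):
        spec = generate_standard_spectrum({"Cu": 275.2}, live_time_s=250.0,
                                          sensitivity_true={"Cu": 2000.0},
                                          config=PhantomConfig(
                                              continuum_rate=0.0,
                                              scatter_rate=0.0),
                                          seed=6)
        with pytest.raises(ValueError, match="net counts"):
            calibrate_sensitivity(spec, {"Cu": 275.2, "Mn": 10.0})


class TestAbsorptionCorrection:
    def test_zero_paths_give_unity(self):
        g = CorrectionGeometry(wall_thickness_um=0.0, cell_diameter_um=0.0)
        assert absorption_correction(8.048, g) == pytest.approx(1.0)

    def test_lower_energy_lines_absorbed_more(self):
        g = CorrectionGeometry()
        a = [absorption_correction(KALPHA_KEV[el], g)
             for el in ("Mn", "Fe", "Ni", "Cu", "Zn")]
        assert all(x > y for x, y in zip(a, a[1:]))
        assert all(x >= 1.0 for x in a)

    def test_wall_factor_matches_cylindrical_ray_integration(self):
        """Slab model vs numerical integration of the exact path through a
        100 um-ID / 10 um-wall cylindrical shell, within 5%.

        The confocal detector sits perpendicular to the beam at 45 deg
        elevation, so exit rays run in the plane spanned by the capillary
        axis (y) and the vertical (z); the cylinder axis is y, hence the
        radial coordinate of a ray point is sqrt(x0^2 + z^2) with x0 the
        emission point's offset along the beam, spanning the cell width.
        """
        e_line = KALPHA_KEV["Mn"]
        g = CorrectionGeometry(cell_diameter_um=0.0)  # isolate wall factor
        slab = absorption_correction(e_line, g)

        mu = xray.mass_attenuation("silica", e_line) * 2.65  # 1/cm
        r_in, r_out = 50.0, 60.0
        sin45 = math.sin(math.radians(45))

        def shell_path(x0, z0):
            # march upward along the 45 deg ray; x stays constant
            ts = np.linspace(0.0, 300.0, 60001)
            z = z0 + ts * sin45
            r = np.hypot(x0, z)
            inside = (r >= r_in) & (r <= r_out)
            return inside.sum() * (ts[1] - ts[0])

        transmissions = []
        for x0 in np.linspace(-15.0, 15.0, 11):
            path_um = shell_path(x0, 20.0)
            transmissions.append(math.exp(-mu * path_um * 1e-4))
        exact = 1.0 / np.mean(transmissions)
        assert slab == pytest.approx(exact, rel=0.05)

    def test_out_of_table_energy_raises(self):
        with pytest.raises(ValueError):
            absorption_correction(1.0)


class TestConcentrationFormulas:
    def test_worked_example(self):
        # 50 counts, S=100 counts/(fg/um2)/s, 0.5 s, A=1 -> 1 fg/um2
        assert areal_concentration(50.0, 100.0, 0.5, 1.0) == pytest.approx(1.0)

    def test_zero_counts_give_zero(self):
        assert areal_concentration(0.0, 100.0, 0.5, 1.2) == 0.0

    def test_linear_and_inverse_scalings(self):
        base = areal_concentration(50.0, 100.0, 0.5, 1.0)
        assert areal_concentration(100.0, 100.0, 0.5, 1.0) == 2 * base
        assert areal_concentration(50.0, 100.0, 0.5, 1.3) == pytest.approx(1.3 * base)
        assert areal_concentration(50.0, 200.0, 0.5, 1.0) == base / 2
        assert areal_concentration(50.0, 100.0, 1.0, 1.0) == base / 2

    def test_invalid_factors_rejected(self):
        with pytest.raises(ValueError):
            areal_concentration(50.0, 0.0, 0.5)
        with pytest.raises(ValueError):
            areal_concentration(-1.0, 100.0, 0.5)

    def test_lod_examples(self):
        assert lod_threshold(0.0, 100.0, 0.5) == 0.0
        # 3*sqrt(100) * 1 / (100 * 0.5) = 0.6 fg/um2
        assert lod_threshold(100.0, 100.0, 0.5, 1.0) == pytest.approx(0.6)

    def test_single_scan_recovery_of_high_exposure_truth(self):
        """Phantom at 3.04 fg/um2 Cu recovered within 10%."""
        from cellxrf.pipeline import StudyConfig, ConditionSpec, run_study
        cfg = StudyConfig(conditions=(ConditionSpec("E", {"Cu": 675},
                                                    {"Cu": 3.04}),),
                          n_replicates=1, seed=5)
        res = run_study(cfg)
        got = res.scans[0].concentration_fg_um2["Cu"]
        counts = res.scans[0].mean_counts["Cu"] * res.scans[0].mask.n_pixels
        assert counts >= 1e4
        assert got == pytest.approx(3.04, rel=0.10)


class TestAggregation:
    def test_mean_and_sample_sd(self):
        r = aggregate_cells("Cu", [0.1, 0.2, 0.3])
        assert r.mean_fg_um2 == pytest.approx(0.2)
        assert r.sd_fg_um2 == pytest.approx(0.1)
        assert r.n_cells == 3

    def test_single_cell_has_no_sd(self):
        r = aggregate_cells("Cu", [0.5])
        assert r.sd_fg_um2 is None
        assert r.display() == "0.50"

    def test_below_lod_flagging(self):
        r = aggregate_cells("Ni", [0.001, 0.002, 0.0], lod_fg_um2=0.05)
        assert r.below_lod and r.display() == "<LOD"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_cells("Cu", [])


class TestAccumulationRanking:
    def test_strong_copper_accumulation_ranks_first(self):
        results = {
            "Cu": {0.0: 0.20, 200.0: 0.39, 675.0: 3.04},
            "Ni": {0.0: 0.0, 800.0: 0.22, 2700.0: 1.20},
            "Zn": {0.0: 0.50, 800.0: 0.50, 2700.0: 0.63},
        }
        ranked = accumulation_ranking(results)
        assert [el for el, _ in ranked] == ["Cu", "Ni", "Zn"]
        assert ranked[0][1] == pytest.approx(2.84)

    def test_tie_broken_alphabetically_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            ranked = accumulation_ranking({"Zn": {0.0: 0.1, 100.0: 0.3},
                                           "Cu": {0.0: 0.2, 100.0: 0.4}})
        assert [el for el, _ in ranked] == ["Cu", "Zn"]
        assert "tie" in caplog.text

    def test_single_element_passthrough(self):
        assert accumulation_ranking({"Cu": {0.0: 0.1, 10.0: 0.5}}) == [
            ("Cu", pytest.approx(0.4))]

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            accumulation_ranking({"Cu": {100.0: 0.5}, "Zn": {0.0: 0.1, 1.0: 0.2}})
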