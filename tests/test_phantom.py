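"""Phantom generator: forward elasticity, dipole traction, bead rendering."""

import numpy as np
import pytest
from scipy.signal import fftconvolve

from cardiotfm import phantom
from cardiotfm.fields import ImagingConfig, TractionField, make_grid
from cardiotfm.substrate import ElasticSubstrate


class TestDipoleTraction:
    def test_zero_peak_stress_gives_zero_field(self, pattern):
        grid = make_grid((60.0, 120.0), 1.5)
        tf = phantom.make_dipole_traction(pattern, 0.0, grid)
        assert np.all(tf.t_x == 0.0) and np.all(tf.t_y == 0.0)

    def test_doubling_stress_doubles_total_force(self, pattern):
        grid = make_grid((60.0, 120.0), 1.5)
        f1 = phantom.make_dipole_traction(pattern, 200.0, grid).total_scalar_force_nN()
        f2 = phantom.make_dipole_traction(pattern, 400.0, grid).total_scalar_force_nN()
        assert f2 == pytest.approx(2.0 * f1, rel=1e-12)

    def test_total_force_matches_gaussian_integral(self):
        """7:1 pattern, sigma 6 µm, peak 400 Pa: total force = 2*(2*pi*sigma^2*peak)."""
        from cardiotfm.cohort import micropattern_geometry
        pat = micropattern_geometry(aspect_ratio_r=7.0, width_W_um=18.9)
        grid = make_grid((90.0, 200.0), 1.8)     # spacing <= sigma/3
        tf = phantom.make_dipole_traction(pat, 400.0, grid, patch_sigma_um=6.0)
        analytic = 2.0 * (2.0 * np.pi * 6.0 ** 2 * 400.0) * 1e-3   # nN
        assert tf.total_scalar_force_nN() == pytest.approx(analytic, rel=0.01)

    def test_force_balance(self, pattern):
        grid = make_grid((60.0, 120.0), 1.5)
        tf = phantom.make_dipole_traction(pattern, 400.0, grid)
        fx, fy = tf.net_force_nN()
        assert np.hypot(fx, fy) < 1e-6 * tf.total_scalar_force_nN()

    def test_overlapping_patches_rejected(self):
        from cardiotfm.cohort import micropattern_geometry
        pat = micropattern_geometry(aspect_ratio_r=2.0, width_W_um=8.0)
        grid = make_grid((60.0, 120.0), 1.5)
        with pytest.raises(ValueError, match="overlap"):
            phantom.make_dipole_traction(pat, 400.0, grid, patch_sigma_um=6.0)


class TestBoussinesqDisplacement:
    def test_zero_traction_gives_zero_displacement(self, substrate_10kpa):
        gx, gy = make_grid((40.0, 40.0), 2.0)
        tf = TractionField(gx, gy, np.zeros((gy.size, gx.size)),
                           np.zeros((gy.size, gx.size)))
        u = phantom.boussinesq_displacement(tf, substrate_10kpa)
        assert np.allclose(u.u_x, 0.0) and np.allclose(u.u_y, 0.0)

    def test_linearity(self, pattern, substrate_10kpa):
        grid = make_grid((60.0, 120.0), 1.5)
        t1 = phantom.make_dipole_traction(pattern, 300.0, grid, patch_sigma_um=5.0)
        t2 = phantom.make_dipole_traction(pattern, 150.0, grid, patch_sigma_um=7.0)
        combo = TractionField(t1.grid_x, t1.grid_y,
                              2.0 * t1.t_x + 3.0 * t2.t_x,
                              2.0 * t1.t_y + 3.0 * t2.t_y)
        u1 = phantom.boussinesq_displacement(t1, substrate_10kpa)
        u2 = phantom.boussinesq_displacement(t2, substrate_10kpa)
        uc = phantom.boussinesq_displacement(combo, substrate_10kpa)
        np.testing.assert_allclose(uc.u_x, 2.0 * u1.u_x + 3.0 * u2.u_x, atol=1e-12)
        np.testing.assert_allclose(uc.u_y, 2.0 * u1.u_y + 3.0 * u2.u_y, atol=1e-12)

    def test_stiffness_ratio_exact(self, pattern, substrate_10kpa):
        """Same traction on 10 vs 35 kPa: displacement ratio exactly 3.5 pointwise."""
        grid = make_grid((60.0, 120.0), 1.5)
        tf = phantom.make_dipole_traction(pattern, 400.0, grid, patch_sigma_um=5.0)
        u10 = phantom.boussinesq_displacement(tf, substrate_10kpa)
        u35 = phantom.boussinesq_displacement(tf, ElasticSubstrate(35_000.0))
        np.testing.assert_allclose(u10.u_x, 3.5 * u35.u_x, rtol=1e-12, atol=1e-15)
        np.testing.assert_allclose(u10.u_y, 3.5 * u35.u_y, rtol=1e-12, atol=1e-15)

    def test_against_cerruti_real_space_convolution(self, substrate_10kpa):
        """Radial decay of a single tangential Gaussian patch matches a direct
        real-space convolution with the Cerruti point-force surface solution
        within 2% beyond 3 sigma (offsets removed by differencing, since the
        spectral solution fixes the k = 0 mode instead of the far field)."""
        E = substrate_10kpa.youngs_modulus_E
        nu = substrate_10kpa.poisson_ratio_nu
        sigma, spacing = 4.0, 1.0
        gx, gy = make_grid((128.0, 128.0), spacing)
        XX, YY = np.meshgrid(gx, gy, indexing="xy")
        cx, cy = gx.mean(), gy.mean()
        tx = 200.0 * np.exp(-((XX - cx) ** 2 + (YY - cy) ** 2) / (2 * sigma ** 2))
        tf = TractionField(gx, gy, tx.copy(), np.zeros_like(tx))
        u_fft = phantom.boussinesq_displacement(tf, substrate_10kpa, padding_factor=4)

        # independent oracle: Cerruti kernel, linear convolution in real space
        n = gx.size
        off = np.arange(-(n - 1), n) * spacing
        OX, OY = np.meshgrid(off, off, indexing="xy")
        R = np.hypot(OX, OY)
        with np.errstate(divide="ignore", invalid="ignore"):
            Kxx = (1 + nu) / (np.pi * E * R ** 3) * ((1 - nu) * R ** 2 + nu * OX ** 2)
        so = ((np.arange(40) + 0.5) / 40 - 0.5) * spacing   # pixel-average at r ~ 0
        SX, SY = np.meshgrid(so, so, indexing="xy")
        SR = np.hypot(SX, SY)
        Kxx[n - 1, n - 1] = np.mean(
            (1 + nu) / (np.pi * E * SR ** 3) * ((1 - nu) * SR ** 2 + nu * SX ** 2))
        ux_conv = fftconvolve(tx - tx.mean(), Kxx, mode="valid") * spacing ** 2

        r = np.abs(gy - cy)
        sel = (r > 3 * sigma) & (r < 45.0)
        ref = np.argmin(np.abs(r - 50.0))
        a = u_fft.u_x[:, n // 2]
        b = ux_conv[:, n // 2]
        da, db = a[sel] - a[ref], b[sel] - b[ref]
        assert np.max(np.abs(da - db) / np.abs(db)) < 0.02

    def test_rejects_irregular_grid(self, substrate_10kpa):
        gx = np.array([0.0, 1.0, 2.5, 3.0])
        gy = np.array([0.0, 1.0, 2.0, 3.0])
        tf = TractionField(gx, gy, np.zeros((4, 4)), np.zeros((4, 4)))
        with pytest.raises(ValueError, match="regular"):
            phantom.boussinesq_displacement(tf, substrate_10kpa)


class TestBeadRendering:
    def test_zero_displacement_identical_to_reference(self, beads, small_imaging):
        nm = phantom.BeadNoiseModel()
        ref = phantom.render_bead_frame(beads, None, small_imaging, nm, seed=9)
        zero = phantom.render_bead_frame(
            beads, _zero_field(small_imaging), small_imaging, nm, seed=9)
        np.testing.assert_array_equal(ref, zero)

    def test_uniform_shift_moves_correlation_peak(self, beads, small_imaging):
        """Whole-frame cross-correlation peaks at the applied (3, 0) px lag."""
        px = small_imaging.px_size
        ref = phantom.render_bead_frame(beads, None, small_imaging, None)
        mov = phantom.render_bead_frame(beads + np.array([3.0 * px, 0.0]),
                                        None, small_imaging, None)
        a = ref.astype(float) - ref.mean()
        b = mov.astype(float) - mov.mean()
        corr = fftconvolve(b, a[::-1, ::-1], mode="same")
        iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
        lag = (ix - (corr.shape[1] // 2), iy - (corr.shape[0] // 2))
        assert lag == (3, 0)

    def test_noise_seed_statistics(self, beads, small_imaging):
        """Different seeds differ only in noise; same seed is bit-identical."""
        nm = phantom.BeadNoiseModel(shot=False, read_sigma=50.0)
        f1 = phantom.render_bead_frame(beads, None, small_imaging, nm, seed=1)
        f2 = phantom.render_bead_frame(beads, None, small_imaging, nm, seed=2)
        f1b = phantom.render_bead_frame(beads, None, small_imaging, nm, seed=1)
        np.testing.assert_array_equal(f1, f1b)
        diff = np.abs(f1.astype(float) - f2.astype(float))
        assert 0.0 < diff.mean() < 4.0 * 50.0


class TestModulationAndSequence:
    def test_raised_cosine_shape(self):
        t = np.arange(0, 7, 1 / 30)
        s = phantom.raised_cosine_modulation(t, 1.0, 0.4)
        assert s[0] == 0.0
        assert np.all((s >= 0.0) & (s <= 1.0))
        np.testing.assert_allclose(s, phantom.raised_cosine_modulation(t + 3.0, 1.0, 0.4),
                                   atol=1e-12)
        # 7 distinct pulses in 7 s at 1 Hz
        from scipy.signal import find_peaks
        peaks, _ = find_peaks(s, height=0.9)
        assert peaks.size == 7

    def test_sequence_construction(self, sim7s):
        assert sim7s.sequence.n_frames == 210
        assert sim7s.truth.modulation[0] == 0.0
        assert sim7s.truth.total_force_truth_nN.max() == pytest.approx(
            sim7s.truth.peak_total_force_nN)

    def test_resource_guard(self, pattern, substrate_10kpa, small_imaging):
        with pytest.raises(ValueError, match="resource guard"):
            phantom.simulate_tfm_sequence(pattern, substrate_10kpa, small_imaging,
                                          duration_s=5000.0)

    def test_byte_identical_tiff_for_same_seed(self, pattern, substrate_10kpa,
                                               tmp_path):
        imaging = ImagingConfig(px_size=0.275, fps=30.0, frame_shape=(100, 300),
                                crop_window_um=(27.0, 82.0))
        paths = []
        for run in ("a", "b"):
            sim = phantom.simulate_tfm_sequence(pattern, substrate_10kpa, imaging,
                                                duration_s=2.0, seed=5)
            p = tmp_path / f"{run}.tif"
            sim.sequence.save_tiff(p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()


class TestSurveyPhantom:
    def test_empty_specs(self, ):
        imaging = ImagingConfig(px_size=0.9, fps=1.0, frame_shape=(300, 300),
                                crop_window_um=(250.0, 250.0))
        img, truth = phantom.make_survey_phantom([], imaging, seed=0)
        assert truth.empty and img.shape == (300, 300)

    def test_truth_table_lists_requested_values(self):
        imaging = ImagingConfig(px_size=0.9, fps=1.0, frame_shape=(800, 800),
                                crop_window_um=(700.0, 700.0))
        img, truth = phantom.make_survey_phantom(
            [((360.0, 360.0), 2500.0, 7.0, 20.0)], imaging, seed=0)
        row = truth.iloc[0]
        assert row.area_um2 == 2500.0 and row.aspect_ratio == 7.0

    def test_deterministic_truth_and_image(self):
        imaging = ImagingConfig(px_size=0.9, fps=1.0, frame_shape=(500, 500),
                                crop_window_um=(400.0, 400.0))
        specs = [((120.0 + 200 * i, 150.0), 600.0 + 100 * i, 3.0, 15.0 * i)
                 for i in range(2)]
        img1, t1 = phantom.make_survey_phantom(specs, imaging, seed=8)
        img2, t2 = phantom.make_survey_phantom(specs, imaging, seed=8)
        np.testing.assert_array_equal(img1, img2)
        assert t1.equals(t2)

    def test_overlapping_specs_rejected(self):
        imaging = ImagingConfig(px_size=0.9, fps=1.0, frame_shape=(300, 300),
                                crop_window_um=(250.0, 250.0))
        specs = [((100.0, 100.0), 2000.0, 4.0, 0.0), ((110.0, 100.0), 2000.0, 4.0, 0.0)]
        with pytest.raises(ValueError, match="overlap"):
            phantom.make_survey_phantom(specs, imaging, seed=0)


def _zero_field(imaging):
    from cardiotfm.fields import DisplacementField, make_grid
    gx, gy = make_grid(imaging.extent_um, 5 * imaging.px_size)
    z = np.zeros((gy.size, gx.size))
    return DisplacementField(gx, gy, z, z.copy())
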