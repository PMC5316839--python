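"""Generator ground truth is self-consistent and statistically faithful."""

import math

import numpy as np
import pytest
from scipy import stats

from cortex_patterns import synthgen
from cortex_patterns.synthgen import (
    GeneratorConfig,
    gen_asterisk,
    gen_force_curves,
    gen_frap_series,
    gen_mesh,
    gen_random_network,
    gen_tracks,
    gen_vortex,
    hertz_force_nN,
    simulation_config,
)
from cortex_patterns._angles import wrap_orientation


class TestConfig:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(pixel_size_nm=0)
        with pytest.raises(ValueError):
            GeneratorConfig(psf_sigma_nm=-1)
        with pytest.raises(ValueError):
            GeneratorConfig(noise_sd=-0.1)

    @pytest.mark.parametrize(
        "gen",
        [
            lambda c: gen_vortex(c)[0].data,
            lambda c: gen_asterisk(c, "aster", 2400.0)[0].data,
            lambda c: gen_random_network(c)[0].data,
            lambda c: gen_mesh(c).data,
        ],
    )
    def test_same_seed_bit_identical(self, gen):
        cfg = GeneratorConfig(seed=7)
        assert np.array_equal(gen(cfg), gen(cfg))


class TestVortex:
    def test_zero_fibres_blank_image(self):
        cfg = GeneratorConfig(seed=0, noise_sd=0.0)
        img, truth = gen_vortex(cfg, n_fibres=0)
        assert np.allclose(img.data, cfg.background_level)
        assert truth.patterns[0].label == "vortex"
        assert truth.fibre_segments == []

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            gen_vortex(GeneratorConfig(), diameter_nm=0.0)

    def test_segment_angles_concentrate_at_plus_minus_pitch(self):
        """Brute-force histogram of drawn segments, relative to radial."""
        cfg = simulation_config(seed=3).replace(noise_sd=0.0, psf_sigma_nm=0.0)
        img, truth = gen_vortex(cfg, pitch_deg=45.0)
        rel = truth.segment_orientations_relative_deg(truth.patterns[0].centre_px)
        # each segment is a chord of the +-45-degree spiral
        assert np.all(np.abs(np.abs(rel) - 45.0) < 5.0)
        assert abs(np.mean(np.abs(rel)) - 45.0) < 2.0
        # both chiralities equally represented
        assert abs(np.mean(rel > 0) - 0.5) < 0.1

    def test_annulus_extent_matches_diameter(self):
        cfg = GeneratorConfig(seed=0, noise_sd=0.0, pixel_size_nm=30.0)
        img, truth = gen_vortex(cfg, diameter_nm=500.0, ring_thickness_nm=120.0)
        mask = img.data > cfg.background_level + 0.2
        rows, cols = np.nonzero(mask)
        extent_px = max(rows.max() - rows.min(), cols.max() - cols.min())
        # outer extent ~ diameter + thickness, i.e. about 500/30 ~ 17 px across
        assert 13 <= extent_px <= 25

    def test_segments_lie_within_pattern_span(self):
        cfg = simulation_config(seed=2)
        img, truth = gen_vortex(cfg)
        centre = np.array(truth.patterns[0].centre_px)
        pts = np.asarray(truth.fibre_segments).reshape(-1, 2)
        r_nm = np.hypot(*(pts - centre).T) * cfg.pixel_size_nm
        span_limit = truth.patterns[0].diameter_nm / 2 + 150.0 + 3 * cfg.psf_sigma_nm
        assert np.all(r_nm <= span_limit)


class TestAsterisk:
    def test_star_arm_angle_histogram_matches_truth(self):
        """Fold-and-count oracle: folded segment angles equal the arm angles."""
        angles = [0.0, 72.0, 144.0, -144.0, -72.0]
        cfg = GeneratorConfig(seed=1, noise_sd=0.0, image_size=(288, 288))
        img, truth = gen_asterisk(cfg, "star", 5000.0, n_arms=5, arm_angles=angles)
        seg = truth.segment_orientations_deg()
        folded = sorted(set(np.round(wrap_orientation(angles), 6)))
        assert sorted(np.unique(np.round(seg, 6))) == folded

    def test_truth_diameter_is_span(self):
        img, truth = gen_asterisk(GeneratorConfig(seed=0), "aster", 2400.0)
        assert truth.patterns[0].diameter_nm == 2400.0
        assert truth.patterns[0].diameter_nm < 3000.0  # below the aster boundary

    def test_arm_angle_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gen_asterisk(GeneratorConfig(), "star", 5000.0, n_arms=3, arm_angles=[0.0])

    def test_single_arm_renders_single_fibre(self):
        img, truth = gen_asterisk(GeneratorConfig(seed=0), "aster", 2400.0, n_arms=1)
        assert truth.patterns[0].arm_count == 1
        assert len(truth.fibre_segments) == 1


class TestRandomNetwork:
    def test_zero_density_background_only(self):
        cfg = GeneratorConfig(seed=0, noise_sd=0.0)
        img, truth = gen_random_network(cfg, segment_density=0.0)
        assert np.allclose(img.data, cfg.background_level)

    def test_segment_angles_uniform(self):
        cfg = GeneratorConfig(seed=5, image_size=(512, 512))
        img, truth = gen_random_network(cfg, segment_density=3.0)
        seg = truth.segment_orientations_deg()
        assert len(seg) >= 500
        stat = stats.kstest(seg, stats.uniform(loc=-90, scale=180).cdf)
        assert stat.pvalue > 0.01


class TestMesh:
    def test_grid_override_pore_count(self):
        from cortex_patterns.mesh import pore_size_distribution, segment_mesh

        cfg = GeneratorConfig(
            seed=0, noise_sd=0.0, background_level=0.0, pixel_size_nm=10.0,
            psf_sigma_nm=10.0, image_size=(400, 400),
        )
        img = gen_mesh(cfg, grid_cells=5, fibre_width_nm=20.0)
        pores = pore_size_distribution(segment_mesh(img), 10.0)
        assert len(pores) == 25

    def test_zero_intensity_single_pore_field(self):
        cfg = GeneratorConfig(seed=0, noise_sd=0.0, background_level=0.0)
        img = gen_mesh(cfg, line_intensity=0.0)
        assert img.data.max() == 0.0


class TestTracks:
    def test_immobilized_tracks_pin_to_centre(self):
        ts = gen_tracks(GeneratorConfig(seed=0), "immobilized", n_tracks=5)
        for tr in ts.tracks:
            assert np.all(tr.positions_nm == np.array(ts.centre_nm))
            assert tr.times_s[-1] == ts.movie_length_s

    def test_mobile_median_distance_converges_to_R_over_sqrt2(self):
        R = 495.0
        ts = gen_tracks(
            GeneratorConfig(seed=2), "mobile", n_tracks=400, core_radius_nm=R,
            dwell_mean_s=40.0,
        )
        d = np.concatenate(
            [np.hypot(*(tr.positions_nm - np.array(ts.centre_nm)).T) for tr in ts.tracks]
        )
        assert d.size >= 1e4 / 4  # plenty of samples
        assert abs(np.median(d) - R / math.sqrt(2)) / (R / math.sqrt(2)) < 0.03

    def test_mobile_dwell_mean_within_ci(self):
        ts = gen_tracks(GeneratorConfig(seed=3), "mobile", n_tracks=1000, dwell_mean_s=20.0)
        dwells = ts.true_dwells_s
        se = np.std(dwells) / math.sqrt(len(dwells))
        assert abs(np.mean(dwells) - 20.0) < 1.96 * se + 1e-9

    def test_invalid_dwell_rejected(self):
        with pytest.raises(ValueError):
            gen_tracks(GeneratorConfig(), "mobile", dwell_mean_s=0.0)


class TestFrap:
    def test_prebleach_frames_at_unit_intensity(self):
        s = gen_frap_series(GeneratorConfig(seed=0, noise_sd=0.0))
        assert np.allclose(s.frames[: s.n_prebleach], 1.0)

    def test_front_advances_v_over_pixel_per_frame(self):
        """58 nm/s at 29-nm pixels and 1-s frames is 2 px per frame."""
        s = gen_frap_series(
            GeneratorConfig(seed=0, noise_sd=0.0), v_truth_nm_s=58.0, bleach_depth=1.0
        )
        profiles = s.line_profiles()  # (pos, t)
        b0 = s.bleach_roi[1]
        fronts = []
        for f in range(s.n_prebleach, s.n_prebleach + 8):
            col = profiles[:, f]
            below = np.nonzero(col[b0:] < 0.5)[0]
            i = b0 + below[0]
            frac = (col[i - 1] - 0.5) / (col[i - 1] - col[i])
            fronts.append(i - 1 + frac)
        slopes = np.diff(fronts)
        assert abs(np.mean(slopes) - 2.0) < 0.2

    def test_zero_velocity_front_is_static(self):
        s = gen_frap_series(GeneratorConfig(seed=0, noise_sd=0.0), v_truth_nm_s=0.0)
        profiles = s.line_profiles()
        post = profiles[:, s.n_prebleach :]
        assert np.allclose(post[:, 0], post[:, -1], atol=1e-9)


class TestForceCurves:
    def test_zero_depth_zero_force(self):
        assert hertz_force_nN(0.0, 1500.0, "sphere") == 0.0

    def test_pyramid_formula_hand_value(self):
        """F = 0.7453 * E' * tan(theta) * d^2 with E' = 2000 Pa, d = 500 nm."""
        e_eff = 2000.0
        expected = 0.7453 * e_eff * math.tan(math.radians(20.0)) * (500e-9) ** 2 * 1e9
        got = hertz_force_nN(
            500.0, e_eff * (1 - 0.5**2), "pyramid", poisson_ratio=0.5, half_angle_deg=20.0
        )
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.136, abs=0.001)

    def test_curve_obeys_model_beyond_contact(self):
        fs = gen_force_curves(GeneratorConfig(seed=0), 1500.0, "sphere", contact_z_nm=500.0)
        c = fs.curves[0]
        u = np.maximum(c.z_nm - 500.0, 0.0)
        depth = u - c.deflection_nm
        expected = hertz_force_nN(depth, 1500.0, "sphere", bead_radius_nm=5000.0)
        assert np.allclose(c.force_nN, expected, atol=1e-10)

    def test_pre_contact_baseline_zero(self):
        fs = gen_force_curves(GeneratorConfig(seed=0), 1500.0, "pyramid", contact_z_nm=400.0)
        c = fs.curves[0]
        assert np.all(c.deflection_nm[c.z_nm < 400.0] == 0.0)
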