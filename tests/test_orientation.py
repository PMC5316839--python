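"""Structure-tensor orientations, signatures and peak detection."""

import numpy as np
import pytest
from skimage.transform import rotate

from cortex_patterns import (
    histogram_peaks,
    modal_angle,
    orientation_histogram,
    structure_tensor_field,
)
from cortex_patterns._angles import angular_difference_deg, wrap_orientation
from cortex_patterns.image import Image
from cortex_patterns.orientation import OrientationHistogram
from cortex_patterns.synthgen import GeneratorConfig, gen_random_network, simulation_config


def grating(angle_deg: float, shape=(128, 128), period_px: float = 8.0) -> Image:
    """Sinusoidal stripes whose crests run along ``angle_deg``."""
    rows, cols = np.mgrid[: shape[0], : shape[1]]
    x, y = cols, -rows
    th = np.radians(angle_deg)
    phase = (-np.sin(th) * x + np.cos(th) * y) * 2 * np.pi / period_px
    return Image(0.5 + 0.5 * np.sin(phase), pixel_size_nm=29.0)


class TestStructureTensor:
    def test_horizontal_stripes_give_zero_angle(self):
        field = structure_tensor_field(grating(0.0))
        hist = orientation_histogram(field, coherence_min=0.5)
        # 0 degrees sits on a bin edge; the mode can be off by half a 2-degree bin
        assert abs(modal_angle(hist)) <= 1.0

    @pytest.mark.parametrize("angle", [30.0, -30.0, 60.0])
    def test_rotated_grating_angle(self, angle):
        field = structure_tensor_field(grating(angle))
        hist = orientation_histogram(field, coherence_min=0.5)
        assert angular_difference_deg(modal_angle(hist), angle) < 1.0

    def test_uniform_image_has_zero_coherence(self):
        field = structure_tensor_field(Image(np.full((32, 32), 0.7), 29.0))
        assert np.all(field.coherence == 0.0)
        assert np.all(np.isnan(field.angle_deg))

    def test_tiny_image_rejected(self):
        with pytest.raises(ValueError):
            structure_tensor_field(Image(np.zeros((2, 5)), 29.0))

    @pytest.mark.parametrize("phi", [15.0, 30.0, 60.0])
    def test_rotation_equivariance(self, phi):
        """Rotating the image by phi shifts the modal orientation by phi."""
        base = grating(10.0, shape=(160, 160))
        rotated = Image(rotate(base.data, phi, mode="reflect"), base.pixel_size_nm)
        interior = np.zeros(rotated.shape, dtype=bool)
        interior[40:-40, 40:-40] = True  # rotation distorts the frame edges
        m0 = modal_angle(
            orientation_histogram(structure_tensor_field(base), coherence_min=0.5)
        )
        m1 = modal_angle(
            orientation_histogram(
                structure_tensor_field(rotated), mask=interior, coherence_min=0.5
            )
        )
        assert angular_difference_deg(m1, m0 + phi) < 2.0


class TestHistogram:
    def test_probabilities_sum_to_one_regardless_of_binning_and_mask(self):
        field = structure_tensor_field(grating(25.0))
        for n_bins in (8, 45, 90, 180):
            hist = orientation_histogram(field, n_bins=n_bins)
            assert np.sum(hist.probabilities) == pytest.approx(1.0, abs=1e-9)
        half = np.zeros(field.angle_deg.shape, dtype=bool)
        half[:, :64] = True
        hist = orientation_histogram(field, mask=half)
        assert np.sum(hist.probabilities) == pytest.approx(1.0, abs=1e-9)

    def test_single_angle_occupies_one_bin(self):
        field = structure_tensor_field(grating(40.0))
        hist = orientation_histogram(field, n_bins=18, coherence_min=0.5)
        assert hist.probabilities.max() > 0.9

    def test_empty_selection_raises(self):
        field = structure_tensor_field(Image(np.full((32, 32), 1.0), 29.0))
        with pytest.raises(ValueError):
            orientation_histogram(field)

    def test_radial_requires_centre(self):
        field = structure_tensor_field(grating(0.0))
        with pytest.raises(ValueError):
            orientation_histogram(field, convention="radial")

    def test_annulus_radial_convention_masses_at_ninety(self):
        """A thin ring's tangents are perpendicular to the radius."""
        rows, cols = np.mgrid[:160, :160]
        r = np.hypot(rows - 79.5, cols - 79.5)
        ring = np.exp(-((r - 45.0) ** 2) / (2 * 2.0**2))
        field = structure_tensor_field(Image(ring, 29.0))
        hist = orientation_histogram(
            field, convention="radial", centre=(79.5, 79.5), coherence_min=0.5
        )
        centres = hist.bin_centres
        edge = np.abs(centres) > 80.0
        assert hist.probabilities[edge].sum() > 0.9

    def test_random_network_histogram_uniform(self):
        """Max deviation from 1/n within 3 s.d. of the multinomial."""
        cfg = GeneratorConfig(seed=11, image_size=(512, 512))
        img, truth = gen_random_network(cfg, segment_density=3.0)
        field = structure_tensor_field(img)
        n_bins = 18
        hist = orientation_histogram(field, n_bins=n_bins, coherence_min=0.5)
        sel = np.isfinite(field.angle_deg) & (field.coherence > 0.5)
        # pixels on one fibre are correlated; count segments, not pixels
        n_eff = len(truth.fibre_segments)
        sd = np.sqrt((1 / n_bins) * (1 - 1 / n_bins) / n_eff)
        assert np.max(np.abs(hist.probabilities - 1 / n_bins)) < 3 * sd


class TestPeaks:
    def test_uniform_histogram_has_no_peaks(self):
        hist = OrientationHistogram(
            bin_edges=np.linspace(-90, 90, 91),
            probabilities=np.full(90, 1 / 90),
            convention="absolute",
        )
        assert histogram_peaks(hist) == []

    def test_five_arm_star_peaks_match_folded_arm_angles(self):
        from cortex_patterns.synthgen import gen_asterisk

        angles = [0.0, 72.0, 144.0, -144.0, -72.0]
        cfg = GeneratorConfig(seed=1, noise_sd=0.01, image_size=(288, 288))
        img, truth = gen_asterisk(cfg, "star", 5000.0, n_arms=5, arm_angles=angles)
        field = structure_tensor_field(img)
        hist = orientation_histogram(field, coherence_min=0.5)
        peaks = histogram_peaks(hist, min_prominence=0.02)
        expected = sorted(wrap_orientation(angles))
        got = sorted(a for a, _ in peaks[:5])
        assert len(got) == 5
        for e, g in zip(expected, got):
            assert angular_difference_deg(e, g) <= 2.5  # within one 2-degree bin

    def test_vortex_signature_two_peaks_at_45(self, sim_vortex):
        img, truth = sim_vortex
        centre = truth.patterns[0].centre_px
        field = structure_tensor_field(img)
        h, w = img.shape
        rr = np.arange(h)[:, None] - centre[0]
        cc = np.arange(w)[None, :] - centre[1]
        mask = rr**2 + cc**2 <= (450.0 / img.pixel_size_nm) ** 2
        hist = orientation_histogram(field, mask=mask, convention="radial", centre=centre)
        peaks = histogram_peaks(hist)
        assert len(peaks) == 2
        angles = sorted(a for a, _ in peaks)
        assert angles[0] == pytest.approx(-45.0, abs=3.0)
        assert angles[1] == pytest.approx(45.0, abs=3.0)


class TestSegmentOracle:
    def test_histogram_matches_true_segment_angles(self):
        """Earth-mover distance to the drawn-segment histogram under 5 degrees."""
        cfg = simulation_config(seed=9).replace(image_size=(512, 512))
        img, truth = gen_random_network(cfg, segment_density=8.0, segment_length_nm=400.0)
        field = structure_tensor_field(img)
        n_bins = 36
        hist = orientation_histogram(field, n_bins=n_bins, coherence_min=0.5)
        seg_counts, _ = np.histogram(
            truth.segment_orientations_deg(), bins=np.linspace(-90, 90, n_bins + 1)
        )
        seg_probs = seg_counts / seg_counts.sum()
        bin_width = 180.0 / n_bins
        emd_deg = np.sum(np.abs(np.cumsum(hist.probabilities - seg_probs))) * bin_width
        assert emd_deg < 5.0
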