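"""Local fibre orientation by structure tensor, and orientation signatures.

The local orientation at each pixel is taken from the structure tensor: the
Gaussian-windowed outer product of the intensity gradient.  Its minor
eigenvector points along the fibres; the normalized eigenvalue anisotropy
(coherence) says how reliable that direction is.  Binning the per-pixel
angles of a pattern gives its orientation signature:

* a vortex, read relative to the radial direction from its centre, shows two
  bell-shaped peaks at +-45 degrees (spiralling fibres of both chiralities);
* a star shows a few distinct peaks (one per bundled arm direction);
* an aster shows a series of many peaks;
* a random network is flat.

Angles are degrees in [-90, 90), counterclockwise from the image x-axis
(columns) with y up; see :mod:`cortex_patterns._angles`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from skimage.feature import structure_tensor

from ._angles import radial_bearing_deg, wrap_orientation
from .image import Image

__all__ = [
    "OrientationField",
    "OrientationHistogram",
    "structure_tensor_field",
    "orientation_histogram",
    "histogram_peaks",
    "modal_angle",
]

DEFAULT_N_BINS = 90  # 2-degree bins
DEFAULT_COHERENCE_MIN = 0.2
DEFAULT_WINDOW_SIGMA = 2.0  # px


@dataclass
class OrientationField:
    """Per-pixel fibre angle (degrees, [-90, 90); NaN where undefined) and coherence."""

    angle_deg: np.ndarray
    coherence: np.ndarray
    window_sigma: float

    def __post_init__(self) -> None:
        if self.angle_deg.shape != self.coherence.shape:
            raise ValueError("angle and coherence must have equal shape")


@dataclass
class OrientationHistogram:
    """Normalized angular frequency distribution over [-90, 90)."""

    bin_edges: np.ndarray  # length n_bins + 1, spanning [-90, 90]
    probabilities: np.ndarray
    convention: str  # absolute | radial
    reference_centre: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if len(self.bin_edges) != len(self.probabilities) + 1:
            raise ValueError("bin_edges must have one more entry than probabilities")
        if abs(float(np.sum(self.probabilities)) - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def structure_tensor_field(image: Image, window_sigma: float = DEFAULT_WINDOW_SIGMA) -> OrientationField:
    """Per-pixel dominant orientation and coherence from the structure tensor.

    The tensor is the gradient outer product smoothed with a Gaussian window
    of ``window_sigma`` pixels.  The returned angle is the direction of the
    tensor's minor eigenvector (along the structure, perpendicular to the
    mean gradient) mapped to [-90, 90); coherence is
    (lambda1 - lambda2) / (lambda1 + lambda2) in [0, 1], zero on constant
    regions, where the angle is NaN.
    """
    if not window_sigma > 0:
        raise ValueError("window_sigma must be positive")
    data = image.data
    if data.shape[0] < 3 or data.shape[1] < 3:
        raise ValueError("image must be at least 3x3 pixels")
    # nearest-edge padding: constant padding would fabricate strong border edges
    Arr, Arc, Acc = structure_tensor(data, sigma=window_sigma, mode="nearest", order="rc")
    # cartesian components with y pointing up: gx = d/dcol, gy = -d/drow
    jxx, jyy, jxy = Acc, Arr, -Arc
    trace = jxx + jyy
    aniso = np.sqrt((jxx - jyy) ** 2 + 4.0 * jxy**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        coherence = np.where(trace > 0, aniso / trace, 0.0)
    # the floor guards against floating-point residue in flat regions, which
    # is tiny but can be perfectly anisotropic
    scale = float(trace.max())
    defined = trace > (1e-6 * scale if scale > 0 else np.inf)
    coherence = np.where(defined, coherence, 0.0)
    # major eigenvector of the gradient tensor points across the structure;
    # rotate by 90 degrees to get the fibre direction
    grad_angle = 0.5 * np.degrees(np.arctan2(2.0 * jxy, jxx - jyy))
    angle = wrap_orientation(grad_angle + 90.0)
    angle = np.where(defined, angle, np.nan)
    return OrientationField(angle_deg=angle, coherence=coherence, window_sigma=window_sigma)


def orientation_histogram(
    field: OrientationField,
    mask: np.ndarray | None = None,
    convention: str = "absolute",
    centre: tuple[float, float] | None = None,
    n_bins: int = DEFAULT_N_BINS,
    coherence_min: float = DEFAULT_COHERENCE_MIN,
) -> OrientationHistogram:
    """Probability histogram of per-pixel orientations.

    Pixels count equally; pixels outside ``mask``, below ``coherence_min``
    or with undefined angle are dropped.  In the ``radial`` convention the
    local radial bearing from ``centre`` (row, col) is subtracted from each
    pixel's angle before binning, wrapping into [-90, 90) - the convention
    under which a vortex yields its +-45 degree twin peaks.
    """
    if n_bins < 8:
        raise ValueError("n_bins must be >= 8")
    if convention not in {"absolute", "radial"}:
        raise ValueError("convention must be 'absolute' or 'radial'")
    if convention == "radial" and centre is None:
        raise ValueError("radial convention requires a centre")
    select = np.isfinite(field.angle_deg) & (field.coherence > coherence_min)
    if mask is not None:
        select &= np.asarray(mask, dtype=bool)
    if not np.any(select):
        raise ValueError("no pixels pass the mask and coherence threshold")
    angles = field.angle_deg[select]
    if convention == "radial":
        rows, cols = np.nonzero(select)
        bearing = radial_bearing_deg(rows, cols, centre)
        angles = wrap_orientation(angles - bearing)
    edges = np.linspace(-90.0, 90.0, n_bins + 1)
    counts, _ = np.histogram(angles, bins=edges)
    probs = counts / counts.sum()
    return OrientationHistogram(
        bin_edges=edges,
        probabilities=probs,
        convention=convention,
        reference_centre=tuple(centre) if centre is not None else None,
    )


def _parabolic_refine(y_prev: float, y0: float, y_next: float) -> float:
    """Sub-bin offset of a parabola through three equally spaced samples."""
    denom = y_prev - 2 * y0 + y_next
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (y_prev - y_next) / denom, -0.5, 0.5))


def histogram_peaks(
    hist: OrientationHistogram, min_prominence: float = 0.01
) -> list[tuple[float, float]]:
    """Local maxima of the angular histogram, with wrap-around at +-90.

    Returns ``(angle_deg, height)`` pairs sorted by height descending; peak
    angles are parabolically refined to sub-bin precision.  Prominence is in
    probability mass per bin.
    """
    if not min_prominence > 0:
        raise ValueError("min_prominence must be positive")
    p = hist.probabilities
    n = len(p)
    tiled = np.concatenate([p, p, p])
    idx, props = find_peaks(tiled, prominence=min_prominence)
    centres = hist.bin_centres
    width = hist.bin_width
    peaks = []
    for i, prom in zip(idx, props["prominences"]):
        if n <= i < 2 * n:  # keep the middle copy only
            j = i - n
            offset = _parabolic_refine(tiled[i - 1], tiled[i], tiled[i + 1])
            angle = wrap_orientation(centres[j] + offset * width)
            peaks.append((float(angle), float(p[j])))
    peaks.sort(key=lambda ah: -ah[1])
    return peaks


def modal_angle(hist: OrientationHistogram, window_bins: int = 2) -> float:
    """Angle of the histogram's mode.

    Refined by the probability-weighted axial mean over ``window_bins``
    neighbouring bins on each side of the highest bin, which removes the
    half-bin quantization when the true mode falls on a bin edge.
    """
    p = hist.probabilities
    n = len(p)
    j = int(np.argmax(p))
    ks = np.arange(-window_bins, window_bins + 1)
    angles = np.radians((hist.bin_centres[j] + ks * hist.bin_width) * 2.0)
    weights = p[(j + ks) % n]
    mean2 = np.arctan2(np.sum(weights * np.sin(angles)), np.sum(weights * np.cos(angles)))
    return float(wrap_orientation(np.degrees(mean2) / 2.0))
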