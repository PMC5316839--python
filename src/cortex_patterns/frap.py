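"""FRAP analysis: normalization, kymographs, iso-kymographs and front velocities.

A line region of interest (lnROI) is laid along an actin fibre; after a
photobleach pulse, the fluorescence along the line recovers as new monomers
are incorporated.  If filaments grow from one end, the recovery advances as
a front and the iso-intensity contours in (line position, time) space are
slanted lines whose slope is the regrowth velocity v_growth; homogeneous
recovery (no filament polarity, as in stress fibres) gives straight
position-independent contours.  Dividing v_growth by the 2.7-nm size of an
actin monomer converts the velocity into monomers added per second.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from matplotlib import colormaps
from skimage import measure

__all__ = [
    "FrapSeries",
    "KymographMatrix",
    "FrapResult",
    "normalize_recovery",
    "kymograph",
    "recovery_fraction",
    "iso_kymograph",
    "fit_growth_velocity",
    "monomer_rate",
    "temporal_projection",
    "ACTIN_MONOMER_NM",
]

ACTIN_MONOMER_NM = 2.7


@dataclass
class FrapSeries:
    """A FRAP time-lapse plus its measurement geometry.

    ``frames`` is a (t, rows, cols) stack; ``ln_roi`` the ordered pixel
    path of the measurement line; ``bleach_roi`` / ``reference_roi`` are
    (r0, c0, r1, c1) half-open rectangles.  At least two pre-bleach frames
    are required - they define the normalization.
    """

    frames: np.ndarray
    times_s: np.ndarray
    ln_roi: list[tuple[int, int]]
    bleach_roi: tuple[int, int, int, int]
    n_prebleach: int
    reference_roi: tuple[int, int, int, int] | None = None
    pixel_size_nm: float = 29.0
    normalized: bool = False
    bleach_corrected: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (t, rows, cols) stack")
        if self.n_prebleach < 2:
            raise ValueError("need at least two pre-bleach frames")
        h, w = self.frames.shape[1:]
        for r, c in self.ln_roi:
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError("ln_roi must lie within the image bounds")

    @property
    def frame_interval_s(self) -> float:
        return float(np.median(np.diff(self.times_s)))

    def line_profiles(self) -> np.ndarray:
        """(|ln_roi|, n_frames) intensity matrix along the line."""
        rows = np.array([p[0] for p in self.ln_roi])
        cols = np.array([p[1] for p in self.ln_roi])
        return self.frames[:, rows, cols].T


@dataclass
class KymographMatrix:
    """Intensity along the lnROI (rows) over time (columns)."""

    values: np.ndarray
    pixel_size_nm: float
    frame_interval_s: float
    times_s: np.ndarray
    normalized: bool
    n_prebleach: int
    bleach_rows: tuple[int, int]  # half-open row range of the bleach region on the line


@dataclass
class FrapResult:
    """Fitted regrowth velocities and the derived monomer rate."""

    velocities_nm_s: tuple[float, ...]
    directionality: str  # one_end | both_ends | homogeneous
    monomer_rate_s: float
    monomer_size_nm: float = ACTIN_MONOMER_NM

    @property
    def v_growth_nm_s(self) -> float:
        return float(np.mean(self.velocities_nm_s)) if self.velocities_nm_s else 0.0


def _roi_mean(frames: np.ndarray, roi) -> np.ndarray:
    r0, c0, r1, c1 = roi
    return frames[:, r0:r1, c0:c1].mean(axis=(1, 2))


def normalize_recovery(series: FrapSeries) -> FrapSeries:
    """Normalize by the per-pixel pre-bleach mean, optionally bleach-corrected.

    Every pixel is divided by its mean over the pre-bleach frames, so the
    pre-bleach signal is 1 by construction.  If a reference region is
    present, each frame is additionally divided by the reference's
    frame-wise mean (itself pre-bleach-normalized), correcting the slow
    observational photobleaching of the whole field.  Normalizing twice is
    a no-op.
    """
    if series.normalized:
        return series
    pre = series.frames[: series.n_prebleach].mean(axis=0)
    rows = np.array([p[0] for p in series.ln_roi])
    cols = np.array([p[1] for p in series.ln_roi])
    if np.any(pre[rows, cols] <= 0):
        raise ValueError("zero pre-bleach mean on the measurement line")
    safe = np.where(pre > 0, pre, 1.0)
    frames = series.frames / safe
    corrected = False
    if series.reference_roi is not None:
        ref = _roi_mean(frames, series.reference_roi)
        ref_pre = ref[: series.n_prebleach].mean()
        if ref_pre > 0:
            frames = frames / (ref / ref_pre)[:, None, None]
            corrected = True
    return replace(series, frames=frames, normalized=True, bleach_corrected=corrected)


def kymograph(series: FrapSeries) -> KymographMatrix:
    """Classic kymograph: column t holds the lnROI intensity profile at frame t."""
    if not series.normalized:
        series = normalize_recovery(series)
    values = series.line_profiles()
    r0, c0, r1, c1 = series.bleach_roi
    on_line = [
        i for i, (r, c) in enumerate(series.ln_roi) if r0 <= r < r1 and c0 <= c < c1
    ]
    bleach_rows = (min(on_line), max(on_line) + 1) if on_line else (0, values.shape[0])
    return KymographMatrix(
        values=values,
        pixel_size_nm=series.pixel_size_nm,
        frame_interval_s=series.frame_interval_s,
        times_s=series.times_s.copy(),
        normalized=series.normalized,
        n_prebleach=series.n_prebleach,
        bleach_rows=bleach_rows,
    )


def recovery_fraction(kymo: KymographMatrix) -> np.ndarray:
    """Per-pixel recovered fraction (I(t) - I_post) / (I_pre - I_post).

    I_pre is the pre-bleach level (1 after normalization) and I_post the
    first post-bleach frame, both per line pixel; only post-bleach columns
    are returned.
    """
    post = kymo.values[:, kymo.n_prebleach :]
    i_pre = kymo.values[:, : kymo.n_prebleach].mean(axis=1)
    i_post = post[:, 0]
    depth = i_pre - i_post
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = (post - i_post[:, None]) / depth[:, None]
    frac[depth < 0.05, :] = np.nan  # pixels that were never meaningfully bleached
    return np.clip(frac, 0.0, 1.5)


def iso_kymograph(
    kymo: KymographMatrix, levels=tuple(np.round(np.linspace(0.1, 0.9, 9), 3))
) -> dict[float, list[np.ndarray]]:
    """Iso-recovery contours in (line position, time) space.

    For each level in (0, 1), returns the contour polylines of the recovery
    fraction as arrays of (position_px, time_index) rows; levels outside the
    data range yield empty lists.
    """
    if not kymo.normalized:
        raise ValueError("iso-kymograph requires a normalized kymograph")
    frac = recovery_fraction(kymo)
    filled = np.where(np.isnan(frac), 1.0, frac)  # unbleached pixels count as recovered
    contours: dict[float, list[np.ndarray]] = {}
    for level in levels:
        if not 0 < level < 1:
            raise ValueError("contour levels must lie in (0, 1)")
        contours[float(level)] = [
            np.asarray(c) for c in measure.find_contours(filled, level)
        ]
    return contours


def _contour_runs(
    poly: np.ndarray, bleach_rows: tuple[int, int] | None, margin: float = 1.5
) -> list[np.ndarray]:
    """Break a closed contour into fittable open runs.

    ``find_contours`` returns closed curves around the unrecovered region;
    besides the moving front(s) these hug the bleach-region edges and the
    first post-bleach column, which carry no velocity information.  Points
    within ``margin`` pixels of the bleach edges or in the first post-bleach
    column are discarded and the survivors split into contiguous runs.
    """
    keep = poly[:, 1] > 0.5
    if bleach_rows is not None:
        lo, hi = bleach_rows
        keep &= (poly[:, 0] > lo + margin) & (poly[:, 0] < hi - 1 - margin)
    runs: list[np.ndarray] = []
    start = None
    for i, k in enumerate(keep):
        if k and start is None:
            start = i
        elif not k and start is not None:
            runs.append(poly[start:i])
            start = None
    if start is not None:
        runs.append(poly[start:])
    return [r for r in runs if len(r) >= 3]


def fit_growth_velocity(
    contours: dict[float, list[np.ndarray]],
    pixel_size_nm: float,
    frame_interval_s: float,
    bleach_rows: tuple[int, int] | None = None,
) -> FrapResult:
    """Least-squares line fits through iso-contour branches; v = |slope| * px / dt.

    Each contour branch contributes one velocity via the slope of its
    position-versus-time regression; branches with fewer than 3 points are
    skipped.  Branches that span positions at an essentially constant time
    are iso-time contours - the signature of homogeneous (polarity-free)
    recovery - and vote for directionality "homogeneous" with v = 0.
    Fronts on either side of the bleach midpoint are reported separately,
    so recovery from both ends yields two velocities.
    """
    all_polys = [c for polys in contours.values() for c in polys if len(c) >= 3]
    if not all_polys:
        raise ValueError("no usable contours to fit")
    mid = 0.5 * (bleach_rows[0] + bleach_rows[1]) if bleach_rows is not None else None
    slopes_lo: list[float] = []
    slopes_hi: list[float] = []
    n_iso_time = 0
    n_front = 0
    for poly in all_polys:
        for run in _contour_runs(poly, bleach_rows):
            # split at the bleach midpoint: converging fronts otherwise merge
            # into one Lambda-shaped branch with a meaningless joint slope
            if mid is not None:
                side = run[:, 0] >= mid
                cuts = [0] + [i for i in range(1, len(run)) if side[i] != side[i - 1]] + [len(run)]
                branches = [run[a:b] for a, b in zip(cuts[:-1], cuts[1:]) if b - a >= 3]
            else:
                branches = [run]
            for br in branches:
                pos, t = br[:, 0], br[:, 1]
                if np.ptp(t) < 1.0:
                    if np.ptp(pos) > 3.0:
                        n_iso_time += 1  # spans the line at one time: homogeneous
                    continue
                n_front += 1
                slope = float(np.polyfit(t, pos, 1)[0])
                side_hi = mid is not None and float(np.mean(pos)) >= mid
                (slopes_hi if side_hi else slopes_lo).append(slope)
    if n_iso_time > n_front:
        return FrapResult(
            velocities_nm_s=(0.0,), directionality="homogeneous", monomer_rate_s=0.0
        )
    if not (slopes_lo or slopes_hi):
        # contours exist but all hug the bleach edges: nothing ever moved
        return FrapResult(
            velocities_nm_s=(0.0,), directionality="homogeneous", monomer_rate_s=0.0
        )
    scale = pixel_size_nm / frame_interval_s
    med_lo = float(np.median(slopes_lo)) if slopes_lo else None
    med_hi = float(np.median(slopes_hi)) if slopes_hi else None
    moving = [m for m in (med_lo, med_hi) if m is not None]
    if max(abs(m) for m in moving) < 0.15:
        # contours drift by well under a pixel per frame: no moving front
        return FrapResult(
            velocities_nm_s=(0.0,), directionality="homogeneous", monomer_rate_s=0.0
        )
    if med_lo is not None and med_hi is not None and med_lo * med_hi < 0:
        # fronts converging from opposite ends move with opposite slopes
        velocities = [abs(med_lo) * scale, abs(med_hi) * scale]
        directionality = "both_ends"
    else:
        velocities = [abs(float(np.median(slopes_lo + slopes_hi))) * scale]
        directionality = "one_end"
    v_mean = float(np.mean(velocities))
    return FrapResult(
        velocities_nm_s=tuple(velocities),
        directionality=directionality,
        monomer_rate_s=monomer_rate(v_mean),
    )


def monomer_rate(v_growth_nm_s: float, monomer_size_nm: float = ACTIN_MONOMER_NM) -> float:
    """Monomers incorporated per second: v_growth / monomer size (2.7 nm)."""
    if not monomer_size_nm > 0:
        raise ValueError("monomer_size_nm must be positive")
    return v_growth_nm_s / monomer_size_nm


def temporal_projection(
    stack: np.ndarray, immobile_fraction: float = 0.8, bright_level: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Colour-coded time projection of a movie plus an immobility mask.

    Each pixel is coloured by the time of its maximum intensity (cold/blue
    early, warm/red late) and weighted by its peak brightness.  Pixels that
    stay bright (above ``bright_level`` of the stack maximum) in at least
    ``immobile_fraction`` of the frames are immobile structures and are
    rendered white.  Returns (RGB float image, immobile boolean mask).
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a (t, rows, cols) stack with at least 2 frames")
    n_frames = stack.shape[0]
    peak = float(stack.max())
    if peak <= 0:
        return np.zeros(stack.shape[1:] + (3,)), np.zeros(stack.shape[1:], dtype=bool)
    t_max = np.argmax(stack, axis=0)
    amp = stack.max(axis=0) / peak
    cmap = colormaps["jet"]
    rgb = cmap(t_max / max(n_frames - 1, 1))[..., :3] * amp[..., None]
    immobile = (stack > bright_level * peak).mean(axis=0) >= immobile_fraction
    rgb[immobile] = 1.0
    return rgb, immobile
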