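"""Synthetic data generator for every analysis stage in the package.

The cortical-actin analyses in this package (orientation signatures, pattern
morphometrics, mesh pore sizes, particle-track statistics, FRAP fronts, AFM
force curves) were designed for microscope data that cannot ship with the
code.  This module produces synthetic stand-ins with recorded ground truth:

* fluorescence-like images of actin **vortices** (rings of spiralling fibres,
  ~500 nm across), **stars** (few bundled arms, ~5 um end-to-end), **asters**
  (many single-fibre arms, ~2.4 um) and **random networks**;
* binary-contrast fibre **meshes** (Poisson line process) for the pore-size
  pipeline;
* particle **tracks** in a mobile (core-confined) and an immobilized regime;
* **FRAP** line series with a recovery front advancing at a known velocity;
* Hertzian AFM **force curves** with known modulus and contact point.

Every generator takes a :class:`GeneratorConfig` carrying the imaging
parameters and a seed; identical configuration yields bit-identical output.
Default optics emulate a high-NA TIRF-SIM system: 29-nm pixels and a 38-nm
Gaussian PSF sigma (about 90 nm FWHM lateral resolution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import line_aa

from ._angles import segment_orientation_deg, wrap_orientation
from .afm import ForceCurve
from .frap import FrapSeries
from .image import Image
from .tracks import Track

__all__ = [
    "GeneratorConfig",
    "PatternTruth",
    "SceneTruth",
    "TrackSet",
    "ForceCurveSet",
    "gen_vortex",
    "gen_asterisk",
    "gen_random_network",
    "gen_mesh",
    "gen_tracks",
    "gen_frap_series",
    "gen_force_curves",
    "hertz_force_nN",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Imaging and noise parameters shared by the image generators.

    Attributes
    ----------
    image_size
        (rows, cols) of the rendered field.
    pixel_size_nm
        Physical pixel edge, nm. Default 29 nm (TIRF-SIM raster).
    psf_sigma_nm
        Sigma of the Gaussian blur emulating the optical PSF, nm.
        Default 38 nm, i.e. ~90 nm FWHM.
    background_level
        Constant background as a fraction of the peak signal.
    noise_sd
        Gaussian intensity noise s.d. as a fraction of the peak signal.
    seed
        Seed for the generator's private RNG.
    """

    image_size: tuple[int, int] = (256, 256)
    pixel_size_nm: float = 29.0
    psf_sigma_nm: float = 38.0
    background_level: float = 0.05
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.psf_sigma_nm < 0:
            raise ValueError("psf_sigma_nm must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.background_level < 0:
            raise ValueError("background_level must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def replace(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


def simulation_config(seed: int = 0) -> GeneratorConfig:
    """Rendering for pattern-geometry simulations (as opposed to instrument emulation).

    Orientation-signature simulations need individual fibres resolved -
    notably inside a 500-nm vortex, whose spiralling fibre texture sits below
    the optical resolution of the default instrument raster.  This profile
    renders the same scale-free geometry on a 4-nm grid with a short 6-nm
    blur and low noise, the synthetic analogue of plotting the simulated
    geometry directly.
    """
    return GeneratorConfig(
        image_size=(224, 224),
        pixel_size_nm=4.0,
        psf_sigma_nm=6.0,
        background_level=0.02,
        noise_sd=0.01,
        seed=seed,
    )


@dataclass
class PatternTruth:
    """Ground truth for one generated pattern."""

    label: str  # vortex | star | aster | random
    centre_px: tuple[float, float]  # (row, col)
    diameter_nm: float
    arm_angles_deg: tuple[float, ...] = ()  # full-circle degrees in [-180, 180)
    arm_count: int = 0

    def __post_init__(self) -> None:
        if self.label not in {"vortex", "star", "aster", "random"}:
            raise ValueError(f"unknown pattern label {self.label!r}")
        if not self.diameter_nm >= 0:
            raise ValueError("diameter_nm must be >= 0")
        for a in self.arm_angles_deg:
            if not -180.0 <= a < 180.0:
                raise ValueError("arm angles must lie in [-180, 180)")


@dataclass
class SceneTruth:
    """Ground truth for a rendered scene: pattern entries plus every drawn segment."""

    patterns: list[PatternTruth] = field(default_factory=list)
    fibre_segments: list[tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=list
    )

    def segment_orientations_deg(self) -> np.ndarray:
        """Axial orientation of each drawn segment, degrees in [-90, 90)."""
        if not self.fibre_segments:
            return np.empty(0)
        seg = np.asarray(self.fibre_segments, dtype=float)  # (n, 2, 2)
        return segment_orientation_deg(seg[:, 0, 0], seg[:, 0, 1], seg[:, 1, 0], seg[:, 1, 1])

    def segment_orientations_relative_deg(self, centre_px) -> np.ndarray:
        """Segment orientations relative to the radial bearing from ``centre_px``."""
        if not self.fibre_segments:
            return np.empty(0)
        seg = np.asarray(self.fibre_segments, dtype=float)
        mid = seg.mean(axis=1)
        bearing = np.degrees(np.arctan2(-(mid[:, 0] - centre_px[0]), mid[:, 1] - centre_px[1]))
        return wrap_orientation(self.segment_orientations_deg() - wrap_orientation(bearing))


# ---------------------------------------------------------------------------
# rendering helpers
# ---------------------------------------------------------------------------


def _math_to_rc(centre_rc, radius_px, angle_rad):
    """Point at polar (radius, angle) about centre, math convention (y up)."""
    return (
        centre_rc[0] - radius_px * math.sin(angle_rad),
        centre_rc[1] + radius_px * math.cos(angle_rad),
    )


def _draw_segment(canvas: np.ndarray, p0, p1) -> None:
    """Accumulate one anti-aliased unit-intensity stroke (endpoints in px, row/col)."""
    h, w = canvas.shape
    r0, c0 = int(round(p0[0])), int(round(p0[1]))
    r1, c1 = int(round(p1[0])), int(round(p1[1]))
    rr, cc, val = line_aa(r0, c0, r1, c1)
    keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    np.maximum.at(canvas, (rr[keep], cc[keep]), val[keep])


def _draw_stroke(canvas, p0, p1, width_px: float) -> None:
    """Stroke of the given width: parallel anti-aliased lines at sub-pixel offsets."""
    if width_px <= 1.0:
        _draw_segment(canvas, p0, p1)
        return
    dr, dc = p1[0] - p0[0], p1[1] - p0[1]
    norm = math.hypot(dr, dc)
    if norm == 0:
        _draw_segment(canvas, p0, p1)
        return
    # unit normal to the stroke
    nr, nc = -dc / norm, dr / norm
    n_off = max(2, int(math.ceil(width_px * 2)))
    for off in np.linspace(-(width_px - 1) / 2, (width_px - 1) / 2, n_off):
        _draw_segment(canvas, (p0[0] + nr * off, p0[1] + nc * off), (p1[0] + nr * off, p1[1] + nc * off))


def _finalize(cfg: GeneratorConfig, canvas: np.ndarray, rng: np.random.Generator) -> Image:
    """Blur by the PSF, normalize, add background and noise, clip at zero."""
    img = canvas
    if cfg.psf_sigma_nm > 0:
        img = gaussian_filter(img, cfg.psf_sigma_nm / cfg.pixel_size_nm)
    peak = img.max()
    if peak > 0:
        img = img / peak
    out = cfg.background_level + (1.0 - cfg.background_level) * img
    if cfg.noise_sd > 0:
        out = out + rng.normal(0.0, cfg.noise_sd, size=out.shape)
    return Image(np.clip(out, 0.0, None), cfg.pixel_size_nm)


def _default_centre(cfg: GeneratorConfig):
    return ((cfg.image_size[0] - 1) / 2.0, (cfg.image_size[1] - 1) / 2.0)


# ---------------------------------------------------------------------------
# pattern scenes
# ---------------------------------------------------------------------------


def gen_vortex(
    cfg: GeneratorConfig,
    diameter_nm: float = 500.0,
    ring_thickness_nm: float = 150.0,
    pitch_deg: float = 45.0,
    n_fibres: int = 80,
    fibre_length_nm: float | None = None,
    centre_px: tuple[float, float] | None = None,
) -> tuple[Image, SceneTruth]:
    """Render an actin vortex: a ring of short fibres spiralling about a centre.

    Fibres sit on an annulus of mean diameter ``diameter_nm`` and cross the
    local radial direction at ``+pitch_deg`` or ``-pitch_deg`` (both
    chiralities equally represented), which is what produces the twin
    orientation peaks at +-45 degrees in the radial-reference histogram.
    """
    if not diameter_nm > 0:
        raise ValueError("diameter_nm must be positive")
    if not diameter_nm > 2 * cfg.pixel_size_nm:
        raise ValueError("diameter_nm must exceed two pixels")
    if n_fibres < 0:
        raise ValueError("n_fibres must be >= 0")
    rng = cfg.rng()
    centre = _default_centre(cfg) if centre_px is None else tuple(centre_px)
    if fibre_length_nm is None:
        # arc just long enough to traverse the annulus at the given pitch
        cos_p = abs(math.cos(math.radians(pitch_deg)))
        fibre_length_nm = ring_thickness_nm / cos_p if cos_p > 1e-6 else 0.5 * diameter_nm
    canvas = np.zeros(cfg.image_size)
    truth = SceneTruth(
        patterns=[PatternTruth("vortex", centre, diameter_nm, arm_count=n_fibres)]
    )
    r_mean = diameter_nm / 2.0 / cfg.pixel_size_nm
    r_half = ring_thickness_nm / 2.0 / cfg.pixel_size_nm
    arc_len_px = fibre_length_nm / cfg.pixel_size_nm
    # a constant-pitch (logarithmic) spiral keeps the angle to the local
    # radial direction at exactly +-pitch everywhere along the arc
    tan_pitch = math.tan(math.radians(pitch_deg)) if pitch_deg % 180 != 90 else None
    for i in range(n_fibres):
        phi = rng.uniform(0.0, 2 * math.pi)
        sign = 1.0 if i % 2 == 0 else -1.0  # equal weight for both chiralities
        rho = r_mean - r_half
        n_steps = max(3, int(math.ceil(arc_len_px / 1.2)))
        prev = _math_to_rc(centre, rho, phi)
        for _ in range(n_steps):
            ds = arc_len_px / n_steps
            if tan_pitch is None:  # pure tangential arc
                d_rho, d_phi = 0.0, sign * ds / max(rho, 1e-9)
            else:
                d_rho = ds * math.cos(math.radians(pitch_deg))
                d_phi = sign * ds * math.sin(math.radians(pitch_deg)) / max(rho, 1e-9)
            rho = rho + d_rho
            phi = phi + d_phi
            point = _math_to_rc(centre, rho, phi)
            truth.fibre_segments.append((prev, point))
            _draw_segment(canvas, prev, point)
            prev = point
    return _finalize(cfg, canvas, rng), truth


def gen_asterisk(
    cfg: GeneratorConfig,
    kind: str,
    span_nm: float,
    n_arms: int | None = None,
    arm_angles: list[float] | None = None,
    bundle_width_nm: float | None = None,
    fibres_per_bundle: int | None = None,
    centre_px: tuple[float, float] | None = None,
) -> tuple[Image, SceneTruth]:
    """Render an asterisk-like pattern: arms radiating from a bright core.

    ``kind='star'`` gives a few thick bundled arms (default 5 arms, ~150 nm
    bundles); ``kind='aster'`` gives many single-fibre arms (default 12).
    The end-to-end span through the core (the pattern diameter delta) is
    ``span_nm``, so each arm extends span/2 from the centre.
    """
    if kind not in {"star", "aster"}:
        raise ValueError("kind must be 'star' or 'aster'")
    if not span_nm > 0:
        raise ValueError("span_nm must be positive")
    if n_arms is None:
        n_arms = 5 if kind == "star" else 12
    if n_arms < 1:
        raise ValueError("n_arms must be >= 1")
    if arm_angles is not None and len(arm_angles) != n_arms:
        raise ValueError("arm_angles length must equal n_arms")
    rng = cfg.rng()
    centre = _default_centre(cfg) if centre_px is None else tuple(centre_px)
    if arm_angles is None:
        # evenly spaced arms with a small jitter; a shared random offset
        # decorrelates scenes generated with different seeds
        base = rng.uniform(0.0, 360.0 / n_arms)
        jitter = rng.uniform(-8.0, 8.0, size=n_arms) if n_arms > 1 else np.zeros(1)
        arm_angles = [
            float((base + k * 360.0 / n_arms + jitter[k] + 180.0) % 360.0 - 180.0)
            for k in range(n_arms)
        ]
    if bundle_width_nm is None:
        bundle_width_nm = 150.0 if kind == "star" else 40.0
    canvas = np.zeros(cfg.image_size)
    truth = SceneTruth(
        patterns=[
            PatternTruth(
                kind, centre, span_nm,
                arm_angles_deg=tuple(float(a) for a in arm_angles),
                arm_count=n_arms,
            )
        ]
    )
    arm_len = span_nm / 2.0 / cfg.pixel_size_nm
    width_px = bundle_width_nm / cfg.pixel_size_nm
    core_r = max(2.0, width_px)
    for a in arm_angles:
        th = math.radians(a)
        tip = _math_to_rc(centre, arm_len, th)
        truth.fibre_segments.append((centre, tip))
        _draw_stroke(canvas, centre, tip, width_px)
    # bright core: a compact blob at the centre
    rr = np.arange(cfg.image_size[0])[:, None] - centre[0]
    cc = np.arange(cfg.image_size[1])[None, :] - centre[1]
    canvas += 1.2 * np.exp(-(rr**2 + cc**2) / (2 * core_r**2))
    return _finalize(cfg, canvas, rng), truth


def gen_random_network(
    cfg: GeneratorConfig,
    segment_density: float = 3.0,
    bundled: bool = False,
    segment_length_nm: float = 1000.0,
) -> tuple[Image, SceneTruth]:
    """Render a randomly oriented fibre network (``segment_density`` per um^2)."""
    if segment_density < 0:
        raise ValueError("segment_density must be >= 0")
    rng = cfg.rng()
    h, w = cfg.image_size
    area_um2 = h * w * (cfg.pixel_size_nm / 1000.0) ** 2
    n_segments = int(round(segment_density * area_um2))
    canvas = np.zeros(cfg.image_size)
    truth = SceneTruth(patterns=[PatternTruth("random", _default_centre(cfg), 0.0)])
    half_len = segment_length_nm / 2.0 / cfg.pixel_size_nm
    width_px = (120.0 if bundled else 40.0) / cfg.pixel_size_nm
    for _ in range(n_segments):
        mid = (rng.uniform(0, h - 1), rng.uniform(0, w - 1))
        theta = rng.uniform(0.0, math.pi)
        dr, dc = -math.sin(theta), math.cos(theta)
        p0 = (mid[0] - dr * half_len, mid[1] - dc * half_len)
        p1 = (mid[0] + dr * half_len, mid[1] + dc * half_len)
        truth.fibre_segments.append((p0, p1))
        _draw_stroke(canvas, p0, p1, width_px)
    return _finalize(cfg, canvas, rng), truth


def gen_mesh(
    cfg: GeneratorConfig,
    line_intensity: float = 0.2,
    fibre_width_nm: float = 30.0,
    grid_cells: int | None = None,
) -> Image:
    """Render a fibre mesh as bright fibres on a dark background.

    Fibres follow an isotropic Poisson line process; ``line_intensity`` is
    the expected number of fibre crossings per micrometre along any straight
    transect, so the mean free chord between fibres is 1/``line_intensity``
    micrometres and mean pore size scales inversely with it.  ``grid_cells=n``
    overrides the random process with a regular grid enclosing exactly n x n
    interior pores (a deterministic fixture for the pore pipeline).

    High-contrast (SEM-like) meshes are what the downstream pore threshold
    expects; pass a config with ``background_level=0`` for that use.
    """
    if line_intensity < 0:
        raise ValueError("line_intensity must be >= 0")
    rng = cfg.rng()
    h, w = cfg.image_size
    canvas = np.zeros((h, w))
    width_px = fibre_width_nm / cfg.pixel_size_nm
    if grid_cells is not None:
        for r in np.linspace(0, h - 1, grid_cells + 1):
            _draw_stroke(canvas, (r, 0), (r, w - 1), width_px)
        for c in np.linspace(0, w - 1, grid_cells + 1):
            _draw_stroke(canvas, (0, c), (h - 1, c), width_px)
        return _finalize(cfg, canvas, rng)
    diag_um = math.hypot(h, w) * cfg.pixel_size_nm / 1000.0
    # crossing rate lambda per um of transect needs lambda * pi/2 lines per
    # um of offset (isotropic orientations average |sin| to 2/pi)
    n_lines = rng.poisson(line_intensity * diag_um * math.pi / 2.0)
    half_diag = math.hypot(h, w) / 2.0
    centre = ((h - 1) / 2.0, (w - 1) / 2.0)
    for _ in range(n_lines):
        theta = rng.uniform(0.0, math.pi)  # normal direction of the line
        offset = rng.uniform(-half_diag, half_diag)
        # foot of the normal, then extend along the line direction
        nr, nc = -math.sin(theta), math.cos(theta)
        foot = (centre[0] + nr * offset, centre[1] + nc * offset)
        dr, dc = nc, -nr  # line direction, perpendicular to the normal
        p0 = (foot[0] - dr * half_diag * 1.5, foot[1] - dc * half_diag * 1.5)
        p1 = (foot[0] + dr * half_diag * 1.5, foot[1] + dc * half_diag * 1.5)
        _draw_stroke(canvas, p0, p1, width_px)
    return _finalize(cfg, canvas, rng)


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------


@dataclass
class TrackSet:
    """Generated particle tracks plus the ground truth that produced them."""

    tracks: list[Track]
    scenario: str
    centre_nm: tuple[float, float]
    core_radius_nm: float
    movie_length_s: float
    frame_interval_s: float
    dwell_mean_s: float | None
    true_dwells_s: np.ndarray | None = None

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for tr in self.tracks:
            for t, (x, y) in zip(tr.times_s, tr.positions_nm):
                rows.append((tr.id, t, x, y))
        return pd.DataFrame(rows, columns=["track_id", "t_s", "x_nm", "y_nm"])


def gen_tracks(
    cfg: GeneratorConfig,
    scenario: str,
    n_tracks: int = 598,
    centre_nm: tuple[float, float] = (0.0, 0.0),
    core_radius_nm: float = 495.0,
    movie_length_s: float = 300.0,
    frame_interval_s: float = 5.0,
    dwell_mean_s: float = 20.0,
) -> TrackSet:
    """Generate particle tracks in the mobile or the immobilized regime.

    mobile
        Each track lives for an exponential dwell (mean ``dwell_mean_s``,
        right-truncated at the movie length, appearing at t=0) and its
        position in every frame is drawn i.i.d. uniformly in the disk of
        radius ``core_radius_nm`` about ``centre_nm`` - a molecule rattling
        inside the pattern core.  The population median distance from the
        centre converges to R/sqrt(2).
    immobilized
        Every track sits exactly at the centre in every frame of the movie,
        so per-track median distances are identically zero and dwell times
        equal the movie length.
    """
    if scenario not in {"mobile", "immobilized"}:
        raise ValueError("scenario must be 'mobile' or 'immobilized'")
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    if not frame_interval_s > 0:
        raise ValueError("frame_interval_s must be positive")
    if movie_length_s < frame_interval_s:
        raise ValueError("movie_length_s must cover at least one frame interval")
    if scenario == "mobile" and not dwell_mean_s > 0:
        raise ValueError("dwell_mean_s must be positive in the mobile scenario")
    rng = cfg.rng()
    cx, cy = centre_nm
    tracks: list[Track] = []
    true_dwells = None
    if scenario == "immobilized":
        n_frames = int(math.floor(movie_length_s / frame_interval_s)) + 1
        times = np.arange(n_frames) * frame_interval_s
        pos = np.column_stack([np.full(n_frames, cx), np.full(n_frames, cy)])
        for i in range(n_tracks):
            tracks.append(Track(id=i, times_s=times.copy(), positions_nm=pos.copy()))
    else:
        raw = rng.exponential(dwell_mean_s, size=n_tracks)
        true_dwells = np.minimum(raw, movie_length_s)
        for i in range(n_tracks):
            n_frames = int(math.floor(true_dwells[i] / frame_interval_s)) + 1
            times = np.arange(n_frames) * frame_interval_s
            r = core_radius_nm * np.sqrt(rng.uniform(size=n_frames))
            phi = rng.uniform(0, 2 * math.pi, size=n_frames)
            pos = np.column_stack([cx + r * np.cos(phi), cy + r * np.sin(phi)])
            tracks.append(Track(id=i, times_s=times, positions_nm=pos))
    return TrackSet(
        tracks=tracks,
        scenario=scenario,
        centre_nm=centre_nm,
        core_radius_nm=core_radius_nm,
        movie_length_s=movie_length_s,
        frame_interval_s=frame_interval_s,
        dwell_mean_s=dwell_mean_s if scenario == "mobile" else None,
        true_dwells_s=true_dwells,
    )


# ---------------------------------------------------------------------------
# FRAP series
# ---------------------------------------------------------------------------


def gen_frap_series(
    cfg: GeneratorConfig,
    v_truth_nm_s: float = 58.0,
    direction: str = "one_end",
    line_length_px: int = 100,
    n_frames: int = 60,
    bleach_depth: float = 0.9,
    frame_interval_s: float = 1.0,
    n_prebleach: int = 2,
    front_width_px: float = 1.5,
    recovery_tau_s: float = 30.0,
    photobleach_tau_s: float | None = None,
) -> FrapSeries:
    """Generate a FRAP time-lapse with a recovery front at a known velocity.

    The measurement line runs horizontally through a small image; a central
    bleach region loses ``bleach_depth`` of its intensity after
    ``n_prebleach`` unit-intensity frames.  Recovery then proceeds by

    * ``one_end``: a single front entering from the low-index end of the
      bleach region at ``v_truth_nm_s``;
    * ``both_ends``: two symmetric fronts entering from both edges;
    * ``homogeneous``: spatially uniform exponential recovery with time
      constant ``recovery_tau_s`` (the stress-fibre control).

    ``photobleach_tau_s`` optionally applies a global observational
    photobleaching decay exp(-t/tau) to every frame, to exercise the
    reference-region correction.
    """
    if not 0 < bleach_depth <= 1:
        raise ValueError("bleach_depth must be in (0, 1]")
    if n_frames < 3 or n_frames <= n_prebleach:
        raise ValueError("need at least 3 frames and more frames than pre-bleach frames")
    if direction not in {"one_end", "both_ends", "homogeneous"}:
        raise ValueError("direction must be one_end | both_ends | homogeneous")
    rng = cfg.rng()
    height = 12
    line_row = 8
    L = line_length_px
    b0, b1 = L // 3, 2 * L // 3  # bleach region on the line
    v_px_per_s = v_truth_nm_s / cfg.pixel_size_nm
    x = np.arange(L, dtype=float)
    frames = np.ones((n_frames, height, L))
    times = np.arange(n_frames) * frame_interval_s
    for f in range(n_prebleach, n_frames):
        t_post = (f - n_prebleach) * frame_interval_s
        profile = np.ones(L)
        in_bleach = (x >= b0) & (x < b1)
        if direction == "homogeneous":
            rec = 1.0 - math.exp(-t_post / recovery_tau_s)
        else:
            front_a = b0 + v_px_per_s * t_post
            rec = 1.0 / (1.0 + np.exp((x - front_a) / front_width_px))
            if direction == "both_ends":
                front_b = b1 - v_px_per_s * t_post
                rec_b = 1.0 / (1.0 + np.exp((front_b - x) / front_width_px))
                rec = np.clip(rec + rec_b, 0.0, 1.0)
        profile[in_bleach] = 1.0 - bleach_depth * (1.0 - rec if np.isscalar(rec) else 1.0 - rec[in_bleach])
        frames[f, line_row - 1 : line_row + 2, :] = profile[None, :]
    if photobleach_tau_s is not None:
        frames *= np.exp(-times / photobleach_tau_s)[:, None, None]
    if cfg.noise_sd > 0:
        frames = np.clip(frames + rng.normal(0, cfg.noise_sd, frames.shape), 0.0, None)
    return FrapSeries(
        frames=frames,
        times_s=times,
        ln_roi=[(line_row, int(c)) for c in range(L)],
        bleach_roi=(line_row - 1, b0, line_row + 2, b1),  # (r0, c0, r1, c1) half-open
        n_prebleach=n_prebleach,
        reference_roi=(0, 0, 3, L),
        pixel_size_nm=cfg.pixel_size_nm,
    )


# ---------------------------------------------------------------------------
# AFM force curves
# ---------------------------------------------------------------------------


def hertz_force_nN(
    depth_nm,
    E_pa: float,
    model: str,
    poisson_ratio: float = 0.5,
    bead_radius_nm: float = 5000.0,
    half_angle_deg: float = 20.0,
):
    """Hertz contact force, in nN, at indentation ``depth_nm``.

    sphere:  F = (4/3) * E/(1-nu^2) * sqrt(R) * d^(3/2)
    pyramid: F = 0.7453 * E/(1-nu^2) * tan(theta) * d^2   (four-sided pyramid)
    """
    d = np.maximum(np.asarray(depth_nm, dtype=float), 0.0)
    e_eff = E_pa / (1.0 - poisson_ratio**2)
    if model == "sphere":
        return (4.0 / 3.0) * e_eff * np.sqrt(bead_radius_nm) * d**1.5 * 1e-9
    if model == "pyramid":
        return 0.7453 * e_eff * math.tan(math.radians(half_angle_deg)) * d**2 * 1e-9
    raise ValueError("model must be 'sphere' or 'pyramid'")


@dataclass
class ForceCurveSet:
    """Generated force curves plus the ground truth that produced them."""

    curves: list[ForceCurve]
    E_true_pa: float
    model: str
    contact_z_nm: float
    poisson_ratio: float
    bead_radius_nm: float
    half_angle_deg: float


def gen_force_curves(
    cfg: GeneratorConfig,
    E_true_pa: float = 1500.0,
    model: str = "sphere",
    contact_z_nm: float = 500.0,
    spring_constant: float = 0.07,
    noise_sd_nm: float = 0.0,
    n_curves: int = 1,
    max_depth_nm: float = 700.0,
    n_samples: int = 400,
    poisson_ratio: float = 0.5,
    bead_radius_nm: float = 5000.0,
    half_angle_deg: float = 20.0,
) -> ForceCurveSet:
    """Generate AFM approach curves obeying a Hertz model beyond the contact point.

    Beyond ``contact_z_nm`` the deflection delta solves the self-consistent
    contact relation k*delta = F(d) with d = (z - z0) - delta; before contact
    the deflection is the (noisy) zero baseline.  ``spring_constant`` is in
    N/m, so force in nN is spring_constant times deflection in nm.
    """
    if not E_true_pa > 0:
        raise ValueError("E_true_pa must be positive")
    if not spring_constant > 0:
        raise ValueError("spring_constant must be positive")
    rng = cfg.rng()
    # choose a z range so indentation reaches ~max_depth_nm
    f_max = hertz_force_nN(
        max_depth_nm, E_true_pa, model, poisson_ratio, bead_radius_nm, half_angle_deg
    )
    z_max = contact_z_nm + max_depth_nm + float(f_max) / spring_constant
    # place the contact point exactly on the grid: the forward model is then
    # sampled without interpolation error on either side
    n_pre = max(10, int(round(n_samples * contact_z_nm / z_max)))
    n_post = max(10, n_samples - n_pre)
    z = np.concatenate(
        [
            np.linspace(0.0, contact_z_nm, n_pre, endpoint=False),
            np.linspace(contact_z_nm, z_max, n_post),
        ]
    )
    u = np.maximum(z - contact_z_nm, 0.0)  # piezo travel past contact

    def _deflection(u_i: float) -> float:
        if u_i <= 0:
            return 0.0
        lo, hi = 0.0, u_i
        for _ in range(80):  # bisection: monotone residual, robust for any exponent
            mid = 0.5 * (lo + hi)
            f = hertz_force_nN(
                u_i - mid, E_true_pa, model, poisson_ratio, bead_radius_nm, half_angle_deg
            )
            if spring_constant * mid < f:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    clean = np.array([_deflection(ui) for ui in u])
    curves = []
    for i in range(n_curves):
        defl = clean.copy()
        if noise_sd_nm > 0:
            defl = defl + rng.normal(0.0, noise_sd_nm, size=defl.shape)
        curves.append(ForceCurve(z_nm=z.copy(), deflection_nm=defl, spring_constant=spring_constant))
    return ForceCurveSet(
        curves=curves,
        E_true_pa=E_true_pa,
        model=model,
        contact_z_nm=contact_z_nm,
        poisson_ratio=poisson_ratio,
        bead_radius_nm=bead_radius_nm,
        half_angle_deg=half_angle_deg,
    )
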