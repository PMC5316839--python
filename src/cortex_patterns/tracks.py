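"""Particle-track statistics for nucleator dynamics at pattern cores.

Arp2/3 complexes attach to and detach from the actin patterns; their tracked
positions summarize into two numbers per track: the median Euclidean
distance sigma from the pattern centre, and the dwell time tau between
appearance and disappearance.  Freely exchanging populations show
exponentially distributed dwell times (a memoryless on-off process), whereas
immobilized populations survive the whole movie, giving a degenerate
distribution pinned at the recording length; ``fit_dwell_model`` selects
between the two by maximum likelihood and AIC, right-censoring the
exponential fit at the movie length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Track",
    "TrackStats",
    "track_median_distance",
    "dwell_time",
    "fit_dwell_model",
    "population_summary",
    "link_frames",
    "read_tracks_csv",
    "write_tracks_csv",
]


@dataclass
class Track:
    """One particle trajectory: strictly increasing times and (x, y) positions in nm."""

    id: int
    times_s: np.ndarray
    positions_nm: np.ndarray  # shape (n, 2)

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        p = np.asarray(self.positions_nm, dtype=float).reshape(-1, 2)
        if t.size == 0:
            raise ValueError("track must have at least one sample")
        if t.size != p.shape[0]:
            raise ValueError("times and positions must have equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("track times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(p))):
            raise ValueError("track samples must be finite")
        self.times_s = t
        self.positions_nm = p


@dataclass
class TrackStats:
    """Per-track summary: median distance to the centre and dwell time."""

    track_id: int
    sigma_nm: float
    tau_s: float
    n_frames: int

    def __post_init__(self) -> None:
        if self.sigma_nm < 0 or self.tau_s < 0:
            raise ValueError("sigma and tau must be non-negative")


def track_median_distance(track: Track, centre_nm: tuple[float, float]) -> float:
    """Median over time points of the Euclidean distance |r(t)| to the centre."""
    centre = np.asarray(centre_nm, dtype=float)
    if not np.all(np.isfinite(centre)):
        raise ValueError("centre must be finite")
    d = np.hypot(*(track.positions_nm - centre).T)
    return float(np.median(d))


def dwell_time(track: Track) -> float:
    """Dwell time tau: last observation time minus first (0 for a single frame)."""
    return float(track.times_s[-1] - track.times_s[0])


def summarize_tracks(
    tracks: list[Track], centre_nm: tuple[float, float]
) -> list[TrackStats]:
    """Per-track sigma and tau for a whole population."""
    return [
        TrackStats(
            track_id=tr.id,
            sigma_nm=track_median_distance(tr, centre_nm),
            tau_s=dwell_time(tr),
            n_frames=len(tr.times_s),
        )
        for tr in tracks
    ]


def fit_dwell_model(
    taus, movie_length_s: float, frame_interval_s: float | None = None
) -> tuple[str, float, float]:
    """Fit exponential (censored) and Gaussian dwell models; pick the lower AIC.

    The exponential fit treats dwell times reaching the movie length as
    right-censored: its MLE mean is total observed time divided by the
    number of uncensored tracks.  If every dwell lies within one frame of
    the movie length the sample is degenerate (nothing ever detached) and is
    reported as gaussian with mean equal to the movie length.

    Returns ``(model, mean_s, se_s)`` where se is the standard error of the
    fitted mean.
    """
    taus = np.asarray(taus, dtype=float)
    if taus.size < 20:
        raise ValueError("need at least 20 dwell times to fit a model")
    if not movie_length_s > 0:
        raise ValueError("movie_length_s must be positive")
    tol = frame_interval_s if frame_interval_s is not None else max(1e-9, 0.01 * movie_length_s)
    censored = taus >= movie_length_s - tol
    n = taus.size
    if np.all(censored):
        # every molecule outlived the movie: on-off kinetics unresolvable
        return ("gaussian", float(movie_length_s), float(np.std(taus) / math.sqrt(n)))

    n_obs = int(np.sum(~censored))
    mean_exp = float(np.sum(taus) / n_obs)  # censored exponential MLE
    with np.errstate(divide="ignore"):
        loglik_exp = -n_obs * math.log(mean_exp) - float(np.sum(taus)) / mean_exp
    aic_exp = 2 * 1 - 2 * loglik_exp

    mu = float(np.mean(taus))
    sd = float(np.std(taus))
    if sd == 0:
        aic_gauss = -np.inf  # point mass: gaussian degenerates and wins
        loglik_gauss = np.inf
    else:
        loglik_gauss = float(
            np.sum(-0.5 * math.log(2 * math.pi) - math.log(sd) - (taus - mu) ** 2 / (2 * sd**2))
        )
        aic_gauss = 2 * 2 - 2 * loglik_gauss

    if aic_exp <= aic_gauss:
        return ("exponential", mean_exp, mean_exp / math.sqrt(n_obs))
    return ("gaussian", mu, sd / math.sqrt(n) if sd > 0 else 0.0)


def population_summary(stats: list[TrackStats], n_bins: int = 30) -> dict:
    """Probability-normalized histograms of sigma and tau plus population medians."""
    if not stats:
        raise ValueError("need at least one track")
    sigma = np.array([s.sigma_nm for s in stats])
    tau = np.array([s.tau_s for s in stats])

    def _hist(values):
        hi = float(values.max())
        edges = np.linspace(0.0, hi if hi > 0 else 1.0, n_bins + 1)
        counts, edges = np.histogram(values, bins=edges)
        probs = counts / counts.sum() if counts.sum() else counts.astype(float)
        return {"bin_edges": edges, "probabilities": probs}

    n = len(stats)
    return {
        "n_tracks": n,
        "sigma_hist": _hist(sigma),
        "tau_hist": _hist(tau),
        "median_sigma_nm": float(np.median(sigma)),
        "sem_sigma_nm": float(np.std(sigma) / math.sqrt(n)),
        "median_tau_s": float(np.median(tau)),
        "mean_tau_s": float(np.mean(tau)),
    }


def link_frames(detections: pd.DataFrame, max_jump_nm: float = 300.0) -> list[Track]:
    """Minimal greedy nearest-neighbour frame linker for building fixtures.

    ``detections`` needs columns ``t_s, x_nm, y_nm``.  Each detection links
    to the nearest unclaimed detection in the next frame within
    ``max_jump_nm``.  This is deliberately simple: imported track tables are
    the primary input; this exists so rendered movies can be turned into
    tracks in tests.
    """
    frames = sorted(detections["t_s"].unique())
    active: list[tuple[list, np.ndarray]] = []  # (samples, last position)
    finished: list[list] = []
    for t in frames:
        pts = detections.loc[detections["t_s"] == t, ["x_nm", "y_nm"]].to_numpy()
        claimed = np.zeros(len(pts), dtype=bool)
        still = []
        for samples, last in active:
            if len(pts):
                dist = np.hypot(*(pts - last).T)
                dist[claimed] = np.inf
                j = int(np.argmin(dist))
                if dist[j] <= max_jump_nm:
                    claimed[j] = True
                    samples.append((t, pts[j, 0], pts[j, 1]))
                    still.append((samples, pts[j]))
                    continue
            finished.append(samples)
        active = still
        for j in range(len(pts)):
            if not claimed[j]:
                active.append(([(t, pts[j, 0], pts[j, 1])], pts[j]))
    finished.extend(s for s, _ in active)
    tracks = []
    for i, samples in enumerate(finished):
        arr = np.asarray(samples, dtype=float)
        tracks.append(Track(id=i, times_s=arr[:, 0], positions_nm=arr[:, 1:3]))
    return tracks


def read_tracks_csv(path) -> list[Track]:
    """Read tracks from CSV with columns ``track_id, t_s, x_nm, y_nm``."""
    df = pd.read_csv(path)
    tracks = []
    for tid, grp in df.groupby("track_id"):
        grp = grp.sort_values("t_s")
        tracks.append(
            Track(id=int(tid), times_s=grp["t_s"].to_numpy(), positions_nm=grp[["x_nm", "y_nm"]].to_numpy())
        )
    return tracks


def write_tracks_csv(tracks: list[Track], path) -> None:
    rows = []
    for tr in tracks:
        for t, (x, y) in zip(tr.times_s, tr.positions_nm):
            rows.append((tr.id, t, x, y))
    pd.DataFrame(rows, columns=["track_id", "t_s", "x_nm", "y_nm"]).to_csv(path, index=False)
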