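"""Cortical-mesh pore-size pipeline.

The cortex is a fibre mesh; its permeability-relevant statistic is the pore
size xi, the diameter of the holes between fibres.  The pipeline: normalize
the image to its maximum, threshold at the deliberately low value 0.002 to
binarize the fibres, invert, and fit each interior hole with its
second-moment equivalent ellipse; xi is twice the mean of the two
semi-axes.  Pore-size samples are summarized by a maximum-likelihood
exponential fit (pore sizes in disordered meshes are exponentially
distributed), and conditions are compared by the ratio of fitted means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label, regionprops

from .image import Image

__all__ = [
    "PoreRecord",
    "segment_mesh",
    "pore_size_distribution",
    "summarize_pores",
    "pore_ratio",
    "MESH_THRESHOLD",
]

MESH_THRESHOLD = 0.002  # fraction of the per-image maximum


@dataclass
class PoreRecord:
    """One pore: equivalent-ellipse geometry of a background component."""

    diameter_nm: float  # xi = 2 * mean(semi-axes)
    centroid_px: tuple[float, float]
    semi_axes_nm: tuple[float, float]  # (major, minor)
    area_px: int

    def __post_init__(self) -> None:
        if not self.diameter_nm > 0:
            raise ValueError("pore diameter must be positive")
        if self.semi_axes_nm[1] > self.semi_axes_nm[0]:
            raise ValueError("semi-axes must be ordered (major, minor)")


def segment_mesh(image: Image, threshold: float = MESH_THRESHOLD) -> np.ndarray:
    """Binary fibre mask: ``image / image.max() > threshold``."""
    data = image.data
    peak = float(data.max())
    if not peak > 0:
        raise ValueError("cannot segment an all-zero image")
    return (data / peak) > threshold


def pore_size_distribution(binary: np.ndarray, pixel_size_nm: float) -> list[PoreRecord]:
    """Pores of a binary fibre mask: equivalent ellipses of the inverted mask.

    Background (pore) components are 4-connected and fibre pixels
    8-connected, the standard complementary pairing.  Components touching
    the image border are excluded: their extent is censored by the field of
    view.  Each remaining component is replaced by the ellipse with the same
    second central moments; xi is twice the mean semi-axis.
    """
    binary = np.asarray(binary, dtype=bool)
    if not np.any(~binary):
        return []
    pores = label(~binary, connectivity=1)
    border = np.unique(
        np.concatenate([pores[0, :], pores[-1, :], pores[:, 0], pores[:, -1]])
    )
    border = set(border[border > 0].tolist())
    records = []
    for rp in regionprops(pores):
        if rp.label in border:
            continue
        semi_major = rp.axis_major_length / 2.0 * pixel_size_nm
        semi_minor = rp.axis_minor_length / 2.0 * pixel_size_nm
        if semi_major <= 0:  # single-pixel pore: fall back to its pixel extent
            semi_major = semi_minor = 0.5 * pixel_size_nm
        records.append(
            PoreRecord(
                diameter_nm=semi_major + semi_minor,
                centroid_px=tuple(rp.centroid),
                semi_axes_nm=(semi_major, max(semi_minor, 1e-12)),
                area_px=int(rp.area),
            )
        )
    return records


def summarize_pores(records: list[PoreRecord]) -> tuple[float, float]:
    """Maximum-likelihood exponential fit to the pore-size sample.

    Returns ``(mean_xi_nm, rate_per_nm)``; the exponential MLE mean is the
    sample mean.  Requires at least 10 pores.
    """
    if len(records) < 10:
        raise ValueError(f"need at least 10 pores to fit, got {len(records)}")
    xi = np.array([r.diameter_nm for r in records])
    mean = float(np.mean(xi))
    return mean, 1.0 / mean


def pore_ratio(summary_a: tuple[float, float], summary_b: tuple[float, float]) -> float:
    """Ratio of fitted mean pore sizes, condition a over condition b."""
    mean_a, _ = summary_a
    mean_b, _ = summary_b
    if mean_b == 0:
        raise ZeroDivisionError("condition b has zero mean pore size")
    return mean_a / mean_b
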