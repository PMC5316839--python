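"""AFM force-curve analysis: contact point, indentation and Hertz fits.

An approach curve records cantilever deflection (delta, nm) against piezo
position (z, nm); force is spring constant times deflection.  The analysis
finds the contact point with a two-segment piecewise fit (flat baseline,
then a power-law indentation branch), converts piezo travel past contact
into indentation depth d = (z - z0) - delta, and extracts the elastic
modulus E by least squares against a Hertz contact model inside a fixed
depth window (default 100-500 nm, where the cortex dominates the response):

    sphere (radius R):          F = (4/3) * E/(1-nu^2) * sqrt(R) * d^(3/2)
    four-sided pyramid (theta): F = 0.7453 * E/(1-nu^2) * tan(theta) * d^2

Units: z and delta in nm, spring constant in N/m, force in nN, E in Pa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ForceCurve",
    "ElasticityResult",
    "find_contact_point",
    "indentation",
    "fit_modulus",
    "relative_modulus_change",
    "NoContactError",
]

DEFAULT_DEPTH_WINDOW_NM = (100.0, 500.0)
DEFAULT_POISSON_RATIO = 0.5  # incompressible material
PYRAMID_COEF = 0.7453


class NoContactError(RuntimeError):
    """The curve shows no superlinear indentation region."""


class FitFailureError(RuntimeError):
    """The Hertz fit produced a non-physical (non-positive) modulus."""


@dataclass
class ForceCurve:
    """One AFM approach curve: piezo position and deflection, both in nm."""

    z_nm: np.ndarray
    deflection_nm: np.ndarray
    spring_constant: float  # N/m

    def __post_init__(self) -> None:
        z = np.asarray(self.z_nm, dtype=float)
        d = np.asarray(self.deflection_nm, dtype=float)
        if z.shape != d.shape or z.ndim != 1:
            raise ValueError("z and deflection must be equal-length 1-D arrays")
        if z.size > 1 and not (np.all(np.diff(z) > 0) or np.all(np.diff(z) < 0)):
            raise ValueError("z must be strictly monotone on the approach segment")
        if not self.spring_constant > 0:
            raise ValueError("spring_constant must be positive")
        if z.size > 1 and z[0] > z[-1]:  # store in approach order, increasing z
            z, d = z[::-1].copy(), d[::-1].copy()
        self.z_nm = z
        self.deflection_nm = d

    @property
    def force_nN(self) -> np.ndarray:
        return self.spring_constant * self.deflection_nm


def find_contact_point(curve: ForceCurve, coarse_step: int = 4) -> float:
    """Contact point z0 by a two-segment piecewise fit.

    For each candidate breakpoint the residual sum of a constant baseline
    before it plus a power-law branch ``a * (z - z0)^p`` after it
    (p in {1.5, 2}, the two Hertz exponents) is minimized; the candidate
    grid is every ``coarse_step``-th sample, refined to every sample around
    the best candidate.  Raises :class:`NoContactError` when the indentation
    branch does not rise above the baseline noise.
    """
    z, defl = curve.z_nm, curve.deflection_nm
    n = z.size
    if n < 50:
        raise ValueError("need at least 50 samples spanning pre- and post-contact")
    baseline_sd = float(np.std(defl[: max(10, n // 10)]))
    rise = float(defl[-10:].mean() - defl[: n // 10].mean())
    if rise < max(3.5 * baseline_sd, 1e-12):
        raise NoContactError("deflection never rises above the baseline")

    def total_ssr(i: int) -> float:
        base = defl[:i]
        ssr = float(np.sum((base - base.mean()) ** 2))
        tail_z = z[i:] - z[i]
        tail_d = defl[i:] - base.mean()
        # two-term basis: the indentation branch is a power law softened by
        # the cantilever's own deflection, well captured by d^1.5 and d^2
        X = np.column_stack([tail_z**1.5, tail_z**2])
        coef, *_ = np.linalg.lstsq(X, tail_d, rcond=None)
        return ssr + float(np.sum((tail_d - X @ coef) ** 2))

    candidates = range(5, n - 10, coarse_step)
    best = min(candidates, key=total_ssr)
    fine = range(max(5, best - coarse_step), min(n - 10, best + coarse_step + 1))
    best = min(fine, key=total_ssr)
    return float(z[best])


def indentation(curve: ForceCurve, contact_z_nm: float) -> tuple[np.ndarray, np.ndarray]:
    """Indentation depth d = (z - z0) - (delta - delta0) past contact.

    Returns ``(depth_nm, force_nN)`` for post-contact samples only; delta0
    is the deflection interpolated at the contact point, so a rigid offset
    of the whole curve leaves the result unchanged.
    """
    z, defl = curve.z_nm, curve.deflection_nm
    if not (z[0] <= contact_z_nm <= z[-1]):
        raise ValueError("contact point must lie within the z range")
    delta0 = float(np.interp(contact_z_nm, z, defl))
    post = z >= contact_z_nm
    depth = (z[post] - contact_z_nm) - (defl[post] - delta0)
    force = curve.spring_constant * (defl[post] - delta0)
    return depth, force


@dataclass
class ElasticityResult:
    """Fitted Hertz model for one curve."""

    E_pa: float
    contact_z_nm: float
    model: str  # sphere | pyramid
    depth_window_nm: tuple[float, float]
    poisson_ratio: float
    fit_rmse_nN: float
    n_samples: int

    def __post_init__(self) -> None:
        if not self.E_pa > 0:
            raise ValueError("E must be positive")
        if not self.depth_window_nm[0] < self.depth_window_nm[1]:
            raise ValueError("depth window must satisfy min < max")


def fit_modulus(
    curve: ForceCurve,
    contact_z_nm: float | None = None,
    model: str = "pyramid",
    depth_window_nm: tuple[float, float] = DEFAULT_DEPTH_WINDOW_NM,
    poisson_ratio: float = DEFAULT_POISSON_RATIO,
    bead_radius_nm: float | None = None,
    half_angle_deg: float | None = None,
) -> ElasticityResult:
    """Least-squares Hertz fit of E inside the depth window.

    ``model='sphere'`` requires ``bead_radius_nm``; ``model='pyramid'``
    requires ``half_angle_deg`` (the face half-angle is not a universal
    constant and must come from the probe's data sheet).  When
    ``contact_z_nm`` is omitted it is estimated with
    :func:`find_contact_point`.
    """
    if model not in {"sphere", "pyramid"}:
        raise ValueError("model must be 'sphere' or 'pyramid'")
    if model == "sphere" and bead_radius_nm is None:
        raise ValueError("sphere model requires bead_radius_nm")
    if model == "pyramid" and half_angle_deg is None:
        raise ValueError("pyramid model requires half_angle_deg")
    if contact_z_nm is None:
        contact_z_nm = find_contact_point(curve)
    depth, force = indentation(curve, contact_z_nm)
    lo, hi = depth_window_nm
    if not lo < hi:
        raise ValueError("depth window must satisfy min < max")
    sel = (depth >= lo) & (depth <= hi)
    if int(np.sum(sel)) < 10:
        raise ValueError("fewer than 10 samples inside the depth window")
    d, f = depth[sel], force[sel]
    exponent = 1.5 if model == "sphere" else 2.0
    x = d**exponent
    coef = float(np.dot(x, f)) / float(np.dot(x, x))  # F = coef * d^m, nN/nm^m
    if model == "sphere":
        e_eff = coef / ((4.0 / 3.0) * math.sqrt(bead_radius_nm) * 1e-9)
    else:
        e_eff = coef / (PYRAMID_COEF * math.tan(math.radians(half_angle_deg)) * 1e-9)
    E = e_eff * (1.0 - poisson_ratio**2)
    if not E > 0:
        raise FitFailureError("fitted modulus is non-positive")
    rmse = float(np.sqrt(np.mean((f - coef * x) ** 2)))
    return ElasticityResult(
        E_pa=E,
        contact_z_nm=float(contact_z_nm),
        model=model,
        depth_window_nm=(float(lo), float(hi)),
        poisson_ratio=poisson_ratio,
        fit_rmse_nN=rmse,
        n_samples=int(np.sum(sel)),
    )


def relative_modulus_change(E_pa: float, E_ctrl_pa: float) -> float:
    """Relative modulus change (E - E_ctrl) / E_ctrl."""
    if not E_ctrl_pa > 0:
        raise ValueError("E_ctrl must be positive")
    return (E_pa - E_ctrl_pa) / E_ctrl_pa
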