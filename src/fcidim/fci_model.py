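"""Analytic correlation integral of the uniform hypersphere.

For points drawn uniformly on the m-dimensional sphere S^m of radius
``r_s`` embedded in R^{m+1}, the fraction of point pairs whose Euclidean
(chord) distance is below ``r`` has a closed form in the reduced radius
``rbar = r / r_s``:

    rho(rbar) = 1/2 + (Omega_{m-1} / (2 Omega_m)) * (rbar^2 - 2)
                * 2F1(1/2, 1 - m/2; 3/2; ((rbar^2 - 2) / 2)^2)

where Omega_m is the total solid angle of S^m.  This sigmoid, steeper
the larger m, is the fitting model used by the global estimator: unlike
the small-radius power law of the Grassberger-Procaccia correlation
dimension, it describes the pair-distance distribution at *all* scales,
which is what makes estimation possible when small neighbourhoods are
unsampled.

Note on the hypergeometric argument: the argument must be the square of
*half* the auxiliary quantity t = rbar^2 - 2, i.e. (t/2)^2.  With the
alternative argument t^2 the expression fails the boundary condition
rho(2) = 1 (e.g. it yields 1/4 for m = 4) and leaves the convergence
disk for odd m; the quadrature representation in
:func:`fci_cdf_oracle` arbitrates.  See docs/methods.md.

The independent oracle is the single remaining integral of the
spherical-coordinate derivation,

    rho(rbar) = (Omega_{m-1} / Omega_m)
                * int_0^{arccos(1 - rbar^2/2)} sin^{m-1}(beta) dbeta,

evaluated by adaptive quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, special

__all__ = [
    "FciParams",
    "total_solid_angle",
    "solid_angle_ratio",
    "fci_cdf",
    "fci_cdf_oracle",
]

#: floating-point slack allowed outside [0, 2] before clamping is refused
_RBAR_CLAMP_TOL = 1e-9


@dataclass(frozen=True)
class FciParams:
    """Parameters of the hypersphere chord-distance model.

    Attributes
    ----------
    sphere_dim : float
        Dimension m >= 1 of the sphere S^m itself (a circle has
        ``sphere_dim == 1``).  Continuous values are allowed: the
        estimator treats the dimension as a free real parameter.
    scale : float
        Sphere radius r_s > 0.
    """

    sphere_dim: float
    scale: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.sphere_dim) or self.sphere_dim < 1:
            raise ValueError(f"sphere_dim must be >= 1, got {self.sphere_dim}")
        if not np.isfinite(self.scale) or self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")


def total_solid_angle(m: float) -> float:
    """Total solid angle Omega_m = 2 pi^{(m+1)/2} / Gamma((m+1)/2) of S^m.

    Evaluated through log-Gamma so that it does not overflow for large m.
    ``m = 0`` gives 2 (the two points of S^0), ``m = 1`` gives 2 pi,
    ``m = 2`` gives 4 pi.
    """
    if m < 0:
        raise ValueError(f"sphere dimension must be >= 0, got {m}")
    return float(
        2.0 * np.exp(0.5 * (m + 1) * np.log(np.pi) - special.gammaln(0.5 * (m + 1)))
    )


def solid_angle_ratio(m: float) -> float:
    """Ratio Omega_{m-1} / Omega_m, computed in log space.

    This ratio normalises the chord CDF and equals the slope factor of
    the model at its midpoint; it grows like sqrt(m / (2 pi)).
    """
    if m < 1:
        raise ValueError(f"sphere dimension must be >= 1, got {m}")
    return float(
        np.exp(special.gammaln(0.5 * (m + 1)) - special.gammaln(0.5 * m))
        / np.sqrt(np.pi)
    )


def _clamp_rbar(rbar: np.ndarray) -> np.ndarray:
    """Clamp reduced radii to [0, 2], tolerating only float-level excess."""
    rbar = np.asarray(rbar, dtype=float)
    if np.any(rbar < -_RBAR_CLAMP_TOL) or np.any(rbar > 2.0 + _RBAR_CLAMP_TOL):
        bad = rbar[(rbar < -_RBAR_CLAMP_TOL) | (rbar > 2.0 + _RBAR_CLAMP_TOL)]
        raise ValueError(
            f"reduced radius must lie in [0, 2]; got values such as {bad.flat[0]!r}"
        )
    return np.clip(rbar, 0.0, 2.0)


def fci_cdf(rbar, m: float):
    """Chord-distance CDF of the uniform unit m-sphere at reduced radius.

    Parameters
    ----------
    rbar : array_like
        Reduced radii r / r_s in [0, 2].  Values outside by no more than
        1e-9 (floating-point noise) are clamped; larger excursions raise.
    m : float
        Sphere dimension, >= 1, not necessarily integer.

    Returns
    -------
    ndarray or float
        CDF values in [0, 1]; rho(0) = 0, rho(sqrt(2)) = 1/2, rho(2) = 1.
    """
    if not np.isfinite(m) or m < 1:
        raise ValueError(f"sphere dimension must be >= 1, got {m}")
    rbar = np.asarray(rbar, dtype=float)
    scalar = rbar.ndim == 0
    rb = _clamp_rbar(np.atleast_1d(rbar))
    t = rb * rb - 2.0
    out = 0.5 + 0.5 * solid_angle_ratio(m) * t * special.hyp2f1(
        0.5, 1.0 - 0.5 * m, 1.5, (0.5 * t) ** 2
    )
    # endpoints are exact by construction; remove residual round-off
    out[rb == 0.0] = 0.0
    out[rb == 2.0] = 1.0
    np.clip(out, 0.0, 1.0, out=out)
    return float(out[0]) if scalar else out


def fci_cdf_oracle(rbar: float, m: int, epsabs: float = 1e-12) -> float:
    """Quadrature ground truth for :func:`fci_cdf` at integer m.

    Integrates (Omega_{m-1}/Omega_m) * sin^{m-1}(beta) from 0 to
    arccos(1 - rbar^2 / 2).  Slow but unambiguous; used to validate the
    closed form.
    """
    if int(m) != m or m < 1:
        raise ValueError(f"oracle requires integer m >= 1, got {m}")
    rb = float(_clamp_rbar(np.asarray(rbar)))
    theta = np.arccos(np.clip(1.0 - rb * rb / 2.0, -1.0, 1.0))
    value, abserr = integrate.quad(
        lambda beta: np.sin(beta) ** (m - 1), 0.0, theta, epsabs=epsabs, limit=200
    )
    if abserr > max(1e-9, 1e-6 * abs(value)):
        raise RuntimeError(
            f"quadrature did not converge (m={m}, rbar={rb}): abserr={abserr}"
        )
    return solid_angle_ratio(m) * value
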