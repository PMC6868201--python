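"""Empirical correlation integral and the correlation-dimension baseline.

The correlation integral (density of neighbours) of a sample
``X = {x^1 ... x^N}`` is the fraction of unordered pairs within
Euclidean distance r:

    rho_X(r) = 2 / (N (N-1)) * sum_{mu < nu} theta(r - |x^mu - x^nu|).

Here it is materialised as a step function over the M = N(N-1)/2 sorted
pair distances, the k-th smallest carrying cumulative value (k-1)/M.
That left-continuous convention (rather than the textbook k/M) is the
package default because it is what the global estimator's fitting
protocol was calibrated against; ``convention="inclusive"`` switches to
k/M.

The classical Grassberger-Procaccia estimator ("CorrDim") reads the
intrinsic dimension off the small-radius power law rho_X(r) ~ r^d as a
log-log slope.  It is provided as a baseline: it is accurate for small
dimensions but systematically underestimates once d exceeds ~10,
because sampling the small-r regime requires exponentially many points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator

__all__ = [
    "EmpiricalCDF",
    "empirical_cdf",
    "subsample_cdf",
    "corr_dim",
    "CorrelationDimension",
]


@dataclass(frozen=True)
class EmpiricalCDF:
    """Sorted pair distances with their cumulative pair fractions."""

    radii: np.ndarray
    cdf: np.ndarray

    def __post_init__(self) -> None:
        if len(self.radii) != len(self.cdf):
            raise ValueError("radii and cdf must have equal length")

    def __len__(self) -> int:
        return len(self.radii)


def _as_sample_matrix(X, min_samples: int = 2) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D sample matrix, got shape {X.shape}")
    if X.shape[0] < min_samples:
        raise ValueError(
            f"need at least {min_samples} samples, got {X.shape[0]}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("sample matrix contains non-finite entries")
    return X


def empirical_cdf(X, convention: str = "exclusive") -> EmpiricalCDF:
    """All-pairs Euclidean distance CDF of a sample matrix.

    Parameters
    ----------
    X : array_like, shape (N, D)
        Sample matrix, rows are observations; N >= 2.
    convention : {"exclusive", "inclusive"}
        "exclusive" assigns (k-1)/M to the k-th smallest of the
        M = N(N-1)/2 distances (package default); "inclusive" assigns
        k/M.

    Notes
    -----
    Ties are kept in stable sort order, each tied distance carrying its
    own rank-based cumulative value.
    """
    X = _as_sample_matrix(X)
    radii = pdist(X)
    radii.sort(kind="stable")
    M = radii.size
    if convention == "exclusive":
        cdf = np.arange(M, dtype=float) / M
    elif convention == "inclusive":
        cdf = np.arange(1, M + 1, dtype=float) / M
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return EmpiricalCDF(radii, cdf)


def subsample_cdf(
    ecdf: EmpiricalCDF, max_points: int = 1000, seed=None
) -> EmpiricalCDF:
    """Uniform random subset of CDF points, ascending order preserved.

    Returns the input unchanged when it already has at most
    ``max_points`` points.  ``seed`` may be an int or a
    ``numpy.random.Generator``.
    """
    if max_points < 2:
        raise ValueError("max_points must be >= 2")
    M = len(ecdf)
    if M <= max_points:
        return ecdf
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(M, size=max_points, replace=False))
    return EmpiricalCDF(ecdf.radii[idx], ecdf.cdf[idx])


def corr_dim(
    X, cdf_ceiling: float = 0.1, min_points: int = 10
) -> float:
    """Grassberger-Procaccia correlation dimension of a sample.

    Fits the slope of log rho_X(r) versus log r over the pairs whose
    cumulative fraction lies in (0, cdf_ceiling]; the slope is the ID
    estimate.

    Raises
    ------
    ValueError
        If fewer than ``min_points`` pair distances fall in the fitting
        window; enlarge ``cdf_ceiling`` or add samples.
    """
    ecdf = empirical_cdf(X)
    mask = (ecdf.cdf > 0) & (ecdf.cdf <= cdf_ceiling) & (ecdf.radii > 0)
    if int(mask.sum()) < min_points:
        raise ValueError(
            f"only {int(mask.sum())} pair distances with cdf in (0, "
            f"{cdf_ceiling}]; increase cdf_ceiling (or the sample size)"
        )
    slope, _ = np.polyfit(np.log(ecdf.radii[mask]), np.log(ecdf.cdf[mask]), 1)
    return float(slope)


class CorrelationDimension(BaseEstimator):
    """Grassberger-Procaccia correlation-dimension estimator.

    Baseline geometric estimator: least-squares slope of the empirical
    correlation integral in log-log scale over its small-radius part.

    Parameters
    ----------
    cdf_ceiling : float, default 0.1
        Upper bound on the cumulative pair fraction defining the
        "small radius" fitting window.
    min_points : int, default 10
        Minimum number of pair distances required inside the window.

    Attributes
    ----------
    dimension_ : float
        Estimated intrinsic dimension (the log-log slope).
    n_pairs_used_ : int
        Number of pair distances inside the fitting window.
    """

    def __init__(self, cdf_ceiling: float = 0.1, min_points: int = 10):
        self.cdf_ceiling = cdf_ceiling
        self.min_points = min_points

    def fit(self, X, y=None):
        X = _as_sample_matrix(X)
        self.dimension_ = corr_dim(X, self.cdf_ceiling, self.min_points)
        ecdf = empirical_cdf(X)
        mask = (ecdf.cdf > 0) & (ecdf.cdf <= self.cdf_ceiling) & (ecdf.radii > 0)
        self.n_pairs_used_ = int(mask.sum())
        return self
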