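"""Multiscale (local) FCI analysis for curved and multidimensional data.

The global estimator is exact only for linearly embedded data; strong
intrinsic curvature inflates it towards the embedding dimension.  The
multiscale variant estimates the dimension *locally*: around a centre
x_0 it gathers the points closer than a cutoff r_c (equivalently, the k
nearest neighbours) and runs the global estimator on that neighbourhood,
giving a curve d_{x0}(r_c) per centre.

Three regimes are typical: at very small cutoffs the estimate is
unreliable (too few neighbours, below ``n_min``); at very large cutoffs
it converges to the global estimate; in between, a densely sampled
manifold shows a plateau at the local dimension.  Centres in flat
regions plateau at the true intrinsic dimension while highly curved
regions overestimate, so the *minimum* local estimate over centres and
valid scales is used as the dimension estimator; an explicit plateau
detector additionally exposes multiple dimensionalities in mixed data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .global_estimator import estimate_id

__all__ = [
    "ScalePoint",
    "MultiscaleCurve",
    "local_subset",
    "multiscale_curve",
    "minimum_plateau_estimate",
    "plateau_modes",
    "MultiscaleFCI",
]


@dataclass(frozen=True)
class ScalePoint:
    """Local estimate at one scale: cutoff, neighbour count, dimension."""

    r_c: float
    n: int
    d_est: float | None  # None when n < n_min or the local fit failed


@dataclass
class MultiscaleCurve:
    """Local-dimension curve d_{x0}(r_c) for one centre."""

    center_index: int
    points: list[ScalePoint] = field(default_factory=list)
    n_min: int = 20

    def valid_points(self) -> list[ScalePoint]:
        return [p for p in self.points if p.d_est is not None]


def local_subset(X, center_index: int, r_c: float) -> np.ndarray:
    """Rows of X strictly closer than ``r_c`` to the centre, centre excluded.

    The centre itself is excluded so that it does not bias the centroid
    of the local preprocessing step.  May be empty.
    """
    X = np.asarray(X, dtype=float)
    if not 0 <= center_index < X.shape[0]:
        raise IndexError(f"center_index {center_index} out of range")
    dists = np.linalg.norm(X - X[center_index], axis=1)
    mask = dists < r_c
    mask[center_index] = False
    return X[mask]


def _default_radius_grid(dists_from_center, n_min, n_scales):
    """Geometric grid from the n_min-th NN distance of the centre up to
    (just past) its farthest point, so the top scale holds everything."""
    sorted_d = np.sort(dists_from_center)
    sorted_d = sorted_d[sorted_d > 0]
    # nudge past the n_min-th neighbour so the strict cutoff keeps it
    lo = sorted_d[min(n_min, len(sorted_d)) - 1] * (1.0 + 1e-9)
    hi = sorted_d[-1] * 1.0001
    if lo <= 0 or lo >= hi:
        lo = hi / 100.0
    return np.geomspace(lo, hi, num=n_scales)


def multiscale_curve(
    X,
    center_index: int,
    scales=None,
    kind: str = "radius",
    n_scales: int = 24,
    n_min: int = 20,
    max_points: int = 1000,
    m_max: float | None = None,
    seed=None,
) -> MultiscaleCurve:
    """Local-dimension curve around one centre.

    Parameters
    ----------
    X : array_like, shape (N, D)
        Sample matrix.
    center_index : int
        Row index of the centre x_0.
    scales : array_like, optional
        Explicit scale grid: cutoff radii (``kind="radius"``) or
        neighbour counts (``kind="knn"``).  When omitted, a geometric
        grid of ``n_scales`` steps is built — radii between the
        n_min-th neighbour distance of the centre and its farthest
        point, or counts between ``n_min`` and N - 1.
    kind : {"radius", "knn"}
        Whether scales are cutoff radii or neighbour counts (the two
        parameterisations are monotonically equivalent).
    n_min : int, default 20
        Validity floor: below this many neighbours the local fit is
        skipped and the point recorded with ``d_est=None``.
    max_points : int, default 1000
        Neighbourhoods larger than this are randomly subsampled
        (seeded) before the local fit, bounding the cost per scale.
    m_max : float, optional
        Bound on the local sphere dimension (defaults to ambient + 1).
    seed : int or numpy.random.Generator, optional
        Drives neighbourhood subsampling and the local fits.
    """
    X = np.asarray(X, dtype=float)
    N = X.shape[0]
    if not 0 <= center_index < N:
        raise IndexError(f"center_index {center_index} out of range")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dists = np.linalg.norm(X - X[center_index], axis=1)
    order = np.argsort(dists, kind="stable")  # order[0] is the centre itself

    if kind == "radius":
        if scales is None:
            scales = _default_radius_grid(dists, n_min, n_scales)
        scales = np.asarray(scales, dtype=float)
        if scales.size == 0:
            raise ValueError("empty scale grid")
        subsets = []
        for r_c in scales:
            mask = dists < r_c
            mask[center_index] = False
            subsets.append((float(r_c), np.flatnonzero(mask)))
    elif kind == "knn":
        if scales is None:
            scales = np.unique(
                np.geomspace(n_min, max(N - 1, n_min + 1), num=n_scales).astype(int)
            )
        scales = np.asarray(scales, dtype=int)
        if scales.size == 0:
            raise ValueError("empty scale grid")
        neighbours = order[1:]  # ascending distance, centre removed
        subsets = []
        for k in scales:
            k = int(min(k, N - 1))
            idx = neighbours[:k]
            subsets.append((float(dists[idx[-1]]), idx))
    else:
        raise ValueError(f"kind must be 'radius' or 'knn', got {kind!r}")

    curve = MultiscaleCurve(center_index=center_index, n_min=n_min)
    for r_c, idx in subsets:
        n = len(idx)
        d_est = None
        if n >= n_min:
            if n > max_points:
                idx = rng.choice(idx, size=max_points, replace=False)
            try:
                est = estimate_id(
                    X[idx],
                    m_max=m_max,
                    seed=rng,
                )
                d_est = est.d_est
            except (ValueError, RuntimeError):
                d_est = None
        curve.points.append(ScalePoint(r_c=r_c, n=n, d_est=d_est))
    return curve


def minimum_plateau_estimate(curves) -> float:
    """Minimum defined local estimate over all centres and valid scales.

    The heuristic dimension estimator for curved manifolds: centres in
    flat regions reach the lowest (correct) plateau, while curvature
    only pushes local estimates up.
    """
    values = [p.d_est for c in curves for p in c.valid_points()]
    if not values:
        raise ValueError(
            "no valid local estimate in any curve; use a denser scale "
            "grid, more samples, or a smaller n_min"
        )
    return float(min(values))


def _runs(values, flatness_tol, min_run):
    """(median, length) of maximal flat runs in one sequence of estimates."""
    runs = []
    i = 0
    n = len(values)
    while i < n:
        j = i + 1
        lo = hi = values[i]
        while j < n:
            new_lo = min(lo, values[j])
            new_hi = max(hi, values[j])
            if (new_hi - new_lo) > flatness_tol * new_lo:
                break
            lo, hi = new_lo, new_hi
            j += 1
        if j - i >= min_run:
            runs.append((float(np.median(values[i:j])), j - i))
            i = j
        else:
            i += 1
    return runs


def _weighted_median(values, weights):
    order = np.argsort(values)
    values = np.asarray(values, dtype=float)[order]
    cum = np.cumsum(np.asarray(weights, dtype=float)[order])
    return float(values[np.searchsorted(cum, 0.5 * cum[-1])])


def _split_wide(cluster, flatness_tol):
    """Recursively split a cluster whose relative width exceeds 3x the
    flatness tolerance at its largest internal relative gap (guards
    against chains of transient runs bridging two true plateaus)."""
    values = [v for v, _ in cluster]
    if min(values) <= 0 or (max(values) - min(values)) <= 3 * flatness_tol * min(values):
        return [cluster]
    gaps = np.diff(values) / np.asarray(values[:-1])
    cut = int(np.argmax(gaps)) + 1
    return _split_wide(cluster[:cut], flatness_tol) + _split_wide(
        cluster[cut:], flatness_tol
    )


def plateau_modes(
    curves,
    flatness_tol: float = 0.1,
    min_run: int = 3,
    min_weight: float = 0.25,
) -> list[float]:
    """Plateau heights across a family of multiscale curves.

    Per curve, finds maximal runs of at least ``min_run`` consecutive
    valid scales whose estimates stay within ``flatness_tol`` relative
    spread, and records each run's median together with its length.
    Run medians from all centres are then clustered on the line
    (single linkage; gaps above ``flatness_tol`` relative start a new
    cluster, and clusters wider than three times the tolerance are
    split at their largest internal gap).  Each cluster is summarised
    by the run-length-weighted median of its members — true plateaus
    span many scales while rising or falling transients only form short
    runs, so weighting by length makes the modes insensitive to
    transients.  Clusters carrying less than ``min_weight`` of the
    heaviest cluster's total run length are discarded as spurious
    (isolated dips or small-neighbourhood spikes).  Modes are returned
    sorted ascending; mixed-dimension datasets show one mode per
    component, and an empty list means no plateau was found.
    """
    if not curves:
        raise ValueError("need at least one curve")
    runs: list[tuple[float, int]] = []
    for curve in curves:
        # validity gaps break runs: split on None before scanning
        segment: list[float] = []
        for p in curve.points:
            if p.d_est is None:
                if segment:
                    runs.extend(_runs(segment, flatness_tol, min_run))
                segment = []
            else:
                segment.append(p.d_est)
        if segment:
            runs.extend(_runs(segment, flatness_tol, min_run))
    if not runs:
        return []
    runs.sort()
    clusters = [[runs[0]]]
    for value, length in runs[1:]:
        if value - clusters[-1][-1][0] > flatness_tol * clusters[-1][-1][0]:
            clusters.append([(value, length)])
        else:
            clusters[-1].append((value, length))
    clusters = [part for c in clusters for part in _split_wide(c, flatness_tol)]
    weights = [sum(w for _, w in c) for c in clusters]
    floor = min_weight * max(weights)
    return sorted(
        _weighted_median([v for v, _ in c], [w for _, w in c])
        for c, weight in zip(clusters, weights)
        if weight >= floor
    )


class MultiscaleFCI(BaseEstimator):
    """Multiscale local FCI intrinsic dimension estimator.

    Runs the global FCI estimator on neighbourhoods of growing scale
    around several centres, then summarises the resulting family of
    local-dimension curves by (i) the minimum valid local estimate
    (dimension of curved manifolds) and (ii) plateau modes
    (dimensionalities of mixed data).

    Parameters
    ----------
    n_centers : int, default 10
        Number of centres drawn uniformly at random (ignored when
        ``centers`` is given).
    centers : sequence of int, optional
        Explicit centre row indices.
    scale_kind : {"radius", "knn"}, default "radius"
        Scan neighbourhoods by cutoff radius or by neighbour count.
    n_scales : int, default 24
        Geometric scale-grid resolution per centre.
    n_min : int, default 20
        Minimum neighbour count for a local estimate to be valid.
    max_points : int, default 1000
        Cap on neighbourhood size fed to each local fit (larger
        neighbourhoods are randomly subsampled).
    m_max : float, optional
        Bound on the local sphere dimension (default ambient + 1).
    flatness_tol : float, default 0.1
        Relative spread defining a flat run and a mode cluster.
    min_run : int, default 3
        Minimum number of consecutive flat scales forming a plateau.
    random_state : int or Generator, optional
        Seed for centre choice, subsampling, and local fits.

    Attributes
    ----------
    dimension_ : float
        Minimum valid local estimate over all centres and scales.
    dimension_rounded_ : int
    plateau_modes_ : list of float
        Detected plateau heights, ascending (may be empty).
    curves_ : list of MultiscaleCurve
        Full per-centre curves for inspection or plotting.
    centers_ : ndarray of int
        Centre indices actually used.
    """

    def __init__(
        self,
        n_centers: int = 10,
        centers=None,
        scale_kind: str = "radius",
        n_scales: int = 24,
        n_min: int = 20,
        max_points: int = 1000,
        m_max: float | None = None,
        flatness_tol: float = 0.1,
        min_run: int = 3,
        min_mode_weight: float = 0.25,
        random_state=None,
    ):
        self.n_centers = n_centers
        self.centers = centers
        self.scale_kind = scale_kind
        self.n_scales = n_scales
        self.n_min = n_min
        self.max_points = max_points
        self.m_max = m_max
        self.flatness_tol = flatness_tol
        self.min_run = min_run
        self.min_mode_weight = min_mode_weight
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 3:
            raise ValueError("need a 2-D matrix with at least 3 samples")
        rng = (
            self.random_state
            if isinstance(self.random_state, np.random.Generator)
            else np.random.default_rng(self.random_state)
        )
        if self.centers is not None:
            centers = np.asarray(self.centers, dtype=int)
        else:
            centers = rng.choice(
                X.shape[0], size=min(self.n_centers, X.shape[0]), replace=False
            )
        self.centers_ = centers
        self.curves_ = [
            multiscale_curve(
                X,
                int(c),
                kind=self.scale_kind,
                n_scales=self.n_scales,
                n_min=self.n_min,
                max_points=self.max_points,
                m_max=self.m_max,
                seed=rng,
            )
            for c in centers
        ]
        self.dimension_ = minimum_plateau_estimate(self.curves_)
        self.dimension_rounded_ = int(round(self.dimension_))
        self.plateau_modes_ = plateau_modes(
            self.curves_, self.flatness_tol, self.min_run, self.min_mode_weight
        )
        return self
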