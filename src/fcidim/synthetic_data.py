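"""Seeded generators for the synthetic manifold families used in validation.

Families (rows are samples):

- binary cube  D_{d,D}:   uniform on the vertex set {0,1}^d, linearly embedded
- gaussian     G_{d,D}:   standard multivariate normal in R^d, linearly embedded
- hypercube    H_{d,D}:   uniform on [0,1]^d, linearly embedded
- curved       C_{d,2d}:  uniform on [0,2pi]^d pushed through a cyclic
                          polar-coordinate map into R^{2d} (strong curvature)
- swiss roll   SR_{2,3}:  uniform [0,1]^2 rolled into R^3
- two cubes:              union of two co-centred hypercube datasets of
                          different intrinsic dimension (multidimensional data)
- blobs        B_{5n,81^2}: 81x81 high-contrast bitmap images of n elliptic
                          blobs, 5 degrees of freedom each (translation x2,
                          size, eccentricity, orientation)

A *linear embedding* appends D - d zero coordinates and applies a Haar-random
rotation of R^D; it is an exact isometry, so pairwise distances (and hence the
correlation integral) are untouched.  All generators are deterministic under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BlobParams",
    "haar_rotation",
    "linear_embed",
    "gen_binary_cube",
    "gen_gaussian",
    "gen_hypercube",
    "gen_curved",
    "gen_swiss_roll",
    "gen_two_cubes",
    "add_noise",
    "render_blob",
    "gen_blob_images",
]


@dataclass(frozen=True)
class BlobParams:
    """Degrees of freedom of one high-contrast elliptic blob.

    Attributes
    ----------
    l : int
        Bitmap side in pixels; odd, >= 3 (the pixel lattice is centred).
    dx, dy : float
        Horizontal / vertical translation in pixels.
    s : float
        Size (scale of the ellipse), > 0.
    e : float
        Eccentricity of the ellipse, > 0.
    theta : float
        Angle of the major axis, radians.
    """

    l: int
    dx: float
    dy: float
    s: float
    e: float
    theta: float

    def __post_init__(self) -> None:
        if self.l < 3 or self.l % 2 == 0:
            raise ValueError(f"bitmap side must be odd and >= 3, got {self.l}")
        if self.s <= 0:
            raise ValueError(f"size must be positive, got {self.s}")
        if self.e <= 0:
            raise ValueError(f"eccentricity must be positive, got {self.e}")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def haar_rotation(D: int, seed=None) -> np.ndarray:
    """Rotation matrix drawn from the Haar measure on SO(D).

    QR decomposition of a Gaussian matrix with the R-diagonal sign fix,
    then determinant forced to +1 by flipping the last column if needed.
    """
    rng = _rng(seed)
    A = rng.standard_normal((D, D))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, -1] *= -1
    return Q


def linear_embed(X, D: int, seed=None) -> np.ndarray:
    """Embed an N x d matrix isometrically into R^D.

    Appends D - d zero columns, then applies one Haar-random rotation of
    the ambient space.  Pairwise distances are preserved exactly.
    """
    X = np.asarray(X, dtype=float)
    N, d = X.shape
    if D < d:
        raise ValueError(f"ambient dimension {D} smaller than intrinsic {d}")
    padded = np.zeros((N, D))
    padded[:, :d] = X
    return padded @ haar_rotation(D, seed).T


def gen_binary_cube(N: int, d: int, D: int, seed=None) -> np.ndarray:
    """Uniform sample of the vertex set {0,1}^d, linearly embedded in R^D."""
    rng = _rng(seed)
    return linear_embed(rng.integers(0, 2, size=(N, d)).astype(float), D, rng)


def gen_gaussian(N: int, d: int, D: int, seed=None) -> np.ndarray:
    """Standard isotropic Gaussian in R^d, linearly embedded in R^D."""
    rng = _rng(seed)
    return linear_embed(rng.standard_normal((N, d)), D, rng)


def gen_hypercube(N: int, d: int, D: int, seed=None) -> np.ndarray:
    """Uniform sample of [0,1]^d, linearly embedded in R^D."""
    rng = _rng(seed)
    return linear_embed(rng.uniform(0.0, 1.0, size=(N, d)), D, rng)


def gen_curved(N: int, d: int, seed=None) -> np.ndarray:
    """Strongly curved d-manifold in R^{2d}.

    x ~ U[0, 2pi]^d is mapped through the cyclic polar map whose i-th
    coordinate pair is (x_{i+1} cos x_i, x_{i+1} sin x_i), indices mod d
    (so the last pair is (x_1 cos x_d, x_1 sin x_d)).  The image is a
    d-dimensional manifold whose curvature defeats global estimators.
    """
    rng = _rng(seed)
    x = rng.uniform(0.0, 2.0 * np.pi, size=(N, d))
    out = np.empty((N, 2 * d))
    for i in range(d):
        radius = x[:, (i + 1) % d]
        out[:, 2 * i] = radius * np.cos(x[:, i])
        out[:, 2 * i + 1] = radius * np.sin(x[:, i])
    return out


def gen_swiss_roll(N: int, seed=None) -> np.ndarray:
    """Swiss roll: (x, y) ~ U[0,1]^2 mapped to (x cos 2pi*y, y, x sin 2pi*y)."""
    rng = _rng(seed)
    x = rng.uniform(size=N)
    y = rng.uniform(size=N)
    return np.column_stack([x * np.cos(2 * np.pi * y), y, x * np.sin(2 * np.pi * y)])


def gen_two_cubes(
    N1: int, N2: int, d1: int, d2: int, D: int, seed=None
):
    """Union of two intersecting hypercube datasets of different dimension.

    Each component is a uniform [0,1]^{d_i} sample centred at the origin
    (so the two cubes intersect there) and independently Haar-rotated in
    R^D.

    Returns
    -------
    (ndarray, ndarray)
        The stacked (N1 + N2) x D matrix and an int label array
        (0 for the first cube, 1 for the second).
    """
    rng = _rng(seed)
    parts = []
    for N, d in ((N1, d1), (N2, d2)):
        cube = rng.uniform(size=(N, d)) - 0.5
        parts.append(linear_embed(cube, D, rng))
    labels = np.repeat([0, 1], [N1, N2])
    return np.vstack(parts), labels


def add_noise(X, sigma: float, seed=None) -> np.ndarray:
    """Add i.i.d. centred Gaussian noise of s.d. ``sigma`` to every coordinate."""
    X = np.asarray(X, dtype=float)
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return X.copy()
    rng = _rng(seed)
    return X + rng.normal(0.0, sigma, size=X.shape)


def render_blob(params: BlobParams) -> np.ndarray:
    """Render one elliptic blob on a centred l x l pixel lattice.

    With lattice coordinates i (row) and j (column) running over
    {-(l-1)/2, ..., (l-1)/2}:

        a = cos(theta) (j - dx) + sin(theta) (i + dy)
        b = -sin(theta) (j - dx) + cos(theta) (i + dy)
        v = 1 - sqrt((a^2 + e^2 b^2) / ((1 + e^2) s^2))

    and finally every pixel with value below 0.01 is set to 0, producing
    a high-contrast image with values in [0, 1].  The lattice is centred
    because the translation range (+-20 px at s <= 3 on an 81 px bitmap)
    only keeps blobs inside the frame when the origin sits mid-frame.
    """
    half = (params.l - 1) // 2
    coords = np.arange(-half, half + 1, dtype=float)
    i, j = np.meshgrid(coords, coords, indexing="ij")
    ct, st = np.cos(params.theta), np.sin(params.theta)
    a = ct * (j - params.dx) + st * (i + params.dy)
    b = -st * (j - params.dx) + ct * (i + params.dy)
    v = 1.0 - np.sqrt((a * a + params.e**2 * b * b) / ((1 + params.e**2) * params.s**2))
    v[v < 0.01] = 0.0
    return v


def draw_blob_params(seed=None, l: int = 81) -> BlobParams:
    """Draw one parameter set from the validation ranges.

    dx, dy ~ U(-20, 20); s ~ U(1, 3); e ~ U(5, 10); theta ~ U(-pi/2, pi/2).
    """
    rng = _rng(seed)
    return BlobParams(
        l=l,
        dx=rng.uniform(-20.0, 20.0),
        dy=rng.uniform(-20.0, 20.0),
        s=rng.uniform(1.0, 3.0),
        e=rng.uniform(5.0, 10.0),
        theta=rng.uniform(-np.pi / 2.0, np.pi / 2.0),
    )


def gen_blob_images(
    N: int, n_blobs: int = 1, seed=None, l: int = 81, return_params: bool = False
):
    """Dataset of N flattened l x l images of ``n_blobs`` summed blobs.

    Each image is the pixel-wise sum of ``n_blobs`` independently drawn
    single-blob images (5 degrees of freedom per blob), flattened
    row-major into an l^2 vector.  With l = 81 the ambient dimension is
    6561 while the intrinsic dimension is 5 * n_blobs.
    """
    rng = _rng(seed)
    X = np.zeros((N, l * l))
    params: list[list[BlobParams]] = []
    for row in range(N):
        draws = [draw_blob_params(rng, l) for _ in range(n_blobs)]
        image = sum(render_blob(p) for p in draws)
        X[row] = image.ravel()
        params.append(draws)
    if return_params:
        return X, params
    return X


FAMILIES = {
    "binary_cube": gen_binary_cube,
    "gaussian": gen_gaussian,
    "hypercube": gen_hypercube,
    "curved": gen_curved,
    "swiss_roll": gen_swiss_roll,
    "two_cubes": gen_two_cubes,
    "blobs": gen_blob_images,
}
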