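"""Spherical geometry helpers and spatial-autocorrelation diagnostics.

Region centroids live on the unit sphere (one hemisphere); angular distance
between centroids is the natural metric both for generating spatially smooth
maps and for checking that rotation-based null maps preserve smoothness.
"""

from __future__ import annotations

import numpy as np


def angular_distance_matrix(xyz: np.ndarray) -> np.ndarray:
    """Pairwise great-circle (angular) distances, in radians.

    Parameters
    ----------
    xyz : (n, 3) array of unit vectors.
    """
    xyz = np.asarray(xyz, dtype=float)
    cos = np.clip(xyz @ xyz.T, -1.0, 1.0)
    return np.arccos(cos)


def knn_weight_matrix(xyz: np.ndarray, k: int = 6) -> np.ndarray:
    """Symmetrized k-nearest-neighbour binary spatial weights.

    Used only as a diagnostic backbone for Moran's I; row-standardization is
    not applied (the I formula normalizes by the total weight).
    """
    n = xyz.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of points ({n})")
    theta = angular_distance_matrix(xyz)
    np.fill_diagonal(theta, np.inf)
    w = np.zeros((n, n))
    idx = np.argsort(theta, axis=1)[:, :k]
    rows = np.repeat(np.arange(n), k)
    w[rows, idx.ravel()] = 1.0
    return np.maximum(w, w.T)


def morans_i(values: np.ndarray, weights: np.ndarray) -> float:
    """Moran's I spatial autocorrelation of a regional map.

    I = (n / sum(W)) * (z' W z) / (z' z) with z the centered map. Values near
    0 indicate no spatial structure; positive values indicate smoothness.
    """
    z = np.asarray(values, dtype=float)
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError("constant map: Moran's I undefined")
    n = z.size
    s0 = weights.sum()
    return float(n / s0 * (z @ weights @ z) / denom)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3-D rotation matrix (Haar measure).

    QR decomposition of a Gaussian matrix, with the sign of R's diagonal
    absorbed so Q is uniform; determinant fixed to +1 by negating the first
    column of any reflection.
    """
    a = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
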