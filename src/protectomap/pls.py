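"""PLS of a regional outcome map on regional gene expression.

Univariate-response partial least squares with deflation (NIPALS): each
component's gene weight vector is proportional to X'y on the deflated
matrices, giving region scores t = Xw that maximize covariance with the
outcome. Per-component significance comes from spin permutations — random
3-D rotations of the region centroids on the sphere with nearest-neighbour
reassignment, which scramble the outcome map while preserving its spatial
autocorrelation. Gene contributions are ranked by bootstrap ratios: the
empirical weight divided by its standard error under resampling regions
with replacement, interpreted like z-scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .spatial import random_rotation

logger = logging.getLogger(__name__)


@dataclass
class PLSModel:
    """Fitted components of a univariate-response PLS."""

    genes: np.ndarray
    weights: np.ndarray          # (n_genes, k), unit-norm columns
    scores: np.ndarray           # (n_regions, k), region scores t_k
    y_loadings: np.ndarray       # (k,), regression of y on t_k
    var_explained: np.ndarray    # (k,), fraction of y variance per component
    n_components: int

    @property
    def cumulative_var(self) -> np.ndarray:
        return np.cumsum(self.var_explained)


def _prepare(X: np.ndarray, y: np.ndarray, scale_x: bool):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X rows and y length differ")
    if y.std() == 0:
        raise ValueError("constant outcome vector")
    Xc = X - X.mean(axis=0)
    if scale_x:
        sd = Xc.std(axis=0)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    yc = y - y.mean()
    return Xc, yc


def _fit_components(Xc: np.ndarray, yc: np.ndarray, k: int):
    """Core deflation loop on centered (and scaled) inputs.

    Returns (weights, scores, y_loadings, var_explained, saliences):
    ``weights`` are the unit-norm direction vectors, ``saliences`` the
    unnormalized X'y covariance vectors on the deflated matrices (the
    quantity the bootstrap resamples). Component signs are fixed so
    corr(t_k, y) >= 0.
    """
    n, m = Xc.shape
    W = np.empty((m, k))
    V = np.empty((m, k))
    T = np.empty((n, k))
    c = np.empty(k)
    frac = np.empty(k)
    ss_y = float(yc @ yc)
    Xd, yd = Xc.copy(), yc.copy()
    for j in range(k):
        v = Xd.T @ yd
        norm = np.linalg.norm(v)
        if norm == 0:
            # outcome orthogonal to every remaining column: degenerate direction
            w = np.zeros(m)
            w[0] = 1.0
        else:
            w = v / norm
        t = Xd @ w
        tt = float(t @ t)
        if tt == 0:
            raise ValueError(f"rank exhausted at component {j + 1}")
        ty = float(t @ yc)
        if ty < 0:
            w, v, t, ty = -w, -v, -t, -ty
        W[:, j] = w
        V[:, j] = v
        T[:, j] = t
        c[j] = ty / tt
        frac[j] = ty ** 2 / (tt * ss_y)
        Xd = Xd - np.outer(t, (t @ Xd) / tt)
        yd = yd - t * (float(t @ yd) / tt)
    return W, T, c, frac, V


def pls_fit(X: pd.DataFrame, y: pd.Series | np.ndarray,
            n_components: int = 3, scale_x: bool = True) -> PLSModel:
    """Fit PLS of a regional outcome on a regions x genes matrix.

    Components are extracted by deflation; the per-component statistic is
    the fraction of outcome variance explained (the quantity the spin test
    compares), and the sign convention makes corr(t_k, y) >= 0.
    """
    genes = X.columns.to_numpy() if isinstance(X, pd.DataFrame) else np.arange(X.shape[1])
    Xc, yc = _prepare(np.asarray(X, dtype=float), np.asarray(y, dtype=float), scale_x)
    rank = np.linalg.matrix_rank(Xc)
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank(X)={rank}")
    W, T, c, frac, _ = _fit_components(Xc, yc, n_components)
    return PLSModel(genes=genes, weights=W, scores=T, y_loadings=c,
                    var_explained=frac, n_components=n_components)


# ---------------------------------------------------------------------------
# spin permutations
# ---------------------------------------------------------------------------

@dataclass
class SpinNulls:
    """Rotation-based permutation indices: row p maps region i -> perm[p, i]."""

    perm: np.ndarray    # (n_perm, n_regions) integer reassignments
    seed: int

    @property
    def n_perm(self) -> int:
        return self.perm.shape[0]


def _spin_indices(xyz: np.ndarray, rot: np.ndarray) -> np.ndarray:
    """perm[i] = region whose rotated centroid lies nearest (by angle) to
    region i, so ``y[perm]`` is the rotated map sampled at the original
    centroids."""
    rotated = xyz @ rot.T
    return np.argmax(xyz @ rotated.T, axis=1)


def spin_permutations(geom: pd.DataFrame, n_perm: int, seed: int) -> SpinNulls:
    """Spherical-rotation null reassignments for one hemisphere.

    Each permutation draws a uniform random rotation, rotates all centroids,
    and reassigns every original region to its nearest rotated centroid
    (duplicates allowed). Applying ``y[perm[p]]`` yields a map with the same
    spatial autocorrelation structure but random alignment.
    """
    if geom["hemisphere"].nunique() != 1:
        raise ValueError("spin permutations require a single-hemisphere geometry")
    if n_perm < 100:
        warnings.warn("n_perm < 100: spin p-values will be unstable")
    xyz = geom[["sx", "sy", "sz"]].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    n = xyz.shape[0]
    perm = np.empty((n_perm, n), dtype=np.intp)
    for p in range(n_perm):
        perm[p] = _spin_indices(xyz, random_rotation(rng))
    coverage = np.array([np.unique(row).size for row in perm])
    logger.info("spin nulls: mean multiset coverage %.1f%% of regions",
                100 * coverage.mean() / n)
    return SpinNulls(perm=perm, seed=seed)


def lv_significance(model: PLSModel, X: pd.DataFrame, y,
                    nulls: SpinNulls, scale_x: bool = True) -> np.ndarray:
    """Per-component spin p-values for the fraction of y variance explained.

    For each null, the outcome map is permuted by the spin indices and the
    PLS refitted; p_k = (1 + #{null frac_k >= empirical frac_k}) / (1 + P).
    """
    Xc, yc = _prepare(np.asarray(X, dtype=float), np.asarray(y, dtype=float), scale_x)
    k = model.n_components
    emp = model.var_explained
    y_arr = np.asarray(y, dtype=float).ravel()
    if k == 1:
        # fully vectorized: for each permuted outcome y_p,
        # frac_1 = corr(X w_p, y_p)^2 with w_p prop. X'y_p
        Yp = y_arr[nulls.perm.T]                  # (n_regions, n_perm)
        Yp = Yp - Yp.mean(axis=0)
        Wn = Xc.T @ Yp                            # (n_genes, n_perm)
        Tn = Xc @ Wn                              # (n_regions, n_perm)
        ty = (Tn * Yp).sum(axis=0)                # (n_perm,)
        tt = (Tn ** 2).sum(axis=0)
        ss_yp = (Yp ** 2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where((tt > 0) & (ss_yp > 0),
                            ty ** 2 / (tt * ss_yp), 0.0)
        null_frac = frac[:, None]
    else:
        null_frac = np.empty((nulls.n_perm, k))
        for p in range(nulls.n_perm):
            yp = y_arr[nulls.perm[p]]
            yp = yp - yp.mean()
            try:
                frac = _fit_components(Xc, yp, k)[3]
            except ValueError:
                frac = np.full(k, np.nan)
            null_frac[p] = frac
    valid = np.isfinite(null_frac).all(axis=1)
    nf = null_frac[valid]
    return (1 + (nf >= emp[None, :]).sum(axis=0)) / (1 + nf.shape[0])


# ---------------------------------------------------------------------------
# bootstrap gene ratios
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Per-gene bootstrap statistics for the retained components.

    ``weight`` holds the empirical unnormalized saliences (X'y covariance on
    the deflated matrices): bootstrapping the unit-normalized direction
    instead would deflate the standard errors, because the replicate norm is
    inflated by the resampling noise pooled over all genes.
    """

    genes: np.ndarray
    components: tuple[int, ...]     # 1-based component indices
    weight: np.ndarray              # (n_genes, len(components)) empirical saliences
    se: np.ndarray                  # bootstrap SEs
    ratio: np.ndarray               # weight / se
    n_boot: int
    n_redrawn: int

    def ranked_scores(self, component: int) -> pd.Series:
        """Bootstrap ratios of one (1-based) component, ranked descending."""
        j = self.components.index(component)
        s = pd.Series(self.ratio[:, j], index=self.genes, name="bootstrap_ratio")
        return s.sort_values(ascending=False, kind="mergesort")


def bootstrap_gene_weights(X: pd.DataFrame, y, component_set=(1,),
                           n_boot: int = 5000, seed: int = 0,
                           scale_x: bool = True) -> BootstrapResult:
    """Bootstrap SEs and ratios for gene weights of selected components.

    Regions are resampled with replacement (X rows and y jointly); each
    replicate's components are sign-aligned to the empirical region scores
    before accumulating. Replicates with a degenerate (constant) resampled
    outcome are redrawn and counted.
    """
    components = tuple(sorted(int(c) for c in component_set))
    if components[0] < 1:
        raise ValueError("components are 1-based")
    k = components[-1]
    Xc, yc = _prepare(np.asarray(X, dtype=float), np.asarray(y, dtype=float), scale_x)
    model = pls_fit(X, y, n_components=k, scale_x=scale_x)
    *_, emp_v = _fit_components(Xc, yc, k)
    n = Xc.shape[0]
    cols = [c - 1 for c in components]
    emp_w = emp_v[:, cols]
    emp_t = model.scores

    rng = np.random.default_rng(seed)
    acc = np.zeros((n_boot, Xc.shape[1], len(cols)))
    n_redrawn = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        yb = yc[idx]
        if yb.std() == 0:
            n_redrawn += 1
            continue
        Xb = Xc[idx]
        try:
            _, Tb, _, _, Vb = _fit_components(Xb - Xb.mean(axis=0),
                                              yb - yb.mean(), k)
        except ValueError:
            n_redrawn += 1
            continue
        for out_j, comp_j in enumerate(cols):
            sign = np.sign(Tb[:, comp_j] @ emp_t[idx, comp_j]) or 1.0
            acc[b, :, out_j] = sign * Vb[:, comp_j]
        b += 1
    if n_redrawn:
        logger.info("bootstrap: %d degenerate replicates redrawn", n_redrawn)
    se = acc.std(axis=0, ddof=1)
    if (se <= 0).any():
        raise ValueError("zero bootstrap SE for at least one gene")
    return BootstrapResult(genes=model.genes, components=components,
                           weight=emp_w, se=se, ratio=emp_w / se,
                           n_boot=n_boot, n_redrawn=n_redrawn)


def region_score_correlation(model: PLSModel, y, component: int = 1):
    """Pearson r (and two-sided p) between region scores and the outcome."""
    t = model.scores[:, component - 1]
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 3:
        raise ValueError("need at least 3 regions")
    r, p = stats.pearsonr(t, y)
    return float(r), float(p)
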