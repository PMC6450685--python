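"""PCA followed by spatiotemporal ICA for one-photon movie demixing.

The ICA stage maximizes the skewness of a concatenated spatio-temporal
signal: each candidate component contributes (1-mu) x its spatial signature
and mu x its temporal signature, rotated within the PCA subspace by a
fixed-point iteration with symmetric decorrelation.  Calcium signals are
sparse and positively skewed, so skewness is the contrast of choice; the
sign of every component is fixed so its trace skewness is non-negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse.linalg import svds

from ._rng import substream

__all__ = ["PCAResult", "pca_reduce", "ICAComponent", "spatiotemporal_ica",
           "footprints_to_traces", "footprint_centroid"]

logger = logging.getLogger(__name__)


@dataclass
class PCAResult:
    spatial: np.ndarray       # components x H x W
    temporal: np.ndarray      # components x frames
    singular_values: np.ndarray
    mean_frame: np.ndarray    # H x W, removed before factorization


def pca_reduce(movie: np.ndarray, n_components: int) -> PCAResult:
    """Rank-``n_components`` SVD of the mean-centered movie.

    movie is frames x H x W; the pixelwise temporal mean is removed first.
    Singular values are returned in non-increasing order.
    """
    m = np.asarray(movie, dtype=float)
    if m.ndim != 3 or m.shape[0] < 2:
        raise ValueError("movie must be frames x H x W with >= 2 frames")
    if not np.all(np.isfinite(m)):
        raise ValueError("movie contains non-finite values")
    t, h, w = m.shape
    if not 1 <= n_components <= min(t, h * w):
        raise ValueError(f"n_components must be in [1, {min(t, h * w)}]")
    mean_frame = m.mean(axis=0)
    x = (m - mean_frame[None]).reshape(t, h * w)
    # dense SVD for small problems; ARPACK only pays off (and only behaves
    # well) on large full-rank movies with k << min(t, pixels)
    if min(t, h * w) <= 1500 or n_components >= min(t, h * w) - 1:
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    else:
        u, s, vt = svds(x, k=n_components, random_state=0)
        order = np.argsort(s)[::-1]
        u, s, vt = u[:, order], s[order], vt[order]
    return PCAResult(spatial=vt.reshape(n_components, h, w), temporal=u.T,
                     singular_values=s, mean_frame=mean_frame)


@dataclass
class ICAComponent:
    footprint: np.ndarray     # H x W
    trace: np.ndarray         # frames
    centroid: tuple[float, float]


def _sym_decorrelate(w: np.ndarray) -> np.ndarray:
    """W <- (W W^T)^(-1/2) W via eigendecomposition."""
    s, e = np.linalg.eigh(w @ w.T)
    s = np.maximum(s, 1e-12)
    return (e * (1.0 / np.sqrt(s))) @ e.T @ w


def spatiotemporal_ica(pca: PCAResult, mu: float = 0.1, max_iter: int = 500,
                       tol: float = 1e-5, seed: int = 0,
                       footprint_threshold_sd: float = 2.0):
    """Skewness-maximizing rotation of the PCA subspace.

    Returns (components, converged).  ``mu`` in [0, 1] weights the temporal
    term: 0 is purely spatial ICA, 1 purely temporal.
    """
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must lie in [0, 1]")
    k, h, wdt = pca.spatial.shape
    spatial = pca.spatial.reshape(k, h * wdt)
    temporal = pca.temporal
    # centered unit-variance signals: the two domains become commensurate
    # and every joint row has identical norm, so symmetric decorrelation
    # leaves the rotated components exactly orthogonal
    def center_scale(m: np.ndarray) -> np.ndarray:
        c = m - m.mean(axis=1, keepdims=True)
        return c / c.std(axis=1, keepdims=True)

    joint = np.concatenate([(1.0 - mu) * center_scale(spatial),
                            mu * center_scale(temporal)], axis=1)

    # joint whitening: the concatenated signatures are correlated across
    # rows, so whiten their k x k Gram before the orthonormal rotation --
    # this is what makes the final components exactly decorrelated
    gram = joint @ joint.T / joint.shape[1]
    evals, evecs = np.linalg.eigh(gram)
    evals = np.maximum(evals, 1e-12)
    g_inv_half = (evecs * (1.0 / np.sqrt(evals))) @ evecs.T
    g_half = (evecs * np.sqrt(evals)) @ evecs.T
    white = g_inv_half @ joint

    rng = substream(seed, "ica")
    w = _sym_decorrelate(rng.standard_normal((k, k)))
    converged = False
    objective = -np.inf
    for it in range(max_iter):
        y = w @ white
        if not np.all(np.isfinite(y)):
            raise FloatingPointError(f"non-finite ICA update at iteration {it}")
        w = _sym_decorrelate((y ** 2) @ white.T / white.shape[1])
        # convergence on the contrast itself: rotations within the skewness-
        # free noise subspace never settle, but the objective does
        new_objective = float(np.abs((y ** 3).mean(axis=1)).sum())
        delta = abs(new_objective - objective) / max(abs(new_objective), 1e-12)
        objective = new_objective
        if it > 0 and delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("spatiotemporal ICA stopped at max_iter=%d (delta=%.2e)",
                       max_iter, delta)

    unmix = w @ g_inv_half                       # k x k, invertible
    footprints = unmix @ spatial
    traces = (pca.temporal.T * pca.singular_values[None, :]) \
        @ (g_half @ w.T)                         # frames x k, = U S unmix^-1
    components = []
    for i in range(k):
        tr = traces[:, i]
        skew = np.mean((tr - tr.mean()) ** 3)
        sign = -1.0 if skew < 0 else 1.0
        fp = sign * footprints[i].reshape(h, wdt)
        components.append(ICAComponent(
            footprint=fp, trace=sign * tr,
            centroid=footprint_centroid(fp, footprint_threshold_sd)))
    return components, converged


def footprint_centroid(footprint: np.ndarray,
                       threshold_sd: float = 2.0) -> tuple[float, float]:
    """Intensity-weighted centroid of the pixels above threshold_sd SDs of
    the footprint distribution (robust against noisy backgrounds)."""
    fp = np.asarray(footprint, dtype=float)
    thr = fp.mean() + threshold_sd * fp.std()
    mask = fp >= thr
    if not mask.any():
        mask = fp == fp.max()
    weights = np.where(mask, np.clip(fp, 0, None), 0.0)
    total = weights.sum()
    if total == 0:
        weights = mask.astype(float)
        total = weights.sum()
    yy, xx = np.mgrid[0:fp.shape[0], 0:fp.shape[1]]
    return (float((xx * weights).sum() / total),
            float((yy * weights).sum() / total))


def footprints_to_traces(movie: np.ndarray, footprints: np.ndarray) -> np.ndarray:
    """Weighted-mean projection: trace[n, t] = sum_p fp_n(p) movie(t, p) / sum_p fp_n(p)."""
    m = np.asarray(movie, dtype=float)
    fp = np.asarray(footprints, dtype=float)
    if fp.shape[1:] != m.shape[1:]:
        raise ValueError("footprint shape must match movie frames")
    flat = fp.reshape(fp.shape[0], -1)
    sums = flat.sum(axis=1)
    if np.any(sums == 0):
        raise ValueError("degenerate all-zero footprint")
    return (flat @ m.reshape(m.shape[0], -1).T) / sums[:, None]
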