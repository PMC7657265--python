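"""Diffusion map embedding of functional connectivity.

The first nontrivial component of the diffusion operator built on FC
row-similarity is the continuous hierarchy; it is binned into equal-size
classes downstream.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import FunctionalMatrix, HierarchyMap


@dataclass
class EmbeddingResult:
    components: np.ndarray  # (n, m) diffusion coordinates, trivial vector dropped
    eigenvalues: np.ndarray  # (m,) descending, in (0, 1]
    alpha: float
    sigma: float
    orientation_sign: int = 1


def _gaussian_affinity(X: np.ndarray, sigma: float, bandwidth: str) -> np.ndarray:
    d2 = squareform(pdist(X, "sqeuclidean"))
    denom = 2.0 * sigma**2 if bandwidth == "2sig2" else sigma**2
    return np.exp(-d2 / denom)


def _cosine_affinity(X: np.ndarray, row_threshold: float) -> np.ndarray:
    Xt = X.copy()
    thr = np.quantile(Xt, row_threshold, axis=1, keepdims=True)
    Xt[Xt < thr] = 0.0
    norms = np.linalg.norm(Xt, axis=1)
    norms[norms == 0] = 1.0
    K = (Xt @ Xt.T) / np.outer(norms, norms)
    return np.clip(K, 0.0, 1.0)


def diffusion_map(
    fc: FunctionalMatrix,
    alpha: float = 1.0,
    sigma: float = 1.0,
    m: int = 10,
    affinity: str = "gaussian",
    bandwidth: str = "2sig2",
    row_threshold: float = 0.9,
) -> EmbeddingResult:
    """Diffusion map of the FC matrix treated as row feature vectors.

    Steps: Gaussian affinity between FC rows; alpha-normalization
    (alpha=1 removes sampling-density effects); row normalization to a
    Markov operator; eigendecomposition via the symmetric conjugate;
    trivial constant eigenvector dropped; component l = lambda_l psi_l.
    """
    X = fc.values
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 nodes to embed")
    if np.isnan(X).any():
        raise ValueError("FC contains NaN")
    if affinity == "gaussian":
        K = _gaussian_affinity(X, sigma, bandwidth)
    elif affinity == "cosine":
        K = _cosine_affinity(X, row_threshold)
    else:
        raise ValueError(f"unknown affinity: {affinity}")
    if np.allclose(K, K[0, 0], atol=1e-14):
        raise ValueError("degenerate input: all rows identical, no nontrivial component")

    q = K.sum(axis=1)
    K1 = K / np.outer(q**alpha, q**alpha)
    d = K1.sum(axis=1)
    # symmetric conjugate of the Markov operator P = D^-1 K1
    inv_sqrt_d = 1.0 / np.sqrt(d)
    A = K1 * np.outer(inv_sqrt_d, inv_sqrt_d)
    A = (A + A.T) / 2.0
    evals, evecs = np.linalg.eigh(A)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # back-transform to eigenvectors of P and normalize the trivial vector to 1
    psi = evecs * inv_sqrt_d[:, None]
    phi0 = psi[:, 0]
    if np.any(phi0 == 0):
        raise ValueError("ill-conditioned operator: zero entry in stationary vector")
    psi = psi / phi0[:, None]
    m_eff = min(m, n - 1)
    components = psi[:, 1 : m_eff + 1] * evals[1 : m_eff + 1][None, :]
    return EmbeddingResult(
        components=components,
        eigenvalues=evals[1 : m_eff + 1],
        alpha=alpha,
        sigma=sigma,
    )


def orient_gradient(emb: EmbeddingResult, reference: np.ndarray) -> EmbeddingResult:
    """Flip component 1 so it correlates nonnegatively with ``reference``."""
    ref = np.asarray(reference, dtype=float)
    comp = emb.components[:, 0]
    if ref.shape != comp.shape:
        raise ValueError("reference length mismatch")
    if not np.isfinite(ref).all():
        raise ValueError("reference contains non-finite values")
    if np.std(comp) == 0:
        raise ValueError("zero-variance component cannot be oriented")
    # sign is stored relative to the raw eigenvector, so orientation is idempotent
    raw = comp * emb.orientation_sign
    r_raw = np.corrcoef(raw, ref)[0, 1]
    new_sign = -1 if r_raw < 0 else 1
    components = emb.components.copy()
    components[:, 0] = new_sign * raw
    return EmbeddingResult(
        components=components,
        eigenvalues=emb.eigenvalues,
        alpha=emb.alpha,
        sigma=emb.sigma,
        orientation_sign=new_sign,
    )


def bin_hierarchy(gradient: np.ndarray, n_bins: int = 10) -> HierarchyMap:
    """Split nodes, sorted by (gradient, index), into equal-size classes.

    With remainder r, the r lowest classes take one extra node.  Class 1
    holds the lowest gradient values.
    """
    g = np.asarray(gradient, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    n = len(g)
    if n < n_bins:
        raise ValueError("need at least n_bins nodes")
    if not np.isfinite(g).all():
        raise ValueError("gradient contains non-finite values")
    order = np.lexsort((np.arange(n), g))
    base, r = divmod(n, n_bins)
    sizes = [base + 1 if b < r else base for b in range(n_bins)]
    classes = np.empty(n, dtype=int)
    start = 0
    for b, size in enumerate(sizes, start=1):
        classes[order[start : start + size]] = b
        start += size
    return HierarchyMap(gradient=g, classes=classes, n_bins=n_bins)
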