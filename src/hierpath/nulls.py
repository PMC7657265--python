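"""Spatially constrained null models and permutation inference.

Three ensembles: (1) distance-binned degree-preserving edge rewiring,
(2) spherical-rotation label permutation with hemisphere mirroring
(preserves spatial autocorrelation), and (3) plain label permutation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .core import Connectome

log = logging.getLogger(__name__)


@dataclass
class NullEnsemble:
    kind: str  # rewire | spin | permute
    members: Union[List[np.ndarray], np.ndarray]
    seed: int
    n_reps: int
    skipped: int = 0


# ---------------------------------------------------------------------------
# rewiring


def rewire_length_preserving(
    c: Connectome,
    n_bins: int = 10,
    n_reps: int = 2000,
    seed: int = 0,
    attempts_per_edge: int = 10,
) -> NullEnsemble:
    """Degree-preserving double-edge swaps restricted to length bins.

    Edges are binned by Euclidean length (equal-width bins); each
    replicate attempts 10x the edge count of swaps, each picking two
    edges from a random bin and exchanging endpoints (a-b, c-d ->
    a-d, c-b) when no self-loop or multi-edge results and both new edges
    fall back into the same length bin.  Weights travel with their
    edges, so the degree sequence, the weight multiset, and the per-bin
    edge-length counts are preserved exactly.
    """
    W = c.weights
    n = c.n_nodes
    iu = np.triu_indices(n, k=1)
    mask = W[iu] > 0
    ei, ej = iu[0][mask], iu[1][mask]
    ew = W[iu][mask]
    n_edges = len(ei)
    if n_edges < 2:
        raise ValueError("graph has fewer than 2 edges; nothing to swap")
    lengths = np.linalg.norm(c.coords[ei] - c.coords[ej], axis=1)
    lo, hi = lengths.min(), lengths.max()
    bin_edges = np.linspace(lo, hi, n_bins + 1)
    bin_id = np.clip(np.searchsorted(bin_edges, lengths, side="right") - 1, 0, n_bins - 1)
    bins = [np.flatnonzero(bin_id == b) for b in range(n_bins)]
    swappable = [(b, idx) for b, idx in enumerate(bins) if len(idx) >= 2]
    if not swappable:
        raise ValueError("no length bin holds 2+ edges; cannot rewire")
    dmat = cdist(c.coords, c.coords)
    all_bin = np.searchsorted(bin_edges, dmat, side="right") - 1
    all_bin[dmat == bin_edges[-1]] = n_bins - 1  # right-closed last bin
    all_bin[(dmat < bin_edges[0]) | (dmat > bin_edges[-1])] = -1  # outside range

    rng = np.random.default_rng([seed, 101])
    members: List[np.ndarray] = []
    skipped = 0
    n_attempts = attempts_per_edge * n_edges
    for _ in range(n_reps):
        a = ei.copy()
        b = ej.copy()
        edge_set = set(map(int, a * n + b))
        accepted = 0
        for _ in range(n_attempts):
            bin_b, pool = swappable[rng.integers(len(swappable))]
            e1, e2 = pool[rng.integers(len(pool))], pool[rng.integers(len(pool))]
            if e1 == e2:
                continue
            x1, y1 = a[e1], b[e1]
            x2, y2 = a[e2], b[e2]
            # swap to x1-y2, x2-y1
            if x1 == y2 or x2 == y1:
                continue
            p1 = (min(x1, y2), max(x1, y2))
            p2 = (min(x2, y1), max(x2, y1))
            if p1 == p2:
                continue
            # both replacement edges must land back in the same length bin
            if all_bin[p1] != bin_b or all_bin[p2] != bin_b:
                continue
            k1, k2 = p1[0] * n + p1[1], p2[0] * n + p2[1]
            if k1 in edge_set or k2 in edge_set:
                continue
            edge_set.discard(int(x1 * n + y1) if x1 < y1 else int(y1 * n + x1))
            edge_set.discard(int(x2 * n + y2) if x2 < y2 else int(y2 * n + x2))
            edge_set.add(int(k1))
            edge_set.add(int(k2))
            a[e1], b[e1] = p1
            a[e2], b[e2] = p2
            accepted += 1
        if accepted == 0:
            skipped += 1
            continue
        M = np.zeros((n, n))
        M[a, b] = ew
        M[b, a] = ew
        members.append(M)
    return NullEnsemble(kind="rewire", members=members, seed=seed, n_reps=n_reps, skipped=skipped)


# ---------------------------------------------------------------------------
# spin permutation


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform rotation from a normalized Gaussian quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def spin_permutation(
    sphere_coords: np.ndarray,
    hemisphere: np.ndarray,
    n_reps: int = 2000,
    seed: int = 0,
    rotations: Optional[Sequence[np.ndarray]] = None,
) -> NullEnsemble:
    """Spherical-rotation assignment vectors, mirrored across hemispheres.

    Per replicate a uniform rotation is applied to one hemisphere and
    its x-mirrored conjugate to the other; each original parcel then
    takes the value of the nearest rotated parcel within its own
    hemisphere.  ``members[r][i] = j`` means parcel i receives the value
    of parcel j.
    """
    sphere_coords = np.asarray(sphere_coords, dtype=float)
    hemisphere = np.asarray(hemisphere, dtype=object)
    n = len(sphere_coords)
    left = np.flatnonzero(hemisphere == "L")
    right = np.flatnonzero(hemisphere == "R")
    if len(left) < 1 or len(right) < 1:
        raise ValueError("both hemispheres must be populated")
    rng = np.random.default_rng([seed, 102])
    mirror = np.diag([-1.0, 1.0, 1.0])
    members = np.empty((n_reps, n), dtype=int)
    for rep in range(n_reps):
        R = rotations[rep] if rotations is not None else _random_rotation(rng)
        R_mirrored = mirror @ R @ mirror
        perm = np.empty(n, dtype=int)
        for idx, Rh in ((left, R), (right, R_mirrored)):
            rotated = sphere_coords[idx] @ Rh.T
            tree = cKDTree(rotated)
            _, nearest = tree.query(sphere_coords[idx])
            perm[idx] = idx[nearest]
        members[rep] = perm
    return NullEnsemble(kind="spin", members=members, seed=seed, n_reps=n_reps)


def label_permutation(n_nodes: int, n_reps: int = 2000, seed: int = 0) -> NullEnsemble:
    """Uniform random node-label permutations."""
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes to permute")
    rng = np.random.default_rng([seed, 103])
    members = np.vstack([rng.permutation(n_nodes) for _ in range(n_reps)])
    return NullEnsemble(kind="permute", members=members, seed=seed, n_reps=n_reps)


# ---------------------------------------------------------------------------
# inference


def permutation_pvalue(observed: float, nulls: np.ndarray, tail: str = "two") -> float:
    """Permutation p with the +1 correction (never exactly 0).

    ``two``-tailed extremity is measured as absolute deviation from the
    null mean.
    """
    nulls = np.asarray(nulls, dtype=float)
    if nulls.size == 0:
        raise ValueError("empty null distribution")
    if tail == "right":
        extreme = nulls >= observed
    elif tail == "left":
        extreme = nulls <= observed
    elif tail == "two":
        mu = nulls.mean()
        extreme = np.abs(nulls - mu) >= abs(observed - mu)
    else:
        raise ValueError(f"unknown tail: {tail}")
    return (1 + int(extreme.sum())) / (1 + nulls.size)


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up; returns the boolean rejection mask."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = q * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        kmax = np.max(np.flatnonzero(below))
        reject[order[: kmax + 1]] = True
    return reject


def moran_i(values: np.ndarray, weights: np.ndarray) -> float:
    """Moran's I spatial autocorrelation of ``values`` under ``weights``
    (diagonal ignored)."""
    z = np.asarray(values, dtype=float)
    z = z - z.mean()
    W = np.asarray(weights, dtype=float).copy()
    np.fill_diagonal(W, 0.0)
    denom = float(z @ z)
    s0 = W.sum()
    if denom == 0 or s0 == 0:
        raise ValueError("degenerate input for Moran's I")
    return float(len(z) / s0 * (z @ W @ z) / denom)
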