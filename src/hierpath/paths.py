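"""Weighted shortest paths on the -log(W) length graph.

Distances and one deterministic optimal path per pair are computed with
a vectorized Floyd-Warshall recursion (strict relaxation, ascending
intermediate order).  Equal-cost alternatives are flagged, not
enumerated.
"""
from __future__ import annotations

import logging
from typing import Iterator, Tuple

import numpy as np

from .core import Connectome, LengthGraph, PathSet

log = logging.getLogger(__name__)

TIE_TOL = 1e-12


def weights_to_lengths(c: Connectome, transform: str = "log") -> LengthGraph:
    """Map weights to lengths: L = -log(W) (default) or L = 1/W.

    A weight of exactly 1 would give a zero-length edge, so the whole
    matrix is rescaled by (1 - 1e-9) first (logged) when that happens.
    """
    W = c.weights.copy()
    if (W < 0).any():
        raise ValueError("negative weights")
    if (W >= 1.0).any():
        log.warning("weights at 1.0 detected; rescaling W by (1 - 1e-9)")
        W = W * (1.0 - 1e-9)
    extant = W > 0
    L = np.full(W.shape, np.inf)
    if transform == "log":
        L[extant] = -np.log(W[extant])
    elif transform == "inv":
        L[extant] = 1.0 / W[extant]
    else:
        raise ValueError(f"unknown transform: {transform}")
    np.fill_diagonal(L, np.inf)
    return LengthGraph(lengths=L)


def all_pairs_paths(lg: LengthGraph) -> PathSet:
    """Floyd-Warshall with predecessor reconstruction, hop counts and
    tie flags.

    ``tie_flags[i, j]`` is set when some intermediate node k off the
    chosen path satisfies |d_ik + d_kj - d_ij| <= 1e-12, i.e. an
    equal-cost alternative exists.  Disconnected pairs keep dist = +inf.
    """
    L = lg.lengths
    n = L.shape[0]
    D = L.copy()
    np.fill_diagonal(D, 0.0)
    # pred[i, j] = node before j on the path from i
    P = np.where(np.isfinite(L), np.arange(n)[:, None], -1)
    np.fill_diagonal(P, -1)
    for k in range(n):
        alt = D[:, k][:, None] + D[k, :][None, :]
        better = alt < D
        D = np.where(better, alt, D)
        P = np.where(better, P[k, :][None, :], P)

    hops = _hop_counts(D, P)
    tie = _tie_flags(D, hops)
    finite = np.isfinite(D) & ~np.eye(n, dtype=bool)
    diameter = int(hops[finite].max()) if finite.any() else 0
    return PathSet(dist=D, pred=P, hops=hops, diameter_hops=diameter, tie_flags=tie)


def _hop_counts(D: np.ndarray, P: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    hops = np.zeros((n, n), dtype=int)
    for i in range(n):
        # process targets in order of increasing distance: the predecessor of
        # any target is strictly closer, hence already resolved
        order = np.argsort(D[i], kind="stable")
        for j in order:
            if j == i or not np.isfinite(D[i, j]):
                continue
            p = P[i, j]
            hops[i, j] = hops[i, p] + 1 if p != i else 1
    return hops


def _tie_flags(D: np.ndarray, hops: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    finite = np.isfinite(D)
    eq_count = np.zeros((n, n), dtype=int)
    for k in range(n):
        col = D[:, k][:, None]
        row = D[k, :][None, :]
        ok = finite[:, k][:, None] & finite[k, :][None, :] & finite
        with np.errstate(invalid="ignore"):
            eq = ok & (np.abs(col + row - D) <= TIE_TOL)
        eq[:, k] = False
        eq[k, :] = False
        eq_count += eq
    # every interior node of the chosen path satisfies the equality test;
    # any surplus witness is an unused equal-cost intermediate
    interior = np.maximum(hops - 1, 0)
    tie = (eq_count > interior) & finite & ~np.eye(n, dtype=bool)
    return tie


def retrieve_path(ps: PathSet, s: int, t: int) -> np.ndarray:
    """Node sequence of the stored optimal path from ``s`` to ``t``."""
    if s == t:
        raise ValueError("source equals target")
    if not np.isfinite(ps.dist[s, t]):
        raise ValueError(f"target {t} unreachable from {s}")
    seq = [t]
    cur = t
    while cur != s:
        cur = int(ps.pred[s, cur])
        if cur < 0 or len(seq) > ps.n_nodes:
            raise RuntimeError("corrupt predecessor matrix")
        seq.append(cur)
    return np.array(seq[::-1], dtype=int)


def iter_paths(ps: PathSet) -> Iterator[Tuple[int, int, np.ndarray]]:
    """Yield (source, target, node sequence) for every finite ordered pair."""
    n = ps.n_nodes
    for s in range(n):
        for t in range(n):
            if s == t or not np.isfinite(ps.dist[s, t]):
                continue
            yield s, t, retrieve_path(ps, s, t)


def path_cost(lg: LengthGraph, path: np.ndarray) -> float:
    return float(np.sum(lg.lengths[path[:-1], path[1:]]))
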