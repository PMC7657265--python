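"""Transition-probability matrices between hierarchy classes.

One-hop matrices T(t) are indexed by 1-based path position t; the
numerator counts paths whose t-th and (t+1)-th nodes fall in classes i
and j, the denominator counts paths with at least t+1 nodes, so each
populated T(t) sums to 1 (rows need not).  Multi-hop matrices M(k) pool
all valid start positions, so M(1) equals the position-pooled one-hop
counts.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np

from .core import HierarchyMap, PathSet
from .paths import iter_paths


@dataclass
class TransitionTensor:
    one_hop: Dict[int, np.ndarray]  # t -> (n_bins, n_bins)
    multi_hop: Dict[int, np.ndarray]  # k -> (n_bins, n_bins)
    one_hop_support: Dict[int, int]  # paths with >= t+1 nodes
    multi_hop_support: Dict[int, int]  # (path, t) pairs with >= t+k nodes
    n_bins: int


def _collect_paths(ps: PathSet, hmap: HierarchyMap) -> List[np.ndarray]:
    if ps.n_nodes != hmap.n_nodes:
        raise ValueError("PathSet and HierarchyMap node counts differ")
    return [hmap.classes[path] for _, _, path in iter_paths(ps)]


def one_hop(ps: PathSet, hmap: HierarchyMap) -> TransitionTensor:
    """T(t) for t = 1 .. max node count - 1 (empty-support t omitted)."""
    return compute_transitions(ps, hmap, multi=False)


def multi_hop(ps: PathSet, hmap: HierarchyMap) -> TransitionTensor:
    """M(k) for k = 1 .. max node count - 1, pooled over start positions."""
    return compute_transitions(ps, hmap, one=False)


def compute_transitions(
    ps: PathSet, hmap: HierarchyMap, one: bool = True, multi: bool = True
) -> TransitionTensor:
    return transitions_from_class_paths(
        _collect_paths(ps, hmap), hmap.n_bins, one=one, multi=multi
    )


def transitions_from_class_paths(
    class_paths: List[np.ndarray], n_bins: int, one: bool = True, multi: bool = True
) -> TransitionTensor:
    """Transition matrices from an explicit list of class sequences
    (1-based classes, one sequence per path)."""
    nb = n_bins
    class_paths = [np.asarray(p, dtype=int) for p in class_paths]
    max_len = max((len(p) for p in class_paths), default=0)
    one_hop_mats: Dict[int, np.ndarray] = {}
    one_sup: Dict[int, int] = {}
    multi_mats: Dict[int, np.ndarray] = {}
    multi_sup: Dict[int, int] = {}
    if one:
        for t in range(1, max_len):  # 1-based position t, needs >= t+1 nodes
            counts = np.zeros((nb, nb))
            denom = 0
            for cp in class_paths:
                if len(cp) >= t + 1:
                    denom += 1
                    counts[cp[t - 1] - 1, cp[t] - 1] += 1
            if denom:
                one_hop_mats[t] = counts / denom
                one_sup[t] = denom
    if multi:
        for k in range(1, max_len):
            counts = np.zeros((nb, nb))
            denom = 0
            for cp in class_paths:
                L = len(cp)
                if L < k + 1:
                    continue
                denom += L - k  # valid start positions t = 1 .. L-k
                np.add.at(counts, (cp[: L - k] - 1, cp[k:] - 1), 1)
            if denom:
                multi_mats[k] = counts / denom
                multi_sup[k] = denom
    return TransitionTensor(
        one_hop=one_hop_mats,
        multi_hop=multi_mats,
        one_hop_support=one_sup,
        multi_hop_support=multi_sup,
        n_bins=nb,
    )


def memory_profile(tt: TransitionTensor) -> "np.ndarray":
    """Per-lag diagonal mass and class-distance spread of M(k).

    Returns a structured summary as a record array with fields
    (k, diag_mass, mean_spread).
    """
    import pandas as pd

    rows = []
    for k in sorted(tt.multi_hop):
        M = tt.multi_hop[k]
        diag = float(np.trace(M))
        i, j = np.indices(M.shape)
        total = M.sum()
        spread = float((M * np.abs(i - j)).sum() / total) if total > 0 else np.nan
        rows.append({"k": k, "diag_mass": diag, "mean_spread": spread})
    return pd.DataFrame(rows)


def near_diagonal_mass(M: np.ndarray, width: int = 1) -> float:
    """Total mass within ``width`` classes of the diagonal."""
    i, j = np.indices(M.shape)
    return float(M[np.abs(i - j) <= width].sum())
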