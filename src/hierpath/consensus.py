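"""Group-consensus structural network and mean functional connectivity.

The consensus keeps, within Euclidean-length bins, the edges that occur
most frequently across subjects, separately for intra- and
interhemispheric edges, so that both the density and the edge-length
distribution of individual matrices are preserved.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .core import FunctionalMatrix


@dataclass
class ConsensusReport:
    n_bins: int
    kept_per_bin: Dict[str, List[int]]
    mean_per_bin: Dict[str, List[float]]
    density: float
    n_intra: int
    n_inter: int


def default_n_bins(subject_weights: Sequence[np.ndarray], reading: str = "count") -> int:
    """Square-root bin-count heuristic.

    ``reading='count'``: sqrt of the mean number of extant edges per
    subject (the interpretation used by the consensus literature).
    ``reading='density'``: sqrt of the mean binary density taken
    literally as a fraction (yields very few bins; selectable for
    comparison).
    """
    n = subject_weights[0].shape[0]
    iu = np.triu_indices(n, k=1)
    counts = [int(np.count_nonzero(W[iu])) for W in subject_weights]
    if reading == "count":
        return max(1, int(round(np.sqrt(np.mean(counts)))))
    if reading == "density":
        dens = np.mean(counts) / len(iu[0])
        return max(1, int(round(np.sqrt(dens))))
    raise ValueError(f"unknown heuristic reading: {reading}")


def consensus_sc(
    subject_weights: Sequence[np.ndarray],
    coords: np.ndarray,
    hemisphere: np.ndarray,
    n_bins: Optional[int] = None,
    weight_mean: str = "all",
):
    """Distance-binned, hemisphere-stratified frequency consensus.

    Within each hemisphere class (intra/inter) edges pooled across
    subjects are binned by Euclidean length into equal-width bins; each
    bin keeps its k most frequent edges, k = round(mean per-subject edge
    count in the bin).  Kept-edge weight is the mean across all subjects
    (``weight_mean='all'``, zeros included) or across expressing
    subjects only (``'nonzero'``).

    Returns ``(weights, report)``.
    """
    if len(subject_weights) < 2:
        raise ValueError("need at least 2 subjects for a consensus")
    shapes = {W.shape for W in subject_weights}
    if len(shapes) != 1:
        raise ValueError(f"subject matrices differ in shape: {shapes}")
    if weight_mean not in ("all", "nonzero"):
        raise ValueError("weight_mean must be 'all' or 'nonzero'")
    n = subject_weights[0].shape[0]
    n_sub = len(subject_weights)
    if n_bins is None:
        n_bins = default_n_bins(subject_weights)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")

    stack = np.stack(subject_weights)  # (n_sub, n, n)
    iu = np.triu_indices(n, k=1)
    present = stack[:, iu[0], iu[1]] > 0  # (n_sub, n_pairs)
    freq = present.sum(axis=0)
    pooled = freq > 0
    if not pooled.any():
        raise ValueError("pooled edge set is empty")
    lengths = cdist(coords, coords)[iu]
    same_hemi = hemisphere[iu[0]] == hemisphere[iu[1]]

    mean_all = stack[:, iu[0], iu[1]].mean(axis=0)
    with np.errstate(invalid="ignore"):
        mean_nz = np.where(
            freq > 0, stack[:, iu[0], iu[1]].sum(axis=0) / np.maximum(freq, 1), 0.0
        )
    mean_w = mean_all if weight_mean == "all" else mean_nz

    keep = np.zeros(len(iu[0]), dtype=bool)
    kept_per_bin = {"intra": [], "inter": []}
    mean_per_bin = {"intra": [], "inter": []}
    for cls, cls_mask in (("intra", same_hemi), ("inter", ~same_hemi)):
        pool = pooled & cls_mask
        if not pool.any():
            continue
        lo, hi = lengths[pool].min(), lengths[pool].max()
        edges_bins = np.linspace(lo, hi, n_bins + 1)
        # right-inclusive last bin
        bin_id = np.clip(np.searchsorted(edges_bins, lengths, side="right") - 1, 0, n_bins - 1)
        for b in range(n_bins):
            in_bin = pool & (bin_id == b)
            cand = np.flatnonzero(in_bin)
            if len(cand) == 0:
                kept_per_bin[cls].append(0)
                mean_per_bin[cls].append(0.0)
                continue
            # mean per-subject edge count in this bin (within this class)
            per_subj = present[:, cls_mask & (bin_id == b)].sum(axis=1)
            k_mean = per_subj.mean()
            k = int(round(k_mean))
            k = min(k, len(cand))
            # rank: frequency desc, mean weight desc, (i, j) asc
            order = sorted(
                cand,
                key=lambda e: (-freq[e], -mean_all[e], int(iu[0][e]), int(iu[1][e])),
            )
            keep[order[:k]] = True
            kept_per_bin[cls].append(k)
            mean_per_bin[cls].append(float(k_mean))

    W = np.zeros((n, n))
    sel = np.flatnonzero(keep)
    W[iu[0][sel], iu[1][sel]] = mean_w[sel]
    W = W + W.T
    report = ConsensusReport(
        n_bins=n_bins,
        kept_per_bin=kept_per_bin,
        mean_per_bin=mean_per_bin,
        density=float(keep.sum() / len(iu[0])),
        n_intra=int((keep & same_hemi).sum()),
        n_inter=int((keep & ~same_hemi).sum()),
    )
    return W, report


def mean_fc(subject_fcs: Sequence[FunctionalMatrix]) -> FunctionalMatrix:
    """Element-wise mean FC across subjects; diagonal reset to 1."""
    if len(subject_fcs) < 1:
        raise ValueError("need at least one FC matrix")
    shapes = {fc.values.shape for fc in subject_fcs}
    if len(shapes) != 1:
        raise ValueError(f"FC matrices differ in shape: {shapes}")
    M = np.mean([fc.values for fc in subject_fcs], axis=0)
    np.fill_diagonal(M, 1.0)
    return FunctionalMatrix(M)
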