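"""Per-node flow statistics through the hierarchy.

For a path v_1..v_n and an interior node v_i, the slope contribution is
h(v_{i+1}) - h(v_i) (outgoing segment only — this matches the worked
two-path example yielding (h(D) + h(B) - 2 h(C)) / 2 for node C).
Turning points are interior nodes where the incoming and outgoing
segment slopes have opposite signs: a local minimum turns the path up,
a local maximum turns it down.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .core import FlowStats, HierarchyMap, PathSet
from .paths import iter_paths


def flow_from_paths(paths, h: np.ndarray, n: int) -> FlowStats:
    """Accumulate slopes and turning events over an explicit path list.

    Zero-slope segments (tied hierarchy values) contribute 0 to the mean
    slope and count as neither turning direction.
    """
    slope_sum = np.zeros(n)
    n_interior = np.zeros(n, dtype=int)
    up = np.zeros(n, dtype=int)
    down = np.zeros(n, dtype=int)
    for path in paths:
        path = np.asarray(path, dtype=int)
        hv = h[path]
        seg = np.diff(hv)  # seg[i] = slope of segment i -> i+1
        for i in range(1, len(path) - 1):
            v = path[i]
            a, b = seg[i - 1], seg[i]
            slope_sum[v] += b
            n_interior[v] += 1
            if a < 0 and b > 0:
                up[v] += 1
            elif a > 0 and b < 0:
                down[v] += 1
    with np.errstate(invalid="ignore"):
        mean_slope = np.where(n_interior > 0, slope_sum / np.maximum(n_interior, 1), np.nan)
        p_up = np.where(n_interior > 0, up / np.maximum(n_interior, 1), np.nan)
        p_down = np.where(n_interior > 0, down / np.maximum(n_interior, 1), np.nan)
    return FlowStats(
        mean_slope=mean_slope, p_turn_up=p_up, p_turn_down=p_down, n_interior=n_interior
    )


def compute_flow_stats(ps: PathSet, hmap: HierarchyMap) -> FlowStats:
    """Flow statistics over every path of an all-pairs PathSet."""
    if ps.n_nodes != hmap.n_nodes:
        raise ValueError("PathSet and HierarchyMap node counts differ")
    return flow_from_paths(
        (path for _, _, path in iter_paths(ps)), hmap.gradient, ps.n_nodes
    )


def node_slopes(ps: PathSet, hmap: HierarchyMap) -> FlowStats:
    """Mean slope of every node over its interior path traversals."""
    return compute_flow_stats(ps, hmap)


def turning_points(ps: PathSet, hmap: HierarchyMap) -> FlowStats:
    """Turning-up / turning-down probabilities per node."""
    return compute_flow_stats(ps, hmap)


def network_aggregate(fs: FlowStats, partition: np.ndarray) -> pd.DataFrame:
    """Unweighted per-label means over nodes with defined statistics."""
    partition = np.asarray(partition, dtype=int)
    rows = []
    for lab in np.unique(partition):
        mask = (partition == lab) & fs.valid
        if not mask.any():
            rows.append(
                {
                    "label": int(lab),
                    "n_nodes": 0,
                    "mean_slope": np.nan,
                    "p_turn_up": np.nan,
                    "p_turn_down": np.nan,
                }
            )
            continue
        rows.append(
            {
                "label": int(lab),
                "n_nodes": int(mask.sum()),
                "mean_slope": float(np.mean(fs.mean_slope[mask])),
                "p_turn_up": float(np.mean(fs.p_turn_up[mask])),
                "p_turn_down": float(np.mean(fs.p_turn_down[mask])),
            }
        )
    return pd.DataFrame(rows)


def slope_hierarchy_correlation(
    fs: FlowStats, hmap: HierarchyMap, spins: Optional[np.ndarray] = None
):
    """Pearson r between per-node mean slope and gradient, with a spin p.

    ``spins`` is an (n_reps, n) array of permutation index vectors (e.g.
    from the spherical-rotation null); the p-value counts null
    correlations at least as extreme in absolute value, with the +1
    correction.  Returns ``(r, p_spin)``; ``p_spin`` is None without
    spins.
    """
    valid = fs.valid & np.isfinite(fs.mean_slope)
    if valid.sum() < 3:
        raise ValueError("need at least 3 nodes with defined slope")
    slope = fs.mean_slope[valid]
    g = hmap.gradient
    r = float(np.corrcoef(slope, g[valid])[0, 1])
    if spins is None:
        return r, None
    null_r = np.empty(len(spins))
    for k, perm in enumerate(spins):
        null_r[k] = np.corrcoef(slope, g[perm][valid])[0, 1]
    p = (1 + int(np.sum(np.abs(null_r) >= abs(r)))) / (1 + len(spins))
    return r, p


def flow_table(fs: FlowStats) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "node": np.arange(1, len(fs.mean_slope) + 1),
            "mean_slope": fs.mean_slope,
            "p_turn_up": fs.p_turn_up,
            "p_turn_down": fs.p_turn_down,
            "n_interior": fs.n_interior,
        }
    )
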