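"""Greedy navigation under a beta-mixed spatial/hierarchical metric.

The agent repeatedly forwards to the structurally connected neighbor
closest to the target under

    d(i, j) = beta * ||coords_i - coords_j||_norm
              + (1 - beta) * |h_i - h_j|_norm

with both distance matrices normalized into [0, 1] over all node pairs.
The hierarchy term uses the absolute difference (a signed difference
cannot rank neighbors).  Failure = revisiting a node or exceeding the
hop cap.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import Connectome, HierarchyMap


@dataclass
class NavConfig:
    beta_grid: np.ndarray = field(default_factory=lambda: np.round(np.arange(0, 21) * 0.05, 10))
    max_hops: Optional[int] = None  # default: n_nodes

    def __post_init__(self):
        self.beta_grid = np.asarray(self.beta_grid, dtype=float)
        if self.beta_grid.min(initial=0) < 0 or self.beta_grid.max(initial=0) > 1:
            raise ValueError("beta grid must lie in [0, 1]")
        if np.any(np.diff(self.beta_grid) <= 0):
            raise ValueError("beta grid must be strictly ascending")
        if self.max_hops is not None and self.max_hops < 1:
            raise ValueError("max_hops must be >= 1")


@dataclass
class NavigationResult:
    beta_grid: np.ndarray
    success: np.ndarray  # (n_sources, n_betas)
    mean_curve: np.ndarray  # (n_betas,)
    detrended: np.ndarray  # (n_sources, n_betas)
    beta_star: np.ndarray  # (n_sources,), nan when flagged degenerate


def distance_matrices(coords: np.ndarray, gradient: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Pairwise spatial and hierarchy distances, scaled into [0, 1].

    Scaling divides by the global maximum so self-distances stay 0 and
    d(i, i) = 0 for every beta.
    """
    ds = cdist(coords, coords)
    dh = np.abs(gradient[:, None] - gradient[None, :])
    if ds.max() > 0:
        ds = ds / ds.max()
    if dh.max() > 0:
        dh = dh / dh.max()
    return ds, dh


def combined_distance(
    i: int, j: int, beta: float, ds_norm: np.ndarray, dh_norm: np.ndarray
) -> float:
    if not 0 <= beta <= 1:
        raise ValueError("beta must lie in [0, 1]")
    return float(beta * ds_norm[i, j] + (1 - beta) * dh_norm[i, j])


def greedy_navigate(
    source: int,
    target: int,
    beta: float,
    c: Connectome,
    hmap: HierarchyMap,
    cfg: Optional[NavConfig] = None,
) -> Tuple[bool, np.ndarray]:
    """Single greedy walk; returns (success, walk).

    Ties in the combined distance are broken by lower node index.
    """
    if source == target:
        raise ValueError("source equals target")
    cfg = cfg or NavConfig()
    ds, dh = distance_matrices(c.coords, hmap.gradient)
    D = beta * ds + (1 - beta) * dh
    adj = c.weights > 0
    if not adj[source].any():
        raise ValueError(f"isolated source {source}")
    max_hops = cfg.max_hops or c.n_nodes
    walk = [source]
    visited = {source}
    cur = source
    for _ in range(max_hops):
        nbrs = np.flatnonzero(adj[cur])
        if len(nbrs) == 0:
            return False, np.array(walk)
        nxt = int(nbrs[np.argmin(D[nbrs, target])])
        walk.append(nxt)
        if nxt == target:
            return True, np.array(walk)
        if nxt in visited:
            return False, np.array(walk)
        visited.add(nxt)
        cur = nxt
    return False, np.array(walk)


def _next_hop_table(adj: np.ndarray, D: np.ndarray, target: int) -> np.ndarray:
    """Greedy next hop toward ``target`` from every node (-1 if isolated)."""
    scores = np.where(adj, D[:, target][None, :], np.inf)
    nxt = np.argmin(scores, axis=1)  # argmin takes the lowest index on ties
    nxt[~adj.any(axis=1)] = -1
    return nxt


def success_curves(
    c: Connectome, hmap: HierarchyMap, cfg: Optional[NavConfig] = None
) -> NavigationResult:
    """Per-source success ratio over the beta grid.

    For fixed beta and target the greedy next hop is a deterministic
    map, so walks from all sources are advanced in lockstep; a walk that
    has not reached the target within the hop cap has entered a cycle
    (equivalently, revisited a node) and is a failure.
    """
    cfg = cfg or NavConfig()
    n = c.n_nodes
    adj = c.weights > 0
    ds, dh = distance_matrices(c.coords, hmap.gradient)
    max_hops = cfg.max_hops or n
    grid = cfg.beta_grid
    success_counts = np.zeros((n, len(grid)))
    idx = np.arange(n)
    for bi, beta in enumerate(grid):
        D = beta * ds + (1 - beta) * dh
        for t in range(n):
            nxt = _next_hop_table(adj, D, t)
            cur = idx.copy()
            reached = cur == t
            stuck = np.zeros(n, dtype=bool)
            for _ in range(max_hops):
                active = ~reached & ~stuck
                if not active.any():
                    break
                step = nxt[cur[active]]
                dead = step < 0
                cur_active = np.where(dead, cur[active], step)
                cur[active] = cur_active
                stuck[np.flatnonzero(active)[dead]] = True
                reached[active] = cur[active] == t
            reached[t] = False  # self-pair not counted
            success_counts[:, bi] += reached
    success = success_counts / (n - 1)
    mean_curve = success.mean(axis=0)
    detrended = success - mean_curve[None, :]
    beta_star = select_beta_from(detrended, grid)
    return NavigationResult(
        beta_grid=grid,
        success=success,
        mean_curve=mean_curve,
        detrended=detrended,
        beta_star=beta_star,
    )


def select_beta_from(detrended: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Argmax of each detrended curve; ties take the smallest beta;
    all-equal curves are flagged as nan."""
    flat = np.ptp(detrended, axis=1) < 1e-15
    stars = grid[np.argmax(detrended, axis=1)].astype(float)
    stars[flat] = np.nan
    return stars


def select_beta(nr: NavigationResult) -> np.ndarray:
    return select_beta_from(nr.success - nr.mean_curve[None, :], nr.beta_grid)


def navigation_table(nr: NavigationResult) -> pd.DataFrame:
    rows = []
    for s in range(nr.success.shape[0]):
        for bi, beta in enumerate(nr.beta_grid):
            rows.append(
                {
                    "source": s + 1,
                    "beta": beta,
                    "success": nr.success[s, bi],
                    "detrended": nr.detrended[s, bi],
                }
            )
    df = pd.DataFrame(rows)
    return df
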