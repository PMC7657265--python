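"""Simple per-node network measures and their correlations with the
path-motif-derived measures.

Betweenness is counted over the pipeline's own unique shortest-path
set, so it is consistent with every motif analysis rather than
re-derived independently.
"""
from __future__ import annotations

from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import Connectome, FlowStats, FunctionalMatrix, LengthGraph, PathSet
from .navigation import NavigationResult
from .paths import iter_paths

MOTIF_MEASURES = ("mean_slope", "p_turn_up", "p_turn_down", "beta_star")


def structural_measures(c: Connectome, lg: LengthGraph, ps: PathSet) -> pd.DataFrame:
    """Betweenness, closeness, clustering, binary degree, mean edge length.

    All but degree are computed on the weighted network; betweenness and
    closeness use the -log length graph.
    """
    n = c.n_nodes
    betweenness = np.zeros(n)
    for _, _, path in iter_paths(ps):
        for v in path[1:-1]:
            betweenness[v] += 1
    betweenness /= 2.0  # ordered pairs double-count each undirected path

    closeness = np.zeros(n)
    finite = np.isfinite(ps.dist)
    for i in range(n):
        reach = finite[i] & (np.arange(n) != i)
        closeness[i] = reach.sum() / ps.dist[i, reach].sum() if reach.any() else 0.0

    G = nx.from_numpy_array(c.weights)
    clustering = np.array([nx.clustering(G, weight="weight")[i] for i in range(n)])

    adj = c.weights > 0
    degree = adj.sum(axis=1)
    d = cdist(c.coords, c.coords)
    with np.errstate(invalid="ignore"):
        mean_edge_length = np.where(
            degree > 0, (d * adj).sum(axis=1) / np.maximum(degree, 1), np.nan
        )
    return pd.DataFrame(
        {
            "betweenness": betweenness,
            "closeness": closeness,
            "clustering": clustering,
            "degree": degree,
            "mean_edge_length": mean_edge_length,
        }
    )


def functional_measures(fc: FunctionalMatrix, partition: np.ndarray) -> pd.DataFrame:
    """FC strength and the participation coefficient on positive FC."""
    partition = np.asarray(partition, dtype=int)
    V = fc.values.copy()
    np.fill_diagonal(V, 0.0)
    strength = V.sum(axis=1)
    pos = np.clip(V, 0.0, None)
    k = pos.sum(axis=1)
    labels = np.unique(partition)
    kappa = np.column_stack([pos[:, partition == lab].sum(axis=1) for lab in labels])
    participation = np.full(len(V), np.nan)
    ok = k > 0
    participation[ok] = 1.0 - np.sum((kappa[ok] / k[ok, None]) ** 2, axis=1)
    return pd.DataFrame({"fc_strength": strength, "participation": participation})


def correlate_measures(
    simple: pd.DataFrame, fs: FlowStats, nr: Optional[NavigationResult] = None
) -> pd.DataFrame:
    """Pearson r for every (simple measure, motif measure) pair.

    Constant or insufficiently populated columns yield NaN.  Rows are
    the simple measures, columns the four motif-derived measures.
    """
    motif = pd.DataFrame(
        {
            "mean_slope": fs.mean_slope,
            "p_turn_up": fs.p_turn_up,
            "p_turn_down": fs.p_turn_down,
            "beta_star": nr.beta_star if nr is not None else np.nan,
        }
    )
    out = pd.DataFrame(index=simple.columns, columns=motif.columns, dtype=float)
    for scol in simple.columns:
        for mcol in motif.columns:
            x = simple[scol].to_numpy(dtype=float)
            y = motif[mcol].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                if np.isfinite(y).any() and np.isfinite(x).any():
                    raise ValueError(
                        f"fewer than 3 valid common nodes for {scol} x {mcol}"
                    )
                out.loc[scol, mcol] = np.nan  # measure absent (e.g. no navigation)
                continue
            if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                out.loc[scol, mcol] = np.nan
                continue
            out.loc[scol, mcol] = float(np.corrcoef(x[ok], y[ok])[0, 1])
    return out
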