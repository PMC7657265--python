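"""Path motifs: hierarchy trajectories along shortest paths.

A motif is the sequence of hierarchy values of the nodes along a path.
Motifs are averaged within (source class, target class, hop length)
cells with 95% confidence half-widths.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .core import HierarchyMap, PathSet
from .paths import iter_paths


@dataclass
class MotifProfile:
    source_class: int
    target_class: int
    length_hops: int
    mean_h: np.ndarray  # positions 0..length_hops
    ci95: np.ndarray
    n_paths: int


def trace_motif(path: np.ndarray, hmap: HierarchyMap, y: str = "gradient") -> np.ndarray:
    """Hierarchy values (or class indices with ``y='bins'``) along a path."""
    path = np.asarray(path, dtype=int)
    if path.size == 0:
        raise ValueError("empty path")
    if path.min() < 0 or path.max() >= hmap.n_nodes:
        raise ValueError("path contains out-of-range nodes")
    values = hmap.gradient if y == "gradient" else hmap.classes.astype(float)
    return values[path]


def mean_motifs(ps: PathSet, hmap: HierarchyMap, y: str = "gradient") -> List[MotifProfile]:
    """Per-cell mean motif with normal-approximation 95% CI half-widths.

    Cells are (source class, target class, hop length); direct edges are
    included as 2-point motifs; empty cells are omitted.
    """
    if ps.n_nodes != hmap.n_nodes:
        raise ValueError("PathSet and HierarchyMap node counts differ")
    acc: Dict[Tuple[int, int, int], List[np.ndarray]] = {}
    for s, t, path in iter_paths(ps):
        key = (int(hmap.classes[s]), int(hmap.classes[t]), len(path) - 1)
        acc.setdefault(key, []).append(trace_motif(path, hmap, y=y))
    profiles = []
    for (sc, tc, hops), motifs in sorted(acc.items()):
        M = np.vstack(motifs)
        mean = M.mean(axis=0)
        if len(motifs) > 1:
            sd = M.std(axis=0, ddof=1)
            ci = 1.96 * sd / np.sqrt(len(motifs))
        else:
            ci = np.zeros_like(mean)
        profiles.append(
            MotifProfile(
                source_class=sc,
                target_class=tc,
                length_hops=hops,
                mean_h=mean,
                ci95=ci,
                n_paths=len(motifs),
            )
        )
    return profiles


def motifs_table(profiles: List[MotifProfile]) -> pd.DataFrame:
    """Long-format table: one row per (cell, hop position)."""
    rows = []
    for p in profiles:
        for pos in range(p.length_hops + 1):
            rows.append(
                {
                    "src_class": p.source_class,
                    "tgt_class": p.target_class,
                    "length": p.length_hops,
                    "position": pos,
                    "mean": p.mean_h[pos],
                    "ci": p.ci95[pos],
                    "n": p.n_paths,
                }
            )
    return pd.DataFrame(rows)
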