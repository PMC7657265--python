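"""Core domain types shared by every pipeline stage.

All types are thin dataclasses around numpy arrays with explicit
validation.  Node indexing is 0-based everywhere in memory; written
tables use 1-based indices (see :mod:`hierpath.io`).
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

log = logging.getLogger(__name__)

#: tolerance below which an asymmetric weight matrix is silently symmetrized
SYMMETRY_TOL = 1e-9


@dataclass
class Connectome:
    """Structural substrate: weighted graph plus node geometry and labels.

    Attributes
    ----------
    weights : (n, n) ndarray
        Symmetric fiber-density matrix, entries in [0, 1], zero diagonal.
    coords : (n, 3) ndarray
        Euclidean node positions (arbitrary length units).
    sphere_coords : (n, 3) ndarray
        Unit-sphere projections used by the spherical-rotation null.
    hemisphere : (n,) ndarray of str
        Per-node ``"L"`` / ``"R"`` label.
    partition : (n,) int ndarray, optional
        Module labels forming a contiguous ``1..m`` set.
    names : list of str
        Node identifiers.
    """

    weights: np.ndarray
    coords: np.ndarray
    sphere_coords: np.ndarray
    hemisphere: np.ndarray
    partition: Optional[np.ndarray] = None
    names: Optional[Sequence[str]] = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.sphere_coords = np.asarray(self.sphere_coords, dtype=float)
        self.hemisphere = np.asarray(self.hemisphere, dtype=object)
        if self.partition is not None:
            self.partition = np.asarray(self.partition, dtype=int)
        if self.names is None:
            self.names = [f"node_{i + 1}" for i in range(self.weights.shape[0])]
        validate_connectome(self)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def validate_connectome(c: Connectome) -> None:
    W = c.weights
    n = W.shape[0]
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"weight matrix must be square, got {W.shape}")
    if np.isnan(W).any():
        raise ValueError("weight matrix contains NaN entries")
    if (W < 0).any():
        raise ValueError("weight matrix contains negative entries")
    if (W > 1).any():
        raise ValueError("weight matrix contains entries > 1")
    asym = np.abs(W - W.T).max() if n else 0.0
    if asym > SYMMETRY_TOL:
        raise ValueError(f"weight matrix asymmetric beyond tolerance ({asym:g})")
    if asym > 1e-12:
        log.warning("symmetrizing weight matrix (max asymmetry %.3g)", asym)
        c.weights = (W + W.T) / 2.0
        W = c.weights
    if np.abs(np.diag(W)).max(initial=0.0) > 0:
        raise ValueError("weight matrix diagonal must be exactly zero")
    for name, arr, shape in (
        ("coords", c.coords, (n, 3)),
        ("sphere_coords", c.sphere_coords, (n, 3)),
    ):
        if arr.shape != shape:
            raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
        if not np.isfinite(arr).all():
            raise ValueError(f"{name} contains non-finite values")
    if c.hemisphere.shape != (n,):
        raise ValueError("hemisphere label required for every node")
    labels = set(c.hemisphere.tolist())
    if not labels <= {"L", "R"}:
        raise ValueError(f"hemisphere labels must be 'L'/'R', got {labels}")
    if c.partition is not None:
        if c.partition.shape != (n,):
            raise ValueError("partition must label every node")
        uniq = np.unique(c.partition)
        if not np.array_equal(uniq, np.arange(1, len(uniq) + 1)):
            raise ValueError("partition labels must form a contiguous 1..m set")
    if len(c.names) != n:
        raise ValueError("names must cover all nodes")


@dataclass
class FunctionalMatrix:
    """Symmetric correlation matrix with unit diagonal, entries in [-1, 1]."""

    values: np.ndarray

    def __post_init__(self):
        V = np.asarray(self.values, dtype=float)
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError(f"FC matrix must be square, got {V.shape}")
        if np.isnan(V).any():
            raise ValueError("FC matrix contains NaN entries")
        if np.abs(V - V.T).max(initial=0.0) > SYMMETRY_TOL:
            raise ValueError("FC matrix asymmetric beyond tolerance")
        V = (V + V.T) / 2.0
        if np.abs(np.diag(V) - 1.0).max(initial=0.0) > 1e-9:
            raise ValueError("FC matrix diagonal must be 1")
        np.fill_diagonal(V, 1.0)
        if V.min(initial=0.0) < -1 - 1e-9 or V.max(initial=0.0) > 1 + 1e-9:
            raise ValueError("FC entries must lie in [-1, 1]")
        self.values = np.clip(V, -1.0, 1.0)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class HierarchyMap:
    """Continuous hierarchy value and decile class per node.

    ``classes`` are 1-based; class 1 holds the lowest gradient values.
    """

    gradient: np.ndarray
    classes: np.ndarray
    n_bins: int = 10

    def __post_init__(self):
        self.gradient = np.asarray(self.gradient, dtype=float)
        self.classes = np.asarray(self.classes, dtype=int)
        if self.gradient.shape != self.classes.shape:
            raise ValueError("gradient and classes must have the same length")
        if not np.isfinite(self.gradient).all():
            raise ValueError("gradient contains non-finite values")
        if self.classes.min(initial=1) < 1 or self.classes.max(initial=1) > self.n_bins:
            raise ValueError("classes must lie in 1..n_bins")
        # class must be nondecreasing in gradient
        order = np.argsort(self.gradient, kind="stable")
        if np.any(np.diff(self.classes[order]) < 0):
            raise ValueError("class labels must be nondecreasing in gradient")

    @property
    def n_nodes(self) -> int:
        return self.gradient.shape[0]


@dataclass
class LengthGraph:
    """Edge-length matrix L = -log(W); absent edges are +inf."""

    lengths: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.lengths.shape[0]

    def adjacency(self) -> np.ndarray:
        A = np.isfinite(self.lengths)
        np.fill_diagonal(A, False)
        return A


@dataclass
class PathSet:
    """All-pairs weighted shortest paths with full reconstruction data.

    ``pred[i, j]`` is the node preceding ``j`` on the chosen path from
    ``i`` to ``j`` (-1 when no path or ``i == j``).  ``tie_flags[i, j]``
    marks pairs with at least one equal-cost alternative path.
    """

    dist: np.ndarray
    pred: np.ndarray
    hops: np.ndarray
    diameter_hops: int
    tie_flags: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.dist.shape[0]


@dataclass
class FlowStats:
    """Per-node slope and turning-point statistics over all paths."""

    mean_slope: np.ndarray
    p_turn_up: np.ndarray
    p_turn_down: np.ndarray
    n_interior: np.ndarray

    @property
    def valid(self) -> np.ndarray:
        """Mask of nodes with at least one interior traversal."""
        return self.n_interior > 0
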