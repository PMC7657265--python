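"""Synthetic multi-subject cohort generator.

Produces bilateral node geometry on a sphere, a planted smooth scalar
gradient, distance-dependent subject connectomes, and a correlation FC
matrix that encodes the gradient, so every downstream stage can be
exercised without external data.

Randomness: one global integer seed drives a named stream per
sub-generator, so stages can be regenerated independently.
"""
from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import List

import numpy as np
from scipy.spatial.distance import cdist

from .core import Connectome, FunctionalMatrix

_STREAMS = {"geometry": 1, "gradient": 2, "masks": 3, "weights": 4, "fc": 5}

#: weights never reach 1.0 so the -log transform stays strictly positive
WEIGHT_CAP = 0.95


@dataclass
class SyntheticConfig:
    n_nodes: int = 200
    n_subjects: int = 20
    seed: int = 0
    lambda_space: float = 40.0
    mu_hier: float = 2.0
    density_target: float = 0.05
    weight_sigma: float = 1.0
    fc_noise: float = 0.3
    n_partitions: int = 7
    smoothness: float = 40.0
    cap_angle_deg: float = 80.0
    linear_weight: float = 1.0
    noise_weight: float = 0.6
    nuisance_weight: float = 0.4
    baseline_weight: float = 2.0
    subject_edge_jitter: float = 0.15

    def __post_init__(self):
        if self.n_nodes < 2 or self.n_nodes % 2:
            raise ValueError("n_nodes must be even and >= 2")
        for name in ("lambda_space", "mu_hier", "weight_sigma", "smoothness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.density_target < 1:
            raise ValueError("density_target must lie in (0, 1)")
        if self.fc_noise < 0:
            raise ValueError("fc_noise must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


@dataclass
class Geometry:
    coords: np.ndarray
    sphere_coords: np.ndarray
    hemisphere: np.ndarray
    partition: np.ndarray


@dataclass
class CohortSample:
    connectome_template: Connectome
    subject_weights: List[np.ndarray]
    fc: FunctionalMatrix
    true_gradient: np.ndarray


def _sample_cap(rng: np.random.Generator, n: int, cap_angle_deg: float) -> np.ndarray:
    """Uniform points on the unit-sphere cap around -x of given angular radius."""
    cos_min = np.cos(np.deg2rad(cap_angle_deg))
    z = rng.uniform(cos_min, 1.0, size=n)  # cosine of angle from cap axis
    phi = rng.uniform(0, 2 * np.pi, size=n)
    s = np.sqrt(1 - z**2)
    # cap axis is -x: axis component goes into -x
    return np.column_stack([-z, s * np.cos(phi), s * np.sin(phi)])


def _farthest_point_seeds(points: np.ndarray, k: int, rng) -> np.ndarray:
    seeds = [int(rng.integers(len(points)))]
    d = np.linalg.norm(points - points[seeds[0]], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        seeds.append(nxt)
        d = np.minimum(d, np.linalg.norm(points - points[nxt], axis=1))
    return np.array(seeds)


def generate_geometry(cfg: SyntheticConfig) -> Geometry:
    """Bilateral spherical geometry with a contiguous mirrored partition.

    Left-hemisphere nodes are sampled on a unit-sphere cap; the right
    hemisphere is the exact mirror image (x -> -x), so node ``i + n/2``
    is the homologue of node ``i``.  The partition is seeded by
    farthest-point sampling on the left and copied to homologues.
    """
    if cfg.n_nodes < 2 * cfg.n_partitions:
        raise ValueError("n_nodes must be >= 2 * n_partitions")
    rng = cfg.rng("geometry")
    half = cfg.n_nodes // 2
    left = _sample_cap(rng, half, cfg.cap_angle_deg)
    right = left * np.array([-1.0, 1.0, 1.0])
    sphere = np.vstack([left, right])
    hemisphere = np.array(["L"] * half + ["R"] * half, dtype=object)
    seeds = _farthest_point_seeds(left, cfg.n_partitions, rng)
    d_seed = cdist(left, left[seeds])
    part_left = np.argmin(d_seed, axis=1) + 1
    partition = np.concatenate([part_left, part_left])
    return Geometry(
        coords=sphere * 100.0,
        sphere_coords=sphere,
        hemisphere=hemisphere,
        partition=partition,
    )


def generate_gradient(cfg: SyntheticConfig, geometry: Geometry) -> np.ndarray:
    """Planted smooth hierarchy: linear field + kernel-smoothed noise.

    Computed on the left hemisphere and copied to homologues, then
    standardized to mean 0, sd 1.
    """
    rng = cfg.rng("gradient")
    half = len(geometry.coords) // 2
    left = geometry.coords[:half]
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    linear = left @ u
    if np.std(linear) > 0:
        linear = (linear - linear.mean()) / linear.std()
    noise = rng.normal(size=half)
    d2 = cdist(left, left, "sqeuclidean")
    K = np.exp(-d2 / (2.0 * cfg.smoothness**2))
    smooth = K @ noise
    if np.std(smooth) > 0:
        smooth = (smooth - smooth.mean()) / smooth.std()
    g = cfg.linear_weight * linear + cfg.noise_weight * smooth
    sd = np.std(g)
    if sd < 1e-12:
        raise ValueError("degenerate gradient field (zero variance)")
    g = (g - g.mean()) / sd
    return np.concatenate([g, g])


def _group_edge_probability(cfg, geometry, g) -> np.ndarray:
    d = cdist(geometry.coords, geometry.coords)
    p = np.exp(-d / cfg.lambda_space) * np.exp(
        -np.abs(g[:, None] - g[None, :]) / cfg.mu_hier
    )
    np.fill_diagonal(p, 0.0)
    iu = np.triu_indices(len(g), k=1)
    # rescale so the expected density matches the target; probabilities are
    # capped at 1, so iterate the scale a few times
    target = cfg.density_target
    if target > np.mean(p[iu] > 0):
        raise ValueError("density_target exceeds the maximum achievable density")
    # bisection on the scale: mean(min(scale*p, 1)) is monotone in scale
    lo = scale = target / p[iu].mean()
    hi = lo
    while np.minimum(hi * p, 1.0)[iu].mean() < target:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError("density_target not reachable by scaling")
    for _ in range(200):
        scale = 0.5 * (lo + hi)
        mean_q = np.minimum(scale * p, 1.0)[iu].mean()
        if abs(mean_q - target) < 1e-9 * target:
            break
        if mean_q < target:
            lo = scale
        else:
            hi = scale
    q = np.minimum(scale * p, 1.0)
    np.fill_diagonal(q, 0.0)
    return q


def generate_subject_sc(
    cfg: SyntheticConfig, geometry: Geometry, g: np.ndarray
) -> List[np.ndarray]:
    """Subject weight matrices sharing a common distance-decaying mask.

    A group mask is drawn once from the distance/hierarchy edge
    probabilities; each subject perturbs it by deleting a fraction of
    edges and inserting an equal count of random non-edges, then assigns
    log-normal weights rescaled into (0, 0.95].
    """
    n = len(g)
    q = _group_edge_probability(cfg, geometry, g)
    rng_mask = cfg.rng("masks")
    rng_w = cfg.rng("weights")
    iu = np.triu_indices(n, k=1)
    group_edges = rng_mask.random(len(iu[0])) < q[iu]
    edge_idx = np.flatnonzero(group_edges)
    non_idx = np.flatnonzero(~group_edges)
    subjects = []
    for _ in range(cfg.n_subjects):
        n_del = int(round(cfg.subject_edge_jitter * len(edge_idx)))
        keep = rng_mask.permutation(len(edge_idx))[n_del:]
        ins = rng_mask.permutation(len(non_idx))[:n_del]
        mask_idx = np.concatenate([edge_idx[keep], non_idx[ins]])
        W = np.zeros((n, n))
        raw = rng_w.lognormal(mean=0.0, sigma=cfg.weight_sigma, size=len(mask_idx))
        w = WEIGHT_CAP * raw / raw.max()
        rows, cols = iu[0][mask_idx], iu[1][mask_idx]
        W[rows, cols] = w
        W[cols, rows] = w
        subjects.append(W)
    return subjects


def generate_fc(cfg: SyntheticConfig, geometry: Geometry, g: np.ndarray) -> FunctionalMatrix:
    """Correlation matrix whose leading structure encodes the gradient.

    Built from latent loadings [g, nuisance smooth field] as
    corr(F F^T + fc_noise I); symmetric, unit diagonal, PSD.
    """
    rng = cfg.rng("fc")
    half = len(g) // 2
    left = geometry.coords[:half]
    d2 = cdist(left, left, "sqeuclidean")
    K = np.exp(-d2 / (2.0 * cfg.smoothness**2))
    nuis_half = K @ rng.normal(size=half)
    nuis = np.concatenate([nuis_half, nuis_half])
    if np.std(nuis) > 0:
        nuis = (nuis - nuis.mean()) / nuis.std()
    # the constant loading keeps row correlations affine in g (no saturation),
    # so the embedding can recover the gradient linearly
    F = np.column_stack([g, cfg.nuisance_weight * nuis, cfg.baseline_weight * np.ones(len(g))])
    sigma = F @ F.T + cfg.fc_noise * np.eye(len(g))
    d = np.sqrt(np.diag(sigma))
    d[d == 0] = 1.0
    fc = sigma / np.outer(d, d)
    fc = (fc + fc.T) / 2.0
    np.fill_diagonal(fc, 1.0)
    return FunctionalMatrix(np.clip(fc, -1.0, 1.0))


def generate_cohort(cfg: SyntheticConfig) -> CohortSample:
    """Run all sub-generators and assemble a full synthetic cohort."""
    geometry = generate_geometry(cfg)
    g = generate_gradient(cfg, geometry)
    subjects = generate_subject_sc(cfg, geometry, g)
    fc = generate_fc(cfg, geometry, g)
    # template connectome carries the mean subject weights (validated geometry)
    mean_w = np.mean(subjects, axis=0)
    template = Connectome(
        weights=np.clip(mean_w, 0.0, WEIGHT_CAP),
        coords=geometry.coords,
        sphere_coords=geometry.sphere_coords,
        hemisphere=geometry.hemisphere,
        partition=geometry.partition,
    )
    return CohortSample(
        connectome_template=template,
        subject_weights=subjects,
        fc=fc,
        true_gradient=g,
    )


def write_cohort(outdir, cfg: SyntheticConfig, cohort: CohortSample) -> None:
    from . import io as hio

    os.makedirs(outdir, exist_ok=True)
    for s, W in enumerate(cohort.subject_weights, start=1):
        hio.save_matrix(os.path.join(outdir, f"subject_{s:02d}.tsv"), W)
    hio.save_matrix(os.path.join(outdir, "fc.tsv"), cohort.fc.values)
    hio.write_node_table(os.path.join(outdir, "nodes.tsv"), cohort.connectome_template)
    np.savetxt(
        os.path.join(outdir, "truth.tsv"),
        cohort.true_gradient,
        fmt=hio.FLOAT_FMT,
    )
    with open(os.path.join(outdir, "config.json"), "w") as fh:
        json.dump(dataclasses.asdict(cfg), fh, indent=2)
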