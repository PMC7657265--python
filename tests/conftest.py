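import numpy as np
import pytest

import hierpath as hp
from hierpath import synthetic as syn


def make_connectome(weights, coords=None, partition=None):
    """Wrap a weight matrix in a Connectome with simple geometry."""
    W = np.asarray(weights, dtype=float)
    n = W.shape[0]
    if coords is None:
        rng = np.random.default_rng(12345 + n)
        sphere = rng.normal(size=(n, 3))
        sphere /= np.linalg.norm(sphere, axis=1, keepdims=True)
        coords = sphere * 100.0
    else:
        coords = np.asarray(coords, dtype=float)
        sphere = coords / np.maximum(np.linalg.norm(coords, axis=1, keepdims=True), 1e-12)
    hemi = np.array(["L" if i < (n + 1) // 2 else "R" for i in range(n)], dtype=object)
    return hp.Connectome(
        weights=W,
        coords=coords,
        sphere_coords=sphere,
        hemisphere=hemi,
        partition=partition,
    )


def random_weighted_graph(n, density, rng, wmax=0.9):
    """Random symmetric weight matrix with continuous weights."""
    W = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    mask = rng.random(len(iu[0])) < density
    w = rng.uniform(0.05, wmax, size=mask.sum())
    W[iu[0][mask], iu[1][mask]] = w
    W += W.T
    return W


@pytest.fixture(scope="session")
def default_cohort():
    cfg = syn.SyntheticConfig(n_nodes=100, n_subjects=6, seed=7)
    return cfg, syn.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_pipeline(default_cohort):
    """Consensus SC, hierarchy map and PathSet on the shared cohort."""
    cfg, cohort = default_cohort
    ct = cohort.connectome_template
    W, _ = hp.consensus_sc(cohort.subject_weights, ct.coords, ct.hemisphere)
    sc = hp.Connectome(
        weights=W,
        coords=ct.coords,
        sphere_coords=ct.sphere_coords,
        hemisphere=ct.hemisphere,
        partition=ct.partition,
    )
    emb = hp.orient_gradient(hp.diffusion_map(cohort.fc), cohort.true_gradient)
    hmap = hp.bin_hierarchy(emb.components[:, 0])
    ps = hp.all_pairs_paths(hp.weights_to_lengths(sc))
    return sc, hmap, ps
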