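"""End-to-end orchestration from a single JSON run configuration."""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from typing import Dict, Optional

import numpy as np

from . import consensus as cns
from . import embedding as emb
from . import flow as flw
from . import io as hio
from . import measures as msr
from . import motifs as mtf
from . import navigation as nav
from . import nulls as nul
from . import paths as pth
from . import synthetic as syn
from . import transitions as trn
from .core import Connectome, FunctionalMatrix

log = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "simulate": {},  # SyntheticConfig fields; omit to run on external files
    "inputs": {},  # alternatively: subjects (glob), fc, nodes
    "n_bins": 10,
    "consensus_bins": None,
    "weight_mean": "all",
    "beta_step": 0.05,
    "null_reps": 200,
    "null_bins": 10,
    "seed": 0,
    "outdir": "hierpath_out",
}


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: str) -> Dict:
    with open(path) as fh:
        user = json.load(fh)
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(user)
    if not cfg.get("simulate") and not cfg.get("inputs"):
        raise ValueError("config must provide either a 'simulate' block or 'inputs'")
    if cfg.get("inputs"):
        for key in ("subjects", "fc", "nodes"):
            if key not in cfg["inputs"]:
                raise ValueError(f"inputs block missing '{key}'")
    return cfg


def run_all(cfg: Dict, outdir: Optional[str] = None) -> Dict:
    """Execute every stage in dependency order; returns the manifest."""
    outdir = outdir or cfg.get("outdir", "hierpath_out")
    os.makedirs(outdir, exist_ok=True)
    manifest: Dict = {"stages": {}, "seed": cfg.get("seed", 0)}

    def record(stage: str, t0: float, files):
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "files": {os.path.basename(f): _sha256(f) for f in files},
        }
        log.info("stage %-12s done (%.2fs)", stage, time.time() - t0)

    # --- inputs -----------------------------------------------------------
    t0 = time.time()
    use_simulation = not cfg.get("inputs")
    if use_simulation:
        sim_kwargs = dict(cfg.get("simulate") or {})
        sim_kwargs.setdefault("seed", cfg.get("seed", 0))
        scfg = syn.SyntheticConfig(**sim_kwargs)
        cohort = syn.generate_cohort(scfg)
        simdir = os.path.join(outdir, "cohort")
        syn.write_cohort(simdir, scfg, cohort)
        template = cohort.connectome_template
        subjects = cohort.subject_weights
        fc = cohort.fc
        record("simulate", t0, [os.path.join(simdir, "nodes.tsv")])
    else:
        import glob as _glob

        paths_ = sorted(_glob.glob(cfg["inputs"]["subjects"]))
        if not paths_:
            raise ValueError(f"no subject matrices match {cfg['inputs']['subjects']}")
        template = hio.read_connectome(paths_[0], cfg["inputs"]["nodes"])
        subjects = [hio.load_matrix(p) for p in paths_]
        fc = hio.read_fc(cfg["inputs"]["fc"])
        record("load", t0, paths_[:1])

    # --- consensus --------------------------------------------------------
    t0 = time.time()
    W, report = cns.consensus_sc(
        subjects,
        template.coords,
        template.hemisphere,
        n_bins=cfg.get("consensus_bins"),
        weight_mean=cfg.get("weight_mean", "all"),
    )
    sc = Connectome(
        weights=W,
        coords=template.coords,
        sphere_coords=template.sphere_coords,
        hemisphere=template.hemisphere,
        partition=template.partition,
        names=template.names,
    )
    f_cons = os.path.join(outdir, "consensus.tsv")
    hio.save_matrix(f_cons, W)
    with open(os.path.join(outdir, "consensus_report.json"), "w") as fh:
        json.dump(dataclasses.asdict(report), fh, indent=2)
    record("consensus", t0, [f_cons])

    # --- hierarchy --------------------------------------------------------
    t0 = time.time()
    embedding = emb.diffusion_map(fc)
    reference = cfg.get("reference_gradient")
    if reference is None and use_simulation:
        reference = cohort.true_gradient
    if reference is not None:
        embedding = emb.orient_gradient(embedding, np.asarray(reference, dtype=float))
    hmap = emb.bin_hierarchy(embedding.components[:, 0], n_bins=cfg.get("n_bins", 10))
    f_grad = os.path.join(outdir, "gradient.tsv")
    hio.write_table(
        __import__("pandas").DataFrame(
            {
                "node": np.arange(1, hmap.n_nodes + 1),
                "gradient": hmap.gradient,
                "class": hmap.classes,
            }
        ),
        f_grad,
    )
    record("embed", t0, [f_grad])

    # --- shortest paths ---------------------------------------------------
    t0 = time.time()
    lg = pth.weights_to_lengths(sc)
    ps = pth.all_pairs_paths(lg)
    psdir = os.path.join(outdir, "pathset")
    hio.write_pathset(psdir, ps)
    record("paths", t0, [os.path.join(psdir, "dist.tsv")])

    # --- motifs -----------------------------------------------------------
    t0 = time.time()
    profiles = mtf.mean_motifs(ps, hmap)
    f_motifs = os.path.join(outdir, "motifs.tsv")
    hio.write_table(mtf.motifs_table(profiles), f_motifs)
    record("motifs", t0, [f_motifs])

    # --- flow -------------------------------------------------------------
    t0 = time.time()
    fs = flw.compute_flow_stats(ps, hmap)
    f_flow = os.path.join(outdir, "flow.tsv")
    hio.write_table(flw.flow_table(fs), f_flow)
    if sc.partition is not None:
        hio.write_table(
            flw.network_aggregate(fs, sc.partition), os.path.join(outdir, "flow_networks.tsv")
        )
    record("flow", t0, [f_flow])

    # --- transitions ------------------------------------------------------
    t0 = time.time()
    tt = trn.compute_transitions(ps, hmap)
    trdir = os.path.join(outdir, "transitions")
    os.makedirs(trdir, exist_ok=True)
    for t, M in tt.one_hop.items():
        hio.save_matrix(os.path.join(trdir, f"T_{t:02d}.tsv"), M)
    for k, M in tt.multi_hop.items():
        hio.save_matrix(os.path.join(trdir, f"M_{k:02d}.tsv"), M)
    with open(os.path.join(trdir, "supports.json"), "w") as fh:
        json.dump(
            {
                "one_hop": {str(k): v for k, v in tt.one_hop_support.items()},
                "multi_hop": {str(k): v for k, v in tt.multi_hop_support.items()},
            },
            fh,
            indent=2,
        )
    record("transitions", t0, [os.path.join(trdir, "supports.json")])

    # --- navigation -------------------------------------------------------
    t0 = time.time()
    step = cfg.get("beta_step", 0.05)
    grid = np.round(np.arange(0, 1 + step / 2, step), 10)
    nres = nav.success_curves(sc, hmap, nav.NavConfig(beta_grid=grid))
    f_nav = os.path.join(outdir, "navigation.tsv")
    hio.write_table(nav.navigation_table(nres), f_nav)
    record("navigate", t0, [f_nav])

    # --- nulls and spin-tested correlation --------------------------------
    t0 = time.time()
    reps = cfg.get("null_reps", 200)
    spins = nul.spin_permutation(
        sc.sphere_coords, sc.hemisphere, n_reps=reps, seed=cfg.get("seed", 0)
    )
    r, p_spin = flw.slope_hierarchy_correlation(fs, hmap, spins.members)
    with open(os.path.join(outdir, "slope_hierarchy.json"), "w") as fh:
        json.dump({"r": r, "p_spin": p_spin, "n_reps": reps}, fh, indent=2)
    record("nulls", t0, [os.path.join(outdir, "slope_hierarchy.json")])

    # --- simple measures --------------------------------------------------
    t0 = time.time()
    simple = msr.structural_measures(sc, lg, ps)
    if sc.partition is not None:
        simple = simple.join(msr.functional_measures(fc, sc.partition))
    f_meas = os.path.join(outdir, "measures.tsv")
    hio.write_table(simple, f_meas)
    corr = msr.correlate_measures(simple, fs, nres)
    corr.insert(0, "measure", corr.index)
    hio.write_table(corr, os.path.join(outdir, "measure_correlations.tsv"))
    record("measures", t0, [f_meas])

    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
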