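# hierpath

Trace communication paths through a continuous unimodal–transmodal-style
cortical hierarchy on structural connectomes.

The package implements a complete multi-stage pipeline:

1. **Synthetic cohort generation** (`hierpath.synthetic`) — bilateral node
   geometry on a sphere, a planted smooth gradient, distance-dependent
   subject connectivity matrices, and a correlation FC matrix that encodes
   the gradient, so every stage is testable without external data.
2. **Group consensus** (`hierpath.consensus`) — hemisphere-stratified,
   distance-binned frequency consensus over subject SC matrices; mean FC.
3. **Hierarchy embedding** (`hierpath.embedding`) — diffusion map of the FC
   matrix (α = 1, σ = 1), gradient orientation, and binning into 10
   equal-size classes.
4. **Shortest paths** (`hierpath.paths`) — all-pairs weighted shortest paths
   under L = −log(W) via Floyd–Warshall with full path reconstruction, hop
   counts, diameter and equal-cost tie flags.
5. **Path motifs** (`hierpath.motifs`) — hierarchy trajectories along paths,
   averaged by (source class, target class, hop length) with 95% CIs.
6. **Flow statistics** (`hierpath.flow`) — per-node mean slope, turning-up /
   turning-down probabilities, per-network aggregation, and the spin-tested
   slope–hierarchy correlation.
7. **Transition matrices** (`hierpath.transitions`) — 1-hop T(t) by path
   position and multi-hop M(k) by lag over hierarchy classes.
8. **Greedy navigation** (`hierpath.navigation`) — β-mixed spatial /
   hierarchical greedy routing, per-source success-ratio curves, and
   detrended β* selection.
9. **Null models** (`hierpath.nulls`) — distance-binned degree-preserving
   rewiring, spherical-rotation (spin) label permutation with hemisphere
   mirroring, plain label permutation, permutation p-values and BH-FDR.
10. **Simple measures** (`hierpath.measures`) — betweenness (over the same
    unique path set), closeness, clustering, degree, mean edge length, FC
    strength, participation, and their correlations with the motif-derived
    measures.

## CLI

Every stage is a subcommand of `hierpath`; `all` runs the full pipeline from
a JSON config:

```bash
hierpath simulate --out cohort/ --n-nodes 200 --n-subjects 20 --seed 1
hierpath consensus --subjects 'cohort/subject_*.tsv' --nodes cohort/nodes.tsv \
    --out consensus.tsv --report report.json
hierpath embed --fc cohort/fc.tsv --out gradient.tsv --reference cohort/truth.tsv
hierpath paths --sc consensus.tsv --nodes cohort/nodes.tsv --out pathset/
hierpath motifs --paths pathset/ --gradient gradient.tsv --out motifs.tsv
hierpath flow --paths pathset/ --gradient gradient.tsv --nodes cohort/nodes.tsv \
    --spin-reps 200 --out flow.tsv
hierpath transitions --paths pathset/ --gradient gradient.tsv --out transitions/
hierpath navigate --sc consensus.tsv --nodes cohort/nodes.tsv \
    --gradient gradient.tsv --out nav.tsv
hierpath nulls --kind spin --nodes cohort/nodes.tsv --reps 2000 --seed 1 --out nulls/
hierpath all --config run.json --outdir out/
```

A minimal `run.json`:

```json
{"simulate": {"n_nodes": 100, "n_subjects": 5}, "null_reps": 200, "seed": 1}
```

All matrix inputs are delimited text (comma/tab/whitespace auto-detected,
bare or with header/row labels); all outputs are tab-separated with headers,
1-based node indices, and full-precision floats (write→read round-trips are
value-identical).

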