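"""Readers and writers for all on-disk artifacts.

Input matrices may be comma-, tab-, or whitespace-delimited, bare or
wrapped with header/row labels (auto-detected).  All output is
tab-delimited with a header row; floats are printed with 17 significant
digits so write -> read round-trips are value-identical.
"""
from __future__ import annotations

import json
import logging
import os
from typing import Optional

import numpy as np
import pandas as pd

from .core import Connectome, FunctionalMatrix, PathSet

log = logging.getLogger(__name__)

FLOAT_FMT = "%.17g"

NODE_COLUMNS = ("name", "x", "y", "z", "sx", "sy", "sz", "hemisphere")


def _sniff_delimiter(first_line: str) -> Optional[str]:
    if "," in first_line:
        return ","
    if "\t" in first_line:
        return "\t"
    return None  # any whitespace


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def load_matrix(path) -> np.ndarray:
    """Load a square numeric matrix, auto-detecting delimiter and labels."""
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty matrix file: {path}")
    delim = _sniff_delimiter(lines[0])
    rows = [ln.split(delim) if delim else ln.split() for ln in lines]
    has_header = not all(_is_number(t) for t in rows[0])
    body = rows[1:] if has_header else rows
    if not body:
        raise ValueError(f"matrix file {path} has no data rows")
    # row labels: non-numeric first cell, or (with a header) a body row as
    # wide as the header line — the corner cell accounts for the extra column
    has_row_labels = not _is_number(body[0][0]) or (
        has_header and len(body[0]) == len(rows[0]) == len(body) + 1
    )
    if has_row_labels:
        body = [r[1:] for r in body]
    try:
        M = np.array([[float(t) for t in r] for r in body], dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric entry in matrix file {path}: {exc}") from exc
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"matrix in {path} is not square: {M.shape}")
    return M


def save_matrix(path, M: np.ndarray, labels=None) -> None:
    """Write a matrix as TSV; with ``labels``, add header and row labels."""
    M = np.asarray(M)
    with open(path, "w") as fh:
        if labels is not None:
            fh.write("node\t" + "\t".join(map(str, labels)) + "\n")
            for lab, row in zip(labels, M):
                fh.write(str(lab) + "\t" + "\t".join(FLOAT_FMT % v for v in row) + "\n")
        else:
            for row in M:
                fh.write("\t".join(FLOAT_FMT % v for v in row) + "\n")


def read_node_table(path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
    delim = _sniff_delimiter(first)
    df = pd.read_csv(path, sep=delim if delim else r"\s+")
    missing = [c for c in NODE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"node table {path} missing columns: {missing}")
    return df


def read_connectome(weights_path, nodes_path) -> Connectome:
    """Read a weight matrix and node table into a validated Connectome.

    Asymmetry within 1e-9 is symmetrized by averaging (logged); larger
    asymmetry, negative weights, NaN entries or a dimension mismatch
    between the matrix and the node table are errors.
    """
    W = load_matrix(weights_path)
    nodes = read_node_table(nodes_path)
    if len(nodes) != W.shape[0]:
        raise ValueError(
            f"dimension mismatch: matrix is {W.shape[0]}x{W.shape[1]} but "
            f"node table has {len(nodes)} rows"
        )
    partition = None
    if "partition" in nodes.columns and not nodes["partition"].isna().any():
        partition = nodes["partition"].to_numpy(dtype=int)
    return Connectome(
        weights=W,
        coords=nodes[["x", "y", "z"]].to_numpy(dtype=float),
        sphere_coords=nodes[["sx", "sy", "sz"]].to_numpy(dtype=float),
        hemisphere=nodes["hemisphere"].to_numpy(dtype=object),
        partition=partition,
        names=nodes["name"].astype(str).tolist(),
    )


def write_node_table(path, c: Connectome) -> None:
    df = pd.DataFrame(
        {
            "name": list(c.names),
            "x": c.coords[:, 0],
            "y": c.coords[:, 1],
            "z": c.coords[:, 2],
            "sx": c.sphere_coords[:, 0],
            "sy": c.sphere_coords[:, 1],
            "sz": c.sphere_coords[:, 2],
            "hemisphere": c.hemisphere,
        }
    )
    if c.partition is not None:
        df["partition"] = c.partition
    write_table(df, path)


def read_fc(path) -> FunctionalMatrix:
    return FunctionalMatrix(load_matrix(path))


def write_table(df: pd.DataFrame, path) -> None:
    """Write any stage output table as TSV, floats at full precision."""
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


# ---------------------------------------------------------------------------
# PathSet archive: a directory of delimited matrices + JSON metadata.

def write_pathset(dirpath, ps: PathSet) -> None:
    os.makedirs(dirpath, exist_ok=True)
    dist = ps.dist.copy()
    save_matrix(os.path.join(dirpath, "dist.tsv"), dist)
    np.savetxt(os.path.join(dirpath, "pred.tsv"), ps.pred, fmt="%d", delimiter="\t")
    np.savetxt(os.path.join(dirpath, "hops.tsv"), ps.hops, fmt="%d", delimiter="\t")
    np.savetxt(
        os.path.join(dirpath, "tie_flags.tsv"),
        ps.tie_flags.astype(int),
        fmt="%d",
        delimiter="\t",
    )
    with open(os.path.join(dirpath, "meta.json"), "w") as fh:
        json.dump({"diameter_hops": int(ps.diameter_hops), "n_nodes": ps.n_nodes}, fh)


def read_pathset(dirpath) -> PathSet:
    dist = load_matrix(os.path.join(dirpath, "dist.tsv"))
    pred = np.loadtxt(os.path.join(dirpath, "pred.tsv"), dtype=int, ndmin=2)
    hops = np.loadtxt(os.path.join(dirpath, "hops.tsv"), dtype=int, ndmin=2)
    ties = np.loadtxt(os.path.join(dirpath, "tie_flags.tsv"), dtype=int, ndmin=2)
    with open(os.path.join(dirpath, "meta.json")) as fh:
        meta = json.load(fh)
    return PathSet(
        dist=dist,
        pred=pred,
        hops=hops,
        diameter_hops=int(meta["diameter_hops"]),
        tie_flags=ties.astype(bool),
    )


def read_gradient(path):
    """Read a gradient table (columns: node, gradient, class) or bare vector."""
    with open(path) as fh:
        first = fh.readline()
    if any(not _is_number(t) for t in first.replace(",", " ").split()):
        df = read_table(path)
        return df["gradient"].to_numpy(dtype=float), (
            df["class"].to_numpy(dtype=int) if "class" in df.columns else None
        )
    vec = np.loadtxt(path, dtype=float)
    return np.atleast_1d(vec), None
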