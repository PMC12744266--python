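"""Readers and writers for the pipeline's on-disk formats.

Count matrices travel as MatrixMarket ``.mtx`` with ``genes.tsv`` /
``cells.tsv`` sidecars (or as ``.h5ad``), gene sets as GMT, interaction
databases and networks as edge TSVs, and ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


# ---------------------------------------------------------------------------
# cell counts (AnnData)

def write_counts_mtx(adata: ad.AnnData, outdir) -> None:
    """Write cells x genes counts as genes x cells MTX plus TSV sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    x = adata.X
    if not scipy.sparse.issparse(x):
        x = scipy.sparse.csr_matrix(np.asarray(x))
    scipy.io.mmwrite(outdir / "counts.mtx", x.T.astype(int))
    pd.Series(adata.var_names, name="gene").to_csv(
        outdir / "genes.tsv", sep="\t", index=False)
    adata.obs.rename_axis("cell").to_csv(outdir / "cells.tsv", sep="\t")


def read_counts_mtx(indir) -> ad.AnnData:
    indir = Path(indir)
    x = scipy.io.mmread(indir / "counts.mtx").tocsr().T
    genes = pd.read_csv(indir / "genes.tsv", sep="\t")["gene"].astype(str)
    cells = pd.read_csv(indir / "cells.tsv", sep="\t", index_col=0)
    cells.index = cells.index.astype(str)
    adata = ad.AnnData(X=x.astype(np.int64), obs=cells)
    adata.var_names = genes
    return adata


def write_counts_h5ad(adata: ad.AnnData, path) -> None:
    adata.write_h5ad(path)


def read_counts_h5ad(path) -> ad.AnnData:
    return ad.read_h5ad(path)


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT file into ``{set_name: {genes}}``."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: malformed GMT line {line!r}")
            name, _desc, *genes = fields
            sets[name] = {g for g in genes if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path,
              descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# edge lists

def write_edges(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_assignment(path) -> dict[str, str]:
    """Two-column TSV ``gene<TAB>topic`` -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "topic"],
                     dtype=str, comment="#")
    # tolerate an explicit header row
    if df.iloc[0].tolist() == ["gene", "topic"]:
        df = df.iloc[1:]
    return dict(zip(df["gene"], df["topic"]))


def write_assignment(assignment: dict[str, str], path) -> None:
    pd.DataFrame(sorted(assignment.items()), columns=["gene", "topic"]).to_csv(
        path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# ground truth

def write_ground_truth(truth, path) -> None:
    payload = {
        "gene_names": list(truth.gene_names),
        "true_edges": sorted([sorted(e) for e in truth.true_edges]),
        "true_de_by_contrast": {
            c: {g: int(s) for g, s in d.items()}
            for c, d in truth.true_de_by_contrast.items()
        },
        "true_missingness": [
            {"protein": p, "condition": c, "label": lab}
            for (p, c), lab in sorted(truth.true_missingness.items())
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_ground_truth(path):
    from .simulate import GroundTruth
    with open(path) as fh:
        payload = json.load(fh)
    return GroundTruth(
        gene_names=list(payload["gene_names"]),
        true_edges={frozenset(e) for e in payload["true_edges"]},
        true_de_by_contrast={
            c: {g: int(s) for g, s in d.items()}
            for c, d in payload["true_de_by_contrast"].items()
        },
        true_missingness={
            (rec["protein"], rec["condition"]): rec["label"]
            for rec in payload["true_missingness"]
        },
    )


# ---------------------------------------------------------------------------
# proteomics

def write_protein_matrix(pm, prefix) -> None:
    prefix = Path(prefix)
    pm.intensities.rename_axis("protein").to_csv(
        prefix.with_suffix(".tsv"), sep="\t", na_rep="NA")
    pm.sample_meta.rename_axis("sample").to_csv(
        prefix.parent / (prefix.name + "_samples.tsv"), sep="\t")


def read_protein_matrix(matrix_path, meta_path):
    from .proteomics import ProteinMatrix
    intens = pd.read_csv(matrix_path, sep="\t", index_col=0, na_values=["NA"])
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return ProteinMatrix(intensities=intens, sample_meta=meta)
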