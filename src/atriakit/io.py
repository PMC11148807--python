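"""Readers and writers for the toolkit's on-disk formats.

Count data travels as Cell Ranger-style Matrix Market triplets (matrix.mtx
or per-layer spliced.mtx / unspliced.mtx, plus barcodes.tsv and
features.tsv); gene sets as two-column TSV (set_name, gene); molecule
tables as CSV (x, y, gene[, section]); DE tables as TSV; ground truth as a
JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

__all__ = [
    "write_count_matrix",
    "read_count_matrix",
    "write_gene_sets",
    "read_gene_sets",
    "write_molecule_table",
    "read_molecule_table",
    "write_de_table",
    "read_de_table",
    "write_ground_truth",
    "read_ground_truth",
]


def write_count_matrix(adata: ad.AnnData, outdir: str | Path) -> Path:
    """Write an AnnData as a Matrix Market triplet directory.

    ``X`` goes to matrix.mtx; any layers go to ``<layer>.mtx``; barcodes
    and features to TSV. Matrices are stored genes x cells, the Cell Ranger
    convention.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(outdir / "matrix.mtx", sp.csr_matrix(np.asarray(adata.X)).T)
    for layer, values in adata.layers.items():
        sio.mmwrite(outdir / f"{layer}.mtx", sp.csr_matrix(np.asarray(values)).T)
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    adata.var.reset_index(names="gene").to_csv(
        outdir / "features.tsv", sep="\t", index=False, header=False
    )
    if len(adata.obs.columns):
        adata.obs.to_csv(outdir / "obs.tsv", sep="\t")
    return outdir


def read_count_matrix(indir: str | Path) -> ad.AnnData:
    """Read a Matrix Market triplet directory written by
    :func:`write_count_matrix` (or Cell Ranger-style layout)."""
    indir = Path(indir)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    features = pd.read_csv(indir / "features.tsv", sep="\t", header=None)
    x = sp.csr_matrix(sio.mmread(_mtx(indir, "matrix"))).T
    layers = {}
    for layer in ("spliced", "unspliced"):
        path = _find_mtx(indir, layer)
        if path is not None:
            layers[layer] = np.asarray(
                sp.csr_matrix(sio.mmread(path)).T.todense(), dtype=float
            )
    var = pd.DataFrame(index=pd.Index(features[0], name="gene"))
    if features.shape[1] > 1:
        var["category"] = features[1].to_numpy()
    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    obs_path = indir / "obs.tsv"
    if obs_path.exists():
        obs = pd.read_csv(obs_path, sep="\t", index_col=0)
        obs.index = obs.index.astype(str)
    return ad.AnnData(
        X=np.asarray(x.todense(), dtype=float), obs=obs, var=var, layers=layers
    )


def _mtx(indir: Path, stem: str) -> Path:
    path = _find_mtx(indir, stem)
    if path is None:
        raise FileNotFoundError(f"no {stem}.mtx in {indir}")
    return path


def _find_mtx(indir: Path, stem: str) -> Path | None:
    for suffix in (".mtx", ".mtx.gz"):
        path = indir / f"{stem}{suffix}"
        if path.exists():
            return path
    return None


def write_gene_sets(sets: Mapping[str, Sequence[str]], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"set_name": name, "gene": gene}
        for name, members in sets.items()
        for gene in members
    ]
    pd.DataFrame(rows, columns=["set_name", "gene"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t")
    if not {"set_name", "gene"} <= set(df.columns):
        df = pd.read_csv(path, sep="\t", header=None, names=["set_name", "gene"])
    return {
        str(name): grp["gene"].astype(str).tolist()
        for name, grp in df.groupby("set_name", sort=True)
    }


def write_molecule_table(molecules: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    molecules.to_csv(path, index=False)
    return path


def read_molecule_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"x", "y", "gene"} - set(df.columns)
    if missing:
        raise ValueError(f"molecule CSV missing columns {sorted(missing)}")
    return df


def write_de_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_de_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = {"gene", "logFC", "pvalue", "fdr", "significant"} - set(table.columns)
    if missing:
        raise ValueError(f"DE table missing columns {sorted(missing)}")
    return table


def write_ground_truth(truth, path: str | Path) -> Path:
    path = Path(path)
    payload = truth.to_dict() if hasattr(truth, "to_dict") else dict(truth)
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
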