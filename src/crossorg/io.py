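"""Plain-text I/O: 10x-style MTX triplets, annotation TSVs, and schema-tagged tables."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

SCHEMA_TAG = "# crossorg-table\tv1"


def write_study(data: ad.AnnData, outdir) -> Path:
    """MatrixMarket triplet (genes x cells, 1-based) with barcode/feature sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = data.X if sparse.issparse(data.X) else sparse.csr_matrix(data.X)
    mmwrite(str(outdir / "matrix.mtx"), X.T.tocoo().astype(int))
    pd.Series(data.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t",
                                     index=False, header=False)
    feats = pd.DataFrame({"id": data.var_names, "name": data.var_names,
                          "type": "Gene Expression"})
    feats.to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    data.obs.to_csv(outdir / "cell_annotations.tsv", sep="\t")
    data.var.to_csv(outdir / "gene_annotations.tsv", sep="\t")
    with open(outdir / "uns.json", "w") as fh:
        json.dump({k: v for k, v in data.uns.items()}, fh, indent=1, sort_keys=True)
    return outdir


def read_study(indir) -> ad.AnnData:
    indir = Path(indir)
    X = sparse.csr_matrix(mmread(str(indir / "matrix.mtx")).T)
    obs = pd.read_csv(indir / "cell_annotations.tsv", sep="\t", index_col=0)
    var = pd.read_csv(indir / "gene_annotations.tsv", sep="\t", index_col=0)
    obs.index = obs.index.astype(str)
    var.index = var.index.astype(str)
    data = ad.AnnData(X=X.astype(np.int32), obs=obs, var=var)
    uns_path = indir / "uns.json"
    if uns_path.exists():
        with open(uns_path) as fh:
            data.uns.update(json.load(fh))
    return data


def read_dense_tsv(path) -> ad.AnnData:
    """Dense cells x genes TSV entry point for real data."""
    tab = pd.read_csv(path, sep="\t", index_col=0)
    return ad.AnnData(X=sparse.csr_matrix(tab.to_numpy()),
                      obs=pd.DataFrame(index=tab.index.astype(str)),
                      var=pd.DataFrame(index=tab.columns.astype(str)))


def write_table(df: pd.DataFrame, path, index: bool = True) -> Path:
    """TSV with a schema-version header line and fixed column order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(SCHEMA_TAG + "\n")
        df.to_csv(fh, sep="\t", index=index)
    return path


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def read_gene_list(path) -> list:
    """Plain text, one gene symbol per line."""
    with open(path) as fh:
        return [ln.strip().upper() for ln in fh if ln.strip() and not ln.startswith("#")]


def write_gene_list(genes, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for g in sorted(set(genes)):
            fh.write(f"{g}\n")
    return path
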