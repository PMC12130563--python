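"""Readers and writers for the pipeline's on-disk artifacts.

Single-cell matrices use the 10x-style MTX triplet (``matrix.mtx`` stored
genes x cells and transposed on read, ``features.tsv``, ``barcodes.tsv``)
plus a ``cells.csv`` with per-cell metadata. Bulk cohorts are CSV with
``sample_id``, ``cohort``, ``label`` columns followed by one column per
gene. Every write goes through a manifest with SHA-256 checksums so
end-to-end runs can be compared byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import DegenerateInputError, ParameterError
from .synth import BulkCohort


def write_mtx(adata: ad.AnnData, outdir: str | Path) -> list[Path]:
    """Write an AnnData as matrix.mtx (genes x cells) + tsv files + cells.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    x = adata.X
    mat = sp.coo_matrix(x.T if sp.issparse(x) else np.asarray(x).T)
    paths = []
    mtx = outdir / "matrix.mtx"
    scipy.io.mmwrite(str(mtx), mat, field="integer" if _integral(mat) else "real")
    paths.append(mtx)
    feats = outdir / "features.tsv"
    pd.DataFrame({"id": adata.var_names, "name": adata.var_names}).to_csv(
        feats, sep="\t", header=False, index=False
    )
    paths.append(feats)
    bars = outdir / "barcodes.tsv"
    pd.Series(adata.obs_names).to_csv(bars, sep="\t", header=False, index=False)
    paths.append(bars)
    cells = outdir / "cells.csv"
    adata.obs.to_csv(cells, index_label="cell_id")
    paths.append(cells)
    return paths


def _integral(mat) -> bool:
    data = mat.data if sp.issparse(mat) else np.asarray(mat)
    return bool(np.all(data == np.round(data)))


def read_mtx(indir: str | Path) -> ad.AnnData:
    """Read an MTX triplet (genes x cells on disk) into a cells x genes AnnData."""
    indir = Path(indir)
    mtx_path = indir / "matrix.mtx"
    for p in (mtx_path, indir / "features.tsv", indir / "barcodes.tsv"):
        if not p.exists():
            raise FileNotFoundError(f"missing {p}")
        if p.stat().st_size == 0:
            raise ParameterError(f"empty file: {p}")
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:
        raise ParameterError(f"cannot parse {mtx_path}: {exc}") from exc
    feats = pd.read_csv(indir / "features.tsv", sep="\t", header=None)
    bars = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)
    n_genes, n_cells = mat.shape
    if len(feats) != n_genes or len(bars) != n_cells:
        raise DegenerateInputError(
            f"dimension mismatch: matrix is {n_genes} genes x {n_cells} cells "
            f"but features.tsv has {len(feats)} rows and barcodes.tsv {len(bars)}"
        )
    obs = pd.DataFrame(index=pd.Index(bars[0].astype(str), name="cell_id"))
    cells_csv = indir / "cells.csv"
    if cells_csv.exists():
        meta = pd.read_csv(cells_csv, index_col="cell_id")
        obs = meta.reindex(obs.index)
    return ad.AnnData(
        X=sp.csr_matrix(mat.T),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(feats[0].astype(str), name="gene")),
    )


def write_bulk(cohort: BulkCohort, path: str | Path) -> Path:
    path = Path(path)
    df = cohort.expr.copy()
    df.insert(0, "label", cohort.labels.reindex(df.index).to_numpy())
    df.insert(0, "cohort", cohort.name)
    df.to_csv(path, index_label="sample_id")
    return path


def read_bulk(path: str | Path) -> BulkCohort:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing {path}")
    if path.stat().st_size == 0:
        raise ParameterError(f"empty file: {path}")
    df = pd.read_csv(path, index_col="sample_id")
    for col in ("cohort", "label"):
        if col not in df.columns:
            raise ParameterError(f"{path} lacks required column {col!r}")
    name = str(df["cohort"].iloc[0])
    labels = df["label"].astype(int)
    expr = df.drop(columns=["cohort", "label"])
    return BulkCohort(name=name, expr=expr, labels=labels)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: str | Path, paths: list[Path]) -> Path:
    outdir = Path(outdir)
    manifest = {
        str(p.relative_to(outdir)): sha256_of(p) for p in sorted(set(paths))
    }
    out = outdir / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
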