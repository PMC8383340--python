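"""Readers and writers for annotated count matrices.

Supported inputs: AnnData ``.h5ad`` files (matrix in ``X``, labels in
``obs``), MatrixMarket triplets (``matrix.mtx`` + ``barcodes.tsv`` +
``features.tsv`` + per-cell ``metadata.tsv``), and dense CSV/TSV where the
header row names genes and label columns sit alongside them.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .preprocess import AnnotatedCounts, PCAEmbedding

__all__ = ["load_counts", "write_corrected_h5ad", "write_corrected_csv"]


class LoadError(ValueError):
    """Raised when an input file cannot be parsed as annotated counts."""


def _infer_format(path: str) -> str:
    if os.path.isdir(path):
        return "mtx"
    ext = os.path.splitext(path)[1].lower()
    if ext == ".h5ad":
        return "h5ad"
    if ext in (".csv", ".tsv", ".txt"):
        return "csv"
    if ext == ".mtx":
        return "mtx"
    raise LoadError(f"cannot infer format from path {path!r}; pass format=")


def load_counts(path: str, format: str | None = None, batch_key: str = "batch",
                celltype_key: str | None = None) -> AnnotatedCounts:
    """Read a cell x gene count matrix with batch (and optional cell-type) labels.

    Parameters
    ----------
    path
        File (``.h5ad``, ``.csv``/``.tsv``, ``.mtx``) or a directory holding a
        MatrixMarket triplet.
    format
        One of ``{"h5ad", "mtx", "csv"}``; inferred from the path if omitted.
    batch_key
        Name of the per-cell batch annotation (obs column / CSV column /
        metadata.tsv column).
    celltype_key
        Optional name of the per-cell cell-type annotation.
    """
    if not os.path.exists(path):
        raise LoadError(f"no such file or directory: {path}")
    fmt = format or _infer_format(path)
    if fmt == "h5ad":
        return _load_h5ad(path, batch_key, celltype_key)
    if fmt == "mtx":
        return _load_mtx(path, batch_key, celltype_key)
    if fmt == "csv":
        return _load_csv(path, batch_key, celltype_key)
    raise LoadError(f"unknown format {fmt!r}")


def _load_h5ad(path, batch_key, celltype_key):
    import anndata as ad

    adata = ad.read_h5ad(path)
    if batch_key not in adata.obs.columns:
        raise LoadError(
            f"batch key {batch_key!r} not found in obs columns "
            f"{list(adata.obs.columns)}")
    if celltype_key is not None and celltype_key not in adata.obs.columns:
        raise LoadError(f"cell-type key {celltype_key!r} not found in obs")
    x = adata.X
    return AnnotatedCounts(
        counts=x if sp.issparse(x) else np.asarray(x),
        gene_ids=list(adata.var_names),
        cell_ids=list(adata.obs_names),
        batch=adata.obs[batch_key].astype(str).to_numpy(),
        cell_type=None if celltype_key is None
        else adata.obs[celltype_key].astype(str).to_numpy(),
    )


def _load_mtx(path, batch_key, celltype_key):
    import scipy.io as sio

    if os.path.isdir(path):
        d = path
        mtx_path = os.path.join(d, "matrix.mtx")
    else:
        d = os.path.dirname(path)
        mtx_path = path
    barcodes = os.path.join(d, "barcodes.tsv")
    features = os.path.join(d, "features.tsv")
    if not os.path.exists(features):
        features = os.path.join(d, "genes.tsv")
    meta = os.path.join(d, "metadata.tsv")
    for p in (mtx_path, barcodes, features, meta):
        if not os.path.exists(p):
            raise LoadError(f"MatrixMarket input incomplete: missing {p}")
    mat = sio.mmread(mtx_path).tocsr()
    cell_ids = pd.read_csv(barcodes, sep="\t", header=None)[0].astype(str).tolist()
    gene_ids = pd.read_csv(features, sep="\t", header=None)[0].astype(str).tolist()
    if mat.shape == (len(gene_ids), len(cell_ids)) and mat.shape[0] != mat.shape[1]:
        mat = mat.T.tocsr()          # genes x cells on disk (CellRanger layout)
    if mat.shape != (len(cell_ids), len(gene_ids)):
        raise LoadError(
            f"matrix shape {mat.shape} does not match {len(cell_ids)} barcodes "
            f"x {len(gene_ids)} features")
    md = pd.read_csv(meta, sep="\t", index_col=0)
    if batch_key not in md.columns:
        raise LoadError(f"batch key {batch_key!r} not found in metadata.tsv")
    md = md.loc[cell_ids]
    return AnnotatedCounts(
        counts=mat,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        batch=md[batch_key].astype(str).to_numpy(),
        cell_type=None if celltype_key is None
        else md[celltype_key].astype(str).to_numpy(),
    )


def _load_csv(path, batch_key, celltype_key):
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if batch_key not in df.columns:
        raise LoadError(f"batch key {batch_key!r} not found in CSV columns")
    label_cols = [batch_key] + ([celltype_key] if celltype_key else [])
    if celltype_key is not None and celltype_key not in df.columns:
        raise LoadError(f"cell-type key {celltype_key!r} not found in CSV columns")
    genes = df.drop(columns=[c for c in df.columns if c in label_cols
                             or not pd.api.types.is_numeric_dtype(df[c])])
    if genes.shape[1] == 0:
        raise LoadError("CSV contains no numeric gene columns")
    try:
        counts = genes.to_numpy(dtype=float)
    except (TypeError, ValueError) as e:
        raise LoadError(f"non-numeric matrix entries: {e}") from e
    return AnnotatedCounts(
        counts=counts,
        gene_ids=list(genes.columns.astype(str)),
        cell_ids=list(df.index.astype(str)),
        batch=df[batch_key].astype(str).to_numpy(),
        cell_type=None if celltype_key is None
        else df[celltype_key].astype(str).to_numpy(),
    )


def write_corrected_h5ad(path: str, data: AnnotatedCounts,
                         corrected: np.ndarray, hvg_ids: list[str],
                         embedding: PCAEmbedding,
                         raw_embedding: PCAEmbedding | None = None) -> None:
    """Write corrected expression (cells x HVGs) and PCA embeddings to h5ad."""
    import anndata as ad

    adata = ad.AnnData(X=np.asarray(corrected, dtype=np.float32))
    adata.obs_names = list(data.cell_ids)
    adata.var_names = list(hvg_ids)
    adata.obs["batch"] = pd.Categorical(data.batch.astype(str))
    if data.cell_type is not None:
        adata.obs["cell_type"] = pd.Categorical(data.cell_type.astype(str))
    adata.obsm["X_pca_corrected"] = np.asarray(embedding.coords, dtype=np.float32)
    if raw_embedding is not None:
        adata.obsm["X_pca_raw"] = np.asarray(raw_embedding.coords, dtype=np.float32)
    adata.write_h5ad(path)


def write_corrected_csv(path: str, data: AnnotatedCounts,
                        embedding: PCAEmbedding) -> None:
    """Write the corrected PCA embedding with labels as a CSV table."""
    df = pd.DataFrame(
        embedding.coords,
        index=pd.Index(data.cell_ids, name="cell_id"),
        columns=[f"PC{i + 1}" for i in range(embedding.n_pc)],
    )
    df.insert(0, "batch", data.batch.astype(str))
    if data.cell_type is not None:
        df.insert(1, "cell_type", data.cell_type.astype(str))
    df.to_csv(path)
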