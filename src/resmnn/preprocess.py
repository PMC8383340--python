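"""Standard scRNA-seq preprocessing feeding the correction network.

The pipeline mirrors the common Scanpy workflow: QC filtering, total-count
normalization to a fixed scale, log1p, highly-variable-gene selection,
per-gene z-scoring with clipping, and PCA to a low-dimensional subspace in
which mutual nearest neighbors are searched and the batch loss is evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "AnnotatedCounts",
    "ScaledMatrix",
    "PCAModel",
    "PCAEmbedding",
    "qc_filter",
    "normalize_and_log",
    "select_hvgs",
    "scale_and_clip",
    "fit_pca",
]


class PreprocessError(ValueError):
    """Raised when an input violates a preprocessing precondition."""


def _as_2d(matrix):
    if sp.issparse(matrix):
        return matrix.tocsr()
    arr = np.asarray(matrix)
    if arr.ndim != 2:
        raise PreprocessError(f"expected a 2-D matrix, got shape {arr.shape}")
    return arr


@dataclass
class AnnotatedCounts:
    """Raw cell x gene counts plus per-cell batch and optional cell-type labels.

    ``counts`` may be dense or scipy-sparse; rows are cells, columns genes.
    At least two batches, each non-empty, are required for any correction run
    (validated at correction time, not construction: single-batch objects are
    legal inputs to preprocessing).
    """

    counts: "np.ndarray | sp.spmatrix"
    gene_ids: list[str]
    cell_ids: list[str]
    batch: np.ndarray
    cell_type: np.ndarray | None = None

    def __post_init__(self):
        self.counts = _as_2d(self.counts)
        self.gene_ids = list(map(str, self.gene_ids))
        self.cell_ids = list(map(str, self.cell_ids))
        self.batch = np.asarray(self.batch)
        n, g = self.counts.shape
        if len(self.cell_ids) != n or len(self.batch) != n:
            raise PreprocessError(
                f"cell label length mismatch: {n} cells, "
                f"{len(self.cell_ids)} ids, {len(self.batch)} batch labels"
            )
        if len(self.gene_ids) != g:
            raise PreprocessError(
                f"gene id length mismatch: {g} genes, {len(self.gene_ids)} ids"
            )
        if self.cell_type is not None:
            self.cell_type = np.asarray(self.cell_type)
            if len(self.cell_type) != n:
                raise PreprocessError("cell_type label length mismatch")
        if (self.counts.min() if not sp.issparse(self.counts)
                else self.counts.data.min(initial=0.0)) < 0:
            raise PreprocessError("counts matrix contains negative entries")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def batches(self) -> np.ndarray:
        return np.unique(self.batch)

    @property
    def n_batches(self) -> int:
        return len(self.batches)

    def subset(self, cell_mask=None, gene_mask=None) -> "AnnotatedCounts":
        cell_mask = slice(None) if cell_mask is None else np.asarray(cell_mask)
        gene_mask = slice(None) if gene_mask is None else np.asarray(gene_mask)
        counts = self.counts[cell_mask][:, gene_mask]
        return AnnotatedCounts(
            counts=counts,
            gene_ids=list(np.asarray(self.gene_ids)[gene_mask]),
            cell_ids=list(np.asarray(self.cell_ids)[cell_mask]),
            batch=self.batch[cell_mask],
            cell_type=None if self.cell_type is None else self.cell_type[cell_mask],
        )


@dataclass
class ScaledMatrix:
    """Z-scored, clipped expression over the selected HVGs (network input X)."""

    values: np.ndarray          # cells x n_hvg, dense
    hvg_ids: list[str]
    mean: np.ndarray            # per-gene mean used for the z-score
    std: np.ndarray             # per-gene SD used for the z-score (ddof=0)
    clip: float = 10.0

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class PCAModel:
    """Fixed PCA loadings: projection is (X - center) @ components."""

    components: np.ndarray       # n_hvg x n_pc, orthonormal columns
    center: np.ndarray           # per-gene mean of the scaled matrix
    explained_variance: np.ndarray

    @property
    def n_pc(self) -> int:
        return self.components.shape[1]

    def project(self, values: np.ndarray, source: str = "input",
                center: bool = True) -> "PCAEmbedding":
        if values.shape[1] != self.components.shape[0]:
            raise PreprocessError(
                f"cannot project {values.shape[1]}-dim data through a "
                f"{self.components.shape[0]}-dim PCA model"
            )
        x = values - self.center if center else values
        return PCAEmbedding(coords=x @ self.components, source=source)


@dataclass
class PCAEmbedding:
    coords: np.ndarray           # cells x n_pc
    source: str = "input"        # "input" (X^pca) or "corrected" (Y^pca)

    @property
    def n_pc(self) -> int:
        return self.coords.shape[1]

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


def qc_filter(data: AnnotatedCounts, min_genes_per_cell: int = 200,
              min_cells_per_gene: int = 3) -> AnnotatedCounts:
    """Drop cells expressing too few genes, then genes seen in too few cells.

    A gene counts as "expressed" in a cell when its count is > 0. Survivor
    order is preserved. Raises if every cell is filtered out.
    """
    if min_genes_per_cell < 0 or min_cells_per_gene < 0:
        raise PreprocessError("QC thresholds must be non-negative")
    counts = data.counts
    nz = counts > 0
    genes_per_cell = np.asarray(nz.sum(axis=1)).ravel()
    cell_mask = genes_per_cell >= min_genes_per_cell
    if not cell_mask.any():
        raise PreprocessError(
            f"qc_filter removed all {data.n_cells} cells "
            f"(min_genes_per_cell={min_genes_per_cell})"
        )
    nz_kept = nz[cell_mask]
    cells_per_gene = np.asarray(nz_kept.sum(axis=0)).ravel()
    gene_mask = cells_per_gene >= min_cells_per_gene
    return data.subset(cell_mask, gene_mask)


def normalize_and_log(data: AnnotatedCounts, scale: float = 1e4):
    """Total-count normalize each cell to ``scale`` and log1p-transform.

    Entry (i, j) becomes log(1 + counts_ij * scale / total_i); the pre-log
    row sums therefore all equal ``scale``. Returns a matrix of the same
    sparsity kind as the input (sparse in, sparse out).
    """
    counts = data.counts
    totals = np.asarray(counts.sum(axis=1)).ravel().astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = [data.cell_ids[i] for i in zero[:5]]
        raise PreprocessError(
            f"{zero.size} cell(s) have zero total count and cannot be "
            f"normalized (first offenders: {names}); apply qc_filter first"
        )
    if sp.issparse(counts):
        out = counts.tocsr().astype(float)
        scale_rows = sp.diags(scale / totals)
        out = scale_rows @ out
        out.data = np.log1p(out.data)
        return out
    return np.log1p(counts * (scale / totals[:, None]))


def select_hvgs(normlog, gene_ids: list[str], n_top: int = 2000) -> list[str]:
    """Rank genes by mean-binned normalized dispersion and keep the top ``n_top``.

    Uses the standard "seurat-flavor" dispersion criterion on log-normalized
    data (dispersion of the de-logged values, normalized within 20 bins of
    mean expression).
    """
    import anndata as ad
    import scanpy as sc

    g = len(gene_ids)
    if n_top > g:
        raise PreprocessError(f"n_top={n_top} exceeds gene count {g}")
    if n_top == g:
        return list(gene_ids)
    mat = normlog.astype(np.float32) if sp.issparse(normlog) else np.asarray(
        normlog, dtype=np.float32)
    adata = ad.AnnData(X=mat)
    adata.var_names = [str(i) for i in range(g)]
    sc.pp.highly_variable_genes(adata, flavor="seurat", n_top_genes=n_top)
    idx = np.flatnonzero(adata.var["highly_variable"].to_numpy())
    # scanpy can return a few more/less on dispersion ties; enforce exactly n_top
    if len(idx) != n_top:
        order = np.argsort(-adata.var["dispersions_norm"].to_numpy(), kind="stable")
        idx = np.sort(order[:n_top])
    return [gene_ids[i] for i in idx]


def scale_and_clip(normlog, gene_ids: list[str], hvg_ids: list[str],
                   clip: float = 10.0, symmetric: bool = False) -> ScaledMatrix:
    """Restrict to HVG columns, z-score each gene, clip extreme values.

    The z-score uses the population SD (ddof=0); a zero-SD gene is guarded by
    substituting SD=1 (its z-scores are then exactly 0). By default only the
    upper tail is clipped at ``+clip`` (the common max_value convention);
    ``symmetric=True`` also clips at ``-clip``.
    """
    if len(hvg_ids) == 0:
        raise PreprocessError("empty HVG list")
    pos = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for g in hvg_ids if g not in pos]
    if missing:
        raise PreprocessError(f"HVG ids not present in gene ids: {missing[:5]}")
    cols = np.array([pos[g] for g in hvg_ids])
    x = normlog[:, cols]
    x = np.asarray(x.todense()) if sp.issparse(x) else np.array(x, dtype=float)
    mean = x.mean(axis=0)
    std = x.std(axis=0, ddof=0)
    std_safe = np.where(std == 0, 1.0, std)
    z = (x - mean) / std_safe
    z = np.minimum(z, clip)
    if symmetric:
        z = np.maximum(z, -clip)
    return ScaledMatrix(values=z, hvg_ids=list(hvg_ids), mean=mean,
                        std=std_safe, clip=clip)


def fit_pca(scaled: ScaledMatrix, n_pc: int = 50,
            random_state: int = 0) -> tuple[PCAModel, PCAEmbedding]:
    """Fit PCA on all cells pooled across batches; return model and embedding.

    Components are ordered by decreasing explained variance, and each
    component's sign is fixed so that its largest-magnitude loading is
    positive, making the embedding reproducible up to floating-point noise.
    Centering uses the post-clip column means.
    """
    from sklearn.decomposition import PCA

    x = scaled.values
    max_pc = min(x.shape)
    if n_pc > max_pc:
        raise PreprocessError(
            f"n_pc={n_pc} exceeds min(cells, genes)={max_pc}")
    p = PCA(n_components=n_pc, svd_solver="full" if max_pc <= 1000 else "randomized",
            random_state=random_state)
    coords = p.fit_transform(x)
    components = p.components_.T.copy()          # n_hvg x n_pc
    flip = np.sign(components[np.abs(components).argmax(axis=0),
                              np.arange(n_pc)])
    flip[flip == 0] = 1.0
    components *= flip
    coords *= flip
    model = PCAModel(components=components, center=p.mean_.copy(),
                     explained_variance=p.explained_variance_.copy())
    return model, PCAEmbedding(coords=coords, source="input")
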