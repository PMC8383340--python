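"""Integration metrics: kNN-graph entropies, ARI F1, and ASW F1.

Good batch correction mixes batches while keeping cell types apart. Three
complementary views are computed on a (typically 50-dimensional PCA)
embedding:

* per-cell batch / cell-type entropies over each cell's 20-nearest-neighbor
  composition: E_i = -(1/M) * sum_m P_im * log(P_im) with M categories and
  P_im the fraction of neighbors of category m (natural log; high batch
  entropy = good mixing, low cell-type entropy = preserved biology);
* ARI F1: k-means cluster labels are compared against batch and cell-type
  labels via the adjusted Rand index on 20 random 80% subsamples; both ARIs
  are rescaled to [0, 1] and combined as
  F1 = 2 * (1 - ARI_batch) * ARI_celltype / (1 - ARI_batch + ARI_celltype);
* ASW F1: the average silhouette width under batch and cell-type labelings,
  rescaled to [0, 1] and combined with the same harmonic form, on the same
  subsampling protocol.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .preprocess import PCAEmbedding

__all__ = [
    "KnnGraph", "MetricReport", "build_knn_graph", "label_entropy",
    "rand_index", "adjusted_rand_index", "ari_f1", "silhouette", "asw_f1",
    "evaluate_embedding", "harmonic_f1",
]


class MetricError(ValueError):
    """Raised on inputs for which a metric is undefined."""


def _coords(embedding) -> np.ndarray:
    c = embedding.coords if isinstance(embedding, PCAEmbedding) else np.asarray(embedding)
    return np.asarray(c, dtype=np.float64)


def _encode(labels) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    cats, codes = np.unique(labels, return_inverse=True)
    return cats, codes


@dataclass
class KnnGraph:
    """Exact k-nearest-neighbor lists (no self-loops) over an embedding."""

    neighbor_ids: np.ndarray     # n x k, sorted by distance
    k: int

    @property
    def n_cells(self) -> int:
        return len(self.neighbor_ids)


def build_knn_graph(embedding, k: int = 20) -> KnnGraph:
    """Exact Euclidean kNN graph; k is truncated to n - 1."""
    from sklearn.neighbors import NearestNeighbors

    coords = _coords(embedding)
    n = len(coords)
    if n < 2:
        raise MetricError("kNN graph needs at least 2 cells")
    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1, metric="euclidean").fit(coords)
    _, idx = nn.kneighbors(coords)
    rows = np.arange(n)[:, None]
    keep = idx != rows                       # drop the self hit wherever it lands
    # with duplicate points the self row may not be first; keep first k_eff others
    out = np.empty((n, k_eff), dtype=np.int64)
    for i in range(n):
        others = idx[i][keep[i]]
        if len(others) < k_eff:              # all-duplicate corner case
            others = np.concatenate([others, idx[i][~keep[i]][1:]])
        out[i] = others[:k_eff]
    return KnnGraph(neighbor_ids=out, k=k_eff)


def label_entropy(graph: KnnGraph, labels, n_categories: int | None = None
                  ) -> np.ndarray:
    """Per-cell neighborhood entropy of a categorical label.

    E_i = -(1/M) * sum_m P_im * log(P_im), with M = ``n_categories`` and
    P_im the fraction of cell i's neighbors carrying category m (0 log 0 = 0,
    natural log). The maximum, attained at a uniform neighborhood, is
    log(M) / M.
    """
    cats, codes = _encode(labels)
    if len(codes) != graph.n_cells:
        raise MetricError("labels do not cover every cell in the graph")
    m = n_categories if n_categories is not None else len(cats)
    if len(cats) > m:
        raise MetricError(f"found {len(cats)} categories, expected <= {m}")
    neigh = codes[graph.neighbor_ids]
    counts = np.stack([(neigh == c).sum(axis=1) for c in range(m)], axis=1)
    p = counts / graph.k
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return -plogp.sum(axis=1) / m


def _contingency(codes_a: np.ndarray, codes_b: np.ndarray) -> np.ndarray:
    na, nb = codes_a.max() + 1, codes_b.max() + 1
    return np.bincount(codes_a * nb + codes_b,
                       minlength=na * nb).reshape(na, nb)


def _comb2(x: np.ndarray) -> np.ndarray:
    return x * (x - 1) / 2.0


def rand_index(labels_a, labels_b) -> float:
    """Rand index: (agreeing pairs) / (all pairs), from the contingency table.

    a = same-label pairs placed together in both labelings; b = different-
    label pairs separated in both; RI = (a + b) / C(n, 2).
    """
    _, ca = _encode(labels_a)
    _, cb = _encode(labels_b)
    if len(ca) != len(cb):
        raise MetricError("labelings have different lengths")
    n = len(ca)
    if n < 2:
        raise MetricError("Rand index needs at least 2 cells")
    table = _contingency(ca, cb)
    a = _comb2(table).sum()
    sum_rows = _comb2(table.sum(axis=1)).sum()
    sum_cols = _comb2(table.sum(axis=0)).sum()
    total = _comb2(np.array(n))
    b = total - sum_rows - sum_cols + a
    return float((a + b) / total)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected Rand index, ARI = (RI - E[RI]) / (max RI - E[RI]).

    Uses the standard permutation-model expectation; the degenerate case of
    a single cluster on both sides is defined as 1.
    """
    from sklearn.metrics import adjusted_rand_score

    la, lb = np.asarray(labels_a), np.asarray(labels_b)
    if len(la) != len(lb):
        raise MetricError("labelings have different lengths")
    return float(adjusted_rand_score(la, lb))


def harmonic_f1(batch_norm: float, celltype_norm: float) -> float:
    """F1 = 2 * (1 - batch) * celltype / (1 - batch + celltype), in [0, 1]."""
    num = 2.0 * (1.0 - batch_norm) * celltype_norm
    den = (1.0 - batch_norm) + celltype_norm
    return float(num / den) if den > 0 else 0.0


def _subsample_seeds(seed: int, reps: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).generate_state(reps)]


def ari_f1(embedding, batch, celltype, frac: float = 0.8, reps: int = 20,
           seed: int = 0, n_clusters: int | None = None) -> dict:
    """ARI-based mixing/separation F1 over random subsamples.

    Each replicate draws ``frac`` of the cells without replacement, clusters
    them with seeded k-means (k = number of cell types present in the
    subsample unless overridden), computes ARI against batch and cell-type
    labels, rescales both via (ARI + 1) / 2, and combines them with the
    harmonic F1. Returns the replicate vectors and their medians.
    """
    from sklearn.cluster import KMeans

    coords = _coords(embedding)
    batch = np.asarray(batch)
    if celltype is None:
        raise MetricError("ARI F1 requires cell-type labels")
    celltype = np.asarray(celltype)
    n = len(coords)
    f1s, ari_b, ari_c = [], [], []
    for rng in _subsample_seeds(seed, reps):
        sub = np.sort(rng.choice(n, size=max(2, int(round(frac * n))),
                                 replace=False))
        k = n_clusters or len(np.unique(celltype[sub]))
        km = KMeans(n_clusters=k, n_init=10,
                    random_state=int(rng.integers(2 ** 31)))
        clusters = km.fit_predict(coords[sub])
        ab = adjusted_rand_index(clusters, batch[sub])
        ac = adjusted_rand_index(clusters, celltype[sub])
        ari_b.append(ab)
        ari_c.append(ac)
        f1s.append(harmonic_f1((ab + 1) / 2, (ac + 1) / 2))
    return {"f1": np.array(f1s), "ari_batch": np.array(ari_b),
            "ari_celltype": np.array(ari_c),
            "median_f1": float(np.median(f1s))}


def silhouette(embedding, labels) -> tuple[np.ndarray, float]:
    """Per-cell silhouette widths and their mean (ASW).

    s_i = (b_i - a_i) / max(a_i, b_i), with a_i the mean distance to the
    cell's own cluster (excluding itself) and b_i the smallest mean distance
    to any other cluster; singleton clusters score 0.
    """
    from sklearn.metrics import silhouette_samples

    coords = _coords(embedding)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise MetricError("silhouette needs at least 2 clusters")
    s = silhouette_samples(coords, labels, metric="euclidean")
    return s, float(s.mean())


def asw_f1(embedding, batch, celltype, frac: float = 0.8, reps: int = 20,
           seed: int = 0) -> dict:
    """Silhouette-based mixing/separation F1 over random subsamples.

    Each replicate draws ``frac`` of the cells, computes the average
    silhouette width under the batch and the cell-type labeling, rescales
    both via (ASW + 1) / 2, and combines them with the harmonic F1.
    """
    coords = _coords(embedding)
    batch = np.asarray(batch)
    if celltype is None:
        raise MetricError("ASW F1 requires cell-type labels")
    celltype = np.asarray(celltype)
    n = len(coords)
    f1s, asw_b, asw_c = [], [], []
    for rng in _subsample_seeds(seed, reps):
        sub = np.sort(rng.choice(n, size=max(2, int(round(frac * n))),
                                 replace=False))
        _, ab = silhouette(coords[sub], batch[sub])
        _, ac = silhouette(coords[sub], celltype[sub])
        asw_b.append(ab)
        asw_c.append(ac)
        f1s.append(harmonic_f1((ab + 1) / 2, (ac + 1) / 2))
    return {"f1": np.array(f1s), "asw_batch": np.array(asw_b),
            "asw_celltype": np.array(asw_c),
            "median_f1": float(np.median(f1s))}


@dataclass
class MetricReport:
    """Full evaluation of one embedding against batch and cell-type labels."""

    batch_entropy: np.ndarray
    celltype_entropy: np.ndarray
    ari: dict = field(default_factory=dict)
    asw: dict = field(default_factory=dict)

    @property
    def median_batch_entropy(self) -> float:
        return float(np.median(self.batch_entropy))

    @property
    def median_celltype_entropy(self) -> float:
        return float(np.median(self.celltype_entropy))

    def summary(self) -> dict:
        return {
            "median_batch_entropy": self.median_batch_entropy,
            "median_celltype_entropy": self.median_celltype_entropy,
            "median_ari_f1": self.ari["median_f1"],
            "median_asw_f1": self.asw["median_f1"],
        }

    def to_json(self, path: str) -> None:
        payload = self.summary()
        payload["batch_entropy_quartiles"] = list(
            np.percentile(self.batch_entropy, [25, 50, 75]))
        payload["celltype_entropy_quartiles"] = list(
            np.percentile(self.celltype_entropy, [25, 50, 75]))
        payload["ari_f1_replicates"] = self.ari["f1"].tolist()
        payload["asw_f1_replicates"] = self.asw["f1"].tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def replicates_to_tsv(self, path: str) -> None:
        import pandas as pd

        pd.DataFrame({
            "replicate": np.arange(len(self.ari["f1"])),
            "ari_f1": self.ari["f1"],
            "ari_batch": self.ari["ari_batch"],
            "ari_celltype": self.ari["ari_celltype"],
            "asw_f1": self.asw["f1"],
            "asw_batch": self.asw["asw_batch"],
            "asw_celltype": self.asw["asw_celltype"],
        }).to_csv(path, sep="\t", index=False)


def evaluate_embedding(embedding, batch, celltype, k: int = 20,
                       frac: float = 0.8, reps: int = 20,
                       seed: int = 0) -> MetricReport:
    """Compute entropies, ARI F1 and ASW F1 for one embedding."""
    batch = np.asarray(batch)
    graph = build_knn_graph(embedding, k=k)
    b_cats, _ = _encode(batch)
    e_b = label_entropy(graph, batch, n_categories=len(b_cats))
    if celltype is None:
        raise MetricError("evaluation requires cell-type labels")
    celltype = np.asarray(celltype)
    c_cats, _ = _encode(celltype)
    e_c = label_entropy(graph, celltype, n_categories=len(c_cats))
    return MetricReport(
        batch_entropy=e_b,
        celltype_entropy=e_c,
        ari=ari_f1(embedding, batch, celltype, frac=frac, reps=reps, seed=seed),
        asw=asw_f1(embedding, batch, celltype, frac=frac, reps=reps,
                   seed=seed + 1),
    )
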