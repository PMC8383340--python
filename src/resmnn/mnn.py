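"""Mutual-nearest-neighbor pair search across batches in PCA space.

For every ordered pair of batches (p, q), each cell of p queries the k
nearest cells of q under Euclidean distance; a cross-batch cell pair (i, j)
is kept when each cell appears in the other's neighbor list. The union over
all batch pairs forms the MNN pair set that drives the batch loss.

Search runs either exactly (scikit-learn) or approximately (pynndescent,
seeded); a paired-duplicate structure across batches makes each cell's copy
its mutual rank-1 neighbor, which the tests exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .preprocess import PCAEmbedding

__all__ = ["NNIndex", "NeighborTable", "MNNPairSet", "build_index",
           "knn_cross", "find_mnn_pairs"]


class MNNError(ValueError):
    """Raised on invalid neighbor-search inputs (empty sets, bad shapes)."""


@dataclass
class NeighborTable:
    """k nearest targets per query, sorted by nondecreasing distance."""

    query_ids: np.ndarray        # global indices of the queries
    neighbor_ids: np.ndarray     # n_query x k global indices into the target set
    distances: np.ndarray        # matching Euclidean distances

    @property
    def k(self) -> int:
        return self.neighbor_ids.shape[1]


@dataclass
class MNNPairSet:
    """Unordered cross-batch cell pairs satisfying mutuality."""

    pairs: np.ndarray                        # K x 2 global cell indices, i < j
    batch_pair_counts: dict = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def as_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in self.pairs}

    def to_tsv(self, path: str, cell_ids=None, batch=None) -> None:
        """Export pairs as TSV (cell a, cell b, batch a, batch b) for inspection."""
        import pandas as pd

        a, b = self.pairs[:, 0], self.pairs[:, 1]
        ids = np.asarray(cell_ids) if cell_ids is not None else None
        df = pd.DataFrame({
            "cell_a": a if ids is None else ids[a],
            "cell_b": b if ids is None else ids[b],
        })
        if batch is not None:
            batch = np.asarray(batch)
            df["batch_a"] = batch[a]
            df["batch_b"] = batch[b]
        df.to_csv(path, sep="\t", index=False)


class NNIndex:
    """k-NN index over one cell set; exact (sklearn) or approximate (NN-descent)."""

    def __init__(self, coords: np.ndarray, ids: np.ndarray,
                 method: str = "exact", seed: int = 0):
        coords = np.asarray(coords, dtype=np.float64)
        if coords.ndim != 2 or coords.shape[0] == 0:
            raise MNNError("cannot index an empty cell set")
        if not np.isfinite(coords).all():
            raise MNNError("non-finite coordinates in index input")
        self.coords = coords
        self.ids = np.asarray(ids)
        self.method = method
        self.seed = seed
        if method == "exact":
            from sklearn.neighbors import NearestNeighbors

            self._nn = NearestNeighbors(metric="euclidean").fit(coords)
        elif method == "approx":
            from pynndescent import NNDescent

            self._nn = NNDescent(coords, metric="euclidean",
                                 n_neighbors=min(30, len(coords)),
                                 random_state=seed, n_jobs=1)
            self._nn.prepare()
        else:
            raise MNNError(f"unknown search method {method!r}")

    def query(self, query_coords: np.ndarray, k: int,
              query_ids: np.ndarray | None = None) -> NeighborTable:
        query_coords = np.asarray(query_coords, dtype=np.float64)
        k_eff = min(k, len(self.coords))
        if self.method == "exact":
            dist, idx = self._nn.kneighbors(query_coords, n_neighbors=k_eff)
        else:
            idx, dist = self._nn.query(query_coords, k=k_eff)
            order = np.argsort(dist, axis=1, kind="stable")
            idx = np.take_along_axis(idx, order, axis=1)
            dist = np.take_along_axis(dist, order, axis=1)
        qids = (np.arange(len(query_coords)) if query_ids is None
                else np.asarray(query_ids))
        return NeighborTable(query_ids=qids, neighbor_ids=self.ids[idx],
                             distances=dist)


def build_index(embedding: "PCAEmbedding | np.ndarray", ids=None,
                method: str = "exact", seed: int = 0) -> NNIndex:
    """Build a Euclidean k-NN index over one cell set (one batch, typically)."""
    coords = embedding.coords if isinstance(embedding, PCAEmbedding) else embedding
    if ids is None:
        ids = np.arange(len(coords))
    return NNIndex(coords, ids, method=method, seed=seed)


def knn_cross(query_coords: np.ndarray, target_index: NNIndex, k: int = 20,
              query_ids=None) -> NeighborTable:
    """Query each cell's k nearest neighbors in another batch's index.

    k is truncated to the target-set size when the target batch is small.
    """
    return target_index.query(query_coords, k=k, query_ids=query_ids)


def _resolve_method(method: str, batch_sizes: np.ndarray) -> str:
    if method != "auto":
        return method
    # exact search is exercised (and cheap) for small batches; approximate
    # NN-descent takes over at scale
    return "exact" if batch_sizes.max() < 1000 else "approx"


def find_mnn_pairs(embedding: "PCAEmbedding | np.ndarray", batch,
                   k: int = 20, method: str = "auto",
                   seed: int = 0) -> MNNPairSet:
    """Find all cross-batch mutual-nearest-neighbor cell pairs.

    For each unordered batch pair {p, q}: cells of p query q's index and vice
    versa; (i, j) is emitted when j is among i's k nearest in q AND i among
    j's k nearest in p. Results are unordered pairs of global cell indices,
    so the output is symmetric in the batch labels, and the total count K is
    invariant to cell order.
    """
    coords = embedding.coords if isinstance(embedding, PCAEmbedding) else np.asarray(embedding)
    batch = np.asarray(batch)
    names, inverse = np.unique(batch, return_inverse=True)
    if len(names) < 2:
        raise MNNError(f"need at least 2 batches for MNN search, got {len(names)}")
    sizes = np.bincount(inverse)
    use = _resolve_method(method, sizes)

    idx_of = [np.flatnonzero(inverse == b) for b in range(len(names))]
    indexes = [build_index(coords[ix], ids=ix, method=use, seed=seed + b)
               for b, ix in enumerate(idx_of)]

    all_pairs: list[tuple[int, int]] = []
    counts: dict[tuple[str, str], int] = {}
    for p, q in combinations(range(len(names)), 2):
        ip, iq = idx_of[p], idx_of[q]
        fwd = knn_cross(coords[ip], indexes[q], k=k, query_ids=ip)
        rev = knn_cross(coords[iq], indexes[p], k=k, query_ids=iq)
        rev_sets = {int(j): set(map(int, row))
                    for j, row in zip(rev.query_ids, rev.neighbor_ids)}
        pairs_pq = sorted(
            (min(int(i), int(j)), max(int(i), int(j)))
            for i, row in zip(fwd.query_ids, fwd.neighbor_ids)
            for j in map(int, row)
            if int(i) in rev_sets[int(j)]
        )
        counts[(str(names[p]), str(names[q]))] = len(pairs_pq)
        all_pairs.extend(pairs_pq)

    pairs = (np.array(sorted(set(all_pairs)), dtype=np.int64)
             if all_pairs else np.empty((0, 2), dtype=np.int64))
    return MNNPairSet(pairs=pairs, batch_pair_counts=counts)
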