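"""Objective and optimization for the batch-correction network.

The total loss is L = L_b + alpha * L_r, where

* L_b (batch loss) is the sum over mutual-nearest-neighbor pairs of the
  Euclidean distance between the two cells' network outputs projected onto
  the fixed PCA loadings (pulling cross-batch pairs together in PCA space);
* L_r (regularization loss) is the sum over cells of the Euclidean distance
  between network output and input (keeping the correction small).

Optimization uses Adam (beta1=0.9, beta2=0.999), minibatches of 1,024 MNN
pairs, a step learning-rate schedule 0.1 * 0.8^(epoch // 20), at most 200
epochs, and early stopping after 10 epochs without improvement of the epoch
loss. All randomness is driven by a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .mnn import MNNPairSet, find_mnn_pairs
from .network import CorrectionNetwork, init_network
from .preprocess import (AnnotatedCounts, PCAEmbedding, PCAModel,
                         ScaledMatrix, fit_pca, normalize_and_log, qc_filter,
                         scale_and_clip, select_hvgs)

__all__ = [
    "TrainingConfig", "TrainingHistory", "PipelineConfig", "CorrectionResult",
    "project_output", "batch_loss", "regularization_loss", "total_loss",
    "train", "correct",
]

_EPS = 1e-12


class TrainingError(ValueError):
    """Raised on invalid training configuration or diverging optimization."""


@dataclass
class TrainingConfig:
    """Hyperparameters of the correction-network optimizer."""

    alpha: float = 1e-3          # weight of the regularization loss
    lr0: float = 0.1             # initial learning rate
    lr_decay: float = 0.8        # multiplicative decay factor
    decay_every: int = 20        # epochs between decays
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    minibatch: int = 1024        # MNN pairs per optimization step
    max_epochs: int = 200
    patience: int = 10           # epochs without improvement before stopping
    seed: int = 0
    reg_scope: str = "pair_cells"   # or "all_cells"
    center_projection: bool = True  # subtract the PCA center before projecting

    def __post_init__(self):
        if self.alpha < 0:
            raise TrainingError("alpha must be >= 0")
        if not 0 < self.lr_decay <= 1:
            raise TrainingError("lr_decay must be in (0, 1]")
        if self.patience < 1:
            raise TrainingError("patience must be >= 1")
        if self.minibatch < 1 or self.max_epochs < 1:
            raise TrainingError("minibatch and max_epochs must be >= 1")
        if self.reg_scope not in ("pair_cells", "all_cells"):
            raise TrainingError(f"unknown reg_scope {self.reg_scope!r}")

    def lr_at(self, epoch: int) -> float:
        """Step-decayed learning rate for a 0-based epoch index."""
        return self.lr0 * self.lr_decay ** (epoch // self.decay_every)


@dataclass
class TrainingHistory:
    """Per-epoch loss terms, learning rates, and the stopping outcome."""

    epoch: list = field(default_factory=list)
    batch_loss: list = field(default_factory=list)
    reg_loss: list = field(default_factory=list)
    total_loss: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1
    reason: str = ""

    @property
    def n_epochs(self) -> int:
        return len(self.epoch)

    def to_tsv(self, path: str) -> None:
        import pandas as pd

        pd.DataFrame({"epoch": self.epoch, "L_b": self.batch_loss,
                      "L_r": self.reg_loss, "L": self.total_loss,
                      "lr": self.lr}).to_csv(path, sep="\t", index=False)


def project_output(y: np.ndarray, pca: PCAModel,
                   center: bool = True) -> PCAEmbedding:
    """Project network output through the fixed input-data PCA loadings."""
    return pca.project(np.asarray(y), source="corrected", center=center)


def batch_loss(coords: "PCAEmbedding | np.ndarray", pairs) -> float:
    """Sum of Euclidean distances between the cells of each MNN pair."""
    c = coords.coords if isinstance(coords, PCAEmbedding) else np.asarray(coords)
    p = pairs.pairs if isinstance(pairs, MNNPairSet) else np.asarray(pairs)
    if len(p) == 0:
        raise TrainingError("empty MNN pair set: batch loss undefined")
    if p.max() >= len(c):
        raise TrainingError("pair index out of range for the embedding")
    diff = c[p[:, 0]] - c[p[:, 1]]
    return float(np.sqrt((diff * diff).sum(axis=1)).sum())


def regularization_loss(y: np.ndarray, x: np.ndarray) -> float:
    """Sum over cells of the Euclidean distance between output and input."""
    y, x = np.asarray(y), np.asarray(x)
    if y.shape != x.shape:
        raise TrainingError(f"shape mismatch: {y.shape} vs {x.shape}")
    diff = y - x
    return float(np.sqrt((diff * diff).sum(axis=1)).sum())


def total_loss(lb: float, lr_: float, alpha: float) -> float:
    """L = L_b + alpha * L_r."""
    if alpha < 0:
        raise TrainingError("alpha must be >= 0")
    return float(lb) + float(alpha) * float(lr_)


def loss_and_grad(y: np.ndarray, x: np.ndarray, pca: PCAModel,
                  pairs_local: np.ndarray, alpha: float,
                  reg_rows: np.ndarray | None = None,
                  center: bool = True):
    """Compute (L_b, L_r, dL/dY) for one forwarded minibatch.

    ``pairs_local`` indexes rows of ``y``; ``reg_rows`` restricts the
    regularization term to a subset of rows (default: all rows). Gradients
    flow through the network output only — the PCA loadings are fixed.
    """
    comp = pca.components.astype(y.dtype)
    offset = pca.center.astype(y.dtype) if center else 0.0
    ypca = (y - offset) @ comp

    d_ypca = np.zeros_like(ypca)
    lb = 0.0
    if len(pairs_local):
        i, j = pairs_local[:, 0], pairs_local[:, 1]
        diff = ypca[i] - ypca[j]
        dist = np.sqrt((diff * diff).sum(axis=1))
        lb = float(dist.sum())
        unit = diff / np.maximum(dist, _EPS)[:, None]
        np.add.at(d_ypca, i, unit)
        np.add.at(d_ypca, j, -unit)
    dy = d_ypca @ comp.T

    rows = np.arange(len(y)) if reg_rows is None else reg_rows
    rdiff = y[rows] - x[rows]
    rdist = np.sqrt((rdiff * rdiff).sum(axis=1))
    lr_ = float(rdist.sum())
    runit = rdiff / np.maximum(rdist, _EPS)[:, None]
    dy[rows] += alpha * runit
    return lb, lr_, dy


class Adam:
    """Adam optimizer over a list of parameter arrays, updated in place."""

    def __init__(self, params: list[np.ndarray], beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.params = params
        self.m = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.astype(np.float64)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= (lr * (m / c1) / (np.sqrt(v / c2) + self.eps)).astype(p.dtype)


def train(net: CorrectionNetwork, scaled: ScaledMatrix, pca: PCAModel,
          pairs: MNNPairSet, cfg: TrainingConfig
          ) -> tuple[CorrectionNetwork, TrainingHistory]:
    """Optimize the network on MNN pairs; returns (net, history).

    Minibatches are drawn over shuffled MNN pairs; both members of each pair
    are forwarded, and the regularization term covers the distinct cells of
    the minibatch (``reg_scope="pair_cells"``) or additionally folds in a
    per-epoch slice of all cells (``reg_scope="all_cells"``). The epoch loss
    is the sum of minibatch total losses; the best-epoch parameters are
    restored on return.
    """
    if pairs.n_pairs == 0:
        raise TrainingError("no MNN pairs were found: nothing to optimize")
    x_all = np.asarray(scaled.values, dtype=net.dtype)
    pair_arr = pairs.pairs
    n_cells = len(x_all)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.params(), cfg.adam_beta1, cfg.adam_beta2, cfg.adam_eps)
    history = TrainingHistory()

    best = np.inf
    best_state = net.copy_params()
    best_epoch = -1
    since_best = 0

    for epoch in range(cfg.max_epochs):
        lr = cfg.lr_at(epoch)
        perm = rng.permutation(pairs.n_pairs)
        n_steps = int(np.ceil(pairs.n_pairs / cfg.minibatch))
        extra = None
        if cfg.reg_scope == "all_cells":
            extra = np.array_split(rng.permutation(n_cells), n_steps)
        ep_lb = ep_lr = 0.0
        for step in range(n_steps):
            chunk = pair_arr[perm[step * cfg.minibatch:(step + 1) * cfg.minibatch]]
            cells = chunk.ravel()
            if extra is not None:
                cells = np.concatenate([cells, extra[step]])
            cells = np.unique(cells)
            local = np.searchsorted(cells, chunk)
            xb = x_all[cells]
            yb, caches = net.forward(xb, training=True)
            lb, lr_loss, dy = loss_and_grad(
                yb, xb, pca, local, cfg.alpha,
                center=cfg.center_projection)
            _, grads = net.backward(caches, dy)
            opt.step(grads, lr)
            ep_lb += lb
            ep_lr += lr_loss
        ep_total = total_loss(ep_lb, ep_lr, cfg.alpha)
        if not np.isfinite(ep_total):
            raise TrainingError(
                f"non-finite loss at epoch {epoch} "
                f"(L_b={ep_lb}, L_r={ep_lr}); try a smaller learning rate")
        history.epoch.append(epoch)
        history.batch_loss.append(ep_lb)
        history.reg_loss.append(ep_lr)
        history.total_loss.append(ep_total)
        history.lr.append(lr)

        if ep_total < best:
            best = ep_total
            best_state = net.copy_params()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                history.reason = "early_stop"
                break
    else:
        history.reason = "max_epochs"

    history.stopped_epoch = history.epoch[-1]
    history.best_epoch = best_epoch
    net.load_params(best_state)
    return net, history


@dataclass
class PipelineConfig:
    """End-to-end configuration: preprocessing, MNN search, and training."""

    qc_min_genes_per_cell: int = 200
    qc_min_cells_per_gene: int = 3
    scale: float = 1e4
    n_hvg: int = 2000
    clip: float = 10.0
    n_pc: int = 50
    k: int = 20
    mnn_method: str = "auto"
    n_blocks: int = 2
    training: TrainingConfig = field(default_factory=TrainingConfig)
    seed: int = 0

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed, training=replace(self.training, seed=seed))


@dataclass
class CorrectionResult:
    """Everything the one-step correction run produced."""

    data: AnnotatedCounts            # post-QC input
    scaled: ScaledMatrix             # network input X
    pca: PCAModel
    raw_embedding: PCAEmbedding      # X^pca
    pairs: MNNPairSet
    network: CorrectionNetwork
    history: TrainingHistory
    corrected: np.ndarray            # network output Y, cells x n_hvg
    corrected_embedding: PCAEmbedding  # Y^pca


def correct(data: AnnotatedCounts, cfg: PipelineConfig | None = None
            ) -> CorrectionResult:
    """Run the full one-step pipeline on a multi-batch dataset.

    preprocess -> PCA -> MNN pair search -> network training -> inference
    forward on all cells -> projection. All batches are integrated in a
    single training run; outputs stay aligned with the (post-QC) cell order.
    """
    cfg = cfg or PipelineConfig()
    if data.n_batches < 2:
        raise TrainingError(
            f"batch correction needs >= 2 batches, got {data.n_batches}")
    clean = qc_filter(data, cfg.qc_min_genes_per_cell, cfg.qc_min_cells_per_gene)
    if clean.n_batches < 2:
        raise TrainingError("QC filtering removed all cells of some batch")
    normlog = normalize_and_log(clean, scale=cfg.scale)
    hvgs = select_hvgs(normlog, clean.gene_ids, n_top=cfg.n_hvg)
    scaled = scale_and_clip(normlog, clean.gene_ids, hvgs, clip=cfg.clip)
    pca, raw_emb = fit_pca(scaled, n_pc=cfg.n_pc, random_state=cfg.seed)
    pairs = find_mnn_pairs(raw_emb, clean.batch, k=cfg.k,
                           method=cfg.mnn_method, seed=cfg.seed)
    if pairs.n_pairs == 0:
        raise TrainingError(
            "no MNN pairs found between any batch pair; batches may share "
            "no cell populations")
    net = init_network(scaled.n_genes, n_blocks=cfg.n_blocks, seed=cfg.seed)
    net, history = train(net, scaled, pca, pairs, cfg.training)
    corrected = net.forward(scaled.values.astype(net.dtype), training=False)
    corrected_emb = project_output(corrected, pca,
                                   center=cfg.training.center_projection)
    return CorrectionResult(
        data=clean, scaled=scaled, pca=pca, raw_embedding=raw_emb,
        pairs=pairs, network=net, history=history,
        corrected=np.asarray(corrected), corrected_embedding=corrected_emb)
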