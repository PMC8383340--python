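"""The batch-correction network: a stack of residual blocks in plain NumPy.

Each block computes y = x + delta(x), where delta is two sequences of
(affine, batch normalization, PReLU). The first affine widens d -> 2d, the
second narrows 2d -> d, so the network maps scaled expression to corrected
expression of identical dimension. Zeroing the delta path makes every block
an exact identity, which is the inductive bias: the network starts near the
identity and learns the batch effect as the residual term.

Forward and backward passes are written out explicitly (no autograd
framework); gradients are validated against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ResidualBlock", "CorrectionNetwork", "init_network",
           "residual_forward", "save_network", "load_network"]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1
_PRELU_INIT = 0.25


class NetworkError(ValueError):
    """Raised on invalid network configuration or input shapes."""


def _uniform_fan_in(rng: np.random.Generator, fan_in: int, shape, dtype):
    # the conventional "default" init: U(-1/sqrt(fan_in), 1/sqrt(fan_in))
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class ResidualBlock:
    """One residual block: affine(d->2d), BN, PReLU, affine(2d->d), BN, PReLU.

    Parameters are plain arrays; ``params()`` yields the trainable ones in a
    fixed order. PReLU uses a single learnable slope per activation layer.
    Batch statistics use the population (ddof=0) variance; running statistics
    are exponential moving averages with momentum 0.1 and are the ones used
    in inference mode.
    """

    def __init__(self, dim: int, rng: np.random.Generator,
                 dtype=np.float32):
        d, h = dim, 2 * dim
        self.dim = d
        self.dtype = dtype
        self.W1 = _uniform_fan_in(rng, d, (d, h), dtype)
        self.b1 = _uniform_fan_in(rng, d, (h,), dtype)
        self.g1 = np.ones(h, dtype)
        self.be1 = np.zeros(h, dtype)
        self.a1 = np.full(1, _PRELU_INIT, dtype)
        self.W2 = _uniform_fan_in(rng, h, (h, d), dtype)
        self.b2 = _uniform_fan_in(rng, h, (d,), dtype)
        self.g2 = np.ones(d, dtype)
        self.be2 = np.zeros(d, dtype)
        self.a2 = np.full(1, _PRELU_INIT, dtype)
        self.rm1 = np.zeros(h, dtype)
        self.rv1 = np.ones(h, dtype)
        self.rm2 = np.zeros(d, dtype)
        self.rv2 = np.ones(d, dtype)

    _PARAM_NAMES = ("W1", "b1", "g1", "be1", "a1", "W2", "b2", "g2", "be2", "a2")
    _STATE_NAMES = ("rm1", "rv1", "rm2", "rv2")

    def params(self) -> list[np.ndarray]:
        return [getattr(self, n) for n in self._PARAM_NAMES]

    def _bn_forward(self, h, g, be, rm, rv, training):
        if training:
            mu = h.mean(axis=0)
            var = h.var(axis=0)
            rm *= 1.0 - _BN_MOMENTUM
            rm += _BN_MOMENTUM * mu.astype(rm.dtype)
            rv *= 1.0 - _BN_MOMENTUM
            rv += _BN_MOMENTUM * var.astype(rv.dtype)
        else:
            mu, var = rm, rv
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (h - mu) * inv_std
        return g * xhat + be, xhat, inv_std

    def forward(self, x: np.ndarray, training: bool = False):
        """Return (y, cache); cache is None unless training."""
        if x.shape[1] != self.dim:
            raise NetworkError(
                f"block expects {self.dim} columns, got {x.shape[1]}")
        h1 = x @ self.W1 + self.b1
        z1, xhat1, inv1 = self._bn_forward(h1, self.g1, self.be1,
                                           self.rm1, self.rv1, training)
        p1 = np.where(z1 > 0, z1, self.a1 * z1)
        h2 = p1 @ self.W2 + self.b2
        z2, xhat2, inv2 = self._bn_forward(h2, self.g2, self.be2,
                                           self.rm2, self.rv2, training)
        p2 = np.where(z2 > 0, z2, self.a2 * z2)
        y = x + p2
        cache = (x, xhat1, inv1, z1, p1, xhat2, inv2, z2) if training else None
        return y, cache

    @staticmethod
    def _bn_backward(dz, xhat, inv_std, g):
        dg = (dz * xhat).sum(axis=0)
        dbe = dz.sum(axis=0)
        n = dz.shape[0]
        dh = (g * inv_std) * (dz - dz.mean(axis=0)
                              - xhat * (dz * xhat).sum(axis=0) / n)
        return dh, dg, dbe

    def backward(self, cache, dy: np.ndarray):
        """Backprop through the block (training-mode batch statistics).

        Returns (dx, grads) with grads ordered as ``params()``.
        """
        x, xhat1, inv1, z1, p1, xhat2, inv2, z2 = cache
        dp2 = dy
        pos2 = z2 > 0
        dz2 = dp2 * np.where(pos2, 1.0, self.a2).astype(dp2.dtype)
        da2 = np.array([(dp2 * np.where(pos2, 0.0, z2)).sum()], dtype=self.a2.dtype)
        dh2, dg2, dbe2 = self._bn_backward(dz2, xhat2, inv2, self.g2)
        dW2 = p1.T @ dh2
        db2 = dh2.sum(axis=0)
        dp1 = dh2 @ self.W2.T
        pos1 = z1 > 0
        dz1 = dp1 * np.where(pos1, 1.0, self.a1).astype(dp1.dtype)
        da1 = np.array([(dp1 * np.where(pos1, 0.0, z1)).sum()], dtype=self.a1.dtype)
        dh1, dg1, dbe1 = self._bn_backward(dz1, xhat1, inv1, self.g1)
        dW1 = x.T @ dh1
        db1 = dh1.sum(axis=0)
        dx = dy + dh1 @ self.W1.T
        return dx, [dW1, db1, dg1, dbe1, da1, dW2, db2, dg2, dbe2, da2]

    def zero_delta(self) -> None:
        """Zero the residual path so the block is exactly the identity map."""
        for name in ("W1", "b1", "be1", "W2", "b2", "be2"):
            getattr(self, name)[...] = 0.0


class CorrectionNetwork:
    """Stack of residual blocks mapping scaled expression X to corrected Y."""

    def __init__(self, input_dim: int = 2000, n_blocks: int = 2,
                 seed: int = 0, dtype=np.float32):
        if input_dim < 1:
            raise NetworkError("input_dim must be >= 1")
        if n_blocks < 1:
            raise NetworkError("need at least one residual block")
        self.input_dim = input_dim
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.blocks = [ResidualBlock(input_dim, rng, dtype)
                       for _ in range(n_blocks)]

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def params(self) -> list[np.ndarray]:
        return [p for b in self.blocks for p in b.params()]

    def forward(self, x: np.ndarray, training: bool = False):
        """Apply all blocks. Returns y (inference) or (y, caches) (training)."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 2 or x.shape[1] != self.input_dim:
            raise NetworkError(
                f"expected (cells, {self.input_dim}) input, got {x.shape}")
        caches = []
        out = x
        for block in self.blocks:
            out, cache = block.forward(out, training=training)
            caches.append(cache)
        return (out, caches) if training else out

    def backward(self, caches, dy: np.ndarray):
        """Backprop dL/dY through all blocks; grads align with ``params()``."""
        grads_rev = []
        d = dy
        for block, cache in zip(reversed(self.blocks), reversed(caches)):
            d, g = block.backward(cache, d)
            grads_rev.append(g)
        grads = [g for block_grads in reversed(grads_rev) for g in block_grads]
        return d, grads

    def zero_delta(self) -> None:
        for b in self.blocks:
            b.zero_delta()

    def copy_params(self) -> list[np.ndarray]:
        state = [p.copy() for p in self.params()]
        state += [getattr(b, n).copy() for b in self.blocks
                  for n in ResidualBlock._STATE_NAMES]
        return state

    def load_params(self, state: list[np.ndarray]) -> None:
        n_p = len(self.params())
        for p, s in zip(self.params(), state[:n_p]):
            p[...] = s
        stats = state[n_p:]
        i = 0
        for b in self.blocks:
            for n in ResidualBlock._STATE_NAMES:
                getattr(b, n)[...] = stats[i]
                i += 1


def init_network(input_dim: int = 2000, n_blocks: int = 2,
                 seed: int = 0, dtype=np.float32) -> CorrectionNetwork:
    """Build a seeded correction network (widths 2*d and d per block)."""
    return CorrectionNetwork(input_dim=input_dim, n_blocks=n_blocks,
                             seed=seed, dtype=dtype)


def residual_forward(x: np.ndarray, block: ResidualBlock,
                     training: bool = False) -> np.ndarray:
    """Forward one residual block: y = x + delta(x)."""
    y, _ = block.forward(np.asarray(x, dtype=block.dtype), training=training)
    return y


def save_network(net: CorrectionNetwork, path: str) -> None:
    """Serialize all parameters and running statistics to an .npz checkpoint."""
    arrays = {"input_dim": np.array(net.input_dim),
              "n_blocks": np.array(net.n_blocks)}
    for bi, b in enumerate(net.blocks):
        for name in ResidualBlock._PARAM_NAMES + ResidualBlock._STATE_NAMES:
            arrays[f"block{bi}_{name}"] = getattr(b, name)
    np.savez(path, **arrays)


def load_network(path: str) -> CorrectionNetwork:
    """Restore a checkpoint; inference outputs are bit-identical to the saved net."""
    with np.load(path) as f:
        net = CorrectionNetwork(int(f["input_dim"]), int(f["n_blocks"]),
                                seed=0, dtype=f["block0_W1"].dtype.type)
        for bi, b in enumerate(net.blocks):
            for name in ResidualBlock._PARAM_NAMES + ResidualBlock._STATE_NAMES:
                setattr(b, name, f[f"block{bi}_{name}"].copy())
    return net
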