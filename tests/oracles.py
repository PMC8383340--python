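"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain loops over the defining formulas, kept
deliberately separate from the package's vectorized / library-backed code
paths so that agreement is a real cross-check.
"""

import numpy as np


def knn_bruteforce(coords, k):
    """k nearest neighbors per point (no self) via full distance matrix."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    return np.argsort(d, axis=1, kind="stable")[:, : min(k, n - 1)]


def knn_cross_bruteforce(query, target, k):
    """Indices into `target` of the k nearest targets per query point."""
    query, target = np.asarray(query, float), np.asarray(target, float)
    d = np.sqrt(((query[:, None, :] - target[None, :, :]) ** 2).sum(-1))
    return np.argsort(d, axis=1, kind="stable")[:, : min(k, len(target))]


def mnn_pairs_bruteforce(coords, batch, k):
    """All mutual cross-batch kNN pairs, per unordered batch pair."""
    coords, batch = np.asarray(coords, float), np.asarray(batch)
    names = np.unique(batch)
    pairs = set()
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            ia = np.flatnonzero(batch == names[a])
            ib = np.flatnonzero(batch == names[b])
            fwd = knn_cross_bruteforce(coords[ia], coords[ib], k)
            rev = knn_cross_bruteforce(coords[ib], coords[ia], k)
            fwd_sets = {int(ia[q]): {int(ib[j]) for j in row}
                        for q, row in enumerate(fwd)}
            rev_sets = {int(ib[q]): {int(ia[j]) for j in row}
                        for q, row in enumerate(rev)}
            for i, neigh in fwd_sets.items():
                for j in neigh:
                    if i in rev_sets[j]:
                        pairs.add((min(i, j), max(i, j)))
    return pairs


def entropy_bruteforce(neighbor_labels_row, n_categories):
    """-(1/M) * sum_m P_m log P_m for one cell's neighbor label list."""
    labels = list(neighbor_labels_row)
    total = 0.0
    cats = sorted(set(labels))
    for c in cats:
        p = labels.count(c) / len(labels)
        if p > 0:
            total += p * np.log(p)
    return -total / n_categories


def rand_index_bruteforce(a, b):
    """RI by enumerating all unordered pairs."""
    a, b = list(a), list(b)
    n = len(a)
    agree = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_a = a[i] == a[j]
            same_b = b[i] == b[j]
            if same_a == same_b:
                agree += 1
    return agree / (n * (n - 1) / 2)


def ari_bruteforce(a, b):
    """ARI from the contingency table via the sum-of-binomials closed form."""
    from math import comb

    a, b = np.asarray(a), np.asarray(b)
    cats_a, ca = np.unique(a, return_inverse=True)
    cats_b, cb = np.unique(b, return_inverse=True)
    n = len(a)
    table = np.zeros((len(cats_a), len(cats_b)), dtype=int)
    for i in range(n):
        table[ca[i], cb[i]] += 1
    sum_ij = sum(comb(int(x), 2) for x in table.ravel())
    sum_a = sum(comb(int(x), 2) for x in table.sum(axis=1))
    sum_b = sum(comb(int(x), 2) for x in table.sum(axis=0))
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    maximum = (sum_a + sum_b) / 2
    if maximum == expected:
        return 1.0
    return (sum_ij - expected) / (maximum - expected)


def silhouette_bruteforce(coords, labels):
    """Per-point silhouette widths via scalar loops over the definition."""
    coords, labels = np.asarray(coords, float), np.asarray(labels)
    n = len(coords)
    dist = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    cats = np.unique(labels)
    s = np.zeros(n)
    for i in range(n):
        own = labels[i]
        mates = [j for j in range(n) if labels[j] == own and j != i]
        if not mates:
            s[i] = 0.0
            continue
        a_i = np.mean([dist[i, j] for j in mates])
        b_i = min(
            np.mean([dist[i, j] for j in range(n) if labels[j] == c])
            for c in cats if c != own
        )
        s[i] = (b_i - a_i) / max(a_i, b_i)
    return s


def batch_loss_bruteforce(coords, pairs):
    """Sum over pairs of sqrt(sum of squared coordinate differences)."""
    total = 0.0
    for i, j in pairs:
        sq = 0.0
        for d in range(coords.shape[1]):
            sq += (coords[i, d] - coords[j, d]) ** 2
        total += np.sqrt(sq)
    return total


def reg_loss_bruteforce(y, x):
    """Sum over rows of the Euclidean output-input distance."""
    total = 0.0
    for i in range(y.shape[0]):
        sq = 0.0
        for d in range(y.shape[1]):
            sq += (y[i, d] - x[i, d]) ** 2
        total += np.sqrt(sq)
    return total


def project_bruteforce(values, center, components):
    """(values - center) @ components via explicit triple loop."""
    n, g = values.shape
    npc = components.shape[1]
    out = np.zeros((n, npc))
    for i in range(n):
        for c in range(npc):
            acc = 0.0
            for j in range(g):
                acc += (values[i, j] - center[j]) * components[j, c]
            out[i, c] = acc
    return out


def residual_block_bruteforce(x, block, training):
    """Layer-by-layer scalar recomputation of one residual block forward."""
    x = np.asarray(x, dtype=float)
    n, d = x.shape
    h = 2 * d
    eps = 1e-5

    def affine(inp, w, b):
        out = np.zeros((n, w.shape[1]))
        for i in range(n):
            for c in range(w.shape[1]):
                acc = b[c]
                for j in range(w.shape[0]):
                    acc += inp[i, j] * w[j, c]
                out[i, c] = acc
        return out

    def bn(inp, g, be, rm, rv):
        out = np.zeros_like(inp)
        for c in range(inp.shape[1]):
            col = inp[:, c]
            if training:
                mu, var = col.mean(), col.var()
            else:
                mu, var = rm[c], rv[c]
            out[:, c] = g[c] * (col - mu) / np.sqrt(var + eps) + be[c]
        return out

    def prelu(inp, a):
        return np.where(inp > 0, inp, float(a[0]) * inp)

    z1 = prelu(bn(affine(x, block.W1, block.b1), block.g1, block.be1,
                  block.rm1, block.rv1), block.a1)
    z2 = prelu(bn(affine(z1, block.W2, block.b2), block.g2, block.be2,
                  block.rm2, block.rv2), block.a2)
    return x + z2
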