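"""Naive reference implementations used for cross-validation.

Every function here recomputes a pipeline quantity from first principles
with explicit loops (brute-force shortest paths, edge-list counting,
pair-counting contingency tables), deliberately sharing no code with the
optimized implementations it is checked against.
"""

from __future__ import annotations

import numpy as np
from scipy.special import comb


def degree_sum(w: np.ndarray) -> np.ndarray:
    n = len(w)
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            out[i] += w[i, j]
    return out


def efficiency_floyd_warshall(w: np.ndarray) -> np.ndarray:
    """All-pairs nodal efficiency with edge length 1/weight."""
    n = len(w)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    e = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                e[i] += 1.0 / d[i, j]
    return e / (n - 1)


def within_module_z(w: np.ndarray, labels: np.ndarray) -> np.ndarray:
    n = len(w)
    adj = (np.asarray(w) > 0).astype(float)
    k_intra = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                k_intra[i] += adj[i, j]
    z = np.zeros(n)
    for c in set(labels.tolist()):
        idx = [i for i in range(n) if labels[i] == c]
        vals = k_intra[idx]
        if len(idx) > 1 and vals.std() > 0:
            for i in idx:
                z[i] = (k_intra[i] - vals.mean()) / vals.std()
    return z


def participation(w: np.ndarray, labels: np.ndarray) -> np.ndarray:
    n = len(w)
    adj = (np.asarray(w) > 0).astype(float)
    p = np.zeros(n)
    for i in range(n):
        k = adj[i].sum()
        if k == 0:
            continue
        s = 0.0
        for c in set(labels.tolist()):
            k_c = sum(adj[i, j] for j in range(n) if labels[j] == c)
            s += (k_c / k) ** 2
        p[i] = 1 - s
    return p


def modularity_q(w: np.ndarray, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Edge-by-edge weighted modularity."""
    n = len(w)
    k = np.array([sum(w[i, j] for j in range(n)) for i in range(n)])
    two_m = k.sum()
    if two_m == 0:
        return 0.0
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += w[i, j] - gamma * k[i] * k[j] / two_m
    return q / two_m


def adjusted_rand_index(l1: np.ndarray, l2: np.ndarray) -> float:
    """ARI from the pair-counting contingency table."""
    l1, l2 = np.asarray(l1), np.asarray(l2)
    n = len(l1)
    cats1, cats2 = np.unique(l1), np.unique(l2)
    table = np.array(
        [[int(np.sum((l1 == a) & (l2 == b))) for b in cats2] for a in cats1]
    )
    index = comb(table, 2).sum()
    a = comb(table.sum(axis=1), 2).sum()
    b = comb(table.sum(axis=0), 2).sum()
    expected = a * b / comb(n, 2)
    max_index = (a + b) / 2
    if max_index == expected:
        return 1.0
    return float((index - expected) / (max_index - expected))
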