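"""Two-stage consensus community detection.

Stage 1 (subject level): Louvain partitions of the weighted thresholded
graph at every cost of a fine grid; a co-classification matrix (frequency
with which each node pair lands in the same community) is consensus
clustered into a single subject partition.

Stage 2 (group level): subject consensus partitions are aggregated into an
allegiance matrix (fraction of subjects co-assigning each node pair) which
is consensus clustered into the group partition.

Louvain runs through igraph's C implementation with a resolution
parameter; each call is seeded and the best-modularity partition over a
number of random restarts is kept.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np

from .graphs import CostGrid, threshold_at_cost

DEFAULT_GAMMA_SUBJECT = 3.0
DEFAULT_GAMMA_GROUP = 2.0


@dataclass
class Partition:
    """Community assignment over the node set.

    Community ids are arbitrary integers, consistent within a partition.
    ``level`` records provenance (subject_consensus, subgroup, group, ...);
    ``converged`` is False when consensus clustering hit its iteration cap.
    """

    labels: np.ndarray
    level: str = "subject_consensus"
    gamma: float = DEFAULT_GAMMA_SUBJECT
    converged: bool = True

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_communities(self) -> int:
        return len(np.unique(self.labels))


@dataclass
class CoClassification:
    """Node-pair co-assignment frequencies across a set of partitions."""

    frequency: np.ndarray
    n_partitions: int


def canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel communities by order of first appearance (0, 1, 2, ...)."""
    _, canon = np.unique(labels, return_inverse=True)
    first = {}
    out = np.empty_like(canon)
    nxt = 0
    for k, c in enumerate(canon):
        if c not in first:
            first[c] = nxt
            nxt += 1
        out[k] = first[c]
    return out


def modularity(weights: np.ndarray, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Weighted Newman-Girvan modularity with resolution gamma.

    Q = (1/2m) * sum_ij [w_ij - gamma * k_i k_j / (2m)] * delta(c_i, c_j).
    """
    w = np.asarray(weights, dtype=float)
    k = w.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        return 0.0
    same = labels[:, None] == labels[None, :]
    return float(((w - gamma * np.outer(k, k) / two_m) * same).sum() / two_m)


def _to_igraph(weights: np.ndarray) -> ig.Graph:
    w = np.asarray(weights, dtype=float)
    src, dst = np.nonzero(np.triu(w, k=1))
    g = ig.Graph(n=w.shape[0], edges=list(zip(src.tolist(), dst.tolist())))
    g.es["weight"] = w[src, dst].tolist()
    return g


def louvain_partition(
    weights: np.ndarray,
    gamma: float = 1.0,
    seed: int | None = None,
    n_restarts: int = 10,
) -> Partition:
    """Best-of-restarts Louvain partition of a weighted adjacency matrix.

    Greedy modularity maximization at resolution ``gamma``; the restart
    with the highest modularity wins (greedy Louvain is order dependent,
    so restarts tame its instability). Deterministic for a given seed.
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("cannot partition an empty graph")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    g = _to_igraph(w)
    if g.ecount() == 0:
        return Partition(labels=np.arange(w.shape[0]), level="louvain", gamma=gamma)
    rnd = random.Random(seed)
    best, best_q = None, -np.inf
    ig.set_random_number_generator(rnd)
    try:
        for _ in range(max(1, n_restarts)):
            vc = g.community_multilevel(weights="weight", resolution=gamma)
            q = g.modularity(vc.membership, weights=g.es["weight"], resolution=gamma)
            if q > best_q:
                best, best_q = np.asarray(vc.membership), q
    finally:
        ig.set_random_number_generator(random)
    return Partition(labels=best, level="louvain", gamma=gamma)


def co_classification(partitions: list[Partition] | list[np.ndarray]) -> CoClassification:
    """Frequency with which each node pair shares a community."""
    mats = [p.labels if isinstance(p, Partition) else np.asarray(p) for p in partitions]
    L = np.stack(mats)
    same = (L[:, :, None] == L[:, None, :]).mean(axis=0)
    return CoClassification(frequency=same, n_partitions=len(mats))


def consensus_cluster(
    co: CoClassification | np.ndarray,
    gamma: float,
    seed: int | None = None,
    tau: float = 0.5,
    n_recluster: int = 10,
    max_iter: int = 20,
    n_restarts: int = 10,
    level: str = "consensus",
) -> Partition:
    """Iterated consensus clustering of a co-classification matrix.

    At each iteration, entries below ``tau`` are zeroed, the thresholded
    matrix is clustered ``n_recluster`` times at resolution ``gamma``, and
    the runs' co-classification matrix replaces the input — until all runs
    agree (up to relabeling) or ``max_iter`` is reached (flagged).
    """
    C = co.frequency if isinstance(co, CoClassification) else np.asarray(co, dtype=float)
    rng = np.random.default_rng(seed)
    parts = None
    for _ in range(max_iter):
        M = np.where(C >= tau, C, 0.0)
        np.fill_diagonal(M, 0.0)
        parts = [
            louvain_partition(M, gamma=gamma, seed=int(rng.integers(2**31)),
                              n_restarts=n_restarts)
            for _ in range(n_recluster)
        ]
        canon = [canonical_labels(p.labels) for p in parts]
        if all(np.array_equal(canon[0], c) for c in canon[1:]):
            return Partition(labels=canon[0], level=level, gamma=gamma, converged=True)
        C = co_classification(parts).frequency
    warnings.warn(f"consensus clustering did not converge in {max_iter} iterations",
                  stacklevel=2)
    return Partition(labels=canonical_labels(parts[0].labels), level=level,
                     gamma=gamma, converged=False)


def subject_consensus(
    fc: np.ndarray,
    fine_grid: CostGrid | None = None,
    gamma: float = DEFAULT_GAMMA_SUBJECT,
    seed: int | None = None,
    n_restarts: int = 10,
    tau: float = 0.5,
) -> tuple[Partition, CoClassification]:
    """Stage-1 consensus partition for one subject.

    One Louvain partition per cost of the fine grid (default 311 costs),
    co-classification across all of them, then consensus clustering at the
    same resolution.
    """
    grid = fine_grid if fine_grid is not None else CostGrid.fine()
    rng = np.random.default_rng(seed)
    parts = []
    for cost in grid:
        g = threshold_at_cost(fc, cost)
        parts.append(
            louvain_partition(g.weights, gamma=gamma,
                              seed=int(rng.integers(2**31)), n_restarts=n_restarts)
        )
    co = co_classification(parts)
    part = consensus_cluster(co, gamma=gamma, seed=int(rng.integers(2**31)),
                             tau=tau, n_restarts=n_restarts, level="subject_consensus")
    return part, co


def allegiance_matrix(subject_partitions: list[Partition]) -> np.ndarray:
    """Fraction of subjects whose consensus partition co-assigns each pair.

    Repeated subjects (bootstrap resamples) count with multiplicity.
    """
    if len(subject_partitions) < 1:
        raise ValueError("need at least one subject partition")
    sizes = {p.n_nodes for p in subject_partitions}
    if len(sizes) != 1:
        raise ValueError(f"subject partitions cover mismatched node sets: sizes {sorted(sizes)}")
    return co_classification(subject_partitions).frequency


def group_partition(
    subject_partitions: list[Partition],
    gamma: float = DEFAULT_GAMMA_GROUP,
    seed: int | None = None,
    n_restarts: int = 10,
    tau: float = 0.5,
    level: str = "group",
) -> tuple[Partition, np.ndarray]:
    """Stage-2 group-level partition from subject consensus partitions."""
    if len(subject_partitions) < 2:
        raise ValueError("need at least two subject partitions for a group partition")
    A = allegiance_matrix(subject_partitions)
    part = consensus_cluster(A, gamma=gamma, seed=seed, tau=tau,
                             n_restarts=n_restarts, level=level)
    return part, A
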