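"""Cost-based thresholding and cost-range validity criteria.

A weighted functional-connectivity matrix is thresholded at a *cost* — the
fraction of all possible edges retained — by keeping the strongest edges.
A cost range is considered analyzable when, across subjects, (a) the
thresholded networks are small-world (sigma > 1), (b) the largest connected
component covers most nodes, and (c) mean degree exceeds log(N).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CostGrid:
    """Ordered grid of edge-density fractions in (0, 1]."""

    costs: tuple[float, ...]

    def __post_init__(self):
        c = np.asarray(self.costs, dtype=float)
        if c.ndim != 1 or len(c) == 0:
            raise ValueError("cost grid must be a non-empty 1-d sequence")
        if np.any(c <= 0) or np.any(c > 1):
            raise ValueError("costs must lie in (0, 1]")
        if np.any(np.diff(c) <= 0):
            raise ValueError("costs must be strictly increasing")

    def __len__(self) -> int:
        return len(self.costs)

    def __iter__(self):
        return iter(self.costs)

    @property
    def width(self) -> float:
        return self.costs[-1] - self.costs[0]

    @classmethod
    def from_range(cls, start: float, stop: float, step: float) -> "CostGrid":
        n = int(round((stop - start) / step)) + 1
        costs = np.round(start + step * np.arange(n), 10)
        return cls(tuple(float(c) for c in costs))

    @classmethod
    def coarse(cls) -> "CostGrid":
        """Default metric grid: 0.09 to 0.40 in 0.01 steps (32 costs)."""
        return cls.from_range(0.09, 0.40, 0.01)

    @classmethod
    def fine(cls) -> "CostGrid":
        """Default community-detection grid: 0.09 to 0.40 in 0.001 steps (311 costs)."""
        return cls.from_range(0.09, 0.40, 0.001)


@dataclass
class ThresholdedGraph:
    """FC matrix retaining only the strongest edges at a given cost.

    ``weights`` keeps the original (non-binarized) edge weights; ``binary``
    is the derived 0/1 adjacency. ``truncated`` flags graphs where fewer
    positive edges were available than the cost requested.
    """

    cost: float
    weights: np.ndarray
    truncated: bool = False
    binary: np.ndarray = field(init=False)

    def __post_init__(self):
        self.binary = (self.weights > 0).astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.binary.sum()) // 2


def threshold_at_cost(fc: np.ndarray, cost: float) -> ThresholdedGraph:
    """Retain the ``floor(cost * N(N-1)/2)`` strongest edges of ``fc``.

    Ties are broken deterministically by ascending (i, j) node index, so
    threshold sets are nested across costs. If the matrix has fewer
    positive edges than requested, all positive edges are kept and the
    result is flagged ``truncated`` (with a warning).
    """
    if not 0 < cost <= 1:
        raise ValueError(f"cost must be in (0, 1], got {cost}")
    fc = np.asarray(fc, dtype=float)
    n = fc.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = fc[iu, ju]
    n_keep = int(np.floor(cost * n * (n - 1) / 2))
    pos = w > 0
    truncated = False
    if n_keep > pos.sum():
        warnings.warn(
            f"cost {cost} requests {n_keep} edges but only {int(pos.sum())} "
            "positive edges exist; retaining all positive edges",
            stacklevel=2,
        )
        n_keep = int(pos.sum())
        truncated = True
    # stable sort on -w keeps ascending (i, j) order among ties
    order = np.argsort(-w, kind="stable")[:n_keep]
    out = np.zeros_like(fc)
    out[iu[order], ju[order]] = w[order]
    out[ju[order], iu[order]] = w[order]
    return ThresholdedGraph(cost=cost, weights=out, truncated=truncated)


def _largest_component(G: nx.Graph) -> nx.Graph:
    if G.number_of_nodes() == 0:
        return G
    return G.subgraph(max(nx.connected_components(G), key=len))


def small_worldness(g: ThresholdedGraph, n_null: int = 20, seed: int | None = None) -> float:
    """Small-world coefficient sigma = (C/C_rand) / (L/L_rand).

    Computed on the binarized graph; C is the mean clustering coefficient,
    L the characteristic path length on the largest connected component.
    Null values are means over ``n_null`` degree-preserving rewirings.
    Returns ``inf`` (with a warning) if the null graphs have no triangles.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    G = nx.from_numpy_array(g.binary)
    G.remove_edges_from(nx.selfloop_edges(G))
    Gl = _largest_component(G)
    C = nx.average_clustering(G)
    L = nx.average_shortest_path_length(Gl)
    rng = np.random.default_rng(seed)
    c_null, l_null = [], []
    n_swap = max(1, 10 * G.number_of_edges())
    for _ in range(n_null):
        H = G.copy()
        try:
            nx.double_edge_swap(H, nswap=n_swap, max_tries=50 * n_swap,
                                seed=int(rng.integers(2**31)))
        except nx.NetworkXException:
            pass  # swap-exhausted small graphs keep whatever was achieved
        c_null.append(nx.average_clustering(H))
        l_null.append(nx.average_shortest_path_length(_largest_component(H)))
    c_rand = float(np.mean(c_null))
    l_rand = float(np.mean(l_null))
    if c_rand == 0 or L == 0:
        warnings.warn("degenerate null (no triangles or zero path length); sigma set to inf",
                      stacklevel=2)
        return float("inf")
    return (C / c_rand) / (L / l_rand)


def validate_cost_range(
    fc_list: list[np.ndarray],
    grid: CostGrid,
    n_null: int = 20,
    lcc_frac: float = 0.8,
    seed: int | None = None,
    log_base: float = np.e,
) -> pd.DataFrame:
    """Evaluate the three cost-range criteria per subject and cost.

    Criteria: (a) small-worldness sigma > 1; (b) largest connected
    component covers at least ``lcc_frac`` of nodes; (c) binary mean degree
    2m/N exceeds log(N) (natural log by default). Returns a long-format
    frame with per-subject pass flags plus cohort pass fractions.
    """
    if not fc_list:
        raise ValueError("fc_list must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for s, fc in enumerate(fc_list):
        for cost in grid:
            g = threshold_at_cost(fc, cost)
            n = g.n_nodes
            mean_deg = 2 * g.n_edges / n
            G = nx.from_numpy_array(g.binary)
            lcc = len(max(nx.connected_components(G), key=len)) / n
            sigma = small_worldness(g, n_null=n_null, seed=int(rng.integers(2**31)))
            rows.append({
                "subject": s, "cost": cost, "sigma": sigma,
                "lcc_fraction": lcc, "mean_degree": mean_deg,
                "pass_sigma": sigma > 1,
                "pass_lcc": lcc >= lcc_frac,
                "pass_degree": mean_deg > np.log(n) / np.log(log_base),
                "truncated": g.truncated,
            })
    report = pd.DataFrame(rows)
    report["pass_all"] = report[["pass_sigma", "pass_lcc", "pass_degree"]].all(axis=1)
    return report


def cohort_pass_fractions(report: pd.DataFrame) -> pd.DataFrame:
    """Fraction of subjects passing each criterion at each cost."""
    cols = ["pass_sigma", "pass_lcc", "pass_degree", "pass_all"]
    return report.groupby("cost")[cols].mean().reset_index()
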