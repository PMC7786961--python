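"""Module-based nodal metrics: within-module degree z and participation.

Both metrics score each node against a fixed (group-level) partition using
binary degrees on the thresholded graph, and are cost-integrated with the
same trapezoidal rule as the integration metrics.
"""

from __future__ import annotations

import warnings

import numpy as np

from .communities import Partition
from .graphs import CostGrid, ThresholdedGraph, threshold_at_cost
from .nodal import integrate_over_costs


def _degrees(g: ThresholdedGraph, weighted: bool) -> np.ndarray:
    return g.weights if weighted else g.binary.astype(float)


def within_module_degree(
    g: ThresholdedGraph, part: Partition, weighted: bool = False
) -> np.ndarray:
    """z_i = (k_ni - mean_module) / sd_module of intra-module degree.

    k_ni counts (binary by default) edges from node i to nodes of its own
    module. Modules with zero degree spread — including singletons, which
    are flagged — get z = 0 for all members.
    """
    if part.n_nodes != g.n_nodes:
        raise ValueError("partition does not cover the graph's node set")
    adj = _degrees(g, weighted)
    labels = part.labels
    z = np.zeros(g.n_nodes)
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        if len(members) == 1:
            warnings.warn(f"singleton module {c}: z set to 0", stacklevel=2)
            continue
        k_intra = adj[np.ix_(members, members)].sum(axis=1)
        sd = k_intra.std()
        if sd > 0:
            z[members] = (k_intra - k_intra.mean()) / sd
    return z


def participation_coefficient(
    g: ThresholdedGraph, part: Partition, weighted: bool = False
) -> np.ndarray:
    """P_i = 1 - sum_n (k_ni / k_i)^2 over modules n; P = 0 for isolated nodes."""
    if part.n_nodes != g.n_nodes:
        raise ValueError("partition does not cover the graph's node set")
    adj = _degrees(g, weighted)
    labels = part.labels
    k = adj.sum(axis=1)
    frac_sq = np.zeros(g.n_nodes)
    with np.errstate(divide="ignore", invalid="ignore"):
        for c in np.unique(labels):
            members = np.flatnonzero(labels == c)
            k_n = adj[:, members].sum(axis=1)
            frac_sq += np.where(k > 0, (k_n / np.where(k > 0, k, 1.0)) ** 2, 0.0)
    p = 1.0 - frac_sq
    p[k == 0] = 0.0
    return p


def integrated_module_metrics(
    fc: np.ndarray,
    part: Partition,
    grid: CostGrid,
    weighted: bool = False,
) -> dict[str, np.ndarray]:
    """Cost-integrated z and P for one subject against a fixed partition."""
    z_by_cost, p_by_cost = {}, {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # singleton-module flags repeat per cost
        for cost in grid:
            g = threshold_at_cost(fc, cost)
            z_by_cost[cost] = within_module_degree(g, part, weighted=weighted)
            p_by_cost[cost] = participation_coefficient(g, part, weighted=weighted)
    return {
        "within_module_z": integrate_over_costs(z_by_cost, grid),
        "participation": integrate_over_costs(p_by_cost, grid),
    }
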