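"""Nodal integration metrics: weighted degree centrality and nodal efficiency.

Metrics are computed per cost threshold on the weighted thresholded graph
and integrated over the cost grid (trapezoidal AUC) into one composite
value per node and subject.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import dijkstra

from .graphs import CostGrid, ThresholdedGraph, threshold_at_cost


def degree_centrality(g: ThresholdedGraph) -> np.ndarray:
    """D_i = sum of surviving edge weights incident to node i."""
    return g.weights.sum(axis=1)


def nodal_efficiency(g: ThresholdedGraph) -> np.ndarray:
    """E_i = mean over j != i of 1 / L_ij, with edge length 1/w.

    L_ij is the weighted shortest-path length; unreachable pairs contribute
    zero. An isolated node has E_i = 0.
    """
    w = g.weights
    n = w.shape[0]
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, 0.0)
    dist = dijkstra(csr_array(lengths), directed=False)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist) & (dist > 0), 1.0 / dist, 0.0)
    return inv.sum(axis=1) / (n - 1)


def integrate_over_costs(
    values_by_cost: Mapping[float, np.ndarray], grid: CostGrid
) -> np.ndarray:
    """Trapezoidal AUC of a per-node metric over the cost grid.

    ``values_by_cost`` must supply a value vector at every grid cost;
    a missing cost raises an error naming it.
    """
    if len(grid) < 2:
        raise ValueError("cost grid must contain at least 2 costs for integration")
    try:
        stack = np.stack([np.asarray(values_by_cost[c], dtype=float) for c in grid])
    except KeyError as e:
        raise ValueError(f"missing metric values at cost {e.args[0]}") from None
    return np.trapezoid(stack, np.asarray(grid.costs), axis=0)


def integrated_nodal_metrics(fc: np.ndarray, grid: CostGrid) -> dict[str, np.ndarray]:
    """Cost-integrated degree and efficiency for one subject's FC matrix."""
    deg, eff = {}, {}
    for cost in grid:
        g = threshold_at_cost(fc, cost)
        deg[cost] = degree_centrality(g)
        eff[cost] = nodal_efficiency(g)
    return {
        "degree": integrate_over_costs(deg, grid),
        "efficiency": integrate_over_costs(eff, grid),
    }
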