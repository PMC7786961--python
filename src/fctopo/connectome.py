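"""Subject-level weighted functional-connectivity matrices.

The connectome is the matrix of pairwise Pearson correlations between
regional BOLD time courses, with the diagonal and all negative correlations
set to zero, yielding a symmetric non-negative weighted graph.
"""

from __future__ import annotations

import numpy as np

from .graphs import CostGrid, threshold_at_cost


def build_fc(data: np.ndarray, node_labels: list[str] | None = None) -> np.ndarray:
    """Pearson-correlation FC matrix from a frames x nodes array.

    Entry (i, j) is ``max(0, r_ij)``; the diagonal is exactly zero.

    Raises if fewer than 3 frames remain or any node has zero variance
    (the offending node is named).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("time series must be 2-d (frames x nodes)")
    n_frames, n_nodes = data.shape
    if n_frames < 3:
        raise ValueError(f"need at least 3 frames to correlate, got {n_frames}")
    sd = data.std(axis=0)
    if np.any(sd == 0):
        idx = int(np.argmax(sd == 0))
        name = node_labels[idx] if node_labels is not None else str(idx)
        raise ValueError(f"zero-variance time series at node {name}")
    r = np.corrcoef(data, rowvar=False)
    np.clip(r, 0.0, None, out=r)
    np.fill_diagonal(r, 0.0)
    # corrcoef can be asymmetric at the last ulp
    return (r + r.T) / 2


def integrated_mean_fc(fc: np.ndarray, grid: CostGrid) -> float:
    """Area under the mean-surviving-edge-weight vs cost curve.

    At each cost the mean weight of retained edges is computed; the means
    are integrated over the cost axis by the trapezoidal rule, giving the
    integrated-FC covariate used to separate topology from raw FC strength.
    """
    if len(grid) < 2:
        raise ValueError("cost grid must contain at least 2 costs")
    means = []
    for cost in grid:
        g = threshold_at_cost(fc, cost)
        w = g.weights[np.triu_indices(g.n_nodes, k=1)]
        w = w[w > 0]
        means.append(w.mean() if len(w) else 0.0)
    return float(np.trapezoid(means, np.asarray(grid.costs)))
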