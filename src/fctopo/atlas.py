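"""Atlas label tables mapping connectome nodes to intrinsic networks.

The pipeline consumes an atlas as a plain table: one row per retained node,
giving its label, its intrinsic-network affiliation (one of the 17
replicable cortical networks, or a subcortical label) and the
community-of-interest used by the sub-network similarity analyses
(the combined default/control system DN-CN, the salience/ventral-attention
system SVAN, or the subcortical block).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

COMMUNITIES_OF_INTEREST = ("DN_CN", "SVAN", "SUBCORTICAL", "OTHER")

#: The 17 cortical intrinsic-network names (split-label convention).
CORTICAL_NETWORKS = (
    "VisCent", "VisPeri",
    "SomMotA", "SomMotB",
    "DorsAttnA", "DorsAttnB",
    "SalVentAttnA", "SalVentAttnB",
    "LimbicA", "LimbicB",
    "ContA", "ContB", "ContC",
    "DefaultA", "DefaultB", "DefaultC",
    "TempPar",
)

_COI_BY_NETWORK = {
    "DefaultA": "DN_CN", "DefaultB": "DN_CN", "DefaultC": "DN_CN",
    "ContA": "DN_CN", "ContB": "DN_CN", "ContC": "DN_CN",
    "SalVentAttnA": "SVAN", "SalVentAttnB": "SVAN",
}


def default_atlas(n_cortical: int = 114, n_subcortical: int = 27) -> pd.DataFrame:
    """Build the default 141-node label table (114 cortical + 27 subcortical).

    Cortical nodes are spread as evenly as possible over the 17 networks;
    subcortical nodes form a single SUBCORTICAL block. Node ids are
    contiguous from 0 in table order.
    """
    if n_cortical < len(CORTICAL_NETWORKS):
        raise ValueError("need at least one cortical node per network")
    counts = np.full(len(CORTICAL_NETWORKS), n_cortical // len(CORTICAL_NETWORKS))
    counts[: n_cortical % len(CORTICAL_NETWORKS)] += 1
    rows = []
    for net, c in zip(CORTICAL_NETWORKS, counts):
        coi = _COI_BY_NETWORK.get(net, "OTHER")
        for k in range(c):
            rows.append((f"{net}_{k + 1}", net, coi))
    for k in range(n_subcortical):
        rows.append((f"Subcortical_{k + 1}", "Subcortical", "SUBCORTICAL"))
    df = pd.DataFrame(rows, columns=["label", "network", "community_of_interest"])
    df.insert(0, "node_id", np.arange(len(df)))
    return df


def validate_atlas(atlas: pd.DataFrame) -> pd.DataFrame:
    """Check AtlasTable invariants; return the table unchanged."""
    required = {"node_id", "label", "network", "community_of_interest"}
    missing = required - set(atlas.columns)
    if missing:
        raise ValueError(f"atlas table missing columns: {sorted(missing)}")
    if len(atlas) < 2:
        raise ValueError("atlas must contain at least 2 nodes")
    if not np.array_equal(atlas["node_id"].to_numpy(), np.arange(len(atlas))):
        raise ValueError("atlas node_ids must be contiguous from 0")
    bad = set(atlas["community_of_interest"]) - set(COMMUNITIES_OF_INTEREST)
    if bad:
        raise ValueError(f"unknown community_of_interest values: {sorted(bad)}")
    return atlas


def scope_nodes(atlas: pd.DataFrame, scope: str) -> np.ndarray:
    """Node ids belonging to one community of interest."""
    if scope not in COMMUNITIES_OF_INTEREST:
        raise ValueError(f"unknown scope {scope!r}")
    return atlas.loc[atlas["community_of_interest"] == scope, "node_id"].to_numpy()
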