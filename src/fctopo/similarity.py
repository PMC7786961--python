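"""Partition similarity: adjusted Rand index, sub-network restriction, and
subgroup bootstrap resampling against a reference partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import atlas as atlas_mod
from .communities import DEFAULT_GAMMA_GROUP, Partition, group_partition

SCOPES = ("whole_brain", "DN_CN", "SVAN", "SUBCORTICAL")


@dataclass
class SimilarityResult:
    """Bootstrap ARI values for one group and scope vs a reference partition."""

    group: str
    scope: str
    ari_values: np.ndarray
    reference: str = "all_HC"

    def __post_init__(self):
        self.ari_values = np.asarray(self.ari_values, dtype=float)

    @property
    def mean(self) -> float:
        return float(self.ari_values.mean())


def adjusted_rand(p1: Partition | np.ndarray, p2: Partition | np.ndarray) -> float:
    """Permutation-model adjusted Rand index between two partitions."""
    l1 = p1.labels if isinstance(p1, Partition) else np.asarray(p1)
    l2 = p2.labels if isinstance(p2, Partition) else np.asarray(p2)
    if len(l1) != len(l2):
        raise ValueError(f"partitions cover different node sets ({len(l1)} vs {len(l2)})")
    return float(adjusted_rand_score(l1, l2))


def restricted_ari(
    p1: Partition | np.ndarray, p2: Partition | np.ndarray, node_subset: np.ndarray
) -> float:
    """ARI of the two partitions restricted to ``node_subset``."""
    node_subset = np.asarray(node_subset)
    if len(node_subset) < 2:
        raise ValueError("node subset must contain at least 2 nodes")
    l1 = p1.labels if isinstance(p1, Partition) else np.asarray(p1)
    l2 = p2.labels if isinstance(p2, Partition) else np.asarray(p2)
    return adjusted_rand(l1[node_subset], l2[node_subset])


def resample_group_similarity(
    partitions_by_group: dict[str, list[Partition]],
    reference: Partition,
    atlas: pd.DataFrame,
    n_subgroups: int = 20,
    subgroup_size: int = 10,
    gamma_group: float = DEFAULT_GAMMA_GROUP,
    seed: int | None = None,
    n_restarts: int = 10,
    scopes: tuple[str, ...] = SCOPES,
) -> list[SimilarityResult]:
    """Bootstrap subgroup ARIs versus a common reference partition.

    Per group, ``n_subgroups`` samples of ``subgroup_size`` subjects are
    drawn with replacement; each sample's group-level partition is built by
    the stage-2 consensus procedure and compared with the reference by
    whole-brain ARI and by ARI restricted to each community-of-interest
    node set from the atlas. Repeated subjects contribute to the allegiance
    matrix with multiplicity.
    """
    atlas_mod.validate_atlas(atlas)
    scope_sets = {
        s: atlas_mod.scope_nodes(atlas, s) for s in scopes if s != "whole_brain"
    }
    rng = np.random.default_rng(seed)
    results: dict[tuple[str, str], list[float]] = {
        (g, s): [] for g in partitions_by_group for s in scopes
    }
    for group_name, parts in partitions_by_group.items():
        if len(parts) == 0:
            raise ValueError(f"group {group_name!r} has no subject partitions")
        for _ in range(n_subgroups):
            idx = rng.integers(len(parts), size=subgroup_size)
            sub = [parts[i] for i in idx]
            sub_part, _ = group_partition(
                sub, gamma=gamma_group, seed=int(rng.integers(2**31)),
                n_restarts=n_restarts, level="subgroup",
            )
            for scope in scopes:
                if scope == "whole_brain":
                    ari = adjusted_rand(sub_part, reference)
                else:
                    ari = restricted_ari(sub_part, reference, scope_sets[scope])
                results[(group_name, scope)].append(ari)
    return [
        SimilarityResult(group=g, scope=s, ari_values=np.asarray(v))
        for (g, s), v in results.items()
    ]


def similarity_table(results: list[SimilarityResult]) -> pd.DataFrame:
    """Long-format table: group, scope, subgroup_index, ari."""
    rows = []
    for r in results:
        for k, a in enumerate(r.ari_values):
            rows.append({"group": r.group, "scope": r.scope,
                         "subgroup_index": k, "ari": a})
    return pd.DataFrame(rows)
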