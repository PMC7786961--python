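"""End-to-end validation experiments on synthetic cohorts.

Each function runs one self-contained experiment through the public
pipeline — planted-partition recovery, lesion-direction recovery of
group-specific module fragmentation, bootstrap-resampling arity, oracle
cross-validation, and type-I-error calibration of the statistics stage —
and returns the measured quantity. They are used by the test suite and by
the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import atlas as am
from . import reference, synthetic
from .cartography import participation_coefficient, within_module_degree
from .communities import (
    Partition,
    group_partition,
    modularity,
    subject_consensus,
)
from .connectome import build_fc
from .graphs import CostGrid, ThresholdedGraph
from .nodal import degree_centrality, nodal_efficiency
from .similarity import SimilarityResult, adjusted_rand, resample_group_similarity
from .stats import ari_anova, nodal_group_glm


def _hc_cohort(n_subjects: int, seed: int, n_frames: int = 240):
    atlas = am.default_atlas()
    planted = synthetic.planted_partition_from_atlas(atlas)
    cfg = synthetic.SimulationConfig(
        n_nodes=len(atlas), planted_partition=planted,
        group_specs=(synthetic.GroupSpec("HC", n_subjects),),
        n_frames=n_frames, seed=seed,
    )
    subjects, cohort, _ = synthetic.generate_cohort(cfg)
    return atlas, planted, subjects, cohort


def planted_recovery_ari(
    seed: int, n_subjects: int = 20, cost_step: float = 0.01
) -> float:
    """Two-stage group-partition recovery of the planted modules.

    Generates a healthy-control-like 141-node cohort (rho_within 0.9,
    rho_between 0.05), runs subject-level consensus at gamma = 3 over the
    cost grid and group-level consensus at gamma = 2, and returns the
    adjusted Rand index of the group partition against the planted labels.
    """
    atlas, planted, subjects, _ = _hc_cohort(n_subjects, seed)
    grid = CostGrid.from_range(0.09, 0.40, cost_step)
    rng = np.random.default_rng(seed)
    parts = [
        subject_consensus(build_fc(s.data), fine_grid=grid, gamma=3.0,
                          seed=int(rng.integers(2**31)))[0]
        for s in subjects
    ]
    gpart, _ = group_partition(parts, gamma=2.0, seed=int(rng.integers(2**31)))
    return adjusted_rand(gpart, planted)


def resampling_arity(
    seed: int, n_subjects: int = 30, cost_step: float = 0.01,
    n_subgroups: int = 20, subgroup_size: int = 10,
) -> dict[str, int]:
    """Count the bootstrap ARI values the resampling procedure emits.

    Runs one synthetic group through subject consensus and the
    20-subgroups-of-10 resampling scheme; returns the number of ARI values
    per scope.
    """
    atlas, planted, subjects, _ = _hc_cohort(n_subjects, seed)
    grid = CostGrid.from_range(0.09, 0.40, cost_step)
    rng = np.random.default_rng(seed)
    parts = [
        subject_consensus(build_fc(s.data), fine_grid=grid, gamma=3.0,
                          seed=int(rng.integers(2**31)))[0]
        for s in subjects
    ]
    reference_part, _ = group_partition(parts, gamma=2.0,
                                        seed=int(rng.integers(2**31)))
    results = resample_group_similarity(
        {"HC": parts}, reference_part, atlas,
        n_subgroups=n_subgroups, subgroup_size=subgroup_size,
        seed=int(rng.integers(2**31)),
    )
    return {r.scope: len(r.ari_values) for r in results}


def _fixture_graphs(seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    graphs = []
    for n in (4, 6, 8, 10, 12):
        for density in (0.4, 0.8, 1.0):
            w = np.abs(rng.normal(size=(n, n)))
            w = (w + w.T) / 2
            mask = np.triu(rng.random((n, n)) < density, 1)
            w = np.where(mask | mask.T, w, 0.0)
            np.fill_diagonal(w, 0.0)
            graphs.append(w)
    return graphs


def oracle_equivalence_max_error(seed: int) -> float:
    """Worst absolute disagreement between pipeline metrics and the naive
    reference implementations over random graphs of <= 12 nodes.

    Covers degree, efficiency, within-module z, participation, modularity
    Q, and the adjusted Rand index.
    """
    import warnings

    rng = np.random.default_rng(seed)
    worst = 0.0
    for w in _fixture_graphs(seed):
        g = ThresholdedGraph(cost=1.0, weights=w)
        labels = rng.integers(0, 3, size=len(w))
        part = Partition(labels=labels)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # singleton-module flags on random labels
            worst = max(
                worst,
                np.abs(degree_centrality(g) - reference.degree_sum(w)).max(),
                np.abs(nodal_efficiency(g)
                       - reference.efficiency_floyd_warshall(w)).max(),
                np.abs(within_module_degree(g, part)
                       - reference.within_module_z(w, labels)).max(),
                np.abs(participation_coefficient(g, part)
                       - reference.participation(w, labels)).max(),
                abs(modularity(w, labels, gamma=1.5)
                    - reference.modularity_q(w, labels, gamma=1.5)),
            )
        l2 = rng.integers(0, 3, size=len(w))
        worst = max(worst, abs(adjusted_rand(labels, l2)
                               - reference.adjusted_rand_index(labels, l2)))
    return float(worst)


def lesion_direction_replicates(
    seed: int,
    n_replicates: int = 10,
    n_per_group: int = 8,
    lesion_delta: float = 0.8,
    cost_step: float = 0.05,
    n_subgroups: int = 10,
    subgroup_size: int = 8,
) -> dict[str, int]:
    """Count replicates recovering the planted lesion double dissociation.

    Each replicate simulates a small-atlas three-group cohort in which the
    AD-like group fragments the DN-CN modules and the bvFTD-like group
    fragments the SVAN module, runs the full two-stage pipeline plus
    bootstrap resampling against the HC reference, and checks that each
    patient group's mean ARI in its lesioned scope falls below HC's.
    """
    atlas = am.default_atlas(n_cortical=34, n_subcortical=6)
    planted = synthetic.planted_partition_from_atlas(atlas)
    mods = synthetic.module_ids_for_scope(atlas, planted)
    grid = CostGrid.from_range(0.10, 0.40, cost_step)
    rng = np.random.default_rng(seed)
    n_dncn = n_svan = 0
    for _ in range(n_replicates):
        specs = (
            synthetic.GroupSpec("HC", n_per_group),
            synthetic.GroupSpec("AD", n_per_group,
                                lesioned_modules=frozenset(mods["DN_CN"]),
                                lesion_delta=lesion_delta),
            synthetic.GroupSpec("bvFTD", n_per_group,
                                lesioned_modules=frozenset(mods["SVAN"]),
                                lesion_delta=lesion_delta),
        )
        cfg = synthetic.SimulationConfig(
            n_nodes=len(atlas), planted_partition=planted, group_specs=specs,
            n_frames=240, seed=int(rng.integers(2**31)),
        )
        subjects, _, _ = synthetic.generate_cohort(cfg)
        parts_by_group: dict[str, list[Partition]] = {"HC": [], "AD": [], "bvFTD": []}
        for s in subjects:
            grp = s.subject_id.rsplit("_", 1)[0]
            p, _ = subject_consensus(build_fc(s.data), fine_grid=grid, gamma=3.0,
                                     seed=int(rng.integers(2**31)))
            parts_by_group[grp].append(p)
        ref, _ = group_partition(parts_by_group["HC"], gamma=2.0,
                                 seed=int(rng.integers(2**31)))
        res = resample_group_similarity(
            parts_by_group, ref, atlas, n_subgroups=n_subgroups,
            subgroup_size=subgroup_size, seed=int(rng.integers(2**31)),
        )
        mean = {(r.group, r.scope): r.mean for r in res}
        n_dncn += int(mean[("AD", "DN_CN")] < mean[("HC", "DN_CN")])
        n_svan += int(mean[("bvFTD", "SVAN")] < mean[("HC", "SVAN")])
    return {"dn_cn": n_dncn, "svan": n_svan, "n_replicates": n_replicates}


def glm_type1_rate(
    seed: int, n_replicates: int = 200, n_per_group: int = 15, n_nodes: int = 5
) -> float:
    """Type-I error of the nodal GLM at nominal p <= .05 under a null with
    no group effect (covariates present but uninformative)."""
    rng = np.random.default_rng(seed)
    hits = total = 0
    for _ in range(n_replicates):
        n = 2 * n_per_group
        cohort = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "group": ["HC"] * n_per_group + ["AD"] * n_per_group,
            "education": rng.normal(14, 2, n),
            "scanner": rng.choice(["A", "B"], n),
            "frames_retained": rng.integers(150, 240, n).astype(float),
        })
        metrics = pd.DataFrame({
            "subject_id": np.tile(cohort["subject_id"], n_nodes),
            "node_id": np.repeat(np.arange(n_nodes), n),
            "metric": "degree",
            "value": rng.normal(size=n * n_nodes),
        })
        res = nodal_group_glm(metrics, cohort)
        hits += int((res.p_uncorrected <= 0.05).sum())
        total += len(res)
    return hits / total


def anova_type1_rate(
    seed: int, n_replicates: int = 200, n_values: int = 20
) -> float:
    """Type-I error of the ARI ANOVA at nominal .05 when all three groups'
    ARI values are drawn from one distribution."""
    rng = np.random.default_rng(seed)
    hits = total = 0
    scopes = ("whole_brain", "DN_CN", "SVAN", "SUBCORTICAL")
    for _ in range(n_replicates):
        results = [
            SimilarityResult(group=g, scope=sc,
                             ari_values=rng.normal(0.7, 0.1, n_values))
            for sc in scopes for g in ("HC", "AD", "bvFTD")
        ]
        out = ari_anova(results)
        p_by_scope = out.groupby("scope")["p_anova"].first()
        hits += int((p_by_scope <= 0.05).sum())
        total += len(p_by_scope)
    return hits / total
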