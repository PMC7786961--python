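"""Synthetic cohorts with planted community structure and group lesions.

Each node's BOLD-like signal is a linear mixture of a per-subject latent
module signal, a shared global signal, and i.i.d. noise:

    x_i(t) = a_m * s_m(t) + rho_between * g(t) [+ merge term] + noise_sd * e_i(t)

where node i belongs to module m and a_m = rho_within, reduced by
lesion_delta for a group's lesioned modules. Module pairs listed in
merge_pairs additionally share a common latent at coupling merge_rho, so
their between-module correlation is raised. This plants block structure in
the empirical correlation matrix that the downstream community pipeline
should recover, and lets group-specific disruptions (module fragmentation,
module merging) be injected with known ground truth.

Behavior scores are coupled to a named nodal metric of each subject's own
connectome, so correlation-recovery tests have a known target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import atlas as atlas_mod
from .communities import Partition
from .scrub import SubjectTimeSeries

GROUPS = ("HC", "AD", "bvFTD")
DOMAIN_SCORES = ("episodic", "executive", "attention", "language", "visuospatial")


@dataclass(frozen=True)
class GroupSpec:
    """Generative parameters for one diagnostic group."""

    name: str
    n_subjects: int
    rho_within: float = 0.9
    rho_between: float = 0.05
    lesioned_modules: frozenset[int] = frozenset()
    lesion_delta: float = 0.0
    merge_pairs: frozenset[tuple[int, int]] = frozenset()
    merge_rho: float | None = None  # default: rho_within / 2

    def __post_init__(self):
        if not 0 <= self.rho_between < self.rho_within <= 1:
            raise ValueError(
                f"group {self.name}: need 0 <= rho_between < rho_within <= 1"
            )
        if self.rho_within - self.lesion_delta < 0:
            raise ValueError(f"group {self.name}: lesion_delta exceeds rho_within")
        if self.n_subjects < 1:
            raise ValueError(f"group {self.name}: n_subjects must be >= 1")


@dataclass(frozen=True)
class BehaviorCoupling:
    """Couples behavior scores to one nodal metric of the subject's connectome."""

    target_metric: str = "mean_degree"
    slope: float = 1.0
    noise_sd: float = 0.5


@dataclass
class SimulationConfig:
    """Full description of a synthetic cohort."""

    n_nodes: int
    planted_partition: Partition
    group_specs: tuple[GroupSpec, ...]
    n_frames: int = 240
    tr_seconds: float = 2.0
    noise_sd: float = 0.6
    spike_prob: float = 0.03
    spike_scale: float = 0.5
    behavior_coupling: BehaviorCoupling = field(default_factory=BehaviorCoupling)
    seed: int = 0

    def __post_init__(self):
        if self.planted_partition.n_nodes != self.n_nodes:
            raise ValueError(
                f"planted partition covers {self.planted_partition.n_nodes} nodes, "
                f"config says {self.n_nodes}"
            )
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")


def planted_partition_from_atlas(atlas: pd.DataFrame) -> Partition:
    """Planted modules = major intrinsic systems (network names with their
    A/B/C split labels merged) plus one subcortical module."""
    base = atlas["network"].str.replace(r"(Cent|Peri|[ABC])$", "", regex=True)
    codes, _ = pd.factorize(base)
    return Partition(labels=codes, level="planted", gamma=np.nan)


def default_config(
    n_per_group: tuple[int, int, int] = (38, 37, 36),
    seed: int = 0,
    lesion_delta: float = 0.8,
    n_frames: int = 240,
) -> tuple[SimulationConfig, pd.DataFrame]:
    """Three-group study-like configuration over the default 141-node atlas.

    The AD-like group fragments the default-mode and frontoparietal-control
    modules (the DN-CN system); the bvFTD-like group fragments the
    salience/ventral-attention module. Returns the config and the atlas.
    """
    atlas = atlas_mod.default_atlas()
    planted = planted_partition_from_atlas(atlas)
    mods = module_ids_for_scope(atlas, planted)
    specs = (
        GroupSpec("HC", n_per_group[0]),
        GroupSpec("AD", n_per_group[1], lesioned_modules=frozenset(mods["DN_CN"]),
                  lesion_delta=lesion_delta),
        GroupSpec("bvFTD", n_per_group[2], lesioned_modules=frozenset(mods["SVAN"]),
                  lesion_delta=lesion_delta),
    )
    cfg = SimulationConfig(n_nodes=len(atlas), planted_partition=planted,
                           group_specs=specs, n_frames=n_frames, seed=seed)
    return cfg, atlas


def module_ids_for_scope(atlas: pd.DataFrame, planted: Partition) -> dict[str, list[int]]:
    """Planted module ids whose nodes fall in each community of interest."""
    out: dict[str, list[int]] = {}
    for scope in ("DN_CN", "SVAN", "SUBCORTICAL"):
        nodes = atlas_mod.scope_nodes(atlas, scope)
        out[scope] = sorted(set(planted.labels[nodes].tolist()))
    return out


def generate_motion_trace(
    n_frames: int, spike_prob: float, spike_scale: float, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """FD (mm) and DVARS (%) traces: sub-threshold baseline plus Bernoulli
    spikes that exceed both 0.5 thresholds. Expected spike count is
    spike_prob * n_frames."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not 0 <= spike_prob <= 1:
        raise ValueError("spike_prob must be in [0, 1]")
    if spike_scale < 0:
        raise ValueError("spike_scale must be non-negative")
    rng = np.random.default_rng(seed)
    fd = rng.uniform(0.05, 0.35, size=n_frames)
    dvars = rng.uniform(0.05, 0.35, size=n_frames)
    spikes = rng.random(n_frames) < spike_prob
    n_spk = int(spikes.sum())
    fd[spikes] = 0.5 + 1e-3 + spike_scale * rng.exponential(1.0, size=n_spk)
    dvars[spikes] = 0.5 + 1e-3 + spike_scale * rng.exponential(1.0, size=n_spk)
    return fd, dvars


def _subject_signals(
    spec: GroupSpec, planted: Partition, n_frames: int, noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    labels = planted.labels
    modules = np.unique(labels)
    latents = {m: rng.standard_normal(n_frames) for m in modules}
    global_sig = rng.standard_normal(n_frames)
    merge_latents = {pair: rng.standard_normal(n_frames) for pair in spec.merge_pairs}
    merge_rho = spec.merge_rho if spec.merge_rho is not None else spec.rho_within / 2
    noise = rng.standard_normal((n_frames, len(labels)))
    data = np.empty((n_frames, len(labels)))
    for i, m in enumerate(labels):
        a = spec.rho_within - (spec.lesion_delta if m in spec.lesioned_modules else 0.0)
        x = a * latents[m] + spec.rho_between * global_sig + noise_sd * noise[:, i]
        for pair, s in merge_latents.items():
            if m in pair:
                x = x + merge_rho * s
        data[:, i] = x
    return data


def _mean_degree(data: np.ndarray) -> float:
    """Subject-level mean positive-correlation strength (behavior target)."""
    r = np.corrcoef(data, rowvar=False)
    np.fill_diagonal(r, 0.0)
    return float(np.clip(r, 0, None).sum(axis=1).mean())


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[SubjectTimeSeries], pd.DataFrame, Partition]:
    """Generate time series, motion traces, and a cohort table.

    Deterministic for a given config seed. Behavior scores (five cognitive
    domain z-scores, positively coupled; NPI total, negatively coupled) are
    linear in the cohort-standardized target metric plus independent noise.
    ``frames_retained`` counts frames passing the 0.5/0.5 motion thresholds.
    """
    rng = np.random.default_rng(config.seed)
    subjects: list[SubjectTimeSeries] = []
    rows = []
    targets = []
    for spec in config.group_specs:
        for k in range(spec.n_subjects):
            sid = f"{spec.name}_{k + 1:03d}"
            data = _subject_signals(spec, config.planted_partition,
                                    config.n_frames, config.noise_sd, rng)
            fd, dvars = generate_motion_trace(
                config.n_frames, config.spike_prob, config.spike_scale,
                seed=int(rng.integers(2**31)),
            )
            subjects.append(SubjectTimeSeries(
                subject_id=sid, data=data, tr_seconds=config.tr_seconds,
                fd=fd, dvars=dvars,
            ))
            targets.append(_mean_degree(data))
            rows.append({
                "subject_id": sid,
                "group": spec.name,
                "age": float(np.round(rng.normal(65, 8), 1)),
                "gender": rng.choice(["F", "M"]),
                "education": int(np.clip(np.round(rng.normal(14, 3)), 6, 22)),
                "scanner": rng.choice(["TrioTim", "PrismaFit"]),
                "frames_retained": int(((fd <= 0.5) & (dvars <= 0.5)).sum()),
            })
    cohort = pd.DataFrame(rows)
    t = np.asarray(targets)
    t_z = (t - t.mean()) / t.std() if t.std() > 0 else np.zeros_like(t)
    bc = config.behavior_coupling
    for name in DOMAIN_SCORES:
        cohort[name] = bc.slope * t_z + bc.noise_sd * rng.standard_normal(len(t_z))
    cohort["npi_total"] = np.clip(
        10 - 4 * (bc.slope * t_z + bc.noise_sd * rng.standard_normal(len(t_z))),
        0, None,
    ).round(1)
    cohort["target_metric"] = t
    cohort["integrated_fc"] = np.nan  # filled by the connectome stage
    return subjects, cohort, config.planted_partition


def generate_gm_volumes(
    cohort: pd.DataFrame,
    config: SimulationConfig,
    atrophy_delta: float = 0.5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Node-wise Gaussian gray-matter volumes (subjects x nodes).

    Nodes of a group's lesioned modules are reduced by ``atrophy_delta`` in
    that group, so atrophy co-varies with lesion status; exists purely to
    exercise the covariate pathway of the statistics stage.
    """
    rng = np.random.default_rng(seed if seed is not None else config.seed + 1)
    spec_by_name = {s.name: s for s in config.group_specs}
    labels = config.planted_partition.labels
    vols = np.empty((len(cohort), len(labels)))
    for r, (_, row) in enumerate(cohort.iterrows()):
        spec = spec_by_name[row["group"]]
        mean = np.full(len(labels), 5.0)
        lesioned = np.isin(labels, list(spec.lesioned_modules))
        mean[lesioned] -= atrophy_delta
        vols[r] = rng.normal(mean, 0.5)
    return pd.DataFrame(vols, index=cohort["subject_id"],
                        columns=np.arange(len(labels)))
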