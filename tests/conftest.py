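import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_fc(rng, n, density=1.0):
    """Random symmetric nonnegative matrix with zero diagonal."""
    w = np.abs(rng.normal(size=(n, n)))
    w = (w + w.T) / 2
    if density < 1.0:
        mask = rng.random((n, n)) < density
        mask = np.triu(mask, 1)
        w = np.where(mask | mask.T, w, 0.0)
    np.fill_diagonal(w, 0.0)
    return w


@pytest.fixture(scope="session")
def fixture_graphs(rng):
    """Small weighted graphs (<= 12 nodes) for brute-force oracle checks."""
    graphs = []
    for n in (4, 6, 8, 10, 12):
        for density in (0.4, 0.8, 1.0):
            graphs.append(random_fc(rng, n, density))
    # hand-built specials: path, star, two blocks
    path = np.zeros((5, 5))
    for i in range(4):
        path[i, i + 1] = path[i + 1, i] = 0.5
    graphs.append(path)
    star = np.zeros((6, 6))
    star[0, 1:] = star[1:, 0] = 0.7
    graphs.append(star)
    blocks = np.zeros((8, 8))
    blocks[:4, :4] = 0.9
    blocks[4:, 4:] = 0.9
    np.fill_diagonal(blocks, 0.0)
    graphs.append(blocks)
    return graphs


@pytest.fixture(scope="session")
def two_block_fc():
    """Exact two-block FC: within-block 0.9, between 0.0."""
    fc = np.zeros((12, 12))
    fc[:6, :6] = 0.9
    fc[6:, 6:] = 0.9
    np.fill_diagonal(fc, 0.0)
    return fc


@pytest.fixture(scope="session")
def small_cohort():
    """Small-atlas three-group cohort with planted DN-CN and SVAN lesions."""
    from fctopo import atlas as am
    from fctopo import synthetic

    atlas = am.default_atlas(n_cortical=34, n_subcortical=6)
    planted = synthetic.planted_partition_from_atlas(atlas)
    mods = synthetic.module_ids_for_scope(atlas, planted)
    specs = (
        synthetic.GroupSpec("HC", 8),
        synthetic.GroupSpec("AD", 8, lesioned_modules=frozenset(mods["DN_CN"]),
                            lesion_delta=0.8),
        synthetic.GroupSpec("bvFTD", 8, lesioned_modules=frozenset(mods["SVAN"]),
                            lesion_delta=0.8),
    )
    cfg = synthetic.SimulationConfig(
        n_nodes=len(atlas), planted_partition=planted, group_specs=specs,
        n_frames=240, seed=42,
    )
    subjects, cohort, _ = synthetic.generate_cohort(cfg)
    return {"config": cfg, "atlas": atlas, "planted": planted,
            "subjects": subjects, "cohort": cohort}
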