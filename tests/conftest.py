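"""Shared fixtures: small constructed rasters and session-scoped worlds."""

import numpy as np
import pytest
from hypothesis import settings

from hyperniche.envspace import extract_env, fit_pca, pc_scores
from hyperniche.raster import EnvRasterStack
from hyperniche.synthetic import default_world, evaluation_world

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture
def small_stack():
    """5x4 two-layer stack on a 1-degree grid, no nodata."""
    nr, nc = 5, 4
    lon_grad = np.tile(np.arange(nc, dtype=float), (nr, 1))
    lat_grad = np.tile(np.arange(nr, dtype=float)[:, None], (1, nc))
    return EnvRasterStack(names=["temp", "precip"],
                          values=np.stack([lon_grad, lat_grad]),
                          west=0.0, north=5.0, cellsize=1.0)


@pytest.fixture(scope="session")
def invasion_world():
    """The default two-group invasion world (pinned master seed)."""
    return default_world()


@pytest.fixture(scope="session")
def invasion_pca(invasion_world):
    """Correlation PCA fitted on all valid cells of the invasion world."""
    df, _, _ = invasion_world.stack.cell_matrix()
    return fit_pca(df)


@pytest.fixture(scope="session")
def invasion_scores(invasion_world, invasion_pca):
    """Retained-axis scores of each group's occurrence records."""
    out = {}
    for g, occ in invasion_world.occurrences.items():
        matrix, dropped = extract_env(invasion_world.stack, occ)
        assert len(dropped) == 0
        out[g] = pc_scores(invasion_pca, matrix)
    return out


@pytest.fixture(scope="session")
def rare_niche_world():
    """Single-group world with a rare niche, for evaluation tests."""
    return evaluation_world()


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One complete synthetic pipeline run, shared across tests."""
    from hyperniche.pipeline import RunConfig, run_pipeline

    out = tmp_path_factory.mktemp("pipeline") / "run"
    return run_pipeline(RunConfig(out_dir=str(out), master_seed=11))
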