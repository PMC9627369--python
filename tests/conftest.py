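import numpy as np
import pytest

from nacfc.pipeline import PipelineConfig, run_pipeline
from nacfc.synthetic import (
    AtlasSpec,
    RoiSpec,
    SimulationSpec,
    assign_targets,
    generate_atlas,
    generate_cohort,
    qc_filter,
)


@pytest.fixture(scope="session")
def atlas():
    return generate_atlas(AtlasSpec(), seed=0)


@pytest.fixture(scope="session")
def small_spec():
    return SimulationSpec(n_pd=12, n_hc=12, n_timepoints=60,
                          n_target_voxels=30, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    table, _ = qc_filter(generate_cohort(small_spec),
                         flag_col=None, fd_threshold=float("inf"))
    return table


@pytest.fixture(scope="session")
def small_targets(atlas, small_spec):
    return assign_targets(atlas, small_spec)


def _study_config(seed: int, n_per_group: int = 100) -> PipelineConfig:
    """The reduced-scale study conditions: n=100/group after QC, 24^3 grid,
    T=200, 200 target voxels per effect seed, moderate noise."""
    return PipelineConfig(
        sim=SimulationSpec(n_pd=n_per_group, n_hc=n_per_group,
                           n_timepoints=200, seed=seed),
        n_perm=500, n_boot=500, first_pass=False,
        qc_flag_col=None, qc_fd_threshold=float("inf"),
        seed=seed,
    )


@pytest.fixture(scope="session")
def study_run():
    """One full pipeline run at the reduced study scale, shared across
    recovery checks."""
    cfg = _study_config(seed=2024)
    manifest, results = run_pipeline(cfg)
    return cfg, manifest, results
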