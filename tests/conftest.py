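import numpy as np
import pytest

from eeglrp import (
    ClassEffect,
    CohortSpec,
    NetSpec,
    RunConfig,
    generate_cohort,
    standard_montage,
)
from eeglrp.net import loocv
from eeglrp.preprocessing import segment


@pytest.fixture(scope="session")
def small_montage():
    """8-channel montage containing the default planted-effect sites."""
    return standard_montage(("Fz", "FCz", "Cz", "CPz", "Pz", "O1", "Oz", "O2"))


@pytest.fixture(scope="session")
def tiny_cohort(small_montage):
    """6+6 subjects, 8 channels, 10 s at 100 Hz, strong alpha effect."""
    spec = CohortSpec(
        n_per_class=6,
        montage=small_montage,
        fs=100.0,
        duration=10.0,
        effects=(ClassEffect(band=(8.0, 13.0), channels=("Oz", "O1"), power_scale=3.0),),
        seed=42,
    )
    return spec, generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_net():
    """Small network geometry for 10-s inputs at 100 Hz (988 conv samples)."""
    return NetSpec(
        n_temporal_filters=2,
        temporal_kernel=13,
        n_spatial_filters=2,
        pool_length=988,
        pool_stride=988,
    )


@pytest.fixture(scope="session")
def tiny_loocv(tiny_cohort, tiny_net, small_montage):
    """A complete (fast) LOOCV run shared by selection/model tests."""
    _, recs = tiny_cohort
    sets = [segment(r, 10.0) for r in recs]
    config = RunConfig(epochs=8, net=tiny_net, seed=5)
    folds, metrics = loocv(sets, small_montage, config, keep_models=True)
    return {
        "sets": sets,
        "config": config,
        "folds": folds,
        "metrics": metrics,
        "montage": small_montage,
    }
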