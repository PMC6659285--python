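import dataclasses
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from streetpa.config import (
    PipelineConfig,
    ScoringConfig,
    WorldConfig,
    default_truth,
)


@pytest.fixture(scope="session")
def small_world() -> WorldConfig:
    return WorldConfig(
        n_neighbourhoods=6,
        respondents_per_nbhd_mean=18,
        street_spacing_m=600.0,
        nbhd_spacing_m=1200.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_truth(small_world):
    return default_truth(small_world, seed=7)


@pytest.fixture(scope="session")
def tiny_cfg() -> PipelineConfig:
    """A pipeline config small enough for sub-10-second end-to-end runs."""
    return PipelineConfig(
        world=WorldConfig(
            n_neighbourhoods=9,
            respondents_per_nbhd_mean=10,
            point_spacing_m=150.0,
            street_spacing_m=700.0,
            nbhd_spacing_m=1100.0,
            seed=3,
        ),
        scoring=ScoringConfig(
            initial_batch=80,
            rmse_window=40,
            rmse_threshold=0.6,
            retrain_every=20,
            max_calibration_images=300,
            regressor_params={"n_estimators": 40, "min_samples_leaf": 2, "n_jobs": 1},
            holdout_n=40,
            seed=3,
        ),
        seed=3,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)
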