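import numpy as np
import pytest

from clonebow import PipelineConfig, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def cohort():
    """Default-noise synthetic cohort shared across read-only tests."""
    scfg = SimulationConfig(seed=42, n_founders=120)
    cells, tracks, gt, trees = simulate_dataset(scfg)
    return {"config": scfg, "cells": cells, "tracks": tracks,
            "gt": gt, "trees": trees}


@pytest.fixture(scope="session")
def cohort_zero_noise():
    scfg = SimulationConfig(seed=7, n_founders=80, channel_noise_sd=0.0)
    cells, tracks, gt, trees = simulate_dataset(scfg)
    return {"config": scfg, "cells": cells, "tracks": tracks,
            "gt": gt, "trees": trees}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
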