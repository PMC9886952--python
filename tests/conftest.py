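import dataclasses

import numpy as np
import pandas as pd
import pytest

import dislearn as dl
from dislearn import preprocessing
from dislearn.synthetic_data import DesignConfig, GeneratingParams


@pytest.fixture(scope="session")
def small_design() -> DesignConfig:
    return DesignConfig(tasks=("fixed",), n_participants_per_task=6)


@pytest.fixture(scope="session")
def clean_trials(small_design):
    """A small simulated experiment after standard preprocessing."""
    trials = dl.simulate_experiment(small_design, mode="condition", seed=101)
    clean, _ = preprocessing.preprocess(trials)
    return clean


@pytest.fixture(scope="session")
def noise_free_params() -> GeneratingParams:
    return GeneratingParams().with_zero_heterogeneity()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_trials(rows) -> pd.DataFrame:
    """Build a minimal trial table from (pid, task, block, trial, condition,
    dloc, tloc, dist, rt, correct) tuples."""
    return pd.DataFrame(
        rows, columns=dl.synthetic_data.TRIAL_COLUMNS
    ).astype({"block": np.int64, "trial": np.int64,
              "target_location": np.int64})
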