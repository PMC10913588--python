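import warnings

import numpy as np
import pandas as pd
import pytest

import hrpsim as h
from hrpsim.synthetic_population import with_group_undercompensation

DELTA = 500.0  # built-in undercompensation (euro) for the flagged recovery group
DELTA_GROUP = "cond_00"


@pytest.fixture(scope="session")
def delta_run() -> h.SimulationResult:
    """Full pipeline at n=150k with a known 500-euro undercompensated group."""
    gen = with_group_undercompensation(
        h.GeneratorConfig(n_population=150_000, seed=7), 0, DELTA
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return h.run_simulation(h.RunConfig(generator=gen))


@pytest.fixture(scope="session")
def null_run() -> h.SimulationResult:
    """Pipeline with the latent severity channel switched off: the survey carries
    no residual signal, so every subgroup should be compensated on average."""
    gen = h.GeneratorConfig(n_population=120_000, seed=11, hidden_severity_sd=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return h.run_simulation(h.RunConfig(generator=gen, pool_fractions=()))


@pytest.fixture()
def toy_persons() -> pd.DataFrame:
    """Small deterministic person table with spending, predictions and residuals."""
    rng = np.random.default_rng(3)
    n = 800
    predicted = rng.uniform(500, 4000, n)
    residual = rng.normal(0, 1500, n) + np.where(rng.random(n) < 0.1, 4000, 0)
    persons = pd.DataFrame(
        {
            "person_id": np.arange(n),
            "spending": predicted + residual,
            "survey_responded": True,
        }
    )
    residuals = pd.DataFrame(
        {
            "person_id": np.arange(n),
            "predicted_spending": predicted,
            "residual_spending": residual,
        }
    )
    predictions = pd.DataFrame(
        {
            "person_id": np.arange(n),
            # noisy but informative predictions of the residual
            "predicted_residual": residual + rng.normal(0, 800, n),
            "sample": "test",
        }
    )
    return persons, residuals, predictions
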