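import numpy as np
import pandas as pd
import pytest

import latentsurv as ls


@pytest.fixture(scope="session")
def scaled_cohort():
    """One scaled-down synthetic cohort shared across tests."""
    return ls.simulate_cohort(ls.CohortConfig.scaled_down(seed=7))


@pytest.fixture(scope="session")
def preprocessed(scaled_cohort):
    matrix, report = ls.preprocess_cohort(scaled_cohort.rna, scaled_cohort.mirna)
    return matrix, report


@pytest.fixture(scope="session")
def records(scaled_cohort, preprocessed):
    matrix, _ = preprocessed
    return ls.records_from_clinical(scaled_cohort.clinical.loc[matrix.patients])


def random_survival(n, rng, hazard=0.01, censor_max=200.0, x=None, beta=0.0):
    """Exponential survival records with optional covariate effect."""
    if x is None:
        x = np.zeros(n)
    rate = hazard * np.exp(beta * x)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.uniform(0, censor_max, n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return [ls.SurvivalRecord(f"p{i}", max(float(time[i]), 1e-6), int(event[i]))
            for i in range(n)]
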