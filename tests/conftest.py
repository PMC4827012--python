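import numpy as np
import pandas as pd
import pytest

from cosinorvd import data_model
from cosinorvd.synthetic import GeneratorConfig, generate_cohort


def toy_table(months, values, **covariate_columns):
    """Minimal baseline cohort frame from explicit months and 25OHD values."""
    months = np.asarray(months)
    df = pd.DataFrame(
        {
            "patient_id": [f"X{i:03d}" for i in range(len(months))],
            "visit": "baseline",
            "month": months,
            "ohd2": 0.0,
            "ohd3": np.asarray(values, dtype=float),
            **covariate_columns,
        }
    )
    return data_model.add_derived(df)


@pytest.fixture(scope="session")
def cohort():
    """One default paper-scale synthetic cohort, with truth columns."""
    return generate_cohort(GeneratorConfig(), seed=7, include_truth=True)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast no-covariate cohort for inference checks."""
    cfg = GeneratorConfig(
        n_baseline=1000, n_nested=0, covariate_effects={},
        amplitude_effects={}, missing_rates={},
    )
    return generate_cohort(cfg, seed=11)
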