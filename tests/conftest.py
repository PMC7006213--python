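import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from prognomics.datatypes import FeatureMatrix, SurvivalData
from prognomics.simcohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """n=200 cohort with a recoverable 3-subtype signal in all layers."""
    cfg = CohortConfig(
        n_samples=200,
        n_features={"expression": 120, "methylation": 80, "mirna": 50},
        n_subtypes=3,
        effect_size={"expression": 2.0, "methylation": 2.0, "mirna": 2.0},
        censor_rate=0.4,
        seed=5,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def survival_rng():
    return np.random.default_rng(123)


def random_survival(rng, n, censor_scale=2.0, lp=None):
    lp = np.zeros(n) if lp is None else lp
    T = rng.exponential(np.exp(-lp))
    C = rng.uniform(0, censor_scale, n)
    return SurvivalData(np.minimum(T, C), (T <= C).astype(int))


@pytest.fixture()
def matrix_factory():
    def make(values, layer="expression", scale="fpkm", prefix="F"):
        values = np.asarray(values, dtype=float)
        n, p = values.shape
        df = pd.DataFrame(
            values,
            index=[f"S{i}" for i in range(n)],
            columns=[f"{prefix}{j}" for j in range(p)],
        )
        return FeatureMatrix(df, layer, scale)

    return make
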