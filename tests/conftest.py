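import numpy as np
import pandas as pd
import pytest

from metabotype.simulate import PARAMETERS, GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A 700-participant default-structure cohort used across modules."""
    return generate_cohort(GeneratorConfig(n_participants=700, seed=42))


@pytest.fixture(scope="session")
def complete_cohort() -> pd.DataFrame:
    """Fully fasting, fully observed cohort (no exclusions fire)."""
    cfg = GeneratorConfig(n_participants=400, seed=7, missing_rate=0.0,
                          nonfasting_rate=0.0, disease_flag_missing_rate=0.0)
    return generate_cohort(cfg)


from metabotype.examples import roster_with_exclusion_counts as make_exclusion_roster  # noqa: E402,F401


def planted_blobs(n_per=150, k=3, p=4, sep=8.0, seed=0):
    """Spherical Gaussian blobs with centers ``sep`` SD apart along a diagonal."""
    rng = np.random.default_rng(seed)
    X = np.concatenate([rng.normal(i * sep, 1.0, size=(n_per, p))
                        for i in range(k)])
    labels = np.repeat(np.arange(k), n_per)
    return X, labels


@pytest.fixture()
def exclusion_roster() -> pd.DataFrame:
    return make_exclusion_roster()
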