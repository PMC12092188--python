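import numpy as np
import pandas as pd
import pytest

from xwas import StudySimConfig, simulate_study


def make_samples(y, male, **covs) -> pd.DataFrame:
    """Build a sample table from an outcome vector and a male mask."""
    y = np.asarray(y)
    male = np.asarray(male, dtype=bool)
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(y))],
            "sex": np.where(male, "male", "female"),
            "status": np.where(y == 1, "case", "control"),
            **covs,
        }
    )


@pytest.fixture(scope="session")
def small_study():
    """A deterministic case-control study with a real effect (OR 1.4)."""
    return simulate_study(
        StudySimConfig(
            n_female=600, n_male=400, n_variants=3, maf=0.3,
            real_or=1.4, causal_index=0, seed=42, study_id="fix",
        )
    )


@pytest.fixture(scope="session")
def tiny_fixture():
    """n=40 dataset for oracle-equivalence checks (no separation)."""
    rng = np.random.default_rng(7)
    male = np.r_[np.zeros(24, bool), np.ones(16, bool)]
    dose = np.where(male, rng.binomial(1, 0.4, 40), rng.binomial(2, 0.4, 40)).astype(float)
    y = rng.binomial(1, 0.4 + 0.08 * dose / 2, 40).astype(float)
    # ensure both outcome classes in both genotype groups
    y[:3] = [0, 1, 0]
    return dose, male, y
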