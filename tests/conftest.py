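import numpy as np
import pandas as pd
import pytest

from neurohit.cohort import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but non-trivial cohort shared across tests."""
    cfg = CohortConfig(n_participants=6, n_songs=8, n_hits=4, duration_sec=60, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def study_cohort():
    """A cohort at the study scale (33 participants, 24 songs, 13 hits)."""
    return simulate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def feature_table(study_cohort):
    from neurohit.features import featurize_cohort

    return featurize_cohort(study_cohort)


def toy_feature_frame(n=24, n_hits=13, d=2.0, seed=0):
    """A feature-shaped frame with a controllable class separation."""
    rng = np.random.default_rng(seed)
    label = np.array(["hit"] * n_hits + ["flop"] * (n - n_hits))
    shift = np.where(label == "hit", d, 0.0)
    return pd.DataFrame(
        {
            "label": label,
            "avg_immersion": 4.1 + shift * 0.07 + rng.normal(0, 0.07, n),
            "retreat": 0.18 - shift * 0.002 + rng.normal(0, 0.002, n),
            "peak_immersion": np.clip(rng.normal(0.07, 0.03, n), 0, 1),
        }
    )
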