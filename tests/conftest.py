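import numpy as np
import pandas as pd
import pytest

from newssdt import RatingsTable, SimulationConfig, simulate_study


def make_table(groups, scale_max=7, metadata=None):
    """Build a validated RatingsTable from a compact group description.

    ``groups`` maps (participant_id, set, phase) -> (true_ratings, fake_ratings).
    Fake items cycle through the three technique categories.
    """
    fake_cats = ("Impersonation", "Conspiracy", "Discrediting")
    rows = []
    for (pid, set_, phase), (true_r, fake_r) in groups.items():
        for i, r in enumerate(true_r):
            rows.append((pid, set_, phase, f"t{i}", "true_news", "Control", r))
        for i, r in enumerate(fake_r):
            rows.append((pid, set_, phase, f"f{i}", "fake_news", fake_cats[i % 3], r))
    df = pd.DataFrame(
        rows,
        columns=["participant_id", "set", "phase", "item_id", "truth", "category", "rating"],
    )
    return RatingsTable(df, scale_max=scale_max, metadata=metadata or {})


@pytest.fixture(scope="session")
def study_table():
    """A default-configuration synthetic study (150 participants)."""
    return simulate_study(SimulationConfig(), seed=11)


@pytest.fixture(scope="session")
def null_small_config():
    """A small full-null configuration for quick calibration loops."""
    return SimulationConfig(n_participants=60)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
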