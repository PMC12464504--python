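import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")

from clustercea import RunConfig, SimConfig, TrialTable, participant_frame, simulate_dataset


@pytest.fixture(scope="session")
def run_cfg() -> RunConfig:
    return RunConfig(cpi_table={2017: 100.0, 2020: 105.0, 2023: 110.0})


@pytest.fixture(scope="session")
def small_sim() -> SimConfig:
    """Reduced-size trial for fast structural tests (same cluster design)."""
    return SimConfig(seed=7, participants_total=500)


@pytest.fixture(scope="session")
def small_dataset(small_sim):
    return simulate_dataset(small_sim)


@pytest.fixture(scope="session")
def small_frame(small_dataset, small_sim):
    table, items = small_dataset
    return participant_frame(table, items, outpatient_flat=small_sim.outpatient_flat)


def make_trial_df(rows):
    """Build a trial DataFrame from (pid, arm, village, township, wave, sbp, utility)."""
    return pd.DataFrame(
        [
            {
                "participant_id": pid,
                "arm": arm,
                "village": vil,
                "township": town,
                "age": 65.0,
                "sex": 0,
                "death_time_years": np.nan,
                "wave_time_years": wave,
                "sbp": sbp,
                "utility": util,
            }
            for pid, arm, vil, town, wave, sbp, util in rows
        ]
    )


@pytest.fixture
def tiny_trial_df():
    """2 participants x 2 waves, schema-conformant."""
    return make_trial_df(
        [
            ("a", "intervention", "v1", "t1", 0.0, 150.0, 0.8),
            ("a", "intervention", "v1", "t1", 1.0, 142.0, 0.85),
            ("b", "control", "v2", "t1", 0.0, 148.0, 0.8),
            ("b", "control", "v2", "t1", 1.0, 146.0, 0.75),
        ]
    )


@pytest.fixture
def tiny_trial(tiny_trial_df):
    return TrialTable(tiny_trial_df)
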