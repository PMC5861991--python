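import numpy as np
import pandas as pd
import pytest

from ensdec import GeneratorConfig, generate_session, extract_counts, POSTCUE_WINDOW
from ensdec.io import Session


@pytest.fixture(scope="session")
def small_session():
    """A tuned 30-unit session reused by read-only tests."""
    cfg = GeneratorConfig(n_units=30, n_trials=200, seed=11,
                          gain_location=2.0, gain_direction=2.0,
                          baseline_log_mean=np.log(8.0), baseline_log_sd=0.5)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def small_counts(small_session):
    session, _ = small_session
    return extract_counts(session, POSTCUE_WINDOW)


@pytest.fixture(scope="session")
def null_session():
    """All gains 1: no tuning, nothing decodable."""
    cfg = GeneratorConfig(n_units=20, n_trials=200, seed=5,
                          gain_location=1.0, gain_direction=1.0,
                          p_location_tuned=0.0, p_direction_tuned=0.0,
                          p_both_tuned=0.0)
    return generate_session(cfg)


def tiny_handmade_session():
    """Two units, four trials, hand-placed spikes for boundary tests."""
    trials = pd.DataFrame({
        "trial_id": [0, 1, 2, 3],
        "target_location": ["ipsi", "contra", "ipsi", "contra"],
        "motion_direction": ["up", "up", "down", "down"],
        "outcome": ["hit", "hit", "hit", "miss"],
        # binary-exact event times so window-boundary behaviour is testable
        "stimulus_onset_s": [0.25] * 4,
        "color_onset_s": [0.5] * 4,
        "color_offset_s": [1.0] * 4,
        "change_time_s": [2.4] * 4,
        "response_time_s": [2.6, np.nan, 2.7, np.nan],
    })
    spikes = pd.DataFrame({
        "unit_id": [0, 0, 0, 1],
        "trial_id": [0, 0, 1, 2],
        # rel. to color offset (1.0): exactly 0.25 (in), exactly 0.75
        # (out, half-open), 0.4 (in)
        "spike_time_s": [1.25, 1.75, 1.4, 0.9],
    })
    units = pd.DataFrame({"unit_id": [0, 1], "electrode_row": [0, 3],
                          "electrode_col": [0, 7], "wired": [True, True]})
    return Session("handmade", trials, spikes, units).validate()


@pytest.fixture()
def handmade_session():
    return tiny_handmade_session()
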