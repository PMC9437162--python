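"""Shared fixtures: small simulated recordings and behavioral sessions.

Everything is generated programmatically at session scope with fixed seeds
so tests are deterministic and no data files ship with the package.
"""

import warnings

import numpy as np
import pytest

from temporalpitch import acc, ffr, stimgen
from temporalpitch.synthetic_data import (ResponderModel, ScalpModel,
                                          simulate_recording,
                                          simulate_session)


@pytest.fixture(scope="session")
def responder_session():
    """120-trial session from a moderately sensitive virtual responder."""
    return simulate_session(ResponderModel(d_true=1.5), n_trials=120, seed=42)


@pytest.fixture(scope="session")
def null_session():
    """120-trial session from a zero-sensitivity responder."""
    return simulate_session(ResponderModel(d_true=0.0), n_trials=120, seed=43)


@pytest.fixture(scope="session")
def alternating_schedule():
    """10-block alternating run for the 376->624 pps condition."""
    base, higher = stimgen.condition_specs("base376_pct66")
    return stimgen.make_alternating_schedule(base, higher, n_blocks=10, seed=2)


@pytest.fixture(scope="session")
def small_recording(alternating_schedule):
    """Simulated recording with the default scalp model (ACC + FFR + noise)."""
    return simulate_recording(ScalpModel(), alternating_schedule, seed=3)


@pytest.fixture(scope="session")
def acc_epochs(small_recording):
    """Cortical-band epochs of the small recording, lightly screened."""
    filt = acc.filter_acc(small_recording)
    eset = acc.extract_epochs(filt)
    return acc.adaptive_rejection(eset, factor=8.0)


@pytest.fixture(scope="session")
def ffr_epoch_sets(small_recording):
    """Broadband 1-s epochs of the small recording, keyed by pulse rate."""
    frec = ffr.filter_ffr(small_recording)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ffr.segment_ffr(frec, rejection_factor=None, seed=6)


def zeros_recording(schedule, sample_rate=acc.EEG_SAMPLE_RATE, pad_s=0.5):
    """All-zero recording with a schedule's event list (bookkeeping tests)."""
    n = int(round((schedule.total_duration_s + pad_s) * sample_rate))
    events = [{
        "block": ev.block, "sweep": ev.sweep,
        "t_base": ev.t_base, "t_higher": ev.t_higher,
        "base_pps": schedule.base.pulse_rate_pps,
        "higher_pps": schedule.higher.pulse_rate_pps,
        "polarity": ev.polarity,
    } for ev in schedule.events]
    return acc.ContinuousRecording(channels=np.zeros((2, n)),
                                   sample_rate=sample_rate, events=events)
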