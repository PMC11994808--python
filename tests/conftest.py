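import numpy as np
import pandas as pd
import pytest

from mcir import IndividualProfile, simulate_individual
from mcir.index import BLOCK_MINUTES, MCIRSeries

EPOCH = pd.Timestamp("2021-01-04 00:00:00")


@pytest.fixture(scope="session")
def quiet_profile():
    """Degenerate profile: no circadian drive, no activity, no noise."""
    return IndividualProfile(participant_id="quiet", hr_circadian_amp=0.0,
                             activity_day_rate=0.0, noise_scale=0.0,
                             sqi_dropout_prob=0.0, rng_seed=1)


@pytest.fixture(scope="session")
def default_series():
    return simulate_individual(IndividualProfile(rng_seed=42), 7)


def make_mcir(values, dose_time=EPOCH, participant_id="T", offset_blocks=0):
    """MCIRSeries on the dose-anchored 15-min grid from a plain array."""
    values = np.asarray(values, dtype=float)
    start = dose_time + pd.Timedelta(minutes=offset_blocks * BLOCK_MINUTES)
    idx = pd.date_range(start, periods=len(values),
                        freq=f"{BLOCK_MINUTES}min")
    return MCIRSeries(participant_id, idx, values)


def oracle_detectable(values):
    """Brute-force enumeration of the detectable-response rule."""
    v0 = np.nan_to_num(np.asarray(values, dtype=float))
    qualifies = False
    for s in range(0, max(len(v0) - 24 + 1, 0)):
        if (v0[s:s + 24] > 0.10).sum() >= 12:
            qualifies = True
            break
    best = run = 0
    for x in v0:
        run = run + 1 if x > 0 else 0
        best = max(best, run)
    return qualifies and best >= 5
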