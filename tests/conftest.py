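import datetime as dt

import numpy as np
import pytest

from paq_agree.accel import EpochSeries
from paq_agree.pipeline import Participant
from paq_agree.simulate import SimulationConfig, simulate_study


def minutes(counts, pid="T1", start=dt.datetime(2017, 5, 15)):
    """Build a per-minute EpochSeries from a plain count list."""
    return EpochSeries(
        participant_id=pid, start_timestamp=start, epoch_seconds=60,
        counts=np.asarray(counts, dtype=np.int64),
    )


def brute_force_nonwear(counts, min_window=60, max_interrupt_run=2, max_cpm=100):
    """Independent all-windows oracle for the non-wear rule.

    A minute is non-wear iff it lies inside some window [i, j] with zero CPM at
    both ends, length >= min_window, every minute <= max_cpm, and every maximal
    nonzero run inside no longer than max_interrupt_run minutes.  Window starts
    are restricted to zero-run starts (prepending zeros never invalidates a
    window, so this loses nothing).
    """
    x = list(counts)
    n = len(x)
    mask = [False] * n
    for i in range(n):
        if x[i] != 0 or (i > 0 and x[i - 1] == 0):
            continue
        run = 0
        last_zero = i
        j = i
        while j < n:
            if x[j] == 0:
                run = 0
                last_zero = j
            else:
                run += 1
                if x[j] > max_cpm or run > max_interrupt_run:
                    break
            j += 1
        if last_zero - i + 1 >= min_window:
            for m in range(i, last_zero + 1):
                mask[m] = True
    return np.array(mask)


@pytest.fixture(scope="session")
def nonwear_oracle():
    return brute_force_nonwear


@pytest.fixture(scope="session")
def small_study():
    """A complete synthetic study small enough for fast end-to-end tests."""
    config = SimulationConfig(n_participants=8, epoch_seconds=60, seed=5)
    return simulate_study(config)


def as_participants(roster):
    return [Participant(p.participant_id, p.sex, p.age, p.bmi, p.group) for p in roster]
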