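"""Shared fixtures: small hand-buildable epochs and simulation configs."""

import numpy as np
import pandas as pd
import pytest

from tmvpa import EpochsDataset, default_montage


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture
def make_epochs(montage):
    """Factory for small epochs datasets with explicit voltages.

    ``data`` is (n_trials, 34, n_samples) in µV; event metadata defaults
    to correct, target-present trials alternating left/right in the
    exemplar task.
    """

    def _make(data, tasks=None, sides=None, correct=None, artifact=None,
              sfreq=500.0, t_start=-100.0, units="uV", subject="s00",
              group="human"):
        data = np.asarray(data, dtype=float)
        n, _, t = data.shape
        times = t_start + 1000.0 / sfreq * np.arange(t)
        events = pd.DataFrame({
            "trial": np.arange(n),
            "task": tasks if tasks is not None else ["exemplar"] * n,
            "target_side": (sides if sides is not None
                            else ["left", "right"] * (n // 2 + 1))[:n],
            "correct": correct if correct is not None else [True] * n,
            "artifact": artifact if artifact is not None else [False] * n,
        })
        return EpochsDataset(data=data, times=times, montage=montage,
                             events=events, subject=subject, group=group,
                             units=units)

    return _make
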