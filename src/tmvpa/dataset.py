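"""Epoched EEG container: trials x channels x samples plus events metadata."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError
from .montage import ChannelMontage

EVENT_COLUMNS = ("trial", "task", "target_side", "correct", "artifact")

UNITS_UV = "uV"
UNITS_Z = "z"


@dataclass
class EpochsDataset:
    """Epoched multichannel EEG for one subject.

    Attributes
    ----------
    data
        Voltage array, shape (n_trials, n_channels, n_samples).  µV before
        preprocessing, unitless z-scores after ``baseline_zscore``.
    times
        Sample times in ms relative to stimulus onset; strictly increasing
        with uniform spacing.
    montage
        Channel montage; ``data`` channel order follows ``montage.names``.
    events
        One row per trial with columns ``trial, task, target_side, correct,
        artifact``.  ``task`` in {exemplar, category}; ``target_side`` in
        {left, right}; ``correct`` / ``artifact`` boolean.
    subject, group
        Subject identifier and group label ("human" / "nonhuman").
    units
        "uV" or "z".
    provenance
        Ordered record of the operations applied so far (name + parameters).
    """

    data: np.ndarray
    times: np.ndarray
    montage: ChannelMontage
    events: pd.DataFrame
    subject: str
    group: str
    units: str = UNITS_UV
    provenance: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ConfigurationError("data must be trials x channels x samples")
        n_trials, n_channels, n_samples = self.data.shape
        if n_channels != len(self.montage.names):
            raise ConfigurationError(
                f"data has {n_channels} channels but montage has "
                f"{len(self.montage.names)}"
            )
        if n_samples != len(self.times):
            raise ConfigurationError("time axis length does not match data")
        if len(self.times) >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0]):
                raise ConfigurationError("time axis must be uniform, increasing")
        if len(self.events) != n_trials:
            raise ConfigurationError("events table length does not match data")
        missing = set(EVENT_COLUMNS) - set(self.events.columns)
        if missing:
            raise SchemaError(f"events table missing columns: {sorted(missing)}")
        if self.units not in (UNITS_UV, UNITS_Z):
            raise ConfigurationError(f"unknown units tag {self.units!r}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def sfreq(self) -> float:
        """Sampling rate in Hz."""
        return 1000.0 / float(self.times[1] - self.times[0])

    def channel_data(self, name: str) -> np.ndarray:
        """(n_trials, n_samples) view of one channel."""
        return self.data[:, self.montage.index(name), :]

    def select_trials(self, mask: np.ndarray, note: str | None = None
                      ) -> "EpochsDataset":
        """Return a copy keeping the trials where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        out = replace(
            self,
            data=self.data[mask].copy(),
            events=self.events.loc[mask].reset_index(drop=True),
            provenance=list(self.provenance),
        )
        if note:
            out.provenance.append({"op": note, "kept": int(mask.sum()),
                                   "of": int(mask.size)})
        return out

    def with_data(self, data: np.ndarray, **prov: Any) -> "EpochsDataset":
        out = replace(self, data=data, provenance=list(self.provenance))
        if prov:
            out.provenance.append(prov)
        return out

    def scalp_features(self, sample_index: int) -> np.ndarray:
        """(n_trials, n_scalp) feature matrix at one time sample."""
        return self.data[:, self.montage.scalp_indices, sample_index]
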