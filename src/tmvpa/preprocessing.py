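"""Epoch-level preprocessing: artifact rejection, trial selection,
running-average smoothing, baseline z-scoring, and the N2pc utility.

The canonical order, fixed by ``preprocess``, is

    reject_artifacts (µV thresholds) -> select_valid_trials ->
    running_average -> baseline_zscore

because rejection thresholds are voltage thresholds and z-scoring is the
final normalization before decoding.  Every operation appends to the
dataset's provenance record, so the output is fully determined by the
input plus that record.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import convolve1d

from .dataset import UNITS_UV, UNITS_Z, EpochsDataset
from .errors import ConfigurationError, ParameterError, SchemaError, UnitsError
from .montage import HEOG, SCALP, VEOG

_ZERO_SD = 1e-12


@dataclass(frozen=True)
class RejectionCriteria:
    """Peak-voltage rejection thresholds in µV, per channel role."""

    heog_uv: float = 25.0
    veog_uv: float = 60.0
    other_uv: float = 80.0

    def __post_init__(self) -> None:
        if min(self.heog_uv, self.veog_uv, self.other_uv) <= 0:
            raise ConfigurationError("rejection thresholds must be > 0")

    def threshold_for_role(self, role: str) -> float:
        return {HEOG: self.heog_uv, VEOG: self.veog_uv,
                SCALP: self.other_uv}[role]


@dataclass
class RejectionLog:
    """Per-trial rejection decisions plus per-criterion counts.

    ``table`` has one row per input trial: trial id, kept flag, and for
    rejected trials the first violated criterion (channel role) and the
    offending channel.
    """

    table: pd.DataFrame
    counts: dict[str, int]

    @property
    def n_kept(self) -> int:
        return int(self.table["kept"].sum())

    @property
    def n_rejected(self) -> int:
        return int((~self.table["kept"]).sum())


def reject_artifacts(epochs: EpochsDataset,
                     criteria: RejectionCriteria | None = None
                     ) -> tuple[EpochsDataset, RejectionLog]:
    """Drop trials whose peak |voltage| exceeds its role threshold.

    Comparison is strict: a sample exactly at the threshold is kept.
    Requires µV input — thresholds are voltages, not z-scores.
    """
    criteria = criteria or RejectionCriteria()
    if epochs.units != UNITS_UV:
        raise UnitsError(
            "artifact rejection requires µV data; got z-scored input")
    roles = [epochs.montage.roles[n] for n in epochs.montage.names]
    thresholds = np.array([criteria.threshold_for_role(r) for r in roles])
    peak = np.max(np.abs(epochs.data), axis=2)          # trials x channels
    violated = peak > thresholds[None, :]
    kept = ~violated.any(axis=1)

    first_criterion, first_channel = [], []
    for tr in range(epochs.n_trials):
        if kept[tr]:
            first_criterion.append(None)
            first_channel.append(None)
        else:
            ch = int(np.argmax(violated[tr]))
            first_criterion.append(roles[ch])
            first_channel.append(epochs.montage.names[ch])
    table = pd.DataFrame({
        "trial": epochs.events["trial"].to_numpy(),
        "kept": kept,
        "criterion": first_criterion,
        "channel": first_channel,
    })
    counts = {role: int((table.loc[~kept, "criterion"] == role).sum())
              for role in (HEOG, VEOG, SCALP)}
    out = epochs.select_trials(kept, note=None)
    out.provenance.append({
        "op": "reject_artifacts", "heog_uv": criteria.heog_uv,
        "veog_uv": criteria.veog_uv, "other_uv": criteria.other_uv,
        "kept": int(kept.sum()), "of": int(kept.size),
    })
    return out, RejectionLog(table=table, counts=counts)


def select_valid_trials(epochs: EpochsDataset) -> EpochsDataset:
    """Keep correct, target-present trials only."""
    for col in ("task", "target_side", "correct"):
        if col not in epochs.events.columns:
            raise SchemaError(f"events table lacks column {col!r}")
    side = epochs.events["target_side"]
    mask = (epochs.events["correct"].astype(bool)
            & side.notna() & side.isin(["left", "right"])).to_numpy()
    if not mask.any():
        warnings.warn("no valid trials remain after selection", stacklevel=2)
    return epochs.select_trials(mask, note="select_valid_trials")


def _smoothing_length(window_ms: float, dt_ms: float) -> int:
    # Smallest odd sample count whose centered span covers the window:
    # at 500 Hz a 20 ms window is 11 samples (span (n-1)*dt = 20 ms).
    if window_ms < dt_ms:
        raise ParameterError(
            f"smoothing window {window_ms} ms is shorter than one sample "
            f"({dt_ms} ms)")
    return 2 * math.ceil(window_ms / (2.0 * dt_ms)) + 1


def running_average(epochs: EpochsDataset, window_ms: float = 20.0
                    ) -> EpochsDataset:
    """Centered moving-average smoothing with truncated edge windows."""
    dt = float(epochs.times[1] - epochs.times[0])
    n = _smoothing_length(window_ms, dt)
    kernel = np.ones(n)
    sums = convolve1d(epochs.data, kernel, axis=2, mode="constant", cval=0.0)
    counts = convolve1d(np.ones(epochs.n_samples), kernel,
                        mode="constant", cval=0.0)
    smoothed = sums / counts[None, None, :]
    return epochs.with_data(smoothed, op="running_average",
                            window_ms=window_ms, n_samples_window=n)


def baseline_zscore(epochs: EpochsDataset,
                    baseline_window_ms: tuple[float, float] = (-100.0, 0.0)
                    ) -> EpochsDataset:
    """Z-score each trial x channel against its own baseline period.

    Subtracts the baseline mean and divides by the baseline population
    SD (denominator n).  Trials with a zero-variance baseline on any
    channel are excluded and recorded in provenance.
    """
    lo, hi = baseline_window_ms
    mask = (epochs.times >= lo) & (epochs.times <= hi)
    if mask.sum() < 2:
        raise ParameterError("baseline window must contain >= 2 samples")
    base = epochs.data[:, :, mask]
    mean = base.mean(axis=2, keepdims=True)
    sd = base.std(axis=2, ddof=0, keepdims=True)
    degenerate = (sd[..., 0] < _ZERO_SD).any(axis=1)     # per trial
    sd_safe = np.where(sd < _ZERO_SD, 1.0, sd)
    z = (epochs.data - mean) / sd_safe
    out = epochs.with_data(z)
    out.units = UNITS_Z
    if degenerate.any():
        out = out.select_trials(~degenerate, note=None)
    out.provenance.append({
        "op": "baseline_zscore", "window_ms": list(baseline_window_ms),
        "sd_convention": "population",
        "excluded_zero_sd_trials": int(degenerate.sum()),
    })
    return out


def preprocess(epochs: EpochsDataset,
               criteria: RejectionCriteria | None = None,
               window_ms: float = 20.0,
               baseline_window_ms: tuple[float, float] = (-100.0, 0.0),
               ) -> tuple[EpochsDataset, RejectionLog]:
    """Full preprocessing chain in the canonical order."""
    clean, log = reject_artifacts(epochs, criteria)
    valid = select_valid_trials(clean)
    smoothed = running_average(valid, window_ms)
    return baseline_zscore(smoothed, baseline_window_ms), log


def n2pc_difference(epochs: EpochsDataset,
                    left_channel: str = "PO7",
                    right_channel: str = "PO8") -> pd.Series:
    """Contralateral-minus-ipsilateral difference waveform.

    For each target-present trial the contralateral electrode is the one
    opposite the target side (PO8 for left targets, PO7 for right
    targets); returns the trial-mean difference as a time-indexed series.
    """
    for ch in (left_channel, right_channel):
        if ch not in epochs.montage.names:
            raise SchemaError(f"channel {ch!r} not in montage")
    sides = epochs.events["target_side"]
    present = sides.isin(["left", "right"]).to_numpy()
    if not present.any():
        raise SchemaError("no target-present trials for N2pc computation")
    left_data = epochs.channel_data(left_channel)[present]
    right_data = epochs.channel_data(right_channel)[present]
    is_left = (sides[present] == "left").to_numpy()
    contra = np.where(is_left[:, None], right_data, left_data)
    ipsi = np.where(is_left[:, None], left_data, right_data)
    diff = (contra - ipsi).mean(axis=0)
    return pd.Series(diff, index=pd.Index(epochs.times, name="time_ms"),
                     name="n2pc_uv" if epochs.units == UNITS_UV else "n2pc_z")
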