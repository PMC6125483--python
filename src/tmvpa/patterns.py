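"""Activation patterns from classifier weights.

A linear classifier's weight vector is a backward (filter) model and is
not directly interpretable as a scalp topography: channels can receive
large weights purely to cancel correlated noise.  The forward-model
(Haufe) transform projects the weights through the data covariance,

    pattern = Σ w / (wᵀ Σ w),

yielding per-channel values proportional to how strongly each channel
expresses the decoded signal (arbitrary units; the normalizer makes the
result invariant to positive rescaling of w).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .dataset import EpochsDataset
from .decoding import AccuracyTimeSeries
from .errors import (DegenerateProjectionError, InsufficientDataError,
                     ParameterError)

_TOL = 1e-12


@dataclass
class ActivationPattern:
    """Window-averaged per-scalp-channel activation pattern."""

    values: np.ndarray          # one per scalp channel, arbitrary units
    channels: tuple[str, ...]
    window_ms: tuple[float, float]
    subject: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("activation pattern contains non-finite values")
        if len(self.values) != len(self.channels):
            raise ParameterError("one pattern value per channel required")


@dataclass
class GroupPatternTest:
    """Channel-wise one-sample t-tests of patterns against zero."""

    channels: tuple[str, ...]
    t: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    significant: np.ndarray     # after BH-FDR at alpha
    alpha: float


def haufe_transform(weights: np.ndarray, data_covariance: np.ndarray,
                    normalize: bool = True) -> np.ndarray:
    """Forward-model projection of one weight vector.

    ``pattern = Σw / (wᵀΣw)`` with ``w`` first rescaled to unit norm, so
    the output is invariant to positive rescaling of the weights (the
    scale of a linear classifier's weight vector is arbitrary).  With
    ``normalize=False`` returns plain ``Σw`` on the unit-norm weights.
    Raises if the quadratic form is not positive — the weights carry no
    variance in the data and no pattern exists.
    """
    w = np.asarray(weights, dtype=float)
    norm = np.linalg.norm(w)
    if norm > _TOL:
        w = w / norm
    cov = np.asarray(data_covariance, dtype=float)
    if cov.shape != (len(w), len(w)):
        raise ParameterError("covariance shape does not match weights")
    sw = cov @ w
    if not normalize:
        return sw
    denom = float(w @ sw)
    if denom <= _TOL:
        raise DegenerateProjectionError(
            f"w'Σw = {denom:.3g} is not positive; degenerate projection")
    return sw / denom


def timepoint_covariance(epochs: EpochsDataset, sample_index: int
                         ) -> np.ndarray:
    """Empirical scalp-channel covariance of the trials at one sample."""
    x = epochs.scalp_features(sample_index)
    return np.cov(x, rowvar=False)


def patterns_from_timeseries(ts: AccuracyTimeSeries, epochs: EpochsDataset,
                             normalize: bool = True) -> np.ndarray:
    """Per-time-point Haufe patterns for a decoding result.

    Covariances are computed from the same (all-trial, not pseudo-trial)
    feature matrices that entered the decoding.
    """
    time_to_sample = {t: i for i, t in enumerate(epochs.times)}
    out = np.empty_like(ts.weights)
    for k, t in enumerate(ts.times):
        cov = timepoint_covariance(epochs, time_to_sample[t])
        out[k] = haufe_transform(ts.weights[k], cov, normalize=normalize)
    return out


def window_average_pattern(patterns: np.ndarray, times: np.ndarray,
                           window_ms: tuple[float, float],
                           channels: tuple[str, ...],
                           subject: str = "", condition: str = ""
                           ) -> ActivationPattern:
    """Mean per-time-point pattern over a closed time window."""
    lo, hi = window_ms
    mask = (np.asarray(times) >= lo) & (np.asarray(times) <= hi)
    if not mask.any():
        raise ParameterError(f"window {window_ms} contains no samples")
    return ActivationPattern(
        values=np.asarray(patterns)[mask].mean(axis=0), channels=channels,
        window_ms=(float(lo), float(hi)), subject=subject, condition=condition)


def group_pattern_test(patterns: list[ActivationPattern] | np.ndarray,
                       channels: tuple[str, ...] | None = None,
                       alpha: float = 0.05) -> GroupPatternTest:
    """Channel-wise group-level test of patterns against zero.

    One-sample two-sided t-test per channel across subjects, BH-FDR
    corrected over channels.
    """
    if isinstance(patterns, (list, tuple)):
        if channels is None:
            channels = patterns[0].channels
        mat = np.vstack([p.values for p in patterns])
    else:
        mat = np.asarray(patterns, dtype=float)
        if channels is None:
            raise ParameterError("channel names required for array input")
    if mat.shape[0] < 3:
        raise InsufficientDataError("group pattern test needs >= 3 subjects")
    res = sps.ttest_1samp(mat, 0.0, axis=0)
    p_raw = np.asarray(res.pvalue)
    reject, p_adj, _, _ = multipletests(p_raw, alpha=alpha, method="fdr_bh")
    return GroupPatternTest(channels=tuple(channels), t=np.asarray(res.statistic),
                            p_raw=p_raw, p_adj=p_adj, significant=reject,
                            alpha=alpha)
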