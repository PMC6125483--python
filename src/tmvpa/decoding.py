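"""Per-subject time-resolved linear decoding.

At each time point the scalp-channel voltages form one feature vector
per trial.  Decoding uses stratified k-fold cross-validation (default
4) with per-fold pseudo-trial averaging: the trials of each class
within a fold are averaged into pseudo-trials before training/testing a
linear soft-margin SVM, and the whole procedure is repeated for many
random fold assignments ("permutations", default 100) whose accuracies
are averaged.  With one pseudo-trial per class per fold, each held-out
fold contributes an accuracy in {0, 50, 100}%.

Two labelings are supported: "location" (left vs right target;
positive class = right) and "type" (exemplar vs category search;
positive class = category).  The positive class fixes the orientation
of the weight vectors so they can be averaged across folds and
permutations without cancellation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .dataset import UNITS_Z, EpochsDataset
from .errors import (ConfigurationError, InsufficientDataError,
                     ParameterError, SchemaError)

POSITIVE_CLASS = {"location": "right", "type": "category"}
LABEL_COLUMNS = {"location": "target_side", "type": "task"}


@dataclass(frozen=True)
class DecodingConfig:
    """Cross-validated decoding parameters.

    ``n_permutations`` is the number of random fold assignments averaged
    per time point; ``svm_c`` the soft-margin regularization constant on
    z-scored inputs; ``time_decim`` decodes every k-th sample (1 = all).
    ``pseudo_per_fold`` > 1 splits each fold's class trials into several
    pseudo-trials instead of one; ``pseudo_average_test=False`` scores
    the held-out fold trial-wise instead of pseudo-averaged.
    """

    n_folds: int = 4
    n_permutations: int = 100
    svm_c: float = 1.0
    chance_pct: float = 50.0
    post_onset_only: bool = True
    time_decim: int = 1
    pseudo_per_fold: int = 1
    pseudo_average_test: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigurationError("need at least 2 folds")
        if self.n_permutations < 1:
            raise ConfigurationError("need at least 1 fold permutation")
        if self.svm_c <= 0:
            raise ConfigurationError("SVM regularization must be > 0")
        if self.time_decim < 1:
            raise ConfigurationError("time decimation must be >= 1")
        if self.pseudo_per_fold < 1:
            raise ConfigurationError("pseudo-trials per fold must be >= 1")


@dataclass
class AccuracyTimeSeries:
    """Decoding accuracy and mean classifier weights over time."""

    times: np.ndarray                   # ms
    accuracy_pct: np.ndarray            # same length as times
    weights: np.ndarray                 # n_times x n_scalp_channels
    subject: str
    condition: str
    group: str = ""

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.accuracy_pct) == len(self.weights)):
            raise ConfigurationError("time axis / accuracy / weights mismatch")
        if np.any(self.accuracy_pct < 0) or np.any(self.accuracy_pct > 100):
            raise ConfigurationError("accuracies must lie in [0, 100]")


@dataclass(frozen=True)
class SummaryStats:
    """Peak accuracy, latency to peak, and window-mean accuracy."""

    peak_accuracy_pct: float
    peak_latency_ms: float
    window_mean_pct: float
    window_ms: tuple[float, float]


def assign_folds(labels: np.ndarray, n_folds: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Random stratified fold assignment.

    Within each class, fold sizes differ by at most one; the remainder
    trials go to folds chosen in random order (round-robin).
    """
    labels = np.asarray(labels)
    folds = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < n_folds:
            raise InsufficientDataError(
                f"class {cls!r} has {len(idx)} trials < {n_folds} folds")
        idx = rng.permutation(idx)
        base, rem = divmod(len(idx), n_folds)
        fold_order = rng.permutation(n_folds)
        sizes = np.full(n_folds, base)
        sizes[fold_order[:rem]] += 1
        assignment = np.repeat(np.arange(n_folds), sizes)
        folds[idx] = assignment
    return folds


def make_pseudotrials(features: np.ndarray, labels: np.ndarray,
                      fold_assignment: np.ndarray, n_pseudo: int = 1
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average each fold's trials per class into pseudo-trials.

    Returns (pseudo_features, pseudo_labels, pseudo_folds) with
    ``n_folds * n_classes * n_pseudo`` rows (fewer if a fold/class cell
    has fewer trials than ``n_pseudo``).
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    xs, ys, fs = [], [], []
    for f in np.unique(fold_assignment):
        for cls in classes:
            members = np.flatnonzero((fold_assignment == f) & (labels == cls))
            if len(members) == 0:
                raise InsufficientDataError(
                    f"fold {f} has no trials of class {cls!r}")
            for chunk in np.array_split(members, min(n_pseudo, len(members))):
                xs.append(features[chunk].mean(axis=0))
                ys.append(cls)
                fs.append(f)
    return np.array(xs), np.array(ys), np.array(fs)


def _degenerate_training(x_pos: np.ndarray, x_neg: np.ndarray) -> bool:
    return (x_pos.shape == x_neg.shape and np.allclose(x_pos, x_neg)) or (
        np.allclose(x_pos, x_pos[0]) and np.allclose(x_neg, x_neg[0])
        and np.allclose(x_pos[0], x_neg[0]))


def decode_timepoint(features: np.ndarray, y_positive: np.ndarray,
                     config: DecodingConfig, rng: np.random.Generator
                     ) -> tuple[float, np.ndarray]:
    """Cross-validated accuracy and mean oriented weights at one time point.

    Parameters
    ----------
    features
        (n_trials, n_channels) matrix.
    y_positive
        Boolean label per trial; True = positive class.  Weight vectors
        are oriented so the positive class scores positive, then
        averaged over folds and permutations.
    """
    features = np.asarray(features, dtype=float)
    y = np.asarray(y_positive, dtype=bool)
    if features.ndim != 2 or len(features) != len(y):
        raise ParameterError("features must be trials x channels, one label each")
    if y.all() or not y.any():
        raise InsufficientDataError("both classes must be present")

    clf = SVC(kernel="linear", C=config.svm_c, shrinking=False)
    n_correct = 0
    n_total = 0
    weight_sum = np.zeros(features.shape[1])
    n_weights = 0
    warned = False
    for _ in range(config.n_permutations):
        folds = assign_folds(y, config.n_folds, rng)
        xp, yp, fp = make_pseudotrials(features, y, folds,
                                       config.pseudo_per_fold)
        for f in range(config.n_folds):
            train = fp != f
            x_tr, y_tr = xp[train], yp[train]
            if config.pseudo_average_test:
                x_te, y_te = xp[~train], yp[~train]
            else:
                te = folds == f
                x_te, y_te = features[te], y[te]
            if _degenerate_training(x_tr[y_tr], x_tr[~y_tr]):
                if not warned:
                    warnings.warn("degenerate training set; scoring at chance",
                                  stacklevel=2)
                    warned = True
                n_correct += len(y_te) / 2.0
                n_total += len(y_te)
                n_weights += 1
                continue
            clf.fit(x_tr, y_tr)
            pred = clf.predict(x_te)
            n_correct += int((pred == y_te).sum())
            n_total += len(y_te)
            # classes_ sorted [False, True]: coef_ already scores the
            # positive class positive.
            weight_sum += clf.coef_[0]
            n_weights += 1
    accuracy = 100.0 * n_correct / n_total
    return accuracy, weight_sum / n_weights


def labels_for(epochs: EpochsDataset, labeling: str) -> np.ndarray:
    """Boolean positive-class labels from the events table."""
    if labeling not in POSITIVE_CLASS:
        raise ParameterError(f"unknown labeling {labeling!r}")
    col = LABEL_COLUMNS[labeling]
    if col not in epochs.events.columns:
        raise SchemaError(f"events table lacks column {col!r}")
    return (epochs.events[col] == POSITIVE_CLASS[labeling]).to_numpy()


def decode_timeseries(epochs: EpochsDataset, labeling: str,
                      config: DecodingConfig | None = None,
                      rng: np.random.Generator | None = None,
                      condition: str | None = None) -> AccuracyTimeSeries:
    """Run ``decode_timepoint`` independently at each (post-onset) sample.

    For the "location" labeling the caller is expected to have subset
    the epochs to a single task first; "type" pools over target sides.
    """
    config = config or DecodingConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if epochs.units != UNITS_Z:
        warnings.warn("decoding is intended to run on z-scored epochs",
                      stacklevel=2)
    y = labels_for(epochs, labeling)
    if y.sum() < config.n_folds or (~y).sum() < config.n_folds:
        raise InsufficientDataError(
            f"need >= {config.n_folds} trials per class, got "
            f"{int(y.sum())} / {int((~y).sum())}")
    sample_idx = np.arange(epochs.n_samples)
    if config.post_onset_only:
        sample_idx = sample_idx[epochs.times >= 0]
    sample_idx = sample_idx[::config.time_decim]

    accs = np.empty(len(sample_idx))
    weights = np.empty((len(sample_idx), epochs.montage.n_scalp))
    for k, si in enumerate(sample_idx):
        accs[k], weights[k] = decode_timepoint(
            epochs.scalp_features(si), y, config, rng)
    return AccuracyTimeSeries(
        times=epochs.times[sample_idx], accuracy_pct=accs, weights=weights,
        subject=epochs.subject, group=epochs.group,
        condition=condition or labeling)


def summarize_accuracy(ts: AccuracyTimeSeries,
                       window_ms: tuple[float, float]) -> SummaryStats:
    """Peak accuracy, latency of the earliest peak, and window mean.

    Peak search is restricted to post-onset samples; the window mean is
    over the closed interval ``window_ms``.
    """
    post = ts.times >= 0
    if not post.any():
        raise ParameterError("no post-onset samples in the time series")
    t_post, a_post = ts.times[post], ts.accuracy_pct[post]
    peak = float(np.max(a_post))
    latency = float(t_post[np.argmax(a_post)])   # earliest maximum
    lo, hi = window_ms
    in_win = (ts.times >= lo) & (ts.times <= hi)
    if not in_win.any():
        raise ParameterError(f"window {window_ms} contains no samples")
    return SummaryStats(
        peak_accuracy_pct=peak, peak_latency_ms=latency,
        window_mean_pct=float(ts.accuracy_pct[in_win].mean()),
        window_ms=(float(lo), float(hi)))


def equate_trial_counts(epochs_by_condition: dict[str, EpochsDataset],
                        rng: np.random.Generator
                        ) -> dict[str, EpochsDataset]:
    """Subsample every condition cell to the smallest cell count.

    Sampling is without replacement and preserves within-cell trial
    order; deterministic given the generator state.
    """
    sizes = {k: ds.n_trials for k, ds in epochs_by_condition.items()}
    if any(n < 1 for n in sizes.values()):
        raise InsufficientDataError(f"empty condition cell: {sizes}")
    m = min(sizes.values())
    out = {}
    for key, ds in epochs_by_condition.items():
        keep = np.sort(rng.choice(ds.n_trials, size=m, replace=False))
        mask = np.zeros(ds.n_trials, dtype=bool)
        mask[keep] = True
        out[key] = ds.select_trials(mask, note="equate_trial_counts")
    return out
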