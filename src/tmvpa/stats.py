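"""Inferential machinery for decoding results.

Per-time-point t-tests against chance, paired and Welch t-tests,
Benjamini–Hochberg and Holm–Bonferroni multiplicity corrections, the
subject-level group-label permutation test, and BCa bootstrap
confidence intervals.

Conventions fixed here: the vs-chance test is two-sided by default
(a one-sided "greater" alternative is available); Monte-Carlo p-values
use add-one smoothing (1+b)/(1+N) so the smallest attainable p is
1/(1+N); permutations reshuffle whole subjects so the within-subject
time course stays intact under the null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, PairingError, ParameterError

_ZERO_SD = 1e-12


@dataclass
class PValueSeries:
    """Raw per-time-point p-values from a one-sample test vs chance."""

    t: np.ndarray
    p: np.ndarray
    degenerate: np.ndarray          # zero-variance time points
    test: str
    times: np.ndarray | None = None


@dataclass
class CorrectionResult:
    """Multiple-comparison correction output."""

    method: str                     # "fdr_bh" or "holm"
    alpha: float
    significant: np.ndarray
    p_adjusted: np.ndarray


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


@dataclass
class GroupPermutationResult:
    """Welch-t group comparison with a permutation null per time point."""

    t_observed: np.ndarray
    p_empirical: np.ndarray
    n_permutations: int
    fdr: CorrectionResult
    holm: CorrectionResult
    times: np.ndarray | None = None


@dataclass
class BcaInterval:
    """Bias-corrected and accelerated bootstrap interval."""

    statistic: str
    estimate: float
    low: float
    high: float
    level: float
    n_boot: int
    degenerate: bool = False


def ttest_vs_chance(accuracies: np.ndarray, chance: float = 50.0,
                    alternative: str = "two-sided",
                    times: np.ndarray | None = None) -> PValueSeries:
    """One-sample t-test of each time point's accuracies against chance.

    ``accuracies`` is subjects x time.  Zero-variance time points are
    flagged: p = 1 if the common value equals chance, else p = 0.
    """
    acc = np.atleast_2d(np.asarray(accuracies, dtype=float))
    if acc.shape[0] < 3:
        raise InsufficientDataError("need >= 3 subjects for the t-test")
    sd = acc.std(axis=0, ddof=1)
    degenerate = sd < _ZERO_SD
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.ttest_1samp(acc, chance, axis=0, alternative=alternative)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    if degenerate.any():
        equal = np.isclose(acc.mean(axis=0), chance)
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
        t[degenerate] = np.where(equal[degenerate], 0.0, np.inf)
    return PValueSeries(t=t, p=p, degenerate=degenerate,
                        test=f"one-sample t vs {chance} ({alternative})",
                        times=times)


def paired_ttest(a: np.ndarray, b: np.ndarray,
                 level: float = 0.95) -> TTestResult:
    """Paired t-test with a CI for the mean difference (two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise PairingError(f"samples not paired: {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise InsufficientDataError("paired t-test needs >= 3 pairs")
    d = a - b
    n = len(d)
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd < _ZERO_SD:
        return TTestResult(t=0.0 if mean == 0 else np.inf, df=n - 1,
                           p=1.0 if mean == 0 else 0.0,
                           ci_low=mean, ci_high=mean, degenerate=True)
    res = sps.ttest_rel(a, b)
    half = sps.t.ppf(0.5 + level / 2, n - 1) * sd / np.sqrt(n)
    return TTestResult(t=float(res.statistic), df=float(n - 1),
                       p=float(res.pvalue),
                       ci_low=float(mean - half), ci_high=float(mean + half))


def welch_ttest(a: np.ndarray, b: np.ndarray) -> TTestResult:
    """Welch's unequal-variance t-test with Welch–Satterthwaite df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each sample needs >= 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    degenerate = va < _ZERO_SD and vb < _ZERO_SD
    if degenerate:
        same = np.isclose(a.mean(), b.mean())
        return TTestResult(t=0.0 if same else np.inf, df=float("nan"),
                           p=1.0 if same else 0.0, ci_low=np.nan,
                           ci_high=np.nan, degenerate=True)
    res = sps.ttest_ind(a, b, equal_var=False)
    return TTestResult(t=float(res.statistic), df=float(res.df),
                       p=float(res.pvalue), ci_low=np.nan, ci_high=np.nan)


def fdr_bh(p_values: np.ndarray, alpha: float = 0.05) -> CorrectionResult:
    """Benjamini–Hochberg step-up FDR correction."""
    p = _check_p(p_values)
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return CorrectionResult("fdr_bh", alpha, reject, p_adj)


def holm_bonferroni(p_values: np.ndarray,
                    alpha: float = 0.05) -> CorrectionResult:
    """Holm–Bonferroni step-down FWER correction."""
    p = _check_p(p_values)
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return CorrectionResult("holm", alpha, reject, p_adj)


def _check_p(p_values: np.ndarray) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ParameterError("p-values must lie in [0, 1]")
    return p


def _welch_t_matrix(x: np.ndarray, na: int) -> np.ndarray:
    """Welch t per column for rows [0:na] vs rows [na:]."""
    a, b = x[:na], x[na:]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    se = np.sqrt(va / len(a) + vb / len(b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / se
    return np.where(se > 0, t, 0.0)


def group_permutation_test(a: np.ndarray, b: np.ndarray,
                           n_permutations: int = 10_000,
                           rng: np.random.Generator | None = None,
                           alpha: float = 0.05) -> GroupPermutationResult:
    """Subject-level group-label permutation test on accuracy matrices.

    ``a`` and ``b`` are subjects x time for the two groups.  The
    observed statistic is Welch's t (a vs b) at each time point; the
    null distribution reshuffles subjects between groups, applying the
    same shuffle at every time point, and the one-sided empirical
    p-value is ``(1 + #{t* >= t_obs}) / (1 + n_permutations)``.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise InsufficientDataError("each group needs >= 3 subjects")
    if a.shape[1] != b.shape[1]:
        raise ParameterError("groups must share the time axis")
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations gives coarse p-values",
                      stacklevel=2)
    rng = rng or np.random.default_rng()
    pooled = np.vstack([a, b])
    na, n = a.shape[0], pooled.shape[0]
    t_obs = _welch_t_matrix(pooled, na)
    exceed = np.zeros(a.shape[1])
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        t_null = _welch_t_matrix(pooled[perm], na)
        exceed += t_null >= t_obs
    p_emp = (1.0 + exceed) / (1.0 + n_permutations)
    return GroupPermutationResult(
        t_observed=t_obs, p_empirical=p_emp, n_permutations=n_permutations,
        fdr=fdr_bh(p_emp, alpha), holm=holm_bonferroni(p_emp, alpha))


def bca_ci(sample: np.ndarray, statistic=np.mean, n_boot: int = 10_000,
           level: float = 0.95, rng: np.random.Generator | None = None,
           name: str | None = None) -> BcaInterval:
    """BCa bootstrap confidence interval for a statistic of one sample.

    Percentile endpoints are adjusted for median bias (fraction of the
    bootstrap distribution below the plug-in estimate) and for skewness
    via the jackknife acceleration constant.  A degenerate (constant)
    sample yields the collapsed interval [c, c] with a flag.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 3:
        raise InsufficientDataError("BCa interval needs >= 3 observations")
    rng = rng or np.random.default_rng()
    est = float(statistic(x))
    if np.ptp(x) < _ZERO_SD:
        return BcaInterval(statistic=_stat_name(statistic, name), estimate=est,
                           low=est, high=est, level=level, n_boot=n_boot,
                           degenerate=True)

    def stat_axis(data, axis=-1):
        return np.apply_along_axis(statistic, axis, data) \
            if not _accepts_axis(statistic) else statistic(data, axis=axis)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.bootstrap((x,), stat_axis, n_resamples=n_boot,
                            confidence_level=level, method="BCa",
                            vectorized=True, rng=rng)
    low, high = res.confidence_interval
    if not (np.isfinite(low) and np.isfinite(high)):
        # Degenerate bootstrap distribution (e.g. statistic constant
        # across resamples): collapse to the point estimate.
        return BcaInterval(statistic=_stat_name(statistic, name), estimate=est,
                           low=est, high=est, level=level, n_boot=n_boot,
                           degenerate=True)
    return BcaInterval(statistic=_stat_name(statistic, name), estimate=est,
                       low=float(low), high=float(high), level=level,
                       n_boot=n_boot)


def _accepts_axis(statistic) -> bool:
    import inspect
    try:
        sig = inspect.signature(statistic)
    except (TypeError, ValueError):
        return statistic in (np.mean, np.median, np.std, np.var)
    return "axis" in sig.parameters


def _stat_name(statistic, name: str | None) -> str:
    return name or getattr(statistic, "__name__", "statistic")
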