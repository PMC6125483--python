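"""End-to-end study orchestration.

``run_study`` replays the full analysis on a (simulated or loaded)
two-group study: preprocessing, three decoding analyses per subject
(left-vs-right target location within exemplar-search trials, the same
within category-search trials, and exemplar-vs-category search pooled
over locations), per-subject summary statistics with group-level BCa
intervals, paired exemplar-vs-category comparisons, the group-label
permutation test on the type-decoding time courses, and window-averaged
activation patterns with channel-wise group tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .dataset import EpochsDataset
from .decoding import (AccuracyTimeSeries, DecodingConfig, SummaryStats,
                       decode_timeseries, equate_trial_counts,
                       summarize_accuracy)
from .errors import DesignError
from .patterns import (ActivationPattern, GroupPatternTest,
                       group_pattern_test, patterns_from_timeseries,
                       window_average_pattern)
from .preprocessing import RejectionCriteria, preprocess
from .simulate import SimulationConfig, simulate_study
from .stats import (BcaInterval, GroupPermutationResult, bca_ci, fdr_bh,
                    group_permutation_test, holm_bonferroni, paired_ttest,
                    ttest_vs_chance)

CONDITIONS = ("exemplar_location", "category_location", "type")


@dataclass(frozen=True)
class DesignCounts:
    """Trial bookkeeping of the block design."""

    total_trials: int
    trials_per_task: dict[str, int]
    targets_per_side_per_task: dict[str, int]


def design_counts(blocks_per_type: int, exemplar_trials_per_block: int,
                  category_trials_per_block: int,
                  targets_per_block: int) -> DesignCounts:
    """Totals implied by the blocked visual-search design.

    Each task runs ``blocks_per_type`` blocks; every block contains
    ``targets_per_block`` target-present trials split equally between
    left and right.
    """
    counts = (blocks_per_type, exemplar_trials_per_block,
              category_trials_per_block, targets_per_block)
    if any(c < 0 for c in counts):
        raise DesignError("design counts must be >= 0")
    if targets_per_block % 2 != 0:
        raise DesignError("targets per block must split evenly left/right")
    per_side = blocks_per_type * targets_per_block // 2
    return DesignCounts(
        total_trials=blocks_per_type * (exemplar_trials_per_block
                                        + category_trials_per_block),
        trials_per_task={
            "exemplar": blocks_per_type * exemplar_trials_per_block,
            "category": blocks_per_type * category_trials_per_block,
        },
        targets_per_side_per_task={"exemplar": per_side, "category": per_side},
    )


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to reproduce one full study run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    decoding: DecodingConfig = field(default_factory=DecodingConfig)
    rejection: RejectionCriteria = field(default_factory=RejectionCriteria)
    location_window_ms: tuple[float, float] = (200.0, 350.0)
    type_window_ms: tuple[float, float] = (100.0, 250.0)
    alpha: float = 0.05
    n_group_permutations: int = 10_000
    n_bootstrap: int = 10_000
    equate_trials: bool = False
    seed: int = 0

    def window_for(self, condition: str) -> tuple[float, float]:
        return (self.type_window_ms if condition == "type"
                else self.location_window_ms)


@dataclass
class SubjectResult:
    subject: str
    group: str
    timeseries: dict[str, AccuracyTimeSeries]
    summaries: dict[str, SummaryStats]
    patterns: dict[str, ActivationPattern]
    n_valid_trials: int


@dataclass
class ResultsBundle:
    """Every table and test of one study run."""

    config: StudyConfig
    subjects: list[SubjectResult]
    accuracies: pd.DataFrame            # long: subject, group, condition, time_ms, accuracy_pct
    summary_table: pd.DataFrame         # per subject x condition summaries
    group_table: pd.DataFrame           # group-level means with BCa CIs
    paired_tests: pd.DataFrame          # exemplar vs category within group
    chance_tests: pd.DataFrame          # per group x condition x time
    type_group_test: GroupPermutationResult | None
    pattern_tests: dict[tuple[str, str], GroupPatternTest]
    provenance: dict[str, Any]


def _concat_trials(datasets: list[EpochsDataset]) -> EpochsDataset:
    base = datasets[0]
    return replace(
        base,
        data=np.concatenate([d.data for d in datasets], axis=0),
        events=pd.concat([d.events for d in datasets], ignore_index=True),
        provenance=list(base.provenance) + [{"op": "concat_cells"}],
    )


def _equate_cells(epochs: EpochsDataset,
                  rng: np.random.Generator) -> EpochsDataset:
    cells = {}
    for task in ("exemplar", "category"):
        for side in ("left", "right"):
            mask = ((epochs.events["task"] == task)
                    & (epochs.events["target_side"] == side)).to_numpy()
            cells[f"{task}_{side}"] = epochs.select_trials(mask)
    return _concat_trials(list(equate_trial_counts(cells, rng).values()))


def analyze_subject(epochs: EpochsDataset, config: StudyConfig,
                    rng: np.random.Generator) -> SubjectResult:
    """Preprocess and run all three decoding analyses for one subject."""
    pp, _ = preprocess(epochs, config.rejection,
                       baseline_window_ms=config.simulation.baseline_window_ms)
    if config.equate_trials:
        pp = _equate_cells(pp, rng)
    subsets = {
        "exemplar_location": pp.select_trials(
            (pp.events["task"] == "exemplar").to_numpy()),
        "category_location": pp.select_trials(
            (pp.events["task"] == "category").to_numpy()),
        "type": pp,
    }
    timeseries, summaries, patterns = {}, {}, {}
    for condition, subset in subsets.items():
        labeling = "type" if condition == "type" else "location"
        ts = decode_timeseries(subset, labeling, config.decoding, rng,
                               condition=condition)
        timeseries[condition] = ts
        window = config.window_for(condition)
        summaries[condition] = summarize_accuracy(ts, window)
        per_tp = patterns_from_timeseries(ts, subset)
        patterns[condition] = window_average_pattern(
            per_tp, ts.times, window, subset.montage.scalp_channels,
            subject=epochs.subject, condition=condition)
    return SubjectResult(subject=epochs.subject, group=epochs.group,
                         timeseries=timeseries, summaries=summaries,
                         patterns=patterns, n_valid_trials=pp.n_trials)


def _accuracy_matrix(subjects: list[SubjectResult], group: str,
                     condition: str) -> np.ndarray:
    return np.vstack([s.timeseries[condition].accuracy_pct
                      for s in subjects if s.group == group])


def _ci_cols(ci: BcaInterval, prefix: str) -> dict[str, float]:
    return {f"{prefix}": ci.estimate, f"{prefix}_ci_low": ci.low,
            f"{prefix}_ci_high": ci.high}


def run_study(config: StudyConfig,
              datasets: list[EpochsDataset] | None = None) -> ResultsBundle:
    """Execute the full pipeline; simulate the study unless given data."""
    if datasets is None:
        datasets = simulate_study(config.simulation)
    groups = sorted({d.group for d in datasets})
    root_ss = np.random.SeedSequence(config.seed)
    subj_ss, boot_ss, perm_ss = root_ss.spawn(3)
    subj_streams = subj_ss.spawn(len(datasets))

    subjects = [analyze_subject(d, config, np.random.default_rng(ss))
                for d, ss in zip(datasets, subj_streams)]

    acc_rows = []
    for s in subjects:
        for cond, ts in s.timeseries.items():
            for t, a in zip(ts.times, ts.accuracy_pct):
                acc_rows.append((s.subject, s.group, cond, t, a))
    accuracies = pd.DataFrame(
        acc_rows, columns=["subject", "group", "condition", "time_ms",
                           "accuracy_pct"])

    summary_table = pd.DataFrame([
        {"subject": s.subject, "group": s.group, "condition": cond,
         "peak_accuracy_pct": st.peak_accuracy_pct,
         "peak_latency_ms": st.peak_latency_ms,
         "window_mean_pct": st.window_mean_pct,
         "window_lo_ms": st.window_ms[0], "window_hi_ms": st.window_ms[1]}
        for s in subjects for cond, st in s.summaries.items()])

    boot_rng = np.random.default_rng(boot_ss)
    group_rows = []
    for group in groups:
        for cond in CONDITIONS:
            sub = summary_table.query("group == @group and condition == @cond")
            if sub.empty:
                continue
            row = {"group": group, "condition": cond, "n_subjects": len(sub)}
            for col, label in (("peak_accuracy_pct", "peak_accuracy_pct"),
                               ("peak_latency_ms", "peak_latency_ms"),
                               ("window_mean_pct", "window_mean_pct")):
                ci = bca_ci(sub[col].to_numpy(), np.mean,
                            n_boot=config.n_bootstrap, rng=boot_rng)
                row.update(_ci_cols(ci, label))
            group_rows.append(row)
    group_table = pd.DataFrame(group_rows)

    paired_rows = []
    for group in groups:
        piv = summary_table.query("group == @group").pivot(
            index="subject", columns="condition",
            values=["peak_accuracy_pct", "window_mean_pct"])
        for metric in ("peak_accuracy_pct", "window_mean_pct"):
            a = piv[(metric, "exemplar_location")].to_numpy()
            b = piv[(metric, "category_location")].to_numpy()
            res = paired_ttest(a, b)
            diff_ci = bca_ci(a - b, np.mean, n_boot=config.n_bootstrap,
                             rng=boot_rng)
            paired_rows.append({
                "group": group, "metric": metric,
                "mean_difference": float(np.mean(a - b)),
                "t": res.t, "df": res.df, "p": res.p,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
                "bca_low": diff_ci.low, "bca_high": diff_ci.high})
    paired_tests = pd.DataFrame(paired_rows)

    chance_rows = []
    for group in groups:
        for cond in CONDITIONS:
            acc = _accuracy_matrix(subjects, group, cond)
            if acc.shape[0] < 3:
                continue
            times = subjects[0].timeseries[cond].times
            pv = ttest_vs_chance(acc, chance=config.decoding.chance_pct,
                                 times=times)
            bh = fdr_bh(pv.p, config.alpha)
            holm = holm_bonferroni(pv.p, config.alpha)
            for i, t in enumerate(times):
                chance_rows.append({
                    "group": group, "condition": cond, "time_ms": t,
                    "t": pv.t[i], "p_raw": pv.p[i],
                    "p_adj_bh": bh.p_adjusted[i],
                    "p_adj_holm": holm.p_adjusted[i],
                    "sig_bh": bool(bh.significant[i]),
                    "sig_holm": bool(holm.significant[i])})
    chance_tests = pd.DataFrame(chance_rows)

    type_group_test = None
    if len(groups) == 2:
        a = _accuracy_matrix(subjects, groups[0], "type")
        b = _accuracy_matrix(subjects, groups[1], "type")
        if a.shape[0] >= 3 and b.shape[0] >= 3:
            type_group_test = group_permutation_test(
                a, b, n_permutations=config.n_group_permutations,
                rng=np.random.default_rng(perm_ss), alpha=config.alpha)
            type_group_test.times = subjects[0].timeseries["type"].times

    pattern_tests = {}
    for group in groups:
        for cond in CONDITIONS:
            pats = [s.patterns[cond] for s in subjects if s.group == group]
            if len(pats) >= 3:
                pattern_tests[(group, cond)] = group_pattern_test(
                    pats, alpha=config.alpha)

    provenance = {
        "n_subjects": {g: sum(s.group == g for s in subjects) for g in groups},
        "decoding": {"n_folds": config.decoding.n_folds,
                     "n_permutations": config.decoding.n_permutations,
                     "svm_c": config.decoding.svm_c,
                     "time_decim": config.decoding.time_decim},
        "windows_ms": {"location": list(config.location_window_ms),
                       "type": list(config.type_window_ms)},
        "equate_trials": config.equate_trials,
        "seed": config.seed,
        "simulation_seed": config.simulation.seed,
    }
    return ResultsBundle(config=config, subjects=subjects,
                         accuracies=accuracies, summary_table=summary_table,
                         group_table=group_table, paired_tests=paired_tests,
                         chance_tests=chance_tests,
                         type_group_test=type_group_test,
                         pattern_tests=pattern_tests, provenance=provenance)


def write_bundle(bundle: ResultsBundle, out_dir: str | Path) -> Path:
    """Write every bundle table as TSV plus a YAML manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.accuracies.to_csv(out / "accuracies.tsv", sep="\t", index=False)
    bundle.summary_table.to_csv(out / "subject_summaries.tsv", sep="\t",
                                index=False)
    bundle.group_table.to_csv(out / "group_summaries.tsv", sep="\t",
                              index=False)
    bundle.paired_tests.to_csv(out / "paired_tests.tsv", sep="\t", index=False)
    bundle.chance_tests.to_csv(out / "chance_tests.tsv", sep="\t", index=False)
    if bundle.type_group_test is not None:
        g = bundle.type_group_test
        pd.DataFrame({
            "time_ms": g.times, "t_observed": g.t_observed,
            "p_empirical": g.p_empirical,
            "p_adj_bh": g.fdr.p_adjusted, "sig_bh": g.fdr.significant,
            "p_adj_holm": g.holm.p_adjusted, "sig_holm": g.holm.significant,
        }).to_csv(out / "type_group_permutation.tsv", sep="\t", index=False)
    pat_rows = []
    for s in bundle.subjects:
        for cond, pat in s.patterns.items():
            for ch, v in zip(pat.channels, pat.values):
                pat_rows.append((s.subject, s.group, cond, ch, v))
    pd.DataFrame(pat_rows, columns=["subject", "group", "condition",
                                    "channel", "pattern"]).to_csv(
        out / "activation_patterns.tsv", sep="\t", index=False)
    test_rows = []
    for (group, cond), gt in bundle.pattern_tests.items():
        for i, ch in enumerate(gt.channels):
            test_rows.append((group, cond, ch, gt.t[i], gt.p_raw[i],
                              gt.p_adj[i], bool(gt.significant[i])))
    pd.DataFrame(test_rows, columns=["group", "condition", "channel", "t",
                                     "p_raw", "p_adj_bh", "sig_bh"]).to_csv(
        out / "pattern_tests.tsv", sep="\t", index=False)
    (out / "manifest.yaml").write_text(
        yaml.safe_dump(bundle.provenance, sort_keys=False))
    return out
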