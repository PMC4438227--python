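"""Visual water-maze behavior: performance, confidence intervals, comparisons.

Each rat learns one shape pair in a two-alternative forced-choice water maze
(10-12 trials per session).  Behavioral performance (BEH) for a pair is the
proportion of correct trials pooled over the last four sessions, with an
exact (Clopper-Pearson) binomial 95% confidence interval.  Pairs are
compared with a permutation test that reshuffles the pooled correct /
incorrect outcomes between the two logs; batch-to-batch consistency of the
six-pair performance profile is a Pearson correlation with a derangement
permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .correspondence import CorrespondenceResult, MatchInput, permutation_pvalue

#: Columns of a trial log.
LOG_COLUMNS = ["rat_id", "batch", "pair", "session", "platform_side",
               "chosen_side", "correct"]


@dataclass
class BehavioralPerformance:
    proportion: float
    n_trials: int
    ci_low: float
    ci_high: float
    window_sessions: int

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.proportion <= self.ci_high <= 1):
            raise ValueError("confidence interval must bracket the proportion")


@dataclass
class DifferenceTestResult:
    observed_diff: float
    null_low: float
    null_high: float
    significant: bool
    n_iter: int


def _validate_log(log: pd.DataFrame) -> pd.DataFrame:
    missing = set(LOG_COLUMNS) - set(log.columns)
    if missing:
        raise ValueError(f"trial log is missing columns {sorted(missing)}")
    agree = log["chosen_side"] == log["platform_side"]
    if not (log["correct"].astype(bool) == agree).all():
        raise ValueError("correct flag inconsistent with chosen vs platform side")
    return log


def performance_last_sessions(log: pd.DataFrame, k: int = 4,
                              alpha: float = 0.05) -> BehavioralPerformance:
    """Proportion correct over the last ``k`` sessions with an exact binomial CI."""
    log = _validate_log(log)
    sessions = np.sort(log["session"].unique())
    if len(sessions) < k:
        raise ValueError(f"log has {len(sessions)} sessions, need at least {k}")
    window = log[log["session"].isin(sessions[-k:])]
    n = len(window)
    n_correct = int(window["correct"].astype(bool).sum())
    low, high = proportion_confint(n_correct, n, alpha=alpha, method="beta")
    return BehavioralPerformance(n_correct / n, n, float(low), float(high), k)


def performance_difference_test(log_a: pd.DataFrame, log_b: pd.DataFrame,
                                n_iter: int = 10000,
                                seed: int | np.random.Generator | None = None,
                                last_k: int | None = 4) -> DifferenceTestResult:
    """Permutation test for a difference in proportion correct.

    Correct/incorrect outcomes of both logs are pooled and reassigned to the
    two groups (preserving group sizes) ``n_iter`` times; the observed
    difference is declared significant when it falls outside the central 95%
    percentile interval of the permuted differences.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be at least 100")
    rng = np.random.default_rng(seed)

    def _outcomes(log: pd.DataFrame) -> np.ndarray:
        log = _validate_log(log)
        if last_k is not None:
            sessions = np.sort(log["session"].unique())
            log = log[log["session"].isin(sessions[-last_k:])]
        return log["correct"].astype(bool).to_numpy()

    a, b = _outcomes(log_a), _outcomes(log_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both logs must contain trials")
    observed = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    diffs = np.empty(n_iter)
    for i in range(n_iter):
        perm = rng.permutation(pooled)
        diffs[i] = perm[:a.size].mean() - perm[a.size:].mean()
    low, high = np.percentile(diffs, [2.5, 97.5])
    significant = observed < low or observed > high
    return DifferenceTestResult(float(observed), float(low), float(high),
                                bool(significant), n_iter)


def batch_consistency(perf_batch1, perf_batch2) -> CorrespondenceResult:
    """Pearson correlation of per-pair performances across the two batches,
    with a derangement permutation p-value."""
    return permutation_pvalue(MatchInput(np.asarray(perf_batch1, float),
                                         np.asarray(perf_batch2, float)),
                              statistic="pearson")


def read_trial_log(path) -> pd.DataFrame:
    log = pd.read_csv(path)
    return _validate_log(log)


def write_trial_log(log: pd.DataFrame, path) -> None:
    _validate_log(log).to_csv(path, index=False)
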