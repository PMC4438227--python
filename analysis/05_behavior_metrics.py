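#!/usr/bin/env python
"""Behavioral performance over the last four sessions, with exact CIs,
pair-difference permutation tests and batch-to-batch consistency.

Writes results/analysis/behavior_performance.csv.
"""

import itertools
import json
from pathlib import Path

import pandas as pd

from shape2behav.behavior import (batch_consistency,
                                  performance_difference_test,
                                  performance_last_sessions)

OUT = Path("results/analysis")


def main() -> None:
    log = pd.read_csv(OUT / "behavior_log.csv")
    meta = json.loads((OUT / "study_meta.json").read_text())
    rows = []
    per_batch = {1: [], 2: []}
    print("proportion correct over the last 4 sessions (95% Clopper-Pearson):")
    for pair_label in log["pair"].unique():
        for batch in (1, 2):
            sub = log[(log["pair"] == pair_label) & (log["batch"] == batch)]
            perf = performance_last_sessions(sub, k=4)
            rows.append({"pair": pair_label, "batch": batch,
                         "proportion": perf.proportion, "n": perf.n_trials,
                         "ci_low": perf.ci_low, "ci_high": perf.ci_high})
            per_batch[batch].append(perf.proportion)
            print(f"  batch {batch} {pair_label:28s} "
                  f"{perf.proportion:.3f} [{perf.ci_low:.3f}, {perf.ci_high:.3f}]")
    pd.DataFrame(rows).to_csv(OUT / "behavior_performance.csv", index=False)

    res = batch_consistency(per_batch[1], per_batch[2])
    print(f"batch 1 vs batch 2 per-pair consistency: r = {res.value:.3f}, "
          f"permutation p = {res.p_perm:.4f} ({res.n_null} derangements)")

    print("pairwise difference tests (10000 shuffles of correct/incorrect):")
    n_sig = 0
    pairs = list(log["pair"].unique())
    for a, b in itertools.combinations(pairs, 2):
        la = log[log["pair"] == a]
        lb = log[log["pair"] == b]
        t = performance_difference_test(la, lb, n_iter=10000, seed=7)
        n_sig += t.significant
        if t.significant:
            print(f"  {a} vs {b}: diff {t.observed_diff:+.3f} significant")
    print(f"{n_sig} of {len(pairs) * (len(pairs) - 1) // 2} "
          f"pair-difference tests significant")


if __name__ == "__main__":
    main()
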