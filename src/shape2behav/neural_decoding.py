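"""Population decoding of shape identity from spike counts.

Spike counts are converted to net firing rates (stimulus-window rate minus
the rate in the 2 s baseline preceding each presentation).  Units are kept
when their best-shape mean net response exceeds 2 Hz and every shape was
presented at least 12 times.  Discriminability of a shape pair is read out
with a linear support-vector machine (penalty C = 0.5) on pseudo-population
vectors: units were recorded at different times, so trials are paired across
units by independent within-condition permutation.  Accuracies are averaged
over resampling iterations that redraw the cell subset (without
replacement, equating cell counts across areas) and the trial pairing; a
chance threshold is the 95th percentile of the same analysis run with
shuffled condition labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVC

DEFAULT_STIM_DURATION = 4.0  # s
DEFAULT_BASELINE_DURATION = 2.0  # s
MIN_NET_HZ = 2.0
MIN_TRIALS = 12


@dataclass
class SpikeCountTable:
    """unit x shape x trial spike counts with matched baseline counts.

    Arrays are NaN-padded along the trial axis so that units may have
    different trial counts per shape.
    """

    unit_ids: list[str]
    area: str
    shapes: list[str]
    counts: np.ndarray  # (U, S, T), NaN-padded
    baseline_counts: np.ndarray  # (U, S, T), matched to counts
    stim_duration: float = DEFAULT_STIM_DURATION
    baseline_duration: float = DEFAULT_BASELINE_DURATION

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.baseline_counts = np.asarray(self.baseline_counts, dtype=float)
        if self.counts.shape != self.baseline_counts.shape:
            raise ValueError("baseline_counts must match counts shape")
        if self.counts.shape[:2] != (len(self.unit_ids), len(self.shapes)):
            raise ValueError("counts must be (units, shapes, trials)")
        if (np.isnan(self.counts) != np.isnan(self.baseline_counts)).any():
            raise ValueError("baseline trials must match stimulus trials")
        if (np.nan_to_num(self.counts) < 0).any() or (np.nan_to_num(self.baseline_counts) < 0).any():
            raise ValueError("spike counts must be non-negative")
        if self.stim_duration <= 0 or self.baseline_duration <= 0:
            raise ValueError("window durations must be positive")
        if np.isnan(self.counts).all(axis=2).any():
            raise ValueError("every unit needs at least one trial per shape")

    @property
    def n_trials(self) -> np.ndarray:
        """Valid trial count per (unit, shape)."""
        return (~np.isnan(self.counts)).sum(axis=2)


@dataclass
class PopulationResponse:
    """Net firing rates (Hz) per unit, shape and trial, plus inclusion masks."""

    unit_ids: list[str]
    area: str
    shapes: list[str]
    net_rates: np.ndarray  # (U, S, T), NaN-padded
    responsive_mask: np.ndarray  # (U,) best-shape mean net rate > threshold
    min_trials_ok: np.ndarray  # (U,) every shape has >= min_trials trials
    n_trials: np.ndarray  # (U, S)


@dataclass
class DecodingConfig:
    penalty: float = 0.5
    n_resample: int = 100
    n_cells: int | None = None  # None -> all included units
    train_fraction: float = 10.0 / 12.0
    n_shuffle_outer: int = 100
    min_net_hz: float = MIN_NET_HZ
    min_trials: int = MIN_TRIALS
    share_cells_across_pairs: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class DecodingResult:
    area: str
    pairs: list[tuple[int, int]]
    pair_labels: list[tuple[str, str]]
    mean_accuracy: np.ndarray  # per pair, over resampling iterations
    sem_accuracy: np.ndarray
    n_cells: int
    n_resample: int
    chance_threshold: float | None = None
    accuracies: np.ndarray | None = field(default=None, repr=False)  # (n_resample, n_pairs)

    @property
    def overall_mean(self) -> float:
        return float(self.mean_accuracy.mean())


def net_responses(table: SpikeCountTable,
                  min_net_hz: float = MIN_NET_HZ,
                  min_trials: int = MIN_TRIALS) -> PopulationResponse:
    """Net rate per trial: count/stim_duration - baseline_count/baseline_duration."""
    net = (table.counts / table.stim_duration
           - table.baseline_counts / table.baseline_duration)
    with np.errstate(invalid="ignore"):
        best = np.nanmean(net, axis=2).max(axis=1)  # best-shape mean net rate
    responsive = best > min_net_hz
    n_trials = table.n_trials
    trials_ok = (n_trials >= min_trials).all(axis=1)
    return PopulationResponse(list(table.unit_ids), table.area, list(table.shapes),
                              net, responsive, trials_ok, n_trials)


def select_units(resp: PopulationResponse,
                 min_net_hz: float = MIN_NET_HZ,
                 min_trials: int = MIN_TRIALS) -> np.ndarray:
    """Indices of units that are responsive and have enough trials per shape."""
    with np.errstate(invalid="ignore"):
        best = np.nanmean(resp.net_rates, axis=2).max(axis=1)
    keep = (best > min_net_hz) & (resp.n_trials >= min_trials).all(axis=1)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        import warnings
        warnings.warn(f"no unit in area {resp.area} passed selection")
    return idx


def _pseudo_population(resp: PopulationResponse, units: np.ndarray,
                       shape_idx: int, n_t: int,
                       rng: np.random.Generator) -> np.ndarray:
    """(n_t, n_units) matrix with an independent trial permutation per unit."""
    cols = np.empty((n_t, units.size))
    for k, u in enumerate(units):
        valid = np.flatnonzero(~np.isnan(resp.net_rates[u, shape_idx]))
        take = rng.permutation(valid)[:n_t]
        cols[:, k] = resp.net_rates[u, shape_idx, take]
    return cols


def pairwise_svm_accuracy(resp: PopulationResponse,
                          pair: tuple[int, int],
                          cfg: DecodingConfig,
                          rng: np.random.Generator,
                          unit_idx: np.ndarray | None = None,
                          shuffle_labels: bool = False) -> float:
    """Cross-validated linear-SVM accuracy for one shape pair.

    Trials are subsampled (without replacement) to the minimum per-condition
    trial count over the included units, split into train/test per condition
    by ``train_fraction``, and classified with a linear SVM at the
    configured penalty.
    """
    units = np.asarray(unit_idx) if unit_idx is not None else select_units(
        resp, cfg.min_net_hz, cfg.min_trials)
    if units.size == 0:
        raise ValueError("no units available for decoding")
    s1, s2 = pair
    n_t = int(resp.n_trials[units][:, [s1, s2]].min())
    if n_t < cfg.min_trials:
        raise ValueError(f"pair {pair} has only {n_t} trials; need {cfg.min_trials}")
    n_train = int(round(cfg.train_fraction * n_t))
    n_train = min(max(n_train, 1), n_t - 2)
    if n_t - n_train < 2:
        raise ValueError("fewer than 2 test trials per condition")

    xa = _pseudo_population(resp, units, s1, n_t, rng)
    xb = _pseudo_population(resp, units, s2, n_t, rng)
    x = np.vstack([xa, xb])
    y = np.repeat([0, 1], n_t)
    if shuffle_labels:
        y = rng.permutation(y)

    # stratified random train/test split
    train_mask = np.zeros(2 * n_t, dtype=bool)
    for label in (0, 1):
        members = np.flatnonzero(y == label)
        train_mask[rng.permutation(members)[:n_train]] = True

    x_tr, y_tr = x[train_mask], y[train_mask]
    x_te, y_te = x[~train_mask], y[~train_mask]
    if len(np.unique(y_tr)) < 2 or np.allclose(x_tr, x_tr[0]):
        # degenerate training set: predict the first class
        return float((y_te == y_tr[0]).mean())
    clf = SVC(kernel="linear", C=cfg.penalty)
    clf.fit(x_tr, y_tr)
    return float((clf.predict(x_te) == y_te).mean())


def resampled_decoding(resp: PopulationResponse,
                       cfg: DecodingConfig,
                       pairs: list[tuple[int, int]] | None = None,
                       rng: np.random.Generator | None = None,
                       shuffle_labels: bool = False) -> DecodingResult:
    """Mean per-pair SVM accuracy over resampled cell and trial subsets.

    Every iteration draws a fresh cell subset (without replacement; shared
    across pairs by default) and a fresh trial pairing/subset, then decodes
    every pair.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if pairs is None:
        n = len(resp.shapes)
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    pool = select_units(resp, cfg.min_net_hz, cfg.min_trials)
    n_cells = cfg.n_cells if cfg.n_cells is not None else pool.size
    if n_cells > pool.size:
        raise ValueError(f"n_cells={n_cells} exceeds the {pool.size} available units")

    acc = np.empty((cfg.n_resample, len(pairs)))
    for it in range(cfg.n_resample):
        cells = rng.choice(pool, size=n_cells, replace=False)
        for k, pair in enumerate(pairs):
            if not cfg.share_cells_across_pairs:
                cells = rng.choice(pool, size=n_cells, replace=False)
            acc[it, k] = pairwise_svm_accuracy(resp, pair, cfg, rng,
                                               unit_idx=cells,
                                               shuffle_labels=shuffle_labels)
    labels = [(resp.shapes[i], resp.shapes[j]) for i, j in pairs]
    return DecodingResult(resp.area, list(pairs), labels,
                          acc.mean(axis=0), acc.std(axis=0, ddof=1) / np.sqrt(cfg.n_resample),
                          n_cells, cfg.n_resample, accuracies=acc)


def shuffled_label_threshold(resp: PopulationResponse,
                             cfg: DecodingConfig,
                             pairs: list[tuple[int, int]] | None = None,
                             rng: np.random.Generator | None = None) -> float:
    """95th percentile of mean accuracies from shuffled-condition-label runs.

    Repeats the full resampled decoding ``n_shuffle_outer`` times with shape
    labels permuted before classification.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    means = np.empty(cfg.n_shuffle_outer)
    for rep in range(cfg.n_shuffle_outer):
        res = resampled_decoding(resp, cfg, pairs=pairs, rng=rng, shuffle_labels=True)
        means[rep] = res.overall_mean
    return float(np.percentile(means, 95))


# ---------------------------------------------------------------------------
# Long-format TSV I/O

def write_spike_table(table: SpikeCountTable, path: str | Path) -> None:
    """Write a long-format TSV plus a JSON sidecar with window durations."""
    path = Path(path)
    rows = []
    for u, unit in enumerate(table.unit_ids):
        for s, shape in enumerate(table.shapes):
            valid = np.flatnonzero(~np.isnan(table.counts[u, s]))
            for t in valid:
                rows.append((unit, table.area, shape, int(t),
                             int(table.counts[u, s, t]),
                             int(table.baseline_counts[u, s, t])))
    pd.DataFrame(rows, columns=["unit_id", "area", "shape", "trial",
                                "stim_count", "baseline_count"]).to_csv(
        path, sep="\t", index=False)
    sidecar = {"stim_duration": table.stim_duration,
               "baseline_duration": table.baseline_duration,
               "shapes": table.shapes}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_spike_table(path: str | Path) -> SpikeCountTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    shapes = sidecar.get("shapes") or sorted(df["shape"].unique())
    units = list(dict.fromkeys(df["unit_id"]))
    area = df["area"].iloc[0]
    max_t = int(df.groupby(["unit_id", "shape"]).size().max())
    counts = np.full((len(units), len(shapes), max_t), np.nan)
    base = np.full_like(counts, np.nan)
    u_idx = {u: i for i, u in enumerate(units)}
    s_idx = {s: i for i, s in enumerate(shapes)}
    for (unit, shape), grp in df.groupby(["unit_id", "shape"]):
        u, s = u_idx[unit], s_idx[shape]
        k = len(grp)
        counts[u, s, :k] = grp["stim_count"].to_numpy()
        base[u, s, :k] = grp["baseline_count"].to_numpy()
    return SpikeCountTable(units, area, list(shapes), counts, base,
                           sidecar["stim_duration"], sidecar["baseline_duration"])
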