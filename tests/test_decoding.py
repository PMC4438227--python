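"""Net responses, unit selection and the resampled SVM readout."""

import copy

import numpy as np
import pytest

from shape2behav.neural_decoding import (DecodingConfig, PopulationResponse,
                                         SpikeCountTable, net_responses,
                                         pairwise_svm_accuracy,
                                         read_spike_table, resampled_decoding,
                                         select_units, write_spike_table)

SHAPES = ["square", "diamond_in_square", "triangle", "lambda", "letter_H", "plus"]


def _table_from_rates(rates_hz, baseline_hz, n_trials, rng, poisson=True):
    """rates_hz: (U, S) mean net-above-baseline rates."""
    rates = np.asarray(rates_hz, float)
    u, s = rates.shape
    lam_stim = (rates + baseline_hz)[:, :, None] * 4.0 * np.ones((u, s, n_trials))
    lam_base = baseline_hz * 2.0 * np.ones((u, s, n_trials))
    if poisson:
        counts = rng.poisson(lam_stim).astype(float)
        base = rng.poisson(lam_base).astype(float)
    else:
        counts, base = lam_stim.copy(), lam_base.copy()
    return SpikeCountTable([f"u{i}" for i in range(u)], "V1", SHAPES[:s],
                           counts, base)


def test_net_responses_matches_per_trial_oracle(rng):
    counts = rng.integers(0, 40, (3, 2, 5)).astype(float)
    base = rng.integers(0, 10, (3, 2, 5)).astype(float)
    counts[0, 0, 4] = np.nan  # ragged trials
    base[0, 0, 4] = np.nan
    table = SpikeCountTable(["a", "b", "c"], "LM", SHAPES[:2], counts, base)
    resp = net_responses(table)
    for u in range(3):
        for s in range(2):
            for t in range(5):
                if np.isnan(counts[u, s, t]):
                    assert np.isnan(resp.net_rates[u, s, t])
                else:
                    expected = counts[u, s, t] / 4.0 - base[u, s, t] / 2.0
                    assert resp.net_rates[u, s, t] == pytest.approx(expected)
    # 12 stim spikes in 4 s minus 2 baseline spikes in 2 s = 2 Hz
    one = SpikeCountTable(["a"], "V1", SHAPES[:1],
                          np.full((1, 1, 12), 12.0), np.full((1, 1, 12), 2.0))
    assert net_responses(one).net_rates[0, 0, 0] == pytest.approx(2.0)
    zero = SpikeCountTable(["a"], "V1", SHAPES[:1],
                           np.zeros((1, 1, 12)), np.zeros((1, 1, 12)))
    assert net_responses(zero).net_rates[0, 0, 0] == 0.0


def test_select_units_threshold_and_trial_count(rng):
    # noiseless rates: unit 0 peaks at 1.9 Hz (out), unit 1 at 2.1 Hz (in),
    # unit 2 at 30 Hz but one shape has only 11 trials (out)
    rates = np.array([[1.9, 0.5], [2.1, 0.0], [30.0, 10.0]])
    table = _table_from_rates(rates, baseline_hz=2.0, n_trials=12, rng=rng,
                              poisson=False)
    table.counts[2, 1, 11] = np.nan
    table.baseline_counts[2, 1, 11] = np.nan
    resp = net_responses(table)
    assert select_units(resp).tolist() == [1]


def test_select_units_planted_subthreshold_population(rng):
    u = 30
    planted = rng.random(u) < 0.4
    best = np.where(planted, rng.uniform(0.1, 1.8, u), rng.uniform(2.3, 12.0, u))
    rates = np.zeros((u, 3))
    rates[np.arange(u), rng.integers(0, 3, u)] = best
    table = _table_from_rates(rates, baseline_hz=1.0, n_trials=12, rng=rng,
                              poisson=False)
    resp = net_responses(table)
    assert set(select_units(resp)) == set(np.flatnonzero(~planted))


def test_separable_conditions_decode_perfectly(rng):
    rates = np.column_stack([np.full(5, 2.0), np.full(5, 40.0)])
    table = _table_from_rates(rates, baseline_hz=1.0, n_trials=12, rng=rng,
                              poisson=False)
    resp = net_responses(table)
    cfg = DecodingConfig(n_resample=5)
    acc = pairwise_svm_accuracy(resp, (0, 1), cfg, rng,
                                unit_idx=np.arange(5))
    assert acc == 1.0


def test_identical_conditions_decode_at_chance(rng):
    rates = np.full((4, 2), 10.0)
    table = _table_from_rates(rates, baseline_hz=2.0, n_trials=60, rng=rng)
    resp = net_responses(table)
    cfg = DecodingConfig(n_resample=200)
    res = resampled_decoding(resp, cfg, pairs=[(0, 1)], rng=rng)
    n_test = 2 * round(60 * (1 - cfg.train_fraction))
    sd = 0.5 / np.sqrt(n_test * cfg.n_resample)
    assert abs(res.mean_accuracy[0] - 0.5) < 4 * sd + 0.02


def test_large_separation_beats_monte_carlo_oracle(rng):
    # 1-D population: two Gaussian-ish conditions 10 SDs apart
    rates = np.array([[5.0, 35.0]])  # Poisson SD at these rates ~ 3 Hz
    table = _table_from_rates(rates, baseline_hz=1.0, n_trials=100, rng=rng)
    resp = net_responses(table)
    cfg = DecodingConfig(n_resample=20)
    res = resampled_decoding(resp, cfg, pairs=[(0, 1)], rng=rng)
    assert res.mean_accuracy[0] > 0.95


def test_resampled_decoding_is_seed_reproducible(rng):
    rates = rng.uniform(2.0, 20.0, (10, 3))
    table = _table_from_rates(rates, baseline_hz=2.0, n_trials=14, rng=rng)
    resp = net_responses(table)
    cfg = DecodingConfig(n_resample=8, n_cells=6, seed=77)
    a = resampled_decoding(resp, cfg)
    b = resampled_decoding(resp, cfg)
    assert np.array_equal(a.accuracies, b.accuracies)
    assert a.n_cells == 6


def test_accuracy_invariant_to_common_rate_offset(rng):
    rates = rng.uniform(2.0, 15.0, (8, 2))
    table = _table_from_rates(rates, baseline_hz=2.0, n_trials=12, rng=rng)
    resp = net_responses(table)
    shifted = copy.deepcopy(resp)
    shifted.net_rates = shifted.net_rates + 7.5  # constant added to every unit
    cfg = DecodingConfig(n_resample=10)
    a = resampled_decoding(resp, cfg, rng=np.random.default_rng(3), pairs=[(0, 1)])
    b = resampled_decoding(shifted, cfg, rng=np.random.default_rng(3), pairs=[(0, 1)])
    assert a.mean_accuracy[0] == pytest.approx(b.mean_accuracy[0])


def test_accuracy_increases_with_separation_and_cells(rng):
    def mean_acc(delta, n_cells):
        rates = np.column_stack([np.full(30, 8.0), np.full(30, 8.0 + delta)])
        table = _table_from_rates(rates, baseline_hz=2.0, n_trials=12,
                                  rng=np.random.default_rng(11))
        resp = net_responses(table)
        cfg = DecodingConfig(n_resample=30, n_cells=n_cells)
        return resampled_decoding(resp, cfg, pairs=[(0, 1)],
                                  rng=np.random.default_rng(5)).mean_accuracy[0]

    weak, strong = mean_acc(1.0, 20), mean_acc(6.0, 20)
    assert strong >= weak + 0.05
    few, many = mean_acc(2.0, 4), mean_acc(2.0, 25)
    assert many >= few


def test_n_cells_exceeding_pool_raises(rng):
    rates = rng.uniform(3.0, 10.0, (5, 2))
    table = _table_from_rates(rates, baseline_hz=2.0, n_trials=12, rng=rng)
    resp = net_responses(table)
    with pytest.raises(ValueError, match="n_cells"):
        resampled_decoding(resp, DecodingConfig(n_resample=2, n_cells=50))


def test_spike_table_tsv_roundtrip(tmp_path, rng):
    rates = rng.uniform(2.0, 10.0, (4, 3))
    table = _table_from_rates(rates, baseline_hz=2.0, n_trials=13, rng=rng)
    table.counts[0, 0, 12] = np.nan
    table.baseline_counts[0, 0, 12] = np.nan
    path = tmp_path / "spikes.tsv"
    write_spike_table(table, path)
    back = read_spike_table(path)
    assert back.unit_ids == table.unit_ids
    assert back.shapes == table.shapes
    assert np.array_equal(np.isnan(back.counts), np.isnan(table.counts))
    assert np.allclose(np.nan_to_num(back.counts), np.nan_to_num(table.counts))
    assert back.stim_duration == table.stim_duration
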