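"""Pixel and filter-bank dissimilarity against brute-force oracles."""

import numpy as np
import pytest

from shape2behav.physical_similarity import (DissimilarityVector,
                                             _PairCorrelation,
                                             build_filter_bank,
                                             filter_responses,
                                             pixel_dissimilarity,
                                             preprocess_image, rescale_unit,
                                             v1sim_dissimilarity)
from shape2behav.stimuli import PX_PER_DEG, ShapeImage, StimulusSet, ShapeSpec, pair_index


def _random_set(rng, shape=(16, 20), px_per_deg=2.0):
    imgs = []
    for gid in ("square", "diamond_in_square", "triangle", "lambda",
                "letter_H", "plus"):
        r = (rng.random(shape) < 0.4).astype(np.uint8)
        r[0, 0] = 1  # guarantee foreground
        imgs.append(ShapeImage(gid, r, px_per_deg))
    specs = [ShapeSpec(im.glyph_id, 5.0) for im in imgs]
    return StimulusSet(imgs, specs)


def test_pixel_dissimilarity_equals_pixel_scan_oracle(rng):
    stim = _random_set(rng)
    vec = pixel_dissimilarity(stim)
    for (i, j), value in zip(stim.pair_index, vec.values):
        a, b = stim.shapes[i].raster, stim.shapes[j].raster
        count = sum(int(a[r, c] != b[r, c])
                    for r in range(a.shape[0]) for c in range(a.shape[1]))
        assert value == count


def test_pixel_dissimilarity_is_a_metric(rng):
    stim = _random_set(rng)
    vec = pixel_dissimilarity(stim)
    d = np.zeros((6, 6))
    for (i, j), v in zip(stim.pair_index, vec.values):
        d[i, j] = d[j, i] = v
    # symmetry is structural; triangle inequality over all triples
    for i in range(6):
        for j in range(6):
            for k in range(6):
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


def test_pixel_dissimilarity_known_difference():
    base = np.zeros((10, 10), dtype=np.uint8)
    base[0, 0] = 1
    other = base.copy()
    other.flat[5:12] ^= 1  # flip exactly 7 pixels
    imgs = [ShapeImage(g, base if n else other, 1.0) for n, g in
            enumerate(["square", "diamond_in_square", "triangle", "lambda",
                       "letter_H", "plus"])]
    stim = StimulusSet(imgs, [ShapeSpec(i.glyph_id, 5.0) for i in imgs])
    vec = pixel_dissimilarity(stim)
    assert vec.values[0] == 7  # pair (0, 1)
    assert vec.values[-1] == 0  # pair (4, 5): identical images


def test_rescale_unit_formula_and_monotonicity():
    vec = DissimilarityVector([2.0, 4.0, 8.0], "raw", "other",
                              [(0, 1), (0, 2), (1, 2)])
    out = rescale_unit(vec)
    assert out.values == pytest.approx([0.625, 0.75, 1.0])
    assert out.scale == "unit_interval"
    vec0 = DissimilarityVector([0.0, 3.0, 6.0], "raw", "other",
                               [(0, 1), (0, 2), (1, 2)])
    out0 = rescale_unit(vec0)
    assert out0.values[0] == pytest.approx(0.5)
    assert np.all(np.argsort(out0.values) == np.argsort(vec0.values))
    with pytest.raises(ValueError):
        rescale_unit(DissimilarityVector([0.0, 0.0], "raw", "other",
                                         [(0, 1), (0, 2)]))


def test_preprocess_normalizes_and_respects_fwhm():
    raster = np.zeros((101, 101), dtype=np.uint8)
    raster[50, 50] = 1
    impulse = ShapeImage("plus", raster, 1.0)
    out = preprocess_image(impulse, fwhm=20.0)
    assert abs(out.mean()) < 1e-9
    assert abs(out.std() - 1.0) < 1e-9
    # a blurred impulse falls to half its peak at radius = FWHM/2 = 10 px
    peak = out[50, 50] - out[0, 0]
    at_10 = out[50, 60] - out[0, 0]
    assert at_10 / peak == pytest.approx(0.5, abs=0.02)
    with pytest.raises(ValueError):
        preprocess_image(ShapeImage("plus", np.ones((8, 8), np.uint8), 1.0), 2.0)


def test_filter_bank_count_support_and_normalization():
    bank = build_filter_bank()
    assert len(bank) == 80
    supports = {f.frequency_cpd: f.support for f in bank.filters}
    assert supports[0.60] == int(np.ceil(2 / (0.60 / PX_PER_DEG)))  # 42 px
    for f in bank.filters:
        assert abs(f.coefficients.mean()) < 1e-9
        assert abs(np.linalg.norm(f.coefficients) - 1.0) < 1e-9
    with pytest.raises(ValueError, match="support"):
        build_filter_bank(image_shape=(64, 64))


def _tiny_set(rng):
    imgs = []
    for gid in ("square", "diamond_in_square", "triangle", "lambda",
                "letter_H", "plus"):
        r = np.zeros((24, 24), dtype=np.uint8)
        rr, cc = rng.integers(4, 20, 2)
        r[rr - 3:rr + 3, cc - 3:cc + 3] = 1
        imgs.append(ShapeImage(gid, r, 3.0))
    return StimulusSet(imgs, [ShapeSpec(i.glyph_id, 2.0) for i in imgs])


def _naive_convolve_same(image, kernel):
    h, w = image.shape
    kh, kw = kernel.shape
    pad = np.zeros((h + kh - 1, w + kw - 1))
    pad[:h, :w] = image
    out = np.zeros((h, w))
    r_off, c_off = (kh - 1) // 2, (kw - 1) // 2
    for r in range(h):
        for c in range(w):
            acc = 0.0
            for i in range(kh):
                for j in range(kw):
                    rr, cc = r + r_off - i, c + c_off - j
                    if 0 <= rr < h and 0 <= cc < w:
                        acc += image[rr, cc] * kernel[i, j]
            out[r, c] = acc
    return out


def test_v1sim_matches_explicit_loop_oracle(rng):
    stim = _tiny_set(rng)
    bank = build_filter_bank(freqs_cpd=[0.6], n_orient=1, px_per_deg=3.0)
    result = v1sim_dissimilarity(stim, bank=bank, fwhm=4.0)
    pre = [preprocess_image(s, fwhm=4.0) for s in stim.shapes]
    kernel = bank.filters[0].coefficients
    resp = [_naive_convolve_same(p, kernel) for p in pre]
    d = []
    for i, j in stim.pair_index:
        x, y = resp[i].ravel(), resp[j].ravel()
        r = (((x - x.mean()) * (y - y.mean())).sum()
             / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        d.append(1.0 - r)
    d = np.asarray(d)
    expected = d / d.max() / 2.0 + 0.5
    assert result.values == pytest.approx(expected, abs=1e-10)


def test_streaming_correlation_equals_whole_stack(rng):
    stim = _tiny_set(rng)
    bank = build_filter_bank(freqs_cpd=[0.3, 0.6], n_orient=4, px_per_deg=3.0)
    streamed = v1sim_dissimilarity(stim, bank=bank, fwhm=4.0)
    stacks = [filter_responses(preprocess_image(s, fwhm=4.0), bank).ravel()
              for s in stim.shapes]
    d = np.array([1.0 - np.corrcoef(stacks[i], stacks[j])[0, 1]
                  for i, j in stim.pair_index])
    expected = d / d.max() / 2.0 + 0.5
    assert streamed.values == pytest.approx(expected, abs=1e-10)


def test_self_dissimilarity_is_zero_and_affine_invariance(rng):
    x = rng.random(500)
    acc = _PairCorrelation()
    acc.update(x, x)
    assert acc.corr() == pytest.approx(1.0)  # D = 1 - corr = 0
    y = rng.random(500)
    a1, a2 = _PairCorrelation(), _PairCorrelation()
    a1.update(x, y)
    a2.update(3.0 * x + 5.0, y)
    assert a1.corr() == pytest.approx(a2.corr(), abs=1e-12)


def test_v1sim_values_bounded_and_rescaled(rng):
    stim = _tiny_set(rng)
    bank = build_filter_bank(freqs_cpd=[0.6], n_orient=2, px_per_deg=3.0)
    out = v1sim_dissimilarity(stim, bank=bank, fwhm=4.0)
    assert out.values.max() == pytest.approx(1.0)
    assert (out.values >= 0.5).all()
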