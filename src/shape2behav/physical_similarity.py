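"""Pixel-based (PIX) and simulated-V1 (V1Sim) shape dissimilarity.

PIX counts the binary pixels that differ between two shapes (a Hamming
distance).  V1Sim passes each image through a bank of oriented band-pass
filters spanning the rat's usable spatial-frequency range and defines
dissimilarity as one minus the Pearson correlation between the two filter
response stacks.  Both 15-pair vectors are rescaled to (0.5, 1] by dividing
by the vector maximum, halving, and adding 0.5.

The filter bank combines five spatial frequencies (0.04, 0.08, 0.15, 0.30,
0.60 cycles/deg) with 16 orientations around the full circle (80 filters);
each filter's support spans two cycles, and filters are normalized to zero
mean and unit norm.  Images are first low-pass filtered (Gaussian,
FWHM = 20 px, roughly the rat's acuity limit) and z-scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft
from scipy.ndimage import gaussian_filter

from .stimuli import PX_PER_DEG, ShapeImage, StimulusSet

#: Spatial frequencies of the V1-model filter bank, cycles per degree.
DEFAULT_FREQS_CPD: tuple[float, ...] = (0.04, 0.08, 0.15, 0.30, 0.60)
DEFAULT_N_ORIENT: int = 16
DEFAULT_FWHM_PX: float = 20.0

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class DissimilarityVector:
    """Per-pair dissimilarities ordered by the canonical 15-pair index."""

    values: np.ndarray
    scale: str  # "raw" | "unit_interval"
    source: str  # "pix" | "v1sim" | "behavior" | "other"
    pair_index: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.pair_index):
            raise ValueError("values must align with pair_index")
        if self.scale == "unit_interval":
            if not (self.values >= 0.5 - 1e-12).all() or not (self.values <= 1 + 1e-12).all():
                raise ValueError("unit_interval values must lie in [0.5, 1]")


@dataclass
class GaborFilter:
    frequency_cpd: float
    orientation: float  # radians
    support: int  # px (square side)
    coefficients: np.ndarray


@dataclass
class FilterBank:
    filters: list[GaborFilter]
    px_per_deg: float

    def __len__(self) -> int:
        return len(self.filters)


def pixel_dissimilarity(stim: StimulusSet) -> DissimilarityVector:
    """Number of differing binary pixels for every shape pair.

    For binary images this equals the sum of squared pixel differences.
    """
    shapes = [s.raster for s in stim.shapes]
    if len({s.shape for s in shapes}) != 1:
        raise ValueError("all rasters must have identical dimensions")
    vals = [float(np.count_nonzero(shapes[i] != shapes[j]))
            for i, j in stim.pair_index]
    return DissimilarityVector(np.array(vals), "raw", "pix", list(stim.pair_index))


def rescale_unit(vec: DissimilarityVector) -> DissimilarityVector:
    """v -> v / max(v) / 2 + 0.5, mapping the vector into (0.5, 1] with max 1."""
    m = vec.values.max()
    if m <= 0:
        raise ValueError("cannot rescale an all-zero dissimilarity vector")
    return DissimilarityVector(vec.values / m / 2.0 + 0.5, "unit_interval",
                               vec.source, list(vec.pair_index))


def preprocess_image(image: ShapeImage, fwhm: float = DEFAULT_FWHM_PX) -> np.ndarray:
    """Gaussian low-pass (given FWHM) then whole-image z-normalization."""
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    sigma = fwhm * _FWHM_TO_SIGMA
    smooth = gaussian_filter(image.raster.astype(float), sigma=sigma)
    sd = smooth.std()
    if sd == 0:
        raise ValueError("image is constant after smoothing")
    return (smooth - smooth.mean()) / sd


def build_filter_bank(freqs_cpd=DEFAULT_FREQS_CPD,
                      n_orient: int = DEFAULT_N_ORIENT,
                      px_per_deg: float = PX_PER_DEG,
                      image_shape: tuple[int, int] | None = None) -> FilterBank:
    """One cosine-phase Gabor per (frequency, orientation).

    The support side covers two cycles of the carrier; the Gaussian envelope
    has sigma = support/4.  Every filter is made exactly zero-mean and
    unit-norm.
    """
    if n_orient < 1:
        raise ValueError("need at least one orientation")
    filters: list[GaborFilter] = []
    for f in freqs_cpd:
        if f <= 0:
            raise ValueError("frequencies must be positive")
        f_px = f / px_per_deg  # cycles per pixel
        support = int(np.ceil(2.0 / f_px))
        if image_shape is not None and support > min(image_shape):
            raise ValueError(
                f"filter support {support} px for {f} cpd exceeds the image "
                f"{image_shape}; downsample the image or drop the frequency"
            )
        half = (support - 1) / 2.0
        y, x = np.mgrid[0:support, 0:support] - half
        sigma = support / 4.0
        envelope = np.exp(-(x ** 2 + y ** 2) / (2.0 * sigma ** 2))
        for k in range(n_orient):
            theta = 2.0 * np.pi * k / n_orient
            carrier = np.cos(2.0 * np.pi * f_px * (x * np.cos(theta) + y * np.sin(theta)))
            g = envelope * carrier
            g = g - g.mean()
            g = g / np.linalg.norm(g)
            g = g - g.mean()  # second pass removes the rounding residue
            g = g / np.linalg.norm(g)
            filters.append(GaborFilter(f, theta, support, g))
    return FilterBank(filters, px_per_deg)


class _PairCorrelation:
    """Streaming Pearson correlation over concatenated response planes.

    Accumulates sums of x, y, x^2, y^2 and xy plane-by-plane so that only one
    pair of response planes is ever held in memory.
    """

    def __init__(self) -> None:
        self.n = 0.0
        self.sx = self.sy = self.sxx = self.syy = self.sxy = 0.0

    def update(self, x: np.ndarray, y: np.ndarray) -> None:
        self.n += x.size
        self.sx += float(x.sum())
        self.sy += float(y.sum())
        self.sxx += float((x * x).sum())
        self.syy += float((y * y).sum())
        self.sxy += float((x * y).sum())

    def corr(self) -> float:
        vx = self.n * self.sxx - self.sx ** 2
        vy = self.n * self.syy - self.sy ** 2
        if vx <= 0 or vy <= 0:
            raise ValueError("zero-variance response stack")
        return (self.n * self.sxy - self.sx * self.sy) / np.sqrt(vx * vy)


def _convolve_same(image_fft: np.ndarray, kernel: np.ndarray,
                   fshape: tuple[int, int], out_shape: tuple[int, int]) -> np.ndarray:
    """FFT convolution ('same', zero padding) reusing a cached image FFT."""
    kf = scipy.fft.rfft2(kernel, fshape)
    full = scipy.fft.irfft2(image_fft * kf, fshape)
    r0 = (kernel.shape[0] - 1) // 2
    c0 = (kernel.shape[1] - 1) // 2
    return full[r0:r0 + out_shape[0], c0:c0 + out_shape[1]]


def filter_responses(image: np.ndarray, bank: FilterBank) -> np.ndarray:
    """Full response stack (n_filters, H, W) for one preprocessed image.

    Convenience for small inputs and cross-checks; the pairwise path below
    streams plane-by-plane instead of materializing stacks.
    """
    planes = []
    for filt in bank.filters:
        s = filt.support
        fshape = (scipy.fft.next_fast_len(image.shape[0] + s - 1),
                  scipy.fft.next_fast_len(image.shape[1] + s - 1))
        img_fft = scipy.fft.rfft2(image, fshape)
        planes.append(_convolve_same(img_fft, filt.coefficients, fshape, image.shape))
    return np.stack(planes)


def v1sim_dissimilarity(stim: StimulusSet,
                        bank: FilterBank | None = None,
                        fwhm: float = DEFAULT_FWHM_PX,
                        stride: int = 1) -> DissimilarityVector:
    """V1-model dissimilarity D = 1 - corr(response stacks) for all pairs.

    Image FFTs are cached per filter size, and pair correlations are
    accumulated filter-by-filter, so peak memory stays at a handful of
    response planes.  ``stride`` subsamples response planes before the
    correlation (1 = use every pixel, as in the headline analysis).
    """
    if bank is None:
        bank = build_filter_bank(px_per_deg=stim.px_per_deg,
                                 image_shape=stim.shapes[0].raster.shape)
    images = [preprocess_image(s, fwhm=fwhm) for s in stim.shapes]
    out_shape = images[0].shape
    accums = {pair: _PairCorrelation() for pair in stim.pair_index}

    by_support: dict[int, list[GaborFilter]] = {}
    for filt in bank.filters:
        by_support.setdefault(filt.support, []).append(filt)

    for support, filts in by_support.items():
        fshape = (scipy.fft.next_fast_len(out_shape[0] + support - 1),
                  scipy.fft.next_fast_len(out_shape[1] + support - 1))
        img_ffts = [scipy.fft.rfft2(im, fshape) for im in images]
        for filt in filts:
            planes = [_convolve_same(ff, filt.coefficients, fshape, out_shape)
                      [::stride, ::stride] for ff in img_ffts]
            for (i, j), acc in accums.items():
                acc.update(planes[i], planes[j])

    d = np.array([1.0 - accums[pair].corr() for pair in stim.pair_index])
    raw = DissimilarityVector(d, "raw", "v1sim", list(stim.pair_index))
    return rescale_unit(raw)
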