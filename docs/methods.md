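# Methods

This package implements an analysis chain that asks where, along a cascade
of rat visual cortical areas (V1 → LM → LI → LL → TO), neural population
discriminability of shapes stops looking like raw image similarity and
starts looking like the animals' behavioral discrimination performance.
Because the original recordings and water-maze logs are not public, a
synthetic-data generator produces inputs with the same structure and known
ground truth, and the whole chain is exercised end to end on them.

## Stimulus model

Six black-and-white shapes (square, diamond in a square, triangle, the
letter lambda, the letter H, a plus sign) are rendered as outline strokes
on an all-black 768 × 1280 px canvas at 1280/102 ≈ 12.549 px/deg (a screen
subtending 102° × 68°). Only three properties of the set are treated as
constraints: the bounding-box widths span 23–33° with mean 27.3°, the
number of white pixels is the same for every shape, and the background is
black. Everything else about the glyph geometry (skeleton proportions,
stroke thickness) is a modeling choice.

Per-shape widths default to 23, 24, 26, 29.8, 33 and 28° (square, diamond,
triangle, lambda, H, plus), summing to a 27.3° mean, with the compact
glyphs taking the smaller boxes; the assignment is configurable since only
the mean and range are constrained.

Rendering is distance-field based: a pixel is white when it lies within
half a stroke width of the glyph skeleton, with the skeleton inset by half
the stroke so the white-pixel bounding box stays on target regardless of
stroke width. Luminance equalization lights exactly the median initial
white-pixel count of closest-to-skeleton pixels per glyph. This amounts to
a sub-pixel stroke edge: with axis-aligned strokes, pixel counts would
otherwise jump by whole rows (several percent at once) as the stroke
crosses integer widths, making a 1% tolerance unreachable by stroke
adjustment alone. Ties (whole rows at identical distance) are broken by a
deterministic sub-millipixel hash jitter, so rendering is reproducible
bit-for-bit. The default stroke width is 35 px (~10% of glyph width):
thick line drawings whose strokes overlap appreciably between shapes.
Thin strokes leave almost no overlap, which would collapse the variance of
the pixel dissimilarity vector; with 35 px strokes the pixel and
filter-bank measures agree at r ≈ 0.90 on the rendered set.

## Physical dissimilarity

**PIX** counts the binary pixels that differ between two shapes (for
binary images this equals the summed squared difference). **V1Sim**
approximates similarity as seen through a population of V1-like filters:
each image is low-pass filtered (Gaussian, FWHM = 20 px, roughly the
acuity limit of the rat at ~1.5 cpd), z-scored, and convolved with a bank
of cosine-phase Gabors — five spatial frequencies (0.04, 0.08, 0.15, 0.30,
0.60 cpd) × 16 orientations spanning the full circle, 80 filters total.
Each filter's square support covers two carrier cycles (e.g. 42 px at
0.60 cpd), the Gaussian envelope has σ = support/4, and coefficients are
normalized to zero mean and unit norm. Dissimilarity for a pair is
D = 1 − Pearson correlation between the two images' concatenated response
stacks (all pixels × all filters). Responses are linear; no rectification
or pooling is applied. Cosine-phase filters repeat with period π, so the
16 orientations contain 8 distinct pairs — the full-circle convention is
kept for fidelity to the published bank size.

Both 15-pair vectors are rescaled to (0.5, 1] by dividing by the vector
maximum, halving and adding 0.5, which places them on the same scale as
two-alternative accuracies.

Implementation: convolutions run in the frequency domain with image FFTs
cached per filter size, and pair correlations are accumulated
filter-by-filter from streaming sums (n, Σx, Σy, Σx², Σy², Σxy), so peak
memory holds a handful of response planes rather than the 80-plane stacks.
A `stride` parameter subsamples response planes for fast approximate runs;
all reported numbers use stride 1.

## Neural decoding

Spike counts over the 4 s stimulus window are converted to rates and the
rate in the 2 s pre-stimulus baseline is subtracted. Units are included
when their best-shape mean net response exceeds 2 Hz and every shape has
at least 12 trials. Pairwise discriminability is read out with a linear
SVM (penalty C = 0.5): because units are recorded at different times,
population response vectors are pseudo-populations assembled by an
independent random within-condition trial permutation per unit. Trials
are subsampled without replacement to the minimum per-condition count,
split 10 train / 2 test per condition at the 12-trial minimum
(train_fraction 10/12, configurable), and accuracy is the test proportion
correct. Per pair, accuracies are averaged over 100 resampling iterations,
each drawing a fresh cell subset (without replacement, default 63 cells to
equate areas) and trial pairing. The chance threshold is the 95th
percentile of the same analysis repeated 100 times with shuffled condition
labels. All randomness flows through explicitly passed NumPy generators,
so results are bit-reproducible for a given seed. Degenerate training sets
(identical vectors) fall back to predicting the first class.

Open choices resolved here: the cell subsample is shared across the six
pairs within one iteration (flag to vary); the trial subset size is the
global per-condition minimum.

## Correspondence statistics

Two descriptive measures compare a six-pair vector of observed decoding
accuracies O with an expected vector E (physical dissimilarity or
behavioral accuracy, both on the 0.5–1 scale):

* ChiSq = Σᵢ (Oᵢ − Eᵢ)²/Eᵢ — lower is a better match;
* the sample Pearson correlation — higher is a better match.

Significance uses a permutation null that destroys the pairing: O is
reshuffled over all 265 derangements of six elements (permutations with no
fixed point, enumerated exhaustively), and p is the proportion of null
statistics strictly more extreme than the observed one — smaller for
chi-square, larger for correlation. The directionality follows from the
statistics' meaning as match measures.

The transformation index contrasts the two ends of the cascade:

    H = [Z(TO, Beh) − Z(TO, Pix)] − [Z(V1, Beh) − Z(V1, Pix)]

with Z the Fisher-transformed (arctanh) Pearson correlation. Positive H
means discriminability is behavior-aligned in TO and pixel-aligned in V1.
A chi-square variant substitutes ChiSq for Z; there the diagnostic sign is
negative. The null distribution applies independent derangements to the
two neural vectors while the behavior and pixel references stay fixed;
since H separates into a TO term minus a V1 term, the joint null is the
outer difference of the two per-area term distributions (265² = 70 225
values). Significance is the 95th percentile (correlation mode, upper
tail) or 5th percentile (chi-square mode, lower tail).

### Known limitation: the derangement null is anti-conservative at n = 6

Excluding shuffles that leave any element in place removes exactly those
permutations whose statistics correlate most strongly with the observed
value. Under a true null (O independent of E) this inflates the rejection
rate at the nominal 0.05 level to roughly 0.10 for both statistics,
whereas the full 719-permutation null is calibrated almost exactly
(≈ 0.052 in 4000-draw simulations; see `tests/test_acceptance.py`). The
restriction is retained because it is the procedure this analysis is
defined by; users who need calibrated error rates at n = 6 should treat
derangement p-values near 0.05 with caution — the effect on p-values far
below 0.05 is minor.

## Behavior

Each rat learns one shape pair in a two-alternative forced-choice visual
water maze (10–12 trials per session; platform side follows the
pseudo-random LRLLRLRR scheme from a random start). Behavioral
performance (BEH) is the proportion of correct trials pooled over the last
four sessions, with an exact Clopper–Pearson 95% binomial interval
(normal approximations are poor at these n ≈ 40–48). Two pairs are
compared by pooling their correct/incorrect outcomes and reshuffling the
assignment 10 000 times, preserving group sizes; a difference is
significant when the observed value falls outside the central [2.5, 97.5]
percentile interval of the permuted differences. Batch-to-batch
consistency of the six-pair performance profile is a Pearson correlation
with the derangement permutation p-value above.

## Synthetic study generator

The generator's one scientific knob is each area's representational
geometry: an area with weight w represents the six shapes with pairwise
dissimilarities (1 − w)·d_pix + w·d_beh, where d_pix is the rescaled pixel
vector of the rendered stimuli and d_beh is the behavioral geometry.
Defaults place the five areas at w = 0, 0.25, 0.5, 0.75, 1 — a linear
pixel-to-behavior gradient from V1 to TO, the hypothesis the analysis is
built to detect. The laminar comparison (V1 upper vs lower) can be
emulated as two populations with different w.

The behavioral geometry assigns six asymptotic accuracies (0.78, 0.60,
0.95, 0.98, 0.52, 0.85) to the six tested pairs — three target shapes each
paired with a similar and a dissimilar distractor, with the letter H vs
plus pair barely above chance and triangle vs letter H near-perfect. The
assignment is chosen so the behavioral vector is nearly uncorrelated with
pixel dissimilarity on those pairs (r ≈ 0.15), the regime in which
physical and behavioral references can dissociate; the nine untested pairs
are filled by a linear pixel→accuracy map fitted on the six, clipped to
[0.5, 1] (the analysis itself only ever uses the six tested pairs).

Populations impose the target geometry by classical (Torgerson) MDS
embedding of the six shapes into k = 5 dimensions; each of 200 units per
area draws a random preferred direction on the unit sphere and fires at
baseline + gain·softplus(projection of the shape coordinate onto that
direction). Baselines are Normal(5, 2) Hz clipped positive; the softplus
keeps rates positive without hard-rectification artifacts; counts are
Poisson (stimulus window 4 s, baseline 2 s), so negative net rates occur,
as in real data. The gain defaults to 5 Hz, which puts 63-cell decoding
in the 70–95% range across pairs — informative but off the ceiling, the
regime where per-pair accuracy still tracks geometric separation. Only
the pairwise geometry matters to every downstream statistic, which is why
random-projection tuning suffices and no explicit tuning-curve model is
needed.

Behavior logs contain one rat per pair per batch, two batches with 17 and
16 sessions, each session 10 or 12 trials. Per-trial correctness is
Bernoulli at a logistic learning curve that reaches 95% of the pair's
asymptotic gain above chance by session 8 (so the last four sessions sit
essentially at asymptote); the ramp can be disabled.

What the generator does **not** emulate: correlated noise across units,
adaptation, response latencies, receptive-field scatter, stimulus motion
(motion exists only as trial structure), rat-to-rat variability within a
pair, and session-level nonstationarity beyond the learning ramp. Tests
passing on these data therefore show that the statistics recover imposed
representational geometry under Poisson noise — not that they are robust
to every property of real recordings.

## Pipeline and problem sizes

`pipeline.run_study` executes all stages from one YAML/JSON config with a
single master seed (per-stage seeds derived via `SeedSequence`), writes
every stage's outputs (PNGs, TSV/CSV, JSON report), and reports only
numbers produced by the same module calls exposed in the API. Defaults
follow the analysis conventions throughout: C = 0.5, 100 resamples, 100
label-shuffle repeats, 10 000 behavioral iterations, FWHM 20 px. When both
physical measures are computed the correspondence reference is their
element-wise average.

Test-suite problem sizes are chosen to keep the full run at desk scale: the
geometry-recovery check uses a 20-seed grid with 200 units/area and decodes
at 40 cells — the reduced-cell readout avoids the accuracy ceiling that
compresses correlations for the easiest pairs — and the shuffled-label
calibration check uses a 10 × 10 shuffle-by-resample grid. The analysis
drivers and acceptance script use the full-scale settings (stride 1,
63 cells, 100 resamples).

## Numerical notes

* Dissimilarity rescaling requires a positive maximum; all-zero vectors
  (identical shapes) raise.
* Pearson/Fisher machinery raises on constant vectors and at |r| = 1
  rather than returning infinities.
* Streaming correlation accumulates in float64; it matches whole-stack
  `corrcoef` to 1e-10 on test fixtures.
* Classical MDS rejects targets whose double-centered Gram matrix has more
  than half its eigenvalue mass negative; mixtures of the default
  geometries are comfortably embeddable at k = 5.
* Derangement enumeration is exhaustive and capped at n = 10.
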