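"""Matching statistics between six-pair performance vectors.

Two descriptive measures quantify how well a vector of observed neural
classifier accuracies O matches an expected vector E (physical dissimilarity
or behavioral accuracy, both on the 0.5-1 scale):

* ``ChiSq = sum_i (O_i - E_i)^2 / E_i`` — lower is a better match;
* the sample Pearson correlation — higher is a better match.

Significance comes from a permutation null that destroys the pairwise
matching: O is reshuffled over all derangements (permutations with no fixed
point; 265 of the 720 permutations of six elements), and the p-value is the
proportion of null statistics strictly more extreme than the observed one
(smaller for chi-square, larger for correlation).

The transformation index H contrasts how strongly two areas (canonically TO
and V1) align with behavior versus with pixel dissimilarity:

    H = [Z(TO, Beh) - Z(TO, Pix)] - [Z(V1, Beh) - Z(V1, Pix)]

with Z the Fisher-transformed Pearson correlation; a chi-square variant
replaces Z by ChiSq (there a *negative* H indicates the pixel-to-behavior
transformation, since low chi-square means good match).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

_DERANGEMENT_CAP = 10  # 10! permutations is the limit for exhaustive search


@dataclass
class MatchInput:
    """Aligned observed (O) and expected (E) vectors over shared pair labels."""

    observed: np.ndarray
    expected: np.ndarray
    pair_labels: list | None = None

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        self.expected = np.asarray(self.expected, dtype=float)
        if self.observed.shape != self.expected.shape or self.observed.ndim != 1:
            raise ValueError("observed and expected must be 1-D and aligned")


@dataclass
class CorrespondenceResult:
    statistic: str  # "chisq" | "pearson"
    value: float
    p_perm: float
    n_null: int


@dataclass
class TransformationIndexResult:
    mode: str  # "correlation" | "chisquare"
    H: float
    null_threshold: float  # 95th percentile (correlation) / 5th (chisquare)
    significant: bool
    null: np.ndarray | None = None


def chi_square_match(inp: MatchInput) -> float:
    """Sum of (O_i - E_i)^2 / E_i; lower means a better match."""
    if (inp.expected <= 0).any():
        raise ValueError("expected values must be positive")
    return float((((inp.observed - inp.expected) ** 2) / inp.expected).sum())


def pearson_match(inp: MatchInput) -> float:
    """Sample Pearson correlation between O and E."""
    o, e = inp.observed, inp.expected
    if o.std() == 0 or e.std() == 0:
        raise ValueError("constant vector has no defined correlation")
    return float(np.corrcoef(o, e)[0, 1])


def fisher_z(r: float) -> float:
    """Fisher transformation arctanh(r); undefined at |r| = 1."""
    if abs(r) >= 1:
        raise ValueError("Fisher Z is unbounded at |r| >= 1")
    return float(np.arctanh(r))


def derangements(n: int) -> np.ndarray:
    """All permutations of range(n) with no element in its original slot.

    Exhaustive enumeration; capped at n = 10 (already 3.6 million candidate
    permutations).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > _DERANGEMENT_CAP:
        raise ValueError(f"exhaustive enumeration capped at n <= {_DERANGEMENT_CAP}")
    idx = np.arange(n)
    out = [p for p in permutations(range(n)) if all(p[i] != i for i in idx)]
    return np.array(out, dtype=int).reshape(len(out), n)


def _null_stats(inp: MatchInput, statistic: str, perms: np.ndarray) -> np.ndarray:
    o, e = inp.observed, inp.expected
    shuffled = o[perms]  # (n_null, n)
    if statistic == "chisq":
        if (e <= 0).any():
            raise ValueError("expected values must be positive")
        return ((shuffled - e) ** 2 / e).sum(axis=1)
    if statistic == "pearson":
        oc = shuffled - shuffled.mean(axis=1, keepdims=True)
        ec = e - e.mean()
        denom = np.sqrt((oc ** 2).sum(axis=1) * (ec ** 2).sum())
        return (oc @ ec) / denom
    raise ValueError(f"unknown statistic {statistic!r}")


def permutation_pvalue(inp: MatchInput, statistic: str = "chisq") -> CorrespondenceResult:
    """Derangement-permutation p-value for a matching statistic.

    "More extreme" is directional: a *smaller* chi-square or a *larger*
    correlation than observed counts toward p.  The comparison is strict, as
    the null excludes the identity permutation by construction.
    """
    obs = chi_square_match(inp) if statistic == "chisq" else pearson_match(inp)
    perms = derangements(len(inp.observed))
    null = _null_stats(inp, statistic, perms)
    if statistic == "chisq":
        p = float((null < obs).sum()) / len(null)
    else:
        p = float((null > obs).sum()) / len(null)
    return CorrespondenceResult(statistic, obs, p, len(null))


def transformation_index(to_vec, v1_vec, beh_vec, pix_vec,
                         mode: str = "correlation",
                         keep_null: bool = False) -> TransformationIndexResult:
    """Transformation index H with its derangement permutation null.

    The null applies independent derangements to each neural vector (TO and
    V1) while behavior and pixel references stay fixed, recomputing all four
    terms.  Because H separates into a TO term minus a V1 term, the full
    joint null is the outer difference of the two per-area term
    distributions (265 x 265 = 70225 values for six pairs).
    """
    to_vec = np.asarray(to_vec, float)
    v1_vec = np.asarray(v1_vec, float)
    beh_vec = np.asarray(beh_vec, float)
    pix_vec = np.asarray(pix_vec, float)
    n = len(to_vec)
    if not (len(v1_vec) == len(beh_vec) == len(pix_vec) == n):
        raise ValueError("all four vectors must share the same pairs")

    if mode == "correlation":
        def term(neural: np.ndarray) -> float:
            return (fisher_z(pearson_match(MatchInput(neural, beh_vec)))
                    - fisher_z(pearson_match(MatchInput(neural, pix_vec))))
    elif mode == "chisquare":
        def term(neural: np.ndarray) -> float:
            return (chi_square_match(MatchInput(neural, beh_vec))
                    - chi_square_match(MatchInput(neural, pix_vec)))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    h = term(to_vec) - term(v1_vec)

    perms = derangements(n)
    to_terms = np.array([term(to_vec[p]) for p in perms])
    v1_terms = np.array([term(v1_vec[p]) for p in perms])
    null = (to_terms[:, None] - v1_terms[None, :]).ravel()

    if mode == "correlation":
        thresh = float(np.percentile(null, 95))
        significant = h > thresh
    else:
        thresh = float(np.percentile(null, 5))
        significant = h < thresh
    return TransformationIndexResult(mode, float(h), thresh, bool(significant),
                                     null if keep_null else None)
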