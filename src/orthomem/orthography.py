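"""Pairwise orthographic similarity between letter strings.

Seven representational schemes are provided, all scored on a common
0-1 scale by dividing a (possibly weighted) match count ``M`` by the
alignment length ``a`` -- the unit inventory (letters or bigrams) of
the longer of the two words:

``slot``
    Absolute letter position, anchored at the start of the word.
``both-slot``
    Weighted mixture of start-anchored and end-anchored slot codes.
``overlap``
    A "noisy" slot code: each studied letter's position is a Gaussian
    centred on its true slot, and a probe letter's match is the
    probability mass falling into its own position bin.
``both-overlap``
    Mixture of forward and end-anchored overlap codes.
``closed-bigram``
    Relative position: adjacent ordered letter pairs plus start/end
    edge-marker bigrams, matched at most once each.
``open-bigram``
    As closed bigrams, but pairs may span up to two intervening
    letters.
``levenshtein``
    Edit-distance similarity ``(a - D) / a``.

All schemes share the exterior-letter weights ``alpha`` (first letter)
and ``omega`` (final letter of the *studied* word), which scale matches
on those units and enter the denominator as ``a + (1 - alpha) +
(1 - omega)`` so that similarity stays in [0, 1] whenever the weights
do not exceed 1.
"""

from __future__ import annotations

import heapq
from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy.special import ndtr

__all__ = [
    "InvalidWordError",
    "ExteriorWeights",
    "OverlapParams",
    "EdgeMix",
    "PairSimilarity",
    "SCHEMES",
    "normalize_word",
    "slot_similarity",
    "end_based_slot_similarity",
    "both_edges_slot_similarity",
    "sigma_schedule",
    "overlap_similarity",
    "both_edges_overlap_similarity",
    "extract_closed_bigrams",
    "closed_bigram_similarity",
    "extract_open_bigrams",
    "open_bigram_similarity",
    "levenshtein_distance",
    "levenshtein_similarity",
    "e_modified_similarity",
    "nearest_neighbors",
    "similarity",
]

START_MARKER = "_"
END_MARKER = "_"


class InvalidWordError(ValueError):
    """Raised when a string cannot be normalized to a valid word."""


@dataclass(frozen=True)
class ExteriorWeights:
    """Weights of the first letter (``alpha``) and the final letter of
    the studied word (``omega``).  ``alpha = omega = 1`` weights every
    letter equally."""

    alpha: float = 1.0
    omega: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.omega < 0:
            raise ValueError("exterior weights must be nonnegative")


@dataclass(frozen=True)
class OverlapParams:
    """Positional-uncertainty schedule of the overlap model.

    The SD of the Gaussian for a letter in serial position ``l`` is
    ``sigma_l = d * (1 - exp(-(l - .5) / r))``: ``d`` is the asymptote
    and ``r`` the growth rate, so uncertainty grows with position and
    saturates at ``d``.
    """

    d: float
    r: float

    def __post_init__(self) -> None:
        if self.d <= 0 or self.r <= 0:
            raise ValueError("overlap parameters d and r must be positive")


@dataclass(frozen=True)
class EdgeMix:
    """Weight ``w`` of the start-anchored code in both-edges schemes;
    ``w = 1`` reduces them to the forward-only code."""

    w: float = 0.75

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("edge-mix weight w must lie in [0, 1]")


@dataclass(frozen=True)
class PairSimilarity:
    """Similarity between one probe/studied word pair.

    ``matches`` is the weighted match count M, ``alignment`` the unit
    count of the longer word, and ``value`` the normalized similarity
    ``M / (a + (1 - alpha) + (1 - omega))``.
    """

    value: float
    matches: float
    alignment: int


def normalize_word(text: str) -> str:
    """Lowercase ``text`` and strip every non-alphabetic character.

    Raises :class:`InvalidWordError` if nothing alphabetic remains.
    """
    word = "".join(ch for ch in str(text).lower() if ch.isalpha())
    if not word:
        raise InvalidWordError(f"not a valid word: {text!r}")
    return word


def _normalized_value(matches: float, alignment: int, ew: ExteriorWeights) -> float:
    return matches / (alignment + (1.0 - ew.alpha) + (1.0 - ew.omega))


def _pair(matches: float, alignment: int, ew: ExteriorWeights) -> PairSimilarity:
    return PairSimilarity(_normalized_value(matches, alignment, ew), matches, alignment)


# ---------------------------------------------------------------------------
# Absolute position codes
# ---------------------------------------------------------------------------


def _slot_matches(probe: str, studied: str, ew: ExteriorWeights) -> float:
    """Weighted count of letters occupying the same start-anchored
    position.  The first-position match carries ``alpha``; a match on
    the final letter of the studied word carries ``omega``."""
    w_j = len(studied)
    matches = 0.0
    for k in range(min(len(probe), w_j)):
        if probe[k] != studied[k]:
            continue
        if k == 0:
            matches += ew.alpha
        elif k == w_j - 1:
            matches += ew.omega
        else:
            matches += 1.0
    return matches


def slot_similarity(probe: str, studied: str, ew: ExteriorWeights = ExteriorWeights()) -> PairSimilarity:
    """Start-anchored slot-code similarity."""
    probe = normalize_word(probe)
    studied = normalize_word(studied)
    a = max(len(probe), len(studied))
    return _pair(_slot_matches(probe, studied, ew), a, ew)


def end_based_slot_similarity(
    probe: str, studied: str, ew: ExteriorWeights = ExteriorWeights()
) -> PairSimilarity:
    """Slot-code similarity with positions indexed from the end of the
    word (-1 = last letter).  ``alpha`` and ``omega`` still weight the
    start and end letters of the original strings, so the comparison is
    run on the reversed strings with the exterior roles swapped."""
    probe = normalize_word(probe)
    studied = normalize_word(studied)
    a = max(len(probe), len(studied))
    swapped = ExteriorWeights(alpha=ew.omega, omega=ew.alpha)
    matches = _slot_matches(probe[::-1], studied[::-1], swapped)
    return _pair(matches, a, ew)


def both_edges_slot_similarity(
    probe: str,
    studied: str,
    ew: ExteriorWeights = ExteriorWeights(),
    mix: EdgeMix = EdgeMix(),
) -> PairSimilarity:
    """Weighted combination ``w * s_start + (1 - w) * s_end``."""
    forward = slot_similarity(probe, studied, ew)
    backward = end_based_slot_similarity(probe, studied, ew)
    value = mix.w * forward.value + (1.0 - mix.w) * backward.value
    matches = mix.w * forward.matches + (1.0 - mix.w) * backward.matches
    return PairSimilarity(value, matches, forward.alignment)


def sigma_schedule(l: int, op: OverlapParams) -> float:
    """Positional-uncertainty SD for serial position ``l`` (1-based)."""
    if l < 1:
        raise ValueError("serial position l must be >= 1")
    return op.d * (1.0 - np.exp(-(l - 0.5) / op.r))


def _overlap_matches(probe: str, studied: str, ew: ExteriorWeights, op: OverlapParams) -> float:
    """Gaussian-uncertainty match count.

    For probe position k (1-based), mass from *every* studied position l
    holding the same letter is summed: Phi(k+.5; l, sigma_l) -
    Phi(k-.5; l, sigma_l).  Exterior weights scale probe position 1
    (alpha) and probe position W(studied) (omega).
    """
    w_j = len(studied)
    positions: dict[str, list[int]] = {}
    for l, ch in enumerate(studied, start=1):
        positions.setdefault(ch, []).append(l)
    matches = 0.0
    for k, ch in enumerate(probe, start=1):
        ls = positions.get(ch)
        if not ls:
            continue
        m_k = 0.0
        for l in ls:
            sig = sigma_schedule(l, op)
            if sig <= 0.0:
                m_k += 1.0 if k == l else 0.0
            else:
                m_k += ndtr((k + 0.5 - l) / sig) - ndtr((k - 0.5 - l) / sig)
        if k == 1:
            m_k *= ew.alpha
        elif k == w_j:
            m_k *= ew.omega
        matches += m_k
    return matches


def overlap_similarity(
    probe: str,
    studied: str,
    ew: ExteriorWeights = ExteriorWeights(),
    op: OverlapParams = OverlapParams(d=1.544, r=1.094),
) -> PairSimilarity:
    """Overlap-model similarity with uncertainty in the studied word.

    The default ``d``/``r`` schedule is the published best-fitting
    perceptual-identification estimate (d = 1.544, r = 1.094).
    """
    probe = normalize_word(probe)
    studied = normalize_word(studied)
    a = max(len(probe), len(studied))
    return _pair(_overlap_matches(probe, studied, ew, op), a, ew)


def both_edges_overlap_similarity(
    probe: str,
    studied: str,
    ew: ExteriorWeights = ExteriorWeights(),
    op: OverlapParams = OverlapParams(d=1.544, r=1.094),
    mix: EdgeMix = EdgeMix(),
) -> PairSimilarity:
    """Both-edges overlap model: forward pass plus an end-anchored pass
    computed on the reversed strings (sigma indexed by distance from the
    word end), mixed by ``w``."""
    probe = normalize_word(probe)
    studied = normalize_word(studied)
    a = max(len(probe), len(studied))
    forward = _overlap_matches(probe, studied, ew, op)
    swapped = ExteriorWeights(alpha=ew.omega, omega=ew.alpha)
    backward = _overlap_matches(probe[::-1], studied[::-1], swapped, op)
    value = mix.w * _normalized_value(forward, a, ew) + (1.0 - mix.w) * _normalized_value(
        backward, a, ew
    )
    return PairSimilarity(value, mix.w * forward + (1.0 - mix.w) * backward, a)


# ---------------------------------------------------------------------------
# Relative position codes (bigrams)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=65536)
def _closed_bigram_bag(word: str) -> Counter:
    bag = Counter(word[i : i + 2] for i in range(len(word) - 1))
    bag[START_MARKER + word[0]] += 1
    bag[word[-1] + END_MARKER] += 1
    return bag


def extract_closed_bigrams(word: str) -> Counter:
    """Multiset of adjacent ordered letter pairs plus the start marker
    ``_x`` and end marker ``x_`` bigrams; a length-W word yields W + 1
    bigrams."""
    return Counter(_closed_bigram_bag(normalize_word(word)))


@lru_cache(maxsize=65536)
def _open_bigram_bag(word: str) -> Counter:
    w = len(word)
    bag: Counter = Counter()
    for gap in (1, 2, 3):
        for i in range(w - gap):
            bag[word[i] + word[i + gap]] += 1
    bag[START_MARKER + word[0]] += 1
    bag[word[-1] + END_MARKER] += 1
    return bag


def extract_open_bigrams(word: str) -> Counter:
    """Multiset of ordered letter pairs at position distances 1-3 plus
    the two edge markers."""
    return Counter(_open_bigram_bag(normalize_word(word)))


def _bigram_similarity(probe: str, studied: str, ew: ExteriorWeights, open_bigrams: bool) -> PairSimilarity:
    probe = normalize_word(probe)
    studied = normalize_word(studied)
    extract = _open_bigram_bag if open_bigrams else _closed_bigram_bag
    bag_i = extract(probe)
    bag_j = extract(studied)
    # Once-only matching: for identical tokens the optimal assignment is
    # simply the min of the two multiplicities per token.
    start = START_MARKER + studied[0]
    end = studied[-1] + END_MARKER
    matches = 0.0
    for token, n in (bag_i & bag_j).items():
        if token == start and probe[0] == studied[0]:
            # edge markers occur once per word, n == 1
            matches += ew.alpha
        elif token == end and probe[-1] == studied[-1]:
            matches += ew.omega
        else:
            matches += float(n)
    a = max(sum(bag_i.values()), sum(bag_j.values()))
    return _pair(matches, a, ew)


def closed_bigram_similarity(
    probe: str, studied: str, ew: ExteriorWeights = ExteriorWeights()
) -> PairSimilarity:
    """Closed-bigram similarity with once-only matching; the alignment
    length is the bigram count of the longer bag."""
    return _bigram_similarity(probe, studied, ew, open_bigrams=False)


def open_bigram_similarity(
    probe: str, studied: str, ew: ExteriorWeights = ExteriorWeights()
) -> PairSimilarity:
    """Open-bigram similarity with once-only matching."""
    return _bigram_similarity(probe, studied, ew, open_bigrams=True)


# ---------------------------------------------------------------------------
# Levenshtein
# ---------------------------------------------------------------------------


def levenshtein_distance(a: str, b: str) -> int:
    """Minimum number of single-letter substitutions, insertions or
    deletions transforming ``a`` into ``b`` (dynamic programming)."""
    a = normalize_word(a)
    b = normalize_word(b)
    if len(a) < len(b):
        a, b = b, a
    previous = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        current = [i]
        for j, cb in enumerate(b, start=1):
            current.append(
                min(
                    previous[j] + 1,  # deletion
                    current[j - 1] + 1,  # insertion
                    previous[j - 1] + (ca != cb),  # substitution
                )
            )
        previous = current
    return previous[-1]


def levenshtein_similarity(a: str, b: str) -> PairSimilarity:
    """Edit-distance similarity ``(a_len - D) / a_len`` with ``a_len``
    the length of the longer word (floored at 0)."""
    a = normalize_word(a)
    b = normalize_word(b)
    align = max(len(a), len(b))
    d = levenshtein_distance(a, b)
    return PairSimilarity(max(align - d, 0) / align, float(align - d), align)


# ---------------------------------------------------------------------------
# Letter-"e" salience adjustment (shallow-processing encoding task)
# ---------------------------------------------------------------------------


def e_modified_similarity(
    base: PairSimilarity,
    probe: str,
    studied: str,
    epsilon: float,
    ew: ExteriorWeights = ExteriorWeights(),
) -> PairSimilarity:
    """Boost similarity when the letter "e" occurs in *both* words.

    Models an encoding task that asks only whether an "e" is present:
    the bonus ``E = epsilon`` is position-free and the denominator grows
    by ``epsilon`` so the value stays normalized:
    ``s* = (M + E) / (a + (1 - alpha) + (1 - omega) + epsilon)``.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    probe = normalize_word(probe)
    studied = normalize_word(studied)
    bonus = epsilon if ("e" in probe and "e" in studied) else 0.0
    denom = base.alignment + (1.0 - ew.alpha) + (1.0 - ew.omega) + epsilon
    return PairSimilarity((base.matches + bonus) / denom, base.matches + bonus, base.alignment)


# ---------------------------------------------------------------------------
# Dispatch and neighbor ranking
# ---------------------------------------------------------------------------

SCHEMES = (
    "slot",
    "both-slot",
    "overlap",
    "both-overlap",
    "closed-bigram",
    "open-bigram",
    "levenshtein",
)


def similarity(
    probe: str,
    studied: str,
    scheme: str,
    ew: ExteriorWeights = ExteriorWeights(),
    op: OverlapParams | None = None,
    mix: EdgeMix = EdgeMix(),
    epsilon: float = 0.0,
) -> PairSimilarity:
    """Dispatch to one of the seven schemes by name.

    ``epsilon > 0`` applies the letter-"e" adjustment on top of any base
    scheme (ignored for the Levenshtein scheme, whose normalization has
    no match/denominator decomposition of the same form).
    """
    if scheme == "slot":
        out = slot_similarity(probe, studied, ew)
    elif scheme == "both-slot":
        out = both_edges_slot_similarity(probe, studied, ew, mix)
    elif scheme == "overlap":
        out = overlap_similarity(probe, studied, ew, op or OverlapParams(d=1.544, r=1.094))
    elif scheme == "both-overlap":
        out = both_edges_overlap_similarity(
            probe, studied, ew, op or OverlapParams(d=1.544, r=1.094), mix
        )
    elif scheme == "closed-bigram":
        out = closed_bigram_similarity(probe, studied, ew)
    elif scheme == "open-bigram":
        out = open_bigram_similarity(probe, studied, ew)
    elif scheme == "levenshtein":
        return levenshtein_similarity(probe, studied)
    else:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    if epsilon > 0.0:
        out = e_modified_similarity(out, probe, studied, epsilon, ew)
    return out


def nearest_neighbors(
    probe: str,
    pool: Iterable[str],
    scheme: str,
    k: int = 5,
    ew: ExteriorWeights = ExteriorWeights(),
    op: OverlapParams | None = None,
    mix: EdgeMix = EdgeMix(),
) -> list[tuple[str, float]]:
    """Top-``k`` most similar pool words to ``probe`` (probe excluded),
    descending by similarity with lexicographic tie-break."""
    probe_n = normalize_word(probe)
    scored = []
    for word in pool:
        w = normalize_word(word)
        if w == probe_n:
            continue
        s = similarity(probe_n, w, scheme, ew=ew, op=op, mix=mix)
        scored.append((w, s.value))
    if not scored:
        raise ValueError("neighbor pool is empty")
    return heapq.nsmallest(min(k, len(scored)), scored, key=lambda t: (-t[1], t[0]))
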