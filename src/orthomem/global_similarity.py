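"""Global (summed) similarity of a probe to a study list.

Recognition is modeled as global matching: the probe is compared with
every study-list word and the pairwise similarities, raised to a power
``p``, are aggregated into a single memory-strength signal

    g = sum_{j in L, j != probe} s_ij^p / N_L

where ``N_L`` is the study-list length.  The nonlinearity ``p``
suppresses low similarities while leaving s = 1 untouched, so that for
large ``p`` only near neighbors of the probe contribute.  Entries equal
to the probe word (targets matching themselves) are excluded from the
sum; the divisor stays ``N_L``.

With an embedding table the orthographic and semantic channels combine
per item as ``w_o * s_ij^p + (1 - w_o) * c_ij^{p*}`` before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import orthography as ortho
from .orthography import EdgeMix, ExteriorWeights, OverlapParams
from .semantics import EmbeddingTable, truncated_cosine

__all__ = [
    "GlobalSimilarityParams",
    "GlobalSimilarity",
    "power_transform",
    "pairwise_profile",
    "global_orthographic_similarity",
    "combined_global_similarity",
]


@dataclass(frozen=True)
class GlobalSimilarityParams:
    """Nonlinearity ``p`` (orthographic), ``p_star`` (semantic) and the
    orthographic channel weight ``w_o``; ``p = 1`` is the linear model
    and ``w_o = 1`` disables the semantic channel."""

    p: float = 1.0
    p_star: float = 1.0
    w_o: float = 1.0

    def __post_init__(self) -> None:
        if self.p <= 0 or self.p_star <= 0:
            raise ValueError("nonlinearity exponents must be positive")
        if not 0.0 <= self.w_o <= 1.0:
            raise ValueError("orthographic weight w_o must lie in [0, 1]")


@dataclass(frozen=True)
class GlobalSimilarity:
    """Aggregated similarity ``g`` over a study list of ``n_items``."""

    g: float
    n_items: int


def power_transform(s, p: float):
    """``s ** p`` for similarities in [0, 1]; identity at p = 1, fixed
    point at s = 1."""
    s = np.asarray(s, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("similarity must lie in [0, 1] for the power transform")
    if p < 0:
        raise ValueError("exponent p must be nonnegative")
    out = s**p
    return float(out) if out.ndim == 0 else out


def pairwise_profile(
    probe: str,
    study_list: Sequence[str],
    scheme: str,
    ew: ExteriorWeights = ExteriorWeights(),
    op: OverlapParams | None = None,
    mix: EdgeMix = EdgeMix(),
    epsilon: float = 0.0,
) -> np.ndarray:
    """Raw (untransformed) similarity of the probe to each list item,
    with entries equal to the probe word set to 0 (self-exclusion)."""
    probe_n = ortho.normalize_word(probe)
    values = np.empty(len(study_list))
    for idx, word in enumerate(study_list):
        w = ortho.normalize_word(word)
        if w == probe_n:
            values[idx] = 0.0
        else:
            values[idx] = ortho.similarity(
                probe_n, w, scheme, ew=ew, op=op, mix=mix, epsilon=epsilon
            ).value
    return values


def global_orthographic_similarity(
    probe: str,
    study_list: Sequence[str],
    scheme: str,
    gsp: GlobalSimilarityParams = GlobalSimilarityParams(),
    ew: ExteriorWeights = ExteriorWeights(),
    op: OverlapParams | None = None,
    mix: EdgeMix = EdgeMix(),
    epsilon: float = 0.0,
) -> GlobalSimilarity:
    """Orthographic global similarity of ``probe`` to ``study_list``."""
    if len(study_list) == 0:
        raise ValueError("study list must be non-empty")
    s = pairwise_profile(probe, study_list, scheme, ew=ew, op=op, mix=mix, epsilon=epsilon)
    g = float(np.sum(s**gsp.p)) / len(study_list)
    return GlobalSimilarity(g=g, n_items=len(study_list))


def combined_global_similarity(
    probe: str,
    study_list: Sequence[str],
    scheme: str,
    table: EmbeddingTable,
    gsp: GlobalSimilarityParams = GlobalSimilarityParams(),
    ew: ExteriorWeights = ExteriorWeights(),
    op: OverlapParams | None = None,
    mix: EdgeMix = EdgeMix(),
    epsilon: float = 0.0,
) -> GlobalSimilarity:
    """Orthographic + semantic global similarity (per-item mixture with
    weight ``w_o``); self-matching list entries contribute 0 to both
    channels."""
    if len(study_list) == 0:
        raise ValueError("study list must be non-empty")
    probe_n = ortho.normalize_word(probe)
    s = pairwise_profile(probe, study_list, scheme, ew=ew, op=op, mix=mix, epsilon=epsilon)
    c = np.empty(len(study_list))
    for idx, word in enumerate(study_list):
        w = ortho.normalize_word(word)
        c[idx] = 0.0 if w == probe_n else truncated_cosine(probe_n, w, table)
    total = gsp.w_o * s**gsp.p + (1.0 - gsp.w_o) * c**gsp.p_star
    return GlobalSimilarity(g=float(np.sum(total)) / len(study_list), n_items=len(study_list))
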