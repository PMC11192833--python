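"""Descriptive summaries: global-similarity binning, lure
classification by minimum edit distance, and per-class error rates.

These are the model-checking views used with global matching models:
trials are split into equal-count ("equal area") bins of global
similarity to trace how hit and false alarm rates and RT quantiles
move with memory-strength, and lures are classified by their minimum
Levenshtein distance to the study list (1 = HS, 2 = MS, 3 = LS,
>= 4 = VLS).  High-similarity lures are further sub-typed by which
letter of the nearest studied word is missing (start/middle/end) --
the within-word primacy diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .orthography import levenshtein_distance, normalize_word

__all__ = [
    "LureClass",
    "bin_by_global_similarity",
    "classify_lure",
    "classify_trials",
    "summarize_by_lure_class",
]

_CLASS_BY_DISTANCE = {1: "HS", 2: "MS", 3: "LS"}
LURE_CLASSES = ("HS", "MS", "LS", "VLS")
RT_QUANTILES = (0.1, 0.5, 0.9)


@dataclass(frozen=True)
class LureClass:
    """Similarity class of one lure probe.

    ``multiplicity`` is "1x" or "2x+" depending on how many list items
    sit at the minimum distance; ``subtype`` locates the unshared
    letter for HS lures (start/middle/end) and is "none" otherwise.
    """

    label: str
    min_distance: int
    multiplicity: str
    subtype: str


def _unshared_letter_position(probe: str, studied: str) -> str:
    """For a distance-1 pair, whether the differing letter is the
    initial, an interior, or the terminal letter.

    For unequal lengths the convention is the first position at which
    the two words diverge (the deleted/added letter); for equal lengths
    it is the substituted position.
    """
    if len(probe) == len(studied):
        diff = [i for i in range(len(probe)) if probe[i] != studied[i]]
        idx, length = diff[0], len(probe)
    else:
        longer, shorter = (probe, studied) if len(probe) > len(studied) else (studied, probe)
        idx = len(shorter)  # default: diverge only by the trailing letter
        for i in range(len(shorter)):
            if longer[i] != shorter[i]:
                idx = i
                break
        length = len(longer)
    if idx == 0:
        return "start"
    if idx == length - 1:
        return "end"
    return "middle"


def classify_lure(probe: str, study_list) -> LureClass:
    """Classify a lure by its minimum Levenshtein distance to the
    study list.  The probe must not itself be on the list."""
    if isinstance(study_list, str):
        study_list = study_list.split(";")
    probe = normalize_word(probe)
    study = [normalize_word(w) for w in study_list]
    if probe in study:
        raise ValueError(f"probe {probe!r} appears in its own study list; not a lure")
    distances = np.array([levenshtein_distance(probe, w) for w in study])
    d_min = int(distances.min())
    at_min = [w for w, d in zip(study, distances) if d == d_min]
    label = _CLASS_BY_DISTANCE.get(d_min, "VLS")
    multiplicity = "1x" if len(at_min) == 1 else "2x+"
    if d_min == 1:
        subtype = _unshared_letter_position(probe, at_min[0])
    else:
        subtype = "none"
    return LureClass(label, d_min, multiplicity, subtype)


def classify_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Classify every lure trial; returns the lure rows with
    ``lure_class``, ``min_distance``, ``multiplicity``, ``subtype``
    columns added."""
    lures = trials[trials["status"] == "lure"].copy()
    records = [classify_lure(row["probe"], row["study_list"]) for _, row in lures.iterrows()]
    lures["lure_class"] = [r.label for r in records]
    lures["min_distance"] = [r.min_distance for r in records]
    lures["multiplicity"] = [r.multiplicity for r in records]
    lures["subtype"] = [r.subtype for r in records]
    return lures


def _rt_quantiles(rt: pd.Series, prefix: str) -> dict[str, float]:
    if len(rt) == 0:
        return {f"{prefix}_q{int(q * 100)}": np.nan for q in RT_QUANTILES}
    return {f"{prefix}_q{int(q * 100)}": float(rt.quantile(q)) for q in RT_QUANTILES}


def bin_by_global_similarity(trials: pd.DataFrame, n_bins: int) -> pd.DataFrame:
    """Equal-count global-similarity bins, separately within targets
    and lures.

    Each row holds the bin's trial count, mean g, P("old") (the hit
    rate for targets, false alarm rate for lures) and the .1/.5/.9 RT
    quantiles for correct and error responses.  Ties in g are broken by
    stable trial order; if every g is identical the "bins" degrade to a
    round-robin split (warned).
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    out = []
    for status, sub in trials.groupby("status"):
        if len(sub) < n_bins:
            raise ValueError(f"fewer {status} trials ({len(sub)}) than bins ({n_bins})")
        g = sub["g"].to_numpy(float)
        if np.all(g == g[0]):
            warnings.warn(f"all {status} global similarities identical; round-robin binning")
        order = np.argsort(g, kind="stable")
        rank = np.empty(len(g), dtype=int)
        rank[order] = np.arange(len(g))
        bins = (rank * n_bins) // len(g)
        correct_resp = "old" if status == "target" else "new"
        for b in range(n_bins):
            rows = sub.iloc[np.flatnonzero(bins == b)]
            correct = rows[rows["response"] == correct_resp]
            error = rows[rows["response"] != correct_resp]
            rec = {
                "status": status,
                "bin": b,
                "n": len(rows),
                "mean_g": float(rows["g"].mean()),
                "p_old": float((rows["response"] == "old").mean()),
            }
            rec.update(_rt_quantiles(correct["rt_seconds"], "correct_rt"))
            rec.update(_rt_quantiles(error["rt_seconds"], "error_rt"))
            out.append(rec)
    return pd.DataFrame(out)


def summarize_by_lure_class(trials: pd.DataFrame) -> pd.DataFrame:
    """False alarm rate and median lure RT per similarity class (with
    HS broken out by missing-letter subtype and MS/LS by 1x/2x+
    multiplicity).  Classes with no trials appear with NaN values."""
    lures = classify_trials(trials)
    rows = []

    def _summary(sub: pd.DataFrame, **keys) -> dict:
        if len(sub) == 0:
            return {**keys, "n": 0, "far": np.nan, "median_rt": np.nan}
        return {
            **keys,
            "n": len(sub),
            "far": float((sub["response"] == "old").mean()),
            "median_rt": float(sub["rt_seconds"].median()),
        }

    for label in LURE_CLASSES:
        sub = lures[lures["lure_class"] == label]
        rows.append(_summary(sub, lure_class=label, subtype="all", multiplicity="all"))
        if label == "HS":
            for subtype in ("start", "middle", "end"):
                rows.append(
                    _summary(
                        sub[sub["subtype"] == subtype],
                        lure_class=label,
                        subtype=subtype,
                        multiplicity="all",
                    )
                )
        elif label in ("MS", "LS"):
            for mult in ("1x", "2x+"):
                rows.append(
                    _summary(
                        sub[sub["multiplicity"] == mult],
                        lure_class=label,
                        subtype="none",
                        multiplicity=mult,
                    )
                )
    return pd.DataFrame(rows)
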