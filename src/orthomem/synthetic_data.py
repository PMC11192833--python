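"""Synthetic word pools, study/test sessions and simulated observers.

The generator emulates the structure of list-learning recognition
experiments with unrelated words: study lists of 40-150 words of 3-11
letters, ~50/50 target/lure test probes, and per-trial choice + RT.
Words default to random strings drawn from English letter frequencies,
which yields realistic incidental orthographic overlap; a small
packaged English word list is available for demos.

Lures are mostly unrelated pool words, but a controllable fraction are
*planted* near-neighbors of studied words: single-letter deletions
(edit distance 1, the rare high-similarity lures, ~1-3% of trials in
comparable experiments) and two- or three-edit variants, so that the
minimum-edit-distance lure classes (HS/MS/LS/VLS) are all populated.

Simulated observers draw their parameters from group-level (truncated)
normal distributions, accumulate global similarity per trial under a
chosen representation scheme, and respond through the LBA race.  One
master seed derives all per-participant streams.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .global_similarity import pairwise_profile
from .inference import _SUPPORT_BOUNDS, FitConfig
from .lba import LBAParams, simulate_trials

__all__ = [
    "StudyDesign",
    "ENGLISH_LETTER_FREQ",
    "DEFAULT_GROUP_MEANS",
    "DEFAULT_GROUP_SDS",
    "generate_pool",
    "generate_session",
    "simulate_study",
    "load_demo_wordlist",
]

# Relative letter frequencies of English text (per mille, approximate).
ENGLISH_LETTER_FREQ: dict[str, float] = {
    "e": 127, "t": 91, "a": 82, "o": 75, "i": 70, "n": 67, "s": 63,
    "h": 61, "r": 60, "d": 43, "l": 40, "c": 28, "u": 28, "m": 24,
    "w": 24, "f": 22, "g": 20, "y": 20, "p": 19, "b": 15, "v": 10,
    "k": 8, "j": 2, "x": 2, "q": 1, "z": 1,
}

_LETTERS = np.array(list(ENGLISH_LETTER_FREQ))
_LETTER_P = np.array(list(ENGLISH_LETTER_FREQ.values()), dtype=float)
_LETTER_P /= _LETTER_P.sum()


@dataclass(frozen=True)
class StudyDesign:
    """Shape of one synthetic experiment.

    Defaults mirror a mid-sized list-learning study: 40-word lists,
    4-7 letter words, equal target/lure test mix, and planted
    near-neighbor lures (deletion/substitution variants of studied
    words) at rates that keep every similarity class populated while
    distance-1 lures stay rare.
    """

    n_participants: int = 8
    list_length: int = 40
    n_test_trials: int = 300
    word_len_range: tuple[int, int] = (4, 7)
    p_target: float = 0.5
    conditions: tuple[str, ...] = ("default",)
    hs_rate: float = 0.02
    ms_rate: float = 0.10
    ls_rate: float = 0.12
    pool_size: int = 2000

    def __post_init__(self) -> None:
        if not 1 <= self.word_len_range[0] <= self.word_len_range[1] <= 11:
            raise ValueError("word lengths must lie in [1, 11] with min <= max")
        if not 0.0 <= self.p_target <= 1.0:
            raise ValueError("p_target must lie in [0, 1]")
        if self.hs_rate + self.ms_rate + self.ls_rate > 1.0:
            raise ValueError("planted-lure rates must not exceed 1")
        if self.pool_size < 2 * self.list_length:
            raise ValueError("pool must hold at least two study lists")


# Generating group-level parameters: high hit rate, moderate baseline
# false alarm rate, similarity driving lure drift (gamma_lure) but not
# target drift, and a Minerva-2-style cubic similarity transform.
DEFAULT_GROUP_MEANS: dict[str, float] = {
    "V_target": 1.0,
    "V_lure": -1.0,
    "gamma_target": 2.0,
    "gamma_lure": 100.0,
    "B": 1.0,
    "t0": 0.25,
    "V0": 2.0,
    "eta_target": 1.2,
    "p": 3.0,
}
DEFAULT_GROUP_SDS: dict[str, float] = {
    "V_target": 0.2,
    "V_lure": 0.2,
    "gamma_target": 2.0,
    "gamma_lure": 15.0,
    "B": 0.15,
    "t0": 0.03,
    "V0": 0.2,
    "eta_target": 0.1,
    "p": 0.3,
}


def load_demo_wordlist() -> list[str]:
    """The packaged list of common English words (3-11 letters)."""
    text = importlib.resources.files("orthomem.data").joinpath("demo_words.txt").read_text()
    return [w for w in text.split() if w]


def _random_word(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(_LETTERS, size=length, p=_LETTER_P))


def generate_pool(
    size: int,
    length_range: tuple[int, int] = (4, 8),
    mode: str = "random-strings",
    seed: int = 0,
) -> list[str]:
    """Unique normalized words, deterministic given ``seed``.

    ``random-strings`` draws letters from English letter frequencies;
    ``packaged-wordlist`` samples from the shipped demo list.
    """
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    if mode == "packaged-wordlist":
        words = [w for w in load_demo_wordlist() if lo <= len(w) <= hi]
        if len(words) < size:
            raise ValueError(
                f"packaged list holds only {len(words)} words of length {lo}-{hi}"
            )
        return list(rng.choice(words, size=size, replace=False))
    if mode != "random-strings":
        raise ValueError(f"unknown pool mode {mode!r}")
    capacity = sum(26**k for k in range(lo, hi + 1))
    if size > capacity / 2:
        raise ValueError(f"cannot draw {size} unique words of length {lo}-{hi}")
    pool: dict[str, None] = {}
    attempts = 0
    while len(pool) < size:
        pool.setdefault(_random_word(rng, lo, hi), None)
        attempts += 1
        if attempts > 100 * size:
            raise RuntimeError("pool generation failed to find enough unique words")
    return list(pool)


def _edited_word(word: str, n_edits: int, rng: np.random.Generator, position: str | None = None) -> str:
    """Apply ``n_edits`` single-letter deletions/substitutions.

    The first edit is a deletion (so distance-1 lures are
    "missing-letter" items); ``position`` pins that deletion to the
    start, middle or end of the word.  Later edits are substitutions at
    random positions.
    """
    letters = list(word)
    if position == "start":
        idx = 0
    elif position == "end":
        idx = len(letters) - 1
    elif position == "middle":
        idx = int(rng.integers(1, len(letters) - 1))
    else:
        idx = int(rng.integers(0, len(letters)))
    del letters[idx]
    for _ in range(n_edits - 1):
        j = int(rng.integers(0, len(letters)))
        old = letters[j]
        choices = [c for c in _LETTERS if c != old]
        letters[j] = str(rng.choice(choices))
    return "".join(letters)


def _planted_lure(
    study: Sequence[str],
    n_edits: int,
    rng: np.random.Generator,
    used: set,
    position: str | None = None,
) -> str | None:
    """A lure at ~``n_edits`` edit distance from some studied word."""
    candidates = [w for w in study if len(w) >= n_edits + 3]
    rng.shuffle(candidates)
    for base in candidates[:20]:
        lure = _edited_word(base, n_edits, rng, position)
        if lure not in used and lure not in study:
            return lure
    return None


def generate_session(
    pool: Sequence[str],
    design: StudyDesign,
    seed: int = 0,
    participant_id: str = "p01",
) -> pd.DataFrame:
    """Study/test trials for one participant.

    The session is split into study-test blocks (each block studies a
    fresh ``list_length``-word list and tests studied targets plus
    lures); conditions rotate across blocks.  No lure appears in its
    own study list.
    """
    rng = np.random.default_rng(seed)
    per_block_cap = 2 * design.list_length
    n_blocks = max(1, math.ceil(design.n_test_trials / per_block_cap))
    base = design.n_test_trials // n_blocks
    trials_per_block = [base + (b < design.n_test_trials % n_blocks) for b in range(n_blocks)]
    pool = list(pool)
    rows = []
    for b, n_trials in enumerate(trials_per_block):
        study = list(rng.choice(pool, size=design.list_length, replace=False))
        study_set = set(study)
        condition = design.conditions[b % len(design.conditions)]
        n_targets = min(int(round(n_trials * design.p_target)), design.list_length)
        targets = list(rng.choice(study, size=n_targets, replace=False))
        n_lures = n_trials - n_targets
        used: set = set(study_set)
        lures = []
        outside = [w for w in pool if w not in study_set]
        rng.shuffle(outside)
        oi = 0
        for _ in range(n_lures):
            u = rng.uniform()
            lure = None
            if u < design.hs_rate:
                pos = str(rng.choice(["start", "middle", "end"]))
                lure = _planted_lure(study, 1, rng, used, position=pos)
            elif u < design.hs_rate + design.ms_rate:
                lure = _planted_lure(study, 2, rng, used)
            elif u < design.hs_rate + design.ms_rate + design.ls_rate:
                lure = _planted_lure(study, 3, rng, used)
            if lure is None:
                while oi < len(outside) and outside[oi] in used:
                    oi += 1
                if oi >= len(outside):
                    raise ValueError("pool exhausted while drawing lures")
                lure = outside[oi]
                oi += 1
            used.add(lure)
            lures.append(lure)
        probes = [(w, "target") for w in targets] + [(w, "lure") for w in lures]
        rng.shuffle(probes)
        study_joined = ";".join(study)
        for probe, status in probes:
            rows.append(
                {
                    "participant_id": participant_id,
                    "condition": condition,
                    "status": status,
                    "probe": probe,
                    "study_list": study_joined,
                    "block": b,
                }
            )
    return pd.DataFrame(rows)


def _draw_participant_params(
    means: Mapping[str, float],
    sds: Mapping[str, float],
    specs,
    rng: np.random.Generator,
) -> dict[str, float]:
    out = {}
    for spec in specs:
        lo, hi = _SUPPORT_BOUNDS[spec.support]
        m, s = means[spec.name], sds[spec.name]
        x = rng.normal(m, s)
        while not lo <= x <= hi:
            x = rng.normal(m, s)
        out[spec.name] = float(x)
    return out


def session_global_similarity(
    trials: pd.DataFrame, config: FitConfig, p: float
) -> np.ndarray:
    """Global similarity of each trial's probe to its study list under
    the configured representation, with nonlinearity ``p``."""
    cache: dict[tuple[str, str], float] = {}
    g = np.empty(len(trials))
    for i, (_, row) in enumerate(trials.iterrows()):
        study = row["study_list"]
        if isinstance(study, str):
            study = study.split(";")
        total = 0.0
        for word in study:
            key = (row["probe"], word)
            if key not in cache:
                cache[key] = pairwise_profile(
                    row["probe"], [word], config.scheme,
                    ew=config.ew, op=config.op, mix=config.mix, epsilon=config.epsilon,
                )[0]
            total += cache[key] ** p
        g[i] = total / len(study)
    return g


def simulate_study(
    design: StudyDesign = StudyDesign(),
    config: FitConfig = FitConfig(),
    group_means: Mapping[str, float] | None = None,
    group_sds: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Full synthetic dataset plus the generating ground truth.

    Participant parameters are drawn from the group distributions,
    per-trial global similarity is computed under ``config``'s
    representation with each participant's own ``p``, and responses/RTs
    come from the LBA race.  Returns the trial table (with a ``g``
    column) and a truth record with the seed, design and parameters.
    """
    means = dict(DEFAULT_GROUP_MEANS, **(group_means or {}))
    sds = dict(DEFAULT_GROUP_SDS, **(group_sds or {}))
    specs = FitConfig(scheme=config.scheme, free_p=True).specs()
    master = np.random.SeedSequence(seed)
    pool_seed, *participant_seeds = master.spawn(design.n_participants + 1)
    pool = generate_pool(
        design.pool_size,
        design.word_len_range,
        seed=int(pool_seed.generate_state(1)[0] % 2**31),
    )
    frames = []
    truth_participants = []
    for idx, pseed in enumerate(participant_seeds):
        rng = np.random.default_rng(pseed)
        pid = f"p{idx + 1:02d}"
        theta = _draw_participant_params(means, sds, specs, rng)
        if not config.free_p:
            theta["p"] = config.p_fixed
        trials = generate_session(
            pool, design, seed=int(pseed.generate_state(1)[0] % 2**31), participant_id=pid
        )
        g = session_global_similarity(trials, config, theta["p"])
        trials["g"] = g
        is_target = (trials["status"] == "target").to_numpy()
        shift = np.where(
            is_target,
            theta["V_target"] + theta["gamma_target"] * g,
            theta["V_lure"] + theta["gamma_lure"] * g,
        )
        v_old = theta["V0"] + shift
        v_new = theta["V0"] - shift
        params = LBAParams(
            A=config.A,
            B_old=theta["B"],
            B_new=theta["B"],
            t0=theta["t0"],
            V0=theta["V0"],
            eta_target=theta["eta_target"],
        )
        response = np.empty(len(trials), dtype=object)
        rt = np.empty(len(trials))
        for status, mask in (("target", is_target), ("lure", ~is_target)):
            if np.any(mask):
                resp_m, rt_m = simulate_trials(v_old[mask], v_new[mask], params, rng, status)
                response[mask] = resp_m
                rt[mask] = rt_m
        trials["response"] = response
        trials["rt_seconds"] = rt
        frames.append(trials)
        truth_participants.append({"participant_id": pid, **theta})
    truth = {
        "seed": seed,
        "design": asdict(design),
        "scheme": config.scheme,
        "group_means": means,
        "group_sds": sds,
        "fixed": {"A": config.A},
        "participants": truth_participants,
    }
    return pd.concat(frames, ignore_index=True), truth
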