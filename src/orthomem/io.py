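"""Trial-table and word-pool formats, plus the serializable run
configuration.

Trial tables are UTF-8 comma-separated files with a header row and the
columns ``participant_id, condition, status, probe, study_list,
response, rt_seconds`` (RT in seconds); the study list is a
semicolon-joined word sequence to avoid CSV quoting ambiguity.
Word pools are plain text, one word per line.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "TrialTableError",
    "read_trial_table",
    "write_trial_table",
    "read_word_pool",
    "write_word_pool",
    "RunConfig",
]

TRIAL_COLUMNS = (
    "participant_id",
    "condition",
    "status",
    "probe",
    "study_list",
    "response",
    "rt_seconds",
)
_STATUS_LABELS = {"target", "lure"}
_RESPONSE_LABELS = {"old", "new"}


class TrialTableError(ValueError):
    """Malformed trial table (message names the offending lines)."""


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Raises :class:`TrialTableError` naming the data line numbers
    (header = line 1) of malformed rows: missing columns, unknown
    status/response labels, or non-numeric/non-positive RT.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"{path}: missing columns {missing}")
    problems = []
    rt = pd.to_numeric(df["rt_seconds"], errors="coerce")
    for idx in df.index:
        line = idx + 2  # header occupies line 1
        if df.at[idx, "status"] not in _STATUS_LABELS:
            problems.append(f"line {line}: unknown status {df.at[idx, 'status']!r}")
        if df.at[idx, "response"] not in _RESPONSE_LABELS:
            problems.append(f"line {line}: unknown response {df.at[idx, 'response']!r}")
        if not np.isfinite(rt[idx]) or rt[idx] <= 0:
            problems.append(f"line {line}: invalid rt_seconds {df.at[idx, 'rt_seconds']!r}")
        if not df.at[idx, "study_list"]:
            problems.append(f"line {line}: empty study_list")
    if problems:
        raise TrialTableError(f"{path}: " + "; ".join(problems[:20]))
    # astype(float) round-trips the full printed precision (to_numeric's
    # fast parser loses the last digits)
    df["rt_seconds"] = df["rt_seconds"].astype(float)
    if "g" in df.columns:
        df["g"] = df["g"].astype(float)
    if "block" in df.columns:
        df["block"] = pd.to_numeric(df["block"], downcast="integer")
    return df


def write_trial_table(trials: pd.DataFrame, path) -> None:
    """Write a trial table; round-trips bit-identically through
    :func:`read_trial_table` up to float formatting (full precision is
    preserved via repr)."""
    df = trials.copy()
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"cannot write table lacking columns {missing}")
    ordered = [c for c in TRIAL_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in TRIAL_COLUMNS
    ]
    df[ordered].to_csv(path, index=False, float_format="%.17g")


def read_word_pool(path) -> list[str]:
    """One word per line, UTF-8."""
    with open(path, "r", encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_word_pool(words, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for word in words:
            fh.write(f"{word}\n")


@dataclass
class RunConfig:
    """Flat, JSON-serializable description of one model run; a run is
    reproducible from the config and seed alone."""

    trials_path: str = ""
    pool_path: str = ""
    embeddings_path: str = ""
    scheme: str = "open-bigram"
    alpha: float = 1.0
    omega: float = 1.0
    w: float = 0.75
    d: float = 1.544
    r: float = 1.094
    epsilon: float = 0.0
    free_p: bool = True
    p_fixed: float = 1.0
    A: float = 0.5
    n_chains: int = 0  # 0 = auto (2d + 2)
    n_iter: int = 500
    seed: int = 0
    output_dir: str = "run"

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)
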