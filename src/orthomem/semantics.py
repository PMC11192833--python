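"""Semantic word similarity from vector embeddings.

Pairwise semantic similarity is the cosine between two word vectors
truncated at zero, ``c_ij = max(cos(v_i, v_j), 0)``: orthogonal vectors
already denote maximal dissimilarity, and truncation keeps the power
transform used downstream from amplifying negative values.

Embeddings load from the common plain-text format ``word v1 ... vD``
(one word per line, an optional ``count dim`` header tolerated), the
layout used by pre-trained word2vec/FastText releases.  Vectors are
L2-normalized at load so cosine reduces to a dot product.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "EmbeddingTable",
    "MissingWordError",
    "read_embedding_table",
    "truncated_cosine",
    "synthetic_embeddings",
]

log = logging.getLogger(__name__)


class MissingWordError(KeyError):
    """A word was not found in the embedding table (strict mode)."""


@dataclass
class EmbeddingTable:
    """Mapping word -> unit-norm vector of fixed dimension.

    ``strict`` controls the lookup policy during model evaluation:
    strict tables raise :class:`MissingWordError` for unknown words,
    lenient tables (default) score unknown words as similarity 0 with a
    logged warning so trials stay usable.
    """

    vectors: dict[str, np.ndarray]
    dim: int
    strict: bool = False
    _warned: set = field(default_factory=set, repr=False)

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    def get(self, word: str) -> np.ndarray | None:
        vec = self.vectors.get(word)
        if vec is None:
            if self.strict:
                raise MissingWordError(word)
            if word not in self._warned:
                self._warned.add(word)
                log.warning("word %r missing from embedding table; similarity set to 0", word)
        return vec


def _normalize_rows(word: str, values: list[str], dim: int, lineno: int) -> np.ndarray:
    if len(values) != dim:
        raise ValueError(
            f"line {lineno}: expected {dim} vector components for {word!r}, got {len(values)}"
        )
    vec = np.asarray(values, dtype=float)
    norm = np.linalg.norm(vec)
    if norm == 0.0 or not np.isfinite(norm):
        raise ValueError(f"line {lineno}: zero or non-finite vector for {word!r}")
    return vec / norm


def read_embedding_table(
    path, restrict_to: Iterable[str] | None = None, strict: bool = False
) -> EmbeddingTable:
    """Load a plain-text embedding table, optionally restricted to a
    word set.  Requested words absent from the file are reported via a
    warning; the table itself simply omits them."""
    wanted = {w.lower() for w in restrict_to} if restrict_to is not None else None
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split()
            if not parts:
                continue
            if lineno == 1 and len(parts) == 2:
                try:  # optional "count dim" header
                    int(parts[0]), int(parts[1])
                    continue
                except ValueError:
                    pass
            word, values = parts[0].lower(), parts[1:]
            if dim is None:
                dim = len(values)
                if dim < 1:
                    raise ValueError(f"line {lineno}: no vector components")
            if wanted is not None and word not in wanted:
                continue
            vectors[word] = _normalize_rows(word, values, dim, lineno)
    if dim is None:
        raise ValueError(f"no embedding rows found in {path}")
    if wanted is not None:
        missing = sorted(wanted - vectors.keys())
        if missing:
            warnings.warn(f"{len(missing)} requested words missing from {path}: {missing[:10]}")
    return EmbeddingTable(vectors=vectors, dim=dim, strict=strict)


def truncated_cosine(i: str, j: str, table: EmbeddingTable) -> float:
    """Cosine similarity truncated at zero; 0 for missing words under
    the lenient lookup policy."""
    vi = table.get(i)
    vj = table.get(j)
    if vi is None or vj is None:
        return 0.0
    return float(max(vi @ vj, 0.0))


def synthetic_embeddings(
    pool: Iterable[str],
    dim: int = 100,
    n_clusters: int = 1,
    within_cluster_cos: float = 0.0,
    seed: int = 0,
) -> EmbeddingTable:
    """Cluster-structured unit vectors for testing.

    Words are assigned round-robin to ``n_clusters`` random centroids;
    each vector is ``sqrt(rho) * centroid + sqrt(1 - rho) * noise`` with
    ``rho = within_cluster_cos``, so the expected cosine is ~``rho``
    within a cluster and ~0 between clusters (exactly 0 in expectation,
    with O(1/sqrt(dim)) spread).  Deterministic given ``seed``.
    """
    words = sorted({w.lower() for w in pool})
    if dim < 2:
        raise ValueError("embedding dimension must be >= 2")
    if not 0.0 <= within_cluster_cos < 1.0:
        raise ValueError("within_cluster_cos must lie in [0, 1)")
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    rng = np.random.default_rng(seed)
    centroids = rng.standard_normal((n_clusters, dim))
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
    rho = within_cluster_cos
    vectors: dict[str, np.ndarray] = {}
    for idx, word in enumerate(words):
        noise = rng.standard_normal(dim)
        noise /= np.linalg.norm(noise)
        vec = np.sqrt(rho) * centroids[idx % n_clusters] + np.sqrt(1.0 - rho) * noise
        vectors[word] = vec / np.linalg.norm(vec)
    return EmbeddingTable(vectors=vectors, dim=dim)
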