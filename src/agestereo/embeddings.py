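"""Sentence-embedding backends behind one uniform contract.

Two backends are provided:

* :class:`SyntheticBackend` — a deterministic test double whose geometry is
  known by construction: every stereotype subdimension owns one coordinate,
  and a lexicon word found in a sentence adds ``signal_weight`` on its
  subdimension's coordinate with the sign of its valence, plus optional
  seeded isotropic noise.  This gives downstream regression a recoverable
  ground truth.
* :class:`TransformerBackend` — a thin, lazily imported adapter around a
  sentence-transformer checkpoint (1,024-dimensional for the large RoBERTa
  family).  Optional; everything else runs without it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np

from .corpus import tokenize
from .lexicon import SUBDIMENSIONS, ScmLexicon

__all__ = [
    "EmbeddingMatrix",
    "EmbeddingBackend",
    "BackendUnavailableError",
    "SyntheticEmbeddingSpec",
    "SyntheticBackend",
    "TransformerBackend",
    "default_axis_assignment",
    "synthetic_embed",
    "embed",
    "save_embeddings",
    "load_embeddings",
]


class BackendUnavailableError(RuntimeError):
    """The requested embedding backend cannot be constructed."""


@dataclass
class EmbeddingMatrix:
    """Row-per-sentence embedding matrix with stable row identifiers."""

    vectors: np.ndarray  # shape (n, dim)
    row_ids: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be 2-D (rows x dim)")
        if self.vectors.shape[0] != len(self.row_ids):
            raise ValueError(
                f"{self.vectors.shape[0]} rows but {len(self.row_ids)} row_ids"
            )
        if self.vectors.size and not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding matrix contains non-finite entries")

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


class EmbeddingBackend(Protocol):
    dim: int

    def encode(self, sentences: Sequence[str]) -> np.ndarray: ...

    def identifier(self) -> str: ...


def default_axis_assignment(dim: int) -> dict[tuple[str, int], int]:
    """Map each (subdimension, valence) cell to a coordinate.

    Both valences of a subdimension share one coordinate — a negative-valence
    word contributes with negative sign, so one positive and one negative
    word of the same subdimension cancel exactly.  Coordinates are distinct
    across subdimensions.
    """
    if dim < len(SUBDIMENSIONS):
        raise ValueError(f"dim={dim} too small for {len(SUBDIMENSIONS)} axes")
    assignment = {}
    for i, sub in enumerate(SUBDIMENSIONS):
        assignment[(sub, +1)] = i
        assignment[(sub, -1)] = i
    return assignment


@dataclass(frozen=True)
class SyntheticEmbeddingSpec:
    """Geometry of the synthetic backend."""

    dim: int = 64
    axis_assignment: dict[tuple[str, int], int] | None = None
    signal_weight: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def axes(self) -> dict[tuple[str, int], int]:
        assignment = (
            self.axis_assignment
            if self.axis_assignment is not None
            else default_axis_assignment(self.dim)
        )
        coords = set(assignment.values())
        if any(c < 0 or c >= self.dim for c in coords):
            raise ValueError("axis coordinates must lie in [0, dim)")
        # coordinates must be distinct across subdimensions
        per_sub = {}
        for (sub, _val), c in assignment.items():
            per_sub.setdefault(sub, set()).add(c)
        flat = [c for s in per_sub.values() for c in s]
        if len(flat) != len(set(flat)):
            raise ValueError("axis coordinates must be distinct across subdimensions")
        return assignment

    def __post_init__(self) -> None:
        if self.signal_weight <= 0:
            raise ValueError("signal_weight must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self.axes()  # validate eagerly


def _sentence_rng(seed: int, sentence: str) -> np.random.Generator:
    # stable across processes: never use hash()
    digest = hashlib.sha256(f"{seed}|{sentence}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def synthetic_embed(
    spec: SyntheticEmbeddingSpec, sentence: str, lexicon: ScmLexicon
) -> np.ndarray:
    """Embed one sentence under the synthetic geometry.

    Case-insensitive exact-token matching (same tokenization as the corpus
    module, independent of any lemmatizer).  Deterministic given
    ``(spec.seed, sentence)``.
    """
    axes = spec.axes()
    vec = np.zeros(spec.dim)
    for tok in tokenize(sentence):
        for entry in lexicon.lookup(tok):
            coord = axes[(entry.subdimension, entry.valence)]
            vec[coord] += entry.valence * spec.signal_weight
    if spec.noise_sd > 0:
        vec = vec + _sentence_rng(spec.seed, sentence).normal(
            0.0, spec.noise_sd, spec.dim
        )
    return vec


class SyntheticBackend:
    """Deterministic embedding backend over a fixed lexicon geometry."""

    def __init__(self, spec: SyntheticEmbeddingSpec, lexicon: ScmLexicon):
        self.spec = spec
        self.lexicon = lexicon
        self.dim = spec.dim

    def encode(self, sentences: Sequence[str]) -> np.ndarray:
        if not sentences:
            return np.zeros((0, self.dim))
        return np.vstack(
            [synthetic_embed(self.spec, s, self.lexicon) for s in sentences]
        )

    def identifier(self) -> str:
        return (
            f"synthetic(dim={self.spec.dim},signal={self.spec.signal_weight},"
            f"noise_sd={self.spec.noise_sd},seed={self.spec.seed})"
        )


class TransformerBackend:
    """Optional sentence-transformer adapter (lazily imported).

    The checkpoint identifier is recorded in output metadata rather than
    assumed: different checkpoints of the same family pool differently.
    """

    DEFAULT_CHECKPOINT = "all-roberta-large-v1"  # 1,024-dimensional

    def __init__(self, checkpoint: str | None = None):
        name = checkpoint or self.DEFAULT_CHECKPOINT
        try:
            from sentence_transformers import SentenceTransformer
        except ImportError as exc:
            raise BackendUnavailableError(
                "transformer backend requires the 'sentence-transformers' package "
                "(install the 'transformer' extra); use the synthetic backend for "
                "offline runs"
            ) from exc
        self._model = SentenceTransformer(name)
        self.checkpoint = name
        self.dim = int(self._model.get_sentence_embedding_dimension())

    def encode(self, sentences: Sequence[str]) -> np.ndarray:
        if not sentences:
            return np.zeros((0, self.dim))
        return np.asarray(self._model.encode(list(sentences)), dtype=float)

    def identifier(self) -> str:
        return f"transformer(checkpoint={self.checkpoint},dim={self.dim})"


def embed(
    backend: EmbeddingBackend,
    sentences: Sequence[str],
    row_ids: Sequence[str] | None = None,
) -> EmbeddingMatrix:
    """Embed sentences, one row per input in input order."""
    if any(not s for s in sentences):
        raise ValueError("sentences must be non-empty strings")
    ids = list(row_ids) if row_ids is not None else [str(i) for i in range(len(sentences))]
    if len(ids) != len(sentences):
        raise ValueError("row_ids length must match sentences")
    vectors = backend.encode(sentences)
    return EmbeddingMatrix(
        vectors=vectors, row_ids=ids, meta={"backend": backend.identifier()}
    )


def save_embeddings(matrix: EmbeddingMatrix, prefix: str | Path) -> None:
    """Persist as ``<prefix>.csv`` plus a ``<prefix>.index.jsonl`` sidecar."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".csv"), matrix.vectors, delimiter=",")
    with open(prefix.with_suffix(".index.jsonl"), "w", encoding="utf-8") as fh:
        for i, rid in enumerate(matrix.row_ids):
            fh.write(json.dumps({"row": i, "row_id": rid}) + "\n")
        fh.write(json.dumps({"meta": matrix.meta}) + "\n")


def load_embeddings(prefix: str | Path) -> EmbeddingMatrix:
    prefix = Path(prefix)
    vectors = np.loadtxt(prefix.with_suffix(".csv"), delimiter=",", ndmin=2)
    row_ids, meta = [], {}
    with open(prefix.with_suffix(".index.jsonl"), encoding="utf-8") as fh:
        for line in fh:
            obj = json.loads(line)
            if "meta" in obj:
                meta = obj["meta"]
            else:
                row_ids.append(obj["row_id"])
    return EmbeddingMatrix(vectors=vectors, row_ids=row_ids, meta=meta)
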