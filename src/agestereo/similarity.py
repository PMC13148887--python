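"""Age-group text-similarity analysis.

Sentence embeddings of the whole corpus are reduced jointly by PCA, then a
mean vector is formed per sample (response) and per age group, and cosine
similarity between the group vectors yields an age-by-age similarity matrix.
Because PCA centers the corpus, group vectors can point in opposite
directions and negative similarities are expected (and informative), unlike
with raw non-negative sentence-embedding similarities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .embeddings import EmbeddingMatrix

__all__ = [
    "AgeSimilarityMatrix",
    "DegenerateInputError",
    "reduce_pca",
    "sample_mean_vectors",
    "age_similarity",
]

logger = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    """Input carries no usable variance or norm."""


@dataclass
class AgeSimilarityMatrix:
    """Symmetric cosine-similarity matrix over age-group mean vectors."""

    ages: list[int]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.ages)
        if self.values.shape != (k, k):
            raise ValueError(f"values must be {k}x{k}, got {self.values.shape}")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if np.any(np.abs(np.diag(self.values) - 1.0) > 1e-9):
            raise ValueError("diagonal must equal 1 within 1e-9")
        if np.any(self.values < -1 - 1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("entries must lie in [-1, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ages, columns=self.ages)

    def entry(self, age_i: int, age_j: int) -> float:
        return float(
            self.values[self.ages.index(age_i), self.ages.index(age_j)]
        )


def reduce_pca(
    matrix: EmbeddingMatrix, n_components: int | float = 0.9
) -> EmbeddingMatrix:
    """Project embeddings onto principal components fitted on all rows.

    ``n_components`` may be an integer count or a variance fraction in
    (0, 1); the default keeps the smallest number of components explaining
    at least 90% of variance.  Explained-variance fractions are stored in
    the output's ``meta``.
    """
    X = matrix.vectors
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 rows")
    total_var = float(np.var(X - X.mean(axis=0), axis=0).sum())
    if total_var <= 0:
        raise DegenerateInputError("zero total variance: all rows identical")
    max_rank = min(X.shape[0], X.shape[1])
    if isinstance(n_components, int) or n_components == int(n_components) and n_components >= 1:
        n = int(n_components)
        if n < 1 or n > max_rank:
            raise ValueError(f"n_components={n} must be in [1, {max_rank}]")
        pca = PCA(n_components=n, svd_solver="full")
    else:
        if not (0 < n_components < 1):
            raise ValueError("variance fraction must lie in (0, 1)")
        pca = PCA(n_components=float(n_components), svd_solver="full")
    scores = pca.fit_transform(X)
    meta = dict(matrix.meta)
    meta.update(
        {
            "pca_n_components": int(pca.n_components_),
            "explained_variance_ratio": pca.explained_variance_ratio_.tolist(),
        }
    )
    return EmbeddingMatrix(vectors=scores, row_ids=list(matrix.row_ids), meta=meta)


def sample_mean_vectors(
    reduced: EmbeddingMatrix, sentence_to_sample: dict[str, str]
) -> tuple[np.ndarray, list[str], list[str]]:
    """Unweighted mean of each sample's sentence vectors.

    Every row must be assigned to exactly one sample.  Samples that end up
    with zero surviving sentences simply do not appear; they are reported in
    the third return element (never emitted as zero rows).

    Returns ``(means, sample_ids, dropped_sample_ids)``.
    """
    missing = [rid for rid in reduced.row_ids if rid not in sentence_to_sample]
    if missing:
        raise ValueError(f"rows without a sample assignment: {missing[:5]}")
    groups: dict[str, list[int]] = {}
    for i, rid in enumerate(reduced.row_ids):
        groups.setdefault(sentence_to_sample[rid], []).append(i)
    sample_ids = list(groups)
    means = np.vstack(
        [reduced.vectors[groups[sid]].mean(axis=0) for sid in sample_ids]
    )
    all_samples = set(sentence_to_sample.values())
    dropped = sorted(all_samples - set(sample_ids))
    if dropped:
        logger.info("dropped %d samples with no surviving sentences", len(dropped))
    return means, sample_ids, dropped


def age_similarity(
    sample_means: np.ndarray,
    sample_ids: list[str],
    sample_to_age: dict[str, int],
) -> AgeSimilarityMatrix:
    """Cosine similarity between per-age mean vectors.

    The group vector of an age is the unweighted mean of that age's
    per-sample mean vectors (samples, not sentences, are the replicates).
    """
    by_age: dict[int, list[int]] = {}
    for i, sid in enumerate(sample_ids):
        by_age.setdefault(sample_to_age[sid], []).append(i)
    ages = sorted(by_age)
    if not ages:
        raise ValueError("no samples provided")
    group = np.vstack([sample_means[by_age[a]].mean(axis=0) for a in ages])
    norms = np.linalg.norm(group, axis=1)
    for a, nrm in zip(ages, norms):
        if nrm == 0:
            raise DegenerateInputError(f"zero-norm group vector for age {a}")
    unit = group / norms[:, None]
    values = unit @ unit.T
    values = np.clip((values + values.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return AgeSimilarityMatrix(ages=ages, values=values)
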