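"""Stereotype-content scoring of sentences and across-age testing.

Labeled training sentences are built from a stereotype lexicon with two
templates —

* single: ``These people are always [ADJECTIVE].``
* pair:   ``These people are always [ADJECTIVE 1] and [ADJECTIVE 2].``

— a partial least squares (PLS) regression maps sentence embeddings to the
two-dimensional (warmth, competence) label space, corpus sentences are
scored on a -1..1 scale (linear predictions are clipped post hoc; a linear
map cannot guarantee the range by itself), and per-age score distributions
are compared with Welch's heteroscedastic one-way ANOVA.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from .embeddings import EmbeddingMatrix
from .lexicon import COMPETENCE, WARMTH, ScmLexicon

__all__ = [
    "SINGLE_TEMPLATE",
    "PAIR_TEMPLATE",
    "TemplateSentence",
    "ScmScorePair",
    "ScmScorer",
    "WelchResult",
    "DegenerateGroupError",
    "build_template_sentences",
    "fit_scm_model",
    "score_sentences",
    "welch_anova",
    "summarize_scores_by_age",
]

logger = logging.getLogger(__name__)

SINGLE_TEMPLATE = "These people are always {adj}."
PAIR_TEMPLATE = "These people are always {adj1} and {adj2}."


@dataclass(frozen=True)
class TemplateSentence:
    text: str
    warmth_label: float
    competence_label: float
    adjectives: tuple[str, ...]


@dataclass(frozen=True)
class ScmScorePair:
    sentence_id: str
    warmth: float
    competence: float


class DegenerateGroupError(ValueError):
    """A score group is unusable for Welch's test (too small / no variance)."""


def _label(dimension: str, valence: int) -> tuple[float, float]:
    """An adjective contributes its valence on its own dimension, 0 on the other."""
    if dimension == WARMTH:
        return float(valence), 0.0
    return 0.0, float(valence)


def build_template_sentences(
    lexicon: ScmLexicon, pair_budget: int = 200, seed: int = 0
) -> list[TemplateSentence]:
    """One single-adjective sentence per lexicon adjective, plus sampled pairs.

    Pairs are drawn only within a (dimension, valence) class — mixed pairs
    would have ambiguous labels — without replacement, up to ``pair_budget``,
    using a seeded generator.  Sentence labels are the mean of the
    constituent adjectives' contributions.
    """
    warm = lexicon.dimension_entries(WARMTH)
    comp = lexicon.dimension_entries(COMPETENCE)
    if not warm or not comp:
        raise ValueError("lexicon needs at least one warmth and one competence entry")

    sentences: list[TemplateSentence] = []
    seen_words: set[tuple[str, str, int]] = set()
    classes: dict[tuple[str, int], list[str]] = {}
    for e in lexicon:
        key = (e.word, e.dimension, e.valence)
        if key in seen_words:
            continue  # same word twice in one (dimension, valence) class
        seen_words.add(key)
        w, c = _label(e.dimension, e.valence)
        sentences.append(
            TemplateSentence(
                text=SINGLE_TEMPLATE.format(adj=e.word),
                warmth_label=w,
                competence_label=c,
                adjectives=(e.word,),
            )
        )
        classes.setdefault((e.dimension, e.valence), []).append(e.word)

    all_pairs: list[tuple[str, int, str, str]] = []
    for (dim, val), words in sorted(classes.items()):
        for a, b in itertools.combinations(sorted(set(words)), 2):
            all_pairs.append((dim, val, a, b))
    rng = np.random.default_rng(seed)
    if pair_budget < len(all_pairs):
        idx = rng.choice(len(all_pairs), size=pair_budget, replace=False)
        chosen = [all_pairs[i] for i in sorted(idx)]
    else:
        chosen = all_pairs
    for dim, val, a, b in chosen:
        wa, ca = _label(dim, val)
        sentences.append(
            TemplateSentence(
                text=PAIR_TEMPLATE.format(adj1=a, adj2=b),
                warmth_label=wa,  # mean of two identical contributions
                competence_label=ca,
                adjectives=(a, b),
            )
        )
    return sentences


@dataclass
class ScmScorer:
    """Fitted linear map from embeddings to (warmth, competence)."""

    pls: PLSRegression
    dim: int
    n_components: int
    train_checksum: str
    meta: dict = field(default_factory=dict)

    def predict(self, vectors: np.ndarray) -> np.ndarray:
        return np.asarray(self.pls.predict(vectors), dtype=float)


def fit_scm_model(
    train: EmbeddingMatrix,
    labels: np.ndarray,
    n_components: int = 25,
) -> ScmScorer:
    """Fit the PLS regression from template embeddings to labels.

    ``labels`` is an (n, 2) array of (warmth, competence) targets that must
    contain both positive and negative examples on each dimension.  The
    effective component count is clamped to the rank of the centered
    training matrix (noise-free synthetic embeddings are deliberately
    low-rank); the value actually used is recorded in the model metadata.
    """
    labels = np.asarray(labels, dtype=float)
    if labels.ndim != 2 or labels.shape[1] != 2:
        raise ValueError("labels must have shape (n, 2)")
    if train.n != labels.shape[0]:
        raise ValueError(f"{train.n} embeddings but {labels.shape[0]} labels")
    for j, name in enumerate((WARMTH, COMPETENCE)):
        if labels[:, j].max() <= 0 or labels[:, j].min() >= 0:
            raise ValueError(
                f"labels need both positive and negative examples on {name} "
                "(no variance on a response dimension)"
            )
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if train.n < n_components + 1:
        raise ValueError(
            f"training matrix has {train.n} rows, too few for "
            f"{n_components} components; use fewer components"
        )
    X = train.vectors
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    if rank == 0:
        raise ValueError("training matrix is rank deficient; use fewer components")
    eff = min(n_components, rank)
    pls = PLSRegression(n_components=eff, scale=False)
    pls.fit(X, labels)
    checksum = hashlib.sha256(
        np.ascontiguousarray(X).tobytes() + np.ascontiguousarray(labels).tobytes()
    ).hexdigest()[:16]
    return ScmScorer(
        pls=pls,
        dim=train.dim,
        n_components=eff,
        train_checksum=checksum,
        meta={
            "requested_components": n_components,
            "effective_components": eff,
            "train_rank": rank,
            "n_train": train.n,
        },
    )


def score_sentences(
    model: ScmScorer, embeddings: EmbeddingMatrix
) -> list[ScmScorePair]:
    """Score sentences; predictions are clipped to [-1, 1].

    The clipping rate is logged and recorded in ``model.meta`` under
    ``last_clip_rate`` so runs can audit how often the linear map leaves the
    nominal scale.
    """
    if embeddings.dim != model.dim:
        raise ValueError(
            f"embedding dim {embeddings.dim} != model training dim {model.dim}"
        )
    if embeddings.n == 0:
        return []
    raw = model.predict(embeddings.vectors)
    clipped = np.clip(raw, -1.0, 1.0)
    clip_rate = float(np.mean(np.any(raw != clipped, axis=1)))
    model.meta["last_clip_rate"] = clip_rate
    if clip_rate > 0:
        logger.info("clipped %.1f%% of score pairs into [-1, 1]", 100 * clip_rate)
    return [
        ScmScorePair(sentence_id=rid, warmth=float(w), competence=float(c))
        for rid, (w, c) in zip(embeddings.row_ids, clipped)
    ]


@dataclass(frozen=True)
class WelchResult:
    F: float
    df1: int
    df2: float
    p_value: float

    def __post_init__(self) -> None:
        if self.F < 0 or self.df1 < 1 or self.df2 <= 0:
            raise ValueError("invalid Welch result")
        if not (0 <= self.p_value <= 1):
            raise ValueError("p_value must lie in [0, 1]")


def welch_anova(groups: list[np.ndarray]) -> WelchResult:
    """Welch's heteroscedastic one-way ANOVA.

    With group means x̄_i, sample variances s_i² (ddof=1), sizes n_i and
    weights w_i = n_i/s_i², W = Σw_i, x̄_w = Σ w_i x̄_i / W:

        F   = [Σ w_i (x̄_i − x̄_w)² / (k−1)]
              / [1 + 2(k−2)/(k²−1) · Σ (1 − w_i/W)²/(n_i−1)]
        df1 = k − 1
        df2 = (k² − 1) / [3 Σ (1 − w_i/W)²/(n_i−1)]

    and the p-value is the upper tail of F(df1, df2).
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise DegenerateGroupError(f"group {i} has n={g.size} < 2")
        if np.var(g, ddof=1) <= 0:
            raise DegenerateGroupError(f"group {i} has zero variance")
    n = np.array([g.size for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    s2 = np.array([g.var(ddof=1) for g in groups])
    w = n / s2
    W = w.sum()
    mw = float((w * m).sum() / W)
    num = float((w * (m - mw) ** 2).sum() / (k - 1))
    lam = float((((1 - w / W) ** 2) / (n - 1)).sum())
    denom = 1.0 + (2.0 * (k - 2) / (k**2 - 1)) * lam
    F = num / denom
    df2 = (k**2 - 1) / (3.0 * lam)
    p = float(stats.f.sf(F, k - 1, df2))
    return WelchResult(F=float(F), df1=k - 1, df2=float(df2), p_value=p)


@dataclass
class AgeScoreSummary:
    """Per-age descriptive statistics plus Welch tests for both dimensions."""

    table: pd.DataFrame
    welch: dict[str, WelchResult | None]
    welch_errors: dict[str, str]


def summarize_scores_by_age(
    scores: list[ScmScorePair], sentence_to_age: dict[str, int]
) -> AgeScoreSummary:
    """Per age: n, mean, sd, quartiles of warmth and competence, plus Welch.

    A dimension whose groups cannot support Welch's test (a group with n < 2
    or zero variance) gets ``None`` with the reason in ``welch_errors``; sd
    for singleton groups is reported as NaN.
    """
    missing = [s.sentence_id for s in scores if s.sentence_id not in sentence_to_age]
    if missing:
        raise ValueError(f"scored sentences without an age: {missing[:5]}")
    df = pd.DataFrame(
        {
            "age": [sentence_to_age[s.sentence_id] for s in scores],
            "warmth": [s.warmth for s in scores],
            "competence": [s.competence for s in scores],
        }
    )
    rows = []
    for age, grp in df.groupby("age"):
        row: dict[str, float] = {"age": age, "n": len(grp)}
        for dim in ("warmth", "competence"):
            v = grp[dim].to_numpy()
            row[f"{dim}_mean"] = float(v.mean())
            row[f"{dim}_sd"] = float(v.std(ddof=1)) if v.size > 1 else float("nan")
            q25, q50, q75 = np.percentile(v, [25, 50, 75])
            row[f"{dim}_q25"] = float(q25)
            row[f"{dim}_median"] = float(q50)
            row[f"{dim}_q75"] = float(q75)
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("age").reset_index(drop=True)

    welch: dict[str, WelchResult | None] = {}
    errors: dict[str, str] = {}
    for dim in ("warmth", "competence"):
        groups = [
            grp[dim].to_numpy() for _, grp in df.groupby("age")
        ]
        try:
            welch[dim] = welch_anova(groups)
        except (DegenerateGroupError, ValueError) as exc:
            welch[dim] = None
            errors[dim] = str(exc)
    return AgeScoreSummary(table=table, welch=welch, welch_errors=errors)
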