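"""Bag-of-words feature generation for citation abstracts.

Tokens are lower-cased, punctuation-split, stopword- and number-free; the
document-term matrix holds raw counts (no tf-idf — term frequency is the
signal the screening models consume). Columns can then be thinned three
ways: a corpus-wide minimum frequency, a per-algorithm variable-importance
ranking, and removal of zero-variance predictors relative to the set being
screened.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .corpus import ValidationError

__all__ = [
    "DocumentTermMatrix",
    "FeatureConfig",
    "load_stopwords",
    "preprocess",
    "build_dtm",
    "filter_min_frequency",
    "remove_zero_variance",
    "top_importance",
    "MIN_FREQUENCY_LEVELS",
    "IMPORTANCE_LEVELS",
]

MIN_FREQUENCY_LEVELS = (5, 10, 100, 500)
IMPORTANCE_LEVELS = (50, 100, 500)


@dataclass
class DocumentTermMatrix:
    """Citations × terms count matrix (sparse, non-negative integers)."""

    row_ids: list[str]
    vocabulary: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.row_ids), len(self.vocabulary)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.vocabulary)} terms"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("negative counts in document-term matrix")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def column_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def total_tokens(self) -> int:
        return int(self.counts.sum())

    def select_columns(self, col_idx: Sequence[int]) -> "DocumentTermMatrix":
        col_idx = list(col_idx)
        return DocumentTermMatrix(
            list(self.row_ids),
            [self.vocabulary[j] for j in col_idx],
            self.counts[:, col_idx],
        )

    def align_to(self, vocabulary: Sequence[str]) -> "DocumentTermMatrix":
        """Reorder/zero-pad columns to match an external term order."""
        pos = {t: j for j, t in enumerate(self.vocabulary)}
        n = len(self.row_ids)
        cols = []
        zero = sp.csr_matrix((n, 1), dtype=np.int64)
        for t in vocabulary:
            cols.append(self.counts[:, [pos[t]]] if t in pos else zero)
        counts = sp.hstack(cols, format="csr") if cols else sp.csr_matrix((n, 0), dtype=np.int64)
        return DocumentTermMatrix(list(self.row_ids), list(vocabulary), counts)

    # -- MTX export / import -------------------------------------------------

    def save(self, prefix) -> None:
        """Write ``<prefix>.mtx`` + ``<prefix>.terms.txt`` + ``<prefix>.rows.txt``."""
        prefix = Path(prefix)
        mmwrite(str(prefix.with_suffix(".mtx")), self.counts.tocoo())
        prefix.with_suffix(".terms.txt").write_text(
            "".join(t + "\n" for t in self.vocabulary), encoding="utf-8"
        )
        prefix.with_suffix(".rows.txt").write_text(
            "".join(r + "\n" for r in self.row_ids), encoding="utf-8"
        )

    @classmethod
    def load(cls, prefix) -> "DocumentTermMatrix":
        prefix = Path(prefix)
        counts = sp.csr_matrix(mmread(str(prefix.with_suffix(".mtx"))))
        terms = prefix.with_suffix(".terms.txt").read_text(encoding="utf-8").splitlines()
        rows = prefix.with_suffix(".rows.txt").read_text(encoding="utf-8").splitlines()
        return cls(rows, terms, counts)


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-thinning setting: a minimum corpus frequency or a top-k
    variable-importance cut (the latter is undefined for the SVM, which has
    no native importance criterion)."""

    mode: str  # "min_frequency" | "importance"
    min_frequency: Optional[int] = None
    importance_k: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mode == "min_frequency":
            if self.min_frequency is None:
                raise ValidationError("min_frequency mode needs a min_frequency value")
        elif self.mode == "importance":
            if self.importance_k is None:
                raise ValidationError("importance mode needs an importance_k value")
        else:
            raise ValidationError(f"unknown feature mode {self.mode!r}")

    def describe(self) -> str:
        if self.mode == "min_frequency":
            return f"freq>={self.min_frequency}"
        return f"top{self.importance_k}"


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"[a-z0-9]+")
_HAS_ALPHA = re.compile(r"[a-z]")


@lru_cache(maxsize=1)
def load_stopwords() -> frozenset:
    """The pinned English stopword list shipped with the package."""
    text = resources.files("slrscreen.data").joinpath("stopwords_en.txt").read_text("utf-8")
    return frozenset(
        w for w in (line.strip() for line in text.splitlines())
        if w and not w.startswith("#")
    )


def preprocess(text: str, stopwords: Optional[frozenset] = None) -> list[str]:
    """Lowercase, strip punctuation, drop stopwords and pure numbers.

    Tokens are maximal runs of [a-z0-9] after lower-casing; a token must
    contain at least one letter (so "80" is dropped but "her2" survives).
    Surviving tokens keep their in-document order and multiplicity.
    """
    if stopwords is None:
        stopwords = load_stopwords()
    return [
        tok
        for tok in _TOKEN.findall(text.lower())
        if _HAS_ALPHA.search(tok) and tok not in stopwords
    ]


def build_dtm(token_lists: Sequence[Sequence[str]], row_ids: Sequence[str]) -> DocumentTermMatrix:
    """Count term occurrences per document over the sorted union vocabulary."""
    if len(token_lists) != len(row_ids):
        raise ValidationError("one token list per row id required")
    if len(set(row_ids)) != len(row_ids):
        raise ValidationError("duplicate row ids in document-term matrix")
    vocab = sorted({t for toks in token_lists for t in toks})
    col = {t: j for j, t in enumerate(vocab)}
    rows, cols, data = [], [], []
    for i, toks in enumerate(token_lists):
        tally: dict[str, int] = {}
        for t in toks:
            tally[t] = tally.get(t, 0) + 1
        for t, n in tally.items():
            rows.append(i)
            cols.append(col[t])
            data.append(n)
    counts = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(row_ids), len(vocab)), dtype=np.int64
    )
    return DocumentTermMatrix(list(row_ids), vocab, counts)


# ---------------------------------------------------------------------------
# Column filters
# ---------------------------------------------------------------------------


def filter_min_frequency(dtm: DocumentTermMatrix, min_count: int) -> DocumentTermMatrix:
    """Drop terms whose corpus-wide total count is below ``min_count``."""
    if min_count < 1:
        raise ValidationError("min_count must be >= 1")
    totals = dtm.column_totals()
    keep = np.flatnonzero(totals >= min_count)
    return dtm.select_columns(keep)


def remove_zero_variance(
    train: DocumentTermMatrix, test: DocumentTermMatrix
) -> tuple[DocumentTermMatrix, DocumentTermMatrix]:
    """Drop zero-variance predictors from both matrices.

    A term is removed when it is constant across all training rows (a
    single level carries no signal and destabilizes some fits) or when it
    appears exclusively in one of the two sets. Both matrices come back on
    the same surviving vocabulary, identically ordered.
    """
    if len(train.row_ids) == 0 or len(test.row_ids) == 0:
        raise ValidationError("zero-variance removal needs non-empty train and test sets")
    union = sorted(set(train.vocabulary) | set(test.vocabulary))
    tr = train.align_to(union)
    te = test.align_to(union)
    dense_tr = np.asarray(tr.counts.todense())
    constant = (dense_tr == dense_tr[0, :]).all(axis=0)
    train_tot = dense_tr.sum(axis=0)
    test_tot = te.column_totals()
    keep = np.flatnonzero(~constant & (train_tot > 0) & (test_tot > 0))
    return tr.select_columns(keep), te.select_columns(keep)


def _nb_importance(X: np.ndarray, y: np.ndarray, laplace: float = 1.0) -> np.ndarray:
    """Per-term class-separation score for naive Bayes: the absolute gap
    between class-conditional log term probabilities (Laplace-smoothed
    term-frequency shares within each class)."""
    scores = np.empty(X.shape[1])
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValidationError("importance ranking needs exactly two classes")
    logp = []
    for c in classes:
        tot = X[y == c].sum(axis=0).astype(float) + laplace
        logp.append(np.log(tot / tot.sum()))
    scores = np.abs(logp[0] - logp[1])
    return scores


def _cart_importance(X: np.ndarray, y: np.ndarray, seed: int, n_bags: int = 25) -> np.ndarray:
    from sklearn.ensemble import BaggingClassifier
    from sklearn.tree import DecisionTreeClassifier

    bag = BaggingClassifier(
        estimator=DecisionTreeClassifier(random_state=seed),
        n_estimators=n_bags,
        random_state=seed,
    ).fit(X, y)
    return np.mean([est.feature_importances_ for est in bag.estimators_], axis=0)


def top_importance(
    dtm: DocumentTermMatrix,
    labels: Sequence[str],
    algorithm: str,
    k: int,
    seed: int = 0,
) -> DocumentTermMatrix:
    """Keep the ``k`` terms with the highest variable importance.

    The criterion is algorithm-specific: bagged CART uses mean decrease in
    impurity averaged over the bags; naive Bayes uses the class-separation
    score of the term's smoothed class-conditional probabilities. The SVM
    has no importance criterion, so importance mode is rejected for it.
    Ties break lexicographically; surviving columns stay in vocabulary
    order.
    """
    if algorithm == "svm":
        raise ValidationError("variable-importance feature selection is not applicable to the SVM")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if len(labels) != len(dtm.row_ids):
        raise ValidationError("one label per matrix row required")
    X = np.asarray(dtm.counts.todense(), dtype=float)
    y = np.asarray(labels)
    if algorithm == "naive_bayes":
        scores = _nb_importance(X, y)
    elif algorithm == "bagged_cart":
        scores = _cart_importance(X, y, seed)
    else:
        raise ValidationError(f"unknown algorithm {algorithm!r}")
    order = sorted(range(len(scores)), key=lambda j: (-scores[j], dtm.vocabulary[j]))
    keep = sorted(order[: min(k, len(order))])
    return dtm.select_columns(keep)
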