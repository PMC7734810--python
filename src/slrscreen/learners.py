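"""Classifiers for include/exclude screening: downsampling, grid tuning, prediction.

Three algorithms are supported, each emitting a probability that a citation
is an exclude:

* ``svm`` — linear support vector machine; the cost parameter is tuned over
  {0.25, 1, 2, 8, 32, 256} and probabilities come from a Platt-style
  sigmoid calibrated on the training data.
* ``naive_bayes`` — per-term count model with Gaussian ("no kernel") or
  kernel-density ("kernel") class-conditional likelihoods and a Laplace
  adjustment that keeps rare-feature likelihoods away from zero; the
  kernel flag and the Laplace weight {0, 0.5, 1} are tuned.
* ``bagged_cart`` — 25 bootstrap-bagged unpruned classification trees; the
  exclusion probability is the fraction of bags voting exclude. No tuning
  metric applies.

Tuning evaluates every grid point with stratified k-fold cross-validation
(default ten folds, fold assignment re-randomized per run) on either mean
fold ROC AUC or mean fold sensitivity of the include class at the 0.5
posterior cut, then refits the winner on all the data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import joblib
import numpy as np
import scipy.sparse as sp
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import BaggingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .corpus import ValidationError
from .textfeat import DocumentTermMatrix

__all__ = [
    "AlgorithmSpec",
    "FittedClassifier",
    "TUNE_METRICS",
    "downsample",
    "tune_and_train",
    "predict_exclusion_prob",
    "save_classifier",
    "load_classifier",
]

TUNE_METRICS = ("roc", "sensitivity")

_SD_FLOOR = 1e-3  # smallest per-term standard deviation / bandwidth


@dataclass(frozen=True)
class AlgorithmSpec:
    """A named algorithm with its tuning-parameter candidate grid."""

    name: str
    svm_costs: tuple = (0.25, 1, 2, 8, 32, 256)
    nb_kernels: tuple = ("no", "yes")
    nb_laplaces: tuple = (0, 0.5, 1)
    cart_bags: int = 25

    def __post_init__(self) -> None:
        if self.name not in ("svm", "naive_bayes", "bagged_cart"):
            raise ValidationError(f"unknown algorithm {self.name!r}")
        if self.name == "svm" and not self.svm_costs:
            raise ValidationError("svm grid must be non-empty")
        if self.name == "naive_bayes" and not (self.nb_kernels and self.nb_laplaces):
            raise ValidationError("naive_bayes grid must be non-empty")
        if self.name == "bagged_cart" and self.cart_bags < 1:
            raise ValidationError("cart_bags must be >= 1")

    def grid(self) -> list[dict]:
        """Candidate parameter points, in declared (tie-break) order."""
        if self.name == "svm":
            return [{"cost": c} for c in self.svm_costs]
        if self.name == "naive_bayes":
            return [
                {"kernel": k, "laplace": l}
                for k, l in itertools.product(self.nb_kernels, self.nb_laplaces)
            ]
        return [{"n_bags": self.cart_bags}]


@dataclass
class FittedClassifier:
    """A tuned, refit model bound to a term order."""

    algorithm: str
    selected_params: dict
    cv_score: float
    vocabulary: list[str]
    model: object
    tune_metric: Optional[str] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.cv_score):
            raise ValidationError("cv_score must be finite")


# ---------------------------------------------------------------------------
# Downsampling
# ---------------------------------------------------------------------------


def downsample(
    features: sp.spmatrix, labels: Sequence[str], seed: int
) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
    """Balance the classes 1:1 by random removal from the majority class.

    In the overall include/exclude task the excludes vastly outnumber the
    includes, so every include is retained and a seeded uniform sample of
    excludes (without replacement) matches their count. The rule is
    symmetric: whichever class is larger is thinned to the size of the
    smaller. Returns ``(features, labels, kept_row_indices)`` with row
    order preserved.
    """
    y = np.asarray(labels)
    inc = np.flatnonzero(y == "include")
    exc = np.flatnonzero(y == "exclude")
    if inc.size == 0:
        raise ValidationError("cannot downsample with zero includes")
    if inc.size + exc.size != y.size:
        raise ValidationError("labels must be binary include/exclude")
    rng = np.random.default_rng(seed)
    if exc.size >= inc.size:
        keep_major = rng.choice(exc, size=inc.size, replace=False)
        kept = np.sort(np.concatenate([inc, keep_major]))
    else:
        keep_major = rng.choice(inc, size=exc.size, replace=False)
        kept = np.sort(np.concatenate([exc, keep_major]))
    X = sp.csr_matrix(features)[kept]
    return X, y[kept], kept


# ---------------------------------------------------------------------------
# Naive Bayes (authored here: klaR-style kernel / Gaussian count model)
# ---------------------------------------------------------------------------


class NaiveBayesCounts:
    """Naive Bayes over term counts with two per-term density families.

    "no kernel": Gaussian per term and class (standard deviation floored at
    ``_SD_FLOOR`` so constant columns stay finite). "kernel": Gaussian
    kernel density estimate over the class's observed counts, Silverman
    bandwidth, same floor.

    The Laplace weight ``laplace`` smooths every per-term likelihood as
    ``(n_c * f(x) + laplace) / (n_c + laplace)`` with ``n_c`` the class
    size; with ``laplace > 0`` no single rare feature can zero out a
    posterior (the model is multiplicative across terms).
    """

    def __init__(self, kernel: bool, laplace: float):
        self.kernel = kernel
        self.laplace = float(laplace)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NaiveBayesCounts":
        self.classes_ = np.array(sorted(np.unique(y)))
        if len(self.classes_) != 2:
            raise ValidationError("naive Bayes needs two classes in training data")
        self.priors_ = {}
        self.n_ = {}
        self.params_ = {}
        for c in self.classes_:
            Xc = X[y == c]
            self.n_[c] = Xc.shape[0]
            self.priors_[c] = Xc.shape[0] / X.shape[0]
            if self.kernel:
                # per-term weighted support points (counts are heavily tied)
                cols = []
                for j in range(X.shape[1]):
                    vals, cnts = np.unique(Xc[:, j], return_counts=True)
                    sd = max(float(Xc[:, j].std(ddof=1)) if Xc.shape[0] > 1 else 0.0, 0.0)
                    h = max(0.9 * sd * Xc.shape[0] ** (-1 / 5), _SD_FLOOR)
                    cols.append((vals, cnts / cnts.sum(), h))
                self.params_[c] = cols
            else:
                mu = Xc.mean(axis=0)
                sd = np.maximum(Xc.std(axis=0, ddof=0), _SD_FLOOR)
                self.params_[c] = (mu, sd)
        return self

    def _log_likelihood(self, X: np.ndarray, c) -> np.ndarray:
        n_c = self.n_[c]
        lam = self.laplace
        if self.kernel:
            ll = np.zeros(X.shape[0])
            for j, (vals, w, h) in enumerate(self.params_[c]):
                z = (X[:, [j]] - vals[None, :]) / h
                f = (w[None, :] * np.exp(-0.5 * z**2)).sum(axis=1) / (h * np.sqrt(2 * np.pi))
                f = (n_c * f + lam) / (n_c + lam) if lam > 0 else f
                ll += np.log(np.maximum(f, 1e-300))
            return ll
        mu, sd = self.params_[c]
        f = np.exp(-0.5 * ((X - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
        if lam > 0:
            f = (n_c * f + lam) / (n_c + lam)
        return np.log(np.maximum(f, 1e-300)).sum(axis=1)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Columns follow ``classes_`` (sorted: exclude, include)."""
        logp = np.column_stack(
            [np.log(self.priors_[c]) + self._log_likelihood(X, c) for c in self.classes_]
        )
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Fitting and scoring helpers
# ---------------------------------------------------------------------------


def _fit_one(algorithm: str, params: dict, X, y: np.ndarray, seed: int, need_proba: bool):
    """Fit one grid point. Returns an object exposing exclusion scores."""
    if algorithm == "svm":
        svc = SVC(kernel="linear", C=params["cost"], random_state=seed)
        if not need_proba:
            return svc.fit(X, y)
        # Platt-style sigmoid calibration fit within the training data
        y_arr = np.asarray(y)
        min_class = min(int((y_arr == c).sum()) for c in np.unique(y_arr))
        est = CalibratedClassifierCV(
            svc, method="sigmoid", cv=min(5, min_class), ensemble=False
        )
        return est.fit(X, y)
    if algorithm == "naive_bayes":
        est = NaiveBayesCounts(kernel=params["kernel"] == "yes", laplace=params["laplace"])
        return est.fit(_dense(X), y)
    est = BaggingClassifier(
        estimator=DecisionTreeClassifier(random_state=seed),
        n_estimators=params["n_bags"],
        random_state=seed,
    )
    return est.fit(_dense(X), y)


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense(), dtype=float) if sp.issparse(X) else np.asarray(X, dtype=float)


def _exclusion_scores(algorithm: str, est, X, proba: bool) -> np.ndarray:
    """Ranking scores (or probabilities) for the exclude class."""
    if algorithm == "svm":
        if proba:
            j = list(est.classes_).index("exclude")
            return est.predict_proba(X)[:, j]
        sign = 1.0 if est.classes_[1] == "exclude" else -1.0
        return sign * est.decision_function(X)
    if algorithm == "naive_bayes":
        j = list(est.classes_).index("exclude")
        return est.predict_proba(_dense(X))[:, j]
    # bagged CART: fraction of bags voting exclude (sub-estimators predict
    # label-encoded classes, indices into est.classes_)
    Xd = _dense(X)
    j = list(est.classes_).index("exclude")
    votes = np.mean([t.predict(Xd) == j for t in est.estimators_], axis=0)
    return votes


def _fold_metric(metric: str, y_val: np.ndarray, scores: np.ndarray) -> float:
    if metric == "roc":
        return float(roc_auc_score(y_val == "exclude", scores))
    # sensitivity of the include class at the 0.5 posterior cut
    inc = y_val == "include"
    predicted_include = scores < 0.5
    return float(predicted_include[inc].mean())


def tune_and_train(
    features,
    labels: Sequence[str],
    spec: AlgorithmSpec,
    metric: Optional[str] = None,
    folds: int = 10,
    seed: int = 0,
    vocabulary: Optional[Sequence[str]] = None,
) -> FittedClassifier:
    """Grid-tune by stratified k-fold CV and refit the winner on all data.

    ``metric`` must be ``"roc"`` or ``"sensitivity"`` for svm/naive_bayes
    and absent for bagged_cart (which has nothing to tune; its single grid
    point is still cross-validated so the recorded score is meaningful).
    Ties go to the earlier grid point in declared order.
    """
    y = np.asarray(labels)
    X = sp.csr_matrix(features)
    if spec.name == "bagged_cart":
        if metric is not None:
            raise ValidationError("tuning metric is not applicable to bagged CART")
        eval_metric = "roc"
    else:
        if metric not in TUNE_METRICS:
            raise ValidationError(f"metric must be one of {TUNE_METRICS}, got {metric!r}")
        eval_metric = metric
    if folds < 2:
        raise ValidationError("folds must be >= 2")
    class_counts = {c: int((y == c).sum()) for c in np.unique(y)}
    if len(class_counts) != 2:
        raise ValidationError("training labels must contain both classes")
    if min(class_counts.values()) < folds:
        raise ValidationError(
            f"a CV fold would lack a class (class counts {class_counts}, folds={folds}); "
            "use more data or fewer folds"
        )

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**32))
    splits = list(skf.split(np.zeros(len(y)), y))
    need_proba = eval_metric == "sensitivity"

    best_params, best_score = None, -np.inf
    for gp_seed, params in enumerate(spec.grid()):
        fold_scores = []
        for tr_idx, va_idx in splits:
            est = _fit_one(spec.name, params, X[tr_idx], y[tr_idx], seed + gp_seed, need_proba)
            scores = _exclusion_scores(spec.name, est, X[va_idx], proba=need_proba)
            fold_scores.append(_fold_metric(eval_metric, y[va_idx], scores))
        mean_score = float(np.mean(fold_scores))
        if mean_score > best_score:  # strict: ties keep the earlier point
            best_params, best_score = params, mean_score

    final = _fit_one(spec.name, best_params, X, y, seed, need_proba=True)
    return FittedClassifier(
        algorithm=spec.name,
        selected_params=best_params,
        cv_score=best_score,
        vocabulary=list(vocabulary) if vocabulary is not None else [],
        model=final,
        tune_metric=metric,
    )


def predict_exclusion_prob(fc: FittedClassifier, features) -> np.ndarray:
    """Per-row probability of exclusion, in input order.

    ``features`` may be a :class:`DocumentTermMatrix` (re-ordered or
    zero-padded to the model's vocabulary binding) or a raw matrix already
    aligned to it.
    """
    if isinstance(features, DocumentTermMatrix):
        if not fc.vocabulary:
            raise ValidationError("classifier has no vocabulary binding to align to")
        X = features.align_to(fc.vocabulary).counts
    else:
        X = sp.csr_matrix(features)
        if fc.vocabulary and X.shape[1] != len(fc.vocabulary):
            raise ValidationError(
                f"feature matrix has {X.shape[1]} columns but the model expects "
                f"{len(fc.vocabulary)}"
            )
    p = _exclusion_scores(fc.algorithm, fc.model, X, proba=True)
    return np.clip(p, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_ARCHIVE_VERSION = 1


def save_classifier(fc: FittedClassifier, path) -> None:
    """Write a self-describing archive (versioned header + fitted state)."""
    joblib.dump(
        {
            "format": "slrscreen-classifier",
            "version": _ARCHIVE_VERSION,
            "algorithm": fc.algorithm,
            "selected_params": fc.selected_params,
            "cv_score": fc.cv_score,
            "tune_metric": fc.tune_metric,
            "vocabulary": fc.vocabulary,
            "model": fc.model,
        },
        path,
    )


def load_classifier(path) -> FittedClassifier:
    blob = joblib.load(path)
    if blob.get("format") != "slrscreen-classifier" or blob.get("version") != _ARCHIVE_VERSION:
        raise ValidationError(f"{path}: not a recognized classifier archive")
    return FittedClassifier(
        algorithm=blob["algorithm"],
        selected_params=blob["selected_params"],
        cv_score=blob["cv_score"],
        vocabulary=blob["vocabulary"],
        model=blob["model"],
        tune_metric=blob["tune_metric"],
    )
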