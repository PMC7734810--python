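"""The two-stage screening cascade: exclude with a PICOS reason, or defer.

Stage one is an overall include/exclude classifier. Only when it puts the
probability of exclusion at or above the decision threshold (default 0.90)
are the pairwise reason models consulted: one include-vs-reason classifier
per exclusion reason present in the training labels. A citation is
auto-excluded only if at least one reason model also clears the threshold;
the reason reported is the highest-priority qualifying reason under the
fixed hierarchy (study design first, time last). A citation the overall
model wants to exclude but no reason model can justify is left
``unclassified`` for a human reviewer; everything below the overall
threshold is emitted as ``include`` (meaning: not auto-excluded).
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import joblib
import numpy as np

from .corpus import (
    HIERARCHY,
    Citation,
    ExclusionReason,
    LabelScheme,
    LabelledDataset,
    ValidationError,
)
from .learners import (
    AlgorithmSpec,
    FittedClassifier,
    downsample,
    predict_exclusion_prob,
    tune_and_train,
)
from .textfeat import (
    DocumentTermMatrix,
    FeatureConfig,
    build_dtm,
    filter_min_frequency,
    preprocess,
    remove_zero_variance,
    top_importance,
)

__all__ = [
    "ScreeningModelConfig",
    "ScreeningModel",
    "ScreeningDecision",
    "featurize",
    "fit_screening_model",
    "classify",
    "screen",
    "select_threshold",
    "write_decisions",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ScreeningModelConfig:
    """Everything needed to fit a screening model reproducibly."""

    scheme: LabelScheme
    feature_config: FeatureConfig
    algorithm: AlgorithmSpec
    metric: Optional[str] = None
    downsample: bool = True
    threshold: float = 0.90
    folds: int = 10
    seed: int = 0
    include_title: bool = False  # prepend the title to the abstract text

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValidationError("threshold must be in (0, 1)")
        if self.algorithm.name == "bagged_cart" and self.metric is not None:
            raise ValidationError("tuning metric is not applicable to bagged CART")
        if self.algorithm.name != "bagged_cart" and self.metric is None:
            raise ValidationError(f"{self.algorithm.name} requires a tuning metric")
        if self.algorithm.name == "svm" and self.feature_config.mode == "importance":
            raise ValidationError("importance feature selection is not applicable to the SVM")


@dataclass
class ScreeningModel:
    """Fitted cascade: overall model + per-reason pairwise models."""

    overall: FittedClassifier
    reason_models: dict[ExclusionReason, FittedClassifier]
    threshold: float
    vocabulary: list[str]
    config: ScreeningModelConfig
    degenerate: bool = False  # no reason models could be fit

    def __post_init__(self) -> None:
        for r, fc in self.reason_models.items():
            if fc.vocabulary != self.vocabulary:
                raise ValidationError(f"reason model {r.value} has a mismatched vocabulary")


@dataclass
class ScreeningDecision:
    """The cascade's verdict for one citation."""

    citation_id: str
    outcome: str  # "include" | "exclude" | "unclassified"
    reason: Optional[ExclusionReason]
    overall_prob: float
    reason_probs: dict[ExclusionReason, float]

    def __post_init__(self) -> None:
        if self.outcome not in ("include", "exclude", "unclassified"):
            raise ValidationError(f"bad outcome {self.outcome!r}")
        if (self.outcome == "exclude") != (self.reason is not None):
            raise ValidationError("a reason is carried iff the outcome is exclude")


def featurize(
    citations: Sequence[Citation],
    include_title: bool = False,
    vocabulary: Optional[Sequence[str]] = None,
) -> DocumentTermMatrix:
    """Tokenize citations and build their document-term matrix; optionally
    align it to an existing model vocabulary."""
    texts = [
        (c.title + " " + c.abstract) if include_title else c.abstract for c in citations
    ]
    dtm = build_dtm([preprocess(t) for t in texts], [c.id for c in citations])
    if vocabulary is not None:
        dtm = dtm.align_to(vocabulary)
    return dtm


def _train_component(
    X, y, config: ScreeningModelConfig, vocabulary, seed: int
) -> FittedClassifier:
    if config.downsample:
        X, y, _ = downsample(X, y, seed)
    return tune_and_train(
        X,
        y,
        config.algorithm,
        metric=config.metric,
        folds=config.folds,
        seed=seed,
        vocabulary=vocabulary,
    )


def fit_screening_model(
    train: LabelledDataset,
    config: ScreeningModelConfig,
    screening_set: Optional[Sequence[Citation]] = None,
) -> ScreeningModel:
    """Fit the full cascade on a labelled training set.

    The feature pipeline (tokenize, count, frequency or importance filter,
    zero-variance removal against ``screening_set`` when one is supplied)
    runs once; all component models share the resulting vocabulary. The
    overall model learns include vs exclude; each pairwise model learns
    include vs one specific reason on the subset of includes plus excludes
    for that reason. Downsampling, when configured, is applied within each
    component's own training rows.
    """
    if train.n_includes == 0 or train.n_excludes == 0:
        raise ValidationError("training data must contain at least one include and one exclude")

    dtm = featurize(train.citations, include_title=config.include_title)
    y = np.array([lb.decision for lb in train.labels])
    fc = config.feature_config
    if fc.mode == "min_frequency":
        dtm = filter_min_frequency(dtm, fc.min_frequency)
    else:
        dtm = top_importance(dtm, y, config.algorithm.name, fc.importance_k, seed=config.seed)
    if screening_set is not None and len(screening_set) > 0:
        test_dtm = featurize(screening_set, include_title=config.include_title)
        dtm, _ = remove_zero_variance(dtm, test_dtm)
    vocabulary = list(dtm.vocabulary)
    X = dtm.counts

    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(0, 2**31 - 1, size=1 + len(HIERARCHY))

    overall = _train_component(X, y, config, vocabulary, int(seeds[0]))

    reason_models: dict[ExclusionReason, FittedClassifier] = {}
    include_idx = np.flatnonzero(y == "include")
    for k, reason in enumerate(HIERARCHY):
        r_idx = np.flatnonzero(
            np.array([lb.reason is reason for lb in train.labels])
        )
        if r_idx.size == 0:
            continue
        subset = np.sort(np.concatenate([include_idx, r_idx]))
        try:
            reason_models[reason] = _train_component(
                X[subset], y[subset], config, vocabulary, int(seeds[1 + k])
            )
        except ValidationError as exc:
            warnings.warn(
                f"pairwise model for {reason.value!r} could not be fit: {exc}", stacklevel=2
            )
    degenerate = not reason_models
    if degenerate:
        warnings.warn(
            "no pairwise reason models could be fit; cascade degenerates to overall-only",
            stacklevel=2,
        )
    return ScreeningModel(
        overall=overall,
        reason_models=reason_models,
        threshold=config.threshold,
        vocabulary=vocabulary,
        config=config,
        degenerate=degenerate,
    )


def resolve_reason(
    qualifying: Sequence[ExclusionReason],
) -> Optional[ExclusionReason]:
    """Highest-priority reason under the hierarchy, or None if none qualify."""
    best = None
    for r in qualifying:
        if best is None or r.priority < best.priority:
            best = r
    return best


def _decide(
    citation_id: str,
    overall_p: float,
    reason_p: dict[ExclusionReason, float],
    threshold: float,
) -> ScreeningDecision:
    if overall_p < threshold:
        return ScreeningDecision(citation_id, "include", None, overall_p, reason_p)
    qualifying = [r for r, p in reason_p.items() if p >= threshold]
    reason = resolve_reason(qualifying)
    if reason is None:
        return ScreeningDecision(citation_id, "unclassified", None, overall_p, reason_p)
    return ScreeningDecision(citation_id, "exclude", reason, overall_p, reason_p)


def classify(model: ScreeningModel, features: DocumentTermMatrix) -> list[ScreeningDecision]:
    """Apply the cascade to feature rows already extracted for citations.

    The stage-one probability gates stage two; the threshold comparison is
    inclusive (a probability exactly at the threshold qualifies).
    """
    aligned = features.align_to(model.vocabulary)
    overall_p = predict_exclusion_prob(model.overall, aligned.counts)
    reason_p = {
        r: predict_exclusion_prob(fc, aligned.counts) for r, fc in model.reason_models.items()
    }
    out = []
    for i, cid in enumerate(aligned.row_ids):
        out.append(
            _decide(
                cid,
                float(overall_p[i]),
                {r: float(p[i]) for r, p in reason_p.items()},
                model.threshold,
            )
        )
    return out


def screen(model: ScreeningModel, test: LabelledDataset | Sequence[Citation]) -> list[ScreeningDecision]:
    """Screen a collection of citations: one decision per citation, in order."""
    citations = test.citations if isinstance(test, LabelledDataset) else list(test)
    if not citations:
        return []
    dtm = featurize(citations, include_title=model.config.include_title)
    return classify(model, dtm)


def select_threshold(roc_points: Sequence[tuple[float, float, float]]) -> float:
    """Pick the threshold of the ROC point closest to the (0, 1) corner.

    ``roc_points`` are ``(false_positive_rate, true_positive_rate,
    threshold)`` triples; ties break toward the higher threshold.
    """
    if not roc_points:
        raise ValidationError("cannot select a threshold from an empty ROC point set")
    best = None
    for fpr, tpr, thr in roc_points:
        if not (0.0 <= fpr <= 1.0 and 0.0 <= tpr <= 1.0):
            raise ValidationError(f"ROC rates must lie in [0, 1]; got ({fpr}, {tpr})")
        d = math.hypot(fpr, 1.0 - tpr)
        if best is None or d < best[0] - 1e-12 or (abs(d - best[0]) <= 1e-12 and thr > best[1]):
            best = (d, thr)
    return best[1]


def write_decisions(decisions: Sequence[ScreeningDecision], path) -> None:
    """Export decisions as CSV: id, outcome, reason, overall probability,
    one column per reason probability."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            ["id", "outcome", "reason", "overall_prob"]
            + [f"prob_{r.value}" for r in HIERARCHY]
        )
        for d in decisions:
            writer.writerow(
                [
                    d.citation_id,
                    d.outcome,
                    d.reason.value if d.reason else "",
                    f"{d.overall_prob:.6f}",
                ]
                + [
                    f"{d.reason_probs[r]:.6f}" if r in d.reason_probs else ""
                    for r in HIERARCHY
                ]
            )


def save_model(model: ScreeningModel, path) -> None:
    joblib.dump({"format": "slrscreen-model", "version": 1, "model": model}, path)


def load_model(path) -> ScreeningModel:
    blob = joblib.load(path)
    if blob.get("format") != "slrscreen-model":
        raise ValidationError(f"{path}: not a screening-model archive")
    return blob["model"]
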