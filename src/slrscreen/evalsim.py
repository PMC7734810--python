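"""Evaluation metrics and the factorial simulation harness.

The confusion counts use the screening-specific definitions, always taken
relative to the final (full-text) decision:

* TP — a true include the cascade did **not** auto-exclude (outcome
  include or unclassified; either way a human still sees it);
* FN — a true include auto-excluded with a reason (the costly error);
* TN — a true exclude auto-excluded with a reason (the work saved);
* FP — a true exclude left for the human (outcome include or unclassified).

So sensitivity = TP/(TP+FN) is the share of true includes the machine did
not throw away, and specificity = TN/(TN+FP) is the share of true excludes
it cleared automatically.

The harness enumerates the full factor grid — datasets × three labelling
schemes × downsampling on/off × seven feature settings × three algorithms
× tuning metrics — with the two structural exclusions (no importance mode
for the SVM, no tuning metric for bagged CART), runs each cell end to end,
and compares factor levels with paired t-tests over matched cells.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .corpus import (
    Citation,
    ExclusionReason,
    LabelScheme,
    LabelledDataset,
    SplitSpec,
    ValidationError,
    deduplicate,
    derive_labels,
    stratified_split,
)
from .learners import AlgorithmSpec, TUNE_METRICS
from .screener import (
    ScreeningDecision,
    ScreeningModelConfig,
    fit_screening_model,
    screen,
)
from .textfeat import (
    IMPORTANCE_LEVELS,
    MIN_FREQUENCY_LEVELS,
    FeatureConfig,
)

__all__ = [
    "ConfusionCounts",
    "PerformanceReport",
    "ScenarioConfig",
    "ScenarioResult",
    "PairedTestResult",
    "confusion_counts",
    "performance_metrics",
    "reason_metrics",
    "enumerate_scenarios",
    "run_scenarios",
    "paired_factor_test",
    "ALGORITHM_NAMES",
]

ALGORITHM_NAMES = ("svm", "naive_bayes", "bagged_cart")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class PerformanceReport:
    """Ratio metrics; a ``None`` field means its denominator was zero."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    precision: Optional[float]
    accuracy: Optional[float]
    excluded_with_reason_rate: Optional[float] = None
    correct_reason_rate: Optional[float] = None
    correct_reason_strict_rate: Optional[float] = None


def confusion_counts(
    decisions: Sequence[ScreeningDecision], citations: Sequence[Citation]
) -> ConfusionCounts:
    """Tally the screening confusion matrix against full-text truth."""
    truth = {c.id: c.true_include for c in citations}
    tp = fn = tn = fp = 0
    for d in decisions:
        if d.citation_id not in truth:
            raise ValidationError(f"decision for unknown citation id {d.citation_id!r}")
        auto_excluded = d.outcome == "exclude"
        if truth[d.citation_id]:
            if auto_excluded:
                fn += 1
            else:
                tp += 1
        else:
            if auto_excluded:
                tn += 1
            else:
                fp += 1
    return ConfusionCounts(tp, fn, tn, fp)


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den else None


def performance_metrics(counts: ConfusionCounts) -> PerformanceReport:
    """Sensitivity, specificity, precision, accuracy from the counts."""
    return PerformanceReport(
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn),
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
        precision=_ratio(counts.tp, counts.tp + counts.fp),
        accuracy=_ratio(counts.tp + counts.tn, counts.total),
    )


def reason_metrics(
    decisions: Sequence[ScreeningDecision],
    citations: Sequence[Citation],
    threshold: float,
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """Reason-level quality of the cascade's second stage.

    Returns ``(excluded_with_reason_rate, correct_reason_rate,
    correct_reason_strict_rate)``:

    * excluded_with_reason_rate — of the citations the overall model put at
      or above the threshold (stage-1 excludes), the share that also
      cleared a reason model and were therefore auto-excluded;
    * correct_reason_rate — among auto-excluded citations that are truly
      excludes, the share whose *reviewer* reason's pairwise probability
      cleared the threshold (the reviewer reason was available to the
      cascade, even if the hierarchy reported another qualifying reason);
    * correct_reason_strict_rate — same denominator, but requiring the
      reported reason to equal the reviewer reason exactly.
    """
    truth = {c.id: c for c in citations}
    stage1 = [d for d in decisions if d.overall_prob >= threshold]
    reasoned = [d for d in stage1 if d.outcome == "exclude"]
    ewr = _ratio(len(reasoned), len(stage1))

    true_excl = [
        d for d in reasoned if d.citation_id in truth and not truth[d.citation_id].true_include
    ]
    n_correct = n_strict = 0
    for d in true_excl:
        rev = truth[d.citation_id].true_reason
        if rev is not None and d.reason_probs.get(rev, 0.0) >= threshold:
            n_correct += 1
        if rev is not None and d.reason is rev:
            n_strict += 1
    crr = _ratio(n_correct, len(true_excl))
    crs = _ratio(n_strict, len(true_excl))
    return ewr, crr, crs


# ---------------------------------------------------------------------------
# Scenario grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the factorial experiment."""

    dataset_tag: str
    scheme: LabelScheme
    downsample: bool
    feature_config: FeatureConfig
    algorithm: str
    metric: Optional[str]

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHM_NAMES:
            raise ValidationError(f"unknown algorithm {self.algorithm!r}")
        if self.algorithm == "svm" and self.feature_config.mode == "importance":
            raise ValidationError("svm cannot be paired with importance feature selection")
        if (self.algorithm == "bagged_cart") != (self.metric is None):
            raise ValidationError("a tuning metric is required except for bagged CART")

    def key_without(self, factor: str) -> tuple:
        """Hashable identity of every factor except ``factor`` (for pairing)."""
        fields_ = {
            "dataset_tag": self.dataset_tag,
            "scheme": self.scheme,
            "downsample": self.downsample,
            "feature_config": self.feature_config,
            "algorithm": self.algorithm,
            "metric": self.metric,
        }
        if factor not in fields_:
            raise ValidationError(f"unknown factor {factor!r}")
        del fields_[factor]
        return tuple(sorted(fields_.items(), key=lambda kv: kv[0]))

    def factor_level(self, factor: str):
        return getattr(self, factor)


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    report: Optional[PerformanceReport]
    counts: Optional[ConfusionCounts]
    runtime_s: float = 0.0
    error: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.error is None


def default_feature_grid() -> list[FeatureConfig]:
    """The seven feature settings: four frequency cuts + three top-k cuts."""
    return [FeatureConfig("min_frequency", min_frequency=m) for m in MIN_FREQUENCY_LEVELS] + [
        FeatureConfig("importance", importance_k=k) for k in IMPORTANCE_LEVELS
    ]


def enumerate_scenarios(
    dataset_tags: Sequence[str],
    schemes: Sequence[LabelScheme] = tuple(LabelScheme),
    downsampling: Sequence[bool] = (True, False),
    feature_grid: Optional[Sequence[FeatureConfig]] = None,
    algorithms: Sequence[str] = ALGORITHM_NAMES,
    metrics: Sequence[str] = TUNE_METRICS,
) -> list[ScenarioConfig]:
    """Cross the factor levels, dropping structurally invalid combinations.

    With five datasets and the full default grid this yields 870 cells:
    naive Bayes 5×3×2×7×2 = 420, SVM 5×3×2×4×2 = 240 (no importance mode),
    bagged CART 5×3×2×7×1 = 210 (no tuning metric).
    """
    if feature_grid is None:
        feature_grid = default_feature_grid()
    configs = []
    for tag, scheme, down, fc, algo in itertools.product(
        dataset_tags, schemes, downsampling, feature_grid, algorithms
    ):
        if algo == "svm" and fc.mode == "importance":
            continue
        algo_metrics: Sequence[Optional[str]] = [None] if algo == "bagged_cart" else metrics
        for metric in algo_metrics:
            configs.append(ScenarioConfig(tag, scheme, down, fc, algo, metric))
    return configs


def _run_one(
    citations: Sequence[Citation], config: ScenarioConfig, seed: int,
    split: SplitSpec, folds: int, threshold: float,
) -> ScenarioResult:
    t0 = time.perf_counter()
    try:
        clean = deduplicate(citations)
        dataset = derive_labels(clean, config.scheme)
        train, test = stratified_split(dataset, SplitSpec(split.train_fraction, seed))
        model_config = ScreeningModelConfig(
            scheme=config.scheme,
            feature_config=config.feature_config,
            algorithm=AlgorithmSpec(config.algorithm),
            metric=config.metric,
            downsample=config.downsample,
            threshold=threshold,
            folds=folds,
            seed=seed,
        )
        model = fit_screening_model(train, model_config, screening_set=test.citations)
        decisions = screen(model, test)
        counts = confusion_counts(decisions, test.citations)
        report = performance_metrics(counts)
        ewr, crr, crs = reason_metrics(decisions, test.citations, threshold)
        report.excluded_with_reason_rate = ewr
        report.correct_reason_rate = crr
        report.correct_reason_strict_rate = crs
        return ScenarioResult(config, report, counts, time.perf_counter() - t0)
    except Exception as exc:  # record, don't abort the batch
        return ScenarioResult(config, None, None, time.perf_counter() - t0, error=str(exc))


def run_scenarios(
    datasets: dict[str, Sequence[Citation]],
    configs: Sequence[ScenarioConfig],
    master_seed: int,
    split: SplitSpec = SplitSpec(0.75, 0),
    folds: int = 10,
    threshold: float = 0.90,
) -> list[ScenarioResult]:
    """Run every scenario end to end; failures are recorded per cell.

    Per-cell seeds are drawn deterministically from ``master_seed``, so a
    repeat run with the same inputs reproduces every number.
    """
    rng = np.random.default_rng(master_seed)
    seeds = rng.integers(0, 2**31 - 1, size=len(configs))
    results = []
    for config, seed in zip(configs, seeds):
        if config.dataset_tag not in datasets:
            results.append(
                ScenarioResult(config, None, None, error=f"unknown dataset {config.dataset_tag!r}")
            )
            continue
        results.append(
            _run_one(datasets[config.dataset_tag], config, int(seed), split, folds, threshold)
        )
    return results


# ---------------------------------------------------------------------------
# Paired factor comparison
# ---------------------------------------------------------------------------


@dataclass
class PairedTestResult:
    factor: str
    level_a: object
    level_b: object
    n_pairs: int
    n_unmatched: int
    mean_difference: float
    t_statistic: Optional[float]
    degrees_of_freedom: int
    p_value: Optional[float]
    degenerate: bool = False  # zero variance of differences with nonzero mean


def paired_factor_test(
    results: Sequence[ScenarioResult],
    factor: str,
    level_a,
    level_b,
    response: str = "sensitivity",
) -> PairedTestResult:
    """Two-sided paired t-test of one factor, all other factors matched.

    Cells are paired when their configurations agree on every factor except
    ``factor``; cells without a partner (including failed runs) are dropped
    and counted in ``n_unmatched``. The difference is level_a − level_b on
    the chosen response.
    """
    if response not in ("sensitivity", "specificity"):
        raise ValidationError("response must be sensitivity or specificity")
    by_key: dict[tuple, dict] = {}
    n_candidates = 0
    for res in results:
        if not res.ok or res.report is None:
            continue
        level = res.config.factor_level(factor)
        if level != level_a and level != level_b:
            continue
        value = getattr(res.report, response)
        if value is None:
            continue
        n_candidates += 1
        by_key.setdefault(res.config.key_without(factor), {})[
            "a" if level == level_a else "b"
        ] = value
    diffs = np.array(
        [slot["a"] - slot["b"] for slot in by_key.values() if "a" in slot and "b" in slot]
    )
    n_unmatched = n_candidates - 2 * len(diffs)
    if len(diffs) < 2:
        raise ValidationError(
            f"paired_factor_test needs >= 2 matched pairs, found {len(diffs)}"
        )
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    df = len(diffs) - 1
    if sd == 0.0:
        # all differences identical: no sampling variability to test against
        return PairedTestResult(
            factor, level_a, level_b, len(diffs), n_unmatched, mean,
            None, df, None if mean != 0.0 else 1.0, degenerate=(mean != 0.0),
        )
    t = mean / (sd / np.sqrt(len(diffs)))
    p = 2.0 * stats.t.sf(abs(t), df)
    return PairedTestResult(
        factor, level_a, level_b, len(diffs), n_unmatched, mean, float(t), df, float(p)
    )
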