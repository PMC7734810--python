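"""Confusion definitions, reason metrics, scenario grid, paired tests."""

import numpy as np
import pytest
from scipy import stats

from slrscreen.corpus import ExclusionReason, LabelScheme, ValidationError
from slrscreen.evalsim import (
    ConfusionCounts,
    PerformanceReport,
    ScenarioConfig,
    ScenarioResult,
    confusion_counts,
    default_feature_grid,
    enumerate_scenarios,
    paired_factor_test,
    performance_metrics,
    reason_metrics,
    run_scenarios,
)
from slrscreen.screener import ScreeningDecision
from slrscreen.synthcorpus import CorpusSpec, generate_corpus
from slrscreen.textfeat import FeatureConfig
from conftest import make_citation

R = ExclusionReason


def decision(cid, outcome, reason=None, overall=0.95, probs=None):
    return ScreeningDecision(cid, outcome, reason, overall, probs or {})


class TestConfusionCounts:
    def test_unclassified_counts_toward_the_human(self):
        """A true include left unclassified is a TP; a true exclude left
        unclassified is an FP — only reasoned exclusions save work."""
        citations = [
            make_citation(0, "a", "include", ft_dec="include"),
            make_citation(1, "b", abs_reason=R.OTHER),
        ]
        decisions = [
            decision("c00", "unclassified"),
            decision("c01", "unclassified"),
        ]
        counts = confusion_counts(decisions, citations)
        assert (counts.tp, counts.fn, counts.tn, counts.fp) == (1, 0, 0, 1)

    def test_two_of_thirtythree_includes_misclassified(self):
        citations, decisions = [], []
        for i in range(33):
            citations.append(make_citation(i, f"inc {i}", "include", ft_dec="include"))
            outcome = "exclude" if i < 2 else "include"
            decisions.append(
                decision(f"c{i:02d}", outcome, R.POPULATION if i < 2 else None)
            )
        counts = confusion_counts(decisions, citations)
        assert counts.tp == 31 and counts.fn == 2

    def test_mixed_fixture_matches_per_citation_tally(self):
        citations = [
            make_citation(0, "a", "include", ft_dec="include"),
            make_citation(1, "b", "include", ft_dec="include"),
            make_citation(2, "c", "include", ft_dec="exclude", ft_reason=R.OUTCOMES),
            make_citation(3, "d", abs_reason=R.TIME),
            make_citation(4, "e", abs_reason=R.OTHER),
            make_citation(5, "f", abs_reason=R.POPULATION),
        ]
        decisions = [
            decision("c00", "include", overall=0.1),
            decision("c01", "exclude", R.TIME),
            decision("c02", "unclassified"),
            decision("c03", "exclude", R.TIME),
            decision("c04", "include", overall=0.2),
            decision("c05", "unclassified"),
        ]
        counts = confusion_counts(decisions, citations)
        # independent tally: truth x auto-excluded
        tp = fn = tn = fp = 0
        for c, d in zip(citations, decisions):
            if c.true_include:
                if d.outcome == "exclude":
                    fn += 1
                else:
                    tp += 1
            elif d.outcome == "exclude":
                tn += 1
            else:
                fp += 1
        assert (counts.tp, counts.fn, counts.tn, counts.fp) == (tp, fn, tn, fp)
        assert counts.total == len(citations)

    def test_unknown_citation_id_rejected(self):
        with pytest.raises(ValidationError):
            confusion_counts([decision("ghost", "include")], [])


class TestPerformanceMetrics:
    def test_psoriasis_sensitivity_from_counts(self):
        report = performance_metrics(ConfusionCounts(tp=31, fn=2, tn=0, fp=0))
        assert report.sensitivity == pytest.approx(31 / 33)

    def test_perfect_specificity(self):
        report = performance_metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=0))
        assert report.specificity == 1.0

    def test_hand_arithmetic(self):
        report = performance_metrics(ConfusionCounts(tp=3, fn=1, tn=5, fp=1))
        assert report.precision == pytest.approx(0.75)
        assert report.accuracy == pytest.approx(0.8)
        assert report.sensitivity == pytest.approx(0.75)
        assert report.specificity == pytest.approx(5 / 6)

    def test_zero_denominators_are_flagged_not_zeroed(self):
        report = performance_metrics(ConfusionCounts(tp=0, fn=0, tn=3, fp=1))
        assert report.sensitivity is None
        assert report.specificity == pytest.approx(0.75)


class TestReasonMetrics:
    citations = [
        make_citation(i, f"t {i}", abs_reason=R.POPULATION) for i in range(6)
    ]

    def test_excluded_with_reason_rate_hand_count(self):
        decisions = [
            decision("c00", "exclude", R.POPULATION, 0.95, {R.POPULATION: 0.95}),
            decision("c01", "exclude", R.POPULATION, 0.93, {R.POPULATION: 0.91}),
            decision("c02", "exclude", R.OTHER, 0.99, {R.OTHER: 0.95, R.POPULATION: 0.3}),
            decision("c03", "unclassified", None, 0.92, {R.POPULATION: 0.1}),
            decision("c04", "include", None, 0.2, {}),
        ]
        ewr, crr, crs = reason_metrics(decisions, self.citations, 0.90)
        assert ewr == pytest.approx(3 / 4)  # 4 above threshold, 3 with a reason
        # reviewer reason is population for all: qualifies for c00, c01 only
        assert crr == pytest.approx(2 / 3)
        assert crs == pytest.approx(2 / 3)

    def test_all_reasons_qualifying_gives_one(self):
        decisions = [
            decision(f"c{i:02d}", "exclude", R.POPULATION, 0.95, {R.POPULATION: 0.95})
            for i in range(3)
        ]
        ewr, crr, crs = reason_metrics(decisions, self.citations[:3], 0.90)
        assert ewr == 1.0 and crr == 1.0 and crs == 1.0

    def test_empty_denominators_flagged(self):
        decisions = [decision("c00", "include", None, 0.1, {})]
        ewr, crr, crs = reason_metrics(decisions, self.citations[:1], 0.90)
        assert ewr is None and crr is None and crs is None


class TestEnumerateScenarios:
    def test_full_grid_totals(self):
        configs = enumerate_scenarios(["d1", "d2", "d3", "d4", "d5"])
        by_algo = {a: sum(c.algorithm == a for c in configs) for a in
                   ("naive_bayes", "svm", "bagged_cart")}
        assert len(configs) == 870
        assert by_algo == {"naive_bayes": 420, "svm": 240, "bagged_cart": 210}

    def test_empty_dataset_list(self):
        assert enumerate_scenarios([]) == []

    def test_single_dataset_breakdown(self):
        configs = enumerate_scenarios(["only"])
        by_algo = {a: sum(c.algorithm == a for c in configs) for a in
                   ("naive_bayes", "svm", "bagged_cart")}
        assert len(configs) == 174
        assert by_algo == {"naive_bayes": 84, "svm": 48, "bagged_cart": 42}

    def test_grid_restriction_matches_closed_form(self):
        configs = enumerate_scenarios(
            ["a", "b"],
            schemes=[LabelScheme.ABSTRACT],
            downsampling=[True],
            feature_grid=[FeatureConfig("min_frequency", min_frequency=5)],
        )
        # 2 datasets x 1 x 1 x 1 x (svm:2 + nb:2 + cart:1 metrics)
        assert len(configs) == 2 * (2 + 2 + 1)

    def test_structural_invariants_enforced(self):
        assert all(
            not (c.algorithm == "svm" and c.feature_config.mode == "importance")
            for c in enumerate_scenarios(["d"])
        )
        with pytest.raises(ValidationError):
            ScenarioConfig("d", LabelScheme.ABSTRACT, True,
                           FeatureConfig("importance", importance_k=50), "svm", "roc")
        with pytest.raises(ValidationError):
            ScenarioConfig("d", LabelScheme.ABSTRACT, True,
                           FeatureConfig("min_frequency", min_frequency=5),
                           "bagged_cart", "roc")

    def test_deterministic_ordering(self):
        assert enumerate_scenarios(["d1", "d2"]) == enumerate_scenarios(["d1", "d2"])


def _result(tag, down, sens, algo="svm", metric="roc"):
    config = ScenarioConfig(
        tag, LabelScheme.ABSTRACT, down,
        FeatureConfig("min_frequency", min_frequency=5), algo, metric,
    )
    report = PerformanceReport(sensitivity=sens, specificity=0.5,
                               precision=0.5, accuracy=0.5)
    return ScenarioResult(config, report, ConfusionCounts(1, 0, 1, 0))


class TestPairedFactorTest:
    def test_textbook_t_statistic(self):
        results = []
        for tag, (a, b) in zip("xyz", [(0.6, 0.5), (0.8, 0.6), (0.9, 0.6)]):
            results.append(_result(tag, True, a))
            results.append(_result(tag, False, b))
        out = paired_factor_test(results, "downsample", True, False)
        # differences 0.1, 0.2, 0.3 -> mean 0.2, t = 0.2/(0.1/sqrt 3)
        assert out.n_pairs == 3 and out.degrees_of_freedom == 2
        assert out.mean_difference == pytest.approx(0.2)
        assert out.t_statistic == pytest.approx(3.464, abs=1e-3)
        t_ref, p_ref = stats.ttest_rel([0.6, 0.8, 0.9], [0.5, 0.6, 0.6])
        assert out.t_statistic == pytest.approx(float(t_ref), abs=1e-9)
        assert out.p_value == pytest.approx(float(p_ref), abs=1e-9)

    def test_all_zero_differences_declares_no_difference(self):
        results = []
        for tag in "xy":
            results.append(_result(tag, True, 0.7))
            results.append(_result(tag, False, 0.7))
        out = paired_factor_test(results, "downsample", True, False)
        assert out.mean_difference == 0.0 and out.p_value == 1.0
        assert not out.degenerate

    def test_constant_nonzero_differences_flagged_degenerate(self):
        results = []
        for tag in "xy":
            results.append(_result(tag, True, 0.8))
            results.append(_result(tag, False, 0.7))
        out = paired_factor_test(results, "downsample", True, False)
        assert out.degenerate and out.t_statistic is None

    def test_unpartnered_configs_dropped_and_counted(self):
        results = [
            _result("x", True, 0.6), _result("x", False, 0.5),
            _result("y", True, 0.9), _result("y", False, 0.7),
            _result("z", True, 0.8),  # no partner
        ]
        out = paired_factor_test(results, "downsample", True, False)
        assert out.n_pairs == 2 and out.n_unmatched == 1

    def test_fewer_than_two_pairs_rejected(self):
        results = [_result("x", True, 0.6), _result("x", False, 0.5)]
        with pytest.raises(ValidationError):
            paired_factor_test(results, "downsample", True, False)

    def test_twelve_config_grid_pairs_six(self):
        results = []
        for tag in "ab":
            for algo, metric in (("svm", "roc"), ("svm", "sensitivity"),
                                 ("bagged_cart", None)):
                for down in (True, False):
                    results.append(_result(tag, down, 0.5 + 0.1 * down, algo, metric))
        out = paired_factor_test(results, "downsample", True, False)
        assert out.n_pairs == 6


class TestRunScenarios:
    @staticmethod
    def _tiny_setup():
        spec = CorpusSpec(n_citations=250, abstract_include_rate=0.3,
                          fulltext_retention_rate=0.5, signature_strength=0.5, seed=0)
        datasets = {"tiny": generate_corpus(spec)}
        configs = enumerate_scenarios(
            ["tiny"],
            schemes=[LabelScheme.FULL_TEXT],
            downsampling=[True, False],
            feature_grid=[FeatureConfig("min_frequency", min_frequency=2)],
            algorithms=["svm"],
            metrics=["roc"],
        )
        return datasets, configs

    def test_one_result_per_config_and_determinism(self):
        datasets, configs = self._tiny_setup()
        a = run_scenarios(datasets, configs, master_seed=5, folds=3)
        b = run_scenarios(datasets, configs, master_seed=5, folds=3)
        assert len(a) == len(configs)
        assert all(r.ok for r in a)
        assert [r.report.sensitivity for r in a] == [r.report.sensitivity for r in b]
        assert [r.report.specificity for r in a] == [r.report.specificity for r in b]

    def test_unknown_dataset_recorded_not_raised(self):
        _, configs = self._tiny_setup()
        results = run_scenarios({}, configs, master_seed=0, folds=3)
        assert all(not r.ok for r in results)
        assert all("unknown dataset" in r.error for r in results)
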