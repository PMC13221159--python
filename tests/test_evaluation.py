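"""Metric formulas, classifier grid, nested CV laws, repeats and bootstrap."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lasap import (
    BlockSet,
    ConfusionCounts,
    CVConfig,
    FeaturePipeline,
    SyntheticConfig,
    accuracy,
    bootstrap_ci_diff,
    build_classifier,
    confusion_rates,
    double_cv,
    f1_score,
    generate_cohort,
    repeated_cv,
    roc_auc,
    summarize_repeats,
)
from lasap.evaluation import decision_scores, default_model_grid

MODELS = [
    "svm-linear", "svm-rbf", "svm-sigmoid", "svm-poly",
    "knn", "random-forest", "extratrees", "adaboost",
]


class TestMetricFormulas:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            (ConfusionCounts(5, 0, 0, 0), 100.0),
            (ConfusionCounts(0, 2, 3, 0), 0.0),
            (ConfusionCounts(3, 1, 2, 0), 100 * 6 / 9),
        ],
    )
    def test_f1_substitution(self, counts, expected):
        assert f1_score(counts) == pytest.approx(expected)

    def test_f1_undefined_is_nan_not_zero(self):
        assert math.isnan(f1_score(ConfusionCounts(0, 0, 0, 4)))

    @pytest.mark.parametrize(
        "counts,expected",
        [
            (ConfusionCounts(2, 0, 0, 2), 100.0),
            (ConfusionCounts(1, 1, 1, 1), 50.0),
            (ConfusionCounts(3, 1, 4, 2), 50.0),
        ],
    )
    def test_accuracy_substitution(self, counts, expected):
        assert accuracy(counts) == pytest.approx(expected)

    def test_rates_substitution(self):
        tpr, fpr, fnr, tnr = confusion_rates(ConfusionCounts(4, 0, 1, 5))
        assert (tpr, fpr, fnr, tnr) == (80.0, 0.0, 20.0, 100.0)

    def test_all_positive_degenerate(self):
        tpr, fpr, _, _ = confusion_rates(ConfusionCounts(5, 5, 0, 0))
        assert (tpr, fpr) == (100.0, 100.0)

    @given(
        tp=st.integers(0, 40), fp=st.integers(0, 40),
        fn=st.integers(0, 40), tn=st.integers(0, 40),
    )
    @settings(deadline=None, max_examples=60)
    def test_complement_identities(self, tp, fp, fn, tn):
        if tp + fn == 0 or tn + fp == 0:
            return
        tpr, fpr, fnr, tnr = confusion_rates(ConfusionCounts(tp, fp, fn, tn))
        assert tpr + fnr == pytest.approx(100.0)
        assert fpr + tnr == pytest.approx(100.0)


def _auc_pair_enumeration(scores, labels):
    """Oracle: concordant pair fraction, ties counted half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = wins = 0.0
    for p in pos:
        for q in neg:
            total += 1
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return 100.0 * wins / total


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 100.0

    def test_all_ties_chance(self):
        assert roc_auc([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0]) == 50.0

    def test_enumerated_example(self):
        assert roc_auc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == 75.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_pair_enumeration_oracle_with_ties(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 13))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            scores = rng.integers(0, 4, size=n).astype(float)  # coarse -> many ties
            assert roc_auc(scores, labels) == pytest.approx(
                _auc_pair_enumeration(scores, labels)
            )


class TestBuildClassifier:
    def test_grid_expansion(self):
        grid = default_model_grid("svm-linear")
        assert [g["C"] for g in grid["svm-linear"]] == [0.01, 0.1, 1.0, 10.0]

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="mlp"):
            build_classifier("mlp")
        with pytest.raises(ValueError):
            default_model_grid("mlp")

    @pytest.mark.parametrize("name", MODELS)
    def test_capacity_on_separable_points(self, name):
        X = np.array([[0.0, 0.0], [0.1, 0.1], [5.0, 5.0], [5.1, 5.1]])
        y = np.array([0, 0, 1, 1])
        params = default_model_grid(name)[name][-1]
        model = build_classifier(name, params)
        if name == "knn":
            model = build_classifier(name, {"n_neighbors": 1})
        model.fit(X, y)
        assert np.array_equal(model.predict(X), y)
        assert decision_scores(model, X).shape == (4,)


@pytest.fixture(scope="module")
def tiny_cv_inputs():
    cohort = generate_cohort(SyntheticConfig(n_participants=100, n_acoustic=60, seed=21))
    cfg = CVConfig(outer_k=10, inner_k=5, seed=7)
    pipe = FeaturePipeline(setting="combined_ortho", lexicon=cohort.lexicon)
    return cohort, cfg, pipe


class TestDoubleCV:
    def test_partition_law(self, tiny_cv_inputs):
        cohort, cfg, pipe = tiny_cv_inputs
        report = double_cv(cohort.blocks, cohort.label, cfg, pipe)
        assert report.outer_k == 10
        sizes = [c.total for c in report.fold_confusions]
        assert sizes == [10] * 10  # every participant in exactly one test fold
        assert sum(c.tp + c.fn for c in report.fold_confusions) == cohort.label.sum()

    def test_deterministic_under_seed(self, tiny_cv_inputs):
        cohort, cfg, pipe = tiny_cv_inputs
        a = double_cv(cohort.blocks, cohort.label, cfg, pipe)
        b = double_cv(cohort.blocks, cohort.label, cfg, pipe)
        assert a.to_dict() == b.to_dict()

    def test_metrics_consistent_with_confusions(self, tiny_cv_inputs):
        cohort, cfg, pipe = tiny_cv_inputs
        report = double_cv(cohort.blocks, cohort.label, cfg, pipe)
        for m, c in zip(report.fold_metrics, report.fold_confusions):
            assert m.accuracy == pytest.approx(accuracy(c))
            tpr, fpr, fnr, tnr = confusion_rates(c)
            assert (m.tpr, m.fpr, m.fnr, m.tnr) == pytest.approx((tpr, fpr, fnr, tnr))

    def test_separable_cohort_high_accuracy(self):
        # huge effects, tiny noise -> essentially linearly separable
        cohort = generate_cohort(
            SyntheticConfig(
                n_participants=100, n_keywords=10, n_acoustic=20,
                ling_effect=4.0, acou_effect=4.0, noise_sd=0.3,
                cross_loading=0.2, seed=3,
            )
        )
        cfg = CVConfig(seed=5)
        report = double_cv(
            cohort.blocks, cohort.label, cfg,
            FeaturePipeline(setting="combined_ortho", lexicon=cohort.lexicon),
        )
        assert report.mean("accuracy") >= 95.0

    def test_no_leakage_from_corrupted_test_rows(self):
        """Corrupting test-fold rows must not change fitted preprocessing
        or selected hyperparameters of that fold."""
        cohort = generate_cohort(SyntheticConfig(n_participants=100, n_acoustic=40, seed=15))
        cfg = CVConfig(seed=2)
        pipe = FeaturePipeline(setting="combined_ortho", lexicon=cohort.lexicon)
        from sklearn.model_selection import StratifiedKFold

        outer = StratifiedKFold(10, shuffle=True, random_state=cfg.seed)
        train_idx, test_idx = next(outer.split(np.zeros(100), cohort.label))
        from lasap.evaluation import _select_hyperparameters

        sel_clean = _select_hyperparameters(
            cohort.blocks, cohort.label, train_idx, cfg, pipe, inner_seed=99
        )
        fit_clean = pipe.fit(cohort.blocks, train_idx)

        corrupted_ling = cohort.linguistic.values.copy()
        corrupted_acou = cohort.acoustic.values.copy()
        corrupted_ling[test_idx] *= 10
        corrupted_acou[test_idx] *= 10
        from lasap.blocks import FeatureBlock

        blocks2 = BlockSet(
            FeatureBlock(corrupted_ling, cohort.linguistic.feature_names,
                         cohort.linguistic.participant_ids, "linguistic"),
            FeatureBlock(corrupted_acou, cohort.acoustic.feature_names,
                         cohort.acoustic.participant_ids, "acoustic"),
        )
        sel_corrupt = _select_hyperparameters(
            blocks2, cohort.label, train_idx, cfg, pipe, inner_seed=99
        )
        fit_corrupt = pipe.fit(blocks2, train_idx)

        assert sel_clean == sel_corrupt
        np.testing.assert_array_equal(
            fit_clean.reducer.components, fit_corrupt.reducer.components
        )
        np.testing.assert_array_equal(
            fit_clean.orthogonalizer.coefficients, fit_corrupt.orthogonalizer.coefficients
        )
        np.testing.assert_array_equal(
            fit_clean.standardizer.means, fit_corrupt.standardizer.means
        )


class TestRepeatedCV:
    def test_repeats_differ_only_by_fold_assignment(self, tiny_cv_inputs):
        cohort, cfg, pipe = tiny_cv_inputs
        reports = repeated_cv(cohort.blocks, cohort.label, cfg, n_repeats=2, preprocessing=pipe)
        assert [r.seed for r in reports] == [cfg.seed, cfg.seed + 1]
        # pooled counts identical (same data), fold slicing differs
        totals = [sum(c.total for c in r.fold_confusions) for r in reports]
        assert totals == [100, 100]

    def test_summary_sd_matches_independent_recomputation(self, tiny_cv_inputs):
        cohort, cfg, pipe = tiny_cv_inputs
        reports = repeated_cv(cohort.blocks, cohort.label, cfg, n_repeats=3, preprocessing=pipe)
        summary = summarize_repeats(reports)
        means = np.array([r.mean("roc_auc") for r in reports])
        assert summary["roc_auc"]["mean"] == pytest.approx(means.mean())
        assert summary["roc_auc"]["sd"] == pytest.approx(
            math.sqrt(((means - means.mean()) ** 2).mean())
        )


class _FakeReport:
    def __init__(self, seed, values):
        self.seed = seed
        self._values = values

    def mean(self, name):
        return self._values[name]


def _fake_pairs(diffs):
    with_reports, without_reports = [], []
    for i, d in enumerate(diffs):
        base = {"f1": 70.0, "accuracy": 70.0, "roc_auc": 70.0}
        shifted = {k: v + d for k, v in base.items()}
        with_reports.append(_FakeReport(i, shifted))
        without_reports.append(_FakeReport(i, base))
    return with_reports, without_reports


class TestBootstrapCI:
    def test_constant_differences(self):
        w, wo = _fake_pairs([3.0] * 10)
        res = bootstrap_ci_diff(w, wo)
        assert res.lower["roc_auc"] == res.upper["roc_auc"] == pytest.approx(3.0)
        assert res.improvement_established("roc_auc")

    def test_symmetric_differences_not_established(self):
        w, wo = _fake_pairs([-2.0, -1.0, 0.0, 1.0, 2.0] * 4)
        res = bootstrap_ci_diff(w, wo)
        assert not res.improvement_established("accuracy")
        assert res.lower["accuracy"] < 0 < res.upper["accuracy"]

    def test_percentile_oracle_linear_interpolation(self, rng):
        diffs = np.sort(rng.normal(5, 3, size=100))
        w, wo = _fake_pairs(diffs.tolist())
        res = bootstrap_ci_diff(w, wo)

        def brute_percentile(sorted_vals, q):
            # linear interpolation between order statistics
            h = (len(sorted_vals) - 1) * q / 100.0
            lo = int(np.floor(h))
            hi = min(lo + 1, len(sorted_vals) - 1)
            return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])

        assert res.lower["f1"] == pytest.approx(brute_percentile(diffs, 2.5))
        assert res.upper["f1"] == pytest.approx(brute_percentile(diffs, 97.5))

    def test_unpaired_lengths_rejected(self):
        w, wo = _fake_pairs([1.0] * 5)
        with pytest.raises(ValueError):
            bootstrap_ci_diff(w, wo[:-1])

    def test_mismatched_seeds_rejected(self):
        w, wo = _fake_pairs([1.0] * 5)
        wo[2].seed = 99
        with pytest.raises(ValueError, match="unpaired"):
            bootstrap_ci_diff(w, wo)
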