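import itertools

import numpy as np
import pytest
from scipy import stats

from sgnn.errors import (
    DegenerateEvaluationError,
    ParameterError,
    SplitError,
)
from sgnn.evaluation import (
    ConfusionCounts,
    confusion,
    evaluate_predictor,
    mann_whitney_two_tailed,
    metrics,
    roc_curve,
    stratified_split,
)
from sgnn.features import default_feature_config
from sgnn.neuralnet import TrainConfig, fit_pipeline
from sgnn.sequence_io import LabeledDataset, SequenceRecord
from sgnn.synthetic import GeneratorConfig, generate_dataset


def make_dataset(n_pos, n_neg):
    records = [
        SequenceRecord(id=f"r{i}", residues="MKQ") for i in range(n_pos + n_neg)
    ]
    labels = ["positive"] * n_pos + ["negative"] * n_neg
    return LabeledDataset(records=records, labels=labels)


class TestConfusion:
    def test_all_correct_positive(self):
        c = confusion(["positive"] * 5, ["positive"] * 5)
        assert (c.tp, c.fp, c.tn, c.fn) == (5, 0, 0, 0)

    def test_all_missed_positive(self):
        c = confusion(["positive"] * 4, ["negative"] * 4)
        assert c.fn == 4 and c.tp == 0

    def test_study_testing_set_counts(self):
        """14 concordant positives, 16 concordant negatives, 2 missed positives."""
        truth = ["positive"] * 16 + ["negative"] * 16
        predicted = ["positive"] * 14 + ["negative"] * 2 + ["negative"] * 16
        c = confusion(truth, predicted)
        assert (c.tp, c.tn, c.fn, c.fp) == (14, 16, 2, 0)
        assert c.total == 32

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            confusion(["positive"], ["positive", "negative"])

    def test_permutation_invariance(self):
        truth = ["positive", "negative", "positive", "negative", "negative"]
        predicted = ["positive", "positive", "negative", "negative", "negative"]
        base = confusion(truth, predicted)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(truth))
        shuffled = confusion([truth[i] for i in perm], [predicted[i] for i in perm])
        assert base == shuffled


class TestMetrics:
    def test_held_out_testing_set_metrics(self):
        """The six formulas on counts (TP=14, TN=16, FN=2, FP=0)."""
        r = metrics(ConfusionCounts(tp=14, fp=0, tn=16, fn=2))
        assert r.sensitivity == pytest.approx(14 / 16)  # 0.875
        assert r.specificity == 1.0
        assert r.accuracy == pytest.approx(30 / 32)  # 0.9375
        assert r.precision == 1.0  # FP = 0
        assert r.f1 == pytest.approx(14 / 15)
        assert r.mcc == pytest.approx(
            (14 * 16) / np.sqrt(14 * 16 * 16 * 18)
        )
        assert r.mcc == pytest.approx(0.8819, abs=1e-4)

    def test_perfect_classifier(self):
        r = metrics(ConfusionCounts(tp=3, fp=0, tn=4, fn=0))
        assert (
            r.sensitivity,
            r.specificity,
            r.precision,
            r.accuracy,
            r.f1,
            r.mcc,
        ) == (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)

    def test_zero_denominators_flagged_undefined(self):
        r = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert r.precision is None
        assert r.sensitivity is None
        assert r.mcc is None
        assert r.specificity == 1.0

    def test_matches_brute_force_formulas_on_random_counts(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            tp, fp, tn, fn = (int(x) for x in rng.integers(0, 20, size=4))
            if tp + fp + tn + fn == 0:
                continue
            r = metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
            if tp + fn:
                assert r.sensitivity == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert r.specificity == pytest.approx(tn / (tn + fp))
            assert r.accuracy == pytest.approx((tp + tn) / (tp + fp + tn + fn))


def auc_by_pairwise_comparison(scores, truth):
    """Rank-free oracle: fraction of (pos, neg) pairs ordered correctly, ties 1/2."""
    pos = [s for s, t in zip(scores, truth) if t == "positive"]
    neg = [s for s, t in zip(scores, truth) if t == "negative"]
    wins = sum(
        1.0 if p > n else (0.5 if p == n else 0.0)
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        curve = roc_curve([0.9, 0.8, 0.2, 0.1], ["positive", "positive", "negative", "negative"])
        assert curve.auc == 1.0
        assert curve.fpr[0] == 0.0 and curve.tpr[0] == 0.0
        assert curve.fpr[-1] == 1.0 and curve.tpr[-1] == 1.0

    def test_identical_scores_give_chance_auc(self):
        curve = roc_curve([0.5] * 6, ["positive"] * 3 + ["negative"] * 3)
        assert curve.auc == pytest.approx(0.5)
        assert len(curve.fpr) == 2  # single diagonal segment

    def test_tied_scores_against_rank_oracle(self):
        scores = [0.9, 0.5, 0.5, 0.4, 0.3, 0.1]
        truth = ["positive", "positive", "negative", "positive", "negative", "negative"]
        curve = roc_curve(scores, truth)
        assert curve.auc == pytest.approx(auc_by_pairwise_comparison(scores, truth))

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateEvaluationError):
            roc_curve([0.1, 0.9], ["positive", "positive"])

    def test_curve_coordinates_non_decreasing(self):
        rng = np.random.default_rng(5)
        scores = rng.choice([0.1, 0.3, 0.5, 0.9], size=20).tolist()
        truth = rng.choice(["positive", "negative"], size=20).tolist()
        if len(set(truth)) < 2:
            truth[0], truth[1] = "positive", "negative"
        curve = roc_curve(scores, truth)
        assert all(a <= b for a, b in zip(curve.fpr, curve.fpr[1:]))
        assert all(a <= b for a, b in zip(curve.tpr, curve.tpr[1:]))

    @pytest.mark.parametrize("seed", range(8))
    def test_auc_equals_u_over_n1n2(self, seed):
        """Trapezoidal AUC equals U/(n1*n2) including ties (small random instances)."""
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(2, 7)), int(rng.integers(2, 7))
        pool = rng.choice([0.1, 0.2, 0.3, 0.5, 0.8], size=n1 + n2)
        truth = ["positive"] * n1 + ["negative"] * n2
        curve = roc_curve(pool.tolist(), truth)
        pos, neg = pool[:n1], pool[n1:]
        u = mann_whitney_two_tailed(pos, neg).u
        assert curve.auc == pytest.approx(u / (n1 * n2))


class TestMannWhitney:
    def test_u_statistics_sum_to_n1n2(self):
        x, y = [1.2, 3.4, 2.2], [0.5, 3.4, 5.6, 2.0]
        res_xy = mann_whitney_two_tailed(x, y)
        res_yx = mann_whitney_two_tailed(y, x)
        assert res_xy.u + res_yx.u == pytest.approx(len(x) * len(y))

    def test_exact_enumeration_example(self):
        """x=[1,2] vs y=[3,4]: 2 of the 6 assignments are as extreme -> p=1/3."""
        res = mann_whitney_two_tailed([1, 2], [3, 4])
        assert res.method == "exact"
        assert res.u == 0.0
        assert res.p_two_tailed == pytest.approx(1 / 3)

    def test_identical_samples_give_central_u(self):
        x = [1.0, 2.0, 3.0]
        res = mann_whitney_two_tailed(x, x)
        assert res.u == pytest.approx(len(x) ** 2 / 2)
        assert res.p_two_tailed == 1.0

    def test_exact_agrees_with_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.normal(size=5)
            y = rng.normal(size=5)
            ours = mann_whitney_two_tailed(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ours.method == "exact"
            assert ours.u == pytest.approx(float(ref.statistic))
            assert ours.p_two_tailed == pytest.approx(float(ref.pvalue))

    def test_normal_approximation_on_larger_samples(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0.0, 1.0, size=20)
        y = rng.normal(0.8, 1.0, size=20)
        ours = mann_whitney_two_tailed(x, y)
        ref = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        assert ours.method == "normal-approximation"
        assert ours.p_two_tailed == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_exact_and_approximate_agree_for_borderline_sizes(self):
        """Sanity band: the two p-value routes agree within 0.05 at n1=n2=6."""
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, size=6)
        y = rng.normal(1, 1, size=6)
        exact = mann_whitney_two_tailed(x, y)
        ref = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        assert abs(exact.p_two_tailed - float(ref.pvalue)) < 0.05

    def test_empty_sample_rejected(self):
        with pytest.raises(ParameterError):
            mann_whitney_two_tailed([], [1.0])


class TestStratifiedSplit:
    def test_study_sized_split(self):
        """32+32 at fraction 0.5 -> 16+16 training and 16+16 testing."""
        ds = make_dataset(32, 32)
        train, test = stratified_split(ds, 0.5, seed=0)
        assert (train.n_positive, train.n_negative) == (16, 16)
        assert (test.n_positive, test.n_negative) == (16, 16)

    def test_partition_properties(self):
        ds = make_dataset(7, 5)
        train, test = stratified_split(ds, 0.5, seed=1)
        train_ids = {r.id for r in train.records}
        test_ids = {r.id for r in test.records}
        assert train_ids & test_ids == set()
        assert train_ids | test_ids == {r.id for r in ds.records}

    def test_rounding_half_up(self):
        ds = make_dataset(5, 3)
        train, test = stratified_split(ds, 0.5, seed=2)
        assert train.n_positive == 3  # round(2.5) half-up
        assert train.n_negative == 2  # round(1.5) half-up

    def test_seed_determinism(self):
        ds = make_dataset(10, 10)
        a = stratified_split(ds, 0.5, seed=3)
        b = stratified_split(ds, 0.5, seed=3)
        assert [r.id for r in a[0].records] == [r.id for r in b[0].records]
        c = stratified_split(ds, 0.5, seed=4)
        assert [r.id for r in a[0].records] != [r.id for r in c[0].records]

    def test_class_too_small_rejected(self):
        ds = make_dataset(1, 5)
        with pytest.raises(SplitError):
            stratified_split(ds, 0.5, seed=0)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ParameterError):
            stratified_split(make_dataset(4, 4), 1.0, seed=0)


@pytest.fixture(scope="module")
def fitted():
    ds = generate_dataset(GeneratorConfig(seed=21))
    train, test = stratified_split(ds, 0.5, seed=21)
    bundle, _ = fit_pipeline(train, default_feature_config(), TrainConfig(seed=21))
    return bundle, test


class TestEvaluatePredictor:

    def test_composes_confusion_and_metrics(self, fitted):
        bundle, test = fitted
        counts, report, curve = evaluate_predictor(bundle, test)
        predicted = [bundle.predict_record(r)[1] for r in test.records]
        manual_counts = confusion(test.labels, predicted)
        assert counts == manual_counts
        assert report == metrics(manual_counts)
        scores = [bundle.predict_record(r)[2] for r in test.records]
        assert curve.auc == pytest.approx(roc_curve(scores, test.labels).auc)

    def test_synthetic_separable_accuracy(self, fitted):
        bundle, test = fitted
        _, report, _ = evaluate_predictor(bundle, test)
        assert report.accuracy >= 0.85
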