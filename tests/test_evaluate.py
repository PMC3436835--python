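import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from helpers_oracles import sweep_enumeration
from mapqcal import (
    LabeledExample,
    SnpCall,
    SnpSpec,
    calibration_curve,
    contingency_from_counts,
    cross_validate,
    f1_score,
    f_paper,
    precision_recall_sweep,
    snp_eval,
)
from mapqcal.evaluate import kfold_indices
from mapqcal.features import FeatureVector
from mapqcal.model import fit_logistic, predict_probabilities


class TestPrecisionRecallSweep:
    def test_all_correct_low_threshold(self):
        (point,) = precision_recall_sweep([1.0, 2.0, 3.0], [True, True, True], [0.0])
        assert point.precision == 1.0 and point.recall == 1.0

    def test_contingency_counts_give_published_precision(self):
        """83 correct and 427 incorrect above threshold, 17 correct below:
        precision 83/510 = 0.163."""
        scores = [1.0] * 83 + [1.0] * 427 + [0.0] * 17
        labels = [True] * 83 + [False] * 427 + [True] * 17
        (point,) = precision_recall_sweep(scores, labels, [0.5])
        assert (point.tp, point.fp, point.fn) == (83, 427, 17)
        assert round(point.precision, 3) == 0.163
        assert point.recall == pytest.approx(0.83)

    def test_matches_enumeration_oracle(self, rng):
        scores = rng.random(20)
        labels = rng.random(20) < 0.5
        thresholds = np.sort(rng.random(7))
        points = precision_recall_sweep(scores, labels, thresholds)
        oracle = sweep_enumeration(scores, labels, thresholds)
        for point, (t, tp, fp, fn, precision, recall) in zip(points, oracle):
            assert (point.tp, point.fp, point.fn) == (tp, fp, fn)
            assert point.precision == pytest.approx(precision)
            assert point.recall == pytest.approx(recall)

    def test_tp_plus_fn_constant_across_thresholds(self, rng):
        scores = rng.random(50)
        labels = rng.random(50) < 0.6
        points = precision_recall_sweep(scores, labels, np.linspace(0, 1, 11))
        totals = {point.tp + point.fn for point in points}
        assert totals == {int(labels.sum())}

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            precision_recall_sweep([1.0], [True, False], [0.5])

    def test_empty_positive_set_precision_convention(self):
        (point,) = precision_recall_sweep([0.1, 0.2], [True, True], [0.9])
        assert point.precision == 1.0 and point.recall == 0.0


class TestFPaper:
    @pytest.mark.parametrize(
        "precision,recall,expected",
        [(0.163, 0.83, 0.136), (0.589, 0.63, 0.304)],
    )
    def test_published_values(self, precision, recall, expected):
        assert round(f_paper(precision, recall), 3) == expected

    def test_boundary_documents_nonstandard_definition(self):
        # half the conventional harmonic mean: perfect scores give 0.5
        assert f_paper(1.0, 1.0) == 0.5
        assert f1_score(1.0, 1.0) == 1.0

    def test_zero_inputs_give_zero(self):
        assert f_paper(0.0, 0.5) == 0.0
        assert f_paper(0.5, 0.0) == 0.0

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(min_value=1e-6, max_value=1.0),
        st.floats(min_value=1e-6, max_value=1.0),
    )
    def test_symmetry_and_bound(self, p, r):
        assert f_paper(p, r) == pytest.approx(f_paper(r, p))
        assert f_paper(p, r) <= min(p, r) + 1e-12


class TestCalibrationCurve:
    def test_perfectly_calibrated_simulation(self):
        """Labels drawn Bernoulli(p): bin accuracies track mean p.

        Family-wise check over the 10 bins: every bin inside the 99.9%
        binomial CI of its mean p, and at most one 1%-tail excursion
        (10 simultaneous 99% intervals are expected to miss ~once per
        ten runs even under perfect calibration)."""
        rng = np.random.default_rng(42)
        p = rng.random(50_000)
        labels = rng.random(50_000) < p
        outside_99 = 0
        for bin_ in calibration_curve(p, labels, n_bins=10):
            if bin_.n == 0:
                continue
            lo = stats.binom.ppf(0.0005, bin_.n, bin_.mean_p) / bin_.n
            hi = stats.binom.ppf(0.9995, bin_.n, bin_.mean_p) / bin_.n
            assert lo <= bin_.empirical_accuracy <= hi
            lo99 = stats.binom.ppf(0.005, bin_.n, bin_.mean_p) / bin_.n
            hi99 = stats.binom.ppf(0.995, bin_.n, bin_.mean_p) / bin_.n
            outside_99 += not lo99 <= bin_.empirical_accuracy <= hi99
        assert outside_99 <= 1

    def test_single_value_occupies_one_bin_with_theoretical_accuracy(self):
        bins = calibration_curve([0.999] * 100, [True] * 100, n_bins=10)
        nonempty = [b for b in bins if b.n]
        assert len(nonempty) == 1
        q = -10 * np.log10(1 - 0.999)
        assert nonempty[0].theoretical_accuracy == pytest.approx(1 - 10 ** (-q / 10))

    def test_bin_counts_sum_to_total(self, rng):
        p = rng.random(1000)
        labels = rng.random(1000) < 0.5
        bins = calibration_curve(p, labels, n_bins=10)
        assert sum(b.n for b in bins) == 1000

    def test_single_bin_reduces_to_overall_accuracy(self, rng):
        p = rng.random(500)
        labels = rng.random(500) < 0.5
        (bin_,) = calibration_curve(p, labels, n_bins=1)
        assert bin_.empirical_accuracy == pytest.approx(labels.mean())

    def test_equal_count_strategy_balances_bins(self, rng):
        p = rng.random(1000)
        labels = rng.random(1000) < p
        bins = calibration_curve(p, labels, n_bins=10, strategy="count")
        assert all(80 <= b.n <= 120 for b in bins)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            calibration_curve([0.5], [True], n_bins=0)
        with pytest.raises(ValueError):
            calibration_curve([1.5], [True])


def _toy_examples(n, seed):
    rng = np.random.default_rng(seed)
    examples = []
    for _ in range(n):
        mismatches = int(rng.integers(0, 6))
        label = rng.random() < 1.0 / (1.0 + mismatches)
        fv = FeatureVector(
            intercept=34.0 + rng.normal(), slope=-0.25, r_value=-0.5,
            n_count=0, n_matches=50 - mismatches, n_mismatches=mismatches,
            n_insertions=0, n_deletions=0, raw_mapq=float(rng.integers(0, 41)),
            mapq_missing=0, n_mappings=int(rng.integers(1, 4)),
        )
        examples.append(LabeledExample(features=fv, label=bool(label)))
    # guarantee both classes
    examples[0] = LabeledExample(examples[0].features, True)
    examples[1] = LabeledExample(examples[1].features, False)
    return examples


class TestCrossValidate:
    def test_five_folds_of_twenty_cover_everything(self):
        folds = kfold_indices(100, 5, seed=3)
        assert [len(fold) for fold in folds] == [20] * 5
        union = np.concatenate(folds)
        assert len(set(union.tolist())) == 100

    def test_two_folds_of_two(self):
        folds = kfold_indices(4, 2, seed=3)
        assert [len(fold) for fold in folds] == [2, 2]

    def test_too_few_examples_rejected(self):
        with pytest.raises(ValueError):
            kfold_indices(3, 4, seed=0)
        with pytest.raises(ValueError):
            kfold_indices(10, 1, seed=0)

    def test_fold_metrics_match_manual_refit_oracle(self):
        examples = _toy_examples(200, seed=9)
        results = cross_validate(examples, k=5, seed=17)
        assert len(results) == 5

        # manual recomputation of fold 1
        folds = kfold_indices(200, 5, seed=17)
        test_idx = folds[0]
        train = [ex for i, ex in enumerate(examples) if i not in set(test_idx.tolist())]
        model = fit_logistic(train)
        X = np.array([examples[i].features.to_array() for i in test_idx])
        y = np.array([examples[i].label for i in test_idx])
        p = predict_probabilities(model, X)
        above = p >= 0.5
        assert results[0].contingency.tp == int(np.sum(above & y))
        assert results[0].contingency.fp == int(np.sum(above & ~y))
        assert results[0].contingency.fn == int(np.sum(~above & y))
        assert results[0].accuracy == pytest.approx(float(np.mean(above == y)))

    def test_each_example_tested_exactly_once(self):
        examples = _toy_examples(103, seed=4)
        results = cross_validate(examples, k=5, seed=2)
        sizes = sorted(len(r.test_indices) for r in results)
        assert sizes == [20, 20, 21, 21, 21]
        union = np.concatenate([r.test_indices for r in results])
        assert len(set(union.tolist())) == 103


class TestSnpEval:
    def _truth(self, n=100):
        return [SnpSpec(position=10 * (i + 1), ref_allele="A", alt_allele="G") for i in range(n)]

    def _call(self, snp):
        return SnpCall(
            ref_name="chr1", position=snp.position, ref_allele=snp.ref_allele,
            alt_allele=snp.alt_allele, alt_depth=5, total_depth=10,
        )

    def test_recall_from_83_of_100(self):
        truth = self._truth()
        calls = [self._call(snp) for snp in truth[:83]]
        result = snp_eval(calls, truth)
        assert (result.tp, result.fn) == (83, 17)
        assert result.recall == pytest.approx(0.83)

    def test_precision_with_false_positives(self):
        truth = self._truth()
        calls = [self._call(snp) for snp in truth[:63]]
        calls += [
            SnpCall(ref_name="chr1", position=100_000 + i, ref_allele="A",
                    alt_allele="C", alt_depth=5, total_depth=10)
            for i in range(44)
        ]
        result = snp_eval(calls, truth)
        assert (result.tp, result.fp) == (63, 44)
        assert round(result.precision, 3) == 0.589

    def test_exact_calls_are_perfect(self):
        truth = self._truth(10)
        result = snp_eval([self._call(snp) for snp in truth], truth)
        assert result.precision == 1.0 and result.recall == 1.0
        assert result.f_paper == 0.5

    def test_alt_allele_must_match(self):
        truth = [SnpSpec(position=50, ref_allele="A", alt_allele="G")]
        wrong_alt = [SnpCall(ref_name="chr1", position=50, ref_allele="A",
                             alt_allele="T", alt_depth=3, total_depth=5)]
        result = snp_eval(wrong_alt, truth)
        assert (result.tp, result.fp, result.fn) == (0, 1, 1)


def test_contingency_from_counts_derives_all_metrics():
    result = contingency_from_counts(63, 44, 37)
    assert round(result.precision, 3) == 0.589
    assert result.recall == pytest.approx(0.63)
    assert round(result.f_paper, 3) == 0.304
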