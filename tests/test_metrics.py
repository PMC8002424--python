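"""Metric arithmetic against independent oracles; Y-randomization verdicts."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import (accuracy_score, matthews_corrcoef,
                             recall_score, roc_auc_score)

from mieqsar.metrics import (balanced_accuracy, compare_with_experiment,
                             compute_metrics, mean_report, roc_auc,
                             y_randomization, zscore)
from mieqsar.qsar import ModelConfig, GAConfig
from mieqsar.synthetic import GeneratorSpec, generate_descriptor_dataset


def test_hand_computed_confusion_arithmetic():
    # TP=2, FP=1, TN=3, FN=2
    y_true = [1, 1, 1, 1, 0, 0, 0, 0]
    y_pred = [1, 1, 0, 0, 1, 0, 0, 0]
    rep = compute_metrics(y_true, y_pred)
    assert (rep.tp, rep.fp, rep.tn, rep.fn) == (2, 1, 3, 2)
    assert rep.acc == pytest.approx(5 / 8)
    assert rep.sensitivity == pytest.approx(0.5)
    assert rep.specificity == pytest.approx(0.75)
    assert rep.ba == pytest.approx(0.625)
    denom = math.sqrt((2 + 1) * (2 + 2) * (3 + 1) * (3 + 2))
    assert rep.mcc == pytest.approx((2 * 3 - 1 * 2) / denom)


def test_one_miss_in_five_gives_point_eight_accuracy():
    rep = compute_metrics([1, 0, 0, 0, 0], [0, 0, 0, 0, 0])
    assert rep.acc == pytest.approx(0.80)


def test_perfect_prediction():
    rep = compute_metrics([1, 1, 0, 0], [1, 1, 0, 0], [2.0, 1.5, -1.0, -2.0])
    assert (rep.acc, rep.mcc, rep.auc) == (1.0, 1.0, 1.0)


def test_degenerate_mcc_is_zero():
    rep = compute_metrics([1, 1], [1, 1])
    assert rep.mcc == 0.0


def oracle_counts(y_true, y_pred):
    """Element-by-element confusion enumeration, no vectorisation."""
    tp = fp = tn = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 1:
            fp += 1
        elif t == 0 and p == 0:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


def test_metrics_agree_with_enumeration_oracle_on_all_length8_vectors():
    """Exhaustive confusion-count oracle over all 2^8 x 2^8 label vectors."""
    vectors = list(itertools.product([0, 1], repeat=8))
    for y_true in vectors:
        for y_pred in vectors:
            rep = compute_metrics(y_true, y_pred)
            tp, fp, tn, fn = oracle_counts(y_true, y_pred)
            assert (rep.tp, rep.fp, rep.tn, rep.fn) == (tp, fp, tn, fn)
            assert rep.acc == pytest.approx((tp + tn) / 8)
            assert rep.sensitivity == pytest.approx(
                tp / (tp + fn) if tp + fn else 0.0)
            assert rep.specificity == pytest.approx(
                tn / (tn + fp) if tn + fp else 0.0)
            assert rep.ba == pytest.approx(
                (rep.sensitivity + rep.specificity) / 2)
            d = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
            assert rep.mcc == pytest.approx(
                (tp * tn - fp * fn) / d if d else 0.0, abs=1e-12)


def test_metrics_agree_with_sklearn_on_random_vectors():
    rng = np.random.default_rng(17)
    for _ in range(100):
        n = int(rng.integers(2, 40))
        y_true = rng.integers(0, 2, n)
        y_pred = rng.integers(0, 2, n)
        rep = compute_metrics(y_true, y_pred)
        assert rep.acc == pytest.approx(accuracy_score(y_true, y_pred))
        assert rep.sensitivity == pytest.approx(
            recall_score(y_true, y_pred, pos_label=1, zero_division=0))
        assert rep.specificity == pytest.approx(
            recall_score(y_true, y_pred, pos_label=0, zero_division=0))
        assert rep.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred),
                                        abs=1e-12)


def test_auc_matches_sklearn_with_ties():
    rng = np.random.default_rng(0)
    for _ in range(25):
        n = int(rng.integers(4, 40))
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            continue
        scores = np.round(rng.normal(size=n), 1)  # coarse grid forces ties
        assert roc_auc(y, scores) == pytest.approx(roc_auc_score(y, scores))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 1), st.integers(-500, 500)),
                min_size=4, max_size=60))
def test_auc_invariant_under_monotone_score_transform(pairs):
    # scores on a coarse grid so strictly monotone maps cannot merge
    # distinct values through float rounding
    y = np.array([p[0] for p in pairs])
    s = np.array([p[1] for p in pairs]) / 10.0
    if y.min() == y.max():
        return
    base = roc_auc(y, s)
    assert roc_auc(y, 3.0 * s + 7.0) == pytest.approx(base)
    assert roc_auc(y, np.exp(s / 25.0)) == pytest.approx(base)


def test_ba_identity():
    assert balanced_accuracy(0.83, 0.81) == pytest.approx(0.82)


def test_zscore_arithmetic():
    assert zscore(0.9, 0.5, 0.1) == pytest.approx(4.0)
    assert zscore(0.5, 0.5, 0.2) == 0.0
    with pytest.raises(ZeroDivisionError):
        zscore(0.9, 0.5, 0.0)


def test_empty_and_mismatched_inputs_raise():
    with pytest.raises(ValueError):
        compute_metrics([], [])
    with pytest.raises(ValueError):
        compute_metrics([1, 0], [1])


def _yrand_config():
    return ModelConfig(cv_folds=5, seed=0,
                       ga=GAConfig(population_size=10, n_generations=5))


def test_y_randomization_verdicts_on_signal_vs_noise():
    sep_spec = GeneratorSpec(n_pos=60, n_neg=60, n_descriptors=5,
                             n_informative=2, class_separation=6.0,
                             overlap_fraction=0.0, label_noise=0.0, seed=30)
    matrix, labels, _ = generate_descriptor_dataset(sep_spec)
    rep = y_randomization(matrix, labels, ["D001", "D002"], _yrand_config(),
                          n_shuffles=30, seed=0)
    assert rep.robust and rep.z_acc > 3.0 and rep.z_mcc > 3.0

    noise_spec = GeneratorSpec(n_pos=60, n_neg=60, n_descriptors=5,
                               n_informative=2, class_separation=0.0,
                               overlap_fraction=0.0, label_noise=0.0,
                               seed=31)
    nmatrix, nlabels, _ = generate_descriptor_dataset(noise_spec)
    nrep = y_randomization(nmatrix, nlabels, ["D001", "D002"],
                           _yrand_config(), n_shuffles=30, seed=0)
    assert not nrep.robust and nrep.z_acc < 3.0


def test_permuted_models_converge_to_prevalence():
    """Mean random-model ACC approaches max(prevalence, 1-prevalence)."""
    spec = GeneratorSpec(n_pos=30, n_neg=90, n_descriptors=4,
                         n_informative=1, class_separation=5.0,
                         overlap_fraction=0.0, label_noise=0.0, seed=32)
    matrix, labels, _ = generate_descriptor_dataset(spec)
    rep = y_randomization(matrix, labels, ["D001"], _yrand_config(),
                          n_shuffles=40, seed=1)
    prevalence = max(np.mean(labels), 1 - np.mean(labels))
    assert abs(rep.acc_ran_avg - prevalence) < 0.12


def test_compare_with_experiment_table():
    predicted = {"a": 1, "b": 0, "c": 1}
    experimental = {"a": 1, "b": 1, "c": 1}
    acc, table = compare_with_experiment(predicted, experimental)
    assert acc == pytest.approx(2 / 3)
    assert table.loc["b", "agree"] == False  # noqa: E712
    acc2, _ = compare_with_experiment(predicted, predicted)
    assert acc2 == 1.0
    with pytest.raises(ValueError):
        compare_with_experiment({"a": 1}, {"b": 1})


def test_mean_report_averages_metrics():
    r1 = compute_metrics([1, 0], [1, 0])
    r2 = compute_metrics([1, 0], [0, 1])
    avg = mean_report([r1, r2])
    assert avg["acc"] == pytest.approx(0.5)
    assert avg["n"] == 4
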