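"""Splitting, GA descriptor selection, SVM training and validation flow."""

import numpy as np
import pytest

from mieqsar.io import CompoundRecord, CompoundSet
from mieqsar.qsar import (GAConfig, ModelConfig, TrainedModel, cross_validate,
                          exhaustive_select_descriptors,
                          ga_select_descriptors, repeated_external_validation,
                          split_train_external, train_svm)
from mieqsar.synthetic import GeneratorSpec, generate_descriptor_dataset
from tests.conftest import matrix_from_array


def _labeled_set(n_pos, n_neg):
    recs = [CompoundRecord(f"p{i}", "CCO", label=1) for i in range(n_pos)]
    recs += [CompoundRecord(f"n{i}", "CCN", label=0) for i in range(n_neg)]
    return CompoundSet(recs)


def test_split_is_stratified_disjoint_and_exhaustive():
    cset = _labeled_set(50, 50)
    train, ext = split_train_external(cset, 0.2, seed=0)
    assert len(train) == 80 and len(ext) == 20
    assert sum(r.label for r in train.records) == 40
    assert sum(r.label for r in ext.records) == 10
    assert set(train.ids) | set(ext.ids) == set(cset.ids)
    assert set(train.ids) & set(ext.ids) == set()


def test_split_deterministic_per_seed_distinct_across_seeds():
    cset = _labeled_set(40, 40)
    first = split_train_external(cset, 0.2, seed=5)
    second = split_train_external(cset, 0.2, seed=5)
    assert first[1].ids == second[1].ids
    externals = {tuple(sorted(split_train_external(cset, 0.2, seed=s)[1].ids))
                 for s in range(5)}
    assert len(externals) == 5   # 5 seeds, 5 distinct 20% external sets


def test_split_rejects_tiny_class():
    cset = _labeled_set(1, 10)
    with pytest.raises(ValueError):
        split_train_external(cset, 0.2, seed=0)


def _small_selection_problem(seed=0):
    """One perfectly separating descriptor among 10, n=60."""
    spec = GeneratorSpec(n_pos=30, n_neg=30, n_descriptors=10,
                         n_informative=1, class_separation=8.0,
                         overlap_fraction=0.0, label_noise=0.0, seed=seed)
    return generate_descriptor_dataset(spec)


def test_ga_finds_separating_descriptor_and_beats_full_mask():
    matrix, labels, truth = _small_selection_problem()
    ga = GAConfig(n_generations=30, seed=1)
    mc = ModelConfig(seed=1)
    subset = ga_select_descriptors(matrix, labels, ga, mc)
    assert truth["informative"][0] in subset
    from mieqsar.qsar import _cv_fitness_factory
    fitness = _cv_fitness_factory(matrix, np.asarray(labels), ga, mc)
    chosen = np.array([n in subset for n in matrix.descriptor_names])
    assert fitness(chosen) >= fitness(np.ones(10, dtype=bool))


def test_ga_matches_exhaustive_oracle_on_small_problem():
    matrix, labels, truth = _small_selection_problem(seed=3)
    ga = GAConfig(n_generations=40, seed=2)
    mc = ModelConfig(seed=2)
    ga_subset = ga_select_descriptors(matrix, labels, ga, mc)
    oracle_subset, oracle_fit = exhaustive_select_descriptors(
        matrix, labels, ga, mc)
    from mieqsar.qsar import _cv_fitness_factory
    fitness = _cv_fitness_factory(matrix, np.asarray(labels), ga, mc)
    ga_fit = fitness(np.array([n in ga_subset
                               for n in matrix.descriptor_names]))
    assert truth["informative"][0] in oracle_subset
    assert ga_fit == pytest.approx(oracle_fit, abs=1e-12)


def test_single_descriptor_is_selected():
    matrix, labels, _ = _small_selection_problem()
    single = matrix.select_columns(["D001"])
    ga = GAConfig(size_penalty=0.0, n_generations=5, seed=0)
    assert ga_select_descriptors(single, labels, ga) == ["D001"]


def test_ga_deterministic_for_fixed_seed():
    matrix, labels, _ = _small_selection_problem(seed=5)
    ga = GAConfig(n_generations=15, seed=11)
    a = ga_select_descriptors(matrix, labels, ga)
    b = ga_select_descriptors(matrix, labels, ga)
    assert a == b


def test_train_svm_separable_toy_perfect_recall():
    vals = np.array([[0, 0], [0, 1], [1, 0], [1, 1],
                     [10, 10], [10, 11], [11, 10], [11, 11]], dtype=float)
    m = matrix_from_array(vals)
    labels = [0] * 4 + [1] * 4
    model = train_svm(m, labels, m.descriptor_names)
    pred, scores = model.predict(m)
    assert np.array_equal(pred, labels)
    # decision score sign is consistent with the predicted label
    assert np.all((scores > 0) == (pred == 1))


def test_train_svm_rejects_single_class_and_empty_subset():
    m = matrix_from_array(np.random.default_rng(0).normal(size=(6, 2)))
    with pytest.raises(ValueError):
        train_svm(m, [1] * 6, m.descriptor_names)
    with pytest.raises(ValueError):
        train_svm(m, [0, 1] * 3, [])


def test_model_json_round_trip_predicts_identically(tmp_path):
    matrix, labels, _ = _small_selection_problem(seed=2)
    model = train_svm(matrix, labels, ["D001", "D004"])
    path = tmp_path / "model.json"
    model.to_json(path)
    back = TrainedModel.from_json(path)
    p1, s1 = model.predict(matrix)
    p2, s2 = back.predict(matrix)
    assert np.array_equal(p1, p2)
    assert np.allclose(s1, s2)


def test_decision_scores_match_sklearn_decision_function():
    from sklearn.svm import SVC
    matrix, labels, _ = _small_selection_problem(seed=8)
    subset = ["D001", "D002"]
    model = train_svm(matrix, labels, subset)
    z = (matrix.select_columns(subset).values - model.scaler_mean) \
        / model.scaler_scale
    ref = SVC(C=5.0, gamma=1.0).fit(z, labels)
    assert np.allclose(model.decision_function(matrix),
                       ref.decision_function(z), atol=1e-8)


def test_cross_validate_separable_is_perfect_and_deterministic():
    matrix, labels, _ = _small_selection_problem(seed=4)
    res1 = cross_validate(matrix, labels, ["D001"], ModelConfig(seed=0))
    assert res1.mean["acc"] == 1.0 and res1.mean["mcc"] == 1.0
    res2 = cross_validate(matrix, labels, ["D001"], ModelConfig(seed=0))
    assert [r.to_dict() for r in res1.fold_reports] == \
        [r.to_dict() for r in res2.fold_reports]


def test_cross_validate_shuffled_labels_near_chance():
    rng = np.random.default_rng(0)
    matrix, labels, _ = _small_selection_problem(seed=6)
    shuffled = rng.permutation(labels)
    res = cross_validate(matrix, shuffled, ["D001", "D002"],
                         ModelConfig(seed=0))
    # binomial null: ACC within 3 SE of 0.5 at n=60
    se = np.sqrt(0.25 / 60)
    assert abs(res.pooled.acc - 0.5) < 3 * se + 0.05


def test_repeated_external_validation_separable():
    spec = GeneratorSpec(n_pos=40, n_neg=40, n_descriptors=6,
                         n_informative=1, class_separation=10.0,
                         overlap_fraction=0.0, label_noise=0.0, seed=12)
    matrix, labels, _ = generate_descriptor_dataset(spec)
    mc = ModelConfig(n_repeats=3, ga=GAConfig(population_size=20,
                                              n_generations=10, seed=0))
    result = repeated_external_validation(matrix, labels, mc)
    assert result.external_mean["acc"] == 1.0
    for rep in result.external_reports:
        assert rep.ba == pytest.approx(
            (rep.sensitivity + rep.specificity) / 2)
    assert result.external_mean["ba"] == pytest.approx(np.mean(
        [r.ba for r in result.external_reports]))


def test_no_information_leak_from_external_rows():
    """Perturbing rows outside the training split leaves the model unchanged."""
    spec = GeneratorSpec(n_pos=30, n_neg=30, n_descriptors=5,
                         n_informative=2, class_separation=2.0,
                         overlap_fraction=0.0, label_noise=0.0, seed=13)
    matrix, labels, _ = generate_descriptor_dataset(spec)
    from mieqsar.qsar import split_ids
    train_ids, ext_ids = split_ids(matrix.compound_ids, labels, 0.2, seed=0)
    pos = {c: i for i, c in enumerate(matrix.compound_ids)}
    tr_labels = np.asarray(labels)[[pos[i] for i in train_ids]]
    tr = matrix.select_rows(train_ids)
    ga = GAConfig(population_size=10, n_generations=5, seed=0)
    subset1 = ga_select_descriptors(tr, tr_labels, ga)
    model1 = train_svm(tr, tr_labels, subset1)

    corrupted = matrix_from_array(matrix.values.copy(),
                                  ids=matrix.compound_ids,
                                  names=matrix.descriptor_names)
    for i in ext_ids:
        corrupted.values[pos[i]] += 1000.0
    tr2 = corrupted.select_rows(train_ids)
    subset2 = ga_select_descriptors(tr2, tr_labels, ga)
    model2 = train_svm(tr2, tr_labels, subset2)
    assert subset1 == subset2
    assert np.array_equal(model1.support_vectors, model2.support_vectors)
    assert model1.intercept == model2.intercept
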