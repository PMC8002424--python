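"""GA descriptor selection wrapped around an RBF-SVM classifier.

Model development follows a fixed recipe: the labeled pool is split
stratified 80/20 into training and external validation; a genetic
algorithm searches descriptor-inclusion bitmasks, scoring each candidate
subset by mean stratified 10-fold cross-validated balanced accuracy of an
RBF-SVM (C = 5.0, γ = 1.0) minus a small per-descriptor parsimony penalty;
the winning subset is refitted on the training split and scored on the
held-out external split. The whole procedure is repeated over several
seeded splits and the external metrics averaged.

Everything downstream of the split sees training data only — the scaler,
the GA fitness and the SVM fit — so external rows cannot leak into model
construction.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .descriptors import DescriptorMatrix
from .io import CompoundSet, Endpoint
from .metrics import PerformanceReport, compute_metrics, mean_report


class FitnessKind(str, Enum):
    CV_ACCURACY = "CV_ACCURACY"
    CV_BALANCED_ACCURACY = "CV_BALANCED_ACCURACY"


@dataclass
class GAConfig:
    """Genetic-algorithm search settings for descriptor selection.

    Defaults: population 50 for 100 generations with uniform crossover
    (p = 0.6), per-gene bit-flip mutation (p = 1/m), tournament selection
    of size 3, sparse initialisation (inclusion p = 0.1) and early stop
    after ``patience`` generations without improvement of the best fitness.
    """

    population_size: int = 50
    n_generations: int = 100
    crossover_prob: float = 0.6
    mutation_prob: Optional[float] = None   # None -> 1/m
    fitness: FitnessKind = FitnessKind.CV_BALANCED_ACCURACY
    size_penalty: float = 0.001
    tournament_size: int = 3
    init_prob: float = 0.1
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for p in (self.crossover_prob, self.init_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")

    @classmethod
    def fast(cls, seed: int = 0) -> "GAConfig":
        """Reduced search budget for large training sets."""
        return cls(population_size=24, n_generations=30, patience=8, seed=seed)


@dataclass
class ModelConfig:
    """SVM and validation-scheme settings (RBF kernel throughout)."""

    C: float = 5.0
    gamma: float = 1.0
    cv_folds: int = 10
    external_fraction: float = 0.2
    n_repeats: int = 5
    ga: GAConfig = field(default_factory=GAConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if not 0 < self.external_fraction < 1:
            raise ValueError("external_fraction must lie in (0, 1)")


@dataclass
class TrainedModel:
    """A fitted RBF-SVM on a selected descriptor subset.

    Prediction is computed from the stored support data, so a model
    round-tripped through JSON predicts identically:
    f(x) = Σ_i α_i exp(−γ‖x_scaled − sv_i‖²) + b, label 1 iff f(x) > 0.
    """

    endpoint: Endpoint
    selected_descriptors: list[str]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    C: float
    gamma: float
    training_fingerprint: str = ""

    def decision_function(self, matrix: DescriptorMatrix) -> np.ndarray:
        sub = matrix.select_columns(self.selected_descriptors)
        if sub.missing_mask.any():
            raise ValueError("query matrix has missing cells")
        z = (sub.values - self.scaler_mean) / self.scaler_scale
        d2 = ((z[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(-1)
        return np.exp(-self.gamma * d2) @ self.dual_coef + self.intercept

    def predict(self, matrix: DescriptorMatrix) -> tuple[np.ndarray, np.ndarray]:
        """Return (binary labels, real-valued decision scores)."""
        scores = self.decision_function(matrix)
        return (scores > 0).astype(int), scores

    def to_json(self, path: str | Path) -> None:
        payload = {
            "endpoint": self.endpoint.value,
            "selected_descriptors": self.selected_descriptors,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "C": self.C,
            "gamma": self.gamma,
            "training_fingerprint": self.training_fingerprint,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedModel":
        d = json.loads(Path(path).read_text())
        return cls(
            endpoint=Endpoint(d["endpoint"]),
            selected_descriptors=d["selected_descriptors"],
            scaler_mean=np.asarray(d["scaler_mean"]),
            scaler_scale=np.asarray(d["scaler_scale"]),
            support_vectors=np.asarray(d["support_vectors"]),
            dual_coef=np.asarray(d["dual_coef"]),
            intercept=float(d["intercept"]),
            C=float(d["C"]),
            gamma=float(d["gamma"]),
            training_fingerprint=d.get("training_fingerprint", ""),
        )


def split_train_external(
    cset: CompoundSet, fraction: float, seed: int
) -> tuple[CompoundSet, CompoundSet]:
    """Stratified split of a labeled compound set; ``fraction`` is the
    external share. Reproducible per seed."""
    labels = [r.label for r in cset.records]
    if any(l is None for l in labels):
        raise ValueError("all records must be labeled for splitting")
    train_ids, ext_ids = split_ids(cset.ids, labels, fraction, seed)
    return cset.subset(train_ids), cset.subset(ext_ids)


def split_ids(
    ids: Sequence[str], labels: Sequence[int], fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    labels = np.asarray(labels, dtype=int)
    for c in np.unique(labels):
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c} has fewer than 2 members; "
                             "stratified split impossible")
    train, ext = train_test_split(
        list(ids), test_size=fraction, stratify=labels, random_state=seed,
        shuffle=True,
    )
    return list(train), list(ext)


def _fold_indices(labels: np.ndarray, n_folds: int, seed: int) -> list:
    n_folds = min(n_folds, int(np.bincount(labels).min()))
    if n_folds < 2:
        raise ValueError("not enough samples per class for cross-validation")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(labels)), labels))


def _svc(config: ModelConfig) -> SVC:
    return SVC(C=config.C, gamma=config.gamma, kernel="rbf")


def _cv_fitness_factory(
    matrix: DescriptorMatrix,
    labels: np.ndarray,
    ga_config: GAConfig,
    model_config: ModelConfig,
):
    """Build the memoised chromosome-fitness function.

    Fitness = mean k-fold CV score of the SVM on the masked, standardized
    training matrix, minus size_penalty × (number of selected descriptors).
    """
    std = matrix.values.std(axis=0, ddof=0)
    std_safe = np.where(std == 0, 1.0, std)
    z = (matrix.values - matrix.values.mean(axis=0)) / std_safe
    folds = _fold_indices(labels, model_config.cv_folds, model_config.seed)
    balanced = ga_config.fitness is FitnessKind.CV_BALANCED_ACCURACY
    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        key = mask.tobytes()
        if key in cache:
            return cache[key]
        k = int(mask.sum())
        if k == 0:
            return -np.inf
        x = z[:, mask]
        scores = []
        for tr, te in folds:
            clf = _svc(model_config).fit(x[tr], labels[tr])
            pred = clf.predict(x[te])
            if balanced:
                rep = compute_metrics(labels[te], pred)
                scores.append(rep.ba)
            else:
                scores.append(float((pred == labels[te]).mean()))
        value = float(np.mean(scores)) - ga_config.size_penalty * k
        cache[key] = value
        return value

    return fitness


def ga_select_descriptors(
    train_matrix: DescriptorMatrix,
    labels: Sequence[int],
    ga_config: Optional[GAConfig] = None,
    model_config: Optional[ModelConfig] = None,
) -> list[str]:
    """Search descriptor-inclusion bitmasks with a generational GA.

    Returns the descriptor names of the best chromosome ever seen. Fully
    deterministic for a fixed ``ga_config.seed``.
    """
    ga = ga_config or GAConfig()
    mc = model_config or ModelConfig()
    labels = np.asarray(labels, dtype=int)
    m = len(train_matrix.descriptor_names)
    if m < 1:
        raise ValueError("no descriptors to select from")
    mut_p = ga.mutation_prob if ga.mutation_prob is not None else 1.0 / m
    rng = np.random.default_rng(ga.seed)
    fitness = _cv_fitness_factory(train_matrix, labels, ga, mc)

    def random_mask() -> np.ndarray:
        mask = rng.random(m) < ga.init_prob
        if not mask.any():
            mask[rng.integers(m)] = True
        return mask

    pop = [random_mask() for _ in range(ga.population_size)]
    fits = np.array([fitness(ind) for ind in pop])
    best_idx = int(np.argmax(fits))
    best_mask, best_fit = pop[best_idx].copy(), fits[best_idx]
    stale = 0

    for _ in range(ga.n_generations):
        children = []
        while len(children) < ga.population_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, ga.population_size,
                                          ga.tournament_size)
                winner = contenders[np.argmax(fits[contenders])]
                parents.append(pop[winner].copy())
            a, b = parents
            if rng.random() < ga.crossover_prob:
                swap = rng.random(m) < 0.5
                a[swap], b[swap] = b[swap].copy(), a[swap].copy()
            for child in (a, b):
                flip = rng.random(m) < mut_p
                child ^= flip
                children.append(child)
        pop = children[: ga.population_size]
        fits = np.array([fitness(ind) for ind in pop])
        # elitism: the best-ever chromosome replaces the current worst
        worst = int(np.argmin(fits))
        pop[worst] = best_mask.copy()
        fits[worst] = best_fit
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = fits[gen_best]
            best_mask = pop[gen_best].copy()
            stale = 0
        else:
            stale += 1
            if stale >= ga.patience:
                break
    return [n for n, b in zip(train_matrix.descriptor_names, best_mask) if b]


def exhaustive_select_descriptors(
    train_matrix: DescriptorMatrix,
    labels: Sequence[int],
    ga_config: Optional[GAConfig] = None,
    model_config: Optional[ModelConfig] = None,
) -> tuple[list[str], float]:
    """Enumerate every non-empty descriptor subset (oracle for small m)."""
    ga = ga_config or GAConfig()
    mc = model_config or ModelConfig()
    labels = np.asarray(labels, dtype=int)
    m = len(train_matrix.descriptor_names)
    if m > 16:
        raise ValueError("exhaustive search is limited to m <= 16")
    fitness = _cv_fitness_factory(train_matrix, labels, ga, mc)
    best_fit, best_mask = -np.inf, None
    for code in range(1, 2 ** m):
        mask = np.array([(code >> i) & 1 for i in range(m)], dtype=bool)
        f = fitness(mask)
        if f > best_fit:
            best_fit, best_mask = f, mask
    names = [n for n, b in zip(train_matrix.descriptor_names, best_mask) if b]
    return names, best_fit


def train_svm(
    train_matrix: DescriptorMatrix,
    labels: Sequence[int],
    subset: Sequence[str],
    model_config: Optional[ModelConfig] = None,
    endpoint: Endpoint = Endpoint.UNLABELED,
) -> TrainedModel:
    """Fit the RBF-SVM on the selected subset, standardized on train only."""
    mc = model_config or ModelConfig()
    subset = list(subset)
    if not subset:
        raise ValueError("descriptor subset must be non-empty")
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels contain a single class")
    sub = train_matrix.select_columns(subset)
    mean = sub.values.mean(axis=0)
    scale = sub.values.std(axis=0, ddof=0)
    scale = np.where(scale == 0, 1.0, scale)
    z = (sub.values - mean) / scale
    clf = _svc(mc).fit(z, labels)
    # sklearn orients the decision function toward classes_[1]; our stored
    # form assumes positive score = label 1
    sign = 1.0 if clf.classes_[1] == 1 else -1.0
    fingerprint = hashlib.sha256(
        z.tobytes() + labels.tobytes() + ",".join(subset).encode()
    ).hexdigest()[:16]
    return TrainedModel(
        endpoint=endpoint,
        selected_descriptors=subset,
        scaler_mean=mean,
        scaler_scale=scale,
        support_vectors=z[clf.support_],
        dual_coef=sign * clf.dual_coef_[0],
        intercept=float(sign * clf.intercept_[0]),
        C=mc.C,
        gamma=mc.gamma,
        training_fingerprint=fingerprint,
    )


@dataclass
class CVResult:
    """Per-fold reports, their metric-wise mean, and the pooled report."""

    fold_reports: list[PerformanceReport]
    mean: dict
    pooled: PerformanceReport


def cross_validate(
    matrix: DescriptorMatrix,
    labels: Sequence[int],
    subset: Sequence[str],
    model_config: Optional[ModelConfig] = None,
) -> CVResult:
    """Stratified k-fold internal validation on a descriptor subset.

    Each fold standardizes and fits on its training part only. Metrics are
    reported both as the mean over folds and pooled over all held-out
    predictions.
    """
    mc = model_config or ModelConfig()
    labels = np.asarray(labels, dtype=int)
    folds = _fold_indices(labels, mc.cv_folds, mc.seed)
    reports = []
    pooled_true, pooled_pred, pooled_score = [], [], []
    for tr, te in folds:
        tr_mat = matrix.select_rows([matrix.compound_ids[i] for i in tr])
        te_mat = matrix.select_rows([matrix.compound_ids[i] for i in te])
        model = train_svm(tr_mat, labels[tr], subset, mc)
        pred, score = model.predict(te_mat)
        reports.append(compute_metrics(labels[te], pred, score))
        pooled_true.extend(labels[te])
        pooled_pred.extend(pred)
        pooled_score.extend(score)
    pooled = compute_metrics(pooled_true, pooled_pred, pooled_score)
    return CVResult(reports, mean_report(reports), pooled)


@dataclass
class RepeatedValidationResult:
    """Outcome of n seeded 80/20 repeats: per-repeat and mean metrics."""

    external_reports: list[PerformanceReport]
    internal_results: list[CVResult]
    selected_descriptors: list[list[str]]
    external_mean: dict
    internal_mean: dict
    models: list[TrainedModel]


def repeated_external_validation(
    matrix: DescriptorMatrix,
    labels: Sequence[int],
    model_config: Optional[ModelConfig] = None,
    endpoint: Endpoint = Endpoint.UNLABELED,
    ga_mode: str = "per_repeat",
) -> RepeatedValidationResult:
    """Average model performance over ``n_repeats`` seeded 80/20 splits.

    ``ga_mode='per_repeat'`` reruns descriptor selection inside every
    training split (no selection leak across repeats); ``'fixed'`` selects
    once on the first training split and reuses that subset — cheaper and
    appropriate once the subset is considered part of the model definition.
    """
    mc = model_config or ModelConfig()
    labels = np.asarray(labels, dtype=int)
    ids = matrix.compound_ids
    ext_reports, int_results, all_subsets, models = [], [], [], []
    fixed_subset: Optional[list[str]] = None
    for rep in range(mc.n_repeats):
        seed = mc.seed + rep
        train_ids, ext_ids = split_ids(ids, labels, mc.external_fraction, seed)
        pos = {cid: i for i, cid in enumerate(ids)}
        tr_mat = matrix.select_rows(train_ids)
        ex_mat = matrix.select_rows(ext_ids)
        tr_lab = labels[[pos[i] for i in train_ids]]
        ex_lab = labels[[pos[i] for i in ext_ids]]
        rep_mc = replace(mc, seed=seed, ga=replace(mc.ga, seed=seed))
        if ga_mode == "per_repeat" or fixed_subset is None:
            subset = ga_select_descriptors(tr_mat, tr_lab, rep_mc.ga, rep_mc)
            if ga_mode == "fixed":
                fixed_subset = subset
        else:
            subset = fixed_subset
        model = train_svm(tr_mat, tr_lab, subset, rep_mc, endpoint)
        pred, score = model.predict(ex_mat)
        ext_reports.append(compute_metrics(ex_lab, pred, score))
        int_results.append(cross_validate(tr_mat, tr_lab, subset, rep_mc))
        all_subsets.append(subset)
        models.append(model)
    return RepeatedValidationResult(
        external_reports=ext_reports,
        internal_results=int_results,
        selected_descriptors=all_subsets,
        external_mean=mean_report(ext_reports),
        internal_mean=mean_report(
            [r for res in int_results for r in res.fold_reports]
        ),
        models=models,
    )
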