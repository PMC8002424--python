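"""Binary-classification metrics and the Y-randomization robustness test.

The six indices used throughout — accuracy (ACC), area under the ROC curve
(AUC), Matthews correlation coefficient (MCC), sensitivity, specificity
and balanced accuracy (BA, the mean of sensitivity and specificity) — are
computed directly from confusion counts. AUC is the probability that a
randomly chosen positive outranks a randomly chosen negative by decision
score, with ties counted one half.

Y-randomization retrains the model on label-permuted data many times; the
original model is called robust when the z-scores of both ACC and MCC
against the permuted ensemble exceed 3.0:

    Z_ACC = (ACC_ori − ACC_ran_avg) / σ_ran_ACC
    Z_MCC = (MCC_ori − MCC_ran_avg) / σ_ran_MCC
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy.stats import rankdata

if TYPE_CHECKING:  # pragma: no cover
    from .descriptors import DescriptorMatrix
    from .qsar import ModelConfig


@dataclass
class PerformanceReport:
    """The six indices plus the confusion counts they derive from."""

    acc: float
    auc: float
    mcc: float
    sensitivity: float
    specificity: float
    ba: float
    tp: int
    fp: int
    tn: int
    fn: int
    n: int

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


@dataclass
class YRandomizationReport:
    acc_ori: float
    mcc_ori: float
    acc_ran_avg: float
    mcc_ran_avg: float
    sigma_ran_acc: float
    sigma_ran_mcc: float
    z_acc: float
    z_mcc: float
    n_random_models: int

    @property
    def robust(self) -> bool:
        """Both z-scores above 3.0."""
        return self.z_acc > 3.0 and self.z_mcc > 3.0

    def to_dict(self) -> dict:
        return {**asdict(self), "robust": self.robust}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """BA is defined as the mean of sensitivity and specificity."""
    return (sensitivity + specificity) / 2.0


def zscore(original: float, random_avg: float, random_sd: float) -> float:
    """Standardized excess of the original metric over the permuted mean."""
    if random_sd == 0:
        raise ZeroDivisionError(
            "degenerate random ensemble: zero standard deviation"
        )
    return (original - random_avg) / random_sd


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUC: P(score_pos > score_neg) with ties counted 1/2."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return math.nan
    ranks = rankdata(scores)
    return (ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def compute_metrics(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    scores: Optional[Sequence[float]] = None,
) -> PerformanceReport:
    """Full report from true labels, predicted labels and decision scores.

    Degenerate rates (empty class) and a zero MCC denominator are reported
    as 0.0 rather than raising; AUC is NaN when scores are absent or a
    class is empty.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch between y_true and y_pred")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    n = int(y_true.size)
    acc = (tp + tn) / n
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    auc = roc_auc(y_true, scores) if scores is not None else math.nan
    return PerformanceReport(acc=acc, auc=auc, mcc=mcc, sensitivity=sens,
                             specificity=spec, ba=balanced_accuracy(sens, spec),
                             tp=tp, fp=fp, tn=tn, fn=fn, n=n)


def mean_report(reports: Sequence[PerformanceReport]) -> dict:
    """Metric-wise mean over reports (confusion counts are summed)."""
    out = {}
    for key in ("acc", "auc", "mcc", "sensitivity", "specificity", "ba"):
        vals = np.array([getattr(r, key) for r in reports])
        finite = vals[~np.isnan(vals)]
        out[key] = float(finite.mean()) if finite.size else math.nan
    for key in ("tp", "fp", "tn", "fn", "n"):
        out[key] = int(sum(getattr(r, key) for r in reports))
    return out


def y_randomization(
    train_matrix: "DescriptorMatrix",
    labels: Sequence[int],
    subset: Sequence[str],
    model_config: "ModelConfig",
    n_shuffles: int = 100,
    seed: int = 0,
) -> YRandomizationReport:
    """Permutation-null robustness test on ACC and MCC.

    The original model's ACC/MCC are measured by the configured
    cross-validation scheme; each random model repeats the identical
    scheme on a seeded permutation of the labels only. Standard deviations
    are the sample (n−1) kind.
    """
    from .qsar import cross_validate  # local import avoids a cycle

    if n_shuffles < 2:
        raise ValueError("n_shuffles must be at least 2")
    labels = np.asarray(labels, dtype=int)
    ori = cross_validate(train_matrix, labels, subset, model_config)
    acc_ori, mcc_ori = ori.mean["acc"], ori.mean["mcc"]
    rng = np.random.default_rng(seed)
    accs, mccs = [], []
    for _ in range(n_shuffles):
        perm = rng.permutation(labels)
        rep = cross_validate(train_matrix, perm, subset, model_config)
        accs.append(rep.mean["acc"])
        mccs.append(rep.mean["mcc"])
    acc_avg, mcc_avg = float(np.mean(accs)), float(np.mean(mccs))
    acc_sd = float(np.std(accs, ddof=1))
    mcc_sd = float(np.std(mccs, ddof=1))
    return YRandomizationReport(
        acc_ori=acc_ori, mcc_ori=mcc_ori,
        acc_ran_avg=acc_avg, mcc_ran_avg=mcc_avg,
        sigma_ran_acc=acc_sd, sigma_ran_mcc=mcc_sd,
        z_acc=zscore(acc_ori, acc_avg, acc_sd),
        z_mcc=zscore(mcc_ori, mcc_avg, mcc_sd),
        n_random_models=n_shuffles,
    )


def compare_with_experiment(
    predicted: dict[str, int], experimental: dict[str, int]
) -> tuple[float, pd.DataFrame]:
    """Agreement rate between model calls and experimental calls.

    Both dicts are keyed by compound id and must cover the same compounds.
    Returns the fraction of agreements plus a per-compound table.
    """
    if set(predicted) != set(experimental):
        raise ValueError("compound ids of predictions and experiments differ")
    if not predicted:
        raise ValueError("empty comparison")
    ids = sorted(predicted)
    rows = [{"id": i, "predicted": int(predicted[i]),
             "experimental": int(experimental[i]),
             "agree": int(predicted[i]) == int(experimental[i])}
            for i in ids]
    table = pd.DataFrame(rows).set_index("id")
    return float(table["agree"].mean()), table
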