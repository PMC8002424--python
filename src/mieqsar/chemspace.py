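"""PCA chemical space and applicability filtering by reference distance.

The training pool pulled from bioassay databases is dominated by
drug-discovery chemistry, while the screening population is biocides. To
keep the model inside its applicability domain, compounds are projected
into a PCA score space fitted on standardized descriptors, and a candidate
is retained only if its Euclidean distance to the biocide reference set
does not exceed the average reference–reference pairwise distance (the
"average biocide similarity distance").
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist
from sklearn.decomposition import PCA

from .descriptors import DescriptorMatrix
from .io import CompoundSet


class DistanceAggregation(str, Enum):
    MEAN = "MEAN"
    MIN = "MIN"


@dataclass
class ChemicalSpace:
    """Fitted standardizer + PCA basis + reference scores and threshold.

    ``threshold`` is the mean Euclidean distance over all unordered pairs
    of reference compounds in score space: a property of the reference set
    alone, against which any candidate is judged.
    """

    descriptor_names: list[str]
    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray          # (n_components, n_descriptors)
    explained_variance: np.ndarray
    reference_ids: list[str]
    reference_scores: np.ndarray    # (n_references, n_components)
    threshold: float

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def transform(self, matrix: DescriptorMatrix) -> np.ndarray:
        """Project a descriptor matrix into score space."""
        missing = [n for n in self.descriptor_names
                   if n not in matrix.descriptor_names]
        if missing:
            raise ValueError(
                f"query matrix lacks fitted descriptors: {missing[:5]}"
            )
        sub = matrix.select_columns(self.descriptor_names)
        if sub.missing_mask.any():
            raise ValueError("query matrix has missing cells; reduce first")
        z = (sub.values - self.mean) / self.scale
        return z @ self.components.T

    def to_json(self, path: str | Path) -> None:
        payload = {
            "descriptor_names": self.descriptor_names,
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "components": self.components.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "reference_ids": self.reference_ids,
            "reference_scores": self.reference_scores.tolist(),
            "threshold": self.threshold,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ChemicalSpace":
        d = json.loads(Path(path).read_text())
        return cls(
            descriptor_names=d["descriptor_names"],
            mean=np.asarray(d["mean"]),
            scale=np.asarray(d["scale"]),
            components=np.asarray(d["components"]),
            explained_variance=np.asarray(d["explained_variance"]),
            reference_ids=d["reference_ids"],
            reference_scores=np.asarray(d["reference_scores"]),
            threshold=float(d["threshold"]),
        )


def fit_chemical_space(
    matrix: DescriptorMatrix,
    reference_ids: Sequence[str],
    n_components: int = 2,
) -> ChemicalSpace:
    """Fit standardizer + PCA on the pooled matrix and set the threshold.

    The matrix should contain both reference and candidate compounds (the
    space is one shared projection). Descriptors are centered and scaled to
    unit variance over the fitted pool; constant columns are dropped with a
    warning. The distance threshold is the mean over all unordered
    reference pairs of their Euclidean score-space distance.
    """
    if matrix.missing_mask.any():
        raise ValueError("matrix has missing cells; run reduce_variables first")
    reference_ids = list(reference_ids)
    id_set = set(matrix.compound_ids)
    unknown = [r for r in reference_ids if r not in id_set]
    if unknown:
        raise ValueError(f"reference ids not in matrix: {unknown[:5]}")
    if len(reference_ids) < 2:
        raise ValueError("need at least 2 references to define a threshold")

    values = matrix.values
    std = values.std(axis=0, ddof=0)
    keep = std > 0
    if not keep.all():
        dropped = [n for n, k in zip(matrix.descriptor_names, keep) if not k]
        warnings.warn(
            f"dropping {len(dropped)} constant descriptor column(s) before "
            f"scaling: {dropped[:5]}"
        )
    names = [n for n, k in zip(matrix.descriptor_names, keep) if k]
    values = values[:, keep]
    mean = values.mean(axis=0)
    scale = values.std(axis=0, ddof=0)
    z = (values - mean) / scale

    n_components = min(n_components, min(z.shape))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(z)

    pos = {cid: i for i, cid in enumerate(matrix.compound_ids)}
    ref_scores = scores[[pos[r] for r in reference_ids]]
    threshold = float(pdist(ref_scores).mean())
    return ChemicalSpace(
        descriptor_names=names,
        mean=mean,
        scale=scale,
        components=pca.components_,
        explained_variance=pca.explained_variance_,
        reference_ids=reference_ids,
        reference_scores=ref_scores,
        threshold=threshold,
    )


def distance_to_references(
    space: ChemicalSpace,
    query_matrix: DescriptorMatrix,
    aggregation: DistanceAggregation | str = DistanceAggregation.MEAN,
) -> np.ndarray:
    """Per-query aggregated Euclidean distance to the reference scores."""
    aggregation = DistanceAggregation(aggregation)
    scores = space.transform(query_matrix)
    dists = cdist(scores, space.reference_scores)
    if aggregation is DistanceAggregation.MEAN:
        return dists.mean(axis=1)
    return dists.min(axis=1)


def filter_by_similarity(
    space: ChemicalSpace,
    candidate_set: CompoundSet,
    matrix: DescriptorMatrix,
    aggregation: DistanceAggregation | str = DistanceAggregation.MEAN,
) -> tuple[CompoundSet, CompoundSet, np.ndarray]:
    """Partition candidates into (retained, removed) by reference distance.

    A candidate is retained iff its aggregated distance is ≤ the space
    threshold (ties at the boundary are kept). Returns the two disjoint
    sets plus the per-candidate distances, aligned with ``candidate_set``.
    """
    sub = matrix.select_rows(candidate_set.ids)
    dists = distance_to_references(space, sub, aggregation)
    retained_ids = [r.id for r, d in zip(candidate_set.records, dists)
                    if d <= space.threshold]
    removed_ids = [r.id for r, d in zip(candidate_set.records, dists)
                   if d > space.threshold]
    return (candidate_set.subset(retained_ids),
            candidate_set.subset(removed_ids), dists)
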