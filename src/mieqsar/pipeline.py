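"""End-to-end orchestration: simulate → filter → balance → model → validate.

This is the narrative the analysis scripts, the CLI and the acceptance
checks all share: generate (or load) a labeled candidate pool plus a
biocide-like reference set, restrict candidates to the reference chemical
space, balance the classes by Tomek-link undersampling, then run the
GA+SVM model development with repeated external validation and, on
request, the Y-randomization robustness test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .chemspace import fit_chemical_space, filter_by_similarity
from .descriptors import DescriptorMatrix
from .imbalance import undersample_to_balance
from .io import CompoundSet, Endpoint
from .metrics import YRandomizationReport, y_randomization
from .qsar import (ModelConfig, RepeatedValidationResult,
                   repeated_external_validation)
from .synthetic import (GeneratorSpec, SyntheticDomainData,
                        generate_reference_and_candidates)


def _concat(a: DescriptorMatrix, b: DescriptorMatrix) -> DescriptorMatrix:
    if a.descriptor_names != b.descriptor_names:
        raise ValueError("descriptor columns differ")
    return DescriptorMatrix(
        a.compound_ids + b.compound_ids, a.descriptor_names,
        np.vstack([a.values, b.values]),
        np.vstack([a.missing_mask, b.missing_mask]),
    )


@dataclass
class EndpointStudyResult:
    """Everything one endpoint's pipeline run produced."""

    endpoint: Endpoint
    n_candidates: int
    n_retained: int
    n_removed: int
    threshold: float
    balanced_counts: dict[int, int]
    validation: RepeatedValidationResult
    y_randomization: Optional[YRandomizationReport]
    domain: SyntheticDomainData

    def summary(self) -> dict:
        out = {
            "endpoint": self.endpoint.value,
            "n_candidates": self.n_candidates,
            "n_retained": self.n_retained,
            "n_removed": self.n_removed,
            "chemspace_threshold": self.threshold,
            "balanced_counts": {str(k): v
                                for k, v in self.balanced_counts.items()},
            "external_mean": self.validation.external_mean,
            "internal_mean": self.validation.internal_mean,
            "selected_descriptors": self.validation.selected_descriptors,
        }
        if self.y_randomization is not None:
            out["y_randomization"] = self.y_randomization.to_dict()
        return out


def run_endpoint_study(
    spec: GeneratorSpec,
    model_config: Optional[ModelConfig] = None,
    endpoint: Endpoint = Endpoint.UNLABELED,
    ga_mode: str = "per_repeat",
    balance: bool = True,
    yrand_shuffles: int = 0,
) -> EndpointStudyResult:
    """Run the full pipeline on one synthetic endpoint dataset.

    ``yrand_shuffles`` > 0 additionally runs Y-randomization (on the
    balanced modeling set, with the first repeat's descriptor subset).
    """
    mc = model_config or ModelConfig()
    domain = generate_reference_and_candidates(spec)

    pool = _concat(domain.reference_matrix, domain.candidate_matrix)
    space = fit_chemical_space(pool, domain.reference_matrix.compound_ids)
    retained, removed, _ = filter_by_similarity(
        space, domain.candidate_set, domain.candidate_matrix)

    label_of = {cid: int(lab) for cid, lab in
                zip(domain.candidate_matrix.compound_ids,
                    domain.candidate_labels)}
    kept_ids = retained.ids
    kept_matrix = domain.candidate_matrix.select_rows(kept_ids)
    kept_labels = np.array([label_of[c] for c in kept_ids])

    if balance and (kept_labels == 0).sum() != (kept_labels == 1).sum():
        model_matrix, model_labels, _ = undersample_to_balance(
            kept_matrix, kept_labels, seed=mc.seed)
    else:
        model_matrix, model_labels = kept_matrix, kept_labels

    validation = repeated_external_validation(
        model_matrix, model_labels, mc, endpoint, ga_mode=ga_mode)

    yrand = None
    if yrand_shuffles > 0:
        yrand = y_randomization(
            model_matrix, model_labels,
            validation.selected_descriptors[0], mc,
            n_shuffles=yrand_shuffles, seed=mc.seed)

    return EndpointStudyResult(
        endpoint=endpoint,
        n_candidates=len(domain.candidate_set),
        n_retained=len(retained),
        n_removed=len(removed),
        threshold=space.threshold,
        balanced_counts={0: int((model_labels == 0).sum()),
                         1: int((model_labels == 1).sum())},
        validation=validation,
        y_randomization=yrand,
        domain=domain,
    )
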