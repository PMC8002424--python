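"""GA+SVM model development with five repeated external validations.

For each endpoint: five seeded 80/20 splits, GA descriptor selection on
the training side, RBF-SVM fit (C=5, γ=1), stratified 10-fold internal
validation and external scoring; the performance table holds the mean of
the six indices over the five repeats. Models and tables go to
results/models/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from mieqsar.descriptors import DescriptorMatrix
from mieqsar.io import Endpoint
from mieqsar.qsar import GAConfig, ModelConfig, repeated_external_validation

SEED = 1
ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "models"
ENDPOINTS = {"pparg": Endpoint.PPARG_INACTIVATION,
             "tlr4": Endpoint.TLR4_ACTIVATION}
GA_MODE = {"pparg": "fixed", "tlr4": "per_repeat"}  # pparg pool is large


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for tag, endpoint in ENDPOINTS.items():
        matrix = DescriptorMatrix.read_csv(
            ROOT / "curated" / f"{tag}_modeling_descriptors.csv")
        labels = pd.read_csv(ROOT / "curated" / f"{tag}_modeling_labels.csv",
                             dtype={"id": str}).set_index("id")["label"]
        y = np.array([labels[i] for i in matrix.compound_ids])
        mc = ModelConfig(ga=GAConfig.fast(SEED), seed=SEED, n_repeats=5)
        result = repeated_external_validation(matrix, y, mc, endpoint,
                                              ga_mode=GA_MODE[tag])
        result.models[0].to_json(OUT / f"{tag}_model.json")
        rows = [{"block": "internal", **{k: round(result.internal_mean[k], 3)
                                         for k in ("acc", "auc", "mcc",
                                                   "sensitivity",
                                                   "specificity", "ba")}},
                {"block": "external", **{k: round(result.external_mean[k], 3)
                                         for k in ("acc", "auc", "mcc",
                                                   "sensitivity",
                                                   "specificity", "ba")}}]
        table = pd.DataFrame(rows)
        table.to_csv(OUT / f"{tag}_performance.csv", index=False)
        (OUT / f"{tag}_selected_descriptors.json").write_text(
            json.dumps(result.selected_descriptors, indent=1))
        print(f"== {tag} ({endpoint.value}) ==")
        print("selected per repeat:", result.selected_descriptors)
        print(table.to_string(index=False))


if __name__ == "__main__":
    main()
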