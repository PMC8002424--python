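"""Chemical-space filtering and class balancing of the simulated pools.

For each endpoint: fit the PCA chemical space on references + candidates,
drop candidates beyond the average reference pairwise distance, then (for
the imbalanced PPAR-γ pool only) undersample the majority class to 1:1
with Tomek links. Writes the modeling tables under results/curated/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mieqsar.chemspace import filter_by_similarity, fit_chemical_space
from mieqsar.descriptors import DescriptorMatrix
from mieqsar.imbalance import undersample_to_balance
from mieqsar.io import CompoundRecord, CompoundSet

SEED = 1
ROOT = Path(__file__).resolve().parents[1] / "results"
DATA, OUT = ROOT / "data", ROOT / "curated"
BALANCE = {"pparg": True, "tlr4": False}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for tag, balance in BALANCE.items():
        cand = DescriptorMatrix.read_csv(DATA / f"{tag}_candidates.csv")
        ref = DescriptorMatrix.read_csv(DATA / f"{tag}_references.csv")
        labels = pd.read_csv(DATA / f"{tag}_labels.csv",
                             dtype={"id": str}).set_index("id")["label"]
        pool = DescriptorMatrix(
            ref.compound_ids + cand.compound_ids, cand.descriptor_names,
            np.vstack([ref.values, cand.values]),
            np.vstack([ref.missing_mask, cand.missing_mask]))
        space = fit_chemical_space(pool, ref.compound_ids)
        space.to_json(OUT / f"{tag}_chemical_space.json")
        cset = CompoundSet([CompoundRecord(i, "C", label=int(labels[i]))
                            for i in cand.compound_ids])
        retained, removed, _ = filter_by_similarity(space, cset, cand)
        print(f"{tag}: threshold {space.threshold:.3f}; retained "
              f"{len(retained)}/{len(cset)} ({len(removed)} removed)")
        kept = cand.select_rows(retained.ids)
        kept_labels = np.array([labels[i] for i in retained.ids])
        if balance:
            kept, kept_labels, log = undersample_to_balance(kept, kept_labels,
                                                            seed=SEED)
            log.write(OUT / f"{tag}_removal_log.csv")
            print(f"{tag}: balanced to "
                  f"{int((kept_labels == 1).sum())}/"
                  f"{int((kept_labels == 0).sum())}")
        kept.write_csv(OUT / f"{tag}_modeling_descriptors.csv")
        pd.DataFrame({"id": kept.compound_ids,
                      "label": kept_labels}).to_csv(
            OUT / f"{tag}_modeling_labels.csv", index=False)


if __name__ == "__main__":
    main()
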