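"""Generate the two synthetic endpoint datasets used by the downstream steps.

Writes, per endpoint, the candidate descriptor matrix with labels and the
biocide-like reference matrix under results/data/. The PPAR-γ-shaped pool
is 903 positives / 2181 negatives (imbalance ≈ 2.4:1); the TLR4-shaped
pool is 60/58 with a stronger class signal.
"""

from pathlib import Path

import pandas as pd

from mieqsar.synthetic import GeneratorSpec, generate_reference_and_candidates

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "data"

SPECS = {
    "pparg": GeneratorSpec(seed=SEED),
    "tlr4": GeneratorSpec(n_pos=60, n_neg=58, n_informative=2,
                          class_separation=3.0, overlap_fraction=0.05,
                          outlier_fraction=0.135, seed=SEED),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for tag, spec in SPECS.items():
        data = generate_reference_and_candidates(spec)
        data.candidate_matrix.write_csv(OUT / f"{tag}_candidates.csv")
        data.reference_matrix.write_csv(OUT / f"{tag}_references.csv")
        pd.DataFrame({"id": data.candidate_matrix.compound_ids,
                      "label": data.candidate_labels}).to_csv(
            OUT / f"{tag}_labels.csv", index=False)
        n_out = int((~data.truth["in_domain"]).sum())
        print(f"{tag}: {len(data.candidate_set)} candidates "
              f"({int(data.candidate_labels.sum())} positive), "
              f"{len(data.reference_set)} references, "
              f"{n_out} candidates placed out of domain")


if __name__ == "__main__":
    main()
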