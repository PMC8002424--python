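"""Binary-mixture screening of the synthetic biocide reference population.

Scores every reference compound with both trained endpoint models and
flags each pair (PPAR-γ-positive, TLR4-positive) as a candidate mixture
of concern for the converging pulmonary-fibrosis pathway.
"""

from pathlib import Path

from mieqsar.descriptors import DescriptorMatrix
from mieqsar.mixtures import screen_mixtures, write_mixture_report
from mieqsar.qsar import TrainedModel

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    screen = DescriptorMatrix.read_csv(ROOT / "data" / "pparg_references.csv")
    preds = {}
    for tag in ("pparg", "tlr4"):
        model = TrainedModel.from_json(ROOT / "models" / f"{tag}_model.json")
        labels, scores = model.predict(screen)
        preds[tag] = {i: (int(l), float(s)) for i, l, s in
                      zip(screen.compound_ids, labels, scores)}
        print(f"{tag}: {int(labels.sum())} of {len(labels)} screened "
              "compounds predicted positive")
    candidates = screen_mixtures(preds["pparg"], preds["tlr4"])
    write_mixture_report(candidates, ROOT / "mixture_candidates.csv")
    flagged = [c for c in candidates if c.flag]
    print(f"{len(flagged)} candidate binary mixtures flagged; top 3 by "
          "combined decision score:")
    for c in flagged[:3]:
        print(f"  {c.ppar_compound_id} x {c.tlr4_compound_id} "
              f"(scores {c.ppar_score:.2f} + {c.tlr4_score:.2f})")


if __name__ == "__main__":
    main()
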