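"""Binary-mixture flagging across the two molecular initiating events.

Pulmonary fibrosis can be driven by the joint perturbation of two distinct
molecular initiating events — PPAR-γ inactivation and TLR4 activation — so
a candidate mixture of concern is any pair of one compound predicted
positive for each endpoint. If a co-exposure pair list is supplied only
those pairs are evaluated; otherwise the full cross product of positives
is flagged. Candidates are ranked by the sum of the two decision scores.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MixtureCandidate:
    """A role-tagged pair: one PPAR-γ hit and one TLR4 hit."""

    ppar_compound_id: str
    tlr4_compound_id: str
    ppar_score: float
    tlr4_score: float
    flag: bool

    @property
    def combined_score(self) -> float:
        return self.ppar_score + self.tlr4_score


def screen_mixtures(
    ppar_predictions: dict[str, tuple[int, float]],
    tlr4_predictions: dict[str, tuple[int, float]],
    co_exposure_pairs: Optional[Sequence[tuple[str, str]]] = None,
) -> list[MixtureCandidate]:
    """Flag binary mixtures whose members hit both endpoints.

    Prediction tables map compound id -> (predicted label, decision
    score). Output is sorted by combined score descending with a
    deterministic id-pair tie-break. A compound appearing in both roles is
    permitted but logged.
    """
    both = set(ppar_predictions) & set(tlr4_predictions)
    for cid in sorted(both):
        logger.info("compound %s appears in both prediction tables", cid)
    if co_exposure_pairs is not None:
        pairs = list(co_exposure_pairs)
    else:
        ppar_pos = [c for c, (lab, _) in ppar_predictions.items() if lab == 1]
        tlr4_pos = [c for c, (lab, _) in tlr4_predictions.items() if lab == 1]
        pairs = [(p, t) for p in ppar_pos for t in tlr4_pos]
    out = []
    for ppar_id, tlr4_id in pairs:
        if ppar_id not in ppar_predictions or tlr4_id not in tlr4_predictions:
            continue
        ppar_lab, ppar_score = ppar_predictions[ppar_id]
        tlr4_lab, tlr4_score = tlr4_predictions[tlr4_id]
        flag = ppar_lab == 1 and tlr4_lab == 1
        out.append(MixtureCandidate(ppar_id, tlr4_id, float(ppar_score),
                                    float(tlr4_score), flag))
    out.sort(key=lambda c: (-c.combined_score,
                            c.ppar_compound_id, c.tlr4_compound_id))
    return out


def write_mixture_report(
    candidates: Sequence[MixtureCandidate], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["ppar_compound_id", "tlr4_compound_id",
                            "ppar_score", "tlr4_score", "flag"])
        writer.writeheader()
        for c in candidates:
            writer.writerow(asdict(c))


def read_co_exposure_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Two-column CSV of (ppar id, tlr4 id) pairs."""
    pairs = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        for row in reader:
            if len(row) >= 2:
                pairs.append((row[0].strip(), row[1].strip()))
    return pairs
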