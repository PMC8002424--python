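"""Compound records and table I/O.

Compounds are carried as SMILES with an opaque id, an optional CAS number
and an optional binary activity label (1 = active in the molecular
initiating event under study: antagonist for PPAR-γ inactivation, agonist
for TLR4 activation). Records whose SMILES does not parse are rejected and
counted in a curation log rather than raising.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")


class Endpoint(str, Enum):
    """Molecular initiating event an activity label refers to."""

    PPARG_INACTIVATION = "PPARG_INACTIVATION"
    TLR4_ACTIVATION = "TLR4_ACTIVATION"
    UNLABELED = "UNLABELED"


@dataclass(frozen=True)
class CompoundRecord:
    """One molecule with identity, structure and optional class label."""

    id: str
    smiles: str
    cas: Optional[str] = None
    label: Optional[int] = None
    source: str = ""

    def canonical_smiles(self) -> str:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES for record {self.id!r}")
        return Chem.MolToSmiles(mol)


@dataclass
class CompoundSet:
    """Ordered collection of records sharing one endpoint."""

    records: list[CompoundRecord] = field(default_factory=list)
    endpoint: Endpoint = Endpoint.UNLABELED

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def labels(self) -> list[Optional[int]]:
        return [r.label for r in self.records]

    def subset(self, ids: Iterable[str]) -> "CompoundSet":
        keep = set(ids)
        return CompoundSet(
            [r for r in self.records if r.id in keep], self.endpoint
        )

    def validate(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.id in seen:
                raise ValueError(f"duplicate id {r.id!r} in compound set")
            seen.add(r.id)
            if r.label is not None and r.label not in (0, 1):
                raise ValueError(f"label of {r.id!r} must be 0/1, got {r.label}")


@dataclass
class CurationLog:
    """Per-run record of rejected or merged rows, serialisable as JSON lines."""

    events: list[dict] = field(default_factory=list)

    def add(self, reason: str, **info) -> None:
        self.events.append({"reason": reason, **info})

    def count(self, reason: Optional[str] = None) -> int:
        if reason is None:
            return len(self.events)
        return sum(1 for e in self.events if e["reason"] == reason)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for e in self.events:
                fh.write(json.dumps(e) + "\n")


DEFAULT_COLUMN_MAP = {"id": "id", "smiles": "smiles", "cas": "cas", "label": "label"}


def read_compound_csv(
    path: str | Path,
    column_map: Optional[dict] = None,
    endpoint: Endpoint = Endpoint.UNLABELED,
) -> tuple[CompoundSet, CurationLog]:
    """Read a compound table from CSV, dropping unparseable SMILES rows.

    ``column_map`` maps the logical names ``id``/``smiles`` (mandatory) and
    ``cas``/``label`` (optional) to header names in the file. Rows whose
    SMILES RDKit cannot parse are dropped and counted in the returned
    curation log.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    log = CurationLog()
    records: list[CompoundRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"empty compound file: {path}")
        for key in ("id", "smiles"):
            if cmap[key] not in reader.fieldnames:
                raise KeyError(
                    f"mandatory column {cmap[key]!r} missing from {path}"
                )
        has_cas = cmap.get("cas") in reader.fieldnames
        has_label = cmap.get("label") in reader.fieldnames
        for row in reader:
            rid = row[cmap["id"]].strip()
            smiles = row[cmap["smiles"]].strip()
            if Chem.MolFromSmiles(smiles) is None:
                log.add("unparseable_smiles", id=rid, smiles=smiles)
                continue
            label: Optional[int] = None
            if has_label and row[cmap["label"]] not in ("", None):
                label = int(float(row[cmap["label"]]))
            cas = row[cmap["cas"]].strip() if has_cas and row[cmap["cas"]] else None
            records.append(
                CompoundRecord(id=rid, smiles=smiles, cas=cas, label=label,
                               source=str(path.name))
            )
    if not records and log.count() == 0:
        raise ValueError(f"no data rows in {path}")
    cset = CompoundSet(records, endpoint)
    cset.validate()
    return cset, log


def read_compound_sdf(
    path: str | Path, endpoint: Endpoint = Endpoint.UNLABELED
) -> tuple[CompoundSet, CurationLog]:
    """Read a V2000 SDF; molecule title (or _Name) becomes the id."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    log = CurationLog()
    records = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            log.add("unparseable_sdf_block", index=i)
            continue
        rid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"sdf_{i}"
        cas = mol.GetProp("CAS") if mol.HasProp("CAS") else None
        label = int(mol.GetProp("label")) if mol.HasProp("label") else None
        records.append(
            CompoundRecord(id=rid, smiles=Chem.MolToSmiles(mol), cas=cas,
                           label=label, source=str(path.name))
        )
    cset = CompoundSet(records, endpoint)
    cset.validate()
    return cset, log


def deduplicate(cset: CompoundSet, log: Optional[CurationLog] = None) -> CompoundSet:
    """Remove exact structural duplicates by canonical-SMILES equality.

    The first occurrence of each structure is kept. Structures that occur
    with conflicting labels are dropped entirely and logged — an
    irreconcilable record is worse than a missing one.
    """
    log = log if log is not None else CurationLog()
    by_canon: dict[str, list[CompoundRecord]] = {}
    order: list[str] = []
    for r in cset.records:
        canon = r.canonical_smiles()
        if canon not in by_canon:
            order.append(canon)
            by_canon[canon] = []
        by_canon[canon].append(r)
    kept: list[CompoundRecord] = []
    for canon in order:
        group = by_canon[canon]
        labels = {r.label for r in group if r.label is not None}
        if len(labels) > 1:
            log.add("conflicting_labels", ids=[r.id for r in group], smiles=canon)
            continue
        first = group[0]
        if first.label is None and labels:
            first = replace(first, label=labels.pop())
        if len(group) > 1:
            log.add("duplicate_structure", kept=first.id,
                    dropped=[r.id for r in group[1:]])
        kept.append(first)
    return CompoundSet(kept, cset.endpoint)


def write_predictions(
    cset: CompoundSet,
    labels: Sequence[int],
    scores: Sequence[float],
    path: str | Path,
) -> None:
    """Write per-compound predicted labels and decision scores as CSV.

    The output round-trips through :func:`read_compound_csv` with
    ``column_map={'label': 'predicted_label'}``.
    """
    if len(labels) != len(cset) or len(scores) != len(cset):
        raise ValueError(
            f"length mismatch: {len(cset)} records, {len(labels)} labels, "
            f"{len(scores)} scores"
        )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "cas", "smiles", "predicted_label", "decision_score"])
        for rec, lab, score in zip(cset.records, labels, scores):
            writer.writerow([rec.id, rec.cas or "", rec.smiles, int(lab),
                             f"{float(score):.6g}"])
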