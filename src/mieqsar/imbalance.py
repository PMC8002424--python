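"""Tomek-link detection and majority-class undersampling to a 1:1 ratio.

A Tomek link is a pair of opposite-class samples that are each other's
nearest neighbour in feature space; majority-class members of such pairs
sit on (or across) the class boundary and are removed first. Because pure
link removal cannot guarantee an exact 1:1 ratio, a seeded uniform random
top-up from the remaining majority completes the balance once no links
remain. Minority-class rows are never touched.

Distances are Euclidean on descriptor columns standardized over the input
(the same convention as the chemical-space module). Nearest-neighbour ties
break toward the smallest compound id.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .descriptors import DescriptorMatrix


@dataclass(frozen=True)
class TomekLinkSet:
    """Unordered opposite-label mutual-nearest-neighbour pairs (by id)."""

    pairs: frozenset[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.pairs)

    def members(self) -> set[str]:
        return {i for pair in self.pairs for i in pair}


@dataclass
class RemovalLog:
    """Audit trail of undersampling: (removed_id, step, reason)."""

    entries: list[tuple[str, int, str]] = field(default_factory=list)

    def add(self, removed_id: str, step: int, reason: str) -> None:
        self.entries.append((removed_id, step, reason))

    def write(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["removed_id", "step", "reason"])
            writer.writerows(self.entries)


def _standardize(values: np.ndarray) -> np.ndarray:
    std = values.std(axis=0, ddof=0)
    std[std == 0] = 1.0
    return (values - values.mean(axis=0)) / std


def _mutual_nearest(ids: list[str], dist: np.ndarray) -> np.ndarray:
    """Index of each point's nearest neighbour, smallest-id tie-break."""
    n = len(ids)
    order = np.argsort(ids)          # ranks for deterministic tie-breaking
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    nn = np.empty(n, dtype=int)
    big = np.inf
    for i in range(n):
        row = dist[i].copy()
        row[i] = big
        best = np.flatnonzero(row == row.min())
        nn[i] = best[np.argmin(rank[best])]
    return nn


def find_tomek_links(
    matrix: DescriptorMatrix, labels: Sequence[int], standardize: bool = True
) -> TomekLinkSet:
    """All opposite-label mutual-nearest-neighbour pairs (Euclidean)."""
    labels = np.asarray(labels, dtype=int)
    if matrix.missing_mask.any():
        raise ValueError("matrix has missing cells")
    if len(labels) != matrix.shape[0]:
        raise ValueError("labels length does not match matrix rows")
    if len(np.unique(labels)) < 2 or matrix.shape[0] < 2:
        warnings.warn("need both classes for Tomek links; returning empty set")
        return TomekLinkSet(frozenset())
    values = _standardize(matrix.values) if standardize else matrix.values
    dist = squareform(pdist(values))
    nn = _mutual_nearest(matrix.compound_ids, dist)
    pairs = set()
    for i in range(len(labels)):
        j = nn[i]
        if nn[j] == i and labels[i] != labels[j]:
            a, b = sorted((matrix.compound_ids[i], matrix.compound_ids[j]))
            pairs.add((a, b))
    return TomekLinkSet(frozenset(pairs))


def undersample_to_balance(
    matrix: DescriptorMatrix,
    labels: Sequence[int],
    seed: int = 0,
    standardize: bool = True,
) -> tuple[DescriptorMatrix, np.ndarray, RemovalLog]:
    """Remove majority samples until class counts are equal.

    Iterates: find current Tomek links, remove their majority-class members
    in order of descending link distance (ties by id), stopping the moment
    balance is reached; when no links remain and the classes are still
    unequal, removes uniformly at random (seeded) from the majority.
    """
    labels = np.asarray(labels, dtype=int)
    counts = {c: int((labels == c).sum()) for c in (0, 1)}
    if counts[0] == counts[1]:
        return matrix, labels, RemovalLog()
    majority = 0 if counts[0] > counts[1] else 1
    minority = 1 - majority
    target = counts[minority]

    log = RemovalLog()
    current = matrix
    cur_labels = labels
    rng = np.random.default_rng(seed)
    step = 0
    while int((cur_labels == majority).sum()) > target:
        links = find_tomek_links(current, cur_labels, standardize=standardize)
        if len(links) == 0:
            break
        step += 1
        values = _standardize(current.values) if standardize else current.values
        pos = {cid: i for i, cid in enumerate(current.compound_ids)}
        lab = {cid: cur_labels[i] for cid, i in pos.items()}
        scored = []
        for a, b in links.pairs:
            d = float(np.linalg.norm(values[pos[a]] - values[pos[b]]))
            scored.append((-d, (a, b)))
        scored.sort()                 # descending distance, then id pair
        to_remove: list[str] = []
        excess = int((cur_labels == majority).sum()) - target
        for _, (a, b) in scored:
            for cid in (a, b):
                if lab[cid] == majority and cid not in to_remove:
                    to_remove.append(cid)
                    if len(to_remove) == excess:
                        break
            if len(to_remove) == excess:
                break
        for cid in to_remove:
            log.add(cid, step, "tomek")
        keep = [cid for cid in current.compound_ids if cid not in set(to_remove)]
        keep_idx = [pos[cid] for cid in keep]
        current = current.select_rows(keep)
        cur_labels = cur_labels[keep_idx]

    excess = int((cur_labels == majority).sum()) - target
    if excess > 0:
        step += 1
        maj_ids = [cid for cid, l in zip(current.compound_ids, cur_labels)
                   if l == majority]
        drop = set(rng.choice(maj_ids, size=excess, replace=False).tolist())
        for cid in sorted(drop):
            log.add(cid, step, "random_topup")
        pos = {cid: i for i, cid in enumerate(current.compound_ids)}
        keep = [cid for cid in current.compound_ids if cid not in drop]
        keep_idx = [pos[cid] for cid in keep]
        current = current.select_rows(keep)
        cur_labels = cur_labels[keep_idx]

    assert int((cur_labels == 0).sum()) == int((cur_labels == 1).sum())
    return current, cur_labels, log
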