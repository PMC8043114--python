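"""Consensus presence/absence proteome maps and their set algebra.

A protein is called *present* in a population only when it was detected
(intensity > 0) in **every** replicate of that population — the
consensus rule that defines each subset's qualitative proteome.  On top
of the resulting binary matrix this module computes exact-membership
(UpSet-style) class counts, raw intersections, per-population exclusive
proteins, pairwise presence differences, and the population dendrogram
on binary profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import DendrogramResult, average_linkage_tree
from .core_io import IntensityMatrix

__all__ = [
    "PresenceMatrix",
    "MembershipSummary",
    "consensus_presence",
    "membership_summary",
    "exclusive_proteins",
    "presence_absence_in",
    "binary_cluster",
]


@dataclass
class PresenceMatrix:
    """Protein x population binary consensus detection calls."""

    protein_ids: list[str]
    populations: tuple[str, ...]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=int)
        if self.calls.shape != (len(self.protein_ids), len(self.populations)):
            raise ValueError("calls shape does not match ids x populations")
        if not np.isin(self.calls, (0, 1)).all():
            raise ValueError("calls must be 0/1")

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    def column(self, population: str) -> np.ndarray:
        if population not in self.populations:
            raise KeyError(f"unknown population {population!r}")
        return self.calls[:, self.populations.index(population)]

    def present_set(self, population: str) -> set[str]:
        col = self.column(population)
        return {pid for pid, c in zip(self.protein_ids, col) if c}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.protein_ids, columns=list(self.populations))

    def write(self, path: str | Path) -> None:
        self.to_frame().rename_axis("protein_id").to_csv(path, sep="\t", encoding="utf-8")


@dataclass
class MembershipSummary:
    """Exact membership classes plus raw intersection cardinalities.

    ``exact_counts[combo]`` counts proteins present in exactly that
    population combination (UpSet semantics): the classes are disjoint
    and sum to the number of distinct proteins.  ``intersections`` holds
    the raw (non-exclusive) pairwise and all-population intersection
    sizes; ``per_population_total`` the consensus proteome size of each
    subset.
    """

    exact_counts: dict[tuple[str, ...], int]
    exact_members: dict[tuple[str, ...], list[str]]
    per_population_total: dict[str, int]
    intersections: dict[tuple[str, ...], int]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"populations": "|".join(combo), "n_populations": len(combo), "count": cnt,
             "members": ";".join(self.exact_members[combo])}
            for combo, cnt in self.exact_counts.items()
        ]
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, encoding="utf-8")


def consensus_presence(matrix: IntensityMatrix) -> PresenceMatrix:
    """Apply the all-replicates consensus rule to an intensity matrix.

    Proteins present in no population at all are dropped: only proteins
    with at least one consensus call are considered for further
    analysis.
    """
    pops = matrix.design.populations
    calls = np.column_stack(
        [(matrix.population_values(p) > 0).all(axis=1) for p in pops]
    ).astype(int)
    keep = calls.any(axis=1)
    return PresenceMatrix(
        protein_ids=[pid for pid, k in zip(matrix.protein_ids, keep) if k],
        populations=pops,
        calls=calls[keep],
    )


def membership_summary(presence: PresenceMatrix) -> MembershipSummary:
    """Partition proteins into exact population-combination classes."""
    if presence.n_proteins == 0:
        raise ValueError("presence matrix is empty")
    pops = presence.populations
    exact_members: dict[tuple[str, ...], list[str]] = {}
    for pid, row in zip(presence.protein_ids, presence.calls):
        combo = tuple(p for p, c in zip(pops, row) if c)
        exact_members.setdefault(combo, []).append(pid)
    exact_members = {c: sorted(m) for c, m in sorted(exact_members.items(), key=lambda kv: (-len(kv[0]), kv[0]))}
    exact_counts = {c: len(m) for c, m in exact_members.items()}

    per_population_total = {p: int(presence.column(p).sum()) for p in pops}
    intersections: dict[tuple[str, ...], int] = {}
    for a, b in combinations(pops, 2):
        intersections[(a, b)] = int((presence.column(a) & presence.column(b)).sum())
    intersections[tuple(pops)] = int(presence.calls.all(axis=1).sum())
    return MembershipSummary(
        exact_counts=exact_counts,
        exact_members=exact_members,
        per_population_total=per_population_total,
        intersections=intersections,
    )


def exclusive_proteins(presence: PresenceMatrix, population: str) -> list[str]:
    """Proteins present in ``population`` and in no other (sorted)."""
    col = presence.column(population)
    others = presence.calls.sum(axis=1) - col
    return sorted(
        pid for pid, c, o in zip(presence.protein_ids, col, others) if c == 1 and o == 0
    )


def presence_absence_in(
    presence: PresenceMatrix, pop_a: str, pop_b: str
) -> tuple[list[str], list[str]]:
    """Sorted set differences: (present in a not b, present in b not a)."""
    set_a = presence.present_set(pop_a)
    set_b = presence.present_set(pop_b)
    return sorted(set_a - set_b), sorted(set_b - set_a)


def binary_cluster(presence: PresenceMatrix) -> DendrogramResult:
    """Cluster populations on their binary presence profiles.

    Euclidean distance on 0/1 columns, average linkage, lexicographic
    tie-break — the qualitative analogue of the expression heatmap
    dendrogram.
    """
    if len(presence.populations) < 2:
        raise ValueError("need at least 2 populations")
    return average_linkage_tree(presence.calls.T, list(presence.populations))
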