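"""MSox-ome extraction, coverage statistics, and temporal overlap.

The MSox-ome of a sample group is the set of peptidoforms carrying at
least one methionine-sulfoxide site and detected (finite AUC) in at least
one sample of the group. Coverage is summarised per group as the number
of MSox peptidoforms, the number of proteins they annotate, and MSox %
of all quantified peptidoforms. Protein-level MSox-omes from the three
time-point batches are partitioned into the disjoint regions of a Venn
diagram, splitting targets into constant (seen at every time point) and
dynamic (all others).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .ingest import sample_columns

CONSTANT = "CONSTANT"
DYNAMIC = "DYNAMIC"


@dataclass(frozen=True)
class CoverageStats:
    """Table-1-shaped coverage summary for one sample group."""

    group_label: str
    n_msox_peptides: int
    n_msox_proteins: int
    n_total_peptides: int
    msox_pct: float

    def __post_init__(self) -> None:
        assert 0 <= self.msox_pct <= 100
        assert self.n_msox_peptides <= self.n_total_peptides


@dataclass
class VennPartition:
    """Disjoint region counts for k (typically 3) protein sets.

    Regions are keyed by the frozenset of set labels whose intersection
    (minus all other sets) the region represents. Fractions are relative
    to the union.
    """

    labels: tuple[str, ...]
    region_counts: dict[frozenset, int]
    region_members: dict[frozenset, frozenset]
    union_size: int

    @property
    def core_fraction(self) -> float:
        if self.union_size == 0:
            return 0.0
        core = self.region_counts.get(frozenset(self.labels), 0)
        return 100.0 * core / self.union_size

    @property
    def exclusive_fractions(self) -> dict[str, float]:
        out = {}
        for lab in self.labels:
            n = self.region_counts.get(frozenset([lab]), 0)
            out[lab] = 100.0 * n / self.union_size if self.union_size else 0.0
        return out

    def to_dict(self) -> dict:
        """JSON-ready summary (region keys rendered as '&'-joined labels)."""
        return {
            "labels": list(self.labels),
            "regions": {
                "&".join(sorted(k, key=list(self.labels).index)): v
                for k, v in self.region_counts.items()
            },
            "union_size": self.union_size,
            "core_fraction": self.core_fraction,
            "exclusive_fractions": self.exclusive_fractions,
        }


def is_msox(mods: Iterable[tuple[int, str]]) -> bool:
    return any(mod == "MSOX" for _, mod in mods)


def detected_mask(table: pd.DataFrame, group: Sequence[str] | None = None) -> pd.Series:
    """True for rows with a finite AUC in ≥1 sample of ``group``."""
    cols = list(group) if group is not None else sample_columns(table)
    return table[cols].notna().any(axis=1)


def extract_msox(
    table: pd.DataFrame, group: Sequence[str] | None = None
) -> pd.DataFrame:
    """Filter to peptidoforms with ≥1 MSox site, detected in ``group``.

    With ``group=None`` detection is assessed over all sample columns.
    Idempotent.
    """
    has_msox = table["mods"].map(is_msox)
    return table[has_msox & detected_mask(table, group)].reset_index(drop=True)


def coverage_stats(
    msox_table: pd.DataFrame,
    full_table: pd.DataFrame,
    group: Sequence[str],
    group_label: str = "",
) -> CoverageStats:
    """Coverage of the MSox-ome within one sample group.

    The denominator is the number of distinct peptidoforms detected in the
    same group in the full table.
    """
    n_total = int(detected_mask(full_table, group).sum())
    if n_total == 0:
        raise ValueError(f"no peptidoforms detected in group {group_label!r}: MSox % undefined")
    msox_det = msox_table[detected_mask(msox_table, group)]
    n_pep = len(msox_det)
    n_prot = msox_det["protein"].nunique()
    return CoverageStats(
        group_label=group_label,
        n_msox_peptides=n_pep,
        n_msox_proteins=n_prot,
        n_total_peptides=n_total,
        msox_pct=100.0 * n_pep / n_total,
    )


def msox_proteins(msox_table: pd.DataFrame, group: Sequence[str] | None = None) -> set[str]:
    """Protein accessions annotated by ≥1 detected MSox peptidoform."""
    det = msox_table[detected_mask(msox_table, group)]
    return set(det["protein"])


def temporal_overlap(protein_sets: Mapping[str, Iterable[str]]) -> VennPartition:
    """Partition k labelled sets into their 2^k − 1 disjoint Venn regions."""
    labels = tuple(protein_sets)
    if len(labels) < 2:
        raise ValueError("need at least 2 sets to partition")
    sets = {lab: set(s) for lab, s in protein_sets.items()}
    union: set[str] = set().union(*sets.values())
    counts: dict[frozenset, int] = {}
    members: dict[frozenset, frozenset] = {}
    for r in range(1, len(labels) + 1):
        for inside in combinations(labels, r):
            region = set(union)
            for lab in inside:
                region &= sets[lab]
            for lab in labels:
                if lab not in inside:
                    region -= sets[lab]
            key = frozenset(inside)
            counts[key] = len(region)
            members[key] = frozenset(region)
    return VennPartition(
        labels=labels,
        region_counts=counts,
        region_members=members,
        union_size=len(union),
    )


def classify_targets(partition: VennPartition) -> dict[str, frozenset]:
    """Split the union into constant (core) and dynamic oxidation targets.

    Constant targets appear at every time point; dynamic targets are
    missing from at least one.
    """
    core = partition.region_members.get(frozenset(partition.labels), frozenset())
    dynamic = frozenset().union(
        *(
            m
            for k, m in partition.region_members.items()
            if k != frozenset(partition.labels)
        )
    )
    return {CONSTANT: frozenset(core), DYNAMIC: dynamic}


def coverage_table(stats: Iterable[CoverageStats]) -> pd.DataFrame:
    """Assemble CoverageStats rows into a tidy frame (one row per group)."""
    return pd.DataFrame(
        [
            {
                "group": s.group_label,
                "msox_peptides": s.n_msox_peptides,
                "msox_proteins": s.n_msox_proteins,
                "total_peptides": s.n_total_peptides,
                "msox_pct": round(s.msox_pct, 2),
            }
            for s in stats
        ]
    )
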