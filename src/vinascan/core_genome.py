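"""Gene-family presence/absence across clades and the conserved core.

A family is *core* when strictly more than a given fraction (default 50%) of
the genomes carry it in at least ``min_clades`` (default 3) of the five MCP
clades. Replication proteins and endolysins — families that are frequently
displaced by non-homologous counterparts — are each collapsed to a single
family for counting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .prophage_annotation import (
    FAMILY_MERGE_MAP,
    LOW_CONFIDENCE_FAMILIES,
    LYSIN_FAMILIES,
    ProphageAnnotation,
)

CLADES = ("A", "B", "C", "D", "E")


@dataclass
class PresenceAbsenceMatrix:
    table: pd.DataFrame  # genomes x families, binary; index = genome_id
    clades: pd.Series  # genome_id -> clade label
    family_merge_map: dict = field(default_factory=lambda: dict(FAMILY_MERGE_MAP))
    low_confidence: tuple = LOW_CONFIDENCE_FAMILIES

    @property
    def genomes(self) -> list:
        return list(self.table.index)

    @property
    def families(self) -> list:
        return list(self.table.columns)

    def clade_fractions(self) -> pd.DataFrame:
        """Per-clade fraction of genomes carrying each family."""
        return self.table.groupby(self.clades).mean()


def build_matrix(
    annotations: Sequence[ProphageAnnotation],
    clade_labels: dict,
    exclusions: Iterable[str] = (),
    merge_map: Optional[dict] = None,
) -> PresenceAbsenceMatrix:
    """Binary genomes-x-families matrix from annotated gene maps.

    ``clade_labels`` maps genome (contig) id -> clade in A-E; genomes listed in
    ``exclusions`` (e.g. highly divergent outliers) are dropped entirely.
    """
    merge_map = dict(FAMILY_MERGE_MAP) if merge_map is None else merge_map
    exclusions = set(exclusions)
    rows = {}
    clades = {}
    for ann in annotations:
        gid = ann.contig_id
        if gid in exclusions:
            continue
        if gid not in clade_labels:
            raise ValueError(f"genome {gid} has no clade label")
        if clade_labels[gid] not in CLADES:
            raise ValueError(f"genome {gid}: unknown clade {clade_labels[gid]!r}")
        fams = {
            merge_map.get(lab, lab)
            for _, lab in ann.gene_map
            if lab != "unknown"
        }
        rows[gid] = fams
        clades[gid] = clade_labels[gid]
    all_fams = sorted(set().union(*rows.values())) if rows else []
    table = pd.DataFrame(
        [[int(f in rows[g]) for f in all_fams] for g in rows],
        index=list(rows),
        columns=all_fams,
        dtype=int,
    )
    return PresenceAbsenceMatrix(table, pd.Series(clades), merge_map)


def core_genes(
    matrix: PresenceAbsenceMatrix,
    fraction: float = 0.5,
    min_clades: int = 3,
) -> set:
    """Families present in strictly more than ``fraction`` of the genomes of at
    least ``min_clades`` clades. Clades with zero genomes cannot contribute."""
    if matrix.table.empty:
        return set()
    fractions = matrix.clade_fractions()
    empty = [c for c in CLADES if c not in fractions.index]
    if empty:
        warnings.warn(f"clades without genomes cannot contribute: {empty}")
    qualifying = (fractions > fraction).sum(axis=0)
    return set(qualifying.index[qualifying >= min_clades])


def lysin_host_table(
    annotations: Sequence[ProphageAnnotation],
    host_assignments: dict,
) -> pd.DataFrame:
    """Contingency table of specific (unmerged) lysin family x host class.

    ``host_assignments`` maps genome id -> host class label. Genomes with no
    detected lysin are tallied in a ``(no lysin)`` row; genomes without a host
    call go in an ``(unassigned)`` column.
    """
    records = []
    for ann in annotations:
        lysins = sorted(ann.families_present & set(LYSIN_FAMILIES))
        host = host_assignments.get(ann.contig_id, "(unassigned)")
        if lysins:
            for fam in lysins:
                records.append((fam, host))
        else:
            records.append(("(no lysin)", host))
    if not records:
        return pd.DataFrame()
    df = pd.DataFrame(records, columns=["lysin", "host"])
    return pd.crosstab(df["lysin"], df["host"])
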