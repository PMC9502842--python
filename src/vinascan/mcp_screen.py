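"""Screen contig proteomes for double jelly-roll MCP genes and assign groups.

Every predicted protein is searched against the MCP profile set (one profile
per varidnavirus group) at the E-value cutoff; borderline hits pass the
conserved-pattern curation rule inside the profile engine, and proteins whose
best hit to a non-MCP conserved-family profile outscores the MCP hit are
rejected as other-domain false positives. A contig may carry more than one
MCP gene and so appear in more than one assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .core_model import Contig, GeneCall
from .gene_calling import find_orfs
from .profile_search import ProfileHit, ProteinProfile, best_hit

GROUPS = ("Vinavirales", "NCLDV", "virophage", "polintovirus", "tectivirus_Bam35")


@dataclass
class McpAssignment:
    contig_id: str
    protein_id: str
    group: str
    hit: ProfileHit
    locus: tuple[int, int]
    strand: str

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group}")


def screen_contigs(
    contigs: Sequence[Contig],
    profiles: Sequence[ProteinProfile],
    evalue_cutoff: float = 0.05,
    gene_calls: Optional[dict] = None,
    decoy_profiles: Sequence[ProteinProfile] = (),
    min_len_aa: int = 30,
) -> list[McpAssignment]:
    """One assignment per MCP-encoding protein; group = group of the best
    (lowest-E, then highest-coverage) accepted hit."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("empty MCP profile set")
    out = []
    for contig in contigs:
        genes = (
            gene_calls.get(contig.id, []) if gene_calls is not None
            else find_orfs(contig, min_len_aa)
        )
        for g in genes:
            hit = best_hit(profiles, g.aa_seq, g.id, evalue_cutoff=evalue_cutoff)
            if hit is None:
                continue
            if decoy_profiles:
                decoy = best_hit(
                    decoy_profiles, g.aa_seq, g.id, evalue_cutoff=evalue_cutoff
                )
                if decoy is not None and decoy.raw_score > hit.raw_score:
                    continue
            group = next(p.group or p.name for p in profiles if p.name == hit.profile_name)
            out.append(
                McpAssignment(contig.id, g.id, group, hit, (g.start, g.end), g.strand)
            )
    return out


def summarize_groups(assignments: Sequence[McpAssignment]) -> pd.DataFrame:
    """Per-group MCP and contig counts (contigs hitting >= 2 groups flagged)."""
    rows = {
        g: {"group": g, "n_mcp": 0, "n_contigs": 0, "n_multi_group_contigs": 0}
        for g in GROUPS
    }
    by_contig: dict[str, set] = {}
    for a in assignments:
        rows[a.group]["n_mcp"] += 1
        by_contig.setdefault(a.contig_id, set()).add(a.group)
    for cid, groups in by_contig.items():
        for g in groups:
            rows[g]["n_contigs"] += 1
            if len(groups) > 1:
                rows[g]["n_multi_group_contigs"] += 1
    return pd.DataFrame(rows.values()).set_index("group")


def assignments_table(assignments: Sequence[McpAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig_id": a.contig_id,
                "protein_id": a.protein_id,
                "group": a.group,
                "score": a.hit.raw_score,
                "evalue": a.hit.evalue,
                "coverage": a.hit.coverage,
                "curated": a.hit.curated,
                "start": a.locus[0],
                "end": a.locus[1],
                "strand": a.strand,
            }
            for a in assignments
        ]
    )
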