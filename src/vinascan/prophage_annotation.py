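"""Gene-map annotation, prophage boundary delineation and classification.

Houses the registry of conserved tailless-phage gene families (the PM2-style
marker proteins). Boundaries of an integrated phage are the transcriptional
regulator genes flanking the structural cassette: a P16 homolog on one side and
a P15 homolog — or, in clade A genomes, the TR_Z1 regulator that occupies the
same locus — on the other. A window of +/-15 kb around the major capsid
protein (MCP) gene is annotated; a record is a *prophage* if at least one gene
lies outside the phage boundaries and a *phage* otherwise, and *complete* if
both boundary genes are present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core_model import Contig, GeneCall
from .gene_calling import find_orfs
from .profile_search import ProteinProfile, best_hit

# ----------------------------------------------------------------- family registry
#
# name -> (min_aa, max_aa, description). Sizes are typical spans for each
# marker family; they parameterize the synthetic generator and sanity checks.

GENE_FAMILIES = {
    "P16": (70, 100, "transcriptional regulator P16; left prophage boundary"),
    "P14_TF": (60, 90, "transcription factor P14"),
    "rep": (250, 330, "rolling-circle-type replication initiation protein"),
    "DNAp": (300, 380, "family B DNA polymerase"),
    "ssb": (100, 130, "single-strand DNA-binding protein"),
    "DNA_met": (230, 290, "DNA methyltransferase"),
    "ORF_h": (120, 160, "putative assembly factor (ORF h / P10-like)"),
    "ATPase": (200, 260, "FtsK/HerA-superfamily genome-packaging ATPase"),
    "P7": (40, 50, "minor structural membrane protein P7"),
    "MCP": (350, 420, "double jelly-roll major capsid protein"),
    "P3": (60, 90, "membrane protein P3"),
    "P8": (50, 80, "membrane protein P8"),
    "GNAT": (140, 170, "GNAT-family acetyltransferase"),
    "P10": (50, 80, "membrane protein P10"),
    "P1_spike": (250, 350, "receptor-binding spike protein (penton-domain)"),
    "fiber": (200, 250, "tail fiber protein homolog"),
    "P5_lysin": (130, 170, "LytD-superfamily endolysin (P5-like)"),
    "CWH_SleB": (130, 170, "SleB-superfamily cell wall hydrolase"),
    "MltE": (150, 190, "MltE-superfamily lytic transglycosylase"),
    "T4lyz": (140, 170, "T4-lysozyme-like endolysin"),
    "P6": (80, 110, "major membrane protein P6"),
    "P17": (40, 60, "holin-class lysis factor P17"),
    "P18": (40, 60, "outer-membrane disruption lysis factor P18"),
    "P15": (60, 90, "transcriptional regulator P15; right prophage boundary"),
    "TR_Z1": (70, 100, "clade-A transcription regulator at the P15 locus"),
    "IS630_transposase": (280, 340, "IS630-family DDE transposase (HGV-2 marker)"),
}

LYSIN_FAMILIES = ("P5_lysin", "CWH_SleB", "MltE", "T4lyz")
REPLICATION_FAMILIES = ("rep", "DNAp")
# short, highly divergent families: kept in matrices but flagged low-confidence
LOW_CONFIDENCE_FAMILIES = ("P7", "P17", "P18")

FAMILY_MERGE_MAP = {
    **{f: "lysin" for f in LYSIN_FAMILIES},
    **{f: "replication" for f in REPLICATION_FAMILIES},
}

BOUNDARY_LEFT = "P16"
BOUNDARY_RIGHT = ("P15", "TR_Z1")

# canonical structural-cassette gene order; <lysin> and <tail_TR> are slots
CASSETTE_ORDER = [
    "P16", "rep", "ORF_h", "ATPase", "P7", "MCP", "P3", "P8",
    "GNAT", "P10", "P1_spike", "<lysin>", "P17", "P18", "<tail_TR>",
]

DEFAULT_WINDOW = 15_000


@dataclass
class ProphageAnnotation:
    contig_id: str
    window: tuple[int, int]
    mcp_locus: tuple[int, int]
    gene_map: list = field(default_factory=list)  # list of (GeneCall, family or "unknown")
    boundaries: dict = field(default_factory=dict)  # side -> (start, end, family)
    classification: str = "unclassified"  # prophage | phage | unclassified
    completeness: str = "partial"  # complete | partial
    flags: list = field(default_factory=list)

    def labeled(self, family: str) -> list[GeneCall]:
        return [g for g, lab in self.gene_map if lab == family]

    @property
    def families_present(self) -> set:
        return {lab for _, lab in self.gene_map if lab != "unknown"}


# ----------------------------------------------------------------- annotation


def annotate_window(
    contig: Contig,
    mcp_locus: tuple[int, int],
    profiles: Sequence[ProteinProfile],
    gene_calls: Optional[list[GeneCall]] = None,
    window: int = DEFAULT_WINDOW,
    evalue_cutoff: float = 0.05,
    min_len_aa: int = 30,
) -> ProphageAnnotation:
    """Label every gene in the +/-``window`` nt around the MCP gene.

    The window is clipped at contig ends (asymmetric rather than shifted) and
    flagged "edge-truncated" when clipping occurs. Every gene intersecting the
    window gets the family of its best accepted profile hit, or "unknown".
    """
    m0, m1 = mcp_locus
    if not (0 <= m0 < m1 <= len(contig)):
        raise ValueError(f"mcp_locus {mcp_locus} outside contig {contig.id}")
    w0 = max(0, m0 - window)
    w1 = min(len(contig), m1 + window)
    ann = ProphageAnnotation(contig.id, (w0, w1), (m0, m1))
    if w0 > 0 and m0 - window < 0 or m1 + window > len(contig):
        pass  # only flag actual clipping below
    if m0 - window < 0 or m1 + window > len(contig):
        ann.flags.append("edge-truncated")
    genes = gene_calls if gene_calls is not None else find_orfs(contig, min_len_aa)
    for g in sorted(genes, key=lambda g: (g.start, g.strand)):
        if g.end <= w0 or g.start >= w1:
            continue
        hit = best_hit(profiles, g.aa_seq, g.id, evalue_cutoff=evalue_cutoff)
        label = hit.profile_name if hit is not None else "unknown"
        ann.gene_map.append((g, label))
    return ann


def find_boundaries(annotation: ProphageAnnotation) -> ProphageAnnotation:
    """Locate boundary genes: the P16 homolog nearest the MCP on one side and
    the nearest P15/TR_Z1 homolog on the opposite side."""
    mcp_mid = sum(annotation.mcp_locus) / 2

    def side(g: GeneCall) -> int:
        return -1 if g.midpoint() < mcp_mid else 1

    p16s = annotation.labeled(BOUNDARY_LEFT)
    rights = [g for fam in BOUNDARY_RIGHT for g in annotation.labeled(fam)]
    annotation.boundaries = {}
    chosen_p16 = None
    if p16s:
        chosen_p16 = min(p16s, key=lambda g: abs(g.midpoint() - mcp_mid))
        annotation.boundaries["p16"] = (chosen_p16.start, chosen_p16.end, BOUNDARY_LEFT)
    if rights:
        if chosen_p16 is not None:
            opposite = [g for g in rights if side(g) != side(chosen_p16)]
        else:
            opposite = rights
        if opposite:
            gright = min(opposite, key=lambda g: abs(g.midpoint() - mcp_mid))
            fam = next(
                f for f in BOUNDARY_RIGHT for g2 in annotation.labeled(f) if g2 is gright
            )
            annotation.boundaries["p15"] = (gright.start, gright.end, fam)
            if fam == "TR_Z1":
                annotation.flags.append("TR_Z1-boundary")
    return annotation


def classify(annotation: ProphageAnnotation) -> tuple[str, str]:
    """Apply the prophage/phage and complete/partial rules.

    prophage: >= 1 gene wholly outside the phage boundaries; phage otherwise;
    unclassified when neither boundary gene was found. complete: both boundary
    genes present (TR_Z1 satisfies the right boundary, flagged); else partial.
    """
    b = annotation.boundaries
    if not b:
        annotation.classification = "unclassified"
        annotation.completeness = "partial"
        return annotation.classification, annotation.completeness
    coords = [v[:2] for v in b.values()]
    span0 = min(c[0] for c in coords)
    span1 = max(c[1] for c in coords)
    mcp_mid = sum(annotation.mcp_locus) / 2
    outside = 0
    for g, _ in annotation.gene_map:
        if len(b) == 2:
            if g.end <= span0 or g.start >= span1:
                outside += 1
        else:
            # single boundary: only genes beyond it, away from the MCP, count
            (b0, b1, _), = b.values()
            if (b0 + b1) / 2 < mcp_mid:
                if g.end <= b0:
                    outside += 1
            else:
                if g.start >= b1:
                    outside += 1
    annotation.classification = "prophage" if outside >= 1 else "phage"
    annotation.completeness = "complete" if len(b) == 2 else "partial"
    return annotation.classification, annotation.completeness


def annotate_and_classify(contig, mcp_locus, profiles, **kw) -> ProphageAnnotation:
    ann = annotate_window(contig, mcp_locus, profiles, **kw)
    find_boundaries(ann)
    classify(ann)
    return ann


# ----------------------------------------------------------------- genome comparison


def _chain_blocks(seq_a: str, seq_b: str, k: int, max_seed_gap: int):
    index: dict[str, list[int]] = {}
    for i in range(len(seq_a) - k + 1):
        index.setdefault(seq_a[i : i + k], []).append(i)
    diagonals: dict[int, list[int]] = {}
    for j in range(len(seq_b) - k + 1):
        for i in index.get(seq_b[j : j + k], ()):
            diagonals.setdefault(i - j, []).append(i)
    blocks = []
    for d, positions in diagonals.items():
        positions.sort()
        run_start = positions[0]
        prev = positions[0]
        for p in positions[1:] + [None]:
            if p is not None and p - prev <= max_seed_gap:
                prev = p
                continue
            blocks.append((run_start, prev + k, d))
            if p is not None:
                run_start = p
                prev = p
    return blocks


def detect_module_replacement(
    genome_a: str,
    genome_b: str,
    identity_threshold: float = 0.90,
    min_block: int = 300,
    k: int = 16,
    genes_a: Optional[list] = None,
    max_seed_gap: int = 100,
) -> tuple[list, list]:
    """Whole-genome comparison of two related (pro)phage sequences.

    Exact k-mer seeds are chained along diagonals into candidate blocks;
    blocks with ungapped identity > ``identity_threshold`` and length >=
    ``min_block`` are reported as shared. Gaps between consecutive shared
    blocks (in A coordinates) are the divergent loci; when ``genes_a``
    [(label, start, end), ...] is given, each locus is annotated with the gene
    labels it overlaps — the signature of, e.g., a swapped replication module.

    Returns (shared_blocks, divergent_loci) with blocks as
    (a_start, a_end, b_start, b_end, identity) and loci as
    (a_start, a_end, [labels]).
    """
    if min(len(genome_a), len(genome_b)) < 1000:
        raise ValueError("sequences must be >= 1 kb")
    shared = []
    for a0, a1, d in _chain_blocks(genome_a, genome_b, k, max_seed_gap):
        if a1 - a0 < min_block:
            continue
        b0, b1 = a0 - d, a1 - d
        if b0 < 0 or b1 > len(genome_b):
            continue
        matches = sum(
            1 for x, y in zip(genome_a[a0:a1], genome_b[b0:b1]) if x == y
        )
        ident = matches / (a1 - a0)
        if ident > identity_threshold:
            shared.append((a0, a1, b0, b1, ident))
    shared.sort()
    # merge overlapping shared blocks in A coordinates
    merged = []
    for blk in shared:
        if merged and blk[0] <= merged[-1][1]:
            prev = merged[-1]
            if blk[1] > prev[1]:
                merged[-1] = (prev[0], blk[1], prev[2], blk[3], min(prev[4], blk[4]))
        else:
            merged.append(blk)
    divergent = []
    for left, right in zip(merged, merged[1:]):
        g0, g1 = left[1], right[0]
        if g1 <= g0:
            continue
        labels = []
        if genes_a:
            labels = [
                lab for lab, s, e in genes_a if s < g1 and e > g0
            ]
        divergent.append((g0, g1, labels))
    return merged, divergent
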