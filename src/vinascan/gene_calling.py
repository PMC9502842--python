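"""Simple ORF-based gene prediction on assembled contigs.

Reports, per stop-bounded frame segment on both strands, the longest
start-to-stop ORF (start codons ATG/GTG/TTG, translation table 11). Edge
segments without a start and/or stop yield flagged partial calls. This is a
deliberately transparent stand-in for a statistical metagenomic gene caller;
externally produced gene maps can be imported via GFF3 instead.
"""

from __future__ import annotations

from Bio.Seq import Seq

from .core_model import Contig, GeneCall, GffFeature, read_genome_map, revcomp

START_CODONS = {"ATG", "GTG", "TTG"}
STOP_CODONS = {"TAA", "TAG", "TGA"}


def _translate(nt: str, complete: bool) -> str:
    aa = str(Seq(nt).translate(table=11))
    if complete and aa:
        # table-11 alternative starts code for Met when used as starts
        aa = "M" + aa[1:]
    return aa


def _scan_strand(seq: str, min_len_aa: int, include_partial: bool):
    """Yield (start, end, aa, partial) in the coordinates of ``seq`` (+ strand)."""
    n = len(seq)
    for frame in range(3):
        seg_start = frame  # start of current stop-bounded segment
        first_start = None  # leftmost start codon in segment
        i = frame
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if first_start is not None:
                    aa_len = (i - first_start) // 3
                    if aa_len >= min_len_aa:
                        nt = seq[first_start : i + 3]
                        if "N" not in nt:
                            yield first_start, i + 3, _translate(seq[first_start:i], True), False
                elif include_partial and seg_start == frame and i - seg_start >= 3 * min_len_aa:
                    # edge-partial: no start codon since the contig edge
                    nt = seq[seg_start : i + 3]
                    if "N" not in nt:
                        yield seg_start, i + 3, _translate(seq[seg_start:i], False), True
                seg_start = i + 3
                first_start = None
            elif first_start is None and codon in START_CODONS:
                first_start = i
            i += 3
        # trailing segment without a stop (runs off the contig end)
        seg_end = i  # last full codon boundary in this frame
        if include_partial and first_start is not None and seg_end - first_start >= 3 * min_len_aa:
            nt = seq[first_start:seg_end]
            if "N" not in nt:
                yield first_start, seg_end, _translate(nt, True), True


def find_orfs(
    contig: Contig,
    min_len_aa: int = 30,
    genetic_code: int = 11,
    include_partial: bool = True,
) -> list[GeneCall]:
    """Predict ORFs of >= ``min_len_aa`` codons (stop excluded) on both strands.

    Intervals are 0-based half-open on the forward strand and include the stop
    codon when present. Output is sorted by (start, strand) and indexed in that
    order. ORFs containing N cannot be translated and are dropped.
    """
    if min_len_aa < 10:
        raise ValueError("min_len_aa must be >= 10")
    if genetic_code != 11:
        raise ValueError("only translation table 11 is supported")
    seq = contig.seq
    n = len(seq)
    if n < 3 * min_len_aa:
        return []
    calls = []
    for start, end, aa, partial in _scan_strand(seq, min_len_aa, include_partial):
        calls.append((start, end, "+", aa, partial))
    rc = revcomp(seq)
    for start, end, aa, partial in _scan_strand(rc, min_len_aa, include_partial):
        calls.append((n - end, n - start, "-", aa, partial))
    calls.sort(key=lambda c: (c[0], c[2], c[1]))
    return [
        GeneCall(contig.id, s, e, strand, aa, gene_index=i, partial=partial)
        for i, (s, e, strand, aa, partial) in enumerate(calls)
    ]


def genes_to_features(genes: list[GeneCall], labels: dict | None = None) -> list[GffFeature]:
    labels = labels or {}
    return [
        GffFeature(
            g.contig_id,
            g.start,
            g.end,
            g.strand,
            "CDS",
            labels.get(g.id, ""),
            (("partial", str(int(g.partial))),) if g.partial else (),
        )
        for g in genes
    ]


def import_gene_calls(gff_path, contigs: list[Contig]) -> list[GeneCall]:
    """Load externally predicted genes from GFF3 and translate them."""
    by_id = {c.id: c for c in contigs}
    genes = []
    counters: dict[str, int] = {}
    for f in read_genome_map(gff_path):
        if f.ftype != "CDS":
            continue
        c = by_id.get(f.contig_id)
        if c is None:
            raise ValueError(f"GFF3 feature on unknown contig {f.contig_id}")
        nt = c.seq[f.start : f.end]
        if f.strand == "-":
            nt = revcomp(nt)
        aa = _translate(nt[:-3] if nt[-3:] in STOP_CODONS else nt, True)
        idx = counters.get(f.contig_id, 0)
        counters[f.contig_id] = idx + 1
        genes.append(GeneCall(f.contig_id, f.start, f.end, f.strand, aa, gene_index=idx))
    return genes
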