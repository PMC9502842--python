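"""Shared domain types and readers/writers for the standard formats the pipeline touches.

All interval arithmetic inside the package uses 0-based half-open coordinates;
file output follows each format's own convention (GFF3 is 1-based inclusive).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq


class ParseError(ValueError):
    """Raised when an input file violates its format or an invariant."""


# --------------------------------------------------------------------------- types


@dataclass
class TruthLabel:
    """Ground-truth annotation attached to a synthetic contig.

    kind is one of ``host_only``, ``prophage``, ``free_phage``.
    ``prophage_interval`` is present iff kind == "prophage".
    ``planted_genes`` lists (family_name, start, end, strand) tuples.
    """

    kind: str
    prophage_interval: Optional[tuple[int, int]] = None
    host_taxon: Optional[str] = None
    planted_genes: list = field(default_factory=list)
    clade: Optional[str] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in {"host_only", "prophage", "free_phage"}:
            raise ValueError(f"unknown truth kind {self.kind!r}")
        if (self.kind == "prophage") != (self.prophage_interval is not None):
            raise ValueError("prophage_interval present iff kind == 'prophage'")


@dataclass
class Contig:
    """A nucleotide record (assembled contig) with provenance and optional truth."""

    id: str
    seq: str
    source: str = ""
    truth: Optional[TruthLabel] = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("contig id must be nonempty")
        if len(self.seq) < 1:
            raise ValueError(f"contig {self.id}: empty sequence")
        self.seq = self.seq.upper()

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneCall:
    """A predicted protein-coding ORF.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the forward
    strand of the contig; the interval includes the stop codon when one is present.
    ``partial`` marks edge-truncated ORFs lacking a start and/or stop codon.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    aa_seq: str
    gene_index: int = 0
    partial: bool = False

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start},{self.end})")
        if (self.end - self.start) % 3 != 0:
            raise ValueError("gene interval length not divisible by 3")
        if "*" in self.aa_seq:
            raise ValueError("internal stop in translation")

    @property
    def id(self) -> str:
        return f"{self.contig_id}|g{self.gene_index}"

    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class Read:
    """A sequencing read; base qualities are ignored throughout."""

    id: str
    seq: str
    dataset_id: str = ""


@dataclass(frozen=True)
class TaxNode:
    taxon_id: str
    parent_id: Optional[str]
    rank: str
    name: str


RANKS = ["domain", "phylum", "class", "order", "family", "genus", "species"]
_RANK_DEPTH = {r: i for i, r in enumerate(RANKS)}


class TaxonomyTree:
    """A rooted taxonomy with the seven canonical ranks.

    Validates single-rootedness, parent existence, acyclicity and that rank
    depth never decreases along a root-to-leaf path.
    """

    def __init__(self, nodes: Iterable[TaxNode]):
        self.nodes: dict[str, TaxNode] = {}
        for n in nodes:
            if n.taxon_id in self.nodes:
                raise ParseError(f"duplicate taxon id {n.taxon_id}")
            if n.rank not in _RANK_DEPTH:
                raise ParseError(f"unknown rank {n.rank!r} for {n.taxon_id}")
            self.nodes[n.taxon_id] = n
        roots = [t for t, n in self.nodes.items() if n.parent_id is None]
        if len(roots) != 1:
            raise ParseError(
                f"taxonomy must have exactly one root, found {len(roots)}"
            )
        self.root = roots[0]
        self._children: dict[str, list[str]] = {t: [] for t in self.nodes}
        for t, n in self.nodes.items():
            if n.parent_id is None:
                continue
            if n.parent_id not in self.nodes:
                raise ParseError(f"orphan node {t}: parent {n.parent_id} missing")
            self._children[n.parent_id].append(t)
        # reachability from root doubles as the cycle check
        seen = set()
        stack = [self.root]
        while stack:
            t = stack.pop()
            seen.add(t)
            stack.extend(self._children[t])
        if seen != set(self.nodes):
            raise ParseError("taxonomy contains a cycle or unreachable nodes")
        for t in self.nodes:
            p = self.nodes[t].parent_id
            if p is not None and _RANK_DEPTH[self.nodes[t].rank] <= _RANK_DEPTH[self.nodes[p].rank]:
                raise ParseError(f"rank of {t} does not deepen from parent {p}")

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.nodes

    def children(self, taxon_id: str) -> list[str]:
        return list(self._children[taxon_id])

    def parent(self, taxon_id: str) -> Optional[str]:
        return self.nodes[taxon_id].parent_id

    def lineage(self, taxon_id: str) -> list[str]:
        """Path from root to ``taxon_id`` inclusive."""
        path = []
        t: Optional[str] = taxon_id
        while t is not None:
            path.append(t)
            t = self.nodes[t].parent_id
        return path[::-1]

    def depth(self, taxon_id: str) -> int:
        return len(self.lineage(taxon_id)) - 1

    def lca(self, taxa: Iterable[str]) -> str:
        paths = [self.lineage(t) for t in taxa]
        if not paths:
            raise ValueError("lca of empty set")
        lca = self.root
        for level in zip(*paths):
            if len(set(level)) == 1:
                lca = level[0]
            else:
                break
        return lca

    def ancestor_at_rank(self, taxon_id: str, rank: str) -> Optional[str]:
        for t in self.lineage(taxon_id):
            if self.nodes[t].rank == rank:
                return t
        return None

    def descendants(self, taxon_id: str) -> set[str]:
        out = set()
        stack = [taxon_id]
        while stack:
            t = stack.pop()
            out.add(t)
            stack.extend(self._children[t])
        return out


# --------------------------------------------------------------------------- FASTA / FASTQ

_VALID_NT = set("ACGTN")


def read_fasta(path, kind: str = "nt") -> list[Contig]:
    """Read a FASTA file into a list of :class:`Contig` (order preserved, uppercased).

    ``kind="aa"`` skips the nucleotide alphabet check so protein FASTA can be
    loaded through the same door. Duplicate ids and empty sequences are rejected.
    """
    records = []
    seen = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if not rec.id:
            raise ParseError(f"record {i}: empty header")
        if rec.id in seen:
            raise ParseError(f"record {i}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"record {i} ({rec.id}): empty sequence")
        if kind == "nt" and not set(seq) <= _VALID_NT:
            bad = sorted(set(seq) - _VALID_NT)
            raise ParseError(f"record {i} ({rec.id}): non-nucleotide symbols {bad}")
        records.append(Contig(rec.id, seq))
    return records


def write_fasta(records, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for r in records:
            rid = r.id if hasattr(r, "id") else r[0]
            seq = r.seq if hasattr(r, "seq") else r[1]
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path, dataset_id: str = "") -> list[Read]:
    return [
        Read(rec.id, str(rec.seq).upper(), dataset_id)
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(reads: Iterable[Read], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# --------------------------------------------------------------------------- GFF3


@dataclass(frozen=True)
class GffFeature:
    """One GFF3 feature row, held in internal 0-based half-open coordinates."""

    contig_id: str
    start: int
    end: int
    strand: str
    ftype: str = "CDS"
    label: str = ""
    attributes: tuple = ()


def write_genome_map(features: Iterable[GffFeature], path, contig_lengths=None) -> None:
    """Write features as GFF3 (converting to 1-based inclusive coordinates).

    ``contig_lengths`` (id -> length), when given, bounds-checks every feature
    and emits ``##sequence-region`` pragmas.
    """
    feats = list(features)
    if contig_lengths is not None:
        for f in feats:
            if f.contig_id not in contig_lengths:
                raise ValueError(f"feature on unknown contig {f.contig_id}")
            if not (0 <= f.start < f.end <= contig_lengths[f.contig_id]):
                raise ValueError(
                    f"feature [{f.start},{f.end}) out of bounds on {f.contig_id}"
                )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if contig_lengths:
            for cid, ln in contig_lengths.items():
                fh.write(f"##sequence-region {cid} 1 {ln}\n")
        for f in feats:
            attrs = [f"label={f.label}"] if f.label else []
            attrs += [f"{k}={v}" for k, v in f.attributes]
            fh.write(
                "\t".join(
                    [
                        f.contig_id,
                        "vinascan",
                        f.ftype,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        ";".join(attrs) or ".",
                    ]
                )
                + "\n"
            )


def read_genome_map(path) -> list[GffFeature]:
    """Read a GFF3 file back into internal-coordinate features."""
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"line {lineno}: expected 9 GFF3 columns")
            cid, _, ftype, start, end, _, strand, _, attr = parts
            attributes = []
            label = ""
            if attr != ".":
                for kv in attr.split(";"):
                    k, _, v = kv.partition("=")
                    if k == "label":
                        label = v
                    else:
                        attributes.append((k, v))
            feats.append(
                GffFeature(cid, int(start) - 1, int(end), strand, ftype, label, tuple(attributes))
            )
    return feats


# --------------------------------------------------------------------------- taxonomy TSV


def load_taxonomy(tsv_path) -> TaxonomyTree:
    """Load a taxonomy table (columns: taxon_id, parent_id, rank, name).

    A blank/''/'-' parent_id marks the root. Validation (single root, no
    orphans, no cycles, deepening ranks) happens in :class:`TaxonomyTree`.
    """
    nodes = []
    with open(tsv_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"taxon_id", "parent_id", "rank", "name"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ParseError(f"taxonomy TSV needs columns {sorted(required)}")
        for row in reader:
            parent = row["parent_id"].strip()
            nodes.append(
                TaxNode(
                    row["taxon_id"].strip(),
                    parent if parent not in ("", "-", "NA") else None,
                    row["rank"].strip(),
                    row["name"].strip(),
                )
            )
    return TaxonomyTree(nodes)


def write_taxonomy(tree: TaxonomyTree, path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon_id\tparent_id\trank\tname\n")
        for t in sorted(tree.nodes):
            n = tree.nodes[t]
            fh.write(f"{n.taxon_id}\t{n.parent_id or ''}\t{n.rank}\t{n.name}\n")
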