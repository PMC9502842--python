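"""MCP dereplication, progressive alignment, NJ trees with bootstrap, clade assignment.

The tree machinery is deliberately distance-based: neighbor joining on
Kimura-corrected p-distances with column-resampling bootstrap gives a
deterministic, desk-scale framework in which the five major capsid-protein
clades (A-E) are defined by labeled anchor sequences, and new sequences are
assigned to the clade of their nearest anchor.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from ._align import AA_X, b62, encode_aa, global_affine, make_protein_aligner

MAX_DISTANCE = 5.0


@dataclass
class Msa:
    rows: list  # list of (seq_id, aligned string)

    @property
    def length(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def __iter__(self):
        return iter(self.rows)

    def __len__(self):
        return len(self.rows)

    def validate(self, originals: Optional[dict] = None) -> None:
        if len({len(r) for _, r in self.rows}) > 1:
            raise ValueError("MSA rows differ in length")
        if originals:
            for sid, row in self.rows:
                if row.replace("-", "") != originals[sid]:
                    raise ValueError(f"ungapping row {sid} does not return the input")


@dataclass
class CladeModel:
    """An anchored clade framework: a support-annotated tree plus labeled leaves."""

    newick: str
    anchors: dict  # seq_id -> clade label in {A..E}
    hgv_anchors: dict = field(default_factory=dict)  # seq_id -> HGV-1/2/3 (clade A)
    supports: dict = field(default_factory=dict)  # frozenset(leaves) -> percent

    def __post_init__(self):
        if not self.anchors:
            raise ValueError("clade model needs >= 1 anchor")


# ------------------------------------------------------------------- dereplication


def dereplicate(
    seqs: Sequence[tuple[str, str]], identity: float = 0.8
) -> tuple[list[tuple[str, str]], dict]:
    """Greedy centroid dereplication at an identity threshold.

    Returns (representatives, member -> representative map). Sequences are
    visited longest-first so the representative is the longest member.
    """
    from ._align import global_identity

    order = sorted(seqs, key=lambda p: (-len(p[1]), p[0]))
    reps: list[tuple[str, str]] = []
    mapping: dict[str, str] = {}
    for sid, seq in order:
        for rid, rseq in reps:
            if global_identity(seq, rseq) >= identity:
                mapping[sid] = rid
                break
        else:
            reps.append((sid, seq))
            mapping[sid] = sid
    return reps, mapping


# ------------------------------------------------------------------- progressive MSA


def _kmer_profile(seq: str, k: int = 3) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _freq_profile(rows: list[str]) -> np.ndarray:
    """Per-column residue frequencies (gaps contribute nothing)."""
    L = len(rows[0])
    f = np.zeros((L, AA_X + 1))
    for row in rows:
        enc = encode_aa(row)
        for i, ch in enumerate(row):
            if ch != "-":
                f[i, enc[i]] += 1
    return f / len(rows)


def _merge_alignments(rows_a: list, rows_b: list, gap_open=11.0, gap_extend=1.0):
    """Align two alignments with expected-BLOSUM62 column scoring; merge rows."""
    fa = _freq_profile([r for _, r in rows_a])
    fb = _freq_profile([r for _, r in rows_b])
    S = np.ascontiguousarray(fa @ b62() @ fb.T)
    _, path = global_affine(S, gap_open, gap_extend)
    out_a = {sid: [] for sid, _ in rows_a}
    out_b = {sid: [] for sid, _ in rows_b}
    i = j = 0
    for move in path:
        if move == 0:
            for sid, r in rows_a:
                out_a[sid].append(r[i])
            for sid, r in rows_b:
                out_b[sid].append(r[j])
            i += 1
            j += 1
        elif move == 1:  # consume a column of A only
            for sid, r in rows_a:
                out_a[sid].append(r[i])
            for sid, _ in rows_b:
                out_b[sid].append("-")
            i += 1
        else:
            for sid, _ in rows_a:
                out_a[sid].append("-")
            for sid, r in rows_b:
                out_b[sid].append(r[j])
            j += 1
    return [(sid, "".join(out_a[sid])) for sid, _ in rows_a] + [
        (sid, "".join(out_b[sid])) for sid, _ in rows_b
    ]


def progressive_align(seqs: Sequence[tuple[str, str]]) -> list[tuple[str, str]]:
    """Guide-tree progressive alignment (k-mer UPGMA guide, BLOSUM62, affine gaps)."""
    seqs = list(seqs)
    if len(seqs) == 0:
        raise ValueError("progressive_align: empty input")
    if len(seqs) == 1:
        return [tuple(seqs[0])]
    if len(seqs) == 2:
        return _merge_alignments([tuple(seqs[0])], [tuple(seqs[1])])
    profiles = [_kmer_profile(s) for _, s in seqs]
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(profiles[i] & profiles[j])
            denom = min(len(profiles[i]), len(profiles[j])) or 1
            D[i, j] = D[j, i] = 1.0 - inter / denom
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    groups: dict[int, list] = {i: [tuple(seqs[i])] for i in range(n)}
    for step, (a, bnode, _, _) in enumerate(Z):
        merged = _merge_alignments(groups.pop(int(a)), groups.pop(int(bnode)))
        groups[n + step] = merged
    (result,) = groups.values()
    order = {sid: k for k, (sid, _) in enumerate(seqs)}
    result.sort(key=lambda r: order[r[0]])
    return result


# ------------------------------------------------------------------- distances


def kimura_distance(p: float) -> float:
    """Kimura's empirical correction d = -ln(1 - p - p^2/5), capped at 5.0."""
    arg = 1.0 - p - 0.2 * p * p
    if arg <= math.exp(-MAX_DISTANCE):
        return MAX_DISTANCE
    return min(-math.log(arg), MAX_DISTANCE)


def msa_pdistance(row_a: str, row_b: str) -> float:
    """p-distance over columns where both rows have a residue."""
    pairs = 0
    diff = 0
    for a, bch in zip(row_a, row_b):
        if a == "-" or bch == "-":
            continue
        pairs += 1
        if a != bch:
            diff += 1
    return diff / pairs if pairs else 1.0


def _distance_matrix(rows: list, columns: Optional[np.ndarray] = None) -> np.ndarray:
    mat = np.array([[c for c in r] for _, r in rows])
    if columns is not None:
        mat = mat[:, columns]
    n = len(rows)
    D = np.zeros((n, n))
    gap = mat == "-"
    for i in range(n):
        for j in range(i + 1, n):
            both = ~(gap[i] | gap[j])
            pairs = both.sum()
            p = (mat[i, both] != mat[j, both]).sum() / pairs if pairs else 1.0
            D[i, j] = D[j, i] = kimura_distance(p)
    return D


def _bipartitions(tree: TreeNode, taxa: frozenset) -> set:
    """Nontrivial bipartitions as frozensets of the side not containing an
    arbitrary reference taxon (canonical orientation)."""
    ref = min(taxa)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(taxa - side) < 2:
            continue
        if ref in side:
            side = taxa - side
        parts.add(side)
    return parts


def neighbor_joining(ids: list, D: np.ndarray) -> TreeNode:
    """Neighbor joining via scikit-bio on a precomputed distance matrix."""
    dm = DistanceMatrix(D, ids)
    return nj(dm)


def build_tree(
    msa: Sequence[tuple[str, str]], n_bootstrap: int = 100, seed: int = 0
) -> tuple[str, dict]:
    """NJ tree from an alignment, with column-resampling bootstrap supports.

    Returns (newick with supports as internal-node labels,
    bipartition -> support-percent map).
    """
    rows = list(msa)
    ids = [sid for sid, _ in rows]
    if len(rows) < 3:
        raise ValueError("build_tree needs >= 3 sequences")
    taxa = frozenset(ids)
    D = _distance_matrix(rows)
    main = neighbor_joining(ids, D)
    main_parts = _bipartitions(main, taxa)
    counts = {p: 0 for p in main_parts}
    rng = np.random.default_rng(seed)
    L = len(rows[0][1])
    for _ in range(n_bootstrap):
        cols = rng.integers(0, L, size=L)
        Db = _distance_matrix(rows, cols)
        parts = _bipartitions(neighbor_joining(ids, Db), taxa)
        for p in main_parts:
            if p in parts:
                counts[p] += 1
    if len(rows) == 3:
        supports = {}
    else:
        supports = {p: 100.0 * c / n_bootstrap for p, c in counts.items()}
    for node in main.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        canon = side if min(taxa) not in side else taxa - side
        if canon in supports:
            node.name = str(int(round(supports[canon])))
    buf = io.StringIO()
    main.write(buf, format="newick")
    return buf.getvalue().strip(), supports


# ------------------------------------------------------------------- clade assignment


_PAIR_ALIGNER = None


def pairwise_corrected_distance(a: str, b: str) -> float:
    """Kimura-corrected p-distance from the best global alignment of a and b."""
    global _PAIR_ALIGNER
    if _PAIR_ALIGNER is None:
        _PAIR_ALIGNER = make_protein_aligner("global")
    aln = next(iter(_PAIR_ALIGNER.align(a.replace("*", "X"), b.replace("*", "X"))))
    counts = aln.counts()
    pairs = counts.identities + counts.mismatches
    p = counts.mismatches / pairs if pairs else 1.0
    return kimura_distance(p)


def assign_clade(
    query_seq: str,
    clade_model: CladeModel,
    anchor_seqs: dict,
) -> tuple[str, Optional[str], float]:
    """Clade of the nearest anchor (plus HGV group when the clade is A).

    An exact distance tie between anchors of different clades yields
    ("ambiguous", None, d).
    """
    if not clade_model.anchors:
        raise ValueError("clade model has no anchors")
    dists = []
    for sid, clade in clade_model.anchors.items():
        if sid not in anchor_seqs:
            raise ValueError(f"anchor {sid} has no sequence")
        dists.append((pairwise_corrected_distance(query_seq, anchor_seqs[sid]), sid, clade))
    dists.sort(key=lambda t: (t[0], t[1]))
    best_d, _, best_clade = dists[0]
    tied_clades = {c for d, _, c in dists if d == best_d}
    if len(tied_clades) > 1:
        return "ambiguous", None, best_d
    hgv = None
    if best_clade == "A" and clade_model.hgv_anchors:
        hdists = [
            (pairwise_corrected_distance(query_seq, anchor_seqs[sid]), sid, grp)
            for sid, grp in clade_model.hgv_anchors.items()
            if sid in anchor_seqs
        ]
        if hdists:
            hdists.sort(key=lambda t: (t[0], t[1]))
            hgroups = {g for d, _, g in hdists if d == hdists[0][0]}
            hgv = hdists[0][2] if len(hgroups) == 1 else "ambiguous"
    return best_clade, hgv, best_d
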