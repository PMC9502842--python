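"""Bacterial host assignment for (pro)phages.

Two independent routes, reported side by side and never merged:

* **flank voting** — every protein on an MCP-encoding contig (optionally
  excluding genes inside known prophage boundaries) is searched against a
  taxon-labeled reference protein database; the deepest taxonomy node
  accounting for at least half of the best hits wins.
* **CRISPR spacers** — repeat-spacer arrays detected on long host contigs are
  matched against the +/-8 kb region around each MCP gene; a
  high-identity, low-E match ties the array's host to the phage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from scipy.optimize import brentq

from ._align import kmer_set, local_protein_alignment, shares_kmer
from .core_model import Contig, GeneCall, TaxonomyTree, revcomp

# ---------------------------------------------------------------------- types


@dataclass
class HostAssignment:
    contig_id: str
    taxon_id: str
    method: str  # flank_vote | crispr
    support: float  # hit fraction (flank_vote) or matching spacer count (crispr)

    def __post_init__(self):
        if self.method not in {"flank_vote", "crispr"}:
            raise ValueError(f"unknown method {self.method}")
        if self.method == "flank_vote" and self.support < 0.5:
            raise ValueError("flank_vote support must be >= 0.5")
        if self.method == "crispr" and self.support < 1:
            raise ValueError("crispr support must be >= 1")


@dataclass
class RefProtein:
    id: str
    seq: str
    taxon_id: str


MIN_REPEAT, MAX_REPEAT = 23, 47
MIN_SPACER, MAX_SPACER = 26, 50


@dataclass
class CrisprArray:
    contig_id: str
    repeat: str
    spacers: list  # list of (seq, (start, end))
    array_interval: tuple[int, int]

    def __post_init__(self):
        if not (MIN_REPEAT <= len(self.repeat) <= MAX_REPEAT):
            raise ValueError(f"repeat length {len(self.repeat)} outside [23,47]")
        for s, _ in self.spacers:
            if not (MIN_SPACER <= len(s) <= MAX_SPACER):
                raise ValueError(f"spacer length {len(s)} outside [26,50]")


@dataclass
class SpacerMatch:
    spacer_id: str
    phage_contig_id: str
    identity: float  # percent
    aligned_length: int
    evalue: float

    def __post_init__(self):
        if self.identity < 95:
            raise ValueError("spacer match identity must be >= 95%")
        if self.evalue > 1e-15:
            raise ValueError("spacer match evalue must be <= 1e-15")


# ---------------------------------------------------------------------- flank voting


def flank_best_hits(
    proteins: Sequence[GeneCall],
    reference_db: Sequence[RefProtein],
    floor_score: float = 50.0,
) -> list[tuple[str, Optional[str]]]:
    """Best reference hit per query protein (None when nothing clears the floor).

    Ties on score resolve to the longer alignment, then the lexicographically
    smaller reference id.
    """
    if not reference_db:
        raise ValueError("empty reference database")
    ref_kmers = [(r, kmer_set(r.seq, 4)) for r in reference_db]
    out = []
    for g in proteins:
        best = None  # (score, -alen, ref_id, taxon)
        for r, ks in ref_kmers:
            if not shares_kmer(ks, g.aa_seq, 4, min_shared=2):
                continue
            score, alen = local_protein_alignment(g.aa_seq, r.seq)
            if score < floor_score:
                continue
            key = (-score, -alen, r.id)
            if best is None or key < best[0]:
                best = (key, r.taxon_id)
        out.append((g.id, best[1] if best else None))
    return out


def vote_host(
    hits: Iterable[tuple[str, Optional[str]]],
    taxonomy: TaxonomyTree,
    contig_id: str = "",
) -> Optional[HostAssignment]:
    """Majority vote over the taxonomy: the deepest node that accounts for at
    least half (>= ceil(n/2)) of the hit-bearing proteins.

    A hit counts for its taxon and every ancestor. Equally deep qualifying
    nodes resolve to their lowest common ancestor. Hitless proteins are
    excluded from the denominator; n = 0 yields None.
    """
    taxa = [t for _, t in hits if t is not None]
    n = len(taxa)
    if n == 0:
        return None
    counts: dict[str, int] = {}
    for t in taxa:
        if t not in taxonomy:
            raise ValueError(f"hit taxon {t} not in taxonomy")
        for node in taxonomy.lineage(t):
            counts[node] = counts.get(node, 0) + 1
    need = math.ceil(n / 2)
    qualifying = [t for t, c in counts.items() if c >= need]
    best_depth = max(taxonomy.depth(t) for t in qualifying)
    deepest = [t for t in qualifying if taxonomy.depth(t) == best_depth]
    winner = deepest[0] if len(deepest) == 1 else taxonomy.lca(deepest)
    return HostAssignment(contig_id, winner, "flank_vote", counts[winner] / n)


# ---------------------------------------------------------------------- CRISPR arrays


def detect_crispr(
    contig: Contig,
    min_contig_len: int = 10_000,
    seed_k: int = 8,
    max_mismatch: int = 1,
) -> list[CrisprArray]:
    """Find repeat-spacer arrays (>= 3 repeat copies, repeat 23-47 nt,
    spacers 26-50 nt) by seed k-mer recurrence and extension.

    Contigs of <= ``min_contig_len`` nt are skipped (arrays on short contigs
    carry too little host signal to type).
    """
    seq = contig.seq
    if len(seq) <= min_contig_len:
        return []
    positions: dict[str, list[int]] = {}
    for i in range(len(seq) - seed_k + 1):
        positions.setdefault(seq[i : i + seed_k], []).append(i)
    min_period = MIN_REPEAT + MIN_SPACER
    max_period = MAX_REPEAT + MAX_SPACER
    covered: list[tuple[int, int]] = []
    arrays = []
    for kmer in sorted(positions):
        pos = positions[kmer]
        if len(pos) < 3:
            continue
        runs = []
        run = [pos[0]]
        for p in pos[1:]:
            if min_period <= p - run[-1] <= max_period:
                run.append(p)
            else:
                if len(run) >= 3:
                    runs.append(run)
                run = [p]
        if len(run) >= 3:
            runs.append(run)
        for run in runs:
            if any(run[0] >= c0 and run[-1] <= c1 for c0, c1 in covered):
                continue
            arr = _extend_array(seq, run, seed_k, max_mismatch)
            if arr is None:
                continue
            starts, rep_len = arr
            repeat = seq[starts[0] : starts[0] + rep_len]
            spacers = []
            ok = True
            for a, b in zip(starts, starts[1:]):
                s0, s1 = a + rep_len, b
                if not (MIN_SPACER <= s1 - s0 <= MAX_SPACER):
                    ok = False
                    break
                spacers.append((seq[s0:s1], (s0, s1)))
            if not ok or not spacers:
                continue
            interval = (starts[0], starts[-1] + rep_len)
            arrays.append(CrisprArray(contig.id, repeat, spacers, interval))
            covered.append(interval)
    arrays.sort(key=lambda a: a.array_interval)
    return arrays


def _extend_array(seq, run, seed_k, max_mismatch):
    """Extend seed positions into maximal near-identical repeat copies."""
    n = len(seq)

    def mismatches(left, right):
        total = []
        ref0 = run[0]
        for p in run[1:]:
            mm = 0
            for off in range(-left, seed_k + right):
                i, j = ref0 + off, p + off
                if i < 0 or j < 0 or i >= n or j >= n or seq[i] != seq[j]:
                    mm += 1
            total.append(mm)
        return max(total)

    def column_exact(off):
        ref0 = run[0]
        for p in run[1:]:
            i, j = ref0 + off, p + off
            if i < 0 or j < 0 or i >= n or j >= n or seq[i] != seq[j]:
                return False
        return True

    left = right = 0
    # greedy extension while all copies stay within max_mismatch ...
    improved = True
    while improved and left + seed_k + right < MAX_REPEAT:
        improved = False
        for dl, dr in ((1, 0), (0, 1)):
            nl, nr = left + dl, right + dr
            if run[0] - nl < 0 or run[-1] + seed_k + nr > n:
                continue
            # repeats must not run into the next copy's spacer minimum
            if any(b - (a + seed_k + nr) < MIN_SPACER - nl for a, b in zip(run, run[1:])):
                continue
            if mismatches(nl, nr) <= max_mismatch:
                left, right = nl, nr
                improved = True
                break
    # ... then trim non-identical boundary columns so exact arrays are
    # recovered at exact coordinates
    while left > 0 and not column_exact(-left):
        left -= 1
    while right > 0 and not column_exact(seed_k + right - 1):
        right -= 1
    rep_len = left + seed_k + right
    if rep_len < MIN_REPEAT:
        return None
    return [p - left for p in run], rep_len


# ---------------------------------------------------------------------- spacer matching

MATCH_SCORE = 1.0
MISMATCH_SCORE = -3.0
KA_K = 0.1  # conservative Karlin-Altschul prefactor for the nt search


def _solve_lambda(match=MATCH_SCORE, mismatch=MISMATCH_SCORE) -> float:
    """Ungapped Karlin-Altschul lambda at uniform nucleotide background."""

    def f(lam):
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    return brentq(f, 1e-6, 10.0)


KA_LAMBDA = _solve_lambda()


def spacer_evalue(score: float, search_space: int) -> float:
    """E = K * space * exp(-lambda * score); the stated search space is the
    summed region length over both strands."""
    return KA_K * search_space * math.exp(-KA_LAMBDA * score)


def _index_region(region: str, word: int) -> dict:
    index: dict[str, list[int]] = {}
    for i in range(len(region) - word + 1):
        index.setdefault(region[i : i + word], []).append(i)
    return index


def _best_ungapped(spacer: str, region: str, index: dict, word: int):
    """Best ungapped seeded extension of spacer vs region (one orientation).

    Returns (score, matches, aligned_length) of the best-scoring extension.
    """
    best = None
    seen_diag = set()
    for j in range(len(spacer) - word + 1):
        for i in index.get(spacer[j : j + word], ()):
            d = i - j
            if d in seen_diag:
                continue
            seen_diag.add(d)
            # score the full spacer footprint on this diagonal, then trim to
            # the max-scoring sub-segment (ungapped Smith-Waterman on a line)
            scores = []
            for q in range(len(spacer)):
                r = q + d
                if 0 <= r < len(region):
                    scores.append(
                        (MATCH_SCORE if spacer[q] == region[r] else MISMATCH_SCORE, spacer[q] == region[r])
                    )
            run_score = best_score = 0.0
            run_start = 0
            run_matches = best_matches = 0
            run_len = best_len = 0
            for sc, is_match in scores:
                if run_score <= 0:
                    run_score, run_matches, run_len = 0.0, 0, 0
                run_score += sc
                run_matches += int(is_match)
                run_len += 1
                if run_score > best_score:
                    best_score, best_matches, best_len = run_score, run_matches, run_len
            if best_score > 0 and (best is None or best_score > best[0]):
                best = (best_score, best_matches, best_len)
    return best


def match_spacers(
    spacers: Sequence[tuple[str, str]],
    phage_regions: Sequence[tuple[str, str]],
    word: int = 7,
    identity_threshold: float = 95.0,
    evalue_threshold: float = 1e-15,
) -> list[SpacerMatch]:
    """Match spacers [(spacer_id, seq)] against phage regions
    [(phage_contig_id, region_seq)] on both strands.

    A match is reported iff identity >= 95% of the aligned length and the
    Karlin-Altschul E-value (over the stated two-strand search space) is
    <= 1e-15.
    """
    out = []
    indexed = [(rid, region, _index_region(region, word)) for rid, region in phage_regions]
    for sid, sp in spacers:
        for rid, region, index in indexed:
            search_space = 2 * len(region)
            best = None
            for orient in (sp, revcomp(sp)):
                cand = _best_ungapped(orient, region, index, word)
                if cand and (best is None or cand[0] > best[0]):
                    best = cand
            if best is None:
                continue
            score, matches, alen = best
            identity = 100.0 * matches / alen
            ev = spacer_evalue(score, search_space)
            if identity >= identity_threshold and ev <= evalue_threshold:
                out.append(SpacerMatch(sid, rid, identity, alen, ev))
    return out


def minimum_exact_match_length(
    region_len: int, evalue_threshold: float = 1e-15
) -> int:
    """Shortest exact match whose E-value clears the threshold for a region."""
    L = 1
    while spacer_evalue(L * MATCH_SCORE, 2 * region_len) > evalue_threshold:
        L += 1
    return L


def crispr_host_assignments(
    matches: Sequence[SpacerMatch],
    spacer_hosts: dict,
) -> list[HostAssignment]:
    """Turn spacer matches into per-phage-contig host calls.

    ``spacer_hosts`` maps spacer_id -> host taxon of the array-bearing contig
    (truth labels on synthetic data, or flank-vote taxa on real data).
    Support is the number of matching spacers backing the winning taxon.
    """
    votes: dict[tuple[str, str], int] = {}
    for m in matches:
        taxon = spacer_hosts.get(m.spacer_id)
        if taxon is None:
            continue
        votes[(m.phage_contig_id, taxon)] = votes.get((m.phage_contig_id, taxon), 0) + 1
    best: dict[str, tuple[int, str]] = {}
    for (cid, taxon), cnt in sorted(votes.items()):
        if cid not in best or cnt > best[cid][0]:
            best[cid] = (cnt, taxon)
    return [
        HostAssignment(cid, taxon, "crispr", cnt) for cid, (cnt, taxon) in sorted(best.items())
    ]
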