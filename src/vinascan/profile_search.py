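"""Position-specific scoring profiles with decoy-calibrated E-values.

This is the pipeline's homology engine: profiles are log-odds PSSMs built from
seed alignments, searched by Smith–Waterman with affine gaps, and thresholded
on an E-value obtained from a Gumbel fit to the max-scores of random background
decoys. Borderline hits (cutoff < E <= 1) pass a mechanical curation rule based
on the conservation pattern at the profile's most informative columns.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._align import (
    AA_ALPHABET,
    AA_X,
    encode_aa,
    global_identity,
    kmer_set,
    local_affine,
    local_affine_score,
    shares_kmer,
)

EULER_GAMMA = 0.57721566490153286

LOG_ODDS_FLOOR = -10.0  # bits; floors log2(0) for residues absent from a column

# coarse physicochemical classes used by the curation rule
RESIDUE_CLASSES = {
    **{a: "hydrophobic" for a in "AVLIMC"},
    **{a: "aromatic" for a in "FWY"},
    **{a: "polar" for a in "STNQ"},
    **{a: "positive" for a in "KRH"},
    **{a: "negative" for a in "DE"},
    **{a: "special" for a in "GP"},
}


@dataclass
class ProteinProfile:
    """A PSSM over the 20 amino acids (+X) with optional Gumbel calibration."""

    name: str
    matrix: np.ndarray  # (n_columns, 21) log-odds in bits
    consensus: str
    calibration: Optional[tuple] = None  # (mu, lambda, decoy_len, n_decoys)
    source_msa_id: str = ""
    group: str = ""  # e.g. varidnavirus group or gene family tag
    frequencies: Optional[np.ndarray] = None  # (n_columns, 20) observed freqs

    def __post_init__(self):
        if self.matrix.shape[0] < 10:
            raise ValueError(f"profile {self.name}: needs >= 10 columns")
        if len(self.consensus) != self.matrix.shape[0]:
            raise ValueError("consensus length must equal column count")
        if self.calibration is not None and self.calibration[1] <= 0:
            raise ValueError("calibration lambda must be > 0")
        self._consensus_kmers = None

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus_kmers(self) -> set:
        if self._consensus_kmers is None:
            self._consensus_kmers = kmer_set(self.consensus, 4)
        return self._consensus_kmers

    def information_ranked_columns(self) -> np.ndarray:
        """Column indices ordered by decreasing information content."""
        if self.frequencies is not None:
            info = (self.frequencies * self.matrix[:, :AA_X]).sum(axis=1)
        else:
            info = self.matrix[:, :AA_X].max(axis=1)
        return np.argsort(-info, kind="stable")


@dataclass
class ProfileHit:
    protein_id: str
    profile_name: str
    raw_score: float  # bits
    evalue: float
    query_interval: tuple[int, int]
    profile_interval: tuple[int, int]
    coverage: float
    curated: bool = False  # accepted via the conserved-pattern rule

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not (0 < self.coverage <= 1):
            raise ValueError("coverage must be in (0, 1]")


@dataclass
class ProteinCluster:
    id: str
    member_ids: list
    member_seqs: list
    msa: list  # list of (seq_id, aligned row)
    profile: Optional[ProteinProfile] = None


# --------------------------------------------------------------------- profile build


def _profile_from_rows(name, rows, pseudocount_weight, background, source_msa_id="",
                       group="", max_gap_fraction=0.5):
    nseq = len(rows)
    length = len(rows[0])
    counts = np.zeros((length, AA_X), dtype=float)
    gaps = np.zeros(length, dtype=float)
    for row in rows:
        enc = encode_aa(row.replace("-", "."))
        for i, ch in enumerate(row):
            if ch == "-" or ch == ".":
                gaps[i] += 1
            elif enc[i] < AA_X:
                counts[i, enc[i]] += 1
    keep = gaps <= max_gap_fraction * nseq
    counts = counts[keep]
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    freqs = counts / totals
    alpha = pseudocount_weight
    bg = background
    with np.errstate(divide="ignore"):
        logodds = np.log2((freqs + alpha * bg) / ((1 + alpha) * bg))
    logodds = np.maximum(logodds, LOG_ODDS_FLOOR)
    matrix = np.zeros((logodds.shape[0], AA_X + 1))
    matrix[:, :AA_X] = logodds
    consensus = "".join(AA_ALPHABET[i] for i in freqs.argmax(axis=1))
    return ProteinProfile(
        name, matrix, consensus, source_msa_id=source_msa_id, group=group, frequencies=freqs
    )


def build_profile(
    msa: Sequence,
    pseudocount_weight: float = 1.0,
    name: str = "profile",
    background: Optional[np.ndarray] = None,
    group: str = "",
    source_msa_id: str = "",
) -> ProteinProfile:
    """Build a log-odds PSSM from an MSA (list of (id, aligned row) or rows).

    Columns with more than 50% gaps are dropped. Per column, the score of
    residue ``a`` is ``log2((f_a + alpha*bg_a) / ((1+alpha)*bg_a))`` with
    observed frequency ``f_a``, background ``bg_a`` (uniform by default) and
    pseudocount weight ``alpha``; the consensus residue maximises ``f_a``.
    """
    rows = [r[1] if isinstance(r, (tuple, list)) else r for r in msa]
    if len(rows) < 2:
        raise ValueError("profile needs >=2 sequences")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("MSA rows must have equal length")
    if background is None:
        background = np.full(AA_X, 1.0 / AA_X)
    return _profile_from_rows(
        name, rows, pseudocount_weight, background, source_msa_id, group
    )


# --------------------------------------------------------------------- calibration


def calibrate_evalue(
    profile: ProteinProfile,
    n_decoys: int = 500,
    decoy_len: int = 300,
    seed: int = 0,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> tuple[float, float]:
    """Fit a Gumbel law to max local-alignment scores of background decoys.

    Method of moments: ``lambda = pi / (sigma * sqrt(6))``,
    ``mu = mean - gamma / lambda``. The fit (with the decoy length) is stored
    on the profile and drives :func:`search_profile` E-values.
    """
    if n_decoys < 100:
        raise ValueError("n_decoys must be >= 100")
    rng = np.random.default_rng(seed)
    decoys = rng.integers(0, AA_X, size=(n_decoys, decoy_len))
    scores = np.empty(n_decoys)
    mat = np.ascontiguousarray(profile.matrix)
    for i in range(n_decoys):
        S = mat[:, decoys[i]]
        scores[i] = local_affine_score(np.ascontiguousarray(S), gap_open, gap_extend)
    sigma = scores.std()
    if sigma == 0:
        raise ValueError("degenerate decoy score variance (sigma = 0)")
    lam = math.pi / (sigma * math.sqrt(6.0))
    mu = scores.mean() - EULER_GAMMA / lam
    profile.calibration = (mu, lam, decoy_len, n_decoys)
    return mu, lam


def evalue_from_score(profile: ProteinProfile, score: float, query_len: int) -> float:
    """Gumbel-tail E-value, scaled linearly to the query length.

    Equivalent to ``K * m * n * exp(-lambda * score)`` with
    ``K = exp(lambda * mu) / (m * n0)`` fixed by the calibration decoy length.
    """
    if profile.calibration is None:
        raise ValueError(f"profile {profile.name} is not calibrated")
    mu, lam, decoy_len, _ = profile.calibration
    return (query_len / decoy_len) * math.exp(-lam * (score - mu))


# --------------------------------------------------------------------- search


def _curation_check(profile, enc_query, path, i0, j0, top_n=10, min_match=0.7):
    """Accept a borderline hit iff >= ``min_match`` of the profile's ``top_n``
    highest-information columns carry a query residue of the consensus class."""
    col_to_query = {}
    i, j = i0, j0
    for move in path:
        if move == 0:
            col_to_query[i] = j
            i += 1
            j += 1
        elif move == 1:
            i += 1
        else:
            j += 1
    cols = profile.information_ranked_columns()[:top_n]
    ok = 0
    for c in cols:
        q = col_to_query.get(int(c))
        if q is None:
            continue
        qa = enc_query[q]
        if qa >= AA_X:
            continue
        if RESIDUE_CLASSES.get(AA_ALPHABET[qa]) == RESIDUE_CLASSES.get(profile.consensus[c]):
            ok += 1
    return ok >= min_match * len(cols)


def search_profile(
    profile: ProteinProfile,
    protein: str,
    protein_id: str = "query",
    evalue_cutoff: float = 0.05,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    curation: bool = True,
    curation_emax: float = 1.0,
    prefilter: bool = False,
    min_coverage: float = 0.0,
) -> Optional[ProfileHit]:
    """Smith–Waterman a protein against a calibrated PSSM.

    Returns a :class:`ProfileHit` iff E <= ``evalue_cutoff``, or, when
    ``curation`` is on, iff ``evalue_cutoff`` < E <= ``curation_emax`` and the
    conserved-pattern check passes. Returns None otherwise. ``min_coverage``
    additionally requires the aligned block to span that fraction of the
    profile — the E-value is per search, so screens over many proteins use a
    coverage floor to suppress short random local hits.
    """
    if profile.calibration is None:
        raise ValueError(f"profile {profile.name} is not calibrated")
    if prefilter and not shares_kmer(profile.consensus_kmers, protein):
        return None
    enc = encode_aa(protein)
    S = np.ascontiguousarray(profile.matrix[:, enc])
    score, i0, i1, j0, j1, path = local_affine(S, gap_open, gap_extend)
    if score <= 0 or i1 <= i0:
        return None
    if (i1 - i0) / len(profile) < min_coverage:
        return None
    ev = evalue_from_score(profile, score, len(protein))
    curated = False
    if ev > evalue_cutoff:
        if not (curation and ev <= curation_emax):
            return None
        if not _curation_check(profile, enc, path, i0, j0):
            return None
        curated = True
    coverage = (i1 - i0) / len(profile)
    return ProfileHit(
        protein_id,
        profile.name,
        float(score),
        float(ev),
        (j0, j1),
        (i0, i1),
        coverage,
        curated,
    )


def best_hit(
    profiles: Sequence[ProteinProfile],
    protein: str,
    protein_id: str = "query",
    evalue_cutoff: float = 0.05,
    prefilter: bool = True,
    min_coverage: float = 0.5,
    **kw,
) -> Optional[ProfileHit]:
    """Best accepted hit across profiles (lowest E, then higher coverage,
    then lexicographic profile name).

    Screens many proteins against many profiles, so a coverage floor
    (default half the profile) guards against the per-search E-value's
    expected rate of short random hits.
    """
    hits = []
    for p in profiles:
        h = search_profile(
            p, protein, protein_id, evalue_cutoff=evalue_cutoff, prefilter=prefilter,
            min_coverage=min_coverage, **kw
        )
        if h is not None:
            hits.append(h)
    if not hits:
        return None
    hits.sort(key=lambda h: (h.evalue, -h.coverage, h.profile_name))
    return hits[0]


# --------------------------------------------------------------------- clustering


def _make_cluster(cid, members, pseudocount_weight=1.0):
    """Assemble a ProteinCluster, aligning members and building its profile."""
    from .phylo import progressive_align  # local import avoids a module cycle

    ids = [m[0] for m in members]
    seqs = [m[1] for m in members]
    if len(seqs) == 1:
        msa = [(ids[0], seqs[0])]
        rows = [seqs[0], seqs[0]]  # degenerate single-member profile
    else:
        msa = progressive_align(list(zip(ids, seqs)))
        rows = [r[1] for r in msa]
    profile = None
    if len(rows[0]) >= 10:
        profile = _profile_from_rows(
            cid, rows, pseudocount_weight, np.full(AA_X, 1.0 / AA_X), source_msa_id=cid
        )
    return ProteinCluster(cid, ids, seqs, msa, profile)


def cluster_proteins(
    proteins: Sequence[tuple[str, str]],
    identity_threshold: float = 0.5,
    build_profiles: bool = True,
) -> list[ProteinCluster]:
    """Greedy centroid clustering at a global-alignment identity threshold.

    Proteins are visited by decreasing length; each joins the first existing
    centroid with identity >= threshold (matches / alignment columns, gaps in
    the denominator) or founds a new cluster.
    """
    if not proteins:
        raise ValueError("cluster_proteins: empty input")
    order = sorted(proteins, key=lambda p: (-len(p[1]), p[0]))
    centroids: list[tuple[str, str]] = []
    membership: list[list[tuple[str, str]]] = []
    for pid, seq in order:
        placed = False
        for ci, (_, cseq) in enumerate(centroids):
            if global_identity(seq, cseq) >= identity_threshold:
                membership[ci].append((pid, seq))
                placed = True
                break
        if not placed:
            centroids.append((pid, seq))
            membership.append([(pid, seq)])
    clusters = []
    for ci, members in enumerate(membership):
        if build_profiles:
            clusters.append(_make_cluster(f"cluster_{ci:03d}", members))
        else:
            clusters.append(
                ProteinCluster(
                    f"cluster_{ci:03d}",
                    [m[0] for m in members],
                    [m[1] for m in members],
                    [(m[0], m[1]) for m in members],
                )
            )
    return clusters


def _profile_pair_stats(a: ProteinProfile, b: ProteinProfile, gap_open=11.0, gap_extend=1.0):
    """Local profile-profile alignment scored by the dot product of the
    columns' rectified log-odds vectors (negative entries clipped so shared
    absences carry no signal), background-corrected by the all-pairs
    mean + 1 sd so a chance column pairing scores negative on average."""
    S = np.maximum(a.matrix, 0.0) @ np.maximum(b.matrix, 0.0).T
    S = np.ascontiguousarray(S - (S.mean() + S.std()))
    score, i0, i1, j0, j1, _ = local_affine(S, gap_open, gap_extend)
    shorter = min(len(a), len(b))
    footprint = min(i1 - i0, j1 - j0) / shorter if shorter else 0.0
    return score, footprint


def _profile_self_score(p: ProteinProfile) -> float:
    m = np.maximum(p.matrix, 0.0)
    S = m @ m.T
    return local_affine_score(np.ascontiguousarray(S - (S.mean() + S.std())), 11.0, 1.0)


def merge_clusters(
    clusters: list[ProteinCluster],
    coverage_threshold: float = 0.5,
    similarity_threshold: float = 0.05,
    max_rounds: int = 50,
) -> list[ProteinCluster]:
    """Iteratively merge similar clusters to a fixpoint.

    A pair merges iff the locally aligned footprint covers >= ``coverage_threshold``
    of the shorter profile AND pair score / min(self-score) >= ``similarity_threshold``.
    After each merge the members are re-aligned and the profile rebuilt.
    """
    clusters = list(clusters)
    for _ in range(max_rounds):
        merged = False
        n = len(clusters)
        for i in range(n):
            if clusters[i].profile is None:
                continue
            for j in range(i + 1, n):
                if clusters[j].profile is None:
                    continue
                score, footprint = _profile_pair_stats(clusters[i].profile, clusters[j].profile)
                self_min = min(
                    _profile_self_score(clusters[i].profile),
                    _profile_self_score(clusters[j].profile),
                )
                if self_min <= 0:
                    continue
                if footprint >= coverage_threshold and score / self_min >= similarity_threshold:
                    a, b = clusters[i], clusters[j]
                    members = list(zip(a.member_ids + b.member_ids, a.member_seqs + b.member_seqs))
                    new = _make_cluster(a.id, members)
                    clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
                    clusters.append(new)
                    merged = True
                    break
            if merged:
                break
        if not merged:
            return clusters
    return clusters


# --------------------------------------------------------------------- serialization


def profile_to_json(profile: ProteinProfile) -> dict:
    return {
        "name": profile.name,
        "consensus": profile.consensus,
        "group": profile.group,
        "source_msa_id": profile.source_msa_id,
        "columns": profile.matrix.tolist(),
        "frequencies": None if profile.frequencies is None else profile.frequencies.tolist(),
        "calibration": list(profile.calibration) if profile.calibration else None,
    }


def profile_from_json(obj: dict) -> ProteinProfile:
    return ProteinProfile(
        obj["name"],
        np.asarray(obj["columns"], dtype=float),
        obj["consensus"],
        calibration=tuple(obj["calibration"]) if obj.get("calibration") else None,
        source_msa_id=obj.get("source_msa_id", ""),
        group=obj.get("group", ""),
        frequencies=None
        if obj.get("frequencies") is None
        else np.asarray(obj["frequencies"], dtype=float),
    )


def save_profiles(profiles: Sequence[ProteinProfile], path) -> None:
    with open(path, "w") as fh:
        json.dump([profile_to_json(p) for p in profiles], fh)


def load_profiles(path) -> list[ProteinProfile]:
    with open(path) as fh:
        return [profile_from_json(o) for o in json.load(fh)]
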