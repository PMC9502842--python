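"""Host inference: flank-vote majority rule, CRISPR arrays and spacer matching."""

import math

import numpy as np
import pytest

from vinascan.core_model import Contig, GeneCall
from vinascan.host_inference import (
    KA_K,
    KA_LAMBDA,
    detect_crispr,
    flank_best_hits,
    match_spacers,
    minimum_exact_match_length,
    spacer_evalue,
    vote_host,
)
from vinascan.synthetic_data import (
    default_reference_db,
    default_taxonomy,
    mutate_protein,
    plant_crispr_array,
    random_dna,
)


# -------------------------------------------------------------------- voting


def test_unanimous_vote(taxonomy):
    hits = [(f"p{i}", "s__Escherichia_coli") for i in range(6)]
    ha = vote_host(hits, taxonomy, "c1")
    assert ha.taxon_id == "s__Escherichia_coli" and ha.support == 1.0


def test_genus_tie_resolves_to_lca(taxonomy):
    hits = [(f"a{i}", "s__Escherichia_coli") for i in range(5)]
    hits += [(f"b{i}", "s__Klebsiella_pneumoniae") for i in range(5)]
    ha = vote_host(hits, taxonomy)
    assert ha.taxon_id == "f__Enterobacteriaceae"


def test_no_hits_returns_none(taxonomy):
    assert vote_host([("p1", None), ("p2", None)], taxonomy) is None
    with pytest.raises(ValueError, match="not in taxonomy"):
        vote_host([("p1", "s__Martian_microbe")], taxonomy)


def _oracle_vote(taxa, taxonomy):
    """Brute-force node enumeration: count each node's subtree hits, pick the
    deepest node with count >= ceil(n/2); ties at that depth -> their LCA."""
    n = len(taxa)
    need = math.ceil(n / 2)
    best = []
    best_depth = -1
    for node in taxonomy.nodes:
        sub = taxonomy.descendants(node)
        cnt = sum(1 for t in taxa if t in sub)
        if cnt >= need:
            d = taxonomy.depth(node)
            if d > best_depth:
                best, best_depth = [node], d
            elif d == best_depth:
                best.append(node)
    return best[0] if len(best) == 1 else taxonomy.lca(best)


def test_vote_matches_bruteforce_oracle(taxonomy):
    species = sorted(
        t for t in taxonomy.nodes if taxonomy.nodes[t].rank in ("species", "genus", "family")
    )
    rng = np.random.default_rng(99)
    for _ in range(300):
        k = int(rng.integers(1, 12))
        taxa = [species[rng.integers(len(species))] for _ in range(k)]
        ha = vote_host([(f"p{i}", t) for i, t in enumerate(taxa)], taxonomy)
        assert ha.taxon_id == _oracle_vote(taxa, taxonomy)
        assert ha.support >= 0.5


# -------------------------------------------------------------------- flank hits


def test_flank_best_hits_exact_and_floor(taxonomy):
    db = default_reference_db()
    g = GeneCall("c1", 0, 3 * (len(db[0].seq) + 1), "+", db[0].seq)
    [(pid, taxon)] = flank_best_hits([g], db)
    assert taxon == db[0].taxon_id
    junk = GeneCall("c1", 0, 90, "+", "M" + "W" * 29)
    [(_, none_taxon)] = flank_best_hits([junk], db)
    assert none_taxon is None
    with pytest.raises(ValueError):
        flank_best_hits([g], [])


def test_flank_vote_recovers_planted_host(full_run):
    report = full_run.truth_report
    assert report["host_genus_accuracy_flank"] is not None
    assert report["host_genus_accuracy_flank"] >= 0.90


# -------------------------------------------------------------------- CRISPR


def test_detect_planted_array_exact():
    rng = np.random.default_rng(0)
    host = Contig("h1", random_dna(11_000, rng))
    protos = [random_dna(32, rng) for _ in range(3)]
    repeat = random_dna(30, rng)
    c2, info = plant_crispr_array(host, protos, repeat, seed=5, position=4000)
    [arr] = detect_crispr(c2)
    assert arr.repeat == repeat
    assert list(arr.array_interval) == info["array_interval"]
    assert [s for s, _ in arr.spacers] == info["spacers"]


def test_short_contig_skipped():
    rng = np.random.default_rng(1)
    host = Contig("h2", random_dna(8_800, rng))
    protos = [random_dna(30, rng) for _ in range(3)]
    c2, _ = plant_crispr_array(host, protos, random_dna(28, rng), seed=2, position=4000)
    assert len(c2) < 10_000
    assert detect_crispr(c2) == []


def test_repeat_free_contig_negative():
    for seed in (3, 4, 5):
        c = Contig("r", random_dna(12_000, np.random.default_rng(seed)))
        assert detect_crispr(c) == []


# -------------------------------------------------------------------- spacers


def test_exact_match_accepted_two_mismatches_rejected():
    rng = np.random.default_rng(6)
    region = random_dna(16_000, rng)
    sp = region[7000:7032]
    [m] = match_spacers([("s1", sp)], [("ph1", region)])
    assert m.identity == 100.0 and m.aligned_length == 32
    mutated = list(sp)
    for i in (5, 20):
        mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
    assert match_spacers([("s2", "".join(mutated))], [("ph1", region)]) == []


def test_reverse_strand_match():
    from vinascan.core_model import revcomp

    rng = np.random.default_rng(7)
    region = random_dna(16_000, rng)
    sp = revcomp(region[5000:5040])
    [m] = match_spacers([("s1", sp)], [("ph1", region)])
    assert m.identity == 100.0


def test_minimum_exact_length_against_formula():
    """Direct Karlin-Altschul evaluation is the oracle for the E-value model."""
    region_len = 16_000
    L = minimum_exact_match_length(region_len)
    space = 2 * region_len
    assert KA_K * space * math.exp(-KA_LAMBDA * L) <= 1e-15
    assert KA_K * space * math.exp(-KA_LAMBDA * (L - 1)) > 1e-15
    assert spacer_evalue(L, space) == pytest.approx(
        KA_K * space * math.exp(-KA_LAMBDA * L)
    )
    assert L <= 32  # a full-length exact 32-nt spacer match always qualifies


def test_lambda_satisfies_karlin_altschul_identity():
    total = 0.25 * math.exp(KA_LAMBDA * 1.0) + 0.75 * math.exp(KA_LAMBDA * -3.0)
    assert total == pytest.approx(1.0, abs=1e-9)
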