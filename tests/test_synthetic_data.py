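"""Generator invariants: determinism, exact planting, CRISPR and read models."""

import numpy as np
import pytest

from vinascan.core_model import Contig
from vinascan.gene_calling import find_orfs
from vinascan.synthetic_data import (
    SimulationConfig,
    clade_consensus,
    generate_metagenome,
    mutate_protein,
    plant_crispr_array,
    random_dna,
    simulate_reads,
)


def test_zero_divergence_mcp_is_clade_consensus(small_sim):
    contigs, _, manifest = small_sim
    for c in contigs:
        info = manifest["contigs"][c.id]
        mcp = next(g for g in find_orfs(c, 30) if (g.start, g.end) == tuple(info["mcp_interval"][:2]))
        assert mcp.aa_seq == clade_consensus(info["clade"])


def test_seeded_determinism(small_sim):
    cfg = SimulationConfig(
        seed=7, n_host_contigs=3, prophage_probability=1.0, divergence=0.0,
        free_phage_fraction=0.0, group_weights={"Vinavirales": 1.0},
    )
    contigs1, _, m1 = small_sim
    contigs2, _, m2 = generate_metagenome(cfg)
    assert [c.seq for c in contigs1] == [c.seq for c in contigs2]
    assert m1["contigs"] == m2["contigs"]


def test_no_prophages_when_probability_zero():
    cfg = SimulationConfig(seed=2, n_host_contigs=4, prophage_probability=0.0)
    contigs, _, manifest = generate_metagenome(cfg)
    assert all(info["kind"] == "host_only" for info in manifest["contigs"].values())
    assert all(c.truth.prophage_interval is None for c in contigs)


def test_prophages_have_flank_genes_on_both_sides():
    cfg = SimulationConfig(
        seed=9, n_host_contigs=6, prophage_probability=1.0, divergence=0.1,
        free_phage_fraction=0.0, group_weights={"Vinavirales": 1.0},
    )
    _, _, manifest = generate_metagenome(cfg)
    for info in manifest["contigs"].values():
        assert info["kind"] == "prophage"
        c0, c1 = info["cassette_interval"]
        hosts = [g for g in info["planted_genes"] if g[0].startswith("host:")]
        assert any(g[2] <= c0 for g in hosts) and any(g[1] >= c1 for g in hosts)


def test_mutate_protein_rate():
    rng = np.random.default_rng(0)
    seq = "M" + "A" * 999
    mut = mutate_protein(seq, 0.3, rng)
    frac = sum(a != b for a, b in zip(seq, mut)) / len(seq)
    assert 0.25 < frac < 0.35
    assert mutate_protein(seq, 0.0, rng) == seq


# ------------------------------------------------------------------ CRISPR planting


def test_plant_crispr_structure():
    rng = np.random.default_rng(1)
    host = Contig("h", random_dna(2000, rng))
    protos = [random_dna(32, rng) for _ in range(3)]
    repeat = random_dna(30, rng)
    c2, info = plant_crispr_array(host, protos, repeat, seed=4)
    a0, a1 = info["array_interval"]
    array = c2.seq[a0:a1]
    assert array.count(repeat) == 4  # N spacers -> N+1 repeats
    assert info["spacers"] == protos  # zero mismatches


def test_plant_crispr_mismatch_identity():
    rng = np.random.default_rng(2)
    host = Contig("h", random_dna(2000, rng))
    proto = random_dna(32, rng)
    _, info = plant_crispr_array(host, [proto, proto], random_dna(28, rng), seed=1, mismatches=2)
    for sp in info["spacers"]:
        ident = sum(a == b for a, b in zip(sp, proto)) / 32
        assert ident == 30 / 32  # 93.75%


def test_plant_crispr_min_repeats_and_bounds():
    rng = np.random.default_rng(3)
    host = Contig("h", random_dna(2000, rng))
    protos = [random_dna(30, rng) for _ in range(2)]
    repeat = random_dna(25, rng)
    c2, info = plant_crispr_array(host, protos, repeat, seed=0)
    a0, a1 = info["array_interval"]
    assert c2.seq[a0:a1].count(repeat) == 3  # still >= 3 repeat copies
    with pytest.raises(ValueError, match="repeat length"):
        plant_crispr_array(host, protos, random_dna(10, rng), seed=0)
    with pytest.raises(ValueError, match="spacer length"):
        plant_crispr_array(host, [random_dna(10, rng)], repeat, seed=0)


# ------------------------------------------------------------------ reads


def test_reads_exact_substrings_without_errors():
    rng = np.random.default_rng(5)
    contigs = [Contig("a", random_dna(5000, rng)), Contig("b", random_dna(3000, rng))]
    from vinascan.core_model import revcomp

    reads = simulate_reads(contigs, 100, 80, 0.0, seed=11)
    by_id = {c.id: c.seq for c in contigs}
    joined = {cid: s + "|" + revcomp(s) for cid, s in by_id.items()}
    assert all(any(r.seq in j for j in joined.values()) for r in reads)
    reads2 = simulate_reads(contigs, 100, 80, 0.0, seed=11)
    assert [(r.id, r.seq) for r in reads] == [(r.id, r.seq) for r in reads2]
    assert simulate_reads(contigs, 0, 80, 0.0, seed=1) == []


def test_read_share_follows_length_share():
    rng = np.random.default_rng(6)
    contigs = [Contig("small", random_dna(10_000, rng)), Contig("big", random_dna(30_000, rng))]
    n = 4000
    manifest = {"reads": {}}
    reads = simulate_reads(contigs, n, 100, 0.0, seed=3, manifest=manifest)
    frac = sum(1 for v in manifest["reads"].values() if v["contig"] == "small") / n
    p = 0.25
    bound = 3 * (p * (1 - p) / n) ** 0.5
    assert abs(frac - p) < bound + 0.01


def test_manifest_gene_conservation(small_sim):
    contigs, _, manifest = small_sim
    for c in contigs:
        planted = manifest["contigs"][c.id]["planted_genes"]
        assert planted == [list(g) for g in c.truth.planted_genes] or [
            tuple(g) for g in planted
        ] == list(c.truth.planted_genes)
        for fam, s, e, st in planted:
            assert 0 <= s < e <= len(c)
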