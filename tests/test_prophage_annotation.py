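"""Window annotation, boundary rules, classification and genome comparison."""

import numpy as np
import pytest

from vinascan.core_model import Contig, GeneCall
from vinascan.gene_calling import find_orfs
from vinascan.prophage_annotation import (
    CASSETTE_ORDER,
    GENE_FAMILIES,
    ProphageAnnotation,
    annotate_and_classify,
    annotate_window,
    classify,
    detect_module_replacement,
    find_boundaries,
)
from vinascan.synthetic_data import (
    INSULATOR,
    SimulationConfig,
    back_translate,
    family_consensus,
    generate_metagenome,
    random_dna,
)


def test_zero_divergence_cassette_fully_labeled(small_sim, fam_profiles):
    contigs, _, manifest = small_sim
    c = contigs[0]
    info = manifest["contigs"][c.id]
    ann = annotate_and_classify(
        c, tuple(info["mcp_interval"][:2]), list(fam_profiles.values())
    )
    labels = {(g.start, g.end): lab for g, lab in ann.gene_map}
    for fam, s, e, st in info["planted_genes"]:
        if fam.startswith(("host:", "filler:")) or (s, e) not in labels:
            continue
        assert labels[(s, e)] == fam
    assert ann.classification == "prophage"
    assert ann.completeness == "complete"


def test_gene_map_is_ordered_partition(small_sim, fam_profiles):
    contigs, _, manifest = small_sim
    c = contigs[0]
    ann = annotate_window(
        c, tuple(manifest["contigs"][c.id]["mcp_interval"][:2]), list(fam_profiles.values())
    )
    starts = [g.start for g, _ in ann.gene_map]
    assert starts == sorted(starts)
    assert len({g.id for g, _ in ann.gene_map}) == len(ann.gene_map)


def test_window_clipping_flagged(small_sim, fam_profiles):
    contigs, _, manifest = small_sim
    c = contigs[0]
    ann = annotate_window(
        c, tuple(manifest["contigs"][c.id]["mcp_interval"][:2]), list(fam_profiles.values())
    )
    w0, w1 = ann.window
    assert 0 <= w0 < w1 <= len(c)
    if w0 == 0 or w1 == len(c):
        assert "edge-truncated" in ann.flags
    with pytest.raises(ValueError, match="outside contig"):
        annotate_window(c, (len(c), len(c) + 300), list(fam_profiles.values()))


# --------------------------------------------------------- boundary rules (constructed)


def _fake_ann(labels_at):
    """Build an annotation from (family, start) tuples; each gene 300 nt."""
    gene_map = []
    for i, (fam, start) in enumerate(labels_at):
        g = GeneCall("x", start, start + 300, "+", "M" + "A" * 99, gene_index=i)
        gene_map.append((g, fam))
    mcp = next(g for g, lab in gene_map if lab == "MCP")
    ann = ProphageAnnotation("x", (0, 100_000), (mcp.start, mcp.end))
    ann.gene_map = gene_map
    return ann


def test_boundaries_at_planted_coordinates():
    ann = _fake_ann([("host", 0), ("P16", 1000), ("MCP", 2000), ("P15", 3000), ("host", 4000)])
    find_boundaries(ann)
    assert ann.boundaries["p16"][:2] == (1000, 1300)
    assert ann.boundaries["p15"][:2] == (3000, 3300)
    assert classify(ann) == ("prophage", "complete")


def test_missing_right_boundary_partial():
    ann = _fake_ann([("host", 0), ("P16", 1000), ("MCP", 2000), ("unknown", 3000)])
    find_boundaries(ann)
    assert "p15" not in ann.boundaries
    assert classify(ann) == ("prophage", "partial")


def test_two_p16_copies_nearest_to_mcp_wins():
    ann = _fake_ann([("P16", 0), ("P16", 1500), ("MCP", 2000), ("P15", 3000)])
    find_boundaries(ann)
    assert ann.boundaries["p16"][0] == 1500


def test_tr_z1_accepted_as_right_boundary():
    ann = _fake_ann([("P16", 1000), ("MCP", 2000), ("TR_Z1", 3000)])
    find_boundaries(ann)
    assert ann.boundaries["p15"][2] == "TR_Z1"
    assert "TR_Z1-boundary" in ann.flags
    assert classify(ann) == ("phage", "complete")


def test_phage_when_nothing_outside():
    ann = _fake_ann([("P16", 0), ("MCP", 1000), ("P15", 2000)])
    find_boundaries(ann)
    assert classify(ann) == ("phage", "complete")


def test_unclassified_without_boundary_genes():
    ann = _fake_ann([("unknown", 0), ("MCP", 1000), ("unknown", 2000)])
    find_boundaries(ann)
    assert classify(ann) == ("unclassified", "partial")


def test_classify_idempotent():
    ann = _fake_ann([("host", 0), ("P16", 1000), ("MCP", 2000), ("P15", 3000), ("host", 4000)])
    find_boundaries(ann)
    first = classify(ann)
    assert classify(ann) == first


# --------------------------------------------------------- genome comparison


def test_identical_genomes_single_block():
    rng = np.random.default_rng(0)
    g = random_dna(5000, rng)
    shared, divergent = detect_module_replacement(g, g)
    assert len(shared) == 1
    a0, a1, b0, b1, ident = shared[0]
    assert (a0, b0) == (0, 0) and a1 == b1 == 5000 and ident == 1.0
    assert divergent == []


def test_swapped_replication_gene_detected():
    rng = np.random.default_rng(1)
    rep_nt = back_translate(family_consensus("rep"), rng)
    left, right = random_dna(2000, rng), random_dna(2000, rng)
    genome_a = left + rep_nt + right
    genome_b = left + random_dna(len(rep_nt), rng) + right
    genes_a = [("rep", len(left), len(left) + len(rep_nt))]
    shared, divergent = detect_module_replacement(genome_a, genome_b, genes_a=genes_a)
    assert len(shared) == 2
    assert len(divergent) == 1
    g0, g1, labels = divergent[0]
    assert "rep" in labels
    assert g0 >= len(left) - 50 and g1 <= len(left) + len(rep_nt) + 50


def test_unrelated_genomes_no_blocks():
    for seed in (2, 3):
        rng = np.random.default_rng(seed)
        a, b = random_dna(4000, rng), random_dna(4000, rng)
        shared, _ = detect_module_replacement(a, b)
        assert shared == []


def test_short_input_rejected():
    with pytest.raises(ValueError):
        detect_module_replacement("ACGT" * 100, "ACGT" * 100)
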