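"""K-mer read classification and abundance arithmetic."""

from fractions import Fraction

import numpy as np
import pytest

from vinascan.abundance import (
    build_index,
    classify_reads,
    round_fold,
    summarize,
    summarize_counts,
)
from vinascan.core_model import Read, revcomp
from vinascan.synthetic_data import marker_gene_sets, random_dna


def test_index_kmer_count():
    rng = np.random.default_rng(0)
    gene = random_dna(40, rng)
    idx = build_index({"X": [gene]}, k=31)
    assert len(idx.kmers) == 10  # 40 - 31 + 1


def test_conflicting_kmers_dropped():
    rng = np.random.default_rng(1)
    gene = random_dna(60, rng)
    idx = build_index({"X": [gene], "Y": [gene]}, k=31)
    assert len(idx.kmers) == 0
    assert idx.n_conflicts == 30


def test_canonicalization_revcomp_invariant():
    rng = np.random.default_rng(2)
    gene = random_dna(100, rng)
    a = build_index({"X": [gene]}, k=31)
    b = build_index({"X": [revcomp(gene)]}, k=31)
    assert a.kmers == b.kmers


def test_classification_rules():
    rng = np.random.default_rng(3)
    gx, gy = random_dna(300, rng), random_dna(300, rng)
    idx = build_index({"X": [gx], "Y": [gy]}, k=31)
    reads = [
        Read("exact", gx[50:150], "d1"),
        Read("random", random_dna(100, rng), "d1"),
        Read("tie", gx[0:62] + gy[0:62], "d1"),  # 32 k-mers each side
    ]
    rep = classify_reads(reads, idx)
    counts = rep.counts.loc["d1"]
    assert counts["X"] == 1
    assert counts["unclassified"] == 2  # the random and the tied read
    assert counts.sum() == 3  # conservation


def test_recovery_of_planted_proportions():
    sets = marker_gene_sets()
    idx = build_index(sets, k=31)
    rng = np.random.default_rng(4)
    labels = sorted(sets)
    reads = []
    truth = []
    for i in range(2000):
        lab = labels[rng.integers(len(labels))]
        gene = sets[lab][rng.integers(len(sets[lab]))]
        start = rng.integers(0, len(gene) - 100)
        reads.append(Read(f"r{i}", gene[start : start + 100], "d1"))
        truth.append(lab)
    rep = classify_reads(reads, idx)
    correct = sum(
        int(rep.counts.loc["d1", lab] > 0) for lab in set(truth)
    )
    acc = sum(rep.counts.loc["d1", lab] for lab in labels) / len(reads)
    assert acc >= 0.99
    # per-label counts match planted counts closely
    import collections

    planted = collections.Counter(truth)
    for lab in labels:
        assert abs(rep.counts.loc["d1", lab] - planted[lab]) <= 0.02 * len(reads)


def test_recovery_with_sequencing_errors():
    sets = marker_gene_sets()
    idx = build_index(sets, k=31)
    rng = np.random.default_rng(5)
    gene = sets["HK97"][0]
    reads = []
    for i in range(500):
        start = rng.integers(0, len(gene) - 100)
        s = list(gene[start : start + 100])
        for j in np.nonzero(rng.random(100) < 0.01)[0]:
            s[j] = "ACGT"[("ACGT".index(s[j]) + 1) % 4]
        reads.append(Read(f"r{i}", "".join(s), "d1"))
    rep = classify_reads(reads, idx)
    assert rep.counts.loc["d1", "HK97"] / 500 >= 0.90


# ---------------------------------------------------------------- summaries


def test_summary_fold_ratio_printed_style():
    """Arithmetic on the census's printed read counts."""
    s = summarize_counts(
        {"HK97": 22_722_487, "DJR:Vinavirales": 13_832, "DJR:rest": 15_101 - 13_832}
    )
    assert s["fold_ratio"] == Fraction(22_722_487, 15_101)
    assert float(s["fold_ratio"]) == pytest.approx(1504.7, abs=0.05)
    assert s["fold_ratio_display"] == 1500
    vina = s["within_percent"]["DJR:Vinavirales"]
    assert vina["percent"] == pytest.approx(91.6, abs=0.05)
    assert vina["display"] == 92


def test_summary_reports_both_hgv_ratios():
    """The two denominators are reported explicitly, never chosen between."""
    of_vina = Fraction(13_147, 13_832)
    of_djr = Fraction(13_147, 15_101)
    assert float(of_vina) * 100 == pytest.approx(95.0, abs=0.05)
    assert float(of_djr) * 100 == pytest.approx(87.1, abs=0.05)
    s = summarize_counts(
        {"DJR:HGV-1": 13_147, "DJR:otherVina": 13_832 - 13_147,
         "DJR:nonVina": 15_101 - 13_832}
    )
    assert s["within_percent"]["DJR:HGV-1"]["fraction"] == of_djr


def test_zero_denominator_undefined():
    s = summarize_counts({"HK97": 10})
    assert s["fold_ratio"] is None and s["fold_ratio_display"] is None


def test_dataset_prevalence():
    s = summarize_counts(
        {"HK97": 100, "DJR": 1},
        datasets_with_label={"DJR": 294, "HK97": 3851},
        n_datasets=3995,
    )
    assert s["dataset_prevalence"]["DJR"]["display"] == 7
    assert s["dataset_prevalence"]["HK97"]["display"] == 96


def test_summarize_pure_function_of_counts():
    rng = np.random.default_rng(6)
    gx = random_dna(300, rng)
    idx = build_index({"HK97": [gx]}, k=31)
    reads = [Read(f"r{i}", gx[i : i + 100], "d1") for i in range(20)]
    rep = classify_reads(reads, idx)
    assert summarize(rep) == summarize(rep)


def test_round_fold():
    assert round_fold(1504.7) == 1500
    assert round_fold(432.18) == 432.2
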