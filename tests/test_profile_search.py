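"""PSSM construction, E-value calibration, search and clustering."""

import math

import numpy as np
import pytest
from scipy.stats import gumbel_r

from vinascan._align import AA_ALPHABET, global_identity
from vinascan.profile_search import (
    EULER_GAMMA,
    LOG_ODDS_FLOOR,
    build_profile,
    calibrate_evalue,
    cluster_proteins,
    merge_clusters,
    search_profile,
)
from vinascan.synthetic_data import mutate_protein, random_protein

AI = AA_ALPHABET.index


def _msa(rows):
    return [(f"s{i}", r) for i, r in enumerate(rows)]


def test_pure_column_closed_form():
    rows = ["A" * 12, "A" * 12]
    p = build_profile(_msa(rows), pseudocount_weight=0.0)
    assert p.matrix[0, AI("A")] == pytest.approx(math.log2(20))
    assert p.matrix[0, AI("C")] == LOG_ODDS_FLOOR
    assert p.consensus == "A" * 12


def test_large_pseudocount_limit():
    rows = ["ACDEFGHIKLMN", "ACDEFGHIKLMN"]
    p = build_profile(_msa(rows), pseudocount_weight=1e9)
    assert np.abs(p.matrix[:, :20]).max() < 1e-6


def test_four_sequence_hand_computed():
    # column 0 across 4 sequences: A,A,A,C -> f_A=0.75, f_C=0.25
    rows = ["AGGGGGGGGGGG", "AGGGGGGGGGGG", "AGGGGGGGGGGG", "CGGGGGGGGGGG"]
    p = build_profile(_msa(rows), pseudocount_weight=1.0)
    bg = 1 / 20
    expect_a = math.log2((0.75 + bg) / (2 * bg))
    expect_c = math.log2((0.25 + bg) / (2 * bg))
    expect_absent = math.log2((0.0 + bg) / (2 * bg))
    assert p.matrix[0, AI("A")] == pytest.approx(expect_a)
    assert p.matrix[0, AI("C")] == pytest.approx(expect_c)
    assert p.matrix[0, AI("W")] == pytest.approx(expect_absent)


def test_gap_columns_dropped_and_errors():
    rows = ["AC-DEFGHIKLMN", "AC-DEFGHIKLMN", "ACWDEFGHIKLMN"]
    p = build_profile(_msa(rows))
    assert len(p) == 12  # the 2/3-gap column is dropped
    with pytest.raises(ValueError, match=">=2"):
        build_profile(_msa(["ACDEFGHIKLMN"]))
    with pytest.raises(ValueError, match="columns"):
        build_profile(_msa(["ACD", "ACD"]))


def test_consensus_scores_sum_of_column_maxima():
    seq = random_protein("t1", 60)
    p = build_profile(_msa([seq, seq, mutate_protein(seq, 0.1, np.random.default_rng(2))]))
    calibrate_evalue(p, seed=0)
    h = search_profile(p, p.consensus, evalue_cutoff=1e9, curation=False)
    assert h.coverage == 1.0
    assert h.raw_score == pytest.approx(p.matrix[:, :20].max(axis=1).sum())


def test_calibration_determinism_and_error():
    seq = random_protein("t2", 80)
    p = build_profile(_msa([seq, seq]))
    c1 = calibrate_evalue(p, seed=5)
    c2 = calibrate_evalue(p, seed=5)
    assert c1 == c2
    with pytest.raises(ValueError, match="uncalibrated|not calibrated"):
        p2 = build_profile(_msa([seq, seq]))
        search_profile(p2, seq)
    with pytest.raises(ValueError, match="n_decoys"):
        calibrate_evalue(p, n_decoys=10)


def test_method_of_moments_recovers_gumbel():
    """The calibration estimator, applied to known-Gumbel samples."""
    mu_true, lam_true = 10.0, 0.3
    x = gumbel_r.rvs(loc=mu_true, scale=1 / lam_true, size=500,
                     random_state=np.random.default_rng(42))
    lam = math.pi / (x.std() * math.sqrt(6))
    mu = x.mean() - EULER_GAMMA / lam
    assert abs(lam - lam_true) / lam_true < 0.15
    assert abs(mu - mu_true) / mu_true < 0.15


def test_diverged_consensus_still_detected(group_profiles):
    """10% substitutions from the seed consensus stay under the E cutoff."""
    vin = group_profiles["Vinavirales"]
    rng = np.random.default_rng(3)
    for i in range(10):
        q = mutate_protein(vin.consensus, 0.1, rng)
        h = search_profile(vin, q, curation=False)
        assert h is not None and h.evalue <= 0.05


def test_decoy_false_positive_control(group_profiles):
    vin = group_profiles["Vinavirales"]
    rng = np.random.default_rng(7)
    n_pass = 0
    for _ in range(200):
        d = "".join(rng.choice(list(AA_ALPHABET), size=200))
        h = search_profile(vin, d, curation=False)
        n_pass += h is not None and h.evalue <= 0.05
    assert n_pass / 200 <= 0.10


# --------------------------------------------------------------------- clustering


def test_cluster_identical_and_distinct():
    a = random_protein("ca", 100)
    b = random_protein("cb", 100)
    clusters = cluster_proteins([("x", a), ("y", a), ("z", b)], build_profiles=False)
    members = sorted(tuple(sorted(c.member_ids)) for c in clusters)
    assert members == [("x", "y"), ("z",)]


def test_cluster_greedy_chain():
    rng = np.random.default_rng(0)
    b = random_protein("chain", 102)[:100]
    a = mutate_protein(b, 0.38, rng) + "AC"  # ~60% id to b, longest
    c = mutate_protein(b, 0.38, np.random.default_rng(99))[:98]
    # a-b and b-c similar, a-c (independent mutations) much less
    assert global_identity(a, b) >= 0.5
    assert global_identity(b, c) >= 0.5
    assert global_identity(a, c) < 0.5
    clusters = cluster_proteins([("A", a), ("B", b), ("C", c)], build_profiles=False)
    members = sorted(tuple(sorted(cl.member_ids)) for cl in clusters)
    assert members == [("A", "B"), ("C",)]


def test_cluster_partition_property():
    rng = np.random.default_rng(1)
    prots = [(f"p{i}", random_protein(f"pp{i}", int(rng.integers(50, 120)))) for i in range(12)]
    clusters = cluster_proteins(prots, build_profiles=False)
    seen = [m for c in clusters for m in c.member_ids]
    assert sorted(seen) == sorted(p[0] for p in prots)


def test_merge_identical_and_disjoint_and_fixpoint():
    base = random_protein("m1", 80)
    other = random_protein("m2", 80)
    rng = np.random.default_rng(5)
    c1 = cluster_proteins(
        [("a", base), ("b", mutate_protein(base, 0.05, rng))]
    )
    c2 = cluster_proteins(
        [("c", base), ("d", mutate_protein(base, 0.05, rng))]
    )
    c3 = cluster_proteins(
        [("e", other), ("f", mutate_protein(other, 0.05, rng))]
    )
    merged = merge_clusters(c1 + c2 + c3)
    families = sorted(tuple(sorted(c.member_ids)) for c in merged)
    assert families == [("a", "b", "c", "d"), ("e", "f")]
    again = merge_clusters(merged)
    assert sorted(tuple(sorted(c.member_ids)) for c in again) == families
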