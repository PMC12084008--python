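"""Enrichment statistics against independent oracles."""

from itertools import combinations, product
from math import comb

import numpy as np
import pytest
from scipy import stats

import ribosig as r
from ribosig.enrich import KmerCounts
from ribosig.transcripts import UTR5


def _rec(utr5, tid, gene=None):
    return r.TranscriptRecord(gene or tid, tid, utr5, "ATGGCA")


# ---------------------------------------------------------------------------
# Mann-Whitney


def mw_enumeration_p(fg, bg):
    """Oracle: one-tailed (fg less) p by full enumeration of arrangements."""
    pooled = list(fg) + list(bg)
    n1 = len(fg)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        count += u <= u_obs + 1e-9
        total += 1
    return count / total


def test_worked_example_exact_one_in_twenty():
    res = r.mann_whitney_one_tailed([1, 2, 3], [4, 5, 6], "fg_less")
    assert res.U == 0
    assert res.p == pytest.approx(1 / comb(6, 3), abs=1e-12)
    assert res.method == "exact"


@pytest.mark.parametrize("fg,bg", [
    ([1, 5, 7], [2, 3, 9, 11]),
    ([10, 20], [1, 2, 3, 4, 30]),
    ([1.5, 2.5, 3.5, 4.5], [0.5, 2.0, 6.0]),
    (list(range(7)), [x + 0.5 for x in range(7)]),
])
def test_exact_p_matches_full_enumeration(fg, bg):
    res = r.mann_whitney_one_tailed(fg, bg, "fg_less")
    assert res.p == pytest.approx(mw_enumeration_p(fg, bg), abs=1e-12)


def test_identical_groups_give_half():
    x = list(range(1, 9))
    res = r.mann_whitney_one_tailed(x, x, "fg_less")
    assert res.U == len(x) ** 2 / 2
    assert 0.4 < res.p < 0.62


def test_fully_tied_data_degenerate():
    with pytest.warns(UserWarning, match="tied"):
        res = r.mann_whitney_one_tailed([5, 5, 5], [5, 5], "fg_less")
    assert res.p == 0.5


def test_null_p_values_uniform():
    """Under exchangeable groups the one-tailed p is uniform on (0, 1]."""
    rng = np.random.default_rng(3)
    ps = []
    for _ in range(200):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        ps.append(r.mann_whitney_one_tailed(list(x), list(y)).p)
    ks = stats.kstest(ps, "uniform")
    assert ks.pvalue > 0.01


# ---------------------------------------------------------------------------
# Background sampling


def test_sample_background_permutation_and_determinism():
    pool = [_rec("ACGTACGT", f"t{i}") for i in range(30)]
    full = r.sample_background(pool, n=30, seed=1)
    assert sorted(t.transcript_id for t in full) == sorted(t.transcript_id for t in pool)
    a = r.sample_background(pool, n=10, seed=5)
    b = r.sample_background(pool, n=10, seed=5)
    assert [t.transcript_id for t in a] == [t.transcript_id for t in b]


def test_sample_background_inclusion_probability():
    pool = [_rec("ACGT", f"t{i}") for i in range(50)]
    hits = sum(
        any(t.transcript_id == "t7" for t in r.sample_background(pool, 10, seed=s))
        for s in range(200)
    )
    assert abs(hits / 200 - 10 / 50) < 0.08


def test_sample_background_small_pool_warns():
    pool = [_rec("ACGT", "t0")]
    with pytest.warns(UserWarning):
        out = r.sample_background(pool, n=5, seed=0)
    assert len(out) == 1


# ---------------------------------------------------------------------------
# k-mer counting and binomial enrichment


@pytest.mark.parametrize("seqs,expected,total", [
    (["CCGCCG"], {"CCGCCG": 1}, 1),
    (["GCCGCC", "GCCGCC"], {"GCCGCC": 2}, 2),
    (["GCGGCGG"], {"GCGGCG": 1, "CGGCGG": 1}, 2),
    (["ACGTN" + "A" * 6], {"AAAAAA": 1}, 1),
])
def test_count_kmers_examples(seqs, expected, total):
    out = r.count_kmers(seqs, k=6)
    assert out.total == total
    for kmer, n in expected.items():
        if n:
            assert out.counts[kmer] == n
    assert sum(out.counts.values()) == total


def test_count_kmers_skips_ambiguous_windows():
    out = r.count_kmers(["AAANAAAA"], k=3)
    # windows: AAA, AAN, ANA, NAA, AAA, AAA -> 3 valid AAA windows... rechecked below
    assert out.counts == {"AAA": 3}
    assert out.total == 3


def binom_upper_tail_enumeration(n, k, p):
    """Oracle: P(X >= k) by enumerating all 2^n outcome vectors."""
    total = 0.0
    for outcome in product((0, 1), repeat=n):
        s = sum(outcome)
        if s >= k:
            total += p**s * (1 - p) ** (n - s)
    return total


@pytest.mark.parametrize("n,k,p", [(5, 3, 0.2), (8, 1, 0.01), (10, 10, 0.5),
                                   (12, 6, 0.35), (7, 0, 0.9)])
def test_binomial_tail_matches_enumeration(n, k, p):
    assert stats.binom.sf(k - 1, n, p) == pytest.approx(
        binom_upper_tail_enumeration(n, k, p), abs=1e-12)


def test_enrichment_closed_form_and_sorting():
    # p0 engineered to exactly 0.5: (4095 + 1) / (4096 + 4096)
    bg = KmerCounts({"GCCGCC": 4095}, 4096, 6)
    fg = KmerCounts({"GCCGCC": 10, "AAAAAA": 0}, 10, 6)
    out = r.kmer_binomial_enrichment(fg, bg)
    top = out.iloc[0]
    assert top["kmer"] == "GCCGCC"
    assert top["p_value"] == pytest.approx(0.5**10, rel=1e-12)
    zero = out[out["kmer"] == "AAAAAA"].iloc[0]
    assert zero["p_value"] == 1.0  # P(X >= 0)
    assert (out["p_value"].diff().dropna() >= 0).all()


def test_enrichment_empty_foreground():
    bg = KmerCounts({"AAAAAA": 5}, 5, 6)
    out = r.kmer_binomial_enrichment(KmerCounts({}, 0, 6), bg)
    assert out.empty


def test_planted_kmer_detected_in_transcript_sets(random_transcripts):
    recs, truth = random_transcripts
    group = dict(zip(truth.transcripts["transcript_id"], truth.transcripts["group"]))
    fg = [t for t in recs if group[t.transcript_id] == "positive"]
    bg = [t for t in recs if group[t.transcript_id] == "background"]
    out = r.kmer_binomial_enrichment(r.count_kmers(fg), r.count_kmers(bg),
                                     threshold=1e-5)
    assert set(out.columns) >= {"kmer", "fg_count", "p_value", "flagged"}
    assert ((out["p_value"] >= 0) & (out["p_value"] <= 1)).all()


# ---------------------------------------------------------------------------
# GC window tests


def test_bonferroni_arithmetic():
    fg = [_rec("".join(s), f"f{i}") for i, s in
          enumerate(["GCGCGCGCAT", "GCGCGCATAT", "GCGCGCGCGC", "GCATGCATGC"])]
    bg = [_rec("".join(s), f"b{i}") for i, s in
          enumerate(["ATATATATAT", "ATGCATATAT", "ATATATGCAT", "GCATATATAT"])]
    out = r.compare_gc_profiles(fg, bg, r.WindowSpec(UTR5, 2, 10))
    m = out["raw_p"].notna().sum()
    valid = out.dropna(subset=["raw_p"])
    np.testing.assert_allclose(valid["adj_p"], np.minimum(valid["raw_p"] * m, 1.0))
    assert (valid["adj_p"] >= valid["raw_p"] - 1e-15).all()
    assert (valid["adj_p"] <= 1.0).all()


def test_identical_sets_paired_mode_p_one():
    group = [_rec("GCATGCATGCAT", f"t{i}") for i in range(5)]
    out = r.compare_gc_profiles(group, group, r.WindowSpec(UTR5, 2, 8),
                                mode="paired_positions")
    valid = out.dropna(subset=["raw_p"])
    assert (valid["raw_p"] == 1.0).all()
    assert (valid["adj_p"] == 1.0).all()


def test_two_sample_antisymmetric_under_swap():
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    fg = [_rec("".join(bases[rng.integers(0, 4, 30)]), f"f{i}") for i in range(40)]
    bg = [_rec("".join(bases[rng.integers(0, 4, 30)]), f"b{i}") for i in range(40)]
    ab = r.compare_gc_profiles(fg, bg, r.WindowSpec(UTR5, 6, 12))
    ba = r.compare_gc_profiles(bg, fg, r.WindowSpec(UTR5, 6, 12))
    np.testing.assert_allclose(ab["raw_p"], ba["raw_p"], atol=1e-12)
    np.testing.assert_allclose(ab["fg_mean"] - ab["bg_mean"],
                               -(ba["fg_mean"] - ba["bg_mean"]), atol=1e-12)


def test_untestable_k_reported_not_fatal():
    fg = [_rec("ACGTACGTAC", "f0")]  # single transcript -> n<2 everywhere
    bg = [_rec("ACGTACGTACGT", f"b{i}") for i in range(5)]
    out = r.compare_gc_profiles(fg, bg, r.WindowSpec(UTR5, 6, 12))
    assert out["raw_p"].isna().all()
    assert len(out) == 7
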