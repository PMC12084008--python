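"""Transcript features: GC windows, lengths, logos, group construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ribosig as r
from ribosig.transcripts import CDS, UTR5

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


def _rec(utr5: str, cds: str = "ATGGCA", gene="g1", tid="t1") -> r.TranscriptRecord:
    return r.TranscriptRecord(gene, tid, utr5, cds)


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [
        ("GCGC", 1.0),
        ("ATAT", 0.0),
        ("CGTCACCGCCCG", 10 / 12),  # 12-mer with exactly two A/T bases
        ("acgu", 0.5),
    ])
    def test_known_values(self, seq, expected):
        assert r.gc_content(seq) == pytest.approx(expected)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            r.gc_content("")


class TestWindowGc:
    def test_utr5_window_anchors_at_start_codon(self):
        assert r.window_gc(_rec("AATTGC"), UTR5, 2) == 1.0
        assert r.window_gc(_rec("AATTGC"), UTR5, 6) == pytest.approx(2 / 6)

    def test_cds_window_includes_start_codon(self):
        assert r.window_gc(_rec("AAAA", cds="ATGGGC"), CDS, 3) == pytest.approx(1 / 3)

    def test_too_short_window_unavailable(self):
        assert r.window_gc(_rec("A" * 10), UTR5, 11) is None

    def test_ambiguous_base_makes_window_ineligible(self):
        rec = r.TranscriptRecord("g", "t", "ANGC", "ATGGGC")
        assert r.window_gc(rec, UTR5, 2) == 1.0       # window "GC" is clean
        assert r.window_gc(rec, UTR5, 4) is None      # window contains N

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seq=st.text(alphabet="ACGT", min_size=2, max_size=60))
    def test_nested_window_counting_identity(self, seq):
        rec = _rec(seq)
        for k in range(1, len(seq)):
            lhs = r.window_gc(rec, UTR5, k + 1) * (k + 1)
            rhs = r.window_gc(rec, UTR5, k) * k + (seq[-(k + 1)] in "GC")
            assert lhs == pytest.approx(rhs, abs=1e-9)


class TestGcProfile:
    def test_identical_sequences_have_zero_sem(self):
        group = [_rec("ACGTACGTACGT", tid=f"t{i}") for i in range(5)]
        prof = r.gc_profile(group, r.WindowSpec(UTR5, 2, 10))
        assert np.allclose(prof["sem"], 0)
        assert (prof["n"] == 5).all()

    def test_short_transcripts_dropped_per_k(self):
        group = [_rec("ACGT"), _rec("ACGTACGT", tid="t2")]
        prof = r.gc_profile(group, r.WindowSpec(UTR5, 2, 8)).set_index("k")
        assert prof.loc[4, "n"] == 2
        assert prof.loc[5, "n"] == 1
        assert prof.loc[8, "n"] == 1

    def test_union_profile_is_weighted_average_of_parts(self, random_transcripts):
        recs, _ = random_transcripts
        recs = [t for t in recs if len(t.utr5) >= 30][:400]
        a, b = recs[:150], recs[150:]
        spec = r.WindowSpec(UTR5, 6, 30)
        pa, pb = r.gc_profile(a, spec), r.gc_profile(b, spec)
        pu = r.gc_profile(a + b, spec)
        expected = (pa["mean_gc"] * pa["n"] + pb["mean_gc"] * pb["n"]) / (pa["n"] + pb["n"])
        np.testing.assert_allclose(pu["mean_gc"], expected, atol=1e-12)

    def test_flat_profile_at_planted_gc(self):
        recs, _ = r.generate_transcriptome(r.SimTranscriptomeParams(
            n_genes=2000, transcripts_per_gene=1.0, utr5_gc=0.90,
            utr5_len_mean=80.0, utr5_len_sd=15.0, frac_positive=0,
            frac_negative=0, seed=9))
        prof = r.gc_profile(r.filter_min_utr5(recs, 30), r.WindowSpec(UTR5, 6, 30))
        assert (abs(prof["mean_gc"] - 0.90) < 0.01).all()


class TestFilterAndLengths:
    def test_min_length_boundary(self):
        group = [_rec("A" * 19, tid="short"), _rec("A" * 20, tid="exact")]
        kept = r.filter_min_utr5(group)
        assert [t.transcript_id for t in kept] == ["exact"]

    def test_idempotent_and_never_grows(self, random_transcripts):
        recs, _ = random_transcripts
        once = r.filter_min_utr5(recs)
        assert len(once) <= len(recs)
        assert r.filter_min_utr5(once) == once

    def test_lengths_preserve_order(self):
        group = [_rec("ACGT", tid="a"), _rec("AC", tid="b")]
        assert r.utr5_lengths(group) == [4, 2]
        assert r.utr5_lengths([]) == []


class TestBackgroundSelection:
    def _pool(self, n_genes=50, per_gene=2):
        return [r.TranscriptRecord(f"g{i}", f"g{i}.t{j}", "ACGTACGT", "ATGGCA")
                for i in range(n_genes) for j in range(per_gene)]

    def test_one_transcript_per_gene_with_exclusions(self):
        pool = self._pool(3)
        out = r.select_background(pool, {"g0"}, seed=1)
        assert len(out) == 2
        assert {t.gene_id for t in out} == {"g1", "g2"}

    def test_deterministic_and_order_invariant(self):
        pool = self._pool(20)
        a = r.select_background(pool, set(), seed=3)
        b = r.select_background(pool[::-1], set(), seed=3)
        assert [t.transcript_id for t in a] == [t.transcript_id for t in b]

    def test_uniform_choice_frequency(self):
        pool = self._pool(400, per_gene=2)
        picks = 0
        total = 0
        for seed in range(50):
            for t in r.select_background(pool, set(), seed=seed):
                picks += t.transcript_id.endswith(".t0")
                total += 1
        assert abs(picks / total - 0.5) < 0.02

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            r.select_background([], set(), seed=0)

    def test_foreground_takes_longest_utr(self):
        pool = [r.TranscriptRecord("g1", "g1.a", "ACGT", "ATGGCA"),
                r.TranscriptRecord("g1", "g1.b", "ACGTACGT", "ATGGCA"),
                r.TranscriptRecord("g2", "g2.a", "AC", "ATGGCA")]
        out = r.foreground_transcripts(pool, {"g1", "g2"})
        assert [t.transcript_id for t in out] == ["g1.b", "g2.a"]


class TestLogoMatrix:
    def test_identical_sequences_give_unit_frequencies(self):
        group = [r.TranscriptRecord("g", f"t{i}", "AC" * 10, "ATG" + "GCA" * 6)
                 for i in range(4)]
        logo = r.build_logo_matrix(group)
        assert len(logo) == 40
        assert list(logo["position"]) == list(range(-20, 0)) + list(range(1, 21))
        assert 0 not in set(logo["position"])
        assert (logo[list("ACGT")].max(axis=1) == 1.0).all()
        np.testing.assert_allclose(logo[list("ACGT")].sum(axis=1), 1.0)

    def test_short_sequences_excluded_not_padded(self):
        group = [r.TranscriptRecord("g", "long", "AC" * 10, "ATG" + "A" * 27),
                 r.TranscriptRecord("g", "short", "ACGT", "ATG" + "A" * 27)]
        logo = r.build_logo_matrix(group)
        assert (logo["n"] == 1).all()

    def test_uniform_sequences_approach_quarter_frequencies(self):
        rng = np.random.default_rng(12)
        bases = np.array(list("ACGT"))
        group = [r.TranscriptRecord(
            "g", f"t{i}",
            "".join(bases[rng.integers(0, 4, 20)]),
            "".join(bases[rng.integers(0, 4, 21)]))
            for i in range(4000)]
        logo = r.build_logo_matrix(group)
        assert (abs(logo[list("ACGT")].to_numpy() - 0.25) < 0.02).all()
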