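"""Unit and property tests for k-mer correction, merging, and screening."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from otuflow import Read, ReadPair, build_spectrum, expected_errors, merge_pair, revcomp, screen_read
from otuflow.readprep import (
    CorrectionResult,
    MergedRead,
    MergeRejection,
    correct_read,
    longest_homopolymer,
)


def _reads(*seqs):
    return [Read(id=f"r{i}", bases=s) for i, s in enumerate(seqs)]


class TestBuildSpectrum:
    def test_direct_enumeration(self):
        sp = build_spectrum(_reads("ACGTA"), 4)
        # ACGT is its own canonical form; CGTA < TACG
        assert sp.as_dict() == {"ACGT": 1, "CGTA": 1}

    def test_canonical_collapse(self):
        sp = build_spectrum(_reads("AAAA", "TTTT"), 4)
        assert sp.as_dict() == {"AAAA": 2}

    def test_ambiguous_windows_skipped(self):
        sp = build_spectrum(_reads("ACNGT"), 3)
        assert sp.as_dict() == {}

    def test_k_longer_than_reads_warns(self):
        with pytest.warns(UserWarning):
            sp = build_spectrum(_reads("ACGT"), 8)
        assert sp.n_kmers == 0

    def test_k_below_three_rejected(self):
        with pytest.raises(ValueError):
            build_spectrum(_reads("ACGT"), 2)


class TestCorrectRead:
    def test_singleton_error_corrected(self):
        reads = _reads(*(["ACGTACGTAC"] * 10 + ["ACGAACGTAC"]))
        sp = build_spectrum(reads, 4)
        res = correct_read(reads[-1], sp, weak_max=1, strong_min=5)
        assert res.read.bases == "ACGTACGTAC"
        assert res.n_corrected == 1

    def test_quals_untouched_by_correction(self):
        reads = _reads(*(["ACGTACGTAC"] * 10))
        bad = Read(id="e", bases="ACGAACGTAC", quals=list(range(10)))
        sp = build_spectrum(reads + [bad], 4)
        res = correct_read(bad, sp, weak_max=1, strong_min=5)
        assert res.read.quals == list(range(10))

    def test_all_strong_is_fixed_point(self):
        reads = _reads(*(["ACGTACGTAC"] * 10))
        sp = build_spectrum(reads, 4)
        res = correct_read(reads[0], sp, weak_max=1, strong_min=5)
        assert res.read.bases == reads[0].bases
        assert res.n_corrected == 0 and not res.flagged

    def test_ambiguous_fix_leaves_read_flagged(self):
        # two strong contexts differing at one site; the query carries a
        # third base there, so both repairs look equally valid
        reads = _reads(*(["AAAACAAAA"] * 10 + ["AAAAGAAAA"] * 10))
        query = Read(id="q", bases="AAAATAAAA")
        sp = build_spectrum(reads + [query], 4)
        res = correct_read(query, sp, weak_max=1, strong_min=5)
        assert res.read.bases == query.bases
        assert res.n_corrected == 0
        assert res.flagged

    def test_correction_budget_respected(self, rng):
        # three isolated errors exceed the 2-correction budget
        template = "".join(rng.choice(list("ACGT"), size=40))
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        bad = list(template)
        for pos in (5, 19, 33):
            bad[pos] = flip[bad[pos]]
        bad = "".join(bad)
        reads = _reads(*([template] * 20))
        sp = build_spectrum(reads, 4)
        res = correct_read(Read(id="q", bases=bad), sp, weak_max=1, strong_min=5)
        assert res.read.bases == bad  # returned unchanged
        assert res.flagged

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_fixed_point_fuzz(self, seed):
        """A read whose every k-mer is strong is never modified."""
        rng = np.random.default_rng(seed)
        template = "".join(rng.choice(list("ACGT"), size=60))
        reads = _reads(*([template] * 5))
        sp = build_spectrum(reads, 8)
        res = correct_read(reads[0], sp, weak_max=1, strong_min=3)
        assert res.read.bases == template and res.n_corrected == 0


def _make_pair(template, read_len, q=30):
    """Mate pair from an error-free template: fwd prefix, rev revcomp suffix."""
    fwd = Read(id="t/1", bases=template[:read_len], quals=[q] * read_len)
    rev_bases = revcomp(template[-read_len:])
    rev = Read(id="t/2", bases=rev_bases, quals=[q] * read_len)
    return ReadPair(fwd=fwd, rev=rev)


class TestMergePair:
    def test_agreement_consensus(self, rng):
        template = "".join(rng.choice(list("ACGT"), size=80))
        pair = _make_pair(template, 50)
        merged = merge_pair(pair)
        assert isinstance(merged, MergedRead)
        assert merged.bases == template
        assert merged.overlap_len == 20
        assert merged.n_conflicts == 0
        assert all(q == 30 for q in merged.quals)

    def test_conflict_resolved_by_quality(self):
        # single-column overlap conflict: fwd says A at q40, rev says G at q20
        fwd = Read(id="x/1", bases="CCCCCCCCCCCCCCCCCCCCA", quals=[30] * 20 + [40])
        rev_seq = "G" + "C" * 20
        rev = Read(id="x/2", bases=revcomp(rev_seq + "GGGGG"), quals=[20] * 26)
        merged = merge_pair(rev_and_fwd(fwd, rev), dq_threshold=6)
        conflict_pos = 20
        assert merged.bases[conflict_pos] == "A"
        assert merged.quals[conflict_pos] == 20  # |40 - 20|

    def test_conflict_below_dq_becomes_n(self):
        fwd = Read(id="x/1", bases="CCCCCCCCCCCCCCCCCCCCA", quals=[30] * 20 + [20])
        rev_seq = "G" + "C" * 20
        rev = Read(id="x/2", bases=revcomp(rev_seq + "GGGGG"), quals=[22] * 26)
        merged = merge_pair(rev_and_fwd(fwd, rev), dq_threshold=6)
        assert merged.bases[20] == "N"
        assert merged.quals[20] == 0
        assert merged.n_ambig == 1

    def test_no_overlap_rejection(self):
        pair = ReadPair(
            fwd=Read(id="a/1", bases="A" * 30, quals=[30] * 30),
            rev=Read(id="a/2", bases="G" * 30, quals=[30] * 30),
        )
        out = merge_pair(pair, min_overlap=20, max_overlap_mismatch_frac=0.0)
        assert isinstance(out, MergeRejection)
        assert out.reason == "too_divergent"

    def test_short_reads_cannot_overlap(self):
        pair = ReadPair(
            fwd=Read(id="a/1", bases="ACGTACGT", quals=[30] * 8),
            rev=Read(id="a/2", bases="ACGTACGT", quals=[30] * 8),
        )
        out = merge_pair(pair, min_overlap=20)
        assert isinstance(out, MergeRejection)
        assert out.reason == "no_overlap"

    @settings(max_examples=40, deadline=None)
    @given(
        st.integers(0, 2**31 - 1),
        st.integers(90, 160),
        st.integers(25, 60),
    )
    def test_error_free_reconstruction(self, seed, template_len, read_len):
        """Error-free mates drawn from a template always reassemble it."""
        if 2 * read_len - template_len < 20:
            read_len = (template_len + 20 + 1) // 2
        rng = np.random.default_rng(seed)
        template = "".join(rng.choice(list("ACGT"), size=template_len))
        merged = merge_pair(_make_pair(template, read_len))
        assert isinstance(merged, MergedRead)
        assert merged.bases == template

    def test_n_count_equals_low_dq_conflicts(self, rng):
        """Consensus 'N' count == overlap conflicts with |Δq| < threshold."""
        template = "".join(rng.choice(list("ACGT"), size=100))
        read_len = 70
        pair = _make_pair(template, read_len)
        # corrupt 5 overlap positions in the forward mate only, with varied quals
        overlap_lo = len(template) - read_len
        fwd = list(pair.fwd.bases)
        fq = list(pair.fwd.quals)
        expected_n = 0
        for i, pos in enumerate(range(overlap_lo, overlap_lo + 5)):
            fwd[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[fwd[pos]]
            fq[pos] = 30 + i * 2  # rev stays at 30 → dq = 0,2,4,6,8
            if abs(fq[pos] - 30) < 6:
                expected_n += 1
        pair = ReadPair(
            fwd=Read(id="t/1", bases="".join(fwd), quals=fq), rev=pair.rev
        )
        merged = merge_pair(pair, dq_threshold=6)
        assert merged.n_conflicts == 5
        assert merged.bases.count("N") == expected_n


def rev_and_fwd(fwd, rev):
    return ReadPair(fwd=fwd, rev=rev)


class TestExpectedErrors:
    @pytest.mark.parametrize(
        "quals, expected",
        [([20, 20], 0.02), ([], 0.0), ([0], 1.0), ([10, 20, 30], 0.111)],
    )
    def test_examples(self, quals, expected):
        assert expected_errors(quals) == pytest.approx(expected, abs=1e-12)

    @given(st.lists(st.integers(0, 41), max_size=50), st.lists(st.integers(0, 41), max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_additive_and_matches_brute_force(self, qa, qb):
        brute = sum(10 ** (-q / 10) for q in qa + qb)
        assert expected_errors(qa + qb) == pytest.approx(brute, abs=1e-12)
        assert expected_errors(qa) + expected_errors(qb) == pytest.approx(
            expected_errors(qa + qb), abs=1e-12
        )

    def test_strictly_decreasing_in_any_quality(self):
        base = [20, 20, 20]
        bumped = [20, 25, 20]
        assert expected_errors(bumped) < expected_errors(base)


class TestScreenRead:
    def test_any_ambiguous_base_rejected(self):
        read = Read(id="r", bases="ACGNT", quals=[30] * 5)
        verdict = screen_read(read, max_ambig=0)
        assert not verdict.kept and verdict.reason == "ambig"

    def test_homopolymer_strict_boundary(self):
        nine = Read(id="r", bases="C" + "A" * 9 + "C", quals=[30] * 11)
        eight = Read(id="r", bases="C" + "A" * 8 + "C", quals=[30] * 10)
        assert not screen_read(nine, max_homop=8).kept
        assert screen_read(nine, max_homop=8).reason == "homopolymer"
        assert screen_read(eight, max_homop=8).kept

    def test_length_window(self):
        read = Read(id="r", bases="ACGT" * 10, quals=[30] * 40)
        assert screen_read(read, min_len=50).reason == "length"
        assert screen_read(read, max_len=30).reason == "length"
        assert screen_read(read, min_len=40, max_len=40).kept

    def test_maxee_boundary(self):
        read = Read(id="r", bases="ACGT" * 75, quals=[20] * 300)  # E = 3.0
        assert screen_read(read, maxee=3.0).kept
        assert screen_read(read, maxee=2.9).reason == "maxee"

    def test_first_failing_reason_wins(self):
        # fails both ambig and homopolymer; ambig is reported
        read = Read(id="r", bases="N" + "A" * 9, quals=[30] * 10)
        assert screen_read(read).reason == "ambig"

    def test_kept_iff_reason_ok(self):
        read = Read(id="r", bases="ACGT", quals=[30] * 4)
        verdict = screen_read(read)
        assert verdict.kept and verdict.reason == "ok"


def test_longest_homopolymer():
    assert longest_homopolymer("") == 0
    assert longest_homopolymer("ACGT") == 1
    assert longest_homopolymer("AAACCCCG") == 4
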