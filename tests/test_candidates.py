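"""Pileup CIGAR semantics, candidate filtering, normalization and labeling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafcall.candidates import (
    enumerate_candidates,
    expand_candidate_alleles,
    label_candidate,
    normalize_variant,
    pileup,
)
from leafcall.io_formats import KnownVariantIndex
from leafcall.records import AlignedRead, PileupColumn, ReadObservation

REF = "ACGTACGTACGTACGTACGT"  # 20 bp scratch reference


def _read(pos, cigar, seq, name="r", mapq=60, rev=False, quals=None, score=None):
    return AlignedRead(
        query_name=name,
        chrom="chr1",
        pos=pos,
        cigar=cigar,
        mapq=mapq,
        seq=seq,
        base_quals=quals or [30] * len(seq),
        is_reverse=rev,
        align_score=score,
    )


def _columns(reads, ref=REF):
    return {c.pos: c for c in pileup(iter(reads), ref, "chr1")}


class TestPileup:
    def test_simple_match_covers_span(self):
        cols = _columns([_read(5, [("M", 4)], "ACGT")])
        assert sorted(cols) == [5, 6, 7, 8]
        for pos, base in zip(range(5, 9), "ACGT"):
            (obs,) = cols[pos].observations
            assert obs.allele == base

    def test_insertion_anchors_on_preceding_base(self):
        # 2M 1I 2M starting at 5: insertion "G" anchored at position 6
        cols = _columns([_read(5, [("M", 2), ("I", 1), ("M", 2)], "AAGCC")])
        assert sorted(cols) == [5, 6, 7, 8]
        alleles6 = sorted(o.allele for o in cols[6].observations)
        assert alleles6 == ["+G", "A"]
        assert [o.allele for o in cols[7].observations] == ["C"]

    def test_deletion_anchor_and_gap(self):
        # 2M 2D 2M at 5: DEL(2) anchored at 6; 7-8 gain no base from this read
        cols = _columns([_read(5, [("M", 2), ("D", 2), ("M", 2)], "AACC")])
        alleles6 = sorted(o.allele for o in cols[6].observations)
        assert alleles6 == ["-2", "A"]
        assert 7 not in cols and 8 not in cols
        assert sorted(cols) == [5, 6, 9, 10]

    def test_soft_clips_never_contribute(self):
        cols = _columns([_read(5, [("S", 2), ("M", 2), ("S", 1)], "TTACG"[:5])])
        assert sorted(cols) == [5, 6]

    def test_n_bases_ignored(self):
        cols = _columns([_read(5, [("M", 3)], "ANG")])
        assert sorted(cols) == [5, 7]

    def test_cigar_length_mismatch_skips_read(self, caplog):
        cols = _columns([_read(5, [("M", 10)], "ACGT"), _read(5, [("M", 4)], "ACGT")])
        assert all(len(c.observations) == 1 for c in cols.values())

    def test_offset3_forward_and_reverse(self):
        fwd = _columns([_read(5, [("M", 4)], "ACGT", rev=False)])
        rev = _columns([_read(5, [("M", 4)], "ACGT", rev=True)])
        # forward read: 3' end is the last query base
        assert [fwd[p].observations[0].offset3 for p in range(5, 9)] == [3, 2, 1, 0]
        # reverse read: 3' end is the leftmost stored base
        assert [rev[p].observations[0].offset3 for p in range(5, 9)] == [0, 1, 2, 3]

    def test_offset_sum_invariant_at_match_positions(self):
        """offset3 + offset5 == read length - 1 at every M position."""
        read = _read(3, [("M", 10)], "ACGTACGTAC")
        cols = _columns([read])
        for qpos, pos in enumerate(range(3, 13)):
            (obs,) = cols[pos].observations
            assert obs.offset3 + qpos == len(read.seq) - 1

    def test_column_counts_match_interval_overlap_oracle(self, rng):
        """Observation count per column equals the number of reads whose
        aligned (M-consuming) span covers that position."""
        reads = []
        for i in range(60):
            pos = int(rng.integers(1, 15))
            ln = int(rng.integers(1, 6))
            reads.append(_read(pos, [("M", ln)], "A" * ln, name=f"r{i}"))
        reads.sort(key=lambda r: r.pos)
        cols = _columns(reads, ref="A" * 30)
        for pos in range(1, 25):
            expected = sum(1 for r in reads if r.pos <= pos < r.pos + r.cigar[0][1])
            got = len(cols[pos].observations) if pos in cols else 0
            assert got == expected


class TestEnumerateCandidates:
    def _col(self, alleles, pos=10, ref_base="A"):
        obs = [ReadObservation(a, 30, 60, False, 5, 95) for a in alleles]
        return PileupColumn("chr1", pos, ref_base, obs)

    def test_simple_snv_kept(self):
        cands = enumerate_candidates(self._col(["A"] * 10 + ["G"] * 5), 0.05, 2)
        assert [(c.alt_allele, c.vtype) for c in cands] == [("G", "SNV")]

    def test_low_fraction_and_count_dropped(self):
        assert enumerate_candidates(self._col(["A"] * 99 + ["T"]), 0.05, 2) == []

    def test_each_indel_class_is_its_own_candidate(self):
        col = self._col(["A"] * 8 + ["+GT"] * 4 + ["-1"] * 3)
        cands = enumerate_candidates(col, 0.05, 2)
        assert sorted(c.alt_allele for c in cands) == ["+GT", "-1"]
        assert sorted(c.vtype for c in cands) == ["DEL", "INS"]

    def test_reference_allele_never_emitted(self):
        cands = enumerate_candidates(self._col(["A"] * 20), 0.0, 0)
        assert cands == []

    @given(
        n_ref=st.integers(0, 40),
        n_alt=st.integers(0, 40),
        min_ratio=st.floats(0.0, 0.5),
        min_alt=st.integers(0, 5),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_filter_exactly_enforced(self, n_ref, n_alt, min_ratio, min_alt):
        total = n_ref + n_alt
        if total == 0:
            return
        cands = enumerate_candidates(self._col(["A"] * n_ref + ["G"] * n_alt), min_ratio, min_alt)
        kept = bool(cands)
        assert kept == (n_alt >= min_alt and n_alt / total >= min_ratio and n_alt > 0)


def _apply(reference, pos, ref, alt):
    """Haplotype produced by substituting ref -> alt at 1-based pos."""
    i = pos - 1
    assert reference[i : i + len(ref)] == ref
    return reference[:i] + alt + reference[i + len(ref) :]


class TestNormalizeVariant:
    def test_snv_unchanged_and_idempotent(self):
        key = normalize_variant("chr1", 5, "A", "G", REF)
        assert key == ("chr1", 5, "A", "G")
        assert normalize_variant(*key, REF) == key

    def test_ref_equals_alt_rejected(self):
        with pytest.raises(ValueError, match="not a variant"):
            normalize_variant("chr1", 1, "AC", "AC", REF)

    def test_ref_mismatch_is_fatal(self):
        with pytest.raises(ValueError, match="does not match"):
            normalize_variant("chr1", 1, "T", "G", REF)

    def test_homopolymer_deletion_shifts_left(self):
        ref = "CAAAT"
        # delete the rightmost A, anchored at position 3
        key = normalize_variant("chr1", 3, "AA", "A", ref)
        assert key == ("chr1", 1, "CA", "C")
        assert _apply(ref, 3, "AA", "A") == _apply(ref, *key[1:])

    def test_left_shift_matches_brute_force_oracle(self, rng):
        """Normalized deletions land on the leftmost anchored representation
        that yields the same haplotype (exhaustive shift search)."""
        for _ in range(200):
            n = 40
            reference = "".join(rng.choice(list("ACGT"), size=n))
            ln = int(rng.integers(1, 4))
            pos = int(rng.integers(2, n - ln - 1))
            raw_ref = reference[pos - 1 : pos + ln]
            raw_alt = reference[pos - 1]
            applied = _apply(reference, pos, raw_ref, raw_alt)
            # brute force: every anchored same-length deletion giving the same haplotype
            equivalents = []
            for p in range(1, pos + 1):
                r = reference[p - 1 : p + ln]
                a = reference[p - 1]
                if len(r) == ln + 1 and _apply(reference, p, r, a) == applied:
                    equivalents.append((p, r, a))
            expected = min(equivalents)
            got = normalize_variant("chr1", pos, raw_ref, raw_alt, reference)
            assert got == ("chr1", *expected)
            assert normalize_variant(*got, reference) == got  # idempotent

    def test_insertion_left_shift_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            n = 40
            reference = "".join(rng.choice(list("ACGT"), size=n))
            ln = int(rng.integers(1, 4))
            pos = int(rng.integers(2, n - 1))
            ins = "".join(rng.choice(list("ACGT"), size=ln))
            raw_ref = reference[pos - 1]
            raw_alt = raw_ref + ins
            applied = _apply(reference, pos, raw_ref, raw_alt)
            equivalents = []
            for p in range(1, pos + 1):
                anchor = reference[p - 1]
                s = applied[p : p + ln]
                if _apply(reference, p, anchor, anchor + s) == applied:
                    equivalents.append((p, anchor, anchor + s))
            expected = min(equivalents)
            got = normalize_variant("chr1", pos, raw_ref, raw_alt, reference)
            assert got == ("chr1", *expected)


class TestLabeling:
    def test_member_and_absent_and_allele_exact(self):
        idx = KnownVariantIndex()
        idx.add("chr1", 100, "A", "G")
        assert label_candidate(("chr1", 100, "A", "G"), idx) == 1
        assert label_candidate(("chr1", 100, "A", "T"), idx) == 0
        assert label_candidate(("chr1", 101, "A", "G"), idx) == 0

    def test_duplicate_insertion_idempotent(self):
        idx = KnownVariantIndex()
        idx.add("chr1", 1, "A", "G")
        idx.add("chr1", 1, "A", "G")
        assert len(idx) == 1


def test_expand_candidate_alleles_anchoring():
    from leafcall.records import CandidateVariant

    ref = "GATTACA"
    snv = CandidateVariant("chr1", 3, "T", "C", "SNV")
    assert expand_candidate_alleles(snv, ref) == (3, "T", "C")
    ins = CandidateVariant("chr1", 4, "T", "+GG", "INS")
    assert expand_candidate_alleles(ins, ref) == (4, "T", "TGG")
    dele = CandidateVariant("chr1", 4, "T", "-2", "DEL")
    assert expand_candidate_alleles(dele, ref) == (4, "TAC", "T")
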