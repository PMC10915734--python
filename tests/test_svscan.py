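"""SV scanning: read QC boundaries, breakend signature orientation, clustering
against a brute-force oracle, DV/DR counting and the retention filters."""

from __future__ import annotations

import itertools

import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from marecs_kit import svscan
from marecs_kit.svscan import (
    AlnSeg,
    BreakendSignature,
    FilterConfig,
    QCConfig,
    SVCandidate,
    WhitelistEntry,
    cluster_signatures,
    compute_reference_support,
    extract_signatures,
    filter_svs,
    qc_records,
    refine_breakpoint,
)

HEADER = pysam.AlignmentHeader.from_dict(
    {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": "chr1", "LN": 10_000_000}, {"SN": "chr2", "LN": 10_000_000}],
    }
)


def _rec(name, chrom, start0, cigar, reverse=False, supplementary=False, seq_len=None):
    a = pysam.AlignedSegment(HEADER)
    a.query_name = name
    a.flag = (16 if reverse else 0) | (2048 if supplementary else 0)
    a.reference_name = chrom
    a.reference_start = start0
    a.mapping_quality = 60
    a.cigarstring = cigar
    if seq_len:
        a.query_sequence = "A" * seq_len
    return a


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

class TestQC:
    def _read(self, length, q):
        return ("r", "A" * length, chr(q + 33) * length)

    @pytest.mark.parametrize(
        "raw_len,kept",
        [(1099, False), (1100, True), (1101, True), (1050, False)],
    )
    def test_length_cutoff_after_trimming(self, raw_len, kept):
        out = list(qc_records([self._read(raw_len, 30)], QCConfig()))
        assert bool(out) is kept
        if kept:
            assert len(out[0][1]) == raw_len - 100

    @pytest.mark.parametrize("q,kept", [(6, False), (7, False), (8, True)])
    def test_quality_cutoff_is_exclusive_at_q7(self, q, kept):
        out = list(qc_records([self._read(2_000, q)], QCConfig()))
        assert bool(out) is kept

    def test_empty_input_gives_empty_output(self):
        assert list(qc_records([], QCConfig())) == []

    def test_malformed_record_names_the_read(self):
        with pytest.raises(svscan.MalformedRecordError, match="oddball"):
            list(qc_records([("oddball", "ACGT", "!!!")], QCConfig()))

    def test_order_preserved_and_lengths_never_grow(self):
        reads = [(f"r{i}", "C" * n, "I" * n) for i, n in enumerate((1500, 900, 2000, 1200))]
        out = list(qc_records(reads, QCConfig()))
        assert [n for n, _s, _q in out] == ["r0", "r2", "r3"]
        by_name = {n: s for n, s, _q in out}
        for name, seq, _q in reads:
            if name in by_name:
                assert len(by_name[name]) <= len(seq)


# ---------------------------------------------------------------------------
# signatures
# ---------------------------------------------------------------------------

class TestSignatures:
    def test_no_supplementary_records_no_signatures(self):
        recs = [_rec("r1", "chr1", 100, "5000M"), _rec("r2", "chr2", 100, "5000M")]
        assert extract_signatures(recs) == []

    def test_inversion_pair_matches_orientation_table(self):
        # read half 1: chr1:+ ending at 10,000; half 2: chr1:- starting at 50,000
        # (minus-strand record; its later read coordinates come first on the
        # reference), the hand-built table says: (+,-) junction at (10001, 55001)
        recs = [
            _rec("inv_read", "chr1", 5_000, "5000M5000S"),
            _rec("inv_read", "chr1", 50_000, "5000M5000S", reverse=True, supplementary=True),
        ]
        sigs = extract_signatures(recs)
        assert len(sigs) == 1
        sig = sigs[0]
        assert sig.sv_type == "INV"
        assert (sig.endA[1], sig.endB[1]) == (10_001, 55_001)

    def test_interchromosomal_pair_is_breakend(self):
        recs = [
            _rec("tra_read", "chr1", 5_000, "5000M5000S"),
            _rec("tra_read", "chr2", 70_000, "5000S5000M", supplementary=True),
        ]
        sigs = extract_signatures(recs)
        assert len(sigs) == 1
        assert sigs[0].sv_type == "TRA"
        assert sigs[0].endA == ("chr1", 10_001, "+")
        assert sigs[0].endB == ("chr2", 70_001, "+")

    def test_deletion_and_duplication_from_gap_sign(self):
        del_recs = [
            _rec("d", "chr1", 1_000, "4000M4000S"),
            _rec("d", "chr1", 9_000, "4000S4000M", supplementary=True),
        ]
        (sig,) = extract_signatures(del_recs)
        assert sig.sv_type == "DEL"
        assert (sig.endA[1], sig.endB[1]) == (5_001, 9_001)

        dup_recs = [
            _rec("u", "chr1", 1_000, "4000M4000S"),
            _rec("u", "chr1", 2_000, "4000S4000M", supplementary=True),
        ]
        (sig,) = extract_signatures(dup_recs)
        assert sig.sv_type == "DUP"
        assert (sig.endA[1], sig.endB[1]) == (2_001, 5_001)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _sig(read_id, a, b, sv_type="INV", chrom="chr1"):
    return BreakendSignature(read_id, sv_type, (chrom, a, "+"), (chrom, b, "-"))


def _brute_force_clusters(sigs, tol):
    """Transitive closure of the pairwise 'both ends within tol' relation."""
    groups = [{i} for i in range(len(sigs))]

    def find(i):
        for g in groups:
            if i in g:
                return g
        raise AssertionError

    for i, j in itertools.combinations(range(len(sigs)), 2):
        si, sj = sigs[i], sigs[j]
        if (
            si.sv_type == sj.sv_type
            and abs(si.endA[1] - sj.endA[1]) <= tol
            and abs(si.endB[1] - sj.endB[1]) <= tol
        ):
            gi, gj = find(i), find(j)
            if gi is not gj:
                gi |= gj
                groups.remove(gj)
    out = set()
    for g in groups:
        a = sorted(sigs[i].endA[1] for i in g)
        b = sorted(sigs[i].endB[1] for i in g)
        out.add((len(g), a[(len(a) - 1) // 2], b[(len(b) - 1) // 2]))
    return out


class TestClustering:
    def test_single_signature_single_candidate(self):
        (cand,) = cluster_signatures([_sig("r1", 1000, 2000)])
        assert cand.dv == 1
        assert cand.breakpointA == ("chr1", 1000)
        assert cand.breakpointB == ("chr1", 2000)

    def test_jittered_junction_merges_to_median(self):
        jitter = [0, -10, 10, -7, 3, 9]
        sigs = [_sig(f"r{i}", 10_000 + d, 60_000 - d) for i, d in enumerate(jitter)]
        (cand,) = cluster_signatures(sigs, position_tol=50)
        assert cand.dv == 6
        expected = _brute_force_clusters(sigs, 50)
        assert {(cand.dv, cand.breakpointA[1], cand.breakpointB[1])} == expected

    def test_distant_junctions_stay_separate(self):
        sigs = [_sig("r1", 10_000, 60_000), _sig("r2", 20_000, 70_000)]
        cands = cluster_signatures(sigs, position_tol=50)
        assert len(cands) == 2

    def test_random_sets_match_brute_force(self):
        import random

        rng = random.Random(42)
        for _trial in range(20):
            sigs = [
                _sig(f"r{i}", rng.choice([5_000, 5_030, 9_000]), rng.choice([40_000, 40_040, 80_000]))
                for i in range(rng.randint(1, 10))
            ]
            cands = cluster_signatures(sigs, position_tol=50)
            got = {(c.dv, c.breakpointA[1], c.breakpointB[1]) for c in cands}
            # DV counts unique reads; read ids are unique here so sizes match
            assert got == _brute_force_clusters(sigs, 50)


# ---------------------------------------------------------------------------
# DV / DR and refinement
# ---------------------------------------------------------------------------

class TestReferenceSupport:
    def _candidate(self):
        sigs = [_sig(f"s{i}", 10_000, 60_000) for i in range(6)]
        (cand,) = cluster_signatures(sigs)
        return cand

    def test_no_spanning_reads_gives_zero(self):
        cand = self._candidate()
        reads = {f"s{i}": [AlnSeg("chr1", 9_000, 9_900, "+", 0, 900)] for i in range(6)}
        assert compute_reference_support(cand, reads).dr == 0

    def test_constructed_spanners_counted_once(self):
        cand = self._candidate()
        reads = {}
        for i in range(6):  # the split supporters themselves
            reads[f"s{i}"] = [AlnSeg("chr1", 8_000, 10_000, "+", 0, 2_000)]
        for i in range(14):  # contiguous spanners across breakpoint A
            reads[f"dr{i}"] = [AlnSeg("chr1", 9_000, 11_000, "+", 0, 2_000)]
        cand = compute_reference_support(cand, reads)
        assert (cand.dv, cand.dr) == (6, 14)
        assert cand.fraction == pytest.approx(0.30)

    def test_chimeric_read_counts_only_as_variant_support(self):
        cand = self._candidate()
        # s0 also spans breakpoint B contiguously: still DV only
        reads = {"s0": [AlnSeg("chr1", 59_000, 61_000, "+", 0, 2_000)]}
        assert compute_reference_support(cand, reads).dr == 0


class TestRefinement:
    @pytest.mark.parametrize(
        "coords,expected",
        [([100, 101, 103], 101), ([100, 102], 100), ([7], 7)],
    )
    def test_lower_median_rule(self, coords, expected):
        sigs = [_sig(f"r{i}", c, c + 1_000) for i, c in enumerate(coords)]
        cand = SVCandidate("INV", ("chr1", 0), ("chr1", 0), dv=len(sigs), signatures=sigs)
        cand = refine_breakpoint(cand)
        assert cand.breakpointA[1] == expected

    def test_refinement_requires_signatures(self):
        cand = SVCandidate("INV", ("chr1", 1), ("chr1", 2), dv=1)
        with pytest.raises(ValueError):
            refine_breakpoint(cand, signatures=[])


# ---------------------------------------------------------------------------
# retention filters
# ---------------------------------------------------------------------------

def _cand(dv, dr, length_bp=1_000_000, sv_type="INV"):
    return SVCandidate(
        sv_type, ("chr1", 1_000_000), ("chr1", 1_000_000 + length_bp), dv=dv, dr=dr
    )


def _brute_force_filter(c, cfg):
    ok = c.dv > cfg.min_dv
    ok = ok and c.dv / (c.dv + c.dr) > cfg.min_fraction
    if c.length is not None and c.length > cfg.large_sv_mb * 1e6:
        ok = ok and any(
            w.sv_type == c.sv_type
            and any(
                ch == w.chrom and w.start - cfg.whitelist_slop <= p <= w.end + cfg.whitelist_slop
                for ch, p in (c.breakpointA, c.breakpointB)
            )
            for w in cfg.karyotype_whitelist
        )
    return ok


class TestFilters:
    def test_dv_rule_boundary(self):
        retained, reasons = filter_svs([_cand(4, 10), _cand(5, 10)])
        assert [c.dv for c in retained] == [5]
        assert "DV=4" in reasons[0][0]

    def test_fraction_rule_boundary(self):
        retained, _ = filter_svs([_cand(5, 50)])  # 5/55 ~ 0.091 <= 0.10
        assert retained == []
        retained, _ = filter_svs([_cand(5, 10)])  # 5/15 = 0.33 > 0.10
        assert len(retained) == 1

    def test_large_sv_needs_karyotype_whitelist(self):
        big = _cand(10, 10, length_bp=6_000_000)
        retained, reasons = filter_svs([big])
        assert retained == [] and "karyotype" in reasons[0][0]
        wl = FilterConfig(
            karyotype_whitelist=[WhitelistEntry("chr1", 900_000, 1_100_000, "INV")]
        )
        retained, _ = filter_svs([big], wl)
        assert retained == [big]

    def test_rejection_reasons_enumerate_every_failed_rule(self):
        _, reasons = filter_svs([_cand(2, 100, length_bp=7_000_000)])
        assert len(reasons[0]) == 3

    def test_random_candidates_match_brute_force(self):
        import random

        rng = random.Random(7)
        cfg = FilterConfig(
            karyotype_whitelist=[WhitelistEntry("chr1", 500_000, 1_500_000, "INV")]
        )
        cands = [
            _cand(
                rng.randint(0, 12),
                rng.randint(0, 60),
                length_bp=rng.choice([100_000, 4_000_000, 6_000_000, 9_000_000]),
                sv_type=rng.choice(["INV", "DEL"]),
            )
            for _ in range(100)
        ]
        retained, _ = filter_svs(cands, cfg)
        assert set(map(id, retained)) == {
            id(c) for c in cands if _brute_force_filter(c, cfg)
        }

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(dv=st.integers(0, 40), dr=st.integers(0, 200), bump=st.integers(1, 20))
    def test_filter_monotone_in_dv(self, dv, dr, bump):
        base, _ = filter_svs([_cand(dv, dr)])
        more, _ = filter_svs([_cand(dv + bump, dr)])
        if base:  # retained must never flip to rejected when DV rises
            assert more
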