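"""Call-set algebra: VCF round-trips, quality filtering, the stand-in
genotyper, set operations against brute-force oracles, masking, and
sceSNV identification."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scesnv import callset
from scesnv.callset import (
    CallSet,
    VariantCall,
    carriers_histogram,
    exclude_regions,
    filter_calls,
    genotype_likelihoods,
    identify_scesnvs,
    intersect_per_cell,
    pileup_genotype,
    read_callset,
    union_callsets,
    write_callset,
)
from scesnv.loci import SNVLocus


def call(pos, alt="G", qual=150.0, mq=70.0, qd=5.0, chrom="chr1", ref="A"):
    return VariantCall(SNVLocus(chrom, pos, ref, alt), qual=qual, mq=mq, qd=qd)


def callset_of(calls, scope=("per_cell", "BC1"), caller="x"):
    cs = CallSet(caller=caller, scope=scope)
    for c in calls:
        cs.add(c)
    return cs


class TestVcfRoundTrip:
    def test_roundtrip_preserves_keys_and_fields(self, tmp_path):
        cs = callset_of(
            [call(10), call(20, alt="T", qual=42.5, mq=60.0, qd=2.5),
             call(30, alt="C", ref="G")],
            scope=("per_cell", "BC1"),
        )
        path = str(tmp_path / "x.vcf")
        write_callset(cs, path, contigs={"chr1": 1000})
        back = read_callset(path, caller="x", scope=("per_cell", "BC1"))
        assert set(back.keys()) == set(cs.keys())
        for key in cs.keys():
            a, b = cs.calls[key], back.calls[key]
            assert b.qual == pytest.approx(a.qual, abs=0.01)
            assert b.mq == pytest.approx(a.mq, abs=0.01)
            assert b.qd == pytest.approx(a.qd, abs=0.01)

    def test_multiallelic_decomposed_and_indels_skipped(self, tmp_path):
        path = tmp_path / "m.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=chr1,length=1000>\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t100\t.\tA\tC,T\t50\t.\t.\n"
            "chr1\t200\t.\tAT\tA\t50\t.\t.\n"
        )
        cs = read_callset(str(path), caller="x")
        assert set(cs.keys()) == {("chr1", 100, "C"), ("chr1", 100, "T")}
        assert cs.n_skipped_non_snv == 1


class TestFilterCalls:
    def test_strict_boundaries(self):
        kept = filter_calls(callset_of([
            call(1, qual=100.0, mq=70.0, qd=5.0),   # QUAL at boundary -> out
            call(2, qual=150.0, mq=60.0, qd=5.0),   # MQ at boundary -> out
            call(3, qual=150.0, mq=61.0, qd=2.0),   # QD at boundary -> out
            call(4, qual=150.0, mq=61.0, qd=2.5),   # all strict -> in
        ]))
        assert set(kept.keys()) == {("chr1", 4, "G")}

    def test_missing_mq_or_qd_fails(self):
        a = VariantCall(SNVLocus("chr1", 1, "A", "G"), qual=500.0, mq=None,
                        qd=5.0)
        b = VariantCall(SNVLocus("chr1", 2, "A", "G"), qual=500.0, mq=99.0,
                        qd=None)
        assert len(filter_calls(callset_of([a, b]))) == 0

    def test_hand_enumerated_vcf(self, tmp_path):
        """10 calls, exactly 4 pass QUAL>100, MQ>60, QD>2 by construction."""
        rows = [
            (10, 150, 70, 5),   # pass
            (20, 99, 70, 5),
            (30, 101, 61, 2.1),  # pass
            (40, 150, 60, 5),
            (50, 150, 55, 5),
            (60, 150, 70, 2.0),
            (70, 150, 70, 1.0),
            (80, 500, 90, 9),   # pass
            (90, 100, 70, 5),
            (95, 102, 60.5, 3),  # pass
        ]
        cs = callset_of([call(p, qual=q, mq=m, qd=d) for p, q, m, d in rows])
        path = str(tmp_path / "ten.vcf")
        write_callset(cs, path, contigs={"chr1": 1000})
        back = read_callset(path, caller="x", scope=("per_cell", "BC1"))
        assert len(filter_calls(back)) == 4

    @given(
        st.lists(
            st.tuples(st.integers(1, 50), st.floats(0, 300),
                      st.floats(0, 100), st.floats(0, 20)),
            max_size=30,
        ),
        st.floats(50, 200), st.floats(30, 90), st.floats(0, 10),
    )
    @settings(deadline=None, max_examples=50)
    def test_filter_monotone_in_thresholds(self, rows, q0, m0, d0):
        cs = callset_of([call(p, qual=q, mq=m, qd=d) for p, q, m, d in rows])
        base = len(filter_calls(cs, q0, m0, d0))
        assert len(filter_calls(cs, q0 + 10, m0, d0)) <= base
        assert len(filter_calls(cs, q0, m0 + 10, d0)) <= base
        assert len(filter_calls(cs, q0, m0, d0 + 1)) <= base


class TestGenotyper:
    def _reads(self, bases, chrom_seq, pos=101):
        import pysam

        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": len(chrom_seq)}]}
        )
        out = []
        for i, b in enumerate(bases):
            a = pysam.AlignedSegment(header)
            a.query_name = f"r{i}"
            a.reference_id = 0
            a.reference_start = pos - 6  # covers pos at offset 5
            a.mapping_quality = 255
            a.cigarstring = "10M"
            seq = list(chrom_seq[pos - 6 : pos + 4])
            seq[5] = b
            a.query_sequence = "".join(seq)
            a.query_qualities = pysam.qualitystring_to_array("I" * 10)
            a.set_tag("CB", "BC1")
            out.append(a)
        return out

    REF = {"chr1": "A" * 300}

    def test_all_reference_no_call(self):
        cs = pileup_genotype(self._reads("A" * 20, self.REF["chr1"]), self.REF)
        assert len(cs) == 0

    def test_balanced_het_call_and_qual_matches_likelihood_oracle(self):
        cs = pileup_genotype(self._reads("A" * 10 + "G" * 10,
                                         self.REF["chr1"]), self.REF,
                             error_rate=0.01)
        assert len(cs) == 1
        got = next(iter(cs.calls.values()))
        assert got.genotype == "het"
        assert got.locus == SNVLocus("chr1", 101, "A", "G")
        # independent posterior computation
        e = 0.01
        import numpy as np

        def lik(p_var):
            return (p_var ** 10) * ((1 - p_var) ** 10)

        l_rr = ((e / 3) ** 10) * ((1 - e) ** 10)
        l_ra = (0.5 * (1 - e) + 0.5 * e / 3) ** 20
        l_aa = ((1 - e) ** 10) * ((e / 3) ** 10)
        p_rr = l_rr / (l_rr + l_ra + l_aa)
        assert got.qual == pytest.approx(-10 * math.log10(p_rr), rel=1e-6)
        assert got.qd == pytest.approx(got.qual / 20, rel=1e-6)
        assert got.mq == 255.0

    def test_pure_variant_hom_alt(self):
        cs = pileup_genotype(self._reads("G" * 15, self.REF["chr1"]), self.REF,
                             error_rate=0.01)
        assert len(cs) == 1
        assert next(iter(cs.calls.values())).genotype == "hom_alt"

    def test_empty_alignments_empty_callset(self):
        assert len(pileup_genotype([], self.REF)) == 0

    def test_likelihood_ranking_sane(self):
        ll = genotype_likelihoods(10, 10, 0.01)
        assert ll["RA"] > ll["RR"] and ll["RA"] > ll["AA"]
        ll = genotype_likelihoods(0, 20, 0.01)
        assert ll["AA"] > ll["RA"] > ll["RR"]


@st.composite
def keysets(draw):
    keys = st.tuples(st.just("chr1"), st.integers(1, 60),
                     st.sampled_from("CGT"))
    return draw(st.lists(keys, unique=True, max_size=25))


def from_keys(keys, scope=("per_cell", "BC1")):
    cs = CallSet(caller="h", scope=scope)
    for chrom, pos, alt in keys:
        ref = "A"
        cs.add(VariantCall(SNVLocus(chrom, pos, ref, alt), qual=200.0,
                           mq=70.0, qd=5.0))
    return cs


class TestSetAlgebra:
    def test_disjoint_intersection_empty(self):
        a = from_keys([("chr1", 1, "G")])
        b = from_keys([("chr1", 2, "G")])
        assert len(intersect_per_cell(a, b)) == 0

    def test_intersection_idempotent(self):
        a = from_keys([("chr1", 1, "G"), ("chr1", 2, "C")])
        assert set(intersect_per_cell(a, a).keys()) == set(a.keys())

    def test_scope_mismatch_rejected(self):
        a = from_keys([("chr1", 1, "G")], scope=("per_cell", "BC1"))
        b = from_keys([("chr1", 1, "G")], scope=("per_cell", "BC2"))
        with pytest.raises(ValueError, match="scope"):
            intersect_per_cell(a, b)

    def test_union_with_empty_is_identity(self):
        a = from_keys([("chr1", 1, "G"), ("chr1", 2, "C")])
        empty = CallSet(caller="e", scope=("pooled",))
        assert set(union_callsets([a, empty]).keys()) == set(a.keys())

    @given(keysets(), keysets())
    @settings(deadline=None, max_examples=100)
    def test_intersection_and_union_match_set_oracle(self, ka, kb):
        a, b = from_keys(ka), from_keys(kb)
        assert set(intersect_per_cell(a, b).keys()) == set(ka) & set(kb)
        assert set(union_callsets([a, b]).keys()) == set(ka) | set(kb)
        # commutativity on keys
        assert set(union_callsets([b, a]).keys()) == \
            set(union_callsets([a, b]).keys())


class TestExcludeRegions:
    def test_bed_coordinate_convention(self, tmp_path):
        bed = tmp_path / "m.bed"
        bed.write_text("chr1\t99\t100\n")
        loci = [SNVLocus("chr1", 99, "A", "G"), SNVLocus("chr1", 100, "A", "G"),
                SNVLocus("chr1", 101, "A", "G")]
        kept = exclude_regions(loci, str(bed))
        assert [l.pos for l in kept] == [99, 101]

    def test_empty_mask_is_identity(self):
        loci = [SNVLocus("chr1", 7, "A", "G")]
        assert exclude_regions(loci, {}) == loci

    def test_malformed_bed_rejected(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("chr1\t50\n")
        with pytest.raises(ValueError, match="malformed"):
            exclude_regions([], str(bed))

    @given(
        st.lists(st.integers(1, 200), unique=True, max_size=50),
        st.lists(st.tuples(st.integers(0, 190), st.integers(1, 20)),
                 max_size=10),
    )
    @settings(deadline=None, max_examples=100)
    def test_matches_interval_scan_oracle(self, positions, raw_intervals):
        from intervaltree import IntervalTree

        tree = IntervalTree()
        intervals = [(s, s + w) for s, w in raw_intervals]
        for s, e in intervals:
            tree[s:e] = True
        loci = [SNVLocus("chr1", p, "A", "G") for p in sorted(positions)]
        kept = exclude_regions(loci, {"chr1": tree})
        oracle = [
            l for l in loci
            if not any(s <= l.pos - 1 < e for s, e in intervals)
        ]
        assert kept == oracle


class TestIdentifyScesnvs:
    def test_empty_pooled_union_returns_per_cell_union(self):
        a = from_keys([("chr1", 1, "G")], scope=("per_cell", "BC1"))
        b = from_keys([("chr1", 2, "C")], scope=("per_cell", "BC2"))
        empty = CallSet(caller="u", scope=("pooled",))
        report = identify_scesnvs([a, b], empty)
        assert {k for k in report.snvs} == {("chr1", 1, "G"), ("chr1", 2, "C")}

    def test_pooled_snv_never_scesnv(self):
        a = from_keys([("chr1", 1, "G"), ("chr1", 2, "C")],
                      scope=("per_cell", "BC1"))
        pooled = from_keys([("chr1", 1, "G")], scope=("pooled",))
        report = identify_scesnvs([a], pooled)
        assert set(report.snvs) == {("chr1", 2, "C")}

    def test_no_per_cell_sets_is_error(self):
        with pytest.raises(ValueError):
            identify_scesnvs([], CallSet(caller="u", scope=("pooled",)))

    @given(
        st.lists(keysets(), min_size=1, max_size=6),
        keysets(),
    )
    @settings(deadline=None, max_examples=60)
    def test_matches_set_algebra_oracle_and_disjointness(self, per_cell_keys,
                                                         pooled_keys):
        per_cell = [
            from_keys(keys, scope=("per_cell", f"BC{i}"))
            for i, keys in enumerate(per_cell_keys)
        ]
        pooled = from_keys(pooled_keys, scope=("pooled",))
        report = identify_scesnvs(per_cell, pooled)
        oracle = set().union(*map(set, per_cell_keys)) - set(pooled_keys)
        assert set(report.snvs) == oracle
        # disjointness invariant
        assert not (set(report.snvs) & set(pooled.keys()))
        # carrier counts match brute force
        for key in report.snvs:
            n = sum(key in set(keys) for keys in per_cell_keys)
            assert len(report.carriers[key]) == n

    @given(keysets(), keysets(), keysets())
    @settings(deadline=None, max_examples=60)
    def test_enlarging_pooled_union_never_adds_scesnvs(self, ka, kp, kextra):
        a = from_keys(ka, scope=("per_cell", "BC1"))
        small = from_keys(kp, scope=("pooled",))
        big = from_keys(list(set(kp) | set(kextra)), scope=("pooled",))
        r_small = identify_scesnvs([a], small)
        r_big = identify_scesnvs([a], big)
        assert set(r_big.snvs) <= set(r_small.snvs)


class TestCarriersHistogram:
    def _report(self, carrier_counts, n_cells=10):
        report = callset.SceSNVReport(n_cells=n_cells)
        for i, c in enumerate(carrier_counts):
            loc = SNVLocus("chr1", i + 1, "A", "G")
            report.snvs[loc.key] = loc
            report.carriers[loc.key] = [f"BC{j}" for j in range(c)]
        return report

    def test_all_single_cell(self):
        hist = carriers_histogram(self._report([1] * 7))
        assert hist["histogram"] == {1: 7}
        assert hist["frac_ge_k"] == 0.0

    def test_fraction_with_two_or_more(self):
        hist = carriers_histogram(self._report([1] * 7 + [2] * 3))
        assert hist["n_ge_k"] == 3
        assert hist["frac_ge_k"] == pytest.approx(0.30)
        assert hist["max_carrier_fraction"] == pytest.approx(0.2)

    def test_empty_report_rejected(self):
        with pytest.raises(ValueError):
            carriers_histogram(self._report([]))
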