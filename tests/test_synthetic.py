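"""Synthetic generator: determinism, gene-model validity, planting rules,
allele sampling, and expression effects."""


import numpy as np
import pytest
from Bio.Seq import Seq

from scesnv import synthetic
from scesnv.genemodel import GeneModel
from scesnv.loci import SNVLocus, revcomp
from scesnv.synthetic import SimConfig


class TestMakeReference:
    def test_deterministic_for_fixed_seed(self):
        ref_a, gm_a = synthetic.make_reference(1, 100_000, 5, seed=1)
        ref_b, gm_b = synthetic.make_reference(1, 100_000, 5, seed=1)
        assert ref_a == ref_b
        assert [
            (g.gene_id, g.chrom, g.strand, g.coding,
             [(iv.start, iv.end) for iv in g.exons],
             [(iv.start, iv.end) for iv in g.cds])
            for g in gm_a
        ] == [
            (g.gene_id, g.chrom, g.strand, g.coding,
             [(iv.start, iv.end) for iv in g.exons],
             [(iv.start, iv.end) for iv in g.cds])
            for g in gm_b
        ]

    def test_cds_frame_and_translation(self, tiny_reference):
        """Total CDS length is a multiple of 3, starts ATG, and the
        translated reference CDS has no internal stop codons."""
        reference, gene_model = tiny_reference
        coding = [g for g in gene_model if g.coding]
        assert coding
        for g in coding:
            assert sum(len(iv) for iv in g.cds) % 3 == 0
            for iv in g.cds:
                assert len(iv) % 3 == 0
            cds = g.cds_sequence(reference)
            assert cds.startswith("ATG")
            aa = str(Seq(cds).translate())
            assert aa.endswith("*")
            assert "*" not in aa[:-1]

    def test_single_gene_intervals_disjoint_and_in_bounds(self):
        reference, gene_model = synthetic.make_reference(
            1, 4000, 1, seed=2, noncoding_fraction=0.0
        )
        (gene,) = list(gene_model)
        intervals = gene.exons + gene.cds + gene.utr5 + gene.utr3
        for iv in intervals:
            assert 1 <= iv.start <= iv.end <= 4000
        # exons are mutually disjoint; cds/utr5/utr3 partition the exons
        exon_pos = set()
        for iv in gene.exons:
            span = set(range(iv.start, iv.end + 1))
            assert not (span & exon_pos)
            exon_pos |= span
        feat_pos = []
        for group in (gene.cds, gene.utr5, gene.utr3):
            for iv in group:
                feat_pos.extend(range(iv.start, iv.end + 1))
        assert len(feat_pos) == len(set(feat_pos))
        assert set(feat_pos) == exon_pos

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="pack"):
            synthetic.make_reference(1, 3000, 10, seed=1)

    def test_minus_strand_cds_reads_from_reverse_complement(self):
        reference, gene_model = synthetic.make_reference(2, 100_000, 12, seed=7)
        minus = [g for g in gene_model if g.coding and g.strand == "-"]
        assert minus
        g = minus[0]
        raw = "".join(
            reference[g.chrom][iv.start - 1 : iv.end] for iv in g.cds
        )
        assert g.cds_sequence(reference) == revcomp(raw)


class TestBarcodes:
    def test_pairwise_hamming_distance_at_least_two(self):
        bcs = synthetic.make_barcodes(100, length=16, seed=5)
        assert len(set(bcs)) == 100
        arr = np.array([[ord(c) for c in bc] for bc in bcs])
        for i in range(len(arr)):
            d = (arr[i] != arr[i + 1 :]).sum(axis=1)
            assert (d >= 2).all()


class TestPlantVariants:
    def test_zero_carrier_fraction_rejected(self, tiny_reference):
        reference, gene_model = tiny_reference
        with pytest.raises(ValueError):
            synthetic.plant_variants(reference, gene_model, n_cells=50,
                                     carrier_fraction=0.0, seed=1)
        with pytest.raises(ValueError):
            synthetic.plant_variants(reference, gene_model, n_cells=50,
                                     carrier_fraction=0.001, seed=1)

    def test_exact_carrier_counts_without_replacement(self, tiny_reference):
        reference, gene_model = tiny_reference
        truth = synthetic.plant_variants(
            reference, gene_model, n_cells=500, n_somatic=10,
            carrier_fraction=0.02, seed=3,
        )
        for v in truth.somatic:
            assert len(v.carriers) == 10

    def test_planted_stop_category_against_codon_oracle(self, tiny_reference):
        """An SNV planted as 'stop' must turn its codon into a stop codon
        under an independent (Biopython) translation."""
        reference, gene_model = tiny_reference
        truth = synthetic.plant_variants(
            reference, gene_model, n_cells=50, n_germline=0, n_somatic=6,
            category_weights={"stop": 1.0}, seed=4,
        )
        assert len(truth.somatic) == 6
        for v in truth.somatic:
            assert v.category == "stop"
            gene = gene_model.get(v.gene_id)
            idx = gene.cds_index_of(v.locus.pos)
            cds = list(gene.cds_sequence(reference))
            base = v.locus.alt if gene.strand == "+" else revcomp(v.locus.alt)
            cds[idx] = base
            aa = str(Seq("".join(cds)).translate())
            ref_aa = str(Seq(gene.cds_sequence(reference)).translate())
            assert aa != ref_aa  # a stop gained or lost somewhere
            ci = idx // 3
            assert aa[ci] == "*" or ref_aa[ci] == "*"

    def test_germline_and_somatic_disjoint_and_carriers_bounded(self, tiny_truth):
        positions = [(v.locus.chrom, v.locus.pos)
                     for v in tiny_truth.germline + tiny_truth.somatic]
        assert len(positions) == len(set(positions))
        n = len(tiny_truth.cell_barcodes)
        for v in tiny_truth.somatic:
            assert set(v.carriers) <= set(tiny_truth.cell_barcodes)
            assert len(v.carriers) / n <= tiny_truth.max_carrier_fraction + 1e-9


class TestSimulateReads:
    def test_no_error_no_somatic_hom_ref_reads_match_reference(self):
        reference, gene_model = synthetic.make_reference(1, 30_000, 4, seed=9)
        truth = synthetic.plant_variants(
            reference, gene_model, n_cells=5, n_germline=4, n_somatic=1,
            carrier_fraction=0.2, max_carrier_fraction=0.2, hom_fraction=0.0,
            seed=10,
        )
        truth.somatic = []
        cfg = SimConfig(n_cells=5, error_rate=0.0, seed=11)
        reads = synthetic.simulate_reads(reference, gene_model, truth, cfg)
        mismatches = 0
        for rec in reads.records:
            chrom = reference[rec.reference_name]
            expect = chrom[rec.reference_start : rec.reference_start
                           + rec.query_length]
            for got, want, rpos in zip(rec.query_sequence, expect,
                                       range(rec.reference_start + 1,
                                             rec.reference_start
                                             + rec.query_length + 1)):
                if got != want:
                    mismatches += 1
                    # only planted het alleles may differ, at their own pos
                    assert any(v.locus.pos == rpos for v in truth.germline)
        assert mismatches > 0  # het sites do emit variant alleles

    def test_zero_variant_content_when_all_hom_ref(self):
        reference, gene_model = synthetic.make_reference(1, 30_000, 4, seed=9)
        truth = synthetic.SyntheticTruth(
            germline=[], somatic=[],
            cell_barcodes=synthetic.make_barcodes(5, seed=1),
            gene_baseline={g.gene_id: 5.0 for g in gene_model}, seed=0,
        )
        cfg = SimConfig(n_cells=5, error_rate=0.0, seed=11)
        reads = synthetic.simulate_reads(reference, gene_model, truth, cfg)
        assert reads.records == []  # no loci -> no targeted reads

    def test_identical_read_stream_on_rerun(self, tiny_reference, tiny_truth,
                                            tmp_path):
        reference, gene_model = tiny_reference
        cfg = SimConfig(n_cells=50, seed=3)
        a = synthetic.simulate_reads(reference, gene_model, tiny_truth, cfg)
        b = synthetic.simulate_reads(reference, gene_model, tiny_truth, cfg)
        pa, pb = tmp_path / "a.sam", tmp_path / "b.sam"
        a.write_sam(str(pa))
        b.write_sam(str(pb))
        assert pa.read_bytes() == pb.read_bytes()

    def test_het_site_pooled_variant_fraction_near_half(self):
        """Pooled variant-UMI fraction at a het site stays within 3
        binomial standard errors of 0.5."""
        reference, gene_model = synthetic.make_reference(1, 30_000, 4, seed=9)
        truth = synthetic.plant_variants(
            reference, gene_model, n_cells=120, n_germline=3, n_somatic=1,
            hom_fraction=0.0, seed=12,
        )
        truth.somatic = []
        cfg = SimConfig(n_cells=120, mean_depth=90.0, error_rate=0.0,
                        expr_prob=1.0, seed=13)
        reads = synthetic.simulate_reads(reference, gene_model, truth, cfg)
        for v in truth.germline:
            n_tot = sum(
                reads.coverage[(v.locus, bc)][0]
                for bc in truth.cell_barcodes
                if (v.locus, bc) in reads.coverage
            )
            n_var = sum(
                reads.coverage[(v.locus, bc)][1]
                for bc in truth.cell_barcodes
                if (v.locus, bc) in reads.coverage
            )
            assert n_tot > 5000
            se = (0.25 / n_tot) ** 0.5
            assert abs(n_var / n_tot - 0.5) < 3 * se

    def test_pcr_duplicates_share_cb_ub_and_position(self, tiny_reads):
        """PCR duplicates appear as distinct records with identical
        (CB, UB, position); at the default duplication rate they make up
        a substantial share of the stream."""
        from collections import Counter

        keys = Counter(
            (rec.get_tag("CB"), rec.get_tag("UB"), rec.reference_start)
            for rec in tiny_reads.records
        )
        n_dup = sum(c - 1 for c in keys.values() if c > 1)
        frac = n_dup / len(tiny_reads.records)
        assert 0.1 < frac < 0.4  # dup rate 0.3 -> ~23% of records


class TestExpressionMatrix:
    def test_dimensions_and_error_on_unmapped_effect(self, tiny_truth):
        df = synthetic.simulate_expression_matrix(tiny_truth, n_genes=10,
                                                  n_cells=50, seed=1)
        assert df.shape == (50, 10)
        fake = SNVLocus("chr1", 1, "A", "C")
        with pytest.raises(KeyError):
            synthetic.true_vaf_vector(tiny_truth, fake)
        with pytest.raises(ValueError):
            synthetic.simulate_expression_matrix(
                tiny_truth, n_genes=10, n_cells=50, effect_snvs=[fake],
                beta=1.0, seed=1,
            )

    def test_beta_zero_independent_of_carrier_status(self, tiny_truth):
        a = synthetic.simulate_expression_matrix(tiny_truth, 10, 50,
                                                 beta=0.0, seed=5)
        b = synthetic.simulate_expression_matrix(
            tiny_truth, 10, 50,
            effect_snvs=[tiny_truth.somatic[0].locus], beta=0.0, seed=5,
        )
        assert (a.to_numpy() == b.to_numpy()).all()

    def test_positive_beta_raises_carrier_mean(self):
        reference, gene_model = synthetic.make_reference(1, 200_000, 30,
                                                         seed=20)
        truth = synthetic.plant_variants(
            reference, gene_model, n_cells=400, n_germline=0, n_somatic=5,
            carrier_fraction=0.5, max_carrier_fraction=0.5, seed=21,
        )
        v = truth.somatic[0]
        df = synthetic.simulate_expression_matrix(
            truth, n_genes=30, n_cells=400, effect_snvs=[v.locus], beta=1.0,
            seed=22,
        )
        carriers = [bc for bc in truth.cell_barcodes if bc in v.carriers]
        others = [bc for bc in truth.cell_barcodes if bc not in v.carriers]
        assert df.loc[carriers, v.gene_id].mean() > df.loc[others, v.gene_id].mean()
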