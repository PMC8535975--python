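"""End-to-end orchestration: split -> per-cell calls -> filter ->
intersect -> pooled/bulk union -> sceSNV identification -> counting ->
annotation -> enrichment -> cis-scReQTL.

`run_pipeline` drives the file-based workflow from a single config;
`discover_scesnvs` is the in-memory core reused by tests and the
synthetic end-to-end evaluation; `make_fixture` writes a complete
synthetic input bundle.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import annotation, barcode_split, callset, readcounts, screqtl, synthetic
from .genemodel import GeneModel


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one pipeline run."""

    # inputs
    pooled_sam: str = ""
    reference_fasta: str = ""
    gene_model_tsv: str = ""
    whitelist: Optional[str] = None
    mask_bed: Optional[str] = None
    catalog_tsvs: Sequence[str] = field(default_factory=list)
    expression_dir: Optional[str] = None
    per_cell_vcf_dirs: Sequence[str] = field(default_factory=list)  # one per caller
    pooled_vcfs: Sequence[str] = field(default_factory=list)
    bulk_vcfs: Sequence[str] = field(default_factory=list)
    out_dir: str = "scesnv_out"
    # thresholds (quality filter, counting, regression)
    qual_min: float = 100.0
    mq_min: float = 60.0
    qd_min: float = 2.0
    minR: int = 3
    min_cells: int = 5
    count_min_mapq: int = 255
    min_baseq: int = 20
    dedup_policy: str = "umi_consensus"
    filter_pooled: bool = False
    # stand-in genotyper
    error_rate: float = 0.005
    genotyper_min_depth: int = 5
    posterior_threshold: float = 0.99
    run_lowfrac: bool = True
    # expression QC / covariates
    qc_min_genes: int = 1000
    qc_max_genes: int = 5000
    qc_mito_max: float = 0.10
    n_pcs: int = 15
    fdr_alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


# --------------------------------------------------------------------------
# In-memory discovery core
# --------------------------------------------------------------------------

def discover_scesnvs(
    records,
    reference: dict[str, str],
    whitelist: Optional[set[str]] = None,
    mask=None,
    config: Optional[PipelineConfig] = None,
    extra_pooled_sets: Sequence[callset.CallSet] = (),
    log: Optional[list] = None,
):
    """Split pooled records by barcode, genotype each cell, filter, union
    the pooled calls, and return (SceSNVReport, BarcodeIndex, pooled
    union CallSet)."""
    cfg = config or PipelineConfig()
    log = log if log is not None else []
    index = barcode_split.split_by_barcode(records, whitelist=whitelist)
    log.append(
        dict(stage="split", n_input=index.n_input, n_kept=index.n_kept,
             dropped=dict(index.dropped), n_cells=len(index.groups))
    )

    per_cell_confident = []
    for bc in index.barcodes():
        raw = callset.pileup_genotype(
            index.groups[bc], reference, error_rate=cfg.error_rate,
            min_depth=cfg.genotyper_min_depth,
            posterior_threshold=cfg.posterior_threshold,
            min_baseq=cfg.min_baseq, caller="pileup", scope=("per_cell", bc),
        )
        per_cell_confident.append(
            callset.filter_calls(raw, cfg.qual_min, cfg.mq_min, cfg.qd_min)
        )
    log.append(
        dict(stage="per_cell_calls",
             qual_min=cfg.qual_min, mq_min=cfg.mq_min, qd_min=cfg.qd_min,
             n_confident=sum(len(c) for c in per_cell_confident))
    )

    pooled_records = [r for bc in index.barcodes() for r in index.groups[bc]]
    pooled_raw = callset.pileup_genotype(
        pooled_records, reference, error_rate=cfg.error_rate,
        min_depth=cfg.genotyper_min_depth,
        posterior_threshold=cfg.posterior_threshold,
        min_baseq=cfg.min_baseq, caller="pileup", scope=("pooled",),
    )
    pooled_sets = [pooled_raw, *extra_pooled_sets]
    if cfg.filter_pooled:
        pooled_sets = [
            callset.filter_calls(cs, cfg.qual_min, cfg.mq_min, cfg.qd_min)
            for cs in pooled_sets
        ]
    union = callset.union_callsets(pooled_sets)
    log.append(dict(stage="pooled_union", n_calls=len(union),
                    filter_pooled=cfg.filter_pooled))

    lowfrac = None
    if cfg.run_lowfrac:
        lowfrac = callset.lowfrac_pooled_caller(
            pooled_records, reference, error_rate=cfg.error_rate,
            min_baseq=cfg.min_baseq,
        )
        log.append(dict(stage="lowfrac_caller", n_calls=len(lowfrac)))

    report = callset.identify_scesnvs(
        per_cell_confident, union, mask=mask, lowfrac_callset=lowfrac
    )
    log.append(dict(stage="scesnv", n_scesnvs=len(report)))
    return report, index, union


def evaluate_recovery(
    report: callset.SceSNVReport,
    truth: synthetic.SyntheticTruth,
    coverage: dict,
    min_depth: int = 5,
) -> dict:
    """Score a sceSNV report against planted somatic truth.

    Sensitivity is computed over somatic SNVs expressed at >= min_depth
    UMIs in at least one carrier cell; precision counts any recovered
    sceSNV at a non-planted-somatic site as a false positive.
    """
    expressed = []
    for v in truth.somatic:
        if any(
            coverage.get((v.locus, bc), (0, 0))[0] >= min_depth
            for bc in v.carriers
        ):
            expressed.append(v.locus)
    recovered_keys = set(report.snvs)
    tp = [loc for loc in expressed if loc.key in recovered_keys]
    planted_keys = {v.locus.key for v in truth.somatic}
    fp = [loc for loc in report.loci() if loc.key not in planted_keys]
    sens = len(tp) / len(expressed) if expressed else float("nan")
    prec = (len(report) - len(fp)) / len(report) if len(report) else float("nan")
    return dict(
        n_planted=len(truth.somatic), n_expressed=len(expressed),
        n_recovered=len(report), n_true_positive=len(tp),
        n_false_positive=len(fp), sensitivity=sens, precision=prec,
    )


# --------------------------------------------------------------------------
# File-based pipeline
# --------------------------------------------------------------------------

def _read_per_cell_vcfs(dirs: Sequence[str], cfg: PipelineConfig):
    """One filtered, caller-intersected CallSet per barcode from VCF dirs
    named <barcode>.vcf (one directory per caller)."""
    per_caller: list[dict[str, callset.CallSet]] = []
    for d in dirs:
        sets = {}
        for fn in sorted(os.listdir(d)):
            if not fn.endswith(".vcf"):
                continue
            bc = fn[: -len(".vcf")]
            cs = callset.read_callset(
                os.path.join(d, fn), caller=os.path.basename(d.rstrip("/")),
                scope=("per_cell", bc),
            )
            sets[bc] = callset.filter_calls(cs, cfg.qual_min, cfg.mq_min,
                                            cfg.qd_min)
        per_caller.append(sets)
    barcodes = set(per_caller[0])
    for sets in per_caller[1:]:
        barcodes &= set(sets)
    out = []
    for bc in sorted(barcodes):
        confident = per_caller[0][bc]
        for sets in per_caller[1:]:
            confident = callset.intersect_per_cell(confident, sets[bc])
        out.append(confident)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow from files; returns the summary dict and
    writes stage artifacts under ``config.out_dir``."""
    os.makedirs(config.out_dir, exist_ok=True)
    log: list[dict] = [dict(stage="config", **asdict(config))]
    summary: dict = {}

    reference = synthetic.read_fasta(config.reference_fasta)
    gene_model = GeneModel.from_tsv(config.gene_model_tsv)
    whitelist = (barcode_split.load_whitelist(config.whitelist)
                 if config.whitelist else None)
    mask = (callset.read_bed_mask(config.mask_bed)
            if config.mask_bed else None)

    if config.per_cell_vcf_dirs:
        per_cell_confident = _read_per_cell_vcfs(config.per_cell_vcf_dirs,
                                                 config)
        pooled_sets = [
            callset.read_callset(p, caller=f"pooled{i}", scope=("pooled",))
            for i, p in enumerate(config.pooled_vcfs)
        ] + [
            callset.read_callset(p, caller=f"bulk{i}", scope=("bulk",))
            for i, p in enumerate(config.bulk_vcfs)
        ]
        if config.filter_pooled:
            pooled_sets = [
                callset.filter_calls(cs, config.qual_min, config.mq_min,
                                     config.qd_min)
                for cs in pooled_sets
            ]
        union = callset.union_callsets(pooled_sets)
        report = callset.identify_scesnvs(per_cell_confident, union, mask=mask)
        index = barcode_split.split_by_barcode(config.pooled_sam,
                                               whitelist=whitelist)
        log.append(dict(stage="scesnv", n_scesnvs=len(report)))
    else:
        extra = [
            callset.read_callset(p, caller=f"bulk{i}", scope=("bulk",))
            for i, p in enumerate(config.bulk_vcfs)
        ]
        report, index, union = discover_scesnvs(
            config.pooled_sam, reference, whitelist=whitelist, mask=mask,
            config=config, extra_pooled_sets=extra, log=log,
        )
    report.to_tsv(os.path.join(config.out_dir, "scesnvs.tsv"))
    summary["n_scesnvs"] = len(report)
    summary["n_cells"] = len(index.groups)
    summary["n_pooled_union"] = len(union)

    if len(report):
        hist = callset.carriers_histogram(report)
        summary["carriers"] = hist
        with open(os.path.join(config.out_dir, "carriers_histogram.json"),
                  "w") as fh:
            json.dump(hist, fh, indent=1)

    # counting / VAF_RNA at the sceSNV loci over the pooled kept stream
    pooled_records = [r for bc in index.barcodes() for r in index.groups[bc]]
    matrix = readcounts.tabulate_counts(
        pooled_records, report.loci(), min_mapq=config.count_min_mapq,
        min_baseq=config.min_baseq, dedup_policy=config.dedup_policy,
        minR=config.minR,
    )
    matrix.to_tsv(os.path.join(config.out_dir, "cell_snv_counts.tsv"))
    log.append(dict(stage="counts", minR=config.minR,
                    dedup_policy=config.dedup_policy,
                    n_pairs=len(matrix.counts)))

    # annotation + enrichment
    if len(report):
        catalogs = [annotation.Catalog.from_tsv(p) for p in config.catalog_tsvs]
        novelty = annotation.classify_novelty(report.loci(), catalogs)
        novelty.to_csv(os.path.join(config.out_dir, "novelty.tsv"), sep="\t",
                       index=False)
        summary["pct_novel"] = novelty.attrs["pct_novel"]
        sce_counts = annotation.category_table(report.loci(), gene_model,
                                               reference)
        summary["sce_categories"] = sce_counts
        psnv_filtered = callset.filter_calls(union, config.qual_min,
                                             config.mq_min, config.qd_min)
        if mask is not None:
            psnv_filtered = callset.exclude_regions(psnv_filtered, mask)
        if len(psnv_filtered):
            p_counts = annotation.category_table(psnv_filtered.loci(),
                                                 gene_model, reference)
            comparison = annotation.compare_categories(sce_counts, p_counts)
            comparison.to_csv(
                os.path.join(config.out_dir, "category_comparison.tsv"),
                sep="\t",
            )
        log.append(dict(stage="annotation", pct_novel=summary["pct_novel"]))

    # cis-scReQTL
    if config.expression_dir:
        expr = synthetic.read_expression_mtx(config.expression_dir)
        expr, qc = screqtl.qc_cells(
            expr, min_genes=config.qc_min_genes, max_genes=config.qc_max_genes,
            mito_max=config.qc_mito_max,
        )
        norm = screqtl.normalize(expr)
        covs = screqtl.pca_covariates(
            norm, k=min(config.n_pcs, min(norm.shape) - 1)
        )
        gene_map = {}
        for loc in report.loci():
            genes = gene_model.genes_at(loc.chrom, loc.pos)
            gene_map[loc] = genes[0].gene_id if genes else None
        results, tally = screqtl.cis_screqtl(
            matrix, norm, covs, gene_map, min_cells=config.min_cells,
            fdr_alpha=config.fdr_alpha,
        )
        screqtl.results_to_df(results).to_csv(
            os.path.join(config.out_dir, "screqtl.tsv"), sep="\t", index=False
        )
        summary["screqtl"] = tally
        log.append(dict(stage="screqtl", **{k: v for k, v in tally.items()}))

    with open(os.path.join(config.out_dir, "pipeline_log.json"), "w") as fh:
        json.dump(log, fh, indent=1, default=str)
    with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    return summary


# --------------------------------------------------------------------------
# Fixture generation
# --------------------------------------------------------------------------

SCALES = {
    "tiny": dict(n_chroms=1, chrom_length=80_000, n_genes=10, n_cells=50,
                 n_germline=12, n_somatic=8),
    "small": dict(n_chroms=2, chrom_length=150_000, n_genes=30, n_cells=200,
                  n_germline=40, n_somatic=20),
}


def make_fixture(out_dir: str, scale: str = "tiny", seed: int = 0) -> dict:
    """Write a complete synthetic input bundle (reference, gene model,
    pooled SAM, truth tables, mask, catalogs, expression) plus a ready
    pipeline config; returns the file map."""
    if scale not in SCALES:
        raise ValueError(f"scale must be one of {sorted(SCALES)}")
    p = SCALES[scale]
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)

    reference, gene_model = synthetic.make_reference(
        p["n_chroms"], p["chrom_length"], p["n_genes"], seed=seed
    )
    truth = synthetic.plant_variants(
        reference, gene_model, n_cells=p["n_cells"],
        n_germline=p["n_germline"], n_somatic=p["n_somatic"], seed=seed + 1,
    )
    cfgsim = synthetic.SimConfig(n_cells=p["n_cells"], seed=seed + 2)
    reads = synthetic.simulate_reads(reference, gene_model, truth, cfgsim)
    expr = synthetic.simulate_expression_matrix(
        truth, n_genes=p["n_genes"], n_cells=p["n_cells"], seed=seed + 3
    )

    files = {
        "reference": os.path.join(out_dir, "reference.fa"),
        "gene_model": os.path.join(out_dir, "genes.tsv"),
        "gtf": os.path.join(out_dir, "genes.gtf"),
        "pooled_sam": os.path.join(out_dir, "pooled.sam"),
        "whitelist": os.path.join(out_dir, "barcodes.tsv"),
        "germline": os.path.join(out_dir, "truth_germline.tsv"),
        "somatic": os.path.join(out_dir, "truth_somatic.tsv"),
        "mask": os.path.join(out_dir, "mask.bed"),
        "expression": os.path.join(out_dir, "expression"),
        "config": os.path.join(out_dir, "pipeline.yaml"),
    }
    synthetic.write_fasta(reference, files["reference"])
    gene_model.to_tsv(files["gene_model"])
    gene_model.to_gtf(files["gtf"])
    reads.write_sam(files["pooled_sam"])
    with open(files["whitelist"], "w") as fh:
        fh.writelines(bc + "\n" for bc in truth.cell_barcodes)
    truth.to_tsvs(files["germline"], files["somatic"])
    synthetic.write_expression_mtx(expr, files["expression"])

    # mask: a few intergenic windows away from every planted locus
    planted = {(v.locus.chrom, v.locus.pos)
               for v in truth.germline + truth.somatic}
    with open(files["mask"], "w") as fh:
        for chrom in sorted(reference):
            written = 0
            while written < 3:
                start = int(rng.integers(0, len(reference[chrom]) - 500))
                window = range(start + 1, start + 501)
                if any((chrom, q) in planted for q in window):
                    continue
                fh.write(f"{chrom}\t{start}\t{start + 500}\n")
                written += 1

    catalog_dir = os.path.join(out_dir, "catalogs")
    os.makedirs(catalog_dir, exist_ok=True)
    known_germ = [v.locus for v in truth.germline if v.known]
    known_som = [v.locus for v in truth.somatic if v.known]
    for name, loci in (("dbsnp_like", known_germ), ("cosmic_like", known_som),
                       ("editing_like", [])):
        path = os.path.join(catalog_dir, f"{name}.tsv")
        with open(path, "w") as fh:
            fh.write("#chrom\tpos\tref\talt\n")
            for loc in sorted(loci):
                fh.write(f"{loc.chrom}\t{loc.pos}\t{loc.ref}\t{loc.alt}\n")
        files[name] = path

    config = PipelineConfig(
        pooled_sam=files["pooled_sam"], reference_fasta=files["reference"],
        gene_model_tsv=files["gene_model"], whitelist=files["whitelist"],
        mask_bed=files["mask"],
        catalog_tsvs=[files["dbsnp_like"], files["cosmic_like"],
                      files["editing_like"]],
        expression_dir=files["expression"],
        out_dir=os.path.join(out_dir, "out"),
        qc_min_genes=1, qc_max_genes=10_000, qc_mito_max=1.0,
        n_pcs=5, min_cells=5, seed=seed,
    )
    config.to_yaml(files["config"])
    return files
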