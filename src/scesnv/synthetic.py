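"""Synthetic barcoded scRNA-seq data with planted variants.

The generator emulates the statistical structure the discovery pipeline
assumes in a droplet 3' scRNA-seq experiment:

* a miniature reference with genes carrying 5'UTR / multi-exon CDS /
  3'UTR structure (plus non-coding genes),
* germline heterozygous SNVs whose expressed allele fraction is
  binomially centered at 0.5,
* somatic SNVs carried by a small fraction of cells (default at most 5%),
* UMI-tagged reads with sequencing error and PCR duplication,
* a negative-binomial cell x gene expression matrix in which selected
  SNVs shift the log-mean of their harboring gene.

Everything is deterministic for a fixed seed, and every planted quantity
is recorded in a truth table so downstream stages can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation import CATEGORIES, classify_function
from .genemodel import Gene, GeneModel, Interval
from .loci import BASES, SNVLocus, revcomp

_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = [
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in _STOPS
]


# --------------------------------------------------------------------------
# Configuration and truth containers
# --------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Read-simulation settings.

    mean_depth is the expected number of UMIs covering an expressed locus
    in one cell; error_rate is the per-base substitution probability;
    umi_dup_rate is the probability that a UMI emits one extra PCR
    duplicate read; expr_prob is the probability that a given cell
    expresses a given locus at all.
    """

    n_cells: int = 50
    mean_depth: float = 30.0
    error_rate: float = 0.005
    umi_dup_rate: float = 0.3
    read_length: int = 90
    expr_prob: float = 0.9
    somatic_vaf: float = 0.5
    umi_length: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("error_rate", "umi_dup_rate", "expr_prob", "somatic_vaf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_cells", "read_length", "umi_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")


@dataclass(frozen=True)
class GermlineVariant:
    locus: SNVLocus
    genotype: str  # "het" | "hom"
    gene_id: Optional[str]
    category: str
    known: bool


@dataclass(frozen=True)
class SomaticVariant:
    locus: SNVLocus
    carriers: frozenset
    gene_id: Optional[str]
    category: str
    known: bool
    vaf: float = 0.5  # expressed VAF in carrier cells


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset."""

    germline: list[GermlineVariant]
    somatic: list[SomaticVariant]
    cell_barcodes: list[str]
    gene_baseline: dict[str, float]
    seed: int
    max_carrier_fraction: float = 0.05

    def __post_init__(self) -> None:
        cells = set(self.cell_barcodes)
        n = len(self.cell_barcodes)
        positions = set()
        for v in self.germline + self.somatic:
            key = (v.locus.chrom, v.locus.pos)
            if key in positions:
                raise ValueError(f"duplicate planted position {key}")
            positions.add(key)
        for v in self.somatic:
            if not v.carriers <= cells:
                raise ValueError(f"carrier not in cell_barcodes for {v.locus}")
            if len(v.carriers) / n > self.max_carrier_fraction + 1e-9:
                raise ValueError(
                    f"{v.locus}: carrier fraction {len(v.carriers)/n:.3f} exceeds "
                    f"maximum {self.max_carrier_fraction}"
                )

    @property
    def somatic_loci(self) -> list[SNVLocus]:
        return [v.locus for v in self.somatic]

    @property
    def germline_loci(self) -> list[SNVLocus]:
        return [v.locus for v in self.germline]

    def all_loci(self) -> list[SNVLocus]:
        return sorted(self.germline_loci + self.somatic_loci)

    def to_tsvs(self, germline_path: str, somatic_path: str) -> None:
        with open(germline_path, "w") as fh:
            fh.write("#chrom\tpos\tref\talt\tgenotype\tgene_id\tcategory\tknown\n")
            for v in self.germline:
                fh.write(
                    f"{v.locus.chrom}\t{v.locus.pos}\t{v.locus.ref}\t{v.locus.alt}"
                    f"\t{v.genotype}\t{v.gene_id or '.'}\t{v.category}\t{int(v.known)}\n"
                )
        with open(somatic_path, "w") as fh:
            fh.write(
                "#chrom\tpos\tref\talt\tvaf\tgene_id\tcategory\tknown"
                "\tn_carriers\tcarrier_barcodes\n"
            )
            for v in self.somatic:
                bars = ",".join(sorted(v.carriers))
                fh.write(
                    f"{v.locus.chrom}\t{v.locus.pos}\t{v.locus.ref}\t{v.locus.alt}"
                    f"\t{v.vaf}\t{v.gene_id or '.'}\t{v.category}\t{int(v.known)}"
                    f"\t{len(v.carriers)}\t{bars}\n"
                )

    def known_keys(self) -> set:
        return {
            (v.locus.chrom, v.locus.pos, v.locus.ref, v.locus.alt)
            for v in self.germline + self.somatic
            if v.known
        }


# --------------------------------------------------------------------------
# Reference + gene model
# --------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.asarray(BASES)[rng.integers(0, 4, size=n)])


def _build_coding_gene(rng: np.random.Generator, gene_id: str, chrom: str,
                       strand: str) -> tuple[str, Gene]:
    """Local (offset-0) sequence and intervals for one coding gene."""
    utr5_len = int(rng.integers(60, 151))
    utr3_len = int(rng.integers(200, 401))
    n_exons = int(rng.integers(2, 4))
    # >= 40 codons per CDS exon keeps every exon longer than a read
    codons_per_exon = rng.integers(40, 81, size=n_exons)
    n_codons = int(codons_per_exon.sum())
    coding = (
        "ATG"
        + "".join(
            np.asarray(_NONSTOP_CODONS)[
                rng.integers(0, len(_NONSTOP_CODONS), size=n_codons - 2)
            ]
        )
        + _STOPS[int(rng.integers(0, 3))]
    )
    intron_lens = [int(rng.integers(80, 301)) for _ in range(n_exons - 1)]

    # assemble local layout 5'->3': [utr5+cds1] intron [cds2] ... [cdsN+utr3]
    seq_parts: list[str] = []
    exons, cds, utr5, utr3 = [], [], [], []
    cursor = 1
    cds_cursor = 0
    for i in range(n_exons):
        part_len = int(codons_per_exon[i]) * 3
        exon_start = cursor
        if i == 0:
            seq_parts.append(_random_seq(rng, utr5_len))
            utr5.append(Interval(cursor, cursor + utr5_len - 1))
            cursor += utr5_len
        seq_parts.append(coding[cds_cursor : cds_cursor + part_len])
        cds.append(Interval(cursor, cursor + part_len - 1))
        cursor += part_len
        cds_cursor += part_len
        if i == n_exons - 1:
            seq_parts.append(_random_seq(rng, utr3_len))
            utr3.append(Interval(cursor, cursor + utr3_len - 1))
            cursor += utr3_len
        exons.append(Interval(exon_start, cursor - 1))
        if i < n_exons - 1:
            seq_parts.append(_random_seq(rng, intron_lens[i]))
            cursor += intron_lens[i]
    local_seq = "".join(seq_parts)
    length = len(local_seq)

    if strand == "-":
        local_seq = revcomp(local_seq)
        flip = lambda iv: Interval(length - iv.end + 1, length - iv.start + 1)
        exons = [flip(iv) for iv in exons]
        cds = [flip(iv) for iv in cds]
        utr5 = [flip(iv) for iv in utr5]
        utr3 = [flip(iv) for iv in utr3]

    gene = Gene(gene_id=gene_id, chrom=chrom, strand=strand, coding=True,
                exons=exons, cds=cds, utr5=utr5, utr3=utr3)
    return local_seq, gene


def _build_noncoding_gene(rng: np.random.Generator, gene_id: str, chrom: str,
                          strand: str) -> tuple[str, Gene]:
    n_exons = int(rng.integers(1, 3))
    exon_lens = [int(rng.integers(150, 401)) for _ in range(n_exons)]
    intron_lens = [int(rng.integers(80, 301)) for _ in range(n_exons - 1)]
    seq_parts, exons = [], []
    cursor = 1
    for i in range(n_exons):
        seq_parts.append(_random_seq(rng, exon_lens[i]))
        exons.append(Interval(cursor, cursor + exon_lens[i] - 1))
        cursor += exon_lens[i]
        if i < n_exons - 1:
            seq_parts.append(_random_seq(rng, intron_lens[i]))
            cursor += intron_lens[i]
    gene = Gene(gene_id=gene_id, chrom=chrom, strand=strand, coding=False,
                exons=exons)
    return "".join(seq_parts), gene


def make_reference(
    n_chroms: int,
    chrom_length: int,
    n_genes: int,
    seed: int,
    noncoding_fraction: float = 0.15,
) -> tuple[dict[str, str], GeneModel]:
    """Build a random reference and a packed, non-overlapping gene model.

    Genes are laid out left to right with random intergenic gaps; raises
    ValueError when the requested genes cannot be packed.
    """
    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{i + 1}" for i in range(n_chroms)]
    sequences = {name: list(_random_seq(rng, chrom_length)) for name in chrom_names}
    cursors = {name: int(rng.integers(200, 500)) for name in chrom_names}

    # evenly spaced non-coding genes, so any model with a few genes and a
    # positive fraction is guaranteed to contain some
    n_noncoding = int(round(noncoding_fraction * n_genes))
    noncoding_ids = (
        set(np.linspace(0, n_genes - 1, n_noncoding).round().astype(int))
        if n_noncoding else set()
    )

    genes: list[Gene] = []
    for gi in range(n_genes):
        chrom = chrom_names[gi % n_chroms]
        gene_id = f"gene{gi:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        if gi in noncoding_ids:
            local_seq, gene = _build_noncoding_gene(rng, gene_id, chrom, strand)
        else:
            local_seq, gene = _build_coding_gene(rng, gene_id, chrom, strand)
        offset = cursors[chrom]  # 0-based genomic start of the gene segment
        if offset + len(local_seq) > chrom_length:
            raise ValueError(
                f"cannot pack {n_genes} genes into {n_chroms} x {chrom_length} bp"
            )
        sequences[chrom][offset : offset + len(local_seq)] = local_seq
        shift = lambda iv: Interval(iv.start + offset, iv.end + offset)
        gene = Gene(
            gene_id=gene.gene_id, chrom=chrom, strand=gene.strand,
            coding=gene.coding,
            exons=[shift(iv) for iv in gene.exons],
            cds=[shift(iv) for iv in gene.cds],
            utr5=[shift(iv) for iv in gene.utr5],
            utr3=[shift(iv) for iv in gene.utr3],
        )
        genes.append(gene)
        cursors[chrom] = offset + len(local_seq) + int(rng.integers(200, 500))

    reference = {name: "".join(seq) for name, seq in sequences.items()}
    return reference, GeneModel(genes)


def write_fasta(reference: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(reference):
            fh.write(f">{name}\n")
            seq = reference[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    out: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                out[name] = []
            elif line and name is not None:
                out[name].append(line.upper())
    return {k: "".join(v) for k, v in out.items()}


# --------------------------------------------------------------------------
# Barcodes
# --------------------------------------------------------------------------

def make_barcodes(n: int, length: int = 16,
                  rng: Optional[np.random.Generator] = None,
                  seed: int = 0) -> list[str]:
    """Distinct fixed-length barcodes with pairwise Hamming distance >= 2.

    The last base is a checksum (sum of base indices mod 4), so two
    distinct barcodes can never differ at a single position.
    """
    if length < 2:
        raise ValueError("barcode length must be >= 2")
    rng = rng if rng is not None else np.random.default_rng(seed)
    base_arr = np.asarray(BASES)
    out: list[str] = []
    seen = set()
    while len(out) < n:
        body = rng.integers(0, 4, size=length - 1)
        bc = "".join(base_arr[body]) + BASES[int(body.sum()) % 4]
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


# --------------------------------------------------------------------------
# Variant planting
# --------------------------------------------------------------------------

DEFAULT_SOMATIC_WEIGHTS = {
    "3-prime-UTR": 0.50,
    "missense": 0.20,
    "synonymous": 0.10,
    "5-prime-UTR": 0.10,
    "stop": 0.05,
    "non-coding-exon": 0.05,
}


def _candidate_positions(gene_model: GeneModel, category: str,
                         chrom_lengths: dict[str, int],
                         rng: np.random.Generator) -> tuple[str, int]:
    """Draw one random genomic position plausible for the category."""
    if category in ("stop", "missense", "synonymous"):
        genes = [g for g in gene_model if g.coding]
        g = genes[int(rng.integers(0, len(genes)))]
        iv = g.cds[int(rng.integers(0, len(g.cds)))]
        return g.chrom, int(rng.integers(iv.start, iv.end + 1))
    if category == "splice":
        genes = [g for g in gene_model if g.introns]
        g = genes[int(rng.integers(0, len(genes)))]
        intron = g.introns[int(rng.integers(0, len(g.introns)))]
        edge = [intron.start, intron.start + 1, intron.end - 1, intron.end]
        return g.chrom, int(edge[int(rng.integers(0, 4))])
    if category == "intron":
        genes = [g for g in gene_model if g.introns]
        g = genes[int(rng.integers(0, len(genes)))]
        intron = g.introns[int(rng.integers(0, len(g.introns)))]
        return g.chrom, int(rng.integers(intron.start, intron.end + 1))
    if category == "3-prime-UTR":
        pools = [(g.chrom, iv) for g in gene_model for iv in g.utr3]
    elif category == "5-prime-UTR":
        pools = [(g.chrom, iv) for g in gene_model for iv in g.utr5]
    elif category == "non-coding-exon":
        pools = [(g.chrom, iv) for g in gene_model if not g.coding
                 for iv in g.exons]
    elif category == "intergenic":
        chrom = sorted(chrom_lengths)[int(rng.integers(0, len(chrom_lengths)))]
        return chrom, int(rng.integers(1, chrom_lengths[chrom] + 1))
    else:
        raise ValueError(f"unknown category {category!r}")
    if not pools:
        raise ValueError(f"gene model has no positions for category {category!r}")
    chrom, iv = pools[int(rng.integers(0, len(pools)))]
    return chrom, int(rng.integers(iv.start, iv.end + 1))


def plant_variants(
    reference: dict[str, str],
    gene_model: GeneModel,
    n_cells: int,
    n_germline: int = 20,
    n_somatic: int = 10,
    carrier_fraction: float = 0.05,
    category_weights: Optional[dict[str, float]] = None,
    known_fraction: float = 0.3,
    hom_fraction: float = 0.2,
    max_carrier_fraction: float = 0.05,
    min_spacing: int = 100,
    barcode_length: int = 16,
    seed: int = 0,
    max_tries: int = 50000,
) -> SyntheticTruth:
    """Plant germline and somatic SNVs and assign somatic carrier cells.

    Germline SNVs land at random exonic positions (heterozygous with
    probability 1 - hom_fraction).  Somatic SNVs are drawn per
    ``category_weights`` by rejection sampling until the classified
    functional category matches the requested one.  All planted loci are
    at least ``min_spacing`` bp apart so reads simulated around one locus
    never overlap another.
    """
    if carrier_fraction <= 0 or carrier_fraction * n_cells < 1:
        raise ValueError(
            f"carrier_fraction {carrier_fraction} x {n_cells} cells yields "
            "no carriers"
        )
    n_carriers = max(1, int(round(carrier_fraction * n_cells)))
    weights = dict(category_weights or DEFAULT_SOMATIC_WEIGHTS)
    for cat in weights:
        if cat not in CATEGORIES:
            raise ValueError(f"unknown category {cat!r}")
    rng = np.random.default_rng(seed)
    barcodes = make_barcodes(n_cells, length=barcode_length, rng=rng)
    chrom_lengths = {c: len(s) for c, s in reference.items()}

    taken: dict[str, list[int]] = {c: [] for c in reference}

    def spaced(chrom: str, pos: int) -> bool:
        return all(abs(pos - p) >= min_spacing for p in taken[chrom])

    def draw_snv(target_category: Optional[str], exonic_only: bool):
        for _ in range(max_tries):
            if target_category is None:
                g = gene_model.genes[int(rng.integers(0, len(gene_model)))]
                iv = g.exons[int(rng.integers(0, len(g.exons)))]
                chrom, pos = g.chrom, int(rng.integers(iv.start, iv.end + 1))
            else:
                chrom, pos = _candidate_positions(
                    gene_model, target_category, chrom_lengths, rng
                )
            if not spaced(chrom, pos):
                continue
            ref = reference[chrom][pos - 1]
            if ref not in BASES:
                continue
            alts = [b for b in BASES if b != ref]
            alt = alts[int(rng.integers(0, 3))]
            snv = SNVLocus(chrom, pos, ref, alt)
            cat = classify_function(snv, gene_model, reference)
            if target_category is not None and cat != target_category:
                continue
            if exonic_only and cat in ("intron", "intergenic", "splice"):
                continue
            taken[chrom].append(pos)
            genes = gene_model.genes_at(chrom, pos)
            gene_id = genes[0].gene_id if genes else None
            return snv, cat, gene_id
        raise ValueError(
            f"could not place an SNV of category {target_category!r} after "
            f"{max_tries} tries"
        )

    germline = []
    for _ in range(n_germline):
        snv, cat, gene_id = draw_snv(None, exonic_only=True)
        genotype = "hom" if rng.random() < hom_fraction else "het"
        known = bool(rng.random() < known_fraction)
        germline.append(GermlineVariant(snv, genotype, gene_id, cat, known))

    cats = sorted(weights)
    probs = np.array([weights[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    somatic = []
    for _ in range(n_somatic):
        cat = cats[int(rng.choice(len(cats), p=probs))]
        snv, cat, gene_id = draw_snv(cat, exonic_only=False)
        carriers = frozenset(
            np.asarray(barcodes)[
                rng.choice(n_cells, size=n_carriers, replace=False)
            ]
        )
        known = bool(rng.random() < known_fraction)
        somatic.append(SomaticVariant(snv, carriers, gene_id, cat, known))

    baseline = {
        g.gene_id: float(rng.lognormal(mean=math.log(8.0), sigma=0.6))
        for g in gene_model
    }
    return SyntheticTruth(
        germline=germline, somatic=somatic, cell_barcodes=barcodes,
        gene_baseline=baseline, seed=seed,
        max_carrier_fraction=max(max_carrier_fraction, carrier_fraction),
    )


# --------------------------------------------------------------------------
# Read simulation
# --------------------------------------------------------------------------

@dataclass
class SimulatedReads:
    """Coordinate-sorted barcoded alignments plus per-(locus, cell) truth."""

    header: pysam.AlignmentHeader
    records: list  # of pysam.AlignedSegment
    # (locus, barcode) -> (n_umis, n_var_umis) before sequencing error
    coverage: dict = field(default_factory=dict)

    def write_sam(self, path: str) -> None:
        with pysam.AlignmentFile(path, "w", header=self.header) as out:
            for rec in self.records:
                out.write(rec)


def _containing_exon(gene_model: GeneModel, locus: SNVLocus) -> Optional[Interval]:
    for g in gene_model.genes_at(locus.chrom, locus.pos):
        for iv in g.exons:
            if locus.pos in iv:
                return iv
    return None


def simulate_reads(
    reference: dict[str, str],
    gene_model: GeneModel,
    truth: SyntheticTruth,
    config: SimConfig,
) -> SimulatedReads:
    """Emit UMI-tagged, CB-tagged, coordinate-sorted alignments.

    Reads are generated around each planted exonic locus: for every cell
    expressing the locus, Poisson(mean_depth) UMIs are drawn; each UMI
    picks its allele (Bernoulli(0.5) at het germline sites, the somatic
    VAF in carrier cells, the hom/ref allele otherwise), a start position
    uniform within the containing exon, and per-base errors at
    error_rate.  PCR duplicates share (CB, UB) and position.  Intronic
    and intergenic loci produce no reads (mature mRNA only).
    """
    rng = np.random.default_rng(config.seed)
    chroms = sorted(reference)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": len(reference[c])} for c in chroms],
            "PG": [{"ID": "scesnv-sim", "PN": "scesnv-sim"}],
        }
    )
    tid = {c: i for i, c in enumerate(chroms)}
    L = config.read_length
    base_arr = np.asarray(BASES)

    plan = []  # (locus, p_var per barcode function)
    for v in truth.germline:
        p = 0.5 if v.genotype == "het" else 1.0
        plan.append((v.locus, {None: p}))  # same p for every cell
    for v in truth.somatic:
        plan.append((v.locus, {"carriers": v.carriers, "vaf": v.vaf}))

    raw = []  # (tid, start0, name, seq, flag, cb, ub)
    counter = 0
    coverage = {}
    for locus, spec_ in sorted(plan, key=lambda t: (t[0].chrom, t[0].pos)):
        exon = _containing_exon(gene_model, locus)
        if exon is None or len(exon) < L:
            continue
        lo = max(exon.start, locus.pos - L + 1)
        hi = min(locus.pos, exon.end - L + 1)
        if hi < lo:
            continue
        template = reference[locus.chrom]
        for bc in truth.cell_barcodes:
            if "carriers" in spec_:
                p_var = spec_["vaf"] if bc in spec_["carriers"] else 0.0
            else:
                p_var = spec_[None]
            if rng.random() >= config.expr_prob:
                continue
            n_umis = int(rng.poisson(config.mean_depth))
            if n_umis == 0:
                continue
            n_var = 0
            for _ in range(n_umis):
                is_var = rng.random() < p_var
                n_var += is_var
                umi = "".join(base_arr[rng.integers(0, 4, size=config.umi_length)])
                start = int(rng.integers(lo, hi + 1))  # 1-based
                n_copies = 1 + (rng.random() < config.umi_dup_rate)
                for _copy in range(n_copies):
                    seq = list(template[start - 1 : start - 1 + L])
                    if is_var:
                        seq[locus.pos - start] = locus.alt
                    n_err = int(rng.binomial(L, config.error_rate))
                    if n_err:
                        err_pos = rng.choice(L, size=n_err, replace=False)
                        for ep in err_pos:
                            cur = seq[ep]
                            others = [b for b in BASES if b != cur]
                            seq[ep] = others[int(rng.integers(0, 3))]
                    flag = 16 if rng.random() < 0.5 else 0
                    raw.append(
                        (tid[locus.chrom], start - 1, f"r{counter:08d}",
                         "".join(seq), flag, bc, umi)
                    )
                    counter += 1
            coverage[(locus, bc)] = (n_umis, n_var)

    raw.sort(key=lambda t: (t[0], t[1], t[2]))
    records = []
    for t, start0, name, seq, flag, cb, ub in raw:
        a = pysam.AlignedSegment(header)
        a.query_name = name
        a.reference_id = t
        a.reference_start = start0
        a.mapping_quality = 255
        a.cigarstring = f"{L}M"
        a.flag = flag
        a.query_sequence = seq
        a.query_qualities = pysam.qualitystring_to_array("I" * L)
        a.set_tag("NH", 1)
        a.set_tag("CB", cb)
        a.set_tag("UB", ub)
        records.append(a)
    return SimulatedReads(header=header, records=records, coverage=coverage)


# --------------------------------------------------------------------------
# Expression matrix
# --------------------------------------------------------------------------

def true_vaf_vector(truth: SyntheticTruth, locus: SNVLocus) -> np.ndarray:
    """Per-cell true expressed VAF of a planted SNV, in barcode order."""
    for v in truth.germline:
        if v.locus == locus:
            val = 0.5 if v.genotype == "het" else 1.0
            return np.full(len(truth.cell_barcodes), val)
    for v in truth.somatic:
        if v.locus == locus:
            return np.array(
                [v.vaf if bc in v.carriers else 0.0 for bc in truth.cell_barcodes]
            )
    raise KeyError(f"{locus} not planted in truth")


def simulate_expression_matrix(
    truth: SyntheticTruth,
    n_genes: int,
    n_cells: int,
    effect_snvs: Sequence[SNVLocus] = (),
    beta: float = 0.0,
    seed: int = 0,
    dispersion: float = 10.0,
) -> pd.DataFrame:
    """Cell x gene negative-binomial counts with optional cis effects.

    For each effect SNV, the log-mean of its harboring gene is shifted by
    ``beta`` times the cell's true VAF.  Returns a DataFrame indexed by
    cell barcode with gene-id columns.
    """
    if n_cells > len(truth.cell_barcodes):
        raise ValueError("n_cells exceeds the truth's cell count")
    rng = np.random.default_rng(seed)
    barcodes = truth.cell_barcodes[:n_cells]
    gene_ids = sorted(truth.gene_baseline)[:n_genes]
    mu = np.array([truth.gene_baseline[g] for g in gene_ids])
    log_mu = np.tile(np.log(mu), (n_cells, 1))

    gene_ix = {g: j for j, g in enumerate(gene_ids)}
    snv_gene = {}
    for v in truth.germline + truth.somatic:
        snv_gene[v.locus] = v.gene_id
    for snv in effect_snvs:
        gid = snv_gene.get(snv)
        if gid is None or gid not in gene_ix:
            raise ValueError(f"effect SNV {snv} has no harboring gene in matrix")
        vaf = true_vaf_vector(truth, snv)[:n_cells]
        log_mu[:, gene_ix[gid]] += beta * vaf

    mean = np.exp(log_mu)
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    counts = rng.poisson(lam)
    return pd.DataFrame(counts, index=barcodes, columns=gene_ids)


def write_expression_mtx(df: pd.DataFrame, out_dir: str) -> None:
    """Write features x cells MTX plus barcodes/features TSVs."""
    import os

    from scipy import io as spio
    from scipy import sparse

    os.makedirs(out_dir, exist_ok=True)
    mat = sparse.csr_matrix(df.to_numpy().T)
    spio.mmwrite(os.path.join(out_dir, "matrix.mtx"), mat)
    with open(os.path.join(out_dir, "barcodes.tsv"), "w") as fh:
        fh.writelines(b + "\n" for b in df.index)
    with open(os.path.join(out_dir, "features.tsv"), "w") as fh:
        fh.writelines(g + "\n" for g in df.columns)


def read_expression_mtx(in_dir: str) -> pd.DataFrame:
    import os

    from scipy import io as spio

    mat = spio.mmread(os.path.join(in_dir, "matrix.mtx")).toarray()
    with open(os.path.join(in_dir, "barcodes.tsv")) as fh:
        barcodes = [l.strip() for l in fh if l.strip()]
    with open(os.path.join(in_dir, "features.tsv")) as fh:
        features = [l.strip() for l in fh if l.strip()]
    return pd.DataFrame(mat.T, index=barcodes, columns=features)
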