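"""Variant call sets and the set algebra that defines sceSNVs.

A sceSNV (single-cell-exclusive SNV) is a variant called confidently in
at least one per-cell alignment but absent from every matched pooled
(pseudo-bulk) scRNA-seq and bulk DNA call set:

    sceSNVs = (U over cells of confident per-cell calls)
              \\ (union of pooled/bulk calls), minus masked regions.

Confidence means passing the quality filter QUAL > 100, MQ > 60,
QD > 2 (strict inequalities) and, when two callers are available,
membership in both callers' per-cell sets.

The module also provides a stand-in per-cell genotyper: a binomial
genotype-likelihood pileup caller that makes the pipeline runnable
end-to-end without external callers.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pysam
from intervaltree import IntervalTree

from .loci import BASES, SNVLocus

Scope = tuple  # ("per_cell", barcode) | ("pooled",) | ("bulk",)


@dataclass(frozen=True)
class VariantCall:
    locus: SNVLocus
    qual: float
    mq: Optional[float] = None
    qd: Optional[float] = None
    genotype: str = "het"  # "het" | "hom_alt"
    depth: Optional[int] = None

    def __post_init__(self) -> None:
        if self.qual < 0:
            raise ValueError("QUAL must be nonnegative")
        if self.qd is not None and self.qd < 0:
            raise ValueError("QD must be nonnegative")


@dataclass
class CallSet:
    """A labeled collection of calls keyed by (chrom, pos, alt)."""

    caller: str
    scope: Scope
    calls: dict = field(default_factory=dict)  # key -> VariantCall
    provenance: list = field(default_factory=list)
    n_skipped_non_snv: int = 0

    def __len__(self) -> int:
        return len(self.calls)

    def __contains__(self, item) -> bool:
        key = item.key if isinstance(item, SNVLocus) else item
        return key in self.calls

    def add(self, call: VariantCall) -> None:
        self.calls[call.locus.key] = call

    def keys(self):
        return self.calls.keys()

    def loci(self) -> list[SNVLocus]:
        return sorted(c.locus for c in self.calls.values())

    @property
    def barcode(self) -> Optional[str]:
        return self.scope[1] if self.scope and self.scope[0] == "per_cell" else None


# --------------------------------------------------------------------------
# VCF I/O
# --------------------------------------------------------------------------

def read_callset(vcf_path: str, caller: str, scope: Scope = ("pooled",)) -> CallSet:
    """Read SNV calls from a VCF; multi-allelic records are decomposed and
    non-SNV records skipped (tallied in ``n_skipped_non_snv``)."""
    cs = CallSet(caller=caller, scope=scope, provenance=[vcf_path])
    with pysam.VariantFile(vcf_path) as vcf:
        for rec in vcf:
            ref = (rec.ref or "").upper()
            gt = _genotype_of(rec)
            for alt in rec.alts or ():
                alt = alt.upper()
                if len(ref) != 1 or len(alt) != 1 or ref not in BASES \
                        or alt not in BASES:
                    cs.n_skipped_non_snv += 1
                    continue
                info = rec.info
                mq = float(info["MQ"]) if "MQ" in info else None
                qd = float(info["QD"]) if "QD" in info else None
                dp = int(info["DP"]) if "DP" in info else None
                cs.add(
                    VariantCall(
                        locus=SNVLocus(rec.chrom, rec.pos, ref, alt),
                        qual=float(rec.qual) if rec.qual is not None else 0.0,
                        mq=mq, qd=qd, genotype=gt, depth=dp,
                    )
                )
    return cs


def _genotype_of(rec) -> str:
    try:
        sample = next(iter(rec.samples.values()))
        alleles = set(sample["GT"])
    except (StopIteration, KeyError):
        return "het"
    alleles.discard(None)
    return "hom_alt" if alleles and 0 not in alleles else "het"


def write_callset(callset: CallSet, path: str,
                  contigs: Optional[dict[str, int]] = None) -> None:
    """Write an uncompressed VCF (QUAL; INFO MQ, QD, DP; sample GT)."""
    header = pysam.VariantHeader()
    header.add_meta("source", f"scesnv:{callset.caller}")
    chroms = {c.locus.chrom for c in callset.calls.values()}
    if contigs:
        for name, length in contigs.items():
            header.contigs.add(name, length=length)
    else:
        for name in sorted(chroms):
            header.contigs.add(name)
    header.info.add("MQ", 1, "Float", "Mean mapping quality")
    header.info.add("QD", 1, "Float", "Quality by depth")
    header.info.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(callset.barcode or "sample")
    with pysam.VariantFile(path, "w", header=header) as out:
        for call in sorted(callset.calls.values(), key=lambda c: c.locus):
            loc = call.locus
            rec = out.new_record(
                contig=loc.chrom, start=loc.pos - 1, stop=loc.pos,
                alleles=(loc.ref, loc.alt), qual=call.qual,
            )
            if call.mq is not None:
                rec.info["MQ"] = call.mq
            if call.qd is not None:
                rec.info["QD"] = call.qd
            if call.depth is not None:
                rec.info["DP"] = call.depth
            rec.samples[0]["GT"] = (1, 1) if call.genotype == "hom_alt" else (0, 1)
            out.write(rec)


# --------------------------------------------------------------------------
# Stand-in per-cell genotyper
# --------------------------------------------------------------------------

def genotype_likelihoods(n_ref: int, n_var: int,
                         error_rate: float) -> dict[str, float]:
    """Log10 likelihoods of {RR, RA, AA} under a binomial error model.

    Each ref-supporting read has probability 1-e of being drawn from an
    R allele (e/3 from A); variant reads the converse; the heterozygote
    emits each allele with probability 1/2.
    """
    e3 = error_rate / 3.0
    p_ref = {"RR": 1 - error_rate, "RA": 0.5 * (1 - error_rate) + 0.5 * e3,
             "AA": e3}
    p_var = {"RR": e3, "RA": 0.5 * (1 - error_rate) + 0.5 * e3,
             "AA": 1 - error_rate}
    return {
        g: n_ref * math.log10(max(p_ref[g], 1e-300))
        + n_var * math.log10(max(p_var[g], 1e-300))
        for g in ("RR", "RA", "AA")
    }


def pileup_genotype(
    alignments: Iterable,
    reference: dict[str, str],
    error_rate: float = 0.005,
    min_depth: int = 5,
    min_alt: int = 2,
    posterior_threshold: float = 0.99,
    min_baseq: int = 20,
    caller: str = "pileup",
    scope: Scope = ("pooled",),
) -> CallSet:
    """Call SNVs from one alignment set with a binomial genotype model.

    At each covered site with depth >= min_depth and at least ``min_alt``
    reads of the top non-reference base, posteriors over {RR, RA, AA}
    (uniform prior) are computed; a call is emitted when
    P(not RR | data) > posterior_threshold.  QUAL is
    -10 log10 P(RR | data), QD = QUAL / depth, MQ = mean MAPQ of the
    contributing reads.
    """
    base_ix = {b: i for i, b in enumerate(BASES)}
    counts: dict[str, np.ndarray] = {}
    mapq_sum: dict[str, np.ndarray] = {}
    mapq_n: dict[str, np.ndarray] = {}

    def arrays(chrom: str):
        if chrom not in counts:
            L = len(reference[chrom])
            counts[chrom] = np.zeros((4, L), dtype=np.int32)
            mapq_sum[chrom] = np.zeros(L, dtype=np.int64)
            mapq_n[chrom] = np.zeros(L, dtype=np.int32)
        return counts[chrom], mapq_sum[chrom], mapq_n[chrom]

    close = None
    if isinstance(alignments, str):
        alignments = close = pysam.AlignmentFile(alignments)
    try:
        for rec in alignments:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            chrom = rec.reference_name
            if chrom not in reference:
                continue
            cnt, msum, mn = arrays(chrom)
            pairs = rec.get_aligned_pairs(matches_only=True)
            if not pairs:
                continue
            qpos = np.fromiter((p[0] for p in pairs), dtype=np.int64)
            rpos = np.fromiter((p[1] for p in pairs), dtype=np.int64)
            seq = rec.query_sequence
            quals = rec.query_qualities
            codes = np.fromiter(
                (base_ix.get(seq[i], -1) for i in qpos), dtype=np.int64
            )
            if quals is not None:
                qarr = np.fromiter((quals[i] for i in qpos), dtype=np.int64)
                ok = (codes >= 0) & (qarr >= min_baseq)
            else:
                ok = codes >= 0
            np.add.at(cnt, (codes[ok], rpos[ok]), 1)
            msum[rpos[ok]] += rec.mapping_quality
            mn[rpos[ok]] += 1
    finally:
        if close is not None:
            close.close()

    cs = CallSet(caller=caller, scope=scope)
    log_prior = math.log10(1.0 / 3.0)
    for chrom in sorted(counts):
        cnt = counts[chrom]
        depth = cnt.sum(axis=0)
        refseq = reference[chrom]
        ref_codes = np.frompyfunc(lambda ch: base_ix.get(ch, -1), 1, 1)(
            np.array(list(refseq), dtype=object)
        ).astype(np.int64)
        nonref = cnt.copy()
        valid = ref_codes >= 0
        nonref[ref_codes[valid], np.nonzero(valid)[0]] = 0
        alt_count = nonref.max(axis=0)
        cand = np.nonzero((depth >= min_depth) & (alt_count >= min_alt) & valid)[0]
        for pos0 in cand:
            ref_base = refseq[pos0]
            alt_code = int(nonref[:, pos0].argmax())
            alt_base = BASES[alt_code]
            n_var = int(cnt[alt_code, pos0])
            n_ref = int(cnt[base_ix[ref_base], pos0])
            ll = genotype_likelihoods(n_ref, n_var, error_rate)
            logs = {g: v + log_prior for g, v in ll.items()}
            m = max(logs.values())
            post = {g: 10 ** (v - m) for g, v in logs.items()}
            z = sum(post.values())
            p_rr = post["RR"] / z
            if 1.0 - p_rr <= posterior_threshold:
                continue
            qual = -10.0 * math.log10(max(p_rr, 1e-300))
            d = int(depth[pos0])
            mq = (mapq_sum[chrom][pos0] / mapq_n[chrom][pos0]
                  if mapq_n[chrom][pos0] else 0.0)
            gt = "hom_alt" if post["AA"] > post["RA"] else "het"
            cs.add(
                VariantCall(
                    locus=SNVLocus(chrom, int(pos0) + 1, ref_base, alt_base),
                    qual=qual, mq=float(mq), qd=qual / d if d else 0.0,
                    genotype=gt, depth=d,
                )
            )
    return cs


# --------------------------------------------------------------------------
# Filtering and algebra
# --------------------------------------------------------------------------

def filter_calls(
    callset: CallSet,
    qual_min: float = 100.0,
    mq_min: float = 60.0,
    qd_min: float = 2.0,
) -> CallSet:
    """Keep calls with QUAL > qual_min, MQ > mq_min and QD > qd_min.

    All inequalities are strict; calls missing MQ or QD fail.
    """
    out = CallSet(caller=callset.caller, scope=callset.scope,
                  provenance=list(callset.provenance) + ["filtered"])
    for key, call in callset.calls.items():
        if call.qual > qual_min and call.mq is not None and call.mq > mq_min \
                and call.qd is not None and call.qd > qd_min:
            out.calls[key] = call
    return out


def intersect_per_cell(callset_a: CallSet, callset_b: CallSet) -> CallSet:
    """Calls whose (chrom, pos, alt) key occurs in both sets.

    The two sets must share the same scope (same cell for per-cell
    scopes); record fields are taken from ``callset_a``.
    """
    if callset_a.scope != callset_b.scope:
        raise ValueError(
            f"scope mismatch: {callset_a.scope} vs {callset_b.scope}"
        )
    out = CallSet(
        caller=f"{callset_a.caller}&{callset_b.caller}",
        scope=callset_a.scope,
        provenance=[callset_a.caller, callset_b.caller],
    )
    for key, call in callset_a.calls.items():
        if key in callset_b.calls:
            out.calls[key] = call
    return out


def union_callsets(callsets: Sequence[CallSet]) -> CallSet:
    """Key union with per-key provenance; first occurrence wins the record."""
    out = CallSet(caller="union", scope=("pooled",))
    prov: dict = defaultdict(list)
    for cs in callsets:
        out.provenance.append((cs.caller, cs.scope))
        for key, call in cs.calls.items():
            if key not in out.calls:
                out.calls[key] = call
            prov[key].append(cs.caller)
    out.key_provenance = dict(prov)  # type: ignore[attr-defined]
    return out


def read_bed_mask(path: str) -> dict[str, IntervalTree]:
    """Read a BED (0-based half-open) mask into per-chrom interval trees."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{i}: malformed BED line")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"{path}:{i}: empty or inverted interval")
            trees[chrom][start:end] = True
    return dict(trees)


def _masked(mask: dict[str, IntervalTree], chrom: str, pos: int) -> bool:
    tree = mask.get(chrom)
    # BED is 0-based half-open: 1-based pos falls in [start, end) at pos-1
    return bool(tree is not None and tree[pos - 1])


def exclude_regions(
    calls_or_loci: Union[CallSet, Sequence[SNVLocus]],
    mask: Union[str, dict[str, IntervalTree]],
):
    """Drop loci whose position falls inside any mask interval."""
    if isinstance(mask, str):
        mask = read_bed_mask(mask)
    if isinstance(calls_or_loci, CallSet):
        out = CallSet(caller=calls_or_loci.caller, scope=calls_or_loci.scope,
                      provenance=list(calls_or_loci.provenance) + ["masked"])
        for key, call in calls_or_loci.calls.items():
            if not _masked(mask, call.locus.chrom, call.locus.pos):
                out.calls[key] = call
        return out
    return [
        loc for loc in calls_or_loci if not _masked(mask, loc.chrom, loc.pos)
    ]


# --------------------------------------------------------------------------
# sceSNV identification
# --------------------------------------------------------------------------

@dataclass
class SceSNVReport:
    """The sceSNV set with per-SNV carrier cells and provenance."""

    snvs: dict = field(default_factory=dict)  # key -> SNVLocus
    carriers: dict = field(default_factory=dict)  # key -> sorted barcodes
    n_cells: int = 0
    recovered_by_lowfrac: dict = field(default_factory=dict)  # key -> bool
    provenance: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.snvs)

    def loci(self) -> list[SNVLocus]:
        return sorted(self.snvs.values())

    def carrier_count(self, locus: SNVLocus) -> int:
        return len(self.carriers.get(locus.key, ()))

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(
                "#chrom\tpos\tref\talt\tn_carrier_cells\tcarrier_barcodes"
                "\trecovered_by_lowfrac_caller\n"
            )
            for loc in self.loci():
                bars = self.carriers[loc.key]
                rec = self.recovered_by_lowfrac.get(loc.key)
                fh.write(
                    f"{loc.chrom}\t{loc.pos}\t{loc.ref}\t{loc.alt}"
                    f"\t{len(bars)}\t{','.join(bars)}"
                    f"\t{'.' if rec is None else int(rec)}\n"
                )


def identify_scesnvs(
    per_cell_confident_sets: Sequence[CallSet],
    pooled_bulk_union: CallSet,
    mask: Optional[Union[str, dict[str, IntervalTree]]] = None,
    lowfrac_callset: Optional[CallSet] = None,
) -> SceSNVReport:
    """sceSNVs = (union of confident per-cell calls) minus the pooled/bulk
    union, minus masked regions.

    ``per_cell_confident_sets`` must already be quality-filtered (and
    caller-intersected when two callers are available).  Carrier count
    per sceSNV is the number of cells whose confident set contains it.
    """
    if not per_cell_confident_sets:
        raise ValueError("no per-cell call sets provided")
    if isinstance(mask, str):
        mask = read_bed_mask(mask)
    report = SceSNVReport(n_cells=len(per_cell_confident_sets))
    carrier_map: dict = defaultdict(set)
    loci_map: dict = {}
    for cs in per_cell_confident_sets:
        bc = cs.barcode or repr(cs.scope)
        report.provenance.append((cs.caller, cs.scope))
        for key, call in cs.calls.items():
            if key in pooled_bulk_union.calls:
                continue
            loc = call.locus
            if mask is not None and _masked(mask, loc.chrom, loc.pos):
                continue
            carrier_map[key].add(bc)
            loci_map[key] = loc
    for key, loc in loci_map.items():
        report.snvs[key] = loc
        report.carriers[key] = sorted(carrier_map[key])
        if lowfrac_callset is not None:
            report.recovered_by_lowfrac[key] = key in lowfrac_callset.calls
    return report


def carriers_histogram(
    report: SceSNVReport, k: int = 2
) -> dict:
    """Carrier-cell histogram of a sceSNV report.

    Returns a dict with the histogram {n_carriers: n_sceSNVs}, the count
    and fraction with >= k carriers, the maximum carrier fraction, and —
    when the report carries low-fraction caller flags — the fraction of
    sceSNVs recovered by that caller.
    """
    if len(report) == 0:
        raise ValueError("empty sceSNV report")
    hist = Counter(len(v) for v in report.carriers.values())
    total = len(report)
    n_ge_k = sum(n for c, n in hist.items() if c >= k)
    out = {
        "histogram": dict(sorted(hist.items())),
        "n_scesnvs": total,
        "n_ge_k": n_ge_k,
        "frac_ge_k": n_ge_k / total,
        "max_carriers": max(hist),
        "max_carrier_fraction": (max(hist) / report.n_cells
                                 if report.n_cells else math.nan),
    }
    if report.recovered_by_lowfrac:
        rec = sum(bool(v) for v in report.recovered_by_lowfrac.values())
        out["n_lowfrac_recovered"] = rec
        out["frac_lowfrac_recovered"] = rec / total
    return out


# --------------------------------------------------------------------------
# Low-fraction pooled caller (Mutect2 analogue)
# --------------------------------------------------------------------------

def lowfrac_pooled_caller(
    alignments: Iterable,
    reference: dict[str, str],
    error_rate: float = 0.005,
    min_alt: int = 3,
    alpha: float = 1e-6,
    min_baseq: int = 20,
) -> CallSet:
    """Call low-fraction variants from pooled reads with a binomial test.

    At each site, the top non-reference base count is tested against the
    error null Binomial(depth, error_rate / 3); sites with p < alpha and
    at least ``min_alt`` supporting reads are emitted.  A deliberately
    permissive analogue of a somatic low-fraction caller.
    """
    from scipy.stats import binomtest

    # reuse the pileup accumulation with a threshold-free pass
    base_ix = {b: i for i, b in enumerate(BASES)}
    counts: dict[str, np.ndarray] = {}
    close = None
    if isinstance(alignments, str):
        alignments = close = pysam.AlignmentFile(alignments)
    try:
        for rec in alignments:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            chrom = rec.reference_name
            if chrom not in reference:
                continue
            if chrom not in counts:
                counts[chrom] = np.zeros((4, len(reference[chrom])),
                                         dtype=np.int32)
            pairs = rec.get_aligned_pairs(matches_only=True)
            if not pairs:
                continue
            qpos = np.fromiter((p[0] for p in pairs), dtype=np.int64)
            rpos = np.fromiter((p[1] for p in pairs), dtype=np.int64)
            seq = rec.query_sequence
            quals = rec.query_qualities
            codes = np.fromiter(
                (base_ix.get(seq[i], -1) for i in qpos), dtype=np.int64
            )
            if quals is not None:
                qarr = np.fromiter((quals[i] for i in qpos), dtype=np.int64)
                ok = (codes >= 0) & (qarr >= min_baseq)
            else:
                ok = codes >= 0
            np.add.at(counts[chrom], (codes[ok], rpos[ok]), 1)
    finally:
        if close is not None:
            close.close()

    cs = CallSet(caller="lowfrac", scope=("pooled",))
    for chrom in sorted(counts):
        cnt = counts[chrom]
        depth = cnt.sum(axis=0)
        refseq = reference[chrom]
        for pos0 in np.nonzero(depth > 0)[0]:
            ref_base = refseq[pos0]
            if ref_base not in base_ix:
                continue
            nonref = cnt[:, pos0].copy()
            nonref[base_ix[ref_base]] = 0
            alt_code = int(nonref.argmax())
            n_var = int(nonref[alt_code])
            if n_var < min_alt:
                continue
            d = int(depth[pos0])
            p = binomtest(n_var, d, error_rate / 3.0,
                          alternative="greater").pvalue
            if p < alpha:
                qual = -10.0 * math.log10(max(p, 1e-300))
                cs.add(
                    VariantCall(
                        locus=SNVLocus(chrom, int(pos0) + 1, ref_base,
                                       BASES[alt_code]),
                        qual=qual, mq=255.0, qd=qual / d, genotype="het",
                        depth=d,
                    )
                )
    return cs
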