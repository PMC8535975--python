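"""Cell-level allele counting and VAF_RNA.

For every (cell, SNV locus) pair this module tabulates the number of
deduplicated reads supporting the reference allele (n_ref), the variant
allele (n_var), and any other base (n_other), and computes the expressed
variant allele fraction

    VAF_RNA = n_var / (n_var + n_ref)

which is considered assessable only when n_ref + n_var reaches the depth
threshold minR (default 3); below minR the VAF is undefined and the pair
is excluded from downstream analyses.

Reads sharing a (CB, UB) pair at a locus are collapsed to a single
observation before counting (policy ``umi_consensus``: majority base,
ties count as n_other).  Policies ``umi_first`` (best base quality, then
lexicographic base) and ``none`` (count every read) are available.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam

from .loci import SNVLocus

DEDUP_POLICIES = ("umi_consensus", "umi_first", "none")


def vaf(n_ref: int, n_var: int, minR: int = 3) -> Optional[float]:
    """VAF_RNA = n_var / (n_var + n_ref); None when coverage is below minR."""
    if n_ref < 0 or n_var < 0:
        raise ValueError("counts must be nonnegative")
    if minR < 1:
        raise ValueError("minR must be >= 1")
    total = n_ref + n_var
    if total < minR:
        return None
    return n_var / total


@dataclass(frozen=True)
class CellSNVCount:
    barcode: str
    locus: SNVLocus
    n_ref: int
    n_var: int
    n_other: int

    def vaf(self, minR: int = 3) -> Optional[float]:
        return vaf(self.n_ref, self.n_var, minR)


@dataclass
class CellSNVMatrix:
    """Sparse (cell x SNV) tallies with an attached minR threshold."""

    loci: list[SNVLocus]
    barcodes: list[str]
    minR: int = 3
    # (barcode, locus) -> (n_ref, n_var, n_other)
    counts: dict = field(default_factory=dict)

    def get(self, barcode: str, locus: SNVLocus) -> tuple[int, int, int]:
        return self.counts.get((barcode, locus), (0, 0, 0))

    def vaf(self, barcode: str, locus: SNVLocus) -> Optional[float]:
        n_ref, n_var, _ = self.get(barcode, locus)
        return vaf(n_ref, n_var, self.minR)

    def defined_pairs(self, minR: Optional[int] = None) -> list[tuple[str, SNVLocus]]:
        minR = self.minR if minR is None else minR
        return [
            (bc, loc)
            for (bc, loc), (nr, nv, _) in sorted(self.counts.items(),
                                                 key=lambda kv: (kv[0][1], kv[0][0]))
            if nr + nv >= minR
        ]

    def vaf_vector(self, locus: SNVLocus) -> dict[str, float]:
        """Defined VAFs for one locus across cells (reference-only cells
        included as 0.0)."""
        out = {}
        for bc in self.barcodes:
            v = self.vaf(bc, locus)
            if v is not None:
                out[bc] = v
        return out

    def to_long_df(self) -> pd.DataFrame:
        rows = []
        for (bc, loc), (nr, nv, no) in sorted(
            self.counts.items(), key=lambda kv: (kv[0][1], kv[0][0])
        ):
            v = vaf(nr, nv, self.minR)
            rows.append(
                (bc, loc.chrom, loc.pos, loc.ref, loc.alt, nr, nv, no,
                 math.nan if v is None else v)
            )
        return pd.DataFrame(
            rows,
            columns=["barcode", "chrom", "pos", "ref", "alt",
                     "n_ref", "n_var", "n_other", "vaf"],
        )

    def to_tsv(self, path: str) -> None:
        df = self.to_long_df()
        with open(path, "w") as fh:
            fh.write(f"#minR={self.minR}\n")
            df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def _record_base_at(rec, pos0: int) -> Optional[tuple[str, int]]:
    """(base, baseq) of an aligned match at 0-based ref pos, else None.

    Deletions and reference skips spanning the position yield None.
    """
    qseq = rec.query_sequence
    quals = rec.query_qualities
    for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
        if rpos == pos0:
            q = quals[qpos] if quals is not None else 40
            return qseq[qpos].upper(), q
    return None


def _dedup(observations: list[dict], policy: str) -> list[str]:
    """Collapse per-UMI read observations to one base each.

    ``observations`` holds dicts with keys base, baseq, start, umi.
    """
    if policy == "none":
        return [o["base"] for o in observations]
    groups: dict[str, list[dict]] = defaultdict(list)
    for o in observations:
        groups[o["umi"]].append(o)
    out = []
    for umi in sorted(groups):
        obs = groups[umi]
        if policy == "umi_first":
            best = min(obs, key=lambda o: (-o["baseq"], o["start"], o["base"]))
            out.append(best["base"])
        else:  # umi_consensus
            tally: dict[str, int] = defaultdict(int)
            for o in obs:
                tally[o["base"]] += 1
            top = max(tally.values())
            winners = sorted(b for b, c in tally.items() if c == top)
            out.append(winners[0] if len(winners) == 1 else "conflict")
    return out


def tabulate_counts(
    alignments: Iterable,
    loci: Sequence[SNVLocus],
    min_mapq: int = 255,
    min_baseq: int = 20,
    dedup_policy: str = "umi_consensus",
    minR: int = 3,
    barcodes: Optional[Sequence[str]] = None,
) -> CellSNVMatrix:
    """Tabulate n_ref / n_var / n_other per (cell, locus).

    ``alignments`` may be an iterable of pysam records, an AlignmentFile,
    or a SAM/BAM path.  Only primary, mapped, CB-tagged records at or
    above ``min_mapq`` contribute; bases below ``min_baseq`` are ignored.
    A UMI-less record under a UMI policy is treated as its own molecule.
    Counts are independent of the input record order.
    """
    if dedup_policy not in DEDUP_POLICIES:
        raise ValueError(f"dedup_policy must be one of {DEDUP_POLICIES}")
    close = None
    known_chroms: Optional[set[str]] = None
    if isinstance(alignments, str):
        alignments = close = pysam.AlignmentFile(alignments)
    if isinstance(alignments, pysam.AlignmentFile):
        known_chroms = set(alignments.references)

    by_chrom: dict[str, list[SNVLocus]] = defaultdict(list)
    for loc in loci:
        by_chrom[loc.chrom].append(loc)
    for ll in by_chrom.values():
        ll.sort(key=lambda l: l.pos)
    if known_chroms is not None:
        for chrom in by_chrom:
            if chrom not in known_chroms:
                import warnings

                warnings.warn(
                    f"locus chromosome {chrom!r} absent from alignment header; "
                    "zero counts reported"
                )

    # (barcode, (chrom,pos)) -> list of observation dicts
    obs: dict[tuple, list[dict]] = defaultdict(list)
    anon = 0
    try:
        for rec in alignments:
            if (
                rec.is_unmapped
                or rec.is_secondary
                or rec.is_supplementary
                or rec.mapping_quality < min_mapq
                or not rec.has_tag("CB")
            ):
                continue
            chrom = rec.reference_name
            cand = by_chrom.get(chrom)
            if not cand:
                continue
            lo, hi = rec.reference_start + 1, rec.reference_end  # 1-based incl
            hits = [l for l in cand if lo <= l.pos <= hi]
            if not hits:
                continue
            bc = rec.get_tag("CB")
            if rec.has_tag("UB"):
                umi = rec.get_tag("UB")
            else:
                anon += 1
                umi = f"_noumi{anon}"
            for loc in hits:
                got = _record_base_at(rec, loc.pos - 1)
                if got is None:
                    continue
                base, q = got
                if q < min_baseq:
                    continue
                obs[(bc, (loc.chrom, loc.pos))].append(
                    dict(base=base, baseq=q, start=rec.reference_start, umi=umi)
                )
    finally:
        if close is not None:
            close.close()

    seen_barcodes = sorted({bc for bc, _ in obs})
    if barcodes is not None:
        seen_barcodes = sorted(set(barcodes) | set(seen_barcodes))
    matrix = CellSNVMatrix(loci=list(loci), barcodes=seen_barcodes, minR=minR)
    for (bc, (chrom, pos)), olist in obs.items():
        bases = _dedup(olist, dedup_policy)
        # multi-allelic: one entry per SNVLocus sharing (chrom, pos)
        for loc in by_chrom[chrom]:
            if loc.pos != pos:
                continue
            n_ref = sum(b == loc.ref for b in bases)
            n_var = sum(b == loc.alt for b in bases)
            n_other = len(bases) - n_ref - n_var
            matrix.counts[(bc, loc)] = (n_ref, n_var, n_other)
    return matrix


def vaf_distribution(
    matrix: CellSNVMatrix,
    snv_subset: Optional[Sequence[SNVLocus]] = None,
    min_cells: int = 1,
) -> dict[SNVLocus, list[float]]:
    """Per-locus defined VAFs across cells, reference-only cells included.

    Loci with fewer than ``min_cells`` cells with a defined VAF are
    excluded.
    """
    loci = list(snv_subset) if snv_subset is not None else matrix.loci
    out: dict[SNVLocus, list[float]] = {}
    for loc in loci:
        vec = matrix.vaf_vector(loc)
        if len(vec) >= min_cells:
            out[loc] = [vec[bc] for bc in sorted(vec)]
    return out
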