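"""SNV annotation: novelty against catalogs, functional categories, and
per-category 2x2 chi-square enrichment.

Functional classification follows a fixed precedence: coding change
(stop > missense > synonymous, by translating the mutated codon on the
coding strand) > splice (within 2 bp inside an intron at an exon-intron
junction) > 3'/5' UTR > non-coding exon > intron > intergenic.  When an
SNV hits several overlapping genes the highest-precedence category wins;
ties break on the lexicographically smallest gene id.

The 2x2 comparison applies the Yates continuity correction with the
statistic clamped at zero when the correction exceeds |ad - bc|:

    chi2 = N * (max(|ad - bc| - N/2, 0))^2 / [(a+b)(c+d)(a+c)(b+d)]

on the table [[a, N_a - a], [c, N_b - c]] (category vs all other
categories, set A vs set B), 1 degree of freedom.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy.stats import chi2 as _chi2_dist

from .genemodel import Gene, GeneModel
from .loci import COMPLEMENT, SNVLocus

CATEGORIES = (
    "3-prime-UTR",
    "missense",
    "intron",
    "synonymous",
    "intergenic",
    "non-coding-exon",
    "5-prime-UTR",
    "splice",
    "stop",
)

# lower rank = higher precedence when one SNV hits several genes
_PRECEDENCE = {
    "stop": 0,
    "missense": 1,
    "synonymous": 2,
    "splice": 3,
    "3-prime-UTR": 4,
    "5-prime-UTR": 4,
    "non-coding-exon": 5,
    "intron": 6,
    "intergenic": 7,
}

SPLICE_WINDOW = 2  # bases into the intron flanking each junction

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = ("TAA", "TAG", "TGA")


def translate_codon(codon: str) -> str:
    return _CODON_TABLE[codon.upper()]


# --------------------------------------------------------------------------
# Catalogs and novelty
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Catalog:
    """A known-variant catalog (dbSNP-like, COSMIC-like, editing-like)."""

    name: str
    keys: frozenset  # of (chrom, pos, ref, alt)

    def __contains__(self, snv: SNVLocus) -> bool:
        return (snv.chrom, snv.pos, snv.ref, snv.alt) in self.keys

    def __len__(self) -> int:
        return len(self.keys)

    @classmethod
    def from_tsv(cls, path: str, name: Optional[str] = None) -> "Catalog":
        opener = gzip.open if path.endswith(".gz") else open
        keys = set()
        with opener(path, "rt") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                chrom, pos, ref, alt = line.split("\t")[:4]
                keys.add((chrom, int(pos), ref.upper(), alt.upper()))
        return cls(name or path, frozenset(keys))


def classify_novelty(
    snvs: Sequence[SNVLocus], catalogs: Sequence[Catalog]
) -> pd.DataFrame:
    """Flag each SNV as novel iff absent from every catalog.

    Returns a DataFrame (chrom, pos, ref, alt, novel) whose ``.attrs``
    carry ``n``, ``n_novel`` and ``pct_novel``.
    """
    rows = []
    for s in snvs:
        novel = not any(s in cat for cat in catalogs)
        rows.append((s.chrom, s.pos, s.ref, s.alt, novel))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "novel"])
    n = len(df)
    n_novel = int(df["novel"].sum()) if n else 0
    df.attrs.update(
        n=n, n_novel=n_novel, pct_novel=(100.0 * n_novel / n if n else math.nan)
    )
    return df


# --------------------------------------------------------------------------
# Functional classification
# --------------------------------------------------------------------------

def _coding_effect(gene: Gene, snv: SNVLocus, reference: dict[str, str]) -> str:
    idx = gene.cds_index_of(snv.pos)
    assert idx is not None
    cds = gene.cds_sequence(reference)
    ci, within = divmod(idx, 3)
    codon = cds[3 * ci : 3 * ci + 3]
    if len(codon) < 3:  # truncated CDS in a hand-made model
        return "synonymous"
    alt_coding = snv.alt if gene.strand == "+" else COMPLEMENT[snv.alt]
    mutated = codon[:within] + alt_coding + codon[within + 1 :]
    aa_ref, aa_alt = translate_codon(codon), translate_codon(mutated)
    if aa_alt == aa_ref:  # includes stop -> stop
        return "synonymous"
    if aa_ref == "*" or aa_alt == "*":  # stop-gain and stop-loss both -> stop
        return "stop"
    return "missense"


def _near_junction(gene: Gene, pos: int) -> bool:
    for intron in gene.introns:
        if intron.start <= pos <= min(intron.start + SPLICE_WINDOW - 1, intron.end):
            return True
        if max(intron.end - SPLICE_WINDOW + 1, intron.start) <= pos <= intron.end:
            return True
    return False


def _gene_category(gene: Gene, snv: SNVLocus, reference: dict[str, str]) -> str:
    pos = snv.pos
    if gene.coding and gene.in_any(gene.cds, pos):
        return _coding_effect(gene, snv, reference)
    if _near_junction(gene, pos):
        return "splice"
    if gene.in_any(gene.utr3, pos):
        return "3-prime-UTR"
    if gene.in_any(gene.utr5, pos):
        return "5-prime-UTR"
    if gene.in_any(gene.exons, pos):
        return "non-coding-exon"
    return "intron"  # inside the gene span, not exonic, not at a junction


def classify_function(
    snv: SNVLocus, gene_model: GeneModel, reference: dict[str, str]
) -> str:
    """Functional category of one SNV under the precedence rule."""
    ref_base = reference[snv.chrom][snv.pos - 1].upper()
    if ref_base != snv.ref:
        raise ValueError(
            f"ref mismatch at {snv}: reference has {ref_base!r}"
        )
    genes = gene_model.genes_at(snv.chrom, snv.pos)
    if not genes:
        return "intergenic"
    best = min(
        ((_gene_category(g, snv, reference), g.gene_id) for g in genes),
        key=lambda t: (_PRECEDENCE[t[0]], t[1]),
    )
    return best[0]


def category_table(
    snvs: Iterable[SNVLocus], gene_model: GeneModel, reference: dict[str, str]
) -> dict[str, int]:
    """Counts over the nine functional categories; values sum to len(snvs)."""
    counts = {c: 0 for c in CATEGORIES}
    for s in snvs:
        counts[classify_function(s, gene_model, reference)] += 1
    return counts


# --------------------------------------------------------------------------
# 2x2 enrichment
# --------------------------------------------------------------------------

def yates_chi_square(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Continuity-corrected chi-square for the 2x2 table [[a, b], [c, d]].

    Returns (statistic, p_value); (nan, nan) when a margin is zero.
    The correction term N/2 is clamped so the statistic is never negative.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("table entries must be nonnegative")
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        return (math.nan, math.nan)
    num = abs(a * d - b * c) - n / 2.0
    if num < 0:
        num = 0.0
    stat = n * num * num / (margins[0] * margins[1] * margins[2] * margins[3])
    return (stat, float(_chi2_dist.sf(stat, 1)))


def compare_categories(
    counts_a: dict[str, int],
    counts_b: dict[str, int],
    categories: Sequence[str] = CATEGORIES,
) -> pd.DataFrame:
    """Per-category 2x2 chi-square comparison of two SNV sets.

    For each category the table is (in-category vs all-other, set A vs
    set B).  Returns a DataFrame indexed by category with columns
    count_a, pct_a, count_b, pct_b, chi_square, p_value; totals are in
    ``.attrs['N_a']`` / ``.attrs['N_b']``.
    """
    n_a = sum(counts_a.get(c, 0) for c in categories)
    n_b = sum(counts_b.get(c, 0) for c in categories)
    if n_a < 1 or n_b < 1:
        raise ValueError("both sets must be nonempty")
    rows = []
    for cat in categories:
        a = counts_a.get(cat, 0)
        c = counts_b.get(cat, 0)
        stat, p = yates_chi_square(a, n_a - a, c, n_b - c)
        rows.append(
            dict(category=cat, count_a=a, pct_a=100.0 * a / n_a,
                 count_b=c, pct_b=100.0 * c / n_b,
                 chi_square=stat, p_value=p)
        )
    df = pd.DataFrame(rows).set_index("category")
    df.attrs.update(N_a=n_a, N_b=n_b)
    return df
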