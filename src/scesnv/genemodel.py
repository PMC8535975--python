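"""Simplified gene model: genes with exon/CDS/UTR intervals on a strand.

The model is deliberately one-transcript-per-gene.  It provides what the
functional annotator needs — strand-aware spliced CDS extraction and
interval membership — and round-trips through a simple TSV as well as
writing standard GTF for interoperability.

All intervals are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from intervaltree import IntervalTree

from .loci import revcomp


@dataclass(frozen=True)
class Interval:
    start: int  # 1-based inclusive
    end: int    # inclusive

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad interval [{self.start}, {self.end}]")

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class Gene:
    """One gene (= one transcript) with its annotated intervals.

    ``exons`` covers the transcribed, spliced sequence; for coding genes
    the exon space partitions into ``utr5`` + ``cds`` + ``utr3``.  Introns
    are the gaps between consecutive exons inside the gene span.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    coding: bool
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.cds = sorted(self.cds, key=lambda iv: iv.start)

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def introns(self) -> list[Interval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end + 1:
                out.append(Interval(a.end + 1, b.start - 1))
        return out

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def in_any(self, intervals: list[Interval], pos: int) -> bool:
        return any(pos in iv for iv in intervals)

    # ---- CDS coordinate machinery -------------------------------------

    def cds_positions(self) -> list[int]:
        """Genomic positions of CDS bases in transcription order."""
        pos = [p for iv in self.cds for p in range(iv.start, iv.end + 1)]
        if self.strand == "-":
            pos.reverse()
        return pos

    def cds_sequence(self, reference: dict[str, str]) -> str:
        """Spliced CDS on the coding strand (starts ATG, ends stop)."""
        seq = "".join(
            reference[self.chrom][iv.start - 1 : iv.end] for iv in self.cds
        )
        return revcomp(seq) if self.strand == "-" else seq

    def cds_index_of(self, pos: int) -> Optional[int]:
        """0-based index of a genomic position within the spliced CDS, or None."""
        if not self.in_any(self.cds, pos):
            return None
        offset = 0
        if self.strand == "+":
            for iv in self.cds:
                if pos in iv:
                    return offset + (pos - iv.start)
                offset += len(iv)
        else:
            for iv in reversed(self.cds):
                if pos in iv:
                    return offset + (iv.end - pos)
                offset += len(iv)
        return None


class GeneModel:
    """A collection of genes with fast by-position lookup."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes: list[Gene] = sorted(genes, key=lambda g: (g.chrom, g.start))
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            # interval tree is half-open
            tree[g.start : g.end + 1] = g

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def get(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def genes_at(self, chrom: str, pos: int) -> list[Gene]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree[pos]]
        return sorted(hits, key=lambda g: g.gene_id)

    # ---- I/O -----------------------------------------------------------

    _FEATURES = ("exon", "CDS", "five_prime_utr", "three_prime_utr")

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("#gene_id\tchrom\tstrand\tcoding\tfeature\tstart\tend\n")
            for g in self.genes:
                rows = [("exon", iv) for iv in g.exons]
                rows += [("CDS", iv) for iv in g.cds]
                rows += [("five_prime_utr", iv) for iv in g.utr5]
                rows += [("three_prime_utr", iv) for iv in g.utr3]
                for feat, iv in rows:
                    fh.write(
                        f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{int(g.coding)}"
                        f"\t{feat}\t{iv.start}\t{iv.end}\n"
                    )

    @classmethod
    def from_tsv(cls, path: str) -> "GeneModel":
        acc: dict[str, dict] = {}
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                gid, chrom, strand, coding, feat, start, end = line.split("\t")
                if feat not in cls._FEATURES:
                    raise ValueError(f"{path}:{i}: unknown feature {feat!r}")
                d = acc.setdefault(
                    gid,
                    dict(chrom=chrom, strand=strand, coding=bool(int(coding)),
                         exon=[], CDS=[], five_prime_utr=[], three_prime_utr=[]),
                )
                d[feat].append(Interval(int(start), int(end)))
        genes = [
            Gene(gene_id=gid, chrom=d["chrom"], strand=d["strand"],
                 coding=d["coding"], exons=d["exon"], cds=d["CDS"],
                 utr5=d["five_prime_utr"], utr3=d["three_prime_utr"])
            for gid, d in acc.items()
        ]
        return cls(genes)

    def to_gtf(self, path: str, source: str = "scesnv") -> None:
        """Write a GTF with gene/transcript/exon/CDS/UTR features."""

        def row(g: Gene, feat: str, iv: Interval) -> str:
            attrs = (
                f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; '
                f'gene_biotype "{"protein_coding" if g.coding else "lncRNA"}";'
            )
            return (
                f"{g.chrom}\t{source}\t{feat}\t{iv.start}\t{iv.end}"
                f"\t.\t{g.strand}\t.\t{attrs}\n"
            )

        with open(path, "w") as fh:
            for g in self.genes:
                fh.write(row(g, "gene", Interval(g.start, g.end)))
                fh.write(row(g, "transcript", Interval(g.start, g.end)))
                for iv in g.exons:
                    fh.write(row(g, "exon", iv))
                for iv in g.cds:
                    fh.write(row(g, "CDS", iv))
                for iv in g.utr5:
                    fh.write(row(g, "five_prime_utr", iv))
                for iv in g.utr3:
                    fh.write(row(g, "three_prime_utr", iv))
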