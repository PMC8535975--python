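"""Single-nucleotide variant loci.

``SNVLocus`` is the universal key of the package: counting, call-set
algebra, annotation and regression all identify a variant by
(chrom, pos, ref, alt) with a 1-based position (VCF convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

BASES = ("A", "C", "G", "T")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


@dataclass(frozen=True, order=True)
class SNVLocus:
    """A single-nucleotide variant site.

    Parameters
    ----------
    chrom : str
        Reference sequence name.
    pos : int
        1-based position (VCF convention).
    ref : str
        Reference allele, one of A/C/G/T.
    alt : str
        Alternate allele, one of A/C/G/T, distinct from ``ref``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"ref/alt must be in {BASES}: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str]:
        """Matching key used by call-set algebra: (chrom, pos, alt).

        Genotype and ref are deliberately not part of the key, so the same
        substitution reported by two callers matches regardless of
        genotype representation.
        """
        return (self.chrom, self.pos, self.alt)

    def __str__(self) -> str:  # e.g. "chr1:1234_G>A"
        return f"{self.chrom}:{self.pos}_{self.ref}>{self.alt}"


def read_loci_tsv(path: str) -> list[SNVLocus]:
    """Read loci from a 4-column TSV (chrom, pos, ref, alt), '#' comments allowed."""
    out: list[SNVLocus] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{i}: expected 4 columns, got {len(fields)}")
            chrom, pos, ref, alt = fields[:4]
            out.append(SNVLocus(chrom, int(pos), ref.upper(), alt.upper()))
    return out


def write_loci_tsv(loci: Iterable[SNVLocus], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tref\talt\n")
        for loc in loci:
            fh.write(f"{loc.chrom}\t{loc.pos}\t{loc.ref}\t{loc.alt}\n")
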