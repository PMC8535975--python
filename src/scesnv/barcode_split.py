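"""Split pooled barcoded alignments into per-cell sets.

The cell of origin is taken from the CB tag (the corrected barcode).
Records that are unmapped, secondary, supplementary, below the MAPQ
cutoff, lacking a CB tag, or tagged with a barcode outside the whitelist
are dropped and tallied by reason; kept + dropped always equals the
input record count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pysam

DROP_REASONS = (
    "unmapped",
    "secondary",
    "supplementary",
    "low_mapq",
    "no_barcode",
    "not_in_whitelist",
)


@dataclass
class BarcodeIndex:
    """Per-barcode alignment groups plus drop accounting."""

    groups: dict[str, list] = field(default_factory=dict)  # barcode -> records
    dropped: Counter = field(default_factory=Counter)
    n_input: int = 0
    header: Optional[pysam.AlignmentHeader] = None

    @property
    def n_kept(self) -> int:
        return sum(len(v) for v in self.groups.values())

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())

    def barcodes(self) -> list[str]:
        return sorted(self.groups)

    def write_per_cell(self, out_dir: str, suffix: str = ".sam") -> dict[str, str]:
        """Materialize one SAM file per barcode; returns barcode -> path."""
        import os

        if self.header is None:
            raise ValueError("no header captured; cannot write SAM")
        os.makedirs(out_dir, exist_ok=True)
        paths = {}
        for bc in self.barcodes():
            path = os.path.join(out_dir, bc + suffix)
            with pysam.AlignmentFile(path, "w", header=self.header) as out:
                for rec in self.groups[bc]:
                    out.write(rec)
            paths[bc] = path
        return paths


def load_whitelist(path: str) -> set[str]:
    """Read a barcode whitelist, one barcode per line.

    A trailing "-1"-style suffix is stripped; barcodes are uppercased and
    deduplicated.  Non-ACGT characters raise with the offending line.
    """
    out: set[str] = set()
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            bc = line.strip()
            if not bc:
                continue
            if "-" in bc:
                bc = bc.split("-", 1)[0]
            bc = bc.upper()
            if not bc or any(ch not in "ACGT" for ch in bc):
                raise ValueError(f"{path}:{i}: invalid barcode {line.strip()!r}")
            out.add(bc)
    return out


def split_by_barcode(
    alignments: Iterable,
    whitelist: Optional[set[str]] = None,
    min_mapq: int = 0,
    header: Optional[pysam.AlignmentHeader] = None,
) -> BarcodeIndex:
    """Group records by their CB tag, preserving input order within cells.

    ``alignments`` may be an iterable of pysam records, a pysam
    AlignmentFile, or a SAM/BAM path.  An explicitly empty whitelist is
    an error (it would drop everything silently).
    """
    if whitelist is not None and len(whitelist) == 0:
        raise ValueError("whitelist provided but empty")
    close = None
    if isinstance(alignments, str):
        alignments = close = pysam.AlignmentFile(alignments)
    if isinstance(alignments, pysam.AlignmentFile):
        header = alignments.header
    index = BarcodeIndex(header=header)
    try:
        for rec in alignments:
            index.n_input += 1
            if rec.is_unmapped:
                index.dropped["unmapped"] += 1
            elif rec.is_secondary:
                index.dropped["secondary"] += 1
            elif rec.is_supplementary:
                index.dropped["supplementary"] += 1
            elif rec.mapping_quality < min_mapq:
                index.dropped["low_mapq"] += 1
            elif not rec.has_tag("CB"):
                index.dropped["no_barcode"] += 1
            else:
                bc = rec.get_tag("CB")
                if whitelist is not None and bc not in whitelist:
                    index.dropped["not_in_whitelist"] += 1
                else:
                    index.groups.setdefault(bc, []).append(rec)
    finally:
        if close is not None:
            close.close()
    assert index.n_kept + index.n_dropped == index.n_input
    return index
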