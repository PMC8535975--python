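"""Published summary counts from an MCF7 anticancer-treatment scRNA-seq
time-course (four time-points t0/t12/t48/t96 with matched bulk DNA).

These are the printed dataset-level tallies that the enrichment and
ratio computations take as input: per-category counts of single-cell-
exclusive SNVs (sceSNVs) versus pooled-alignment SNVs (pSNVs), and the
headline discovery counts per time-point.  They let the category
chi-square comparison and the recovery-percentage arithmetic be
recomputed exactly without any sequence data.
"""

from __future__ import annotations

# Functional-annotation category counts: {timepoint: {category: (sceSNV, pSNV)}}
CATEGORY_COUNTS = {
    "t0": {
        "3-prime-UTR": (8075, 6062),
        "missense": (2010, 1129),
        "intron": (1609, 24634),
        "synonymous": (897, 1365),
        "intergenic": (276, 6484),
        "non-coding-exon": (250, 414),
        "5-prime-UTR": (152, 816),
        "splice": (16, 105),
        "stop": (100, 6),
    },
    "t12": {
        "3-prime-UTR": (5785, 6340),
        "missense": (1562, 1513),
        "intron": (870, 19247),
        "synonymous": (758, 1844),
        "intergenic": (182, 4680),
        "non-coding-exon": (142, 357),
        "5-prime-UTR": (78, 1027),
        "splice": (15, 120),
        "stop": (78, 6),
    },
    "t48": {
        "3-prime-UTR": (4109, 5618),
        "missense": (1323, 1388),
        "intron": (667, 17559),
        "synonymous": (580, 1756),
        "intergenic": (161, 4475),
        "non-coding-exon": (102, 331),
        "5-prime-UTR": (118, 1098),
        "splice": (9, 103),
        "stop": (62, 2),
    },
    "t96": {
        "3-prime-UTR": (6562, 5272),
        "missense": (1744, 915),
        "intron": (1045, 14351),
        "synonymous": (793, 1213),
        "intergenic": (236, 4941),
        "non-coding-exon": (200, 421),
        "5-prime-UTR": (80, 622),
        "splice": (18, 78),
        "stop": (116, 5),
    },
}

# Transcriptome-wide discovery tallies per time-point:
# n_pooled: pooled-alignment union; n_scesnv: sceSNVs; n_lowfrac: sceSNVs
# also found by the pooled low-fraction caller; n_cells: cells in dataset;
# max_cells_with_scesnv: largest carrier-cell count of any sceSNV;
# n_ge2: sceSNVs seen in two or more cells.
TRANSCRIPTOME_WIDE = {
    "t0": dict(n_pooled=489048, n_scesnv=13385, n_lowfrac=1310, n_cells=1749,
               max_cells_with_scesnv=90, n_ge2=636),
    "t12": dict(n_pooled=524598, n_scesnv=9470, n_lowfrac=936, n_cells=2778,
                max_cells_with_scesnv=44, n_ge2=472),
    "t48": dict(n_pooled=446779, n_scesnv=7131, n_lowfrac=560, n_cells=1891,
                max_cells_with_scesnv=33, n_ge2=318),
    "t96": dict(n_pooled=335839, n_scesnv=10794, n_lowfrac=856, n_cells=1250,
                max_cells_with_scesnv=30, n_ge2=429),
}

# Counts restricted to the exonic regions of a 334-gene cancer panel
# (POP targeted-exome capture): per-cell confident intersection vs sceSNVs.
POP_PANEL = {
    "t0": dict(n_intersection=149, n_scesnv=73, n_lowfrac=6),
    "t12": dict(n_intersection=101, n_scesnv=61, n_lowfrac=7),
    "t48": dict(n_intersection=79, n_scesnv=38, n_lowfrac=1),
    "t96": dict(n_intersection=86, n_scesnv=45, n_lowfrac=2),
}


def category_counts(timepoint: str) -> tuple[dict[str, int], dict[str, int]]:
    """(sceSNV counts, pSNV counts) dictionaries for one time-point."""
    table = CATEGORY_COUNTS[timepoint]
    return (
        {cat: sce for cat, (sce, _) in table.items()},
        {cat: p for cat, (_, p) in table.items()},
    )
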