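# Methods

## The discovery model

The pipeline contrasts two regimes of variant calling on the same barcoded
alignment stream. The pooled (pseudo-bulk) regime maximizes recall: calls
from all callers and all matched datasets (pooled scRNA-seq, bulk DNA) are
unioned without quality filtering. The per-cell regime maximizes precision:
the stream is split by the corrected cell barcode (CB tag), each cell's
alignments are genotyped independently, calls are filtered at
`QUAL > 100`, `MQ > 60`, `QD > 2` (all strict; calls missing MQ or QD
fail), and, when two callers are available, only calls made by both in the
same cell survive. Single-cell-exclusive SNVs are the per-cell survivors
absent from the pooled union:

    sceSNV = (∪ over cells of confident per-cell calls) \ pooled/bulk union

followed by removal of loci inside a repeat-region BED mask. Call identity
throughout is the key (chrom, pos, alt): genotype and ref are not matched,
so the same substitution reported with different genotypes by different
callers still intersects. A configuration switch (`filter_pooled`) applies
the same quality filter to the pooled union, which is the setting used for
the category-distribution comparisons (the "pSNV" sets), where both sides
must be filtered identically.

Records that are unmapped, secondary, supplementary, or below the MAPQ
cutoff are dropped before splitting, with per-reason tallies; kept plus
dropped always equals input. The barcode source is the corrected CB tag,
not the raw CR tag, because the upstream aligner's corrected assignment is
the conventional cell identity.

## Per-cell allele counting (VAF_RNA)

For each (cell, SNV) pair, every primary alignment whose aligned base
covers the position contributes after UMI collapsing: base equal to ref →
`n_ref`, equal to alt → `n_var`, anything else → `n_other`; deletions and
reference skips spanning the position contribute to none. The expressed
allele fraction `VAF_RNA = n_var/(n_var + n_ref)` is reported only where
`n_ref + n_var ≥ minR` (default 3) — an undefined VAF means "not
assessable", and such cells are excluded from downstream regressions
rather than imputed as zero. VAF distributions include assessable cells
with only reference reads (VAF 0), which is what makes the germline
heterozygous distribution center at 0.5 and the somatic distribution pile
up near 0.

UMI policy (default `umi_consensus`): reads sharing (CB, UB) at a locus
collapse to one observation by majority base; ties count as `n_other`.
`umi_first` keeps the best-quality read's base (ties broken by start, then
base, so counts are independent of record order); `none` counts every
read. Counting is strand-agnostic — 3' libraries report reads on both
reference strands. Multi-allelic sites are represented as separate loci
sharing (chrom, pos), each with its own counts from the same base tally.
Defaults `min_mapq = 255` (the STAR unique-mapper convention) and
`min_baseq = 20` are logged in output headers and configurable.

## The stand-in genotyper

External caller VCFs are the primary input. So the pipeline also runs
without them, a binomial genotype-likelihood caller is included: at each
site with depth ≥ `min_depth` (default 5) and ≥ 2 reads of the top
non-reference base, likelihoods of {RR, RA, AA} are computed with per-base
error `e` (ref read | RA has probability (1−e)/2 + e/6, etc.), a uniform
genotype prior is applied, and a call is emitted when
P(not RR | data) > 0.99. `QUAL = −10·log10 P(RR|data)`,
`QD = QUAL/depth`, `MQ` = mean MAPQ of contributing reads. The analogous
low-fraction pooled caller tests the top non-reference count against
Binomial(depth, e/3) and calls at p < 1e−6 — a deliberately permissive
stand-in for somatic low-fraction callers, used only to report the
"recovered by low-fraction caller" fraction of a sceSNV set.

With one built-in caller, the per-cell "intersection of two callers" is
the identity; the two-caller path is exercised through externally supplied
per-cell VCF directories (one per caller, files named by barcode).

## Functional categories and enrichment

Classification uses a one-transcript-per-gene model with explicit exon /
CDS / UTR intervals and a fixed precedence: coding change (translate the
mutated codon on the coding strand; stop-gain and stop-loss → `stop`,
amino-acid change → `missense`, silent — including stop→stop — →
`synonymous`) > `splice` (within 2 bp inside an intron at a junction) >
`3-prime-UTR` / `5-prime-UTR` > `non-coding-exon` > `intron` >
`intergenic`. An SNV hitting several overlapping genes takes the
highest-precedence category; ties break on the smallest gene id. An SNV
whose stated ref disagrees with the reference is rejected loudly.

Novelty: an SNV is novel iff its (chrom, pos, ref, alt) key is absent from
every supplied catalog.

Category enrichment between two sets uses, per category, the 2×2 table
(in-category vs all-other × set A vs set B) and the Yates
continuity-corrected chi-square with 1 df, computed in closed form with
the correction clamped so the statistic is never negative:

    χ² = N·(max(|ad − bc| − N/2, 0))² / [(a+b)(c+d)(a+c)(b+d)]

The correction is applied because recomputing the published MCF7
time-course tables from their printed per-category counts reproduces the
printed statistics only with it (stop 275, 3'-UTR 10,883, synonymous 287,
intergenic 1,751, splice 8 at t0; stop 275 at t96). Two printed t0 values
are not reproducible from the printed counts by corrected or uncorrected
computation — missense (printed 2,808; corrected recomputation 2,789) and
intron (printed 9,236; recomputed 9,326) — and are treated as likely
typesetting errors: the test suite asserts the recomputed values and the
implementation is not tuned toward the printed ones. A zero category
margin makes the statistic undefined (reported as NaN), not zero.

## cis-scReQTL

Cells failing QC are removed first: fewer than 1,000 detected genes, more
than 5,000 detected genes (doublet proxy; the defensible range is
4,500–5,500 and the cutoff is a config value), or mitochondrial count
fraction above 0.10 (range 0.075–0.15), with mitochondrial genes
identified by a configurable name prefix. Counts are then depth-scaled to
the median cell total and log1p-transformed — a deliberately simple,
deterministic normalization standing in for variance-stabilizing
transforms, which are out of scope. Covariates are the scores of the top
15 principal components of the normalized matrix (sign fixed so each
component's largest-magnitude loading is positive, for determinism).

For each SNV with a defined VAF in ≥ 5 cells (the inclusive ≥5 reading of
"more than 5 cells" is the default and configurable), ordinary least
squares regresses the harboring gene's normalized expression on VAF with
intercept and PCs, over exactly the cells where VAF is defined. The
two-sided t-test of the VAF coefficient gives p; Benjamini–Hochberg
(step-up, implemented directly and cross-checked against statsmodels in
tests) gives q across all tested pairs. Expression is the response and
VAF the predictor — the usual eQTL orientation; the slope t-test is
symmetric in the simple-regression case. Constant-VAF and unmapped-gene
SNVs are skipped with tallies. Both the FDR-significant and the p < 0.05
counts are reported.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes:

* **Reference and genes.** Random chromosomes with packed, non-overlapping
  genes; coding genes have a 5' UTR (60–150 bp), 2–3 CDS exons of 40–80
  codons each (ATG start, single terminal stop, no internal stops),
  introns of 80–300 bp, and a 3' UTR of 200–400 bp; a configurable
  fraction of genes (default 0.15, placed at evenly spaced indices so
  small models still contain some) are non-coding. Minus-strand genes are
  built on the coding strand and reverse-complemented into the genome.
  Every exon exceeds the read length so reads fit inside exons.
* **Variants.** Germline SNVs land at random exonic positions
  (heterozygous with probability 0.8 by default); somatic SNVs are drawn
  by rejection sampling until their classified category matches a
  requested category distribution (default: mostly 3'-UTR and missense,
  mirroring a 3'-biased library), and each receives
  `round(carrier_fraction × n_cells)` carrier cells sampled without
  replacement (default fraction 0.05 — the observed ceiling for cells
  carrying one sceSNV; `carrier_fraction × n_cells < 1` is an error). All
  planted loci are ≥ 100 bp apart so reads for one locus never cover
  another. A configurable fraction (default 0.3) is flagged as present in
  the synthetic known-variant catalogs.
* **Reads.** For each exonic planted locus and each cell expressing it
  (probability 0.9), Poisson(depth 30) UMIs are drawn; each UMI picks its
  allele — Bernoulli(0.5) at heterozygous germline sites, the somatic VAF
  (default 0.5, i.e. a heterozygous somatic mutation; low observed VAF
  should arise from sampling, not be baked into the truth) in carrier
  cells, ref otherwise — a uniform start within the containing exon, and
  a 90 bp ungapped alignment with per-base errors at 0.005. With
  probability 0.3 a UMI emits one PCR duplicate sharing (CB, UB,
  position) with independent errors. Records carry CB/UB/NH tags, MAPQ
  255, base quality 40, and are coordinate-sorted; identical seeds give
  byte-identical SAM output. Cell barcodes are 16-mers whose last base is
  a checksum, guaranteeing pairwise Hamming distance ≥ 2 without
  implementing barcode correction.
* **Expression.** Cell × gene counts are negative-binomial
  (gamma–Poisson, dispersion 10) around per-gene lognormal baselines; for
  designated effect SNVs the harboring gene's log-mean is shifted by
  β × (cell's true VAF).

The paper-scale defaults used by tests and the acceptance script are 50
cells / depth 30 / error 0.005 / carrier VAF 0.5 for discovery, and
400 cells / 200 genes / β = 0.5 / 200 carriers for effect recovery —
miniature but structure-preserving versions of the thousands of cells in a
real dataset, chosen so every run is exact and fast.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: ambient RNA and empty droplets, barcode
sequencing errors, doublets, spliced-read alignment artifacts, intronic
(pre-mRNA) coverage (planted intronic/intergenic SNVs produce no reads and
therefore cannot be discovered, only annotated), allele-specific
expression, RNA editing, mapping bias, and base-quality miscalibration.
Error reads here are honest random substitutions at full base quality;
real false positives are clustered and context-dependent.

## Numerical choices and degenerate inputs

Loci are 1-based inclusive everywhere (VCF convention); BED masks are
converted from 0-based half-open at the boundary. UMI-consensus base ties
count as `n_other`; records without a UB tag under a UMI policy count as
their own molecules. Genotype posteriors use log10 likelihoods with a
1e−300 floor; QUAL is capped only by that floor. An empty whitelist,
an empty per-cell call-set list, an all-cells-fail QC, and a zero-depth
cell are explicit errors rather than silent empties. Carrier histograms on
an empty sceSNV report raise. PCA components beyond the matrix rank raise.
The pipeline writes every threshold it used into its log so any reported
number can be audited against the persisted artifacts.

## Known limitations

The built-in genotyper is a simple binomial model without local
reassembly, strand bias tests, or base-quality recalibration — external
caller VCFs remain the intended path for real data. The gene model is one
transcript per gene, so isoform arbitration and transcript-level
annotation subtleties are out of scope. The normalization is a stand-in;
batch, cell-cycle, and cell-type structure are not modeled or corrected.
The low-fraction pooled caller recovers essentially all simulated somatic
sites at depth 1,500 because simulated errors are independent; its
recovery fraction on synthetic data is therefore much higher than the
~10% seen with a real somatic caller on real data.
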