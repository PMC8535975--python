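"""Cell QC, normalization, PCA covariates and cis-scReQTL regression.

For each SNV with an assessable VAF_RNA in at least ``min_cells`` cells,
the normalized expression of the harboring gene is regressed on the
per-cell VAF with the top principal components of expression (default
15) and an intercept as covariates:

    expr_g ~ intercept + VAF_snv + PC1 ... PCk

The two-sided t test of the VAF coefficient gives the p-value;
Benjamini-Hochberg controls the FDR across all tested (SNV, gene)
pairs.
"""

from __future__ import annotations


from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.decomposition import PCA

from .loci import SNVLocus
from .readcounts import CellSNVMatrix


# --------------------------------------------------------------------------
# Cell QC
# --------------------------------------------------------------------------

@dataclass
class QCReport:
    n_input: int
    n_kept: int
    removed: dict  # reason -> list of barcodes


def qc_cells(
    counts: pd.DataFrame,
    min_genes: int = 1000,
    max_genes: int = 5000,
    mito_max: float = 0.10,
    mito_prefix: str = "MT-",
) -> tuple[pd.DataFrame, QCReport]:
    """Remove low-quality cells and putative doublets.

    Cells are dropped when the number of detected genes (nonzero counts)
    is below ``min_genes`` ("low_genes"), above ``max_genes``
    ("high_genes", doublet proxy), or when the fraction of counts in
    mitochondrial genes (identified by name prefix) exceeds ``mito_max``
    ("high_mito").  A cell failing several rules is reported once, under
    the first matching reason in that order.
    """
    detected = (counts > 0).sum(axis=1)
    total = counts.sum(axis=1)
    mito_cols = [c for c in counts.columns if c.startswith(mito_prefix)]
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = (
            counts[mito_cols].sum(axis=1) / total if mito_cols
            else pd.Series(0.0, index=counts.index)
        )
    mito_frac = mito_frac.fillna(0.0)

    removed: dict[str, list[str]] = {"low_genes": [], "high_genes": [],
                                     "high_mito": []}
    keep = []
    for bc in counts.index:
        if detected[bc] < min_genes:
            removed["low_genes"].append(bc)
        elif detected[bc] > max_genes:
            removed["high_genes"].append(bc)
        elif mito_frac[bc] > mito_max:
            removed["high_mito"].append(bc)
        else:
            keep.append(bc)
    if not keep:
        raise ValueError("no cells survive QC")
    out = counts.loc[keep]
    return out, QCReport(n_input=len(counts), n_kept=len(keep), removed=removed)


def normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Median-depth scaling followed by log1p.

    Each cell's counts are scaled so its total equals the median cell
    total, then log1p-transformed.  Deterministic; zero-depth cells are
    an error (they should have been removed by QC).
    """
    depth = counts.sum(axis=1)
    if (depth == 0).any():
        bad = list(counts.index[depth == 0])[:3]
        raise ValueError(f"zero-depth cell(s): {bad}")
    target = float(np.median(depth))
    scaled = counts.mul(target / depth, axis=0)
    return np.log1p(scaled)


def pca_covariates(normalized: pd.DataFrame, k: int = 15) -> pd.DataFrame:
    """Scores of the top-k principal components of the centered matrix.

    The sign of each component is fixed so its largest-magnitude loading
    is positive.  ``k`` exceeding the matrix rank is an error; k=0 gives
    an empty covariate frame (regressions fall back to intercept only).
    """
    if k == 0:
        return pd.DataFrame(index=normalized.index)
    n, p = normalized.shape
    if k > min(n, p):
        raise ValueError(f"k={k} exceeds matrix dimensions {normalized.shape}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(normalized.to_numpy())
    if np.any(pca.explained_variance_ <= 1e-12):
        raise ValueError(f"k={k} exceeds the rank of the centered matrix")
    for j in range(k):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            pca.components_[j] = -load
            scores[:, j] = -scores[:, j]
    return pd.DataFrame(
        scores, index=normalized.index,
        columns=[f"PC{j + 1}" for j in range(k)],
    )


# --------------------------------------------------------------------------
# FDR
# --------------------------------------------------------------------------

def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min over j >= i of (m * p_(j) / j), clipped to [0, 1], mapped
    back to the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# --------------------------------------------------------------------------
# cis-scReQTL
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ReQTLResult:
    snv: SNVLocus
    gene: str
    n_cells: int
    beta: float
    t: float
    p_value: float
    q_value: float


def cis_screqtl(
    cell_snv_matrix: CellSNVMatrix,
    expression: pd.DataFrame,
    covariates: Optional[pd.DataFrame],
    gene_map: dict[SNVLocus, Optional[str]],
    min_cells: int = 5,
    fdr_alpha: float = 0.05,
) -> tuple[list[ReQTLResult], dict]:
    """Regress harboring-gene expression on per-cell VAF_RNA.

    Cells with undefined VAF (coverage below minR) are excluded from a
    pair's regression; eligibility requires a defined VAF in at least
    ``min_cells`` cells present in the expression matrix.  Returns the
    results sorted by q-value and a tally of skipped SNVs.
    """
    skipped = {"no_gene": 0, "gene_not_in_matrix": 0, "too_few_cells": 0,
               "constant_vaf": 0}
    tested: list[dict] = []
    cells_in_expr = set(expression.index)
    for locus in sorted(set(cell_snv_matrix.loci), key=lambda l: (l.chrom, l.pos, l.alt)):
        gene = gene_map.get(locus)
        if gene is None:
            skipped["no_gene"] += 1
            continue
        if gene not in expression.columns:
            skipped["gene_not_in_matrix"] += 1
            continue
        vec = cell_snv_matrix.vaf_vector(locus)
        cells = sorted(bc for bc in vec if bc in cells_in_expr)
        if len(cells) < min_cells:
            skipped["too_few_cells"] += 1
            continue
        v = np.array([vec[bc] for bc in cells])
        if np.ptp(v) == 0:
            skipped["constant_vaf"] += 1
            continue
        y = expression.loc[cells, gene].to_numpy()
        X = pd.DataFrame({"vaf": v}, index=cells)
        if covariates is not None and covariates.shape[1] > 0:
            X = pd.concat([X, covariates.loc[cells]], axis=1)
        X = sm.add_constant(X, prepend=True)
        fit = sm.OLS(y, X).fit()
        tested.append(
            dict(snv=locus, gene=gene, n_cells=len(cells),
                 beta=float(fit.params["vaf"]), t=float(fit.tvalues["vaf"]),
                 p=float(fit.pvalues["vaf"]))
        )
    qvals = benjamini_hochberg([t["p"] for t in tested])
    results = [
        ReQTLResult(snv=t["snv"], gene=t["gene"], n_cells=t["n_cells"],
                    beta=t["beta"], t=t["t"], p_value=t["p"],
                    q_value=float(q))
        for t, q in zip(tested, qvals)
    ]
    results.sort(key=lambda r: (r.q_value, r.p_value, str(r.snv)))
    skipped["n_tested"] = len(results)
    skipped["n_significant_fdr"] = sum(r.q_value <= fdr_alpha for r in results)
    skipped["n_significant_p"] = sum(r.p_value < 0.05 for r in results)
    return results, skipped


def results_to_df(results: Sequence[ReQTLResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (str(r.snv), r.gene, r.n_cells, r.beta, r.t, r.p_value, r.q_value)
            for r in results
        ],
        columns=["snv", "gene", "n_cells", "beta", "t", "p", "q"],
    )
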