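"""Expression normalization, four-stage cell QC, and the expressed-gene rule.

The QC criteria, applied sequentially:

1. non-mitochondrial library size > ``min_nonmito_libsize`` (strict);
2. expressed genes per cell (RPKM >= ``expressed_rpkm``) > ``min_genes_per_cell``
   (strict);
3. among survivors of 1-2, maximum pairwise Spearman correlation over the
   expressed-gene RPKM submatrix >= ``min_max_spearman``;
4. cells of excluded embryos (e.g. aneuploid) dropped.

Every failure is annotated with a reason code in ``qc_fail_reasons``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats

from .types import ExpressionDataset

logger = logging.getLogger("scembryo")

#: Reason codes written into qc_fail_reasons.
REASON_LIBSIZE = "low_nonmito_libsize"
REASON_NGENES = "few_expressed_genes"
REASON_CORRELATION = "low_max_spearman"
REASON_EMBRYO = "excluded_embryo"


from dataclasses import dataclass, field


@dataclass
class QCThresholds:
    """Cut-offs for cell QC, gene selection and methylome cell QC."""

    min_nonmito_libsize: int = 50_000
    min_genes_per_cell: int = 3000
    min_max_spearman: float = 0.5
    excluded_embryos: tuple[str, ...] = ()
    expressed_rpkm: float = 1.0
    expressed_min_cells: int = 5
    meth_min_reads: int = 100_000
    meth_min_mapped_frac: float = 0.07

    def __post_init__(self) -> None:
        for name in (
            "min_nonmito_libsize",
            "min_genes_per_cell",
            "min_max_spearman",
            "expressed_rpkm",
            "expressed_min_cells",
            "meth_min_reads",
            "meth_min_mapped_frac",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"threshold {name} must be >= 0")


def normalize_expression(
    counts: pd.DataFrame,
    genes: pd.DataFrame,
    total_mapped_reads: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute RPKM and TPM from counts.

    RPKM_gc = counts_gc / (length_kb_g * total_mapped_reads_c / 1e6).

    TPM uses a library size **excluding mitochondrial genes**:
    TPM_gc = 1e6 * (counts_gc/length_kb_g) / sum_{g' non-mito}(counts_{g'c}/length_kb_{g'}),
    so TPM columns sum to 1e6 over non-mitochondrial genes.  A cell whose
    only expressed genes are mitochondrial has an undefined TPM column
    (all-NaN), flagged with a warning.
    """
    if (genes["length_bp"] <= 0).any():
        raise ValueError("gene lengths must be > 0")
    length_kb = genes["length_bp"].astype(float) / 1000.0
    reads_m = total_mapped_reads.astype(float) / 1e6
    if (reads_m <= 0).any():
        raise ValueError("total_mapped_reads must be > 0")

    per_kb = counts.div(length_kb, axis=0)
    rpkm = per_kb.div(reads_m, axis=1)

    nonmito = ~genes["is_mito"].values
    denom = per_kb.loc[nonmito].sum(axis=0)
    undefined = denom == 0
    if undefined.any():
        logger.warning(
            "TPM undefined for %d cell(s) with empty non-mitochondrial library: %s",
            int(undefined.sum()),
            list(counts.columns[undefined])[:5],
        )
    denom = denom.replace(0, np.nan)
    tpm = per_kb.div(denom, axis=1) * 1e6
    return rpkm, tpm


def count_expressed_genes(rpkm: pd.DataFrame, expressed_rpkm: float = 1.0) -> pd.Series:
    """Number of expressed genes (RPKM >= cut-off) per cell."""
    return (rpkm >= expressed_rpkm).sum(axis=0)


def _max_pairwise_spearman(rpkm_sub: pd.DataFrame) -> pd.Series:
    """Per-cell maximum Spearman correlation against any other cell."""
    cells = rpkm_sub.columns
    if len(cells) == 2:
        rho = scipy.stats.spearmanr(rpkm_sub.iloc[:, 0], rpkm_sub.iloc[:, 1])[0]
        return pd.Series([rho, rho], index=cells)
    corr, _ = scipy.stats.spearmanr(rpkm_sub.values, axis=0)
    corr = np.asarray(corr)
    np.fill_diagonal(corr, -np.inf)
    return pd.Series(corr.max(axis=1), index=cells)


def qc_filter_cells(
    ds: ExpressionDataset, thresholds: QCThresholds | None = None
) -> ExpressionDataset:
    """Apply the four QC criteria and annotate qc_pass / qc_fail_reasons.

    Criterion 3 is computed only among the survivors of criteria 1-2 (its
    Spearman submatrix is the dataset-level expressed-gene set over those
    survivors), so adding a cell that fails an earlier criterion cannot
    change another cell's status.  Criterion 4 applies to all cells.
    Returns a new dataset with updated cell metadata; the matrix axes are
    unchanged (filtering is an annotation, not a subset).
    """
    thr = thresholds or QCThresholds()
    if ds.rpkm is None:
        raise ValueError("qc_filter_cells requires RPKM (run normalize_expression)")

    reasons: dict[str, list[str]] = {c: [] for c in ds.counts.columns}

    nonmito = ~ds.genes["is_mito"].values
    libsize = ds.counts.loc[nonmito].sum(axis=0)
    for c in ds.counts.columns[libsize <= thr.min_nonmito_libsize]:
        reasons[c].append(REASON_LIBSIZE)

    n_genes = count_expressed_genes(ds.rpkm, thr.expressed_rpkm)
    for c in ds.counts.columns[n_genes <= thr.min_genes_per_cell]:
        reasons[c].append(REASON_NGENES)

    survivors = [c for c in ds.counts.columns if not reasons[c]]
    if len(survivors) < 2:
        logger.warning(
            "criterion 3 skipped: fewer than 2 cells survive criteria 1-2"
        )
    else:
        expressed = select_expressed_genes(ds, thr, cells=survivors)
        if len(expressed) == 0:
            logger.warning("criterion 3 skipped: no expressed genes among survivors")
        else:
            max_rho = _max_pairwise_spearman(ds.rpkm.loc[expressed, survivors])
            for c in max_rho.index[max_rho < thr.min_max_spearman]:
                reasons[c].append(REASON_CORRELATION)

    excluded = set(thr.excluded_embryos)
    if excluded:
        for c in ds.counts.columns[ds.cells["embryo_id"].isin(excluded)]:
            reasons[c].append(REASON_EMBRYO)

    cells = ds.cells.copy()
    cells["qc_fail_reasons"] = [reasons[c] for c in cells.index]
    cells["qc_pass"] = [len(reasons[c]) == 0 for c in cells.index]
    n_pass = int(cells["qc_pass"].sum())
    logger.info("QC: %d / %d cells retained", n_pass, len(cells))
    return ExpressionDataset(
        counts=ds.counts, genes=ds.genes, cells=cells, rpkm=ds.rpkm, tpm=ds.tpm
    )


def select_expressed_genes(
    ds: ExpressionDataset,
    thresholds: QCThresholds | None = None,
    cells: list[str] | None = None,
) -> pd.Index:
    """Genes expressed (RPKM >= cut-off) in at least ``expressed_min_cells``
    QC-passing cells (or an explicit cell subset)."""
    thr = thresholds or QCThresholds()
    if ds.rpkm is None:
        raise ValueError("select_expressed_genes requires RPKM")
    if cells is None:
        cells = list(ds.cells.index[ds.cells["qc_pass"]])
    n = (ds.rpkm[cells] >= thr.expressed_rpkm).sum(axis=1)
    return ds.rpkm.index[n >= thr.expressed_min_cells]
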