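"""Expression-side X-dosage analysis.

Chromosome output sums, two-sided Wilcoxon rank-sum comparisons,
female-to-male per-gene expression ratios, nearest-k positional moving
averages along a chromosome, and XIST stratification.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats

from .types import ExpressionDataset

logger = logging.getLogger("scembryo")


def chromosome_output(
    ds: ExpressionDataset, chrom: str, cells: list[str] | None = None
) -> pd.Series:
    """Per-cell sum of RPKM over the genes annotated on ``chrom``.

    Callers performing X analyses should pass only sex-consistent cells
    (see :func:`scembryo.sex.xci_eligible_cells`).
    """
    if ds.rpkm is None:
        raise ValueError("chromosome_output requires RPKM")
    genes = ds.genes.index[ds.genes["chrom"] == chrom]
    rpkm = ds.rpkm if cells is None else ds.rpkm[list(cells)]
    if len(genes) == 0:
        logger.warning("chromosome %s has no annotated genes: sums are 0", chrom)
        return pd.Series(0.0, index=rpkm.columns, name=chrom)
    return rpkm.loc[genes].sum(axis=0).rename(chrom)


def wilcoxon_two_sided(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration for small untied samples, normal approximation with
    tie correction otherwise.  Two constant, equal groups give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("each group needs at least one value")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(
        scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue
    )


def fm_gene_ratios(
    ds: ExpressionDataset,
    sex_calls: pd.DataFrame,
    chrom: str,
    cells: list[str] | None = None,
    min_mean_rpkm: float = 5.0,
) -> pd.DataFrame:
    """Per-gene female-to-male expression ratios within a cell stratum.

    A gene is eligible iff its mean RPKM across the stratum's cells (sexes
    pooled) is strictly greater than ``min_mean_rpkm``.  The ratio is the
    female group mean over the male group mean, reported on the log2 scale
    with no pseudocount; genes with a zero male mean are dropped with a
    log entry.  Requires at least one cell of each sex in the stratum.
    """
    if ds.rpkm is None:
        raise ValueError("fm_gene_ratios requires RPKM")
    cells = list(cells) if cells is not None else list(ds.rpkm.columns)
    sexes = sex_calls.loc[cells, "cell_sex"]
    f_cells = [c for c in cells if sexes[c] == "female"]
    m_cells = [c for c in cells if sexes[c] == "male"]
    if not f_cells or not m_cells:
        raise ValueError("stratum must contain at least one cell of each sex")

    genes = ds.genes.index[ds.genes["chrom"] == chrom]
    rpkm = ds.rpkm.loc[genes, cells]
    eligible = rpkm.mean(axis=1) > min_mean_rpkm
    rpkm = rpkm.loc[eligible]

    mean_f = rpkm[f_cells].mean(axis=1)
    mean_m = rpkm[m_cells].mean(axis=1)
    undefined = mean_m == 0
    if undefined.any():
        logger.info(
            "fm_gene_ratios: dropping %d gene(s) with zero male mean",
            int(undefined.sum()),
        )
    out = pd.DataFrame(
        {
            "mean_f": mean_f[~undefined],
            "mean_m": mean_m[~undefined],
        }
    )
    out["ratio"] = out["mean_f"] / out["mean_m"]
    out["log2_ratio"] = np.log2(out["ratio"].where(out["ratio"] > 0))
    return out


def moving_average_track(
    positions, values, k: int = 20
) -> pd.DataFrame:
    """Nearest-k moving average of per-gene values along a chromosome.

    For each focal gene the window is the ``k`` genes nearest by absolute
    position difference, the focal gene included, regardless of side
    (windows near chromosome ends are asymmetric, not truncated).
    Distance ties are broken toward the smaller position.  The result is
    sorted by position; input ordering does not matter.  With fewer than
    ``k`` genes the window is all genes, with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    positions = np.asarray(positions, dtype=np.int64)
    values = np.asarray(values, dtype=float)
    if positions.shape != values.shape:
        raise ValueError("positions and values must have the same length")
    n = len(positions)
    if n == 0:
        return pd.DataFrame(columns=["position", "value", "smoothed"])
    if n < k:
        logger.warning("moving_average_track: %d genes < k=%d, window = all genes", n, k)
        k = n

    order = np.argsort(positions, kind="mergesort")
    pos = positions[order]
    val = values[order]
    smoothed = np.empty(n)
    for i in range(n):
        lo = hi = i  # inclusive window bounds in sorted order
        while hi - lo + 1 < k:
            d_left = pos[i] - pos[lo - 1] if lo > 0 else np.inf
            d_right = pos[hi + 1] - pos[i] if hi < n - 1 else np.inf
            if d_left <= d_right:  # tie -> smaller position
                lo -= 1
            else:
                hi += 1
        smoothed[i] = val[lo : hi + 1].mean()
    return pd.DataFrame({"position": pos, "value": val, "smoothed": smoothed})


def xist_summary(
    ds: ExpressionDataset,
    sex_calls: pd.DataFrame,
    cells: list[str] | None = None,
    xist_gene: str = "XIST",
) -> dict:
    """XIST RPKM distributions stratified by sex x treatment, with a
    female-vs-male Wilcoxon p-value per treatment arm.

    Returns ``{arm: {"female": values, "male": values, "p_f_vs_m": p}}``.
    """
    if ds.rpkm is None:
        raise ValueError("xist_summary requires RPKM")
    if xist_gene not in ds.rpkm.index:
        raise ValueError(f"required gene {xist_gene!r} absent from the dataset")
    cells = list(cells) if cells is not None else list(ds.rpkm.columns)
    xist = ds.rpkm.loc[xist_gene, cells]
    sexes = sex_calls.loc[cells, "cell_sex"]
    arms = ds.cells.loc[cells, "treatment"]

    out: dict = {}
    for arm in sorted(arms.unique()):
        in_arm = arms == arm
        f = xist[in_arm & (sexes == "female")].values
        m = xist[in_arm & (sexes == "male")].values
        p = wilcoxon_two_sided(f, m) if len(f) and len(m) else float("nan")
        out[arm] = {"female": f, "male": m, "p_f_vs_m": p}
    return out
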