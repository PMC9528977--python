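"""Small-RNA biotype composition, differential expression, and the
miRNA-mRNA opposite-direction network filter.

The differential-expression test here is a deliberately generic rank-based
stand-in (two-sided Wilcoxon on counts-per-million, BH across features,
log2 fold change of group mean CPM with pseudocount 1): robust at low
counts and free of distributional claims.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .dosage import wilcoxon_two_sided
from .types import SmallRNADataset

logger = logging.getLogger("scembryo")


@dataclass
class BiotypeProfile:
    """Per-cell and group-pooled biotype proportions.

    ``per_cell`` is cells x biotypes (rows sum to 1; all-NaN for zero-total
    cells, which are excluded from tests); ``pooled`` is group x biotypes
    where each entry is total molecules of the biotype over total molecules
    across the group's cells.
    """

    per_cell: pd.DataFrame
    pooled: pd.DataFrame
    groups: pd.Series


def biotype_proportions(ds: SmallRNADataset, groups: pd.Series) -> BiotypeProfile:
    """Biotype composition per cell and pooled per group.

    ``groups`` maps cell_id -> group label (e.g. treatment arm).  Both the
    mean-of-cells view (per_cell) and the pooled-molecule view are
    reported; they coincide when all cells have equal totals.
    """
    by_bt = ds.counts.groupby(ds.biotypes, observed=True).sum()  # biotype x cell
    totals = by_bt.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.warning(
            "%d cell(s) with zero small-RNA molecules excluded from proportions",
            int(zero.sum()),
        )
    per_cell = by_bt.div(totals.where(~zero)).T  # cells x biotypes

    groups = groups.loc[ds.counts.columns]
    pooled_counts = by_bt.T.groupby(groups, observed=True).sum()  # group x biotype
    pooled = pooled_counts.div(pooled_counts.sum(axis=1), axis=0)
    return BiotypeProfile(per_cell=per_cell, pooled=pooled, groups=groups)


def test_biotype_shift(
    profile: BiotypeProfile, group_a: str, group_b: str
) -> pd.DataFrame:
    """Per-biotype two-sided Wilcoxon on per-cell proportions, BH across
    biotypes.  Zero-total cells are excluded.  Requires >= 2 cells/group."""
    ok = ~profile.per_cell.isna().any(axis=1)
    cells_a = profile.per_cell.index[(profile.groups == group_a) & ok]
    cells_b = profile.per_cell.index[(profile.groups == group_b) & ok]
    if len(cells_a) < 2 or len(cells_b) < 2:
        raise ValueError("need at least 2 cells with molecules per group")
    rows = []
    for bt in profile.per_cell.columns:
        a = profile.per_cell.loc[cells_a, bt].values
        b = profile.per_cell.loc[cells_b, bt].values
        rows.append(
            {
                "biotype": bt,
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
                "p_value": wilcoxon_two_sided(a, b),
            }
        )
    out = pd.DataFrame(rows).set_index("biotype")
    out["fdr"] = scipy.stats.false_discovery_control(out["p_value"], method="bh")
    return out


def _cpm(counts: pd.DataFrame) -> pd.DataFrame:
    totals = counts.sum(axis=0).astype(float)
    return counts.div(totals.where(totals > 0), axis=1) * 1e6


def de_features(
    counts: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
    biotypes: pd.Series | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Generic two-group differential-expression stand-in on any count
    matrix (features x cells).

    log2fc = log2((mean CPM_B + pc) / (mean CPM_A + pc)); p from a
    two-sided Wilcoxon on per-cell CPM; BH-FDR across all tested features.
    All-zero features are excluded.
    """
    cells_a = list(groups.index[groups == group_a].intersection(counts.columns))
    cells_b = list(groups.index[groups == group_b].intersection(counts.columns))
    if len(cells_a) < 2 or len(cells_b) < 2:
        raise ValueError("need at least 2 cells per group")
    cpm = _cpm(counts[cells_a + cells_b])
    nonzero = counts[cells_a + cells_b].sum(axis=1) > 0
    cpm = cpm.loc[nonzero]

    mean_a = cpm[cells_a].mean(axis=1)
    mean_b = cpm[cells_b].mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    pvals = np.array(
        [
            wilcoxon_two_sided(cpm.loc[f, cells_a].values, cpm.loc[f, cells_b].values)
            for f in cpm.index
        ]
    )
    out = pd.DataFrame(
        {
            "mean_cpm_a": mean_a,
            "mean_cpm_b": mean_b,
            "log2fc": log2fc,
            "p_value": pvals,
        },
        index=cpm.index,
    )
    if biotypes is not None:
        out.insert(0, "biotype", biotypes.loc[out.index])
    out["fdr"] = scipy.stats.false_discovery_control(out["p_value"], method="bh")
    return out


def de_smallrna(
    ds: SmallRNADataset, groups: pd.Series, group_a: str, group_b: str
) -> pd.DataFrame:
    """Differential expression of small-RNA features (B versus A)."""
    return de_features(ds.counts, groups, group_a, group_b, biotypes=ds.biotypes)


def mirna_mrna_edges(
    de_mirna: pd.DataFrame,
    de_gene: pd.DataFrame,
    target_pairs: pd.DataFrame,
    min_abs_log2fc: float = 0.25,
    max_fdr: float = 0.05,
) -> pd.DataFrame:
    """Opposite-direction miRNA-mRNA regulatory edges.

    An edge (mirna, gene) is kept iff the pair is in the target table,
    both members are significant (FDR <= ``max_fdr``) in their input DE
    tables, both |log2fc| >= ``min_abs_log2fc`` (boundary included), and
    the fold-change signs are opposite.

    ``target_pairs`` needs columns (mirna_id, gene_id); the DE tables need
    ``log2fc`` and ``fdr`` indexed by feature id.
    """
    if target_pairs.empty:
        return pd.DataFrame(
            columns=["mirna_id", "gene_id", "mirna_log2fc", "gene_log2fc"]
        )
    rows = []
    for _, pair in target_pairs.iterrows():
        mi, g = pair["mirna_id"], pair["gene_id"]
        if mi not in de_mirna.index or g not in de_gene.index:
            continue
        m_fc = float(de_mirna.loc[mi, "log2fc"])
        g_fc = float(de_gene.loc[g, "log2fc"])
        if de_mirna.loc[mi, "fdr"] > max_fdr or de_gene.loc[g, "fdr"] > max_fdr:
            continue
        if abs(m_fc) < min_abs_log2fc or abs(g_fc) < min_abs_log2fc:
            continue
        if np.sign(m_fc) == np.sign(g_fc):
            continue
        rows.append(
            {
                "mirna_id": mi,
                "gene_id": g,
                "mirna_log2fc": m_fc,
                "gene_log2fc": g_fc,
            }
        )
    out = pd.DataFrame(
        rows, columns=["mirna_id", "gene_id", "mirna_log2fc", "gene_log2fc"]
    )
    return out.drop_duplicates(subset=["mirna_id", "gene_id"]).reset_index(drop=True)
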