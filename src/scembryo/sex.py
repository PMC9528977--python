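"""Expression-based sex inference for cells and embryos.

A cell's sex is read off the summed RPKM of Y-linked genes: sums above 100
are male, below 50 female, and anything in [50, 100] (boundaries included)
is ambiguous — the stated ranges are strict, so the boundary values have no
assignment.  Embryo sex is the majority vote over that embryo's unambiguous
cells; ties are undetermined.  A cell whose own call disagrees with its
embryo's sex is flagged as a conflict, and conflicting or ambiguous cells
are excluded from downstream X-chromosome analyses.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import ExpressionDataset

logger = logging.getLogger("scembryo")

MALE_THRESHOLD = 100.0   # sum RPKM chrY strictly above -> male
FEMALE_THRESHOLD = 50.0  # sum RPKM chrY strictly below -> female

#: Columns of the per-cell sex-call table.
SEX_CALL_COLUMNS = ("sum_rpkm_chry", "cell_sex", "embryo_sex", "conflict")


def infer_cell_sex(ds: ExpressionDataset) -> pd.DataFrame:
    """Per-cell ΣRPKM(chrY) and the resulting sex label.

    Returns a table indexed by cell_id with columns ``sum_rpkm_chry`` and
    ``cell_sex`` (male / female / ambiguous).  With no Y-linked genes in
    the annotation every call is "NA", with a warning.
    """
    if ds.rpkm is None:
        raise ValueError("infer_cell_sex requires RPKM")
    chry = ds.genes.index[ds.genes["chrom"] == "chrY"]
    if len(chry) == 0:
        logger.warning("no chrY genes in annotation: sex calls are NA")
        return pd.DataFrame(
            {"sum_rpkm_chry": np.nan, "cell_sex": "NA"}, index=ds.rpkm.columns
        )
    sums = ds.rpkm.loc[chry].sum(axis=0)
    sex = pd.Series("ambiguous", index=sums.index, dtype=object)
    sex[sums > MALE_THRESHOLD] = "male"
    sex[sums < FEMALE_THRESHOLD] = "female"
    return pd.DataFrame({"sum_rpkm_chry": sums, "cell_sex": sex})


def infer_embryo_sex(
    cell_calls: pd.DataFrame, embryo_ids: pd.Series
) -> pd.DataFrame:
    """Majority-vote embryo sex and per-cell conflict flags.

    ``cell_calls`` is the output of :func:`infer_cell_sex`; ``embryo_ids``
    maps cell_id -> embryo_id.  The vote counts only unambiguous cells;
    an embryo with no unambiguous cell, or a tie, is "undetermined".
    Returns the cell table extended with ``embryo_sex`` and ``conflict``.
    """
    calls = cell_calls.copy()
    calls["embryo_id"] = embryo_ids.loc[calls.index]

    embryo_sex: dict[str, str] = {}
    for embryo, grp in calls.groupby("embryo_id"):
        votes = grp["cell_sex"].value_counts()
        n_m = int(votes.get("male", 0))
        n_f = int(votes.get("female", 0))
        if n_m == n_f:  # includes the all-ambiguous case (0 == 0)
            embryo_sex[embryo] = "undetermined"
        else:
            embryo_sex[embryo] = "male" if n_m > n_f else "female"

    calls["embryo_sex"] = calls["embryo_id"].map(embryo_sex)
    calls["conflict"] = [
        cs in ("male", "female") and es in ("male", "female") and cs != es
        for cs, es in zip(calls["cell_sex"], calls["embryo_sex"])
    ]
    n_conf = int(calls["conflict"].sum())
    if n_conf:
        logger.info("%d cell(s) conflict with their embryo's sex", n_conf)
    return calls.drop(columns=["embryo_id"])


def sex_calls(ds: ExpressionDataset) -> pd.DataFrame:
    """Convenience: cell-level calls plus embryo majority vote and flags."""
    cells = infer_cell_sex(ds)
    if (cells["cell_sex"] == "NA").all():
        cells["embryo_sex"] = "undetermined"
        cells["conflict"] = False
        return cells
    return infer_embryo_sex(cells, ds.cells["embryo_id"])


def xci_eligible_cells(calls: pd.DataFrame) -> pd.Index:
    """Cells usable for X-chromosome analyses: unambiguous, consistent with
    their embryo's determined sex."""
    ok = (
        calls["cell_sex"].isin(["male", "female"])
        & calls["embryo_sex"].isin(["male", "female"])
        & ~calls["conflict"]
    )
    return calls.index[ok]
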