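"""Shared data containers for the blastocyst multi-omics pipeline.

Tabular data live in plain :class:`pandas.DataFrame` objects wrapped in small
dataclasses that carry the cross-table contracts (matching axes, closed
vocabularies, coordinate conventions).  All genomic coordinates are internal
**0-based half-open**; file formats that use other conventions (Bismark
coverage is 1-based inclusive) are converted at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("scembryo")

#: Closed chromosome vocabulary ("chr"-prefixed internal naming).
CHROMOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23)) + (
    "chrX",
    "chrY",
    "chrM",
)

LINEAGES: tuple[str, ...] = ("EPI", "PE", "mural", "polar", "unknown")
TREATMENTS: tuple[str, ...] = ("control", "dex")
SEXES: tuple[str, ...] = ("male", "female", "ambiguous", "NA")
SMALLRNA_BIOTYPES: tuple[str, ...] = ("miRNA", "tRNA", "snoRNA", "snRNA", "other")

#: Columns of a gene annotation table (indexed by gene_id).
ANNOTATION_COLUMNS: tuple[str, ...] = (
    "gene_name",
    "chrom",
    "strand",
    "tss_positions",
    "start",
    "end",
    "length_bp",
    "is_mito",
    "biotype",
)

#: Columns of a cell metadata table (indexed by cell_id).
METADATA_COLUMNS: tuple[str, ...] = (
    "embryo_id",
    "treatment",
    "lineage",
    "qc_pass",
    "qc_fail_reasons",
    "sex",
)


def normalize_chrom(chrom: str) -> str:
    """Map a chromosome name to the internal "chr"-prefixed convention.

    ``"X" -> "chrX"``, ``"MT"/"M" -> "chrM"``, ``"chr1" -> "chr1"``.
    """
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = "chr" + c[3:]
    else:
        c = "chr" + c
    if c in ("chrMT", "chrMt"):
        c = "chrM"
    return c


class GenomicWindow(NamedTuple):
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int


def validate_window(window: GenomicWindow) -> None:
    if not window.start < window.end:
        raise ValueError(
            f"invalid window {window.chrom}:{window.start}-{window.end}: "
            "start must be < end"
        )


def validate_annotation(genes: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene annotation table (index = gene_id).

    Checks the invariants of the annotation contract: unique gene ids,
    start < end, positive lengths, every TSS inside [start, end], and
    chromosomes drawn from the declared vocabulary.
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in genes.columns]
    if missing:
        raise ValueError(f"annotation is missing columns: {missing}")
    if genes.index.duplicated().any():
        dups = genes.index[genes.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate gene_id in annotation: {dups}")
    if (genes["start"] >= genes["end"]).any():
        bad = genes.index[genes["start"] >= genes["end"]].tolist()[:5]
        raise ValueError(f"annotation rows with start >= end: {bad}")
    if (genes["length_bp"] <= 0).any():
        raise ValueError("annotation rows with non-positive length_bp")
    bad_chrom = set(genes["chrom"]) - set(CHROMOSOMES)
    if bad_chrom:
        raise ValueError(f"annotation chromosomes outside vocabulary: {sorted(bad_chrom)}")
    for gid, row in genes.iterrows():
        for tss in row["tss_positions"]:
            if not (row["start"] <= tss <= row["end"]):
                raise ValueError(
                    f"gene {gid}: TSS {tss} outside [{row['start']}, {row['end']}]"
                )
    return genes


def validate_cell_metadata(cells: pd.DataFrame) -> pd.DataFrame:
    """Validate a cell metadata table (index = cell_id)."""
    missing = [c for c in METADATA_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell metadata is missing columns: {missing}")
    if cells.index.duplicated().any():
        raise ValueError("duplicate cell_id in metadata")
    bad = set(cells["treatment"]) - set(TREATMENTS)
    if bad:
        raise ValueError(f"unknown treatment labels: {sorted(bad)}")
    bad = set(cells["lineage"]) - set(LINEAGES)
    if bad:
        raise ValueError(f"unknown lineage labels: {sorted(bad)}")
    bad = set(cells["sex"]) - set(SEXES)
    if bad:
        raise ValueError(f"unknown sex labels: {sorted(bad)}")
    for cid, row in cells.iterrows():
        if bool(row["qc_pass"]) != (len(row["qc_fail_reasons"]) == 0):
            raise ValueError(
                f"cell {cid}: qc_pass inconsistent with qc_fail_reasons"
            )
    return cells


def empty_cell_metadata(cell_ids: Iterable[str]) -> pd.DataFrame:
    """A metadata table with defaults for every contract column."""
    ids = list(cell_ids)
    return pd.DataFrame(
        {
            "embryo_id": ["NA"] * len(ids),
            "treatment": ["control"] * len(ids),
            "lineage": ["unknown"] * len(ids),
            "qc_pass": [True] * len(ids),
            "qc_fail_reasons": [[] for _ in ids],
            "sex": ["NA"] * len(ids),
        },
        index=pd.Index(ids, name="cell_id"),
    )


@dataclass
class ExpressionDataset:
    """Gene x cell expression matrices plus annotation and metadata.

    ``counts`` holds non-negative integer read counts; ``rpkm``/``tpm`` are
    the derived normalizations (may be ``None`` until computed).  The TPM
    library size excludes mitochondrial genes, so TPM columns sum to 1e6
    over non-mitochondrial genes (columns with an empty non-mito library
    are NaN and flagged by the normalizer).
    """

    counts: pd.DataFrame
    genes: pd.DataFrame
    cells: pd.DataFrame
    rpkm: pd.DataFrame | None = None
    tpm: pd.DataFrame | None = None

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def validate(self) -> "ExpressionDataset":
        validate_annotation(self.genes)
        validate_cell_metadata(self.cells)
        if not self.counts.index.equals(self.genes.index):
            raise ValueError("counts rows do not match annotation gene_ids (gene axis)")
        if not self.counts.columns.equals(self.cells.index):
            raise ValueError("counts columns do not match metadata cell_ids (cell axis)")
        if (self.counts.values < 0).any():
            raise ValueError("negative values in counts")
        for name, mat in (("rpkm", self.rpkm), ("tpm", self.tpm)):
            if mat is not None:
                if not (
                    mat.index.equals(self.counts.index)
                    and mat.columns.equals(self.counts.columns)
                ):
                    raise ValueError(f"{name} axes do not match counts axes")
        if self.tpm is not None:
            nonmito = ~self.genes["is_mito"].values
            sums = self.tpm.loc[nonmito].sum(axis=0)
            ok = sums.isna() | (np.abs(sums - 1e6) <= 1.0)  # 1e-6 relative
            if not ok.all():
                raise ValueError("TPM non-mitochondrial column sums differ from 1e6")
        return self

    def subset_cells(self, cell_ids: Sequence[str]) -> "ExpressionDataset":
        ids = list(cell_ids)
        return ExpressionDataset(
            counts=self.counts[ids],
            genes=self.genes,
            cells=self.cells.loc[ids],
            rpkm=None if self.rpkm is None else self.rpkm[ids],
            tpm=None if self.tpm is None else self.tpm[ids],
        )


#: Columns of the per-CpG record table inside MethylationCalls.
METH_RECORD_COLUMNS: tuple[str, ...] = ("chrom", "pos", "met", "unmet")


@dataclass
class MethylationCalls:
    """Per-cell CpG methylation calls.

    ``records`` has columns (chrom, pos, met, unmet) with ``pos`` the
    0-based CpG coordinate, sorted by (chrom, pos), met+unmet >= 1 on every
    row.  ``total_reads`` and ``mapped_fraction`` are sequencing-level QC
    metadata consumed by the methylome cell filter.
    """

    cell_id: str
    records: pd.DataFrame
    total_reads: int = 0
    mapped_fraction: float = float("nan")

    def validate(self) -> "MethylationCalls":
        missing = [c for c in METH_RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"methylation records missing columns: {missing}")
        r = self.records
        if len(r):
            if ((r["met"] + r["unmet"]) < 1).any():
                raise ValueError(f"cell {self.cell_id}: record with met+unmet < 1")
            for chrom, grp in r.groupby("chrom", sort=False):
                pos = grp["pos"].values
                if not (np.diff(pos) > 0).all():
                    raise ValueError(
                        f"cell {self.cell_id}: positions not strictly increasing on {chrom}"
                    )
        return self

    def global_rate(self) -> float:
        """Overall methylation rate, pooled over all CpGs (NaN if no records)."""
        if len(self.records) == 0:
            return float("nan")
        met = self.records["met"].sum()
        tot = met + self.records["unmet"].sum()
        return float(met / tot)


@dataclass
class WindowMethylation:
    """Region x cell methylation-rate table with per-cell CpG coverage.

    ``windows`` is a table with columns (chrom, start, end), one row per
    window; ``rates`` and ``coverages`` are window x cell frames aligned to
    it.  A rate is NaN exactly where the coverage is 0; otherwise it equals
    sum(met)/coverage over the window's CpGs for that cell.
    """

    windows: pd.DataFrame
    rates: pd.DataFrame
    coverages: pd.DataFrame

    def validate(self) -> "WindowMethylation":
        if not (
            len(self.windows) == len(self.rates) == len(self.coverages)
        ):
            raise ValueError("windows/rates/coverages row counts differ")
        if not self.rates.columns.equals(self.coverages.columns):
            raise ValueError("rates and coverages cell axes differ")
        zero = self.coverages.values == 0
        if not np.isnan(self.rates.values[zero]).all():
            raise ValueError("rate present where coverage is 0")
        if np.isnan(self.rates.values[~zero]).any():
            raise ValueError("rate missing where coverage > 0")
        return self


@dataclass
class SmallRNADataset:
    """Feature x cell small-RNA molecule counts with per-feature biotypes."""

    counts: pd.DataFrame
    biotypes: pd.Series
    cells: pd.DataFrame

    def validate(self) -> "SmallRNADataset":
        if not self.counts.index.equals(self.biotypes.index):
            raise ValueError("small-RNA counts rows do not match biotype map")
        if not self.counts.columns.equals(self.cells.index):
            raise ValueError("small-RNA counts columns do not match cell metadata")
        if self.biotypes.isna().any():
            raise ValueError("feature without a biotype assignment")
        if (self.counts.values < 0).any():
            raise ValueError("negative small-RNA counts")
        return self


@dataclass
class WeightedCorrelation:
    """Coverage-weighted Pearson correlation with a Fisher-z confidence interval.

    ``n_effective`` is the Kish effective sample size (sum w)^2 / sum(w^2);
    the CI is undefined (NaN bounds) when n_effective <= 3 or r is undefined.
    """

    r: float
    ci_low: float
    ci_high: float
    n_effective: float

    @property
    def defined(self) -> bool:
        return not np.isnan(self.r)
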