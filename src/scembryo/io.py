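"""Readers and writers for the external formats the pipeline touches.

Formats: gene x cell TSV matrices, MatrixMarket triplets (with ``.rows.txt``
/ ``.cols.txt`` sidecars), BED-like annotation TSV, cell-metadata TSV,
Bismark-coverage methylation files, bedGraph tracks, and small-RNA count +
biotype TSVs.

Coordinate conventions: internal storage is 0-based half-open.  The Bismark
coverage dialect is 1-based inclusive and is converted at this boundary
(file position p maps to internal ``pos = p - 1``).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import (
    ANNOTATION_COLUMNS,
    ExpressionDataset,
    METADATA_COLUMNS,
    MethylationCalls,
    empty_cell_metadata,
    normalize_chrom,
)

logger = logging.getLogger("scembryo")

_ANNOT_FILE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "gene_id",
    "gene_name",
    "strand",
    "tss_positions",
    "length_bp",
    "is_mito",
    "biotype",
]


# ---------------------------------------------------------------------------
# gene annotation / cell metadata
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a BED-like gene annotation TSV into an annotation table.

    Column order follows BED (chrom, start, end, name, ...); the
    ``tss_positions`` field is a comma-joined integer list.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _ANNOT_FILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation file {path} missing columns: {missing}")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["tss_positions"] = [
        [int(x) for x in str(v).split(",")] for v in df["tss_positions"]
    ]
    df["is_mito"] = df["is_mito"].astype(bool)
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()[:5]
        raise ValueError(f"duplicate gene_id in {path}: {dups}")
    df = df.set_index("gene_id")
    return df[list(ANNOTATION_COLUMNS)]


def write_annotation(genes: pd.DataFrame, path: str | Path) -> None:
    out = genes.reset_index()
    out["tss_positions"] = [
        ",".join(str(int(x)) for x in v) for v in out["tss_positions"]
    ]
    out[_ANNOT_FILE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_cell_metadata(path: str | Path) -> pd.DataFrame:
    # keep_default_na: "NA" is a meaningful categorical level (sex), not NaN
    df = pd.read_csv(
        path, sep="\t", dtype={"cell_id": str, "embryo_id": str},
        keep_default_na=False, na_values=[],
    )
    if "cell_id" not in df.columns:
        raise ValueError(f"metadata file {path} lacks a cell_id column")
    df = df.set_index("cell_id")
    if "qc_fail_reasons" in df.columns:
        df["qc_fail_reasons"] = [
            [] if pd.isna(v) or v == "" else str(v).split(";")
            for v in df["qc_fail_reasons"]
        ]
    else:
        df["qc_fail_reasons"] = [[] for _ in range(len(df))]
    for col, default in (
        ("embryo_id", "NA"),
        ("treatment", "control"),
        ("lineage", "unknown"),
        ("sex", "NA"),
    ):
        if col not in df.columns:
            df[col] = default
    if "qc_pass" not in df.columns:
        df["qc_pass"] = [len(r) == 0 for r in df["qc_fail_reasons"]]
    df["qc_pass"] = df["qc_pass"].astype(bool)
    extra = [c for c in df.columns if c not in METADATA_COLUMNS]
    return df[list(METADATA_COLUMNS) + extra]


def write_cell_metadata(cells: pd.DataFrame, path: str | Path) -> None:
    out = cells.copy().reset_index()
    out["qc_fail_reasons"] = [";".join(v) for v in out["qc_fail_reasons"]]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _read_matrix(path: Path) -> pd.DataFrame:
    """Read a genes-as-rows TSV matrix, or an MTX triplet with sidecar
    ``<stem>.rows.txt`` / ``<stem>.cols.txt`` name files."""
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        rows = (
            Path(str(path)[: -len(".mtx")] + ".rows.txt").read_text().split()
        )
        cols = (
            Path(str(path)[: -len(".mtx")] + ".cols.txt").read_text().split()
        )
        dense = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat
        )
        if dense.shape != (len(rows), len(cols)):
            raise ValueError(
                f"{path}: matrix shape {dense.shape} does not match sidecar "
                f"names ({len(rows)} rows, {len(cols)} cols)"
            )
        out = pd.DataFrame(dense, index=rows, columns=cols)
        out.index.name = "gene_id"
        out.columns.name = "cell_id"
        return out
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    df.columns.name = "cell_id"
    return df


def read_expression(
    matrix_path: str | Path,
    annotation_path: str | Path,
    metadata_path: str | Path | None = None,
) -> ExpressionDataset:
    """Read a counts matrix plus annotation (and optional metadata).

    Genes absent from the annotation are dropped with a logged count; a
    matrix cell id absent from the metadata is a hard error naming the id.
    """
    matrix_path = Path(matrix_path)
    counts = _read_matrix(matrix_path)
    genes = read_annotation(annotation_path)

    unknown = counts.index.difference(genes.index)
    if len(unknown):
        logger.info(
            "read_expression: dropping %d matrix genes absent from annotation",
            len(unknown),
        )
        counts = counts.loc[counts.index.intersection(genes.index)]
    genes = genes.loc[counts.index]

    if metadata_path is not None:
        cells = read_cell_metadata(metadata_path)
        missing = counts.columns.difference(cells.index)
        if len(missing):
            raise ValueError(
                f"matrix cells missing from metadata: {sorted(missing)[:10]}"
            )
        cells = cells.loc[counts.columns]
    else:
        cells = empty_cell_metadata(counts.columns)

    counts = counts.astype(np.int64)
    ds = ExpressionDataset(counts=counts, genes=genes, cells=cells)
    return ds.validate()


def write_expression(ds: ExpressionDataset, outdir: str | Path, stem: str = "counts") -> dict:
    """Write counts (TSV), annotation and metadata; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / f"{stem}.tsv",
        "annotation": outdir / "genes.tsv",
        "metadata": outdir / "cells.tsv",
    }
    ds.counts.to_csv(paths["matrix"], sep="\t")
    write_annotation(ds.genes, paths["annotation"])
    write_cell_metadata(ds.cells, paths["metadata"])
    return paths


def write_matrix_mtx(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a matrix as MatrixMarket triplets plus name sidecars."""
    path = Path(path)
    stem = str(path)[: -len(".mtx")] if path.suffix == ".mtx" else str(path)
    scipy.io.mmwrite(stem + ".mtx", scipy.sparse.csr_matrix(matrix.values))
    Path(stem + ".rows.txt").write_text("\n".join(map(str, matrix.index)) + "\n")
    Path(stem + ".cols.txt").write_text("\n".join(map(str, matrix.columns)) + "\n")


# ---------------------------------------------------------------------------
# Bismark-coverage methylation files
# ---------------------------------------------------------------------------

def read_methylation_calls(
    cov_path: str | Path,
    cell_id: str,
    total_reads: int = 0,
    mapped_fraction: float = float("nan"),
) -> MethylationCalls:
    """Parse a Bismark-coverage file into :class:`MethylationCalls`.

    The dialect is ``chrom  start  end  met%  count_met  count_unmet`` with
    1-based inclusive coordinates; the percentage column is ignored in
    favor of the counts.  Rows with met+unmet = 0 are dropped with a
    warning; malformed rows raise with the offending line number.
    Duplicate positions within the file are summed (per-strand dialects).
    """
    rows: list[tuple[str, int, int, int]] = []
    with open(cov_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 6:
                raise ValueError(
                    f"{cov_path}: malformed row at line {lineno}: {line!r}"
                )
            try:
                chrom = normalize_chrom(parts[0])
                pos1 = int(parts[1])
                met = int(parts[4])
                unmet = int(parts[5])
            except ValueError as exc:
                raise ValueError(
                    f"{cov_path}: malformed row at line {lineno}: {line!r}"
                ) from exc
            if met < 0 or unmet < 0:
                raise ValueError(
                    f"{cov_path}: negative count at line {lineno}"
                )
            if met + unmet == 0:
                logger.warning(
                    "%s line %d: met+unmet == 0, row dropped", cov_path, lineno
                )
                continue
            rows.append((chrom, pos1 - 1, met, unmet))  # 1-based -> 0-based

    if rows:
        df = pd.DataFrame(rows, columns=["chrom", "pos", "met", "unmet"])
        df = (
            df.groupby(["chrom", "pos"], as_index=False, sort=True)[["met", "unmet"]]
            .sum()
        )
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    else:
        df = pd.DataFrame(columns=["chrom", "pos", "met", "unmet"]).astype(
            {"chrom": str, "pos": np.int64, "met": np.int64, "unmet": np.int64}
        )
    return MethylationCalls(
        cell_id=cell_id,
        records=df,
        total_reads=total_reads,
        mapped_fraction=mapped_fraction,
    ).validate()


def write_methylation_calls(calls: MethylationCalls, cov_path: str | Path) -> None:
    """Serialize calls back to the Bismark-coverage dialect (sorted)."""
    r = calls.records
    with open(cov_path, "w") as fh:
        for chrom, pos, met, unmet in zip(r["chrom"], r["pos"], r["met"], r["unmet"]):
            pct = 100.0 * met / (met + unmet)
            fh.write(f"{chrom}\t{pos + 1}\t{pos + 1}\t{pct:.6g}\t{met}\t{unmet}\n")


# ---------------------------------------------------------------------------
# bedGraph tracks
# ---------------------------------------------------------------------------

def write_track(track: pd.DataFrame, path: str | Path, name: str = "track") -> None:
    """Write a (chrom, start, end, value) table as bedGraph.

    NaN values are omitted with a log entry; coordinates are already
    0-based half-open internally so they are written as-is.
    """
    n_nan = int(track["value"].isna().sum()) if len(track) else 0
    if n_nan:
        logger.info("write_track %s: omitting %d NaN rows", path, n_nan)
    with open(path, "w") as fh:
        fh.write(f'# track type=bedGraph name="{name}"\n')
        for _, row in track.iterrows():
            if pd.isna(row["value"]):
                continue
            fh.write(
                f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}\t"
                f"{row['value']:.10g}\n"
            )


def read_track(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph file back into a (chrom, start, end, value) table."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    if df.empty:
        df = pd.DataFrame(columns=["chrom", "start", "end", "value"]).astype(
            {"chrom": str, "start": np.int64, "end": np.int64, "value": float}
        )
    return df


# ---------------------------------------------------------------------------
# small RNA
# ---------------------------------------------------------------------------

def read_smallrna(
    counts_path: str | Path,
    biotype_path: str | Path,
    metadata_path: str | Path | None = None,
):
    """Read small-RNA counts (features x cells TSV) and a biotype map TSV."""
    from .types import SmallRNADataset

    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    bmap = pd.read_csv(biotype_path, sep="\t", index_col=0)
    if "biotype" not in bmap.columns:
        raise ValueError(f"{biotype_path} lacks a biotype column")
    missing = counts.index.difference(bmap.index)
    if len(missing):
        raise ValueError(
            f"features missing from biotype map: {sorted(missing)[:10]}"
        )
    biotypes = bmap.loc[counts.index, "biotype"]
    if metadata_path is not None:
        cells = read_cell_metadata(metadata_path).loc[counts.columns]
    else:
        cells = empty_cell_metadata(counts.columns)
    return SmallRNADataset(
        counts=counts.astype(np.int64), biotypes=biotypes, cells=cells
    ).validate()


def write_smallrna(ds, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "smallrna_counts.tsv",
        "biotypes": outdir / "smallrna_biotypes.tsv",
        "metadata": outdir / "smallrna_cells.tsv",
    }
    ds.counts.to_csv(paths["counts"], sep="\t")
    ds.biotypes.rename("biotype").to_frame().to_csv(paths["biotypes"], sep="\t")
    write_cell_metadata(ds.cells, paths["metadata"])
    return paths
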