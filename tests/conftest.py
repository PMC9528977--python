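"""Shared fixtures and hand-built dataset helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from scembryo.types import ExpressionDataset, MethylationCalls, empty_cell_metadata


def make_genes(rows):
    """Annotation table from (gene_id, chrom, start, end, length_bp, is_mito)
    tuples; TSS defaults to the start position."""
    recs = []
    for gid, chrom, start, end, length, is_mito in rows:
        recs.append(
            {
                "gene_id": gid,
                "gene_name": gid,
                "chrom": chrom,
                "strand": "+",
                "tss_positions": [start],
                "start": start,
                "end": end,
                "length_bp": length,
                "is_mito": is_mito,
                "biotype": "protein_coding",
            }
        )
    return pd.DataFrame(recs).set_index("gene_id")


def make_dataset(counts=None, rpkm=None, genes=None, cells=None, tpm=None):
    """ExpressionDataset from whichever matrices a test hand-crafts."""
    base = counts if counts is not None else rpkm
    if genes is None:
        genes = make_genes(
            [(g, "chr1", 1000 * i, 1000 * i + 500, 500, False)
             for i, g in enumerate(base.index)]
        )
    if cells is None:
        cells = empty_cell_metadata(base.columns)
    if counts is None:
        counts = pd.DataFrame(0, index=base.index, columns=base.columns)
    return ExpressionDataset(counts=counts, genes=genes, cells=cells, rpkm=rpkm, tpm=tpm)


def make_calls(cell_id, records, total_reads=200_000, mapped_fraction=0.2):
    """MethylationCalls from (chrom, pos, met, unmet) tuples."""
    df = pd.DataFrame(records, columns=["chrom", "pos", "met", "unmet"])
    df = df.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return MethylationCalls(
        cell_id=cell_id,
        records=df,
        total_reads=total_reads,
        mapped_fraction=mapped_fraction,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
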