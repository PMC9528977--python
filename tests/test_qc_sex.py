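"""Normalization contracts, the four-stage cell QC, the expressed-gene rule,
and cell/embryo sex inference."""

import numpy as np
import pandas as pd
import pytest

from scembryo.qc import (
    QCThresholds,
    normalize_expression,
    qc_filter_cells,
    select_expressed_genes,
)
from scembryo.sex import infer_cell_sex, infer_embryo_sex
from scembryo.types import empty_cell_metadata
from conftest import make_dataset, make_genes


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_rpkm_hand_arithmetic():
    """10 counts on a 2-kb gene in a 1e6-read library give RPKM = 5."""
    genes = make_genes([("g1", "chr1", 0, 2000, 2000, False)])
    counts = pd.DataFrame({"c1": [10]}, index=["g1"])
    reads = pd.Series({"c1": 1_000_000})
    rpkm, tpm = normalize_expression(counts, genes, reads)
    assert rpkm.loc["g1", "c1"] == pytest.approx(5.0)
    assert tpm.loc["g1", "c1"] == pytest.approx(1e6)


def test_rpkm_scale_invariance():
    """Doubling all counts and the library size leaves RPKM unchanged."""
    genes = make_genes(
        [("g1", "chr1", 0, 1000, 1000, False), ("g2", "chr1", 2000, 3500, 1500, False)]
    )
    counts = pd.DataFrame({"c1": [10, 30]}, index=genes.index)
    rpkm1, _ = normalize_expression(counts, genes, pd.Series({"c1": 1e6}))
    rpkm2, _ = normalize_expression(counts * 2, genes, pd.Series({"c1": 2e6}))
    pd.testing.assert_frame_equal(rpkm1, rpkm2)


def test_tpm_excludes_mito_from_library_and_flags_mito_only_cell():
    genes = make_genes(
        [("g1", "chr1", 0, 1000, 1000, False), ("gm", "chrM", 0, 1000, 1000, True)]
    )
    counts = pd.DataFrame({"ok": [5, 5], "mito_only": [0, 7]}, index=genes.index)
    _, tpm = normalize_expression(counts, genes, pd.Series({"ok": 1e6, "mito_only": 1e6}))
    # non-mito TPM sums to 1e6 for the healthy cell
    assert tpm.loc[["g1"], "ok"].sum() == pytest.approx(1e6)
    # the mito-only cell is undefined
    assert tpm["mito_only"].isna().all()


# ---------------------------------------------------------------------------
# QC criteria
# ---------------------------------------------------------------------------

def _qc_fixture():
    """4 cells: a good one, a boundary-libsize one, two for Spearman."""
    n = 40
    rng = np.random.default_rng(5)
    genes = make_genes(
        [(f"g{i}", "chr1", 1000 * i, 1000 * i + 1000, 1000, False) for i in range(n)]
    )
    base = rng.integers(2000, 8000, n)
    counts = pd.DataFrame(
        {
            "good": base,
            "boundary": (base * 50_000 / base.sum()).astype(int),
            "friend": base + rng.integers(0, 300, n),
            "outlier": base[::-1].copy(),
        },
        index=genes.index,
    )
    # force the boundary cell's non-mito library to exactly 50,000
    diff = 50_000 - counts["boundary"].sum()
    counts.loc["g0", "boundary"] += diff
    reads = counts.sum(axis=0)
    rpkm, tpm = normalize_expression(counts, genes, reads)
    cells = empty_cell_metadata(counts.columns)
    cells["embryo_id"] = ["E1", "E1", "E2", "E2"]
    return make_dataset(counts=counts, rpkm=rpkm, genes=genes, cells=cells, tpm=tpm)


def test_boundary_libsize_fails_strictly():
    """A non-mito library of exactly 50,000 reads fails (the rule is
    'more than 50,000')."""
    ds = _qc_fixture()
    thr = QCThresholds(min_genes_per_cell=10, min_max_spearman=0.0)
    out = qc_filter_cells(ds, thr)
    assert not out.cells.loc["boundary", "qc_pass"]
    assert "low_nonmito_libsize" in out.cells.loc["boundary", "qc_fail_reasons"]
    assert out.cells.loc["good", "qc_pass"]


def test_spearman_outlier_fails_criterion_three():
    """The anti-correlated cell alone fails the max-pairwise-Spearman
    criterion (direct Spearman computation on the fixture)."""
    import scipy.stats

    ds = _qc_fixture()
    thr = QCThresholds(
        min_nonmito_libsize=60_000, min_genes_per_cell=10, expressed_min_cells=2
    )
    out = qc_filter_cells(ds, thr)
    assert not out.cells.loc["outlier", "qc_pass"]
    assert out.cells.loc["good", "qc_pass"] and out.cells.loc["friend", "qc_pass"]
    rho = scipy.stats.spearmanr(ds.rpkm["good"], ds.rpkm["outlier"])[0]
    assert rho < 0.5  # the fixture really is anti-correlated


def test_excluded_embryo_cells_dropped():
    ds = _qc_fixture()
    thr = QCThresholds(
        min_nonmito_libsize=0, min_genes_per_cell=0, min_max_spearman=0.0,
        excluded_embryos=("E2",),
    )
    out = qc_filter_cells(ds, thr)
    assert list(out.cells.index[~out.cells["qc_pass"]]) == ["friend", "outlier"]
    assert out.cells.loc["friend", "qc_fail_reasons"] == ["excluded_embryo"]


def test_criterion_three_unaffected_by_earlier_failures():
    """Adding a cell that fails criterion 1 never changes other cells'
    pass status (criterion 3 sees only survivors of 1-2)."""
    ds = _qc_fixture()
    thr = QCThresholds(min_nonmito_libsize=60_000, min_genes_per_cell=10,
                       expressed_min_cells=2)
    full = qc_filter_cells(ds, thr)
    without = qc_filter_cells(ds.subset_cells(["good", "friend", "outlier"]), thr)
    for c in ["good", "friend", "outlier"]:
        assert full.cells.loc[c, "qc_pass"] == without.cells.loc[c, "qc_pass"]


def test_qc_monotone_in_thresholds(rng):
    """Raising any threshold never adds a retained cell."""
    from scembryo.simulate import SimulationConfig, generate_expression

    ds, _ = generate_expression(
        SimulationConfig(
            seed=77, n_embryos=3, cells_per_embryo=(8, 8),
            n_genes={"chr1": 50, "chrX": 10, "chrY": 3, "chrM": 2},
            low_quality_fraction=0.3,
        )
    )
    base = QCThresholds(min_nonmito_libsize=20_000, min_genes_per_cell=20,
                        min_max_spearman=0.3)
    retained_base = set(qc_filter_cells(ds, base).cells.query("qc_pass").index)
    for stricter in (
        QCThresholds(min_nonmito_libsize=80_000, min_genes_per_cell=20, min_max_spearman=0.3),
        QCThresholds(min_nonmito_libsize=20_000, min_genes_per_cell=40, min_max_spearman=0.3),
        QCThresholds(min_nonmito_libsize=20_000, min_genes_per_cell=20, min_max_spearman=0.9),
    ):
        retained = set(qc_filter_cells(ds, stricter).cells.query("qc_pass").index)
        assert retained <= retained_base


def test_criterion_three_skipped_with_one_survivor(caplog):
    ds = _qc_fixture()
    thr = QCThresholds(min_nonmito_libsize=1_000_000_000, min_genes_per_cell=0)
    out = qc_filter_cells(ds, thr)  # everyone fails criterion 1
    assert not out.cells["qc_pass"].any()
    assert all(
        "low_max_spearman" not in r for r in out.cells["qc_fail_reasons"]
    )


# ---------------------------------------------------------------------------
# expressed-gene rule
# ---------------------------------------------------------------------------

def test_expressed_gene_rule_inclusive_at_five_cells():
    """RPKM >= 1 in exactly 5 cells retains the gene; 4 cells drops it;
    an all-zero gene is dropped."""
    cells = [f"c{i}" for i in range(6)]
    rpkm = pd.DataFrame(
        {
            "five": [1.0, 1.0, 1.0, 1.0, 1.0, 0.0],
            "four": [2.0, 2.0, 2.0, 2.0, 0.5, 0.0],
            "zero": [0.0] * 6,
        },
        index=cells,
    ).T
    ds = make_dataset(rpkm=rpkm)
    ds.cells["qc_pass"] = True
    kept = select_expressed_genes(ds, QCThresholds())
    assert list(kept) == ["five"]


# ---------------------------------------------------------------------------
# sex inference
# ---------------------------------------------------------------------------

def _sex_dataset(sums):
    """One chrY gene whose RPKM equals the requested per-cell sum."""
    genes = make_genes(
        [("y1", "chrY", 0, 1000, 1000, False), ("a1", "chr1", 0, 1000, 1000, False)]
    )
    rpkm = pd.DataFrame(
        {c: [v, 10.0] for c, v in sums.items()}, index=genes.index
    )
    return make_dataset(rpkm=rpkm, genes=genes)


def test_cell_sex_rule_and_boundaries():
    """>100 male, <50 female, [50, 100] ambiguous including both
    boundary values."""
    ds = _sex_dataset({"m": 150.0, "f": 0.0, "amb": 75.0, "b50": 50.0, "b100": 100.0})
    calls = infer_cell_sex(ds)
    assert calls.loc["m", "cell_sex"] == "male"
    assert calls.loc["f", "cell_sex"] == "female"
    for c in ("amb", "b50", "b100"):
        assert calls.loc[c, "cell_sex"] == "ambiguous"


def test_no_chry_genes_gives_na_calls():
    genes = make_genes([("a1", "chr1", 0, 1000, 1000, False)])
    ds = make_dataset(rpkm=pd.DataFrame({"c1": [5.0]}, index=genes.index), genes=genes)
    calls = infer_cell_sex(ds)
    assert (calls["cell_sex"] == "NA").all()


def test_embryo_majority_vote_and_conflict_flag():
    """10 male vs 1 female calls -> male embryo, the dissenting cell
    flagged; an all-female embryo has no conflicts; 2-2 is undetermined."""
    sums = {f"m{i}": 200.0 for i in range(10)}
    sums["f0"] = 0.0
    sums.update({f"e2_f{i}": 0.0 for i in range(3)})
    sums.update({"e3_a": 200.0, "e3_b": 200.0, "e3_c": 0.0, "e3_d": 0.0})
    ds = _sex_dataset(sums)
    calls = infer_cell_sex(ds)
    embryos = pd.Series(
        ["E1"] * 11 + ["E2"] * 3 + ["E3"] * 4, index=list(sums)
    )
    out = infer_embryo_sex(calls, embryos)
    assert out.loc["m0", "embryo_sex"] == "male"
    assert bool(out.loc["f0", "conflict"])
    assert not out.loc[[f"m{i}" for i in range(10)], "conflict"].any()
    assert (out.loc[[f"e2_f{i}" for i in range(3)], "embryo_sex"] == "female").all()
    assert not out.loc[[f"e2_f{i}" for i in range(3)], "conflict"].any()
    assert (out.loc[["e3_a", "e3_b", "e3_c", "e3_d"], "embryo_sex"] == "undetermined").all()


def test_all_ambiguous_embryo_undetermined():
    ds = _sex_dataset({"a": 75.0, "b": 60.0})
    calls = infer_cell_sex(ds)
    out = infer_embryo_sex(calls, pd.Series(["E1", "E1"], index=["a", "b"]))
    assert (out["embryo_sex"] == "undetermined").all()
    assert not out["conflict"].any()
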