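"""Windowing, weighted statistics, the DMR stand-in, and the X F:M track."""

import numpy as np
import pandas as pd
import pytest

from scembryo.methylome import (
    DMRParams,
    call_dmrs,
    global_methylation,
    group_weighted_mean,
    meth_cell_qc,
    nearest_tss,
    tile_windows,
    weighted_meth_expr_correlation,
    window_methylation,
    x_fm_methylation_track,
    xist_region_methylation,
)
from scembryo.qc import QCThresholds
from scembryo.types import GenomicWindow, MethylationCalls, WindowMethylation
from conftest import make_calls, make_genes


# ---------------------------------------------------------------------------
# cell QC
# ---------------------------------------------------------------------------

def test_meth_qc_boundaries_inclusive():
    """Exactly 0.1 M reads and 7% mapped is retained; 99,999 reads is
    dropped; an empty cohort stays empty."""
    ok = make_calls("ok", [("chr1", 10, 1, 1)], total_reads=100_000, mapped_fraction=0.07)
    low = make_calls("low", [("chr1", 10, 1, 1)], total_reads=99_999, mapped_fraction=0.5)
    unmapped = make_calls("um", [("chr1", 10, 1, 1)], total_reads=1_000_000,
                          mapped_fraction=0.069)
    retained, summary = meth_cell_qc([ok, low, unmapped], QCThresholds())
    assert [c.cell_id for c in retained] == ["ok"]
    assert summary.loc["low", "qc_pass"] == False  # noqa: E712
    assert meth_cell_qc([], QCThresholds())[0] == []


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

def test_tile_windows_enumeration():
    """10-kb chromosome, 3-kb bins: (0,3000),(3000,6000),(6000,9000),
    (9000,10000); half-size steps start at 0,1500,3000,4500."""
    w = tile_windows({"chr1": 10_000}, 3000)
    assert list(map(tuple, w[["start", "end"]].values)) == [
        (0, 3000), (3000, 6000), (6000, 9000), (9000, 10_000)
    ]
    w2 = tile_windows({"chr1": 6000}, 3000, step=1500)
    assert list(w2["start"]) == [0, 1500, 3000, 4500]
    single = tile_windows({"chr1": 5000}, 5000)
    assert len(single) == 1
    with pytest.raises(ValueError):
        tile_windows({"chr1": 100}, 0)


def test_window_methylation_hand_example():
    """CpGs (3,1) and (0,4) in one window: rate 3/8, coverage 8; a window
    with no CpGs is missing; an all-methylated window has rate 1."""
    calls = make_calls(
        "c1",
        [("chr1", 100, 3, 1), ("chr1", 200, 0, 4), ("chr1", 1200, 5, 0)],
    )
    windows = pd.DataFrame(
        {"chrom": ["chr1"] * 3, "start": [0, 1000, 2000], "end": [1000, 2000, 3000]}
    )
    wm = window_methylation([calls], windows)
    assert wm.rates.iloc[0, 0] == pytest.approx(3 / 8)
    assert wm.coverages.iloc[0, 0] == 8
    assert wm.rates.iloc[1, 0] == pytest.approx(1.0)
    assert np.isnan(wm.rates.iloc[2, 0]) and wm.coverages.iloc[2, 0] == 0
    wm.validate()


def test_group_weighted_mean_hand_and_identity(rng):
    """Rates 0.2 (cov 10) and 0.8 (cov 30) give 0.65; equal coverages give
    the arithmetic mean; a single cell returns its own rate; and the
    weighted mean equals pooled met/total to 1e-12 on random windows."""
    assert group_weighted_mean([0.2, 0.8], [10, 30]) == pytest.approx(0.65)
    assert group_weighted_mean([0.2, 0.8], [7, 7]) == pytest.approx(0.5)
    assert group_weighted_mean([0.3], [5]) == pytest.approx(0.3)
    assert np.isnan(group_weighted_mean([np.nan, np.nan], [0, 0]))

    for _ in range(200):
        cov = rng.integers(0, 20, size=8)
        met = rng.binomial(cov, 0.4)
        with np.errstate(invalid="ignore"):
            rates = np.where(cov > 0, met / np.where(cov > 0, cov, 1), np.nan)
        if cov.sum() == 0:
            continue
        pooled = met.sum() / cov.sum()
        assert abs(group_weighted_mean(rates, cov) - pooled) < 1e-12


def test_global_methylation_pooling_identity():
    """Concatenating two cells' records equals the coverage-weighted mean
    of their rates; degenerate cells behave."""
    a = make_calls("a", [("chr1", 10, 3, 1), ("chr1", 20, 1, 3)])
    b = make_calls("b", [("chr1", 30, 5, 5)])
    merged = make_calls("ab", [("chr1", 10, 3, 1), ("chr1", 20, 1, 3), ("chr1", 30, 5, 5)])
    rates = global_methylation([a, b])
    weights = [8, 10]
    weighted = np.average(rates[["a", "b"]], weights=weights)
    assert merged.global_rate() == pytest.approx(weighted)

    zero = make_calls("z", [("chr1", 5, 0, 4)])
    assert zero.global_rate() == 0.0
    empty = MethylationCalls("e", pd.DataFrame(columns=["chrom", "pos", "met", "unmet"]))
    assert np.isnan(empty.global_rate())


# ---------------------------------------------------------------------------
# DMR caller
# ---------------------------------------------------------------------------

def _wm_from_counts(met_a, cov_a, met_b, cov_b):
    """WindowMethylation for one window from per-cell count arrays."""
    met = np.concatenate([met_a, met_b]).astype(float)
    cov = np.concatenate([cov_a, cov_b]).astype(float)
    cells = [f"a{i}" for i in range(len(met_a))] + [f"b{i}" for i in range(len(met_b))]
    with np.errstate(invalid="ignore"):
        rates = np.where(cov > 0, met / np.where(cov > 0, cov, 1), np.nan)
    return (
        WindowMethylation(
            windows=pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [3000]}),
            rates=pd.DataFrame([rates], columns=cells),
            coverages=pd.DataFrame([cov.astype(int)], columns=cells),
        ),
        [c for c in cells if c.startswith("a")],
        [c for c in cells if c.startswith("b")],
    )


def test_dmr_strong_difference_called_with_direction():
    """Pooled 90/100 vs 10/100 methylated: a DMR, hypo in group B, with
    Fisher p below 1e-10 (oracle: scipy hypergeometric tail)."""
    wm, a, b = _wm_from_counts(
        met_a=np.full(10, 9), cov_a=np.full(10, 10),
        met_b=np.full(10, 1), cov_b=np.full(10, 10),
    )
    out = call_dmrs(wm, a, b, DMRParams())
    assert len(out) == 1 and bool(out.loc[0, "is_dmr"])
    assert out.loc[0, "direction"] == "hypo"  # B vs A
    assert out.loc[0, "p_value"] < 1e-10
    import scipy.stats

    oracle = scipy.stats.fisher_exact([[90, 10], [10, 90]])[1]
    assert out.loc[0, "p_value"] == pytest.approx(oracle)


def test_dmr_identical_groups_not_called():
    wm, a, b = _wm_from_counts(
        met_a=np.full(8, 5), cov_a=np.full(8, 10),
        met_b=np.full(8, 5), cov_b=np.full(8, 10),
    )
    out = call_dmrs(wm, a, b, DMRParams())
    assert not out["is_dmr"].any()


def test_dmr_window_with_too_few_covered_cells_untested():
    """Four covered cells in group A (n_min = 5) leave the window
    untested; zero testable windows give an empty table."""
    wm, a, b = _wm_from_counts(
        met_a=np.array([9, 9, 9, 9]), cov_a=np.array([10, 10, 10, 10]),
        met_b=np.full(10, 1), cov_b=np.full(10, 10),
    )
    out = call_dmrs(wm, a, b, DMRParams())
    assert len(out) == 0


# ---------------------------------------------------------------------------
# nearest TSS
# ---------------------------------------------------------------------------

def test_nearest_tss_rules():
    """TSS inside the window gives distance 0; otherwise the interval gap;
    equidistant genes tie-break lexicographically."""
    genes = make_genes(
        [("inside", "chr1", 1500, 2500, 1000, False),
         ("left", "chr1", 500, 600, 100, False),
         ("right", "chr1", 2600, 2700, 100, False)]
    )
    gid, d = nearest_tss(GenomicWindow("chr1", 1000, 2000), genes)
    assert (gid, d) == ("inside", 0)

    genes2 = make_genes(
        [("left", "chr1", 500, 600, 100, False),
         ("right", "chr1", 2600, 2700, 100, False)]
    )
    gid, d = nearest_tss(GenomicWindow("chr1", 1000, 2000), genes2)
    assert (gid, d) == ("left", 500)  # 500 vs 601 on the right

    genes3 = make_genes(
        [("zeta", "chr1", 700, 800, 100, False),
         ("alpha", "chr1", 2299, 2400, 100, False)]
    )
    # both at distance 300 from [1000, 2000)
    gid, d = nearest_tss(GenomicWindow("chr1", 1000, 2000), genes3)
    assert (gid, d) == ("alpha", 300)


# ---------------------------------------------------------------------------
# weighted correlation
# ---------------------------------------------------------------------------

def _brute_weighted_corr(m, w, x):
    """Independent oracle: explicit weighted-moment formulas."""
    m, w, x = map(np.asarray, (m, w, x))
    sw = sum(w)
    mm = sum(w * m) / sw
    mx = sum(w * x) / sw
    vm = sum(w * (m - mm) ** 2) / sw
    vx = sum(w * (x - mx) ** 2) / sw
    cov = sum(w * (m - mm) * (x - mx)) / sw
    return cov / np.sqrt(vm * vx)


def test_weighted_correlation_perfect_linear():
    x = np.arange(10, dtype=float)
    up = weighted_meth_expr_correlation(0.05 * x + 0.1, np.full(10, 3), x)
    assert up.r == pytest.approx(1.0)
    down = weighted_meth_expr_correlation(0.9 - 0.05 * x, np.full(10, 3), x)
    assert down.r == pytest.approx(-1.0)


def test_weighted_correlation_matches_brute_force(rng):
    for _ in range(20):
        m = rng.random(10)
        w = rng.integers(1, 30, 10)
        x = rng.normal(size=10)
        wc = weighted_meth_expr_correlation(m, w, x)
        assert wc.r == pytest.approx(_brute_weighted_corr(m, w, x), abs=1e-12)
        assert wc.ci_low <= wc.r <= wc.ci_high
        assert wc.n_effective == pytest.approx(w.sum() ** 2 / (w**2).sum())


def test_weighted_correlation_degenerate_inputs():
    flat = weighted_meth_expr_correlation([0.5] * 5, [4] * 5, [1, 2, 3, 4, 5])
    assert np.isnan(flat.r)
    with pytest.raises(ValueError):
        weighted_meth_expr_correlation([0.1, 0.2], [1, 1], [0.0, 1.0])


# ---------------------------------------------------------------------------
# X F:M methylation track
# ---------------------------------------------------------------------------

def _track_inputs(rng, n_bins=8, nf=6, nm=6, f_rate=0.3, m_rate=0.3, cov=40):
    cells = [f"f{i}" for i in range(nf)] + [f"m{i}" for i in range(nm)]
    sex = pd.Series(["female"] * nf + ["male"] * nm, index=cells)
    cov_mat = np.full((n_bins, nf + nm), cov)
    rates = np.concatenate(
        [
            rng.binomial(cov, f_rate, size=(n_bins, nf)) / cov,
            rng.binomial(cov, m_rate, size=(n_bins, nm)) / cov,
        ],
        axis=1,
    )
    wm = WindowMethylation(
        windows=pd.DataFrame(
            {"chrom": "chrX", "start": np.arange(n_bins) * 100_000,
             "end": (np.arange(n_bins) + 1) * 100_000}
        ),
        rates=pd.DataFrame(rates, columns=cells),
        coverages=pd.DataFrame(cov_mat, columns=cells),
    )
    return wm, sex


def test_track_flat_when_sexes_equal(rng):
    wm, sex = _track_inputs(rng, f_rate=0.4, m_rate=0.4, cov=500)
    track = x_fm_methylation_track(wm, sex, window_bins=4)
    assert np.allclose(track["smoothed"], 1.0, atol=0.1)


def test_track_bin_eligibility_strict_coverage(rng):
    """A cell at coverage exactly 10 does not count toward the >=5
    requirement ('greater than 10' is strict)."""
    wm, sex = _track_inputs(rng, nf=5, nm=5)
    wm.coverages.loc[0, "f0"] = 10  # leaves only 4 females with cov > 10
    wm.coverages.loc[1, "f0"] = 11
    track = x_fm_methylation_track(wm, sex, window_bins=4)
    assert 0 not in track.index or (track["start"] != 0).all()
    assert (track["start"] == 100_000).any()


def test_xist_region_methylation_pooled_oracle(rng):
    calls = [
        make_calls("c1", [("chrX", 100, 3, 1), ("chrX", 150, 1, 1)]),
        make_calls("c2", [("chrX", 120, 0, 4)]),
        make_calls("c3", [("chrX", 900, 5, 0)]),
    ]
    regions = {"promoter": GenomicWindow("chrX", 0, 500)}
    out = xist_region_methylation(calls, regions, {"grp": ["c1", "c2"]})
    # pooled oracle: (3+1+0) / (4+2+4)
    assert out.loc[0, "weighted_mean"] == pytest.approx(4 / 10)
    single = xist_region_methylation(calls, regions, {"solo": ["c2"]})
    assert single.loc[0, "weighted_mean"] == pytest.approx(0.0)
    missing = xist_region_methylation(calls, regions, {"none": ["c3"]})
    assert np.isnan(missing.loc[0, "weighted_mean"])
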