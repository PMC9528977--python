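"""Coverage-weighted single-cell methylome quantification.

Per-cell window methylation rates with CpG coverage, group weighted means
(algebraically the pooled met/total ratio), global per-cell levels, a
pooled-count Fisher-exact DMR caller, nearest-TSS annotation, weighted
methylation-expression correlation with Fisher-z confidence intervals, and
the X-chromosome female-to-male 100-kb methylation track.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .qc import QCThresholds
from .types import GenomicWindow, MethylationCalls, WindowMethylation

logger = logging.getLogger("scembryo")


# ---------------------------------------------------------------------------
# cell QC and windowing
# ---------------------------------------------------------------------------

def meth_cell_qc(
    calls: list[MethylationCalls], thresholds: QCThresholds | None = None
) -> tuple[list[MethylationCalls], pd.DataFrame]:
    """Retain cells with >= 0.1 M total reads and >= 7% mapped (inclusive).

    Returns the retained calls and a per-cell summary table with the pass
    flag and both metrics.
    """
    thr = thresholds or QCThresholds()
    rows = []
    retained = []
    for c in calls:
        ok = (
            c.total_reads >= thr.meth_min_reads
            and c.mapped_fraction >= thr.meth_min_mapped_frac
        )
        rows.append(
            {
                "cell_id": c.cell_id,
                "total_reads": c.total_reads,
                "mapped_fraction": c.mapped_fraction,
                "qc_pass": ok,
            }
        )
        if ok:
            retained.append(c)
    summary = pd.DataFrame(
        rows, columns=["cell_id", "total_reads", "mapped_fraction", "qc_pass"]
    ).set_index("cell_id")
    logger.info("methylome QC: %d / %d cells retained", len(retained), len(calls))
    return retained, summary


def tile_windows(
    chrom_lengths: dict[str, int], size: int, step: int | None = None
) -> pd.DataFrame:
    """Tile chromosomes into sliding windows [i*step, i*step + size).

    ``step == size`` (the default) gives non-overlapping bins; the final
    partial window is kept, truncated at the chromosome end.  ``step``
    larger than ``size`` leaves gaps and warns.
    """
    if size <= 0 or (step is not None and step <= 0):
        raise ValueError("window size and step must be > 0")
    step = size if step is None else step
    if step > size:
        logger.warning("tile_windows: step %d > size %d leaves gaps", step, size)
    rows = []
    for chrom, clen in chrom_lengths.items():
        start = 0
        while start < clen:
            rows.append({"chrom": chrom, "start": start, "end": min(start + size, clen)})
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def window_methylation(
    calls: list[MethylationCalls], windows: pd.DataFrame
) -> WindowMethylation:
    """Per-window, per-cell methylation rate and CpG coverage.

    Coverage is the summed (met + unmet) over CpGs with position in
    [start, end); the rate is pooled met/coverage, missing (NaN) where the
    coverage is 0.  Windows may overlap (sliding windows).
    """
    windows = windows.reset_index(drop=True)
    cell_ids = [c.cell_id for c in calls]
    n_w = len(windows)
    met_sum = np.zeros((n_w, len(calls)))
    tot_sum = np.zeros((n_w, len(calls)), dtype=np.int64)

    win_by_chrom = {
        chrom: grp for chrom, grp in windows.groupby("chrom", sort=False)
    }
    for ci, cell in enumerate(calls):
        for chrom, grp in cell.records.groupby("chrom", sort=False):
            if chrom not in win_by_chrom:
                continue
            pos = grp["pos"].values
            met = np.concatenate([[0], np.cumsum(grp["met"].values)])
            tot = np.concatenate(
                [[0], np.cumsum((grp["met"] + grp["unmet"]).values)]
            )
            w = win_by_chrom[chrom]
            lo = np.searchsorted(pos, w["start"].values, side="left")
            hi = np.searchsorted(pos, w["end"].values, side="left")
            met_sum[w.index, ci] = met[hi] - met[lo]
            tot_sum[w.index, ci] = tot[hi] - tot[lo]

    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(tot_sum > 0, met_sum / np.where(tot_sum > 0, tot_sum, 1), np.nan)
    return WindowMethylation(
        windows=windows,
        rates=pd.DataFrame(rates, columns=cell_ids),
        coverages=pd.DataFrame(tot_sum, columns=cell_ids),
    )


# ---------------------------------------------------------------------------
# weighted summaries
# ---------------------------------------------------------------------------

def group_weighted_mean(rates, coverages) -> float:
    """Coverage-weighted mean methylation rate over cells.

    sum(rate_i * cov_i) / sum(cov_i) over cells with coverage, which equals
    the pooled sum(met)/sum(met + unmet).  NaN if no cell has coverage.
    """
    rates = np.asarray(rates, dtype=float)
    cov = np.asarray(coverages, dtype=float)
    mask = cov > 0
    if not mask.any():
        return float("nan")
    return float(np.sum(rates[mask] * cov[mask]) / np.sum(cov[mask]))


def global_methylation(calls: list[MethylationCalls]) -> pd.Series:
    """Per-cell overall methylation rate pooled over all CpGs."""
    return pd.Series(
        {c.cell_id: c.global_rate() for c in calls}, name="global_methylation"
    )


def group_global_methylation(
    rates: pd.Series, cells: pd.DataFrame, by: list[str] = ("lineage", "treatment")
) -> pd.DataFrame:
    """Mean and median of per-cell global rates by cell-metadata groups."""
    df = rates.to_frame("rate").join(cells[list(by)])
    out = df.groupby(list(by), observed=True)["rate"].agg(["mean", "median", "count"])
    return out.rename(columns={"count": "n_cells"})


# ---------------------------------------------------------------------------
# DMR stand-in caller
# ---------------------------------------------------------------------------

@dataclass
class DMRParams:
    """Cut-offs of the pooled-count DMR stand-in.

    A window is testable iff each group has at least ``n_min`` cells with
    window coverage >= ``c_min``; the test is a two-sided Fisher exact on
    the groups' pooled (met, unmet) counts; a DMR needs BH-FDR <= ``q``
    and an absolute pooled-rate difference >= ``min_delta``.
    """

    n_min: int = 5
    c_min: int = 3
    q: float = 0.05
    min_delta: float = 0.10


def call_dmrs(
    wm: WindowMethylation,
    cells_a: list[str],
    cells_b: list[str],
    params: DMRParams | None = None,
) -> pd.DataFrame:
    """Call differentially methylated windows between two cell groups.

    Direction is B versus A: "hyper" means group B is more methylated.
    Returns a table of all *testable* windows with pooled rates, delta,
    p, BH-FDR, and an ``is_dmr`` flag; rows are sorted by p-value.
    """
    par = params or DMRParams()
    cells_a, cells_b = list(cells_a), list(cells_b)

    cov_a = wm.coverages[cells_a].values
    cov_b = wm.coverages[cells_b].values
    rate_a = wm.rates[cells_a].values
    rate_b = wm.rates[cells_b].values

    n_ok_a = (cov_a >= par.c_min).sum(axis=1)
    n_ok_b = (cov_b >= par.c_min).sum(axis=1)
    testable = (n_ok_a >= par.n_min) & (n_ok_b >= par.n_min)
    if not testable.any():
        logger.warning("call_dmrs: zero testable windows")
        return pd.DataFrame(
            columns=[
                "chrom", "start", "end", "n_cells_a", "n_cells_b",
                "rate_a", "rate_b", "delta_rate", "direction",
                "p_value", "fdr", "is_dmr",
            ]
        )

    # pooled counts: rate * coverage recovers the summed met exactly
    met_a = np.nansum(np.where(cov_a > 0, rate_a * cov_a, 0.0), axis=1)
    met_b = np.nansum(np.where(cov_b > 0, rate_b * cov_b, 0.0), axis=1)
    tot_a = cov_a.sum(axis=1).astype(float)
    tot_b = cov_b.sum(axis=1).astype(float)

    idx = np.flatnonzero(testable)
    pvals = np.empty(len(idx))
    for j, w in enumerate(idx):
        table = [
            [int(round(met_a[w])), int(round(tot_a[w] - met_a[w]))],
            [int(round(met_b[w])), int(round(tot_b[w] - met_b[w]))],
        ]
        pvals[j] = scipy.stats.fisher_exact(table, alternative="two-sided")[1]

    fdr = scipy.stats.false_discovery_control(pvals, method="bh")
    pr_a = met_a[idx] / tot_a[idx]
    pr_b = met_b[idx] / tot_b[idx]
    delta = pr_b - pr_a

    out = wm.windows.iloc[idx].copy().reset_index(drop=True)
    out["n_cells_a"] = n_ok_a[idx]
    out["n_cells_b"] = n_ok_b[idx]
    out["rate_a"] = pr_a
    out["rate_b"] = pr_b
    out["delta_rate"] = delta
    out["direction"] = np.where(delta > 0, "hyper", "hypo")
    out["p_value"] = pvals
    out["fdr"] = fdr
    out["is_dmr"] = (fdr <= par.q) & (np.abs(delta) >= par.min_delta)
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _tss_table(genes: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for gid, row in genes.iterrows():
        for t in row["tss_positions"]:
            rows.append({"gene_id": gid, "chrom": row["chrom"], "tss": int(t)})
    return pd.DataFrame(rows).sort_values(["chrom", "tss", "gene_id"])


def nearest_tss(
    window: GenomicWindow, genes: pd.DataFrame, _tss: pd.DataFrame | None = None
) -> tuple[str, int]:
    """Nearest gene by isoform TSS distance to a window.

    Distance is 0 when a TSS falls inside [start, end); otherwise the gap
    to the closest contained coordinate.  Equidistant genes tie-break by
    lexicographically smaller gene_id.
    """
    tss = _tss if _tss is not None else _tss_table(genes)
    sub = tss[tss["chrom"] == window.chrom]
    if sub.empty:
        sub = tss
    if sub.empty:
        raise ValueError("annotation has no TSS positions")
    t = sub["tss"].values
    d = np.where(
        t < window.start,
        window.start - t,
        np.where(t >= window.end, t - (window.end - 1), 0),
    )
    best = d.min()
    candidates = sorted(sub["gene_id"].values[d == best])
    return candidates[0], int(best)


def annotate_nearest_tss(dmrs: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Add nearest_gene / tss_distance columns to a DMR table."""
    tss = _tss_table(genes)
    out = dmrs.copy()
    nearest, dist = [], []
    for _, row in dmrs.iterrows():
        g, d = nearest_tss(
            GenomicWindow(row["chrom"], int(row["start"]), int(row["end"])),
            genes,
            _tss=tss,
        )
        nearest.append(g)
        dist.append(d)
    out["nearest_gene"] = nearest
    out["tss_distance"] = dist
    return out


# ---------------------------------------------------------------------------
# weighted methylation-expression correlation
# ---------------------------------------------------------------------------

def weighted_meth_expr_correlation(
    rates, coverages, expression
) -> "WeightedCorrelation":
    """Coverage-weighted Pearson correlation of window methylation with
    expression across cells, with a 95% Fisher-z confidence interval.

    Weights are the per-cell CpG coverages; the effective sample size is
    the Kish n_eff = (sum w)^2 / sum(w^2) and the CI is
    tanh(atanh(r) +/- 1.96 / sqrt(n_eff - 3)), undefined when n_eff <= 3.
    Zero weighted variance in either variable gives an undefined (NaN) r.
    """
    from .types import WeightedCorrelation

    rates = np.asarray(rates, dtype=float)
    w = np.asarray(coverages, dtype=float)
    x = np.asarray(expression, dtype=float)
    mask = (w > 0) & ~np.isnan(rates) & ~np.isnan(x)
    if mask.sum() < 3:
        raise ValueError("need at least 3 cells with coverage")
    m, w, x = rates[mask], w[mask], x[mask]

    sw = w.sum()
    mean_m = np.sum(w * m) / sw
    mean_x = np.sum(w * x) / sw
    var_m = np.sum(w * (m - mean_m) ** 2) / sw
    var_x = np.sum(w * (x - mean_x) ** 2) / sw
    n_eff = sw**2 / np.sum(w**2)
    if var_m == 0 or var_x == 0:
        logger.warning("weighted correlation undefined: zero weighted variance")
        return WeightedCorrelation(float("nan"), float("nan"), float("nan"), float(n_eff))
    cov = np.sum(w * (m - mean_m) * (x - mean_x)) / sw
    r = float(np.clip(cov / np.sqrt(var_m * var_x), -1.0, 1.0))

    if n_eff <= 3:
        return WeightedCorrelation(r, float("nan"), float("nan"), float(n_eff))
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = 1.959963984540054 / np.sqrt(n_eff - 3)
    return WeightedCorrelation(
        r, float(np.tanh(z - half)), float(np.tanh(z + half)), float(n_eff)
    )


# ---------------------------------------------------------------------------
# X-chromosome F:M methylation track
# ---------------------------------------------------------------------------

def x_fm_methylation_track(
    wm: WindowMethylation,
    cell_sex: pd.Series,
    window_bins: int = 50,
    min_cells: int = 5,
    min_cov: int = 10,
) -> pd.DataFrame:
    """Female-to-male methylation ratio track over tiled bins.

    A bin is eligible iff it has coverage strictly greater than ``min_cov``
    in at least ``min_cells`` female and ``min_cells`` male cells.  The
    per-sex bin level is the unweighted mean of per-cell rates among those
    covered cells; the track is the mean ratio over a centered sliding
    window of ``window_bins`` consecutive eligible bins, truncated at the
    chromosome ends.  Bins with a zero male mean are dropped with a log
    entry.
    """
    f_cells = list(cell_sex.index[cell_sex == "female"])
    m_cells = list(cell_sex.index[cell_sex == "male"])
    f_cells = [c for c in f_cells if c in wm.rates.columns]
    m_cells = [c for c in m_cells if c in wm.rates.columns]

    cov_f = wm.coverages[f_cells].values > min_cov
    cov_m = wm.coverages[m_cells].values > min_cov
    eligible = (cov_f.sum(axis=1) >= min_cells) & (cov_m.sum(axis=1) >= min_cells)

    rate_f = wm.rates[f_cells].values
    rate_m = wm.rates[m_cells].values
    with np.errstate(invalid="ignore"):
        mean_f = np.nanmean(np.where(cov_f, rate_f, np.nan), axis=1)
        mean_m = np.nanmean(np.where(cov_m, rate_m, np.nan), axis=1)

    out = wm.windows.loc[eligible].copy()
    out["mean_f"] = mean_f[eligible]
    out["mean_m"] = mean_m[eligible]
    zero_m = out["mean_m"] == 0
    if zero_m.any():
        logger.info(
            "x_fm_methylation_track: dropping %d bin(s) with zero male mean",
            int(zero_m.sum()),
        )
        out = out.loc[~zero_m]
    out["ratio"] = out["mean_f"] / out["mean_m"]

    if len(out) < window_bins:
        logger.warning(
            "x_fm_methylation_track: %d eligible bins < window of %d, "
            "window = all bins",
            len(out),
            window_bins,
        )
    out = out.sort_values(["chrom", "start"], kind="mergesort")
    out["smoothed"] = (
        out.groupby("chrom", sort=False)["ratio"]
        .transform(lambda s: s.rolling(window_bins, center=True, min_periods=1).mean())
    )
    return out.reset_index(drop=True)


def xist_region_methylation(
    calls: list[MethylationCalls],
    regions: dict[str, GenomicWindow],
    groups: dict[str, list[str]],
) -> pd.DataFrame:
    """Weighted mean methylation of named regions per cell group.

    ``regions`` maps a region name (e.g. "promoter", "gene_body") to its
    coordinates — the XIST regulatory-feature coordinates are an input,
    not computed.  ``groups`` maps a group label (e.g. treatment arm of
    female TE cells) to cell ids.  Missing coverage gives NaN with a
    warning.
    """
    windows = pd.DataFrame(
        [
            {"chrom": w.chrom, "start": w.start, "end": w.end, "name": name}
            for name, w in regions.items()
        ]
    )
    wm = window_methylation(calls, windows[["chrom", "start", "end"]])
    rows = []
    for gname, cell_ids in groups.items():
        cell_ids = [c for c in cell_ids if c in wm.rates.columns]
        for i, name in enumerate(windows["name"]):
            val = group_weighted_mean(
                wm.rates.iloc[i][cell_ids].values,
                wm.coverages.iloc[i][cell_ids].values,
            )
            if np.isnan(val):
                logger.warning(
                    "region %s has no coverage in group %s", name, gname
                )
            rows.append({"region": name, "group": gname, "weighted_mean": val,
                         "n_cells": len(cell_ids)})
    return pd.DataFrame(rows)
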