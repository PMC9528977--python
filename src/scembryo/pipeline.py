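"""End-to-end orchestration: config validation, stage running, reporting.

The pipeline runs simulate -> qc -> sex -> dosage -> methylome -> smallrna
on a synthetic dataset (or user-supplied files via the CLI), records every
stage's summary in a machine-readable JSON report, and is byte-deterministic
under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as scio
from .dosage import (
    chromosome_output,
    fm_gene_ratios,
    moving_average_track,
    wilcoxon_two_sided,
    xist_summary,
)
from .methylome import (
    DMRParams,
    annotate_nearest_tss,
    call_dmrs,
    global_methylation,
    group_global_methylation,
    meth_cell_qc,
    tile_windows,
    weighted_meth_expr_correlation,
    window_methylation,
    x_fm_methylation_track,
    xist_region_methylation,
)
from .qc import QCThresholds, qc_filter_cells, select_expressed_genes
from .sex import sex_calls, xci_eligible_cells
from .simulate import SimulationConfig, generate_dataset
from .smallrna import (
    biotype_proportions,
    de_features,
    de_smallrna,
    mirna_mrna_edges,
    test_biotype_shift,
)
from .types import GenomicWindow

logger = logging.getLogger("scembryo")

_DOSAGE_DEFAULTS = {"k": 20, "min_mean_rpkm": 5.0, "autosome": "chr1"}
_METH_DEFAULTS = {
    "dmr_window_size": 3000,
    "fm_bin_size": 100_000,
    "fm_window_bins": 50,
    "fm_min_cells": 5,
    "fm_min_cov": 10,
    "n_correlation_dmrs": 10,
    "dmr": {"n_min": 5, "c_min": 3, "q": 0.05, "min_delta": 0.10},
}
_SMALLRNA_DEFAULTS = {"min_abs_log2fc": 0.25, "max_fdr": 0.05, "n_target_genes": 50}
_TOP_DEFAULTS = {"seed": 0, "log_level": "INFO"}

#: keys that are nested sections (recursed into); any other dict-valued key
#: (n_genes, chrom_lengths, ...) is a value replaced wholesale.
_SECTIONS = ("simulate", "qc", "dosage", "methylome", "smallrna", "dmr")


@dataclasses.dataclass
class PipelineConfig:
    """Validated, fully-defaulted pipeline configuration."""

    seed: int
    log_level: str
    simulate: SimulationConfig
    qc: QCThresholds
    dosage: dict
    methylome: dict
    smallrna: dict

    def as_dict(self) -> dict:
        return {
            "seed": self.seed,
            "log_level": self.log_level,
            "simulate": dataclasses.asdict(self.simulate),
            "qc": dataclasses.asdict(self.qc),
            "dosage": self.dosage,
            "methylome": self.methylome,
            "smallrna": self.smallrna,
        }

    def hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _default_tree() -> dict:
    return {
        **_TOP_DEFAULTS,
        "simulate": dataclasses.asdict(SimulationConfig()),
        # the per-cell expressed-gene threshold is scaled from the full
        # transcriptome (>3000 of ~33k annotated genes) to the synthetic
        # 1333-gene transcriptome; all other cut-offs carry over unchanged
        "qc": {**dataclasses.asdict(QCThresholds()), "min_genes_per_cell": 800},
        "dosage": dict(_DOSAGE_DEFAULTS),
        "methylome": {**_METH_DEFAULTS, "dmr": dict(_METH_DEFAULTS["dmr"])},
        "smallrna": dict(_SMALLRNA_DEFAULTS),
    }


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, val in user.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValueError(f"unknown config key: {here!r}")
        ref = defaults[key]
        if key in _SECTIONS and isinstance(ref, dict):
            if not isinstance(val, dict):
                raise ValueError(f"config key {here!r} must be a mapping")
            out[key] = _merge(ref, val, here)
            continue
        if isinstance(ref, bool) and not isinstance(val, bool):
            raise ValueError(f"config key {here!r} expects a boolean")
        if isinstance(ref, (int, float)) and not isinstance(ref, bool):
            if not isinstance(val, (int, float)) or isinstance(val, bool):
                raise ValueError(f"config key {here!r} expects a number")
        if isinstance(ref, str) and not isinstance(val, str):
            raise ValueError(f"config key {here!r} expects a string")
        if isinstance(ref, (tuple, list)) and not isinstance(val, (tuple, list)):
            raise ValueError(f"config key {here!r} expects a sequence")
        if isinstance(ref, tuple):
            val = tuple(val)
        out[key] = val
    return out


def validate_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load and validate a YAML config, filling defaults.

    An empty (or absent) file yields the all-defaults config; unknown keys
    are rejected naming the offending key; obvious type and positivity
    violations raise before any stage runs.
    """
    user: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a YAML mapping")
        user = loaded
    if overrides:
        user = _merge_user(user, overrides)

    tree = _merge(_default_tree(), user)

    meth = tree["methylome"]
    for key in ("dmr_window_size", "fm_bin_size", "fm_window_bins"):
        if meth[key] <= 0:
            raise ValueError(f"config key methylome.{key!r} must be > 0")
    sim_kwargs = dict(tree["simulate"])
    sim_kwargs["seed"] = int(tree["seed"])
    sim = SimulationConfig(**sim_kwargs)  # runs its own validation
    qc = QCThresholds(**{**tree["qc"], "excluded_embryos": tuple(tree["qc"]["excluded_embryos"])})
    return PipelineConfig(
        seed=int(tree["seed"]),
        log_level=str(tree["log_level"]),
        simulate=sim,
        qc=qc,
        dosage=tree["dosage"],
        methylome=meth,
        smallrna=tree["smallrna"],
    )


def _merge_user(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge_user(out[k], v)
        else:
            out[k] = v
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage on a synthetic dataset and write a JSON report.

    Stage order: simulate -> qc -> sex -> dosage -> methylome -> smallrna.
    A stage failure aborts with the stage name and cause; outputs written
    so far are retained next to a ``FAILED_<stage>`` marker.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "config_hash": config.hash(), "stages": {}}
    state: dict = {}
    stages = [
        ("simulate", _stage_simulate),
        ("qc", _stage_qc),
        ("sex", _stage_sex),
        ("dosage", _stage_dosage),
        ("methylome", _stage_methylome),
        ("smallrna", _stage_smallrna),
    ]
    for name, fn in stages:
        try:
            report["stages"][name] = _jsonable(fn(config, state, outdir))
        except Exception as exc:
            (outdir / f"FAILED_{name}").write_text(f"{type(exc).__name__}: {exc}\n")
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _stage_simulate(config: PipelineConfig, state: dict, outdir: Path) -> dict:
    expr, meth, srna, truth = generate_dataset(config.simulate)
    state.update(expr=expr, meth=meth, srna=srna, truth=truth)

    scio.write_expression(expr, outdir / "expression")
    meth_dir = outdir / "methylation"
    meth_dir.mkdir(parents=True, exist_ok=True)
    meth_meta = []
    for calls in meth:
        scio.write_methylation_calls(calls, meth_dir / f"{calls.cell_id}.cov")
        meth_meta.append(
            {
                "cell_id": calls.cell_id,
                "total_reads": calls.total_reads,
                "mapped_fraction": calls.mapped_fraction,
            }
        )
    pd.DataFrame(meth_meta).to_csv(meth_dir / "cells.tsv", sep="\t", index=False)
    scio.write_smallrna(srna, outdir / "smallrna")
    truth.cells.to_csv(outdir / "truth_cells.tsv", sep="\t")
    if truth.dmrs is not None:
        truth.dmrs.to_csv(outdir / "truth_dmrs.tsv", sep="\t", index=False)
    return {
        "n_cells": expr.n_cells,
        "n_genes": expr.n_genes,
        "n_meth_cells": len(meth),
        "n_smallrna_features": len(srna.counts),
    }


def _stage_qc(config: PipelineConfig, state: dict, outdir: Path) -> dict:
    expr = qc_filter_cells(state["expr"], config.qc)
    state["expr"] = expr
    expressed = select_expressed_genes(expr, config.qc)
    state["expressed_genes"] = expressed
    scio.write_cell_metadata(expr.cells, outdir / "qc_cells.tsv")
    reasons = pd.Series(
        [r for rs in expr.cells["qc_fail_reasons"] for r in rs]
    ).value_counts()
    return {
        "n_cells_retained": int(expr.cells["qc_pass"].sum()),
        "n_cells_total": expr.n_cells,
        "n_expressed_genes": int(len(expressed)),
        "fail_reasons": reasons.to_dict(),
    }


def _stage_sex(config: PipelineConfig, state: dict, outdir: Path) -> dict:
    expr = state["expr"]
    calls = sex_calls(expr)
    state["sex_calls"] = calls
    calls.to_csv(outdir / "sex_calls.tsv", sep="\t")
    summary = {
        "n_male_cells": int((calls["cell_sex"] == "male").sum()),
        "n_female_cells": int((calls["cell_sex"] == "female").sum()),
        "n_ambiguous_cells": int((calls["cell_sex"] == "ambiguous").sum()),
        "n_conflicts": int(calls["conflict"].sum()),
    }
    truth = state.get("truth")
    if truth is not None and truth.cells is not None:
        # recovery scored on QC-passing cells (QC precedes sex inference)
        passing = calls.index[expr.cells.loc[calls.index, "qc_pass"]]
        match = calls.loc[passing, "cell_sex"].eq(truth.cells.loc[passing, "sex"])
        summary["cell_sex_recovery"] = float(match.mean())
    return summary


def _te_cells(expr, calls) -> list[str]:
    """QC-passing, sex-consistent trophectoderm (mural + polar) cells."""
    eligible = set(xci_eligible_cells(calls))
    return [
        c
        for c in expr.cells.index
        if expr.cells.loc[c, "qc_pass"]
        and expr.cells.loc[c, "lineage"] in ("mural", "polar")
        and c in eligible
    ]


def _stage_dosage(config: PipelineConfig, state: dict, outdir: Path) -> dict:
    expr, calls = state["expr"], state["sex_calls"]
    cells = _te_cells(expr, calls)
    autosome = config.dosage["autosome"]
    k = int(config.dosage["k"])
    min_rpkm = float(config.dosage["min_mean_rpkm"])

    sums = pd.DataFrame(
        {
            "chrX": chromosome_output(expr, "chrX", cells),
            autosome: chromosome_output(expr, autosome, cells),
        }
    )
    sums["sex"] = calls.loc[cells, "cell_sex"]
    sums["treatment"] = expr.cells.loc[cells, "treatment"]
    sums.to_csv(outdir / "chromosome_output.tsv", sep="\t")

    def _vals(chrom, sex, arm):
        m = (sums["sex"] == sex) & (sums["treatment"] == arm)
        return sums.loc[m, chrom].values

    tests = {
        "x_f_vs_m_treated": wilcoxon_two_sided(
            _vals("chrX", "female", "dex"), _vals("chrX", "male", "dex")
        ),
        "x_f_vs_m_control": wilcoxon_two_sided(
            _vals("chrX", "female", "control"), _vals("chrX", "male", "control")
        ),
        "x_female_treated_vs_control": wilcoxon_two_sided(
            _vals("chrX", "female", "dex"), _vals("chrX", "female", "control")
        ),
        "autosome_f_vs_m_control": wilcoxon_two_sided(
            _vals(autosome, "female", "control"), _vals(autosome, "male", "control")
        ),
        "autosome_f_vs_m_treated": wilcoxon_two_sided(
            _vals(autosome, "female", "dex"), _vals(autosome, "male", "dex")
        ),
    }

    med_t = np.median(_vals("chrX", "female", "dex"))
    med_c = np.median(_vals("chrX", "female", "control"))
    ratio = float(med_t / med_c) if med_c > 0 else float("nan")

    tracks = {}
    ratios_out = []
    for arm in ("control", "dex"):
        arm_cells = [c for c in cells if expr.cells.loc[c, "treatment"] == arm]
        for chrom in ("chrX", autosome):
            ratios = fm_gene_ratios(
                expr, calls, chrom, cells=arm_cells, min_mean_rpkm=min_rpkm
            )
            r = ratios.copy()
            r["chrom"], r["arm"] = chrom, arm
            ratios_out.append(r)
            genes = expr.genes.loc[ratios.index]
            positions = genes["tss_positions"].map(min).values
            track = moving_average_track(positions, ratios["ratio"].values, k=k)
            tracks[(arm, chrom)] = track
            scio.write_track(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": track["position"],
                        "end": track["position"] + 1,
                        "value": track["smoothed"],
                    }
                ),
                outdir / f"fm_expression_track_{chrom}_{arm}.bedGraph",
                name=f"FM_expression_{chrom}_{arm}",
            )
    pd.concat(ratios_out).to_csv(outdir / "fm_gene_ratios.tsv", sep="\t")

    xist = xist_summary(expr, calls, cells=cells) if "XIST" in expr.rpkm.index else None
    summary = {
        "n_te_cells": len(cells),
        "wilcoxon_p": tests,
        "x_output_female_treated_to_control_ratio": ratio,
        "fm_track_mean": {
            f"{arm}_{chrom}": float(t["smoothed"].mean()) for (arm, chrom), t in tracks.items()
        },
    }
    if xist is not None:
        summary["xist_p_f_vs_m"] = {arm: d["p_f_vs_m"] for arm, d in xist.items()}
    state["dosage_cells"] = cells
    return summary


def _stage_methylome(config: PipelineConfig, state: dict, outdir: Path) -> dict:
    expr, calls_meta = state["expr"], state["sex_calls"]
    truth = state["truth"]
    meth_all = state["meth"]
    mcfg = config.methylome

    retained, qc_table = meth_cell_qc(meth_all, config.qc)
    qc_table.to_csv(outdir / "meth_qc.tsv", sep="\t")
    cells_meta = expr.cells

    rates = global_methylation(retained)
    groups = group_global_methylation(
        rates, cells_meta.loc[rates.index], by=["lineage", "treatment"]
    )
    groups.to_csv(outdir / "global_methylation.tsv", sep="\t")

    # DMRs between arms on non-overlapping tiles
    sim = config.simulate
    lengths = {c: int(sim.chrom_lengths[c]) for c in sim.meth_chroms}
    tiles = tile_windows(lengths, int(mcfg["dmr_window_size"]))
    wm = window_methylation(retained, tiles)
    ids = [c.cell_id for c in retained]
    arm = cells_meta.loc[ids, "treatment"]
    cells_a = [c for c in ids if arm[c] == "control"]
    cells_b = [c for c in ids if arm[c] == "dex"]
    par = DMRParams(**{k: v for k, v in mcfg["dmr"].items()})
    dmr_table = call_dmrs(wm, cells_a, cells_b, par)
    dmr_table = annotate_nearest_tss(dmr_table, expr.genes)
    dmr_table.to_csv(outdir / "dmrs.tsv", sep="\t", index=False)
    dmrs = dmr_table[dmr_table["is_dmr"]]
    with open(outdir / "dmrs.bed", "w") as fh:
        for _, row in dmrs.iterrows():
            fh.write(
                f"{row['chrom']}\t{row['start']}\t{row['end']}\t"
                f"{row['direction']}\t{row['delta_rate']:.4f}\n"
            )

    # weighted methylation-expression correlation for the top DMR windows
    corr_rows = []
    widx = {tuple(w): i for i, w in enumerate(wm.windows.itertuples(index=False))}
    shared = [c for c in ids if c in expr.tpm.columns]
    for _, row in dmrs.head(int(mcfg["n_correlation_dmrs"])).iterrows():
        i = widx[(row["chrom"], row["start"], row["end"])]
        gene = row["nearest_gene"]
        expr_vals = np.log2(expr.tpm.loc[gene, shared].values + 1)
        try:
            wc = weighted_meth_expr_correlation(
                wm.rates.iloc[i][shared].values,
                wm.coverages.iloc[i][shared].values,
                expr_vals,
            )
        except ValueError:
            continue
        corr_rows.append(
            {
                "chrom": row["chrom"], "start": row["start"], "end": row["end"],
                "gene": gene, "r": wc.r, "ci_low": wc.ci_low,
                "ci_high": wc.ci_high, "n_effective": wc.n_effective,
            }
        )
    corr_df = pd.DataFrame(
        corr_rows,
        columns=["chrom", "start", "end", "gene", "r", "ci_low", "ci_high", "n_effective"],
    )
    corr_df.to_csv(outdir / "dmr_expression_correlation.tsv", sep="\t", index=False)

    # X-chromosome F:M track per arm on 100-kb bins
    bins = tile_windows({"chrX": lengths.get("chrX", 0)}, int(mcfg["fm_bin_size"]))
    track_means = {}
    truth_sex = truth.cells["sex"]
    for arm_name in ("control", "dex"):
        arm_cells = [c for c in ids if arm[c] == arm_name]
        arm_calls = [c for c in retained if c.cell_id in set(arm_cells)]
        wm_bins = window_methylation(arm_calls, bins)
        track = x_fm_methylation_track(
            wm_bins,
            truth_sex.loc[arm_cells],
            window_bins=int(mcfg["fm_window_bins"]),
            min_cells=int(mcfg["fm_min_cells"]),
            min_cov=int(mcfg["fm_min_cov"]),
        )
        scio.write_track(
            track.rename(columns={"smoothed": "value"})[["chrom", "start", "end", "value"]],
            outdir / f"fm_methylation_track_chrX_{arm_name}.bedGraph",
            name=f"FM_methylation_chrX_{arm_name}",
        )
        track_means[arm_name] = (
            float(track["smoothed"].mean()) if len(track) else float("nan")
        )

    # XIST promoter / gene-body methylation, female TE cells by arm
    xist_summary_rows = None
    if "XIST" in expr.genes.index and expr.genes.loc["XIST", "chrom"] in lengths:
        g = expr.genes.loc["XIST"]
        t0 = int(min(g["tss_positions"]))
        regions = {
            "promoter": GenomicWindow(g["chrom"], max(0, t0 - 1000), t0 + 500),
            "gene_body": GenomicWindow(g["chrom"], int(g["start"]), int(g["end"])),
        }
        fem_te = [
            c
            for c in ids
            if truth_sex.get(c) == "female"
            and cells_meta.loc[c, "lineage"] in ("mural", "polar")
        ]
        groups_map = {
            a: [c for c in fem_te if arm[c] == a] for a in ("control", "dex")
        }
        xist_meth = xist_region_methylation(retained, regions, groups_map)
        xist_meth.to_csv(outdir / "xist_region_methylation.tsv", sep="\t", index=False)
        xist_summary_rows = {
            f"{row['region']}_{row['group']}": row["weighted_mean"]
            for _, row in xist_meth.iterrows()
        }

    # planted-DMR recovery against truth
    recovery = {}
    if truth.dmrs is not None and len(truth.dmrs):
        called = {
            (r["chrom"], r["start"], r["end"])
            for _, r in dmrs.iterrows()
        }
        planted = {
            (r["chrom"], r["start"], r["end"]) for _, r in truth.dmrs.iterrows()
        }
        tp = len(called & planted)
        recovery = {
            "n_planted": len(planted),
            "n_called": len(called),
            "sensitivity": tp / len(planted),
            "false_discoveries": len(called - planted),
        }

    state["meth_retained"] = retained
    return {
        "n_meth_cells_retained": len(retained),
        "global_methylation_by_group": {
            f"{lin}_{trt}": {"mean": row["mean"], "median": row["median"], "n": row["n_cells"]}
            for (lin, trt), row in groups.iterrows()
        },
        "n_dmrs": int(len(dmrs)),
        "dmr_recovery": recovery,
        "fm_methylation_track_mean": track_means,
        "xist_region_methylation": xist_summary_rows,
        "n_correlations": int(len(corr_df)),
    }


def _stage_smallrna(config: PipelineConfig, state: dict, outdir: Path) -> dict:
    expr, srna, truth = state["expr"], state["srna"], state["truth"]
    scfg = config.smallrna
    groups = srna.cells["treatment"]

    profile = biotype_proportions(srna, groups)
    profile.pooled.to_csv(outdir / "biotype_pooled_proportions.tsv", sep="\t")
    profile.per_cell.to_csv(outdir / "biotype_per_cell_proportions.tsv", sep="\t")
    shift = test_biotype_shift(profile, "control", "dex")
    shift.to_csv(outdir / "biotype_shift_tests.tsv", sep="\t")

    de_s = de_smallrna(srna, groups, "control", "dex")
    de_s.to_csv(outdir / "smallrna_de.tsv", sep="\t")

    # generic mRNA DE stand-in on TE cells
    te = [
        c
        for c in expr.cells.index
        if expr.cells.loc[c, "qc_pass"]
        and expr.cells.loc[c, "lineage"] in ("mural", "polar")
    ]
    de_g = de_features(
        expr.counts[te], expr.cells.loc[te, "treatment"], "control", "dex"
    )
    de_g.to_csv(outdir / "mrna_de.tsv", sep="\t")

    # synthetic target-pair table: candidate miRNAs x strongest DE genes
    mirnas = de_s.index[de_s["biotype"] == "miRNA"] if "biotype" in de_s else de_s.index
    top_genes = de_g.reindex(de_g["log2fc"].abs().sort_values(ascending=False).index)
    top_genes = top_genes.head(int(scfg["n_target_genes"])).index
    pairs = pd.DataFrame(
        [(m, g) for m in mirnas for g in top_genes], columns=["mirna_id", "gene_id"]
    )
    edges = mirna_mrna_edges(
        de_s, de_g, pairs,
        min_abs_log2fc=float(scfg["min_abs_log2fc"]),
        max_fdr=float(scfg["max_fdr"]),
    )
    edges.to_csv(outdir / "mirna_mrna_edges.tsv", sep="\t", index=False)

    summary = {
        "pooled_proportions": {
            arm: {bt: float(v) for bt, v in row.items()}
            for arm, row in profile.pooled.iterrows()
        },
        "biotype_shift_fdr": shift["fdr"].to_dict(),
        "n_de_smallrna": int((de_s["fdr"] <= float(scfg["max_fdr"])).sum()),
        "n_edges": int(len(edges)),
    }
    if truth.smallrna is not None:
        planted = truth.smallrna[truth.smallrna["planted_log2fc"] != 0]
        est = de_s["log2fc"].reindex(planted.index)
        summary["planted_smallrna_log2fc_mae"] = float(
            (est - planted["planted_log2fc"]).abs().mean()
        )
    return summary
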