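"""Synthetic multi-embryo, multi-omic data with planted, recoverable effects.

The generator emulates the statistical structure of a day-7 human blastocyst
multi-omics experiment: cells from several embryos across four lineages
(EPI, PE, mural, polar), two sexes, and a control/dexamethasone design;
sparse per-cell CpG methylation; and biotype-labeled small-RNA counts.

Planted effects, all recorded in a :class:`TruthTable`:

* X-linked expression dampening ``d`` in treated female cells (the
  dosage-compensation signal), with XIST exempt and instead elevated;
* X-chromosome-wide hypermethylation in treated female cells;
* explicit differentially methylated regions (DMRs) for a chosen group;
* a biotype-composition shift and per-feature fold changes in small RNAs.

Read sampling is multinomial over per-gene rates plus an *unassigned* read
mass (intergenic / multi-mapping reads that count toward the mapped library
size but not toward any gene).  The unassigned mass is held at the untreated
baseline, so a planted X dampening propagates into RPKM space nearly
undiluted: E[treated/control X output] = d / (1 - a_X (1 - d)) where a_X is
the assigned X share of the library.

All generators are byte-deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    ExpressionDataset,
    MethylationCalls,
    SmallRNADataset,
    SMALLRNA_BIOTYPES,
    empty_cell_metadata,
)

logger = logging.getLogger("scembryo")

_LINEAGE_ORDER = ("EPI", "PE", "mural", "polar")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with desk-scale defaults.

    Defaults are the study conditions the pipeline is exercised under:
    6 embryos x 40 cells, 1000 autosomal + 300 X + 20 Y genes, a 20,000-CpG
    methylome over a scaled genome (chr1 4.5 Mb, chrX 3 Mb), control
    small-RNA biotype proportions of 9.83 / 36.3 / 1.79 / 1.18 % (miRNA /
    tRNA / snoRNA / snRNA) with a -5.9 point tRNA shift under treatment,
    X dampening d = 0.7 and X hypermethylation +0.1 in treated females,
    and a lineage methylation gradient EPI < PE < mural < polar around a
    Beta(2, 7) region prior (mean 22.2%).
    """

    seed: int = 0
    # design
    n_embryos: int = 6
    cells_per_embryo: tuple[int, int] = (40, 40)
    sex_ratio: float = 0.5          # fraction of female embryos per arm
    treated_fraction: float = 0.5   # fraction of embryos in the dex arm
    lineage_proportions: tuple[float, float, float, float] = (0.12, 0.08, 0.50, 0.30)
    # genome
    n_genes: dict = field(
        default_factory=lambda: {"chr1": 1000, "chrX": 300, "chrY": 20, "chrM": 13}
    )
    chrom_lengths: dict = field(
        default_factory=lambda: {
            "chr1": 4_500_000,
            "chrX": 3_000_000,
            "chrY": 500_000,
            "chrM": 16_569,
        }
    )
    gene_length_log_mean: float = math.log(1500.0)
    gene_length_log_sd: float = 0.6
    # expression
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 1.0
    library_log_mean: float = math.log(5e5)
    library_log_sd: float = 0.3
    assigned_fraction: float = 0.5
    x_dampening: float = 0.7
    chry_expression_factor: float = 0.1  # Y output is a sliver of the transcriptome
    xist_factor: float = 5.0
    xist_treatment_multiplier: float = 2.0
    cell_gene_noise_sd: float = 0.3
    mito_fraction: float = 0.10
    dropout_rate: float = 0.10
    # planted low-quality cells (shallow, sparse libraries that QC should drop)
    low_quality_fraction: float = 0.08
    low_quality_libsize_factor: float = 0.05
    low_quality_dropout: float = 0.70
    # methylome
    meth_chroms: tuple[str, ...] = ("chr1", "chrX")
    meth_region_size: int = 3000
    cpgs_per_region: int = 8
    meth_alpha: float = 2.0
    meth_beta: float = 7.0
    meth_concentration: float = 100.0
    lineage_meth_offsets: dict = field(
        default_factory=lambda: {
            "EPI": 0.0,
            "PE": 0.003,
            "mural": 0.037,
            "polar": 0.054,
            "unknown": 0.0,
        }
    )
    treatment_meth_offset: float = -0.02
    x_hypermeth_delta: float = 0.10
    cpg_coverage_lambda: float = 5.0
    cpg_capture_prob: float = 0.20
    n_planted_dmrs: int = 12
    planted_dmr_delta: float = 0.30
    planted_dmr_group: tuple[str, str] = ("treatment", "dex")
    planted_dmrs: list | None = None   # explicit [(region_idx, col, value, delta)]
    meth_reads_log_mean: float = math.log(6e5)
    meth_reads_log_sd: float = 0.8
    mapped_frac_alpha: float = 6.0
    mapped_frac_beta: float = 30.0
    # small RNA
    smallrna_biotype_props: dict = field(
        default_factory=lambda: {
            "miRNA": 0.0983,
            "tRNA": 0.363,
            "snoRNA": 0.0179,
            "snRNA": 0.0118,
            "other": 0.509,
        }
    )
    planted_biotype_shift: tuple[str, float] = ("tRNA", -0.059)
    smallrna_features: dict = field(
        default_factory=lambda: {
            "miRNA": 120,
            "tRNA": 60,
            "snoRNA": 30,
            "snRNA": 15,
            "other": 40,
        }
    )
    smallrna_concentration: float = 300.0
    smallrna_total_log_mean: float = math.log(5e4)
    smallrna_total_log_sd: float = 0.4
    n_planted_de_smallrnas: int = 4
    planted_de_log2fc: tuple[float, ...] = (1.0, -1.0, 1.5, -1.5)
    planted_de_smallrnas: list | None = None   # explicit [(feature_id, log2fc)]

    def __post_init__(self) -> None:
        if not (0 < self.x_dampening <= 1):
            raise ValueError("x_dampening d must lie in (0, 1]")
        if self.xist_factor < 1:
            raise ValueError("xist_factor must be >= 1")
        for name in ("sex_ratio", "treated_fraction", "dropout_rate",
                     "cpg_capture_prob", "mito_fraction", "assigned_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if abs(sum(self.lineage_proportions) - 1.0) > 1e-9:
            raise ValueError("lineage_proportions must sum to 1")
        props = sum(self.smallrna_biotype_props.values())
        if abs(props - 1.0) > 1e-6:
            raise ValueError("smallrna_biotype_props must sum to 1")


@dataclass
class TruthTable:
    """Ground truth of a simulated dataset, for parameter-recovery scoring.

    Each generator fills the slice it owns; :meth:`merged` combines them.
    ``cells`` carries the true sex (metadata carries "NA" until inferred).
    """

    cells: pd.DataFrame | None = None
    genes: pd.DataFrame | None = None
    regions: pd.DataFrame | None = None
    dmrs: pd.DataFrame | None = None
    smallrna: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)

    def merged(self, *others: "TruthTable") -> "TruthTable":
        out = TruthTable(
            cells=self.cells,
            genes=self.genes,
            regions=self.regions,
            dmrs=self.dmrs,
            smallrna=self.smallrna,
            params=dict(self.params),
        )
        for o in others:
            for attr in ("cells", "genes", "regions", "dmrs", "smallrna"):
                if getattr(out, attr) is None:
                    setattr(out, attr, getattr(o, attr))
            out.params.update(o.params)
        return out


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # separate deterministic stream per generator so omics layers can be
    # regenerated independently of one another
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


# ---------------------------------------------------------------------------
# study design (cells)
# ---------------------------------------------------------------------------

def generate_cells(config: SimulationConfig) -> pd.DataFrame:
    """Simulate the embryo/cell design table (ground-truth covariates).

    Treatment and sex are embryo-level: arms get ``round(n * fraction)``
    embryos and each arm gets a balanced sex split, so both sexes are
    present in both arms at the default sex_ratio.
    """
    rng = _rng(config, 0)
    n = config.n_embryos
    n_treated = int(round(n * config.treated_fraction))
    arms = ["dex"] * n_treated + ["control"] * (n - n_treated)
    sexes: list[str] = []
    for arm in ("dex", "control"):
        k = arms.count(arm)
        n_f = int(round(k * config.sex_ratio))
        sexes.extend(["female"] * n_f + ["male"] * (k - n_f))

    rows = []
    lo, hi = config.cells_per_embryo
    for i in range(n):
        embryo = f"E{i + 1:02d}"
        n_cells = int(rng.integers(lo, hi + 1))
        lineages = rng.choice(
            _LINEAGE_ORDER, size=n_cells, p=list(config.lineage_proportions)
        )
        for j in range(n_cells):
            rows.append(
                {
                    "cell_id": f"{embryo}_c{j + 1:03d}",
                    "embryo_id": embryo,
                    "treatment": arms[i],
                    "sex": sexes[i],
                    "lineage": lineages[j],
                }
            )
    return pd.DataFrame(rows).set_index("cell_id")


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _generate_genes(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for chrom, n in config.n_genes.items():
        if n == 0:
            continue
        clen = int(config.chrom_lengths[chrom])
        lengths = np.clip(
            rng.lognormal(config.gene_length_log_mean, config.gene_length_log_sd, n),
            200,
            max(300, clen // 10),
        ).astype(int)
        starts = np.sort(rng.integers(0, max(1, clen - int(lengths.max()) - 1), n))
        for i in range(n):
            start = int(starts[i])
            end = min(start + int(lengths[i]), clen)
            strand = "+" if rng.random() < 0.5 else "-"
            tss = [start] if strand == "+" else [end]
            if end - start > 600 and rng.random() < 0.3:
                # second isoform TSS inside the gene body
                tss.append(int(rng.integers(start + 1, end)))
            tss = sorted(set(min(max(t, start), end) for t in tss))
            rows.append(
                {
                    "gene_id": f"{chrom.replace('chr', 'G')}_{i + 1:04d}",
                    "gene_name": f"{chrom.replace('chr', 'G')}_{i + 1:04d}",
                    "chrom": chrom,
                    "strand": strand,
                    "tss_positions": tss,
                    "start": start,
                    "end": end,
                    "length_bp": end - start,
                    "is_mito": chrom == "chrM",
                    "biotype": "protein_coding",
                }
            )
    genes = pd.DataFrame(rows).set_index("gene_id")
    # name a mid-chromosome X-linked gene XIST (lncRNA, dampening-exempt)
    x_ids = genes.index[genes["chrom"] == "chrX"]
    if len(x_ids):
        xist_old = x_ids[len(x_ids) // 2]
        genes = genes.rename(index={xist_old: "XIST"})
        genes.loc["XIST", ["gene_name", "biotype"]] = ["XIST", "lncRNA"]
    return genes


def generate_expression(
    config: SimulationConfig, cells: pd.DataFrame | None = None
) -> tuple[ExpressionDataset, TruthTable]:
    """Simulate counts, RPKM and TPM for the full cell design.

    Per-cell counts are multinomial over gene rates (plus the constant
    unassigned mass): rate_g scaled by ``d`` for X-linked genes of treated
    female cells, zeroed for Y-linked genes of female cells, and XIST
    boosted by ``xist_factor`` in females (doubled again under treatment).
    Dropout is independent zeroing.  RPKM/TPM come from the pipeline's own
    normalizer with the simulated mapped library sizes.
    """
    from .qc import normalize_expression

    if cells is None:
        cells = generate_cells(config)
    rng = _rng(config, 1)
    genes = _generate_genes(config, rng)
    n_g, n_c = len(genes), len(cells)

    base = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, n_g)
    base[(genes["chrom"] == "chrY").values] *= config.chry_expression_factor
    is_mito = genes["is_mito"].values
    if is_mito.any() and config.mito_fraction > 0:
        target = config.mito_fraction / (1 - config.mito_fraction)
        base[is_mito] *= target * base[~is_mito].sum() / base[is_mito].sum()

    is_x = (genes["chrom"] == "chrX").values
    is_y = (genes["chrom"] == "chrY").values
    is_xist = genes.index == "XIST"

    female = (cells["sex"] == "female").values
    treated = (cells["treatment"] == "dex").values

    mod = np.ones((n_g, n_c))
    mod[np.ix_(is_y, female)] = 0.0
    damp_targets = is_x & ~is_xist
    mod[np.ix_(damp_targets, female & treated)] = config.x_dampening
    mod[np.ix_(is_xist, female)] *= config.xist_factor
    mod[np.ix_(is_xist, female & treated)] *= config.xist_treatment_multiplier

    rates = base[:, None] * mod
    if config.cell_gene_noise_sd > 0:
        # mild per-gene biological noise on top of the library-size factor
        rates = rates * rng.lognormal(0, config.cell_gene_noise_sd, size=(n_g, n_c))
    unassigned = base.sum() * (1 - config.assigned_fraction) / config.assigned_fraction

    lib = rng.lognormal(config.library_log_mean, config.library_log_sd, n_c)
    low_quality = rng.random(n_c) < config.low_quality_fraction
    lib[low_quality] *= config.low_quality_libsize_factor
    lib = np.maximum(lib, 1000).astype(np.int64)

    counts = np.empty((n_g, n_c), dtype=np.int64)
    for c in range(n_c):
        p = np.append(rates[:, c], unassigned)
        p /= p.sum()
        draw = rng.multinomial(lib[c], p)
        counts[:, c] = draw[:-1]
    drop = np.where(low_quality, config.low_quality_dropout, config.dropout_rate)
    if (drop > 0).any():
        keep = rng.random((n_g, n_c)) >= drop[None, :]
        counts *= keep

    counts_df = pd.DataFrame(counts, index=genes.index, columns=cells.index)
    meta = empty_cell_metadata(cells.index)
    meta[["embryo_id", "treatment", "lineage"]] = cells[
        ["embryo_id", "treatment", "lineage"]
    ]
    meta["total_mapped_reads"] = lib

    rpkm, tpm = normalize_expression(counts_df, genes, pd.Series(lib, index=cells.index))
    ds = ExpressionDataset(counts=counts_df, genes=genes, cells=meta, rpkm=rpkm, tpm=tpm)
    ds.validate()

    truth_genes = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "base_rate": base,
            "is_xist": is_xist,
            "dampened_in_treated_females": damp_targets,
        },
        index=genes.index,
    )
    truth_cells = cells.copy()
    truth_cells["low_quality"] = low_quality
    truth = TruthTable(
        cells=truth_cells,
        genes=truth_genes,
        params={
            "x_dampening": config.x_dampening,
            "xist_factor": config.xist_factor,
            "xist_treatment_multiplier": config.xist_treatment_multiplier,
            "assigned_fraction": config.assigned_fraction,
        },
    )
    return ds, truth


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

def _tile_regions(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for chrom in config.meth_chroms:
        clen = int(config.chrom_lengths[chrom])
        for start in range(0, clen, config.meth_region_size):
            rows.append(
                {"chrom": chrom, "start": start, "end": min(start + config.meth_region_size, clen)}
            )
    return pd.DataFrame(rows)


def generate_methylome(
    config: SimulationConfig, cells: pd.DataFrame
) -> tuple[list[MethylationCalls], TruthTable]:
    """Simulate sparse per-cell CpG calls over a region-tiled genome.

    ``cells`` must carry ground-truth covariates (embryo_id, sex,
    treatment, lineage), e.g. the ``cells`` slice of a TruthTable.

    Hierarchy: region mean mu_r ~ Beta(alpha, beta); group offsets (lineage
    gradient, treatment shift, X hypermethylation in treated females,
    planted DMR deltas) added and clipped to [0, 1]; per-CpG per-cell
    coverage ~ Poisson(lambda) thinned by the capture probability; the
    methylated count is beta-binomial around the cell's region mean.
    """
    rng = _rng(config, 2)
    regions = _tile_regions(config)
    n_r = len(regions)
    cell_ids = list(cells.index)
    n_c = len(cell_ids)

    mu = rng.beta(config.meth_alpha, config.meth_beta, n_r)

    # CpG positions: fixed panel shared by all cells
    cpg_chrom: list[np.ndarray] = []
    cpg_pos: list[np.ndarray] = []
    cpg_region: list[np.ndarray] = []
    for r in range(n_r):
        start, end = regions.loc[r, "start"], regions.loc[r, "end"]
        k = min(config.cpgs_per_region, end - start)
        pos = start + np.sort(rng.choice(end - start, size=k, replace=False))
        cpg_pos.append(pos)
        cpg_chrom.append(np.repeat(regions.loc[r, "chrom"], k))
        cpg_region.append(np.repeat(r, k))
    pos_arr = np.concatenate(cpg_pos)
    chrom_arr = np.concatenate(cpg_chrom)
    region_arr = np.concatenate(cpg_region)
    n_cpg = len(pos_arr)

    # per-cell region means
    lin_off = cells["lineage"].map(config.lineage_meth_offsets).fillna(0.0).values.astype(float)
    treated = (cells["treatment"] == "dex").values
    female = (cells["sex"] == "female").values
    off = np.tile(lin_off, (n_r, 1))
    off[:, treated] += config.treatment_meth_offset
    is_x_region = (regions["chrom"] == "chrX").values
    off[np.ix_(is_x_region, treated & female)] += config.x_hypermeth_delta

    planted = config.planted_dmrs
    if planted is None and config.n_planted_dmrs > 0:
        # host regions chosen so the delta cannot clip at 0 or 1 even after
        # the group offsets; hyper and hypo DMRs alternate
        delta = config.planted_dmr_delta
        margin = 0.08
        ok_pos = ~is_x_region & (mu + delta + margin < 1)
        ok_neg = ~is_x_region & (mu - abs(delta) - margin > 0)
        n_pos = (config.n_planted_dmrs + 1) // 2
        n_neg = config.n_planted_dmrs - n_pos
        if ok_pos.sum() < n_pos or ok_neg.sum() < n_neg:
            raise ValueError(
                "not enough non-X regions to host the requested planted DMRs"
            )
        idx_pos = rng.choice(np.flatnonzero(ok_pos), size=n_pos, replace=False)
        idx_neg = rng.choice(np.flatnonzero(ok_neg), size=n_neg, replace=False)
        col, val = config.planted_dmr_group
        planted = [(int(r), col, val, delta) for r in np.sort(idx_pos)] + [
            (int(r), col, val, -delta) for r in np.sort(idx_neg)
        ]
    planted = planted or []
    dmr_rows = []
    for r_idx, col, val, delta in planted:
        members = (cells[col] == val).values
        lo, hi = mu[r_idx] + off[r_idx][members].min(), mu[r_idx] + off[r_idx][members].max()
        if lo + delta < 0 or hi + delta > 1:
            logger.warning(
                "planted DMR at region %d: delta %.3f clipped to [0, 1]", r_idx, delta
            )
        off[r_idx, members] += delta
        dmr_rows.append(
            {
                "region_idx": r_idx,
                "chrom": regions.loc[r_idx, "chrom"],
                "start": regions.loc[r_idx, "start"],
                "end": regions.loc[r_idx, "end"],
                "group_col": col,
                "group_value": val,
                "delta": delta,
            }
        )

    M = np.clip(mu[:, None] + off, 0.0, 1.0)  # region x cell true means

    cov = rng.poisson(config.cpg_coverage_lambda, size=(n_cpg, n_c))
    cov *= rng.random((n_cpg, n_c)) < config.cpg_capture_prob

    mu_site = M[region_arr, :]  # n_cpg x n_c
    s = config.meth_concentration
    p = mu_site.copy()
    interior = (mu_site > 0) & (mu_site < 1) & (cov > 0)
    p[interior] = rng.beta(mu_site[interior] * s, (1 - mu_site[interior]) * s)
    met = np.zeros_like(cov)
    covered = cov > 0
    met[covered] = rng.binomial(cov[covered], p[covered])

    calls: list[MethylationCalls] = []
    reads = np.maximum(
        rng.lognormal(config.meth_reads_log_mean, config.meth_reads_log_sd, n_c), 1
    ).astype(np.int64)
    mapped = rng.beta(config.mapped_frac_alpha, config.mapped_frac_beta, n_c)
    for c, cid in enumerate(cell_ids):
        mask = covered[:, c]
        rec = pd.DataFrame(
            {
                "chrom": chrom_arr[mask],
                "pos": pos_arr[mask],
                "met": met[mask, c],
                "unmet": cov[mask, c] - met[mask, c],
            }
        )
        calls.append(
            MethylationCalls(
                cell_id=cid,
                records=rec,
                total_reads=int(reads[c]),
                mapped_fraction=float(mapped[c]),
            )
        )

    regions_truth = regions.copy()
    regions_truth["mu"] = mu
    truth = TruthTable(
        cells=cells.copy(),
        regions=regions_truth,
        dmrs=pd.DataFrame(
            dmr_rows,
            columns=[
                "region_idx", "chrom", "start", "end", "group_col", "group_value", "delta",
            ],
        ),
        params={
            "meth_mean": config.meth_alpha / (config.meth_alpha + config.meth_beta),
            "x_hypermeth_delta": config.x_hypermeth_delta,
            "treatment_meth_offset": config.treatment_meth_offset,
            "lineage_meth_offsets": dict(config.lineage_meth_offsets),
        },
    )
    return calls, truth


# ---------------------------------------------------------------------------
# small RNA
# ---------------------------------------------------------------------------

def generate_smallrna(
    config: SimulationConfig, cells: pd.DataFrame
) -> tuple[SmallRNADataset, TruthTable]:
    """Simulate biotype-labeled small-RNA molecule counts.

    Per-cell biotype composition is Dirichlet around the arm's base
    proportions (the planted biotype shift applied, renormalized, in the
    treated arm); within-biotype feature shares are fixed Dirichlet draws;
    planted DE features are scaled by 2**log2fc in treated cells.  Every
    cell total is >= 1 by construction.
    """
    rng = _rng(config, 3)
    biotypes = [b for b in SMALLRNA_BIOTYPES if config.smallrna_features.get(b, 0) > 0]
    feat_ids: list[str] = []
    feat_bt: list[str] = []
    shares: dict[str, np.ndarray] = {}
    for bt in biotypes:
        n = config.smallrna_features[bt]
        feat_ids.extend(f"{bt}_{i + 1:03d}" for i in range(n))
        feat_bt.extend([bt] * n)
        shares[bt] = rng.dirichlet(np.ones(n))

    base = np.array([config.smallrna_biotype_props[b] for b in biotypes])
    shift_bt, shift_delta = config.planted_biotype_shift
    treated_props = base.copy()
    if shift_bt in biotypes and shift_delta != 0:
        i = biotypes.index(shift_bt)
        new = np.clip(base[i] + shift_delta, 0.0, 1.0)
        others = np.arange(len(biotypes)) != i
        treated_props[i] = new
        treated_props[others] = base[others] * (1 - new) / (1 - base[i])

    planted = config.planted_de_smallrnas
    if planted is None and config.n_planted_de_smallrnas > 0:
        # plant on above-average-share miRNAs so the fold change is
        # identifiable above molecule-sampling noise
        mirnas = [f for f, b in zip(feat_ids, feat_bt) if b == "miRNA"]
        mi_shares = shares["miRNA"]
        eligible = [f for f, s in zip(mirnas, mi_shares) if s >= 1.0 / len(mirnas)]
        chosen = rng.choice(
            eligible, size=min(config.n_planted_de_smallrnas, len(eligible)),
            replace=False,
        )
        planted = [
            (f, config.planted_de_log2fc[i % len(config.planted_de_log2fc)])
            for i, f in enumerate(sorted(chosen))
        ]
    planted = planted or []
    lfc_map = dict(planted)

    treated = (cells["treatment"] == "dex").values
    n_c = len(cells)
    totals = np.maximum(
        rng.lognormal(config.smallrna_total_log_mean, config.smallrna_total_log_sd, n_c),
        1,
    ).astype(np.int64)

    counts = np.zeros((len(feat_ids), n_c), dtype=np.int64)
    feat_bt_arr = np.array(feat_bt)
    for c in range(n_c):
        props = treated_props if treated[c] else base
        comp = rng.dirichlet(props * config.smallrna_concentration)
        p = np.empty(len(feat_ids))
        for bi, bt in enumerate(biotypes):
            sel = feat_bt_arr == bt
            sh = shares[bt].copy()
            if treated[c]:
                ids_bt = np.array(feat_ids)[sel]
                mult = np.array([2.0 ** lfc_map.get(f, 0.0) for f in ids_bt])
                sh = sh * mult
                sh /= sh.sum()
            p[sel] = comp[bi] * sh
        counts[:, c] = rng.multinomial(totals[c], p / p.sum())

    counts_df = pd.DataFrame(counts, index=feat_ids, columns=cells.index)
    meta = empty_cell_metadata(cells.index)
    meta[["embryo_id", "treatment", "lineage"]] = cells[
        ["embryo_id", "treatment", "lineage"]
    ]
    ds = SmallRNADataset(
        counts=counts_df,
        biotypes=pd.Series(feat_bt, index=counts_df.index, name="biotype"),
        cells=meta,
    ).validate()

    truth_feats = pd.DataFrame(
        {
            "biotype": feat_bt,
            "planted_log2fc": [lfc_map.get(f, 0.0) for f in feat_ids],
        },
        index=pd.Index(feat_ids, name="feature"),
    )
    truth = TruthTable(
        cells=cells.copy(),
        smallrna=truth_feats,
        params={
            "planted_biotype_shift": tuple(config.planted_biotype_shift),
            "biotype_props_control": {b: float(p) for b, p in zip(biotypes, base)},
            "biotype_props_treated": {b: float(p) for b, p in zip(biotypes, treated_props)},
        },
    )
    return ds, truth


# ---------------------------------------------------------------------------
# whole dataset
# ---------------------------------------------------------------------------

def generate_dataset(config: SimulationConfig):
    """Generate all three omics layers for one shared cell design.

    Returns ``(expression, methylome_calls, smallrna, truth)`` with a
    merged :class:`TruthTable`.
    """
    cells = generate_cells(config)
    expr, t1 = generate_expression(config, cells)
    meth, t2 = generate_methylome(config, cells)
    srna, t3 = generate_smallrna(config, cells)
    return expr, meth, srna, t1.merged(t2, t3)
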