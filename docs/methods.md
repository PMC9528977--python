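# Methods

`scembryo` re-implements, as a tested library, the bespoke computational
procedures used to analyse single-cell multi-omics (scRNA-seq, scBS-seq,
small-RNA-seq) of day-7 human blastocysts cultured with or without a
synthetic glucocorticoid (dexamethasone, DEX). The pipeline covers cell QC
and expression-based sex inference, X-chromosome dosage-compensation
readouts on both the expression and methylation side, coverage-weighted
sliding-window methylome quantification, small-RNA biotype profiling, and
miRNA–mRNA opposite-direction network construction. It is exercised end to
end on a synthetic embryo multi-omics generator with planted, recoverable
effects.

## Normalization and cell QC

RPKM is counts / (gene length in kb × mapped reads in millions). TPM uses a
library size that **excludes mitochondrial genes**, so TPM columns sum to
10⁶ over non-mitochondrial genes; a cell whose only expressed genes are
mitochondrial has an undefined (NaN) TPM column, flagged with a warning.

Cell QC applies four criteria sequentially:

1. non-mitochondrial library size strictly greater than 50,000 reads;
2. more than 3,000 expressed genes per cell (expressed = RPKM ≥ 1; the
   per-cell definition is not uniquely determined by the workflow being
   reproduced, and RPKM ≥ 1 was chosen for consistency with the
   dataset-level expressed-gene rule);
3. among the survivors of 1–2, the maximum pairwise Spearman correlation
   over the expressed-gene RPKM submatrix must reach 0.5 (the expressed-gene
   set for this step is computed over those survivors);
4. cells of explicitly excluded embryos (e.g. aneuploid) are dropped.

Because criterion 3 sees only survivors of 1–2, adding a cell that fails an
earlier criterion never changes another cell's status. Genes are retained
for analysis when RPKM ≥ 1 in at least five QC-passing cells (inclusive).
Methylome cells additionally require ≥ 0.1 M total reads and ≥ 7% mapped
reads (both inclusive).

The default pipeline configuration scales the per-cell expressed-gene
threshold from >3,000 (appropriate for a ~33k-gene annotation) to >800 for
the 1,333-gene synthetic transcriptome; the library-level default keeps the
full-scale value.

## Sex inference

Cell sex is read from the summed RPKM of Y-linked genes: sums strictly
above 100 are male, strictly below 50 female, and [50, 100] ambiguous —
the stated ranges are all strict, so the boundary values have no
assignment. Embryo sex is the majority vote over unambiguous cells (ties
are undetermined — no tie rule is stated, so none is invented), and cells
conflicting with their embryo's sex are flagged and excluded, together with
ambiguous cells, from all X-chromosome analyses.

## Expression-side X dosage

* **Chromosome output**: the per-cell sum of RPKM over a chromosome's
  annotated genes; chromosome 1 serves as the autosomal control.
* **Group comparisons**: two-sided Wilcoxon rank-sum (exact enumeration for
  small untied samples, normal approximation with tie correction
  otherwise); two constant equal groups give p = 1.
* **F:M per-gene ratios**: a gene is eligible when its mean RPKM across the
  stratum's pooled cells is strictly greater than 5 (a single pooled
  cut-off avoids sex-specific selection bias); the ratio is the female
  group mean over the male group mean, reported as log2 with no pseudocount
  (the eligibility cut-off makes zero means rare; undefined ratios are
  dropped rather than smoothed). Means rather than medians are used; the
  source leaves this open.
* **Moving average**: for each focal gene, the mean over the k = 20 genes
  nearest by absolute TSS distance, focal gene included, sides ignored
  (end-of-chromosome windows become asymmetric rather than truncated, so
  the window size stays constant). Distance ties break toward the smaller
  position; gene position is the minimum TSS across isoforms (a
  deterministic single coordinate). The result is invariant to input
  ordering.
* **XIST**: per-cell XIST RPKM stratified by sex × treatment arm, with a
  female-vs-male Wilcoxon within each arm.

## Methylome

Internal genomic coordinates are 0-based half-open everywhere; the
Bismark-coverage dialect (1-based inclusive) is converted at the I/O
boundary, and duplicate CpG positions within one cell's file are summed to
tolerate per-strand reporting.

* **Windowing**: chromosomes are tiled into sliding windows
  [i·step, i·step + size); step = size gives non-overlapping bins and the
  final partial window is kept. The visualization default for 3-kb sliding
  windows is a 1.5-kb step (50% overlap; the step is not stated in the
  source and half-window steps are the common convention).
* **Window methylation**: per window per cell, coverage = Σ(met + unmet)
  over CpGs in [start, end) and rate = Σmet / coverage, missing at zero
  coverage.
* **Group weighted mean**: Σ(rate·cov)/Σcov over covered cells, which is
  algebraically the pooled Σmet/Σ(met+unmet) — an identity the tests check
  to 1e-12.
* **DMR stand-in**: the original caller's "stringent parameters" live in
  unavailable supplementary text, so an explicit stand-in is provided: a
  window is testable when each group has ≥ 5 cells with coverage ≥ 3; the
  test is a two-sided Fisher exact on the pooled (met, unmet) counts per
  group; a DMR needs BH-FDR ≤ 0.05 **and** an absolute pooled-rate
  difference ≥ 0.1. Direction is group B vs group A. This is a deliberately
  conservative, fully specified replacement, not a reproduction.
* **Nearest TSS**: distance from the window interval to the nearest isoform
  TSS (0 if contained); equidistant genes tie-break lexicographically.
* **Weighted methylation–expression correlation**: weighted Pearson with
  per-cell window CpG coverage as weights (coverage is the displayed
  precision proxy for single-cell rates). The 95% CI uses the Fisher
  z-transform with the Kish effective sample size n_eff = (Σw)²/Σw²,
  CI = tanh(atanh(r) ± 1.96/√(n_eff − 3)), undefined for n_eff ≤ 3; r is
  clipped to [−1, 1] and undefined when either weighted variance is zero.
  The expression variable is log2(TPM + 1) of the nearest gene
  (variance-stabilized default; the scale is not stated in the source).
* **X F:M methylation track**: chrX is tiled into 100-kb non-overlapping
  bins; a bin is eligible when its coverage is strictly greater than 10 in
  at least five female and five male cells; the per-sex level is the
  unweighted mean of per-cell rates among those covered cells (coverage is
  already gated, so a plain mean is used); the track is the mean F:M ratio
  over a centered sliding window of 50 consecutive eligible bins, truncated
  at the ends. With fewer than 50 eligible bins the window is all bins,
  with a warning — the desk-scale synthetic chrX (30 bins) exercises this
  path.
* **XIST promoter/gene-body methylation**: the region coordinates are an
  input (the named regulatory feature cannot be derived); the statistic is
  the group weighted mean over female trophectoderm cells per treatment arm.

Multiple testing uses Benjamini–Hochberg with per-stage families (DMR
windows; small-RNA features; biotypes): the source reports FDRs without
family definitions, and per-stage families are explicit and conservative.

## Small RNA

Biotype composition is reported both as per-cell proportions (rows sum to
1 over miRNA/tRNA/snoRNA/snRNA/other — the "other" bucket closes the
composition) and as group-pooled molecule proportions; the two agree when
all cells have equal totals. Zero-total cells are excluded from tests.
The biotype-shift test and the per-feature differential expression are
rank-based stand-ins (two-sided Wilcoxon on per-cell proportions or CPM,
BH correction, log2 fold change of group mean CPM with pseudocount 1): the
original tests are unnamed, and a rank test is robust at low counts and
makes no distributional claims. The same generic two-group machinery
(`de_features`) provides the mRNA fold changes for the network stage — a
clearly labeled stand-in for the original model-based differential
expression, which is out of scope here.

A miRNA–mRNA edge is kept when the pair appears in the user-supplied
target table, both members are significant (FDR ≤ 0.05), both
|log2 fold change| ≥ 0.25 (boundary included), and the signs are opposite.
Target prediction itself is out of scope; the synthetic pipeline builds a
stand-in target table from candidate miRNAs × strongest differentially
expressed genes purely so the filter has input.

## The synthetic data generator

The generator emulates the *statistical structure* the analyses assume, at
desk scale, with every planted effect recorded in a truth table.

**Design.** 6 embryos × 40 cells by default; treatment and sex are
embryo-level and balanced across arms; lineages (EPI 12%, PE 8%, mural
50%, polar 30%) are drawn per cell, reflecting the TE-dominant composition
of a blastocyst.

**Expression.** Genes live on a scaled genome (chr1 4.5 Mb with 1,000
genes, chrX 3 Mb with 300, chrY 20, chrM 13). Per-gene baseline rates are
lognormal (log-mean 1, log-sd 1); chrY baselines carry a ×0.1 factor so
Y output is a sliver of the transcriptome, as in real cells —
male ΣRPKM(chrY) still sits far above the 100 calling threshold; chrM
rates are scaled so mitochondrial reads are 10% of the assigned library.
Per-cell counts are multinomial over (gene rates × modifiers) plus an
**unassigned read mass** fixed at 50% of the untreated baseline library:
intergenic and multi-mapping reads that count toward the mapped library
size but not toward any gene. Without that mass, a planted X dampening
would be partially cancelled in RPKM space by multinomial renormalization;
with it, E[treated/control female X output] = d/(1 − a_X(1 − d)) ≈ 0.72
for d = 0.7 (a_X = assigned X share of the library), inside the recovery
band the tests check. Modifiers: X-linked genes of treated female cells
× d (default 0.7); Y-linked genes of female cells × 0; XIST (a named chrX
lncRNA, dampening-exempt) × 5 in females and × 2 again under treatment —
a 10× factor would push the female X output ratio onto the recovery band
edge, because XIST itself is X-linked. Mild per-gene-per-cell lognormal
noise (sd 0.3) prevents per-cell chromosome sums from being unrealistically
tight; library sizes are lognormal (median 500k, log-sd 0.3); dropout is
independent zeroing at 10%. An 8% fraction of planted low-quality cells
(5% library, 70% dropout) gives the QC stage true positives.

**Methylome.** The genome is tiled into 3-kb regions, 8 CpGs per region
(20,000 CpGs total). Region means are Beta(2, 7) (mean 22.2%, the early
human embryo's hypomethylated state); lineage offsets (+0.3, +3.7, +5.4
percentage points for PE, mural, polar) reproduce the lineage gradient;
treated cells get −2 points globally and treated female cells +10 points on
chrX; planted DMRs add ±0.3 for a chosen group on host regions selected so
the shift cannot clip at 0 or 1. Per-CpG per-cell coverage is
Poisson(λ = 5) thinned at capture probability 0.2; methylated counts are
beta-binomial around the cell's region mean with concentration 100 — mild
within-region heterogeneity, chosen so the pooled-count Fisher DMR
stand-in is approximately calibrated. Real scBS-seq is far more dispersed
(a CpG in one cell is essentially 0/1 per allele), so on real data the
Fisher stand-in would be anticonservative; this idealization is a known,
deliberate limitation. Per-cell sequencing metadata (total reads,
mapped fraction) are drawn so a small tail fails the methylome QC.

**Small RNA.** Control biotype proportions are 9.83 / 36.3 / 1.79 / 1.18 %
(miRNA / tRNA / snoRNA / snRNA, remainder "other") — the measured control
composition of the system being emulated; the treated arm shifts tRNA by
−5.9 points with the remainder renormalized, which lands the treated
miRNA/snoRNA/snRNA levels close to their measured treated values as well.
Per-cell composition is Dirichlet (concentration 300); within-biotype
feature shares are fixed Dirichlet(1) draws; planted DE features (default
four miRNAs at log2fc ±1, ±1.5) are chosen among above-average-share
miRNAs so recovery is identifiable above molecule-sampling noise; per-cell
totals are lognormal with median 50,000 molecules and every total ≥ 1.

**What the generator does not emulate** — and hence what passing tests do
*not* show about real data: embryo-level random effects (cells are
exchangeable within sex × treatment × lineage), realistic gene length and
expression distributions, allele-level methylation binarization,
XIST-locus-specific promoter hypomethylation (the planted X effect is a
uniform chrX shift, so the XIST-region readout exercises the machinery,
not the locus biology), read-level artifacts (UMIs, bisulfite conversion
errors), and real miRNA target structure.

## Null experiments

A null calibration run must plant *no* treatment effect: the dampening
d = 1 **and** the XIST treatment multiplier = 1 (the XIST response is
itself a planted treatment effect on the X). With both off, treated and
control female cells are exchangeable and the rejection rate of the
X-output comparison is nominal, which the tests verify over 200 seeds.

## Problem sizes

The test suite and the acceptance script run the generator at the default
desk scale above (240 cells, 1,333 genes, 20,000 CpGs, 265 small-RNA
features) and scale the multi-seed recovery experiments to 100–200 seeds
of 200–40-cell designs; these sizes were chosen so the full suite runs in
about a minute on a laptop while leaving every recovery margin wide.

## Known limitations

* The DMR caller is an explicit stand-in, not a reproduction of the
  original (unavailable) parameters; its calibration depends on the mild
  within-region dispersion noted above.
* The weighted-correlation CI is a standard weighted analogue (Fisher z
  with Kish n_eff); the original variance estimator is unspecified.
* The differential-expression stand-ins are rank tests, not the original
  model-based tests; fold-change estimates carry the renormalization
  distortions described for the generator (small, and covered by the
  recovery tolerances).
* TPM's mitochondrial-exclusion rule means TPM is undefined for
  mito-only cells; downstream stages treat those columns as missing.
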