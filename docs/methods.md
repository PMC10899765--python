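# Methods

This note documents the statistical procedures implemented in nucleoscreen,
the design choices made where a procedure admitted more than one reasonable
definition, what the synthetic-data generators do and do not emulate, and
the package's known limitations.

## Screen statistics

**Plate adjustment.** Raw well phenotype percentages are adjusted per plate
by control-anchored min–max scaling on control *medians* (negative control →
0, phenotype-matched positive control → 100). Anchoring was chosen over
z-scoring because the secondary screen's inhibition scale is explicitly
anchored the same way (siNT = 0%, siPOLR1A = 100%), making the two screens'
scales congruent; a z-score alternative can be layered on the same
`WellRecord` tables if needed. Values outside [0, 100] are legitimate and
preserved (observed inhibitions in practice range from below 0% to above
100%). Both transforms are invariant to affine changes of the raw intensity
or percentage scale, which the test suite asserts over random affine
transforms.

**SSMD.** The effect-size statistic is the strictly standardized mean
difference estimated by its UMVUE, β̂ = c(k)·m/s with
c(k) = Γ((k−1)/2)/Γ((k−2)/2)·√(2/(k−1)), computed via log-gamma for
stability. For the triplicate screen c(3) = 1/√π exactly; no approximation
is used. s is the sample standard deviation with denominator k−1. s = 0
returns signed infinity with a warning; k < 3 is an error. Unbiasedness is
verified against a Monte-Carlo oracle (10⁵ normal triplicates).

**Hit calling.** A dual cutoff: mean percent effect at or above the
library-wide empirical (1−q) quantile (linear interpolation; ties at the
boundary included, matching a "top q%" reading) *and* SSMD ≥ 1.645. The
quantile is computed over library mimics only — controls are never hits and
never enter the quantile. Library-wide (rather than per-plate) quantiles
were chosen because the hit budget ("top 2.5%") is a property of the
campaign, not of a plate. Defaults: q = 0.025 for the one-nucleolus
phenotype and q = 0.01 for 5+ nucleoli.

**Validation rule.** A rescreened hit passes when its rescreen replicates
give SSMD ≥ 1.645 with positive mean percent effect. This is the package's
own operational definition (campaigns typically report pass counts without a
formula); it is deliberately the same strength criterion as the primary
SSMD cutoff, applied to fresh plates.

**QC.** Z′ = 1 − 3(σ_pos+σ_neg)/|μ_pos−μ_neg| and S/B = median(pos)/
median(neg), per plate and phenotype, on the raw phenotype (or 5-EU
intensity) scale. Z′ ≤ 1 always; equal control means give −∞, a failed
plate.

**Chromosome distribution.** Hit loci are tested against the genome-wide
miRNA-gene chromosome distribution by Pearson chi-squared with expected
counts scaled to the hit total; chromosomes with expected count < 1 are
pooled into an "other" bin before testing. Standardized residuals
(O−E)/√E rank per-chromosome enrichment.

**PCA.** The five hit-level variables (both percent effects, percent
viability, percent inhibition, nucleolar-target count) are standardized to
zero mean and unit variance; constant features are dropped with a warning.
Sign convention: each component's largest-magnitude loading is positive.

## Target bioinformatics

**zTPM.** Per experiment, z-scores of log2 TPM computed over genes with
TPM > 0 in that experiment; zeros map to −∞. No pseudocount is added: the
−3 cutoff presumes a z-scale over *detected* genes, and a pseudocount would
shift that scale. A gene is expressed when zTPM > −3 (strict) in at least
one experiment.

**Interaction filtering.** Keep validated human interactions where the
miRNA reduces the target ("down"), restricted to expressed genes;
deduplicate (miRNA, gene) keeping an evidence count. The operation is
row-order independent and idempotent.

**Group comparison.** The hit vs non-hit nucleolar-target comparison uses
an equal-variance Student's t-test by default (reading "unpaired two-sided
t-test" in its conventional sense), with Welch's variant behind a flag.

**Over-representation.** A local one-sided hypergeometric tail
P(X ≥ overlap) per gene set with Benjamini–Hochberg adjustment across sets
and gene ratio = overlap/|query| — a self-contained stand-in for web
enrichment services, so results are reproducible offline. The percentile
universe for "genes targeted by ≥ k hits" is the set of genes with at least
one hit interaction (configurable).

## Seed scanning

Exact Watson–Crick antisense matching only; no G:U wobble, no
thermodynamics, no conservation. T/U are interchangeable on input. Two
modes:

* **Long-transcript scan** — all maximal ungapped antisense matches whose
  miRNA-side span starts at nucleotide 1 or 2, length ≥ L (default L = 7,
  a CLI flag; it emulates a short-word search without a heuristic engine).
  Matches under the two start rules are reported separately. The scanner is
  verified identical to exhaustive substring enumeration on random 10 kb
  transcripts.
* **UTR sites** — canonical 6mer (miRNA nt 2–7), 7mer-A1 (+A opposite
  nt 1), 7mer-m8 (nt 2–8), 8mer; each seed occurrence reported once with
  the strongest requested type; tandem pairs are two sites whose starts lie
  within a window (default 50 nt). Site definitions follow the standard
  nt-2-anchored convention.

Coordinates are 0-based half-open internally; the CLI adds 1-based
inclusive columns for reading.

**Scrambling** permutes a site span's nucleotides (composition preserved)
and redraws until no 6mer seed core for any miRNA in the given set remains
in the span ± one seed length — since every canonical site type contains
the 6mer core, this guarantees zero sites of any type. Bounded retries;
compositions that cannot avoid a match raise.

## Processing signatures

RAMP ratios are computed per replicate as (I_i/I_j)_treatment /
(I_i/I_j)_control and averaged as the mean of per-replicate log2 ratios.
Averaging log ratios per replicate (rather than logging the mean ratio)
keeps the statistic exactly invariant to per-lane loading and
symmetrizes noise on the log scale; the alternative is available by
pre-aggregating. The default pair set is all ordered pairs of the probe
set's precursors (47S/45S, 30S, 21S, 21S-C, 18S-E for ITS1; 32S, 12S for
ITS2) — a curated pair list can be supplied. Antisymmetry
(entry(i,j) = −entry(j,i)) and the all-zero control row are asserted
invariants.

Ward clustering runs on Euclidean distance over signature rows via the
standard Lance–Williams update (scipy linkage), cut at k = 4 by default.
LDA is the classical canonical discriminant: eigenvectors of the
between/within scatter pencil, directions normalized to unit within-class
score variance (making scores affine-invariant up to sign when
unregularized); singleton clusters are projected but excluded from scatter
estimation; a singular within-class scatter is ridge-regularized with a
warning.

## Assay quantification

ΔΔC_T averages technical replicates on the Ct scale first (standard
comparative-CT practice for technical duplicates), computes
ΔCt = Ct_target − Ct_reference per sample (reference 7SL), subtracts the
calibrator's ΔCt (siNT), and reports 2^−ΔΔCt. Dual-luciferase
normalization uses the primary/normalizer ratio per well divided by the
*mean* control ratio (median switchable); the promoter orientation is
Fluc/Rluc, the UTR orientation Rluc/Fluc normalized within construct, so
each construct's siNT mean is 1 and WT vs SCR are compared by Welch's
t-test. Densitometry divides signal by loading and anchors at the control
mean. Outlier wells are flagged, never auto-removed.

The one-way ANOVA comparison machinery uses the pooled mean-squared error
for per-group t statistics against the comparator (N−k df) and Holm–Šídák
step-down adjustment: sort raw p ascending, adjusted
p_i = max_{j≤i} 1−(1−p_j)^(m−j+1), clipped at 1. For m = 1 this equals
single-step Šídák; adjusted values are ≥ raw and rank-monotone.

## Transcriptome comparison

Sibling profiles are compared by OLS of one treatment's per-gene log2 fold
changes on the other's (R² = squared Pearson correlation, two-sided slope
test); non-finite genes are dropped listwise with counts logged.
Differential-expression estimation itself is an input, not recomputed.
Target vs non-target distributions are compared by right-continuous ECDFs
and the two-sample Kolmogorov–Smirnov test (asymptotic p) — KS is this
package's declared choice for the ECDF comparison.

## Synthetic data: what it emulates, and what it does not

All generators draw from explicit `numpy.random.Generator` streams derived
from one seed (per-stream CRC-keyed spawn); identical configs give
byte-identical outputs, and ground truth is always emitted.

* **Nucleolus counts.** Per-cell counts are categorical on 1..10 (the 5+
  bin exists; support is capped at 10, within a segmenter's practical
  range). The negative-control distribution puts ~87% of mass on 2–4
  nucleoli. An effect of magnitude m mixes the baseline toward a
  one-nucleolus or five-plus limiting distribution (m = 1 gives ≥ 90% of
  cells in the target bin). Plate bias and well noise act additively on the
  *logits* of the two phenotype masses, keeping probabilities valid; cell
  number is Poisson around the configured mean (default 1000 imaged cells,
  configurable — plate layouts put controls in fixed columns, also
  configurable, since real campaigns vary in both). Toxic mimics get a
  Uniform(0.5, 1) viability factor, emulating "percent viability" as
  relative cell count.
* **5-EU plates.** Well values are Normal around a linear interpolation
  between the control anchors by true inhibition fraction.
* **Interaction database.** Hit miRNAs draw Poisson nucleolar-target counts
  inflated by a configurable enrichment factor (default 2); decoy rows of
  wrong species/direction/validation exercise the filters; a configurable
  gene fraction is TPM-0 everywhere.
* **Precursor tables.** Replicate lanes are archetype mean × lognormal
  noise × a per-lane loading factor; the four default archetypes (no
  change; 30S down; 30S up/21S down, mild and severe) mirror the defect
  classes such screens observe.
* **Sequences.** Backgrounds are rejection-sampled free of incidental seed
  matches for the configured miRNAs (defaults: the two MIR-28 siblings,
  which share the AGGAGCU seed), so planted sites are exactly the sites
  present, with flanking bases adjusted so a planted site has exactly its
  requested type.
* **Assay tables.** Sibling log2-fold-change pairs share a latent per-gene
  effect; with noise only on the second sibling the OLS slope is the
  configured slope and the noise variance follows in closed form from the
  configured R² (defaults slope 1, R² 0.61). Calibrator/control samples
  are generated at null effect.

The generators emulate the *statistical structure* of screen data, not its
physics: no real microscope PSFs or illumination fields, no real database
content or genome annotation, no amplification-efficiency or probe-affinity
effects, lognormal noise throughout. Passing tests therefore demonstrate
the correctness and calibration of the statistics under their stated
models — not robustness to every artifact of real instruments.

## Problem sizes and numerical choices

The recovery studies run at the campaign's scale where that is what is
being claimed: the screen-recovery study simulates 2603 mimics in
triplicate with 100 planted hits at magnitude 0.8. The 100 hits are split
74 one-nucleolus / 26 five-plus: the top-2.5% and top-1.0% quantile rules
cap the callable sets at ~65 and ~26 mimics respectively, so this split
matches the calling capacities and makes ≥ 90% sensitivity attainable in
principle (a split concentrating > 65 planted hits in the one-nucleolus
phenotype could never reach it, by construction of the quantile rule).
Monte-Carlo calibrations use 10⁵ draws (SSMD) and a few thousand
simulations (type-I rates). The seed-scanner oracle uses 100 random 10 kb
transcripts. Imaging round trips use 256×256 fields with ≥ 2 px object
spacing, where noise-free segmentation recovers planted counts exactly.

Degenerate inputs are handled explicitly rather than silently: equal
control medians fail the plate; zero replicate s.d. gives signed-infinity
SSMD with a warning; zero denominators in RAMP skip the pair for that
replicate; zero-variance correlation inputs return NaN with a warning;
empty queries/libraries raise.

## Limitations

* No spatial plate-effect correction (B-score/median polish) — only
  control anchoring; strong within-plate gradients would leak into percent
  effects.
* Imaging segmentation is a deliberate classical contract (Otsu +
  watershed), not a learned model, and carries no illumination correction
  or z-stack handling.
* The over-representation test treats gene sets as fixed and independent;
  BH is across sets only.
* Differential expression, duplex thermodynamics, conservation scoring and
  chimeric-read analysis are out of scope; their outputs are consumed as
  inputs where relevant.
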