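# nucleoscreen

Analysis pipeline for high-content screens of **ribosome biogenesis (RB)**
read out through nucleolar phenotypes. The package covers the full analysis
path of a 384-well microRNA-mimic screening campaign: per-cell nucleolus
counting from fluorescence images (DNA / fibrillarin / 5-ethynyl-uridine
channels), plate-adjusted percent effects and SSMD-based dual-cutoff hit
calling, anchored nucleolar rRNA biogenesis inhibition scoring, miRNA
target-enrichment bioinformatics on validated interaction tables, canonical
seed-site scanning of transcripts and 3′ UTRs, RAMP pre-rRNA processing
signatures with Ward clustering and LDA, and the downstream assay
normalizations (ΔΔC_T qPCR, dual-luciferase in both orientations,
densitometry, electropherogram ratios, sibling-transcriptome regression).

It is aimed at screening and RNA-biology groups who want these statistics as
tested, composable library functions rather than spreadsheet recipes. A
seeded synthetic-data module generates every input with known ground truth,
so each stage is testable without any external database or deposited reads.

## The statistics at the core

**Percent effect.** A well's raw phenotype percentage x (e.g. % of nuclei
with exactly one nucleolus) is rescaled per plate against control medians:

    PE = 100 · (x − median(neg)) / (median(pos) − median(neg))

so the negative control (siNT) sits at 0 and the phenotype-matched positive
control (siNOL11 for one-nucleolus, siKIF11 for 5+ nucleoli) at 100.

**UMVUE SSMD.** For k replicate percent effects with mean m and standard
deviation s, the strictly standardized mean difference is estimated by the
uniformly-minimum-variance unbiased estimator

    β̂ = c(k) · m / s,   c(k) = Γ((k−1)/2) / Γ((k−2)/2) · √(2/(k−1))

with c(3) = 1/√π ≈ 0.5642. A mimic is a **hit** when its mean PE reaches the
library's top-2.5% (one-nucleolus) or top-1.0% (5+) empirical quantile *and*
β̂ ≥ 1.645 ("at least fairly strong").

**Anchored inhibition.** In the 5-EU secondary screen, per-well median
nucleolar 5-EU intensity is mapped to percent inhibition with siNT at 0% and
siPOLR1A at 100%; mimics with replicate-mean inhibition ≥ 50% are secondary
hits.

**RAMP signatures.** A pre-rRNA processing defect is summarized by pairwise
precursor ratios r_ij = I_i/I_j per lane, normalized to the control lane of
the same replicate and averaged on the log2 scale; signatures are clustered
with Ward linkage and visualized by canonical LDA.

## Worked example

Simulate a one-plate-layout screen with two planted hits, run the primary
screen, and report:

```python
from nucleoscreen.synthetic import SimConfig, gen_nucleolus_counts
from nucleoscreen import screen as sc
from nucleoscreen.report import ScreenCounts

cfg = SimConfig(
    seed=1, n_mimics=336,
    effect_sizes={
        "mimic-0007": ("one-nucleolus", 0.8),
        "mimic-0021": ("five-plus", 0.7),
    },
)
wells, truth = gen_nucleolus_counts(cfg)
result = sc.primary_screen(wells, cfg.mimic_ids)
print(result.loc[["mimic-0007", "mimic-0021"]].round(2))
print(f"hits called: {int(result['hit'].sum())} / {len(result)}")
pct = ScreenCounts().percentages()
print(f"campaign hit rate: {pct['hit_rate_pct']}%  "
      f"validation: {pct['validation_rate_pct']}%")
```

prints

```
            mean_pe_one  ssmd_one  hit_one  ...  ssmd_five  hit_five   hit
mimic                                       ...
mimic-0007        86.37     22.44     True  ...     -14.48     False  True
mimic-0021        -5.90     -3.97    False  ...      12.65      True  True

hits called: 6 / 336
campaign hit rate: 2.8%  validation: 97.3%
```

`mimic-0007`, planted at magnitude 0.8, shows a mean one-nucleolus percent
effect of 86 (i.e. 86% of the way from the siNT to the siNOL11 control
median) with SSMD ≈ 22, far beyond the 1.645 cutoff, and is called on the
one-nucleolus side only; `mimic-0021` is called on the 5+ side. At a 2.5%
quantile cutoff a 336-mimic library can flag at most ~8 mimics, so 6 calls
with 2 planted hits reflects the quantile rule operating on a mostly-null
library. The `ScreenCounts` reporting layer turns the campaign's funnel
counts (here its defaults: 64 + 9 hits of 2603 mimics, 71 of 73 validated)
into the percentages a screen report quotes.

A thin CLI mirrors the library:
`nucleoscreen simulate | segment | screen | secondary | targets | seedscan |
ramp | assays | compare` (see `nucleoscreen --help`).

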