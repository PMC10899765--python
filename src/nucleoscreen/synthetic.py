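"""Seeded synthetic-data generators for every pipeline input.

These generators emulate the statistical structure of a 384-well microRNA
mimic screen for altered nucleolar number and its downstream assays: per-cell
nucleolus-count tables with plate effects, anchored 5-EU intensity plates,
a validated miRNA:mRNA interaction database with planted nucleolar-target
enrichment, pre-rRNA precursor quantification tables drawn from archetypal
processing-defect signatures, planted seed sites in UTR sequences, and tidy
assay tables (qPCR Ct, dual-luciferase, densitometry, electropherogram,
sibling log2-fold-change profiles).

Every generator takes a :class:`SimConfig` and derives all randomness from
``config.seed`` through explicit ``numpy.random.Generator`` objects — no
global state — so an identical config yields byte-identical outputs. Ground
truth is always emitted alongside the data and is sufficient to score every
downstream stage.
"""

from __future__ import annotations

import string
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import seeds as seedmod

CONTROL_NAMES = ("siNT", "siNOL11", "siKIF11", "siPOLR1A")

#: baseline per-cell nucleolus-count distribution (counts 1..10) for
#: negative-control cells; >=80% of mass on {2,3,4}, matching the typical
#: two-to-four nucleoli of untreated epithelial nuclei.
BASELINE_COUNT_PROBS = np.array(
    [0.07, 0.37, 0.31, 0.19, 0.03, 0.015, 0.008, 0.004, 0.002, 0.001]
)
#: limiting distribution for a full-strength one-nucleolus effect
ONE_NUCLEOLUS_TARGET = np.array(
    [0.95, 0.035, 0.01, 0.005, 0, 0, 0, 0, 0, 0.0]
)
#: limiting distribution for a full-strength 5+ nucleoli effect
FIVEPLUS_TARGET = np.array(
    [0.0, 0.01, 0.02, 0.02, 0.40, 0.30, 0.15, 0.06, 0.03, 0.01]
)

#: default pre-rRNA processing archetypes: per-precursor level relative to
#: the negative control. ITS1-probe species 47S/45S, 30S, 21S, 21S-C, 18S-E;
#: ITS2-probe species 32S, 12S.
PRECURSORS = ("47S/45S", "30S", "21S", "21S-C", "18S-E", "32S", "12S")
ARCHETYPES: dict[str, dict[str, float]] = {
    "n.c.": {p: 1.0 for p in PRECURSORS},
    "30S down": {**{p: 1.0 for p in PRECURSORS}, "30S": 0.45},
    "30S up, 21S down": {
        **{p: 1.0 for p in PRECURSORS},
        "30S": 1.8, "21S": 0.6, "21S-C": 0.65, "18S-E": 0.7,
    },
    "30S up, 21S down severe": {
        **{p: 1.0 for p in PRECURSORS},
        "30S": 3.2, "21S": 0.22, "21S-C": 0.28, "18S-E": 0.3,
    },
}

#: the MIR-28 sibling mature sequences (shared AGGAGCU seed at nt 2-8)
DEFAULT_MIRNAS = {
    "hsa-miR-28-5p": "AAGGAGCUCACAGUCUAUUGAG",
    "hsa-miR-708-5p": "AAGGAGCUUACAAUCUAGCUGGG",
}


def well_name(row: int, col: int) -> str:
    return f"{string.ascii_uppercase[row]}{col + 1:02d}"


def _default_control_wells(rows: int, cols: int) -> dict[str, tuple[str, ...]]:
    half = rows // 2
    return {
        "siNT": tuple(well_name(r, 0) for r in range(rows)),
        "siNOL11": tuple(well_name(r, 1) for r in range(half)),
        "siKIF11": tuple(well_name(r, 1) for r in range(half, rows)),
        "siPOLR1A": tuple(well_name(r, cols - 1) for r in range(rows)),
    }


@dataclass
class SimConfig:
    """Design of the simulated screen; ``seed`` fully determines all outputs.

    ``effect_sizes`` maps mimic -> (phenotype, magnitude in [0, 1]) where
    phenotype is ``"one-nucleolus"`` or ``"five-plus"``. ``inhibition`` maps
    mimic -> true nucleolar rRNA biogenesis inhibition fraction; mimics
    absent from it default to their effect magnitude (hits) or 0 (non-hits).
    """

    seed: int = 0
    plate_rows: int = 16
    plate_cols: int = 24
    n_replicate_plates: int = 3
    n_mimics: int = 336
    cells_per_well_mean: float = 1000.0
    control_wells: Mapping[str, tuple[str, ...]] | None = None
    effect_sizes: Mapping[str, tuple[str, float]] = field(default_factory=dict)
    inhibition: Mapping[str, float] = field(default_factory=dict)
    toxic_mimics: frozenset = frozenset()
    plate_bias_sd: float = 0.15
    noise_sd: float = 0.1
    # secondary (5-EU) screen
    eu_neg_mean: float = 1000.0
    eu_pos_mean: float = 200.0
    eu_sd: float = 60.0
    n_eu_replicates: int = 5
    # interaction database
    n_db_mirnas: int = 200
    n_db_genes: int = 2000
    frac_nucleolar: float = 0.15
    frac_rp: float = 0.02
    frac_unexpressed: float = 0.1
    mean_targets: float = 40.0
    mean_nucleolar_targets: float = 8.0
    enrichment_factor: float = 2.0
    # precursor quantification
    archetype_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in ARCHETYPES.items()}
    )
    precursor_noise_sd: float = 0.08
    n_blot_replicates: int = 3
    # sibling transcriptome tables
    sibling_n_genes: int = 10_000
    sibling_shared_sd: float = 1.0
    sibling_r2: float = 0.61
    sibling_slope: float = 1.0
    sibling_noise_a: float = 0.0
    sibling_target_fraction: float = 0.05
    sibling_target_shift: float = -0.5

    def __post_init__(self):
        if self.control_wells is None:
            self.control_wells = _default_control_wells(
                self.plate_rows, self.plate_cols
            )
        unknown = set(self.control_wells) - set(CONTROL_NAMES)
        if unknown:
            raise ValueError(f"unknown control names {sorted(unknown)}")
        all_pos = [w for ws in self.control_wells.values() for w in ws]
        if len(all_pos) != len(set(all_pos)):
            raise ValueError("control well positions overlap")
        for mimic, (phen, mag) in self.effect_sizes.items():
            if phen not in ("one-nucleolus", "five-plus"):
                raise ValueError(f"{mimic}: unknown phenotype {phen!r}")
            if not 0.0 <= mag <= 1.0:
                raise ValueError(f"{mimic}: magnitude {mag} outside [0, 1]")
        if self.plate_bias_sd < 0 or self.noise_sd < 0:
            raise ValueError("noise s.d. must be nonnegative")
        if self.eu_sd <= 0:
            raise ValueError("eu_sd must be positive")
        if self.cells_per_well_mean <= 0:
            raise ValueError("cells_per_well_mean must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator for a named stream, derived from ``seed``."""
        key = zlib.crc32(stream.encode()) % 2**31
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)

    @property
    def mimic_ids(self) -> list[str]:
        return [f"mimic-{i:04d}" for i in range(1, self.n_mimics + 1)]

    def library_wells(self) -> list[str]:
        ctrl = {w for ws in self.control_wells.values() for w in ws}
        return [
            well_name(r, c)
            for c in range(self.plate_cols)
            for r in range(self.plate_rows)
            if well_name(r, c) not in ctrl
        ]


def screen_truth(config: SimConfig) -> pd.DataFrame:
    """Ground-truth table: one row per library mimic."""
    rows = []
    for m in config.mimic_ids:
        phen, mag = config.effect_sizes.get(m, ("none", 0.0))
        inh = config.inhibition.get(m, mag if phen != "none" else 0.0)
        rows.append((m, phen, mag, inh))
    return pd.DataFrame(
        rows, columns=["mimic", "phenotype", "magnitude", "inhibition"]
    )


def _effect_probs(phenotype: str, magnitude: float) -> np.ndarray:
    target = (
        ONE_NUCLEOLUS_TARGET if phenotype == "one-nucleolus" else FIVEPLUS_TARGET
    )
    return (1.0 - magnitude) * BASELINE_COUNT_PROBS + magnitude * target


def _plate_layouts(config: SimConfig) -> list[list[tuple[str, str]]]:
    """Assign treatments to wells: list of layouts, each [(well, treatment)]."""
    lib = config.library_wells()
    layouts = []
    mimics = config.mimic_ids
    for start in range(0, len(mimics), len(lib)):
        chunk = mimics[start : start + len(lib)]
        layout = [
            (w, ctrl)
            for ctrl, wells in config.control_wells.items()
            for w in wells
        ]
        layout += list(zip(lib, chunk))
        layouts.append(layout)
    return layouts


# positive-control effects used for all simulated plates
_CONTROL_EFFECTS = {
    "siNT": ("none", 0.0),
    "siNOL11": ("one-nucleolus", 0.9),
    "siKIF11": ("five-plus", 0.9),
    "siPOLR1A": ("none", 0.0),  # POLR1A acts on 5-EU, not nucleolar number
}


def gen_nucleolus_counts(
    config: SimConfig, per_cell: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the primary screen's per-cell nucleolus counts.

    Returns ``(table, truth)``. With ``per_cell=False`` (default) the table is
    well-level with columns ``plate, well, treatment, n_cells, count_1 ..
    count_10, pct_one, pct_fiveplus, percent_viability``; with
    ``per_cell=True`` it is the long per-cell table ``plate, well, treatment,
    cell_id, nucleolus_count``. Both views come from the same draws.

    Per-cell counts are categorical on 1..10. Effects mix the baseline
    distribution toward a one-nucleolus or five-plus limiting distribution
    proportionally to magnitude. A per-plate bias and per-well noise act
    additively on the logits of the two phenotype masses (keeping
    probabilities valid), and per-well cell number is Poisson with a
    Uniform(0.5, 1) viability factor for toxic mimics.
    """
    rng = config.rng("counts")
    truth = screen_truth(config)
    layouts = _plate_layouts(config)
    recs = []
    for li, layout in enumerate(layouts):
        for rep in range(config.n_replicate_plates):
            plate = f"P{li + 1}R{rep + 1}"
            bias = rng.normal(0.0, config.plate_bias_sd)
            for well, trt in layout:
                phen, mag = _CONTROL_EFFECTS.get(
                    trt, config.effect_sizes.get(trt, ("none", 0.0))
                )
                p = _effect_probs(phen, mag)
                p1, p5 = p[0], p[4:].sum()
                e1, e5 = rng.normal(0.0, config.noise_sd, size=2)
                q1 = expit(logit(np.clip(p1, 1e-9, 1 - 1e-9)) + bias + e1)
                q5 = expit(logit(np.clip(p5, 1e-9, 1 - 1e-9)) + bias + e5)
                # rescale so the two phenotype masses and the middle remain
                # a valid distribution
                tot = q1 + q5
                if tot > 0.98:
                    q1, q5 = 0.98 * q1 / tot, 0.98 * q5 / tot
                mid_w = p[1:4] / p[1:4].sum() if p[1:4].sum() > 0 else (
                    np.array([1.0, 0.0, 0.0])
                )
                tail_w = p[4:] / p[4:].sum() if p[4:].sum() > 0 else (
                    np.array([1.0, 0, 0, 0, 0, 0.0])
                )
                probs = np.concatenate(
                    [[q1], mid_w * (1.0 - q1 - q5), tail_w * q5]
                )
                viability = (
                    rng.uniform(0.5, 1.0) if trt in config.toxic_mimics else 1.0
                )
                n = rng.poisson(config.cells_per_well_mean * viability)
                counts = rng.multinomial(n, probs)
                recs.append((plate, well, trt, n, viability, counts))
    cols = {
        "plate": [r[0] for r in recs],
        "well": [r[1] for r in recs],
        "treatment": [r[2] for r in recs],
        "n_cells": [r[3] for r in recs],
    }
    counts_mat = np.array([r[5] for r in recs])
    table = pd.DataFrame(cols)
    for j in range(10):
        table[f"count_{j + 1}"] = counts_mat[:, j]
    with np.errstate(invalid="ignore"):
        n = counts_mat.sum(axis=1).astype(float)
        table["pct_one"] = 100.0 * counts_mat[:, 0] / n
        table["pct_fiveplus"] = 100.0 * counts_mat[:, 4:].sum(axis=1) / n
    table["percent_viability"] = 100.0 * np.array([r[4] for r in recs])
    if per_cell:
        table = expand_per_cell(table)
    return table, truth


def expand_per_cell(well_table: pd.DataFrame) -> pd.DataFrame:
    """Expand a well-level count table to one row per cell."""
    count_cols = [f"count_{j}" for j in range(1, 11)]
    frames = []
    for _, row in well_table.iterrows():
        counts = row[count_cols].to_numpy(dtype=int)
        vals = np.repeat(np.arange(1, 11), counts)
        frames.append(
            pd.DataFrame(
                {
                    "plate": row["plate"],
                    "well": row["well"],
                    "treatment": row["treatment"],
                    "cell_id": np.arange(len(vals)),
                    "nucleolus_count": vals,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def gen_5eu_plate(
    config: SimConfig, truth: pd.DataFrame
) -> pd.DataFrame:
    """Simulate the anchored 5-EU secondary screen.

    Each mimic in ``truth`` plus the siNT / siPOLR1A anchor controls is
    measured on ``n_eu_replicates`` replicate plates. Well values are Normal
    with mean interpolating linearly between the negative-control mean
    (inhibition 0) and the positive-control mean (inhibition 1).
    """
    rng = config.rng("eu")
    mu_n, mu_p, sd = config.eu_neg_mean, config.eu_pos_mean, config.eu_sd
    treatments = ["siNT"] * 8 + ["siPOLR1A"] * 8 + list(truth["mimic"])
    inh = dict(zip(truth["mimic"], truth["inhibition"]))
    recs = []
    for rep in range(config.n_eu_replicates):
        plate = f"EU{rep + 1}"
        for i, trt in enumerate(treatments):
            if trt == "siNT":
                f = 0.0
            elif trt == "siPOLR1A":
                f = 1.0
            else:
                f = inh[trt]
            mean = mu_n - f * (mu_n - mu_p)
            recs.append(
                (plate, f"W{i + 1:03d}", trt, rng.normal(mean, sd))
            )
    return pd.DataFrame(
        recs, columns=["plate", "well", "treatment", "median_nucleolar_EU"]
    )


def gen_interaction_db(
    config: SimConfig, hits: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, list[str], dict[str, list[str]]]:
    """Simulate a validated miRNA:mRNA interaction database with planted
    nucleolar-target enrichment.

    Returns ``(interactions, tpm, nucleolar_genes, rp_groups)``.
    ``interactions`` has columns mirna, gene, species, direction, validated
    and includes decoy rows (wrong species / direction) that downstream
    filtering must remove. Hit miRNAs draw Poisson(enrichment_factor x
    mean_nucleolar_targets) nucleolar targets versus Poisson(
    mean_nucleolar_targets) for non-hits. A ``frac_unexpressed`` fraction of
    genes has TPM 0 in all four pseudo-experiments.
    """
    rng = config.rng("interactions")
    mirnas = [f"hsa-miR-sim-{i}" for i in range(1, config.n_db_mirnas + 1)]
    if hits is None:
        hits = mirnas[: max(1, config.n_db_mirnas // 10)]
    hitset = set(hits)
    genes = np.array([f"GENE{i:05d}" for i in range(1, config.n_db_genes + 1)])
    n_nuc = int(round(config.frac_nucleolar * len(genes)))
    nucleolar = list(genes[:n_nuc])
    n_rp = max(2, int(round(config.frac_rp * len(genes))))
    rp_s = list(genes[n_nuc : n_nuc + n_rp // 2])
    rp_l = list(genes[n_nuc + n_rp // 2 : n_nuc + n_rp])
    unexpr = set(
        rng.choice(genes, int(config.frac_unexpressed * len(genes)), replace=False)
    )
    other = np.array([g for g in genes if g not in set(nucleolar)])
    rows = []
    for m in mirnas:
        lam = config.mean_nucleolar_targets * (
            config.enrichment_factor if m in hitset else 1.0
        )
        k_nuc = min(rng.poisson(lam), len(nucleolar))
        k_oth = min(rng.poisson(config.mean_targets), len(other))
        for g in rng.choice(nucleolar, k_nuc, replace=False):
            rows.append((m, g, "Homo sapiens", "down", True))
        for g in rng.choice(other, k_oth, replace=False):
            rows.append((m, g, "Homo sapiens", "down", True))
        # decoys exercising the filters
        for g in rng.choice(genes, 3, replace=False):
            rows.append((m, g, "Mus musculus", "down", True))
        rows.append((m, rng.choice(genes), "Homo sapiens", "up", True))
        rows.append((m, rng.choice(genes), "Homo sapiens", "down", False))
    interactions = pd.DataFrame(
        rows, columns=["mirna", "gene", "species", "direction", "validated"]
    )
    tpm = pd.DataFrame(
        rng.lognormal(mean=3.0, sigma=1.5, size=(len(genes), 4)),
        index=genes,
        columns=[f"exp{k + 1}" for k in range(4)],
    )
    tpm.loc[list(unexpr)] = 0.0
    tpm.index.name = "gene"
    return interactions, tpm, nucleolar, {"S": rp_s, "L": rp_l}


def gen_precursor_quants(
    config: SimConfig,
    treatments: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate northern-blot precursor quantifications.

    ``treatments`` maps treatment name -> archetype name; by default three
    treatments per archetype are generated. The control ``siNT`` is always
    included with all-ones means. Replicate lane intensities are archetype
    mean x lognormal noise x a per-lane loading factor (RAMP ratios are
    loading-invariant, so the factor is harmless downstream but realistic).

    Returns ``(quants, truth)`` with ``quants`` long-format
    (treatment, replicate, precursor, intensity).
    """
    rng = config.rng("precursors")
    arch = {k: dict(v) for k, v in config.archetype_means.items()}
    for name, means in arch.items():
        if any(v < 0 for v in means.values()):
            raise ValueError(f"archetype {name!r} has negative intensities")
    if treatments is None:
        treatments = {
            f"{a.replace(' ', '_')}-t{j}": a
            for a in arch
            for j in range(1, 4)
        }
    rows = []
    for rep in range(1, config.n_blot_replicates + 1):
        for trt, a in [("siNT", "n.c."), *treatments.items()]:
            loading = rng.lognormal(0.0, 0.1)
            for prec in PRECURSORS:
                base = 100.0 * arch[a].get(prec, 1.0)
                noise = rng.lognormal(0.0, config.precursor_noise_sd)
                rows.append((trt, rep, prec, base * loading * noise))
    quants = pd.DataFrame(
        rows, columns=["treatment", "replicate", "precursor", "intensity"]
    )
    truth = pd.DataFrame(
        [("siNT", "n.c."), *treatments.items()],
        columns=["treatment", "archetype"],
    )
    return quants, truth


@dataclass(frozen=True)
class SitePlan:
    """A planted seed site: plant ``n_sites`` sites of ``site_type`` for
    ``mirna`` on ``transcript`` starting at ``position`` with ``spacing``
    nucleotides between consecutive site starts."""

    mirna: str
    transcript: str
    position: int
    site_type: str = "6mer"
    n_sites: int = 1
    spacing: int = 20


def _site_target_seq(mirna: seedmod.MatureMiRNA, site_type: str) -> str:
    if site_type == "6mer":
        return mirna.seed6
    if site_type == "7mer-m8":
        return mirna.seed7m8
    if site_type == "7mer-A1":
        return mirna.seed6 + "A"
    if site_type == "8mer":
        return mirna.seed7m8 + "A"
    raise ValueError(f"unknown site type {site_type!r}")


def _random_clean_seq(
    rng: np.random.Generator, length: int, mirnas: Sequence[seedmod.MatureMiRNA]
) -> str:
    """Random RNA with no seed match for any of ``mirnas`` (rejection redraw)."""
    bases = np.array(list("ACGU"))
    seq = "".join(rng.choice(bases, length))
    for _ in range(200):
        dirty = False
        for m in mirnas:
            i = seq.find(m.seed6)
            while i != -1:
                repl = "".join(rng.choice(bases, 6))
                seq = seq[:i] + repl + seq[i + 6 :]
                dirty = True
                i = seq.find(m.seed6)
        if not dirty:
            return seq
    raise RuntimeError("failed to generate seed-free background")


def gen_sequences(
    config: SimConfig,
    site_plans: Sequence[SitePlan] = (),
    mirna_seqs: Mapping[str, str] | None = None,
    transcript_lengths: Mapping[str, int] | None = None,
) -> dict:
    """Generate FASTA-ready sequences with planted seed sites.

    Returns a dict with keys ``mirnas`` (id -> MatureMiRNA), ``transcripts``
    (id -> sequence with planted sites), ``scrambled`` (id -> scrambled
    variant with zero remaining sites) and ``plans``. Backgrounds are free of
    incidental seed matches for the configured miRNAs, so planted sites are
    exactly the sites present.
    """
    rng = config.rng("sequences")
    mirna_seqs = dict(mirna_seqs or DEFAULT_MIRNAS)
    mirnas = {k: seedmod.MatureMiRNA(k, v) for k, v in mirna_seqs.items()}
    lengths = dict(transcript_lengths or {})
    for p in site_plans:
        lengths.setdefault(p.transcript, 300)
    transcripts = {
        t: _random_clean_seq(rng, L, list(mirnas.values()))
        for t, L in lengths.items()
    }
    spans: dict[str, list[tuple[int, int]]] = {t: [] for t in transcripts}
    for p in site_plans:
        m = mirnas[p.mirna]
        target = _site_target_seq(m, p.site_type)
        seq = transcripts[p.transcript]
        for k in range(p.n_sites):
            a = p.position + k * p.spacing
            b = a + len(target)
            if b > len(seq):
                raise ValueError(
                    f"site for {p.mirna} at {a} overlaps end of "
                    f"{p.transcript} (length {len(seq)})"
                )
            seq = seq[:a] + target + seq[b:]
            # keep the planted site exactly the requested type: no
            # accidental m8 match 5' of it, no accidental A1 3' of it
            if p.site_type in ("6mer", "7mer-A1") and a > 0:
                m8 = m.seed7m8[0]
                if seq[a - 1] == m8:
                    repl = rng.choice([c for c in "ACGU" if c != m8])
                    seq = seq[: a - 1] + str(repl) + seq[a:]
            if p.site_type in ("6mer", "7mer-m8") and b < len(seq):
                if seq[b] == "A":
                    repl = rng.choice(["C", "G", "U"])
                    seq = seq[:b] + str(repl) + seq[b + 1 :]
            spans[p.transcript].append((a, b))
        transcripts[p.transcript] = seq
    scrambled = {}
    for t, sp in spans.items():
        if not sp:
            continue
        seq = transcripts[t]
        for a, b in sp:
            seq = seedmod.scramble_site(seq, (a, b), mirnas.values(), rng)
        scrambled[t] = seq
    return {
        "mirnas": mirnas,
        "transcripts": transcripts,
        "scrambled": scrambled,
        "plans": list(site_plans),
    }


def gen_assay_tables(
    config: SimConfig,
    ct_effects: Mapping[tuple[str, str], float] | None = None,
    reporter_effects: Mapping[str, float] | None = None,
    densitometry_effects: Mapping[str, float] | None = None,
    n_bio_replicates: int = 3,
    ct_sd: float = 0.1,
    reporter_cv: float = 0.08,
    densitometry_cv: float = 0.1,
) -> dict[str, pd.DataFrame]:
    """Simulate the downstream assay inputs.

    * ``ct``: qPCR Ct table (sample, target, technical replicate, Ct) with
      reference gene 7SL and calibrator siNT; ``ct_effects`` maps
      (sample, target) -> true log2 fold change vs siNT.
    * ``promoter`` / ``utr``: dual-luciferase plates in both orientations;
      ``reporter_effects`` maps sample -> true relative activity (the UTR
      plate applies the effect to the WT construct only; SCR stays at null).
    * ``densitometry``: paired signal/loading lanes;
      ``densitometry_effects`` maps sample -> true relative level.
    * ``electropherogram``: per-sample 18S/28S/total peak areas.
    * ``sibling_lfc``: per-gene log2 fold changes for two sibling miRNA
      treatments sharing a latent effect, tuned to ``sibling_slope`` /
      ``sibling_r2``; a ``sibling_target_fraction`` of genes is flagged as
      targets and shifted by ``sibling_target_shift`` in both columns.
    """
    rng = config.rng("assays")
    ct_effects = dict(ct_effects or {})
    reporter_effects = dict(reporter_effects or {})
    densitometry_effects = dict(densitometry_effects or {})
    samples = sorted(
        {"siNT"}
        | {s for s, _ in ct_effects}
        | set(reporter_effects)
        | set(densitometry_effects)
    )
    targets = sorted({t for _, t in ct_effects} or {"CDKN1A"})

    ct_rows = []
    for s in samples:
        for rep in range(1, n_bio_replicates + 1):
            ct_ref = 15.0 + rng.normal(0, ct_sd)
            for t in targets:
                lfc = ct_effects.get((s, t), 0.0)
                dct = 7.0 - lfc  # calibrator delta-Ct is 7.0
                for tech in (1, 2):
                    ct_rows.append(
                        (s, t, rep, tech, ct_ref + dct + rng.normal(0, ct_sd))
                    )
                ct_rows.append((s, "7SL", rep, 1, ct_ref))
                ct_rows.append((s, "7SL", rep, 2, ct_ref + rng.normal(0, ct_sd / 2)))
    ct = pd.DataFrame(
        ct_rows, columns=["sample", "target", "replicate", "tech", "ct"]
    ).drop_duplicates(subset=["sample", "target", "replicate", "tech"])

    prom_rows, utr_rows = [], []
    for s in samples:
        eff = reporter_effects.get(s, 1.0)
        for rep in range(1, n_bio_replicates + 1):
            scale = rng.lognormal(0, 0.2)  # transfection efficiency
            fluc = 5000.0 * eff * scale * rng.lognormal(0, reporter_cv)
            rluc = 2000.0 * scale * rng.lognormal(0, reporter_cv)
            prom_rows.append((s, rep, fluc, rluc))
            for construct in ("WT", "SCR"):
                e = eff if construct == "WT" else 1.0
                sc = rng.lognormal(0, 0.2)
                r = 3000.0 * e * sc * rng.lognormal(0, reporter_cv)
                f = 6000.0 * sc * rng.lognormal(0, reporter_cv)
                utr_rows.append((s, construct, rep, r, f))
    promoter = pd.DataFrame(
        prom_rows, columns=["sample", "replicate", "fluc", "rluc"]
    )
    utr = pd.DataFrame(
        utr_rows, columns=["sample", "construct", "replicate", "rluc", "fluc"]
    )

    dens_rows = []
    for s in samples:
        eff = densitometry_effects.get(s, 1.0)
        for rep in range(1, n_bio_replicates + 1):
            loading = rng.lognormal(0, 0.15) * 1000.0
            dens_rows.append(
                (s, rep, eff * loading * rng.lognormal(0, densitometry_cv), loading)
            )
    densitometry = pd.DataFrame(
        dens_rows, columns=["sample", "replicate", "signal", "loading"]
    )

    ep_rows = []
    for s in samples:
        eff = densitometry_effects.get(s, 1.0)  # reuse as 18S depletion proxy
        for rep in range(1, n_bio_replicates + 1):
            total = rng.lognormal(0, 0.05) * 1000.0
            a18 = 0.28 * total * eff * rng.lognormal(0, 0.05)
            a28 = 0.52 * total * rng.lognormal(0, 0.05)
            ep_rows.append((s, rep, a18, a28, total))
    electropherogram = pd.DataFrame(
        ep_rows, columns=["sample", "replicate", "area_18s", "area_28s", "total"]
    )

    n = config.sibling_n_genes
    tau = config.sibling_shared_sd
    beta = config.sibling_slope
    sa = config.sibling_noise_a
    # OLS(B on A) slope = beta*tau^2/(tau^2+sa^2); with sa=0 the slope is
    # beta and sb follows from the requested R^2 in closed form
    if tau > 0:
        denom_a = tau**2 + sa**2
        sb2 = (
            beta**2 * tau**4 / denom_a
        ) / config.sibling_r2 - beta**2 * tau**2
    else:
        sb2 = 1.0  # no shared effect: independent noise only
    g = rng.normal(0, tau, n)
    a = g + rng.normal(0, sa, n)
    b = beta * g + rng.normal(0, np.sqrt(max(sb2, 0.0)), n)
    is_target = np.zeros(n, dtype=bool)
    k = int(config.sibling_target_fraction * n)
    is_target[rng.choice(n, k, replace=False)] = True
    a[is_target] += config.sibling_target_shift
    b[is_target] += config.sibling_target_shift
    sibling = pd.DataFrame(
        {
            "gene": [f"G{i:05d}" for i in range(n)],
            "lfc_a": a,
            "lfc_b": b,
            "target": is_target,
        }
    )
    return {
        "ct": ct,
        "promoter": promoter,
        "utr": utr,
        "densitometry": densitometry,
        "electropherogram": electropherogram,
        "sibling_lfc": sibling,
    }
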