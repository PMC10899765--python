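"""miRNA target-enrichment bioinformatics.

Expression filtering on the zTPM scale, nucleolar metadatabase merging,
interaction-table filtering and annotation, per-miRNA and per-gene target
counting with hit/non-hit comparison, and a local hypergeometric
over-representation test with Benjamini-Hochberg correction.

zTPM is the per-experiment z-score of log2 TPM computed over genes detected
(TPM > 0) in that experiment; undetected genes get -inf and can never pass
the expression cutoff. A gene is called expressed when its zTPM exceeds -3
in at least one experiment (strict inequality).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def ztpm(tpm: pd.DataFrame) -> pd.DataFrame:
    """Per-experiment z-scores of log2 TPM over detected genes.

    TPM = 0 entries map to -inf (never expressed). An experiment with fewer
    than two detected genes has no defined scale and raises.
    """
    if tpm.empty:
        raise ValueError("empty TPM matrix")
    if (tpm.to_numpy() < 0).any():
        raise ValueError("TPM values must be nonnegative")
    out = pd.DataFrame(
        -np.inf, index=tpm.index, columns=tpm.columns, dtype=float
    )
    for col in tpm.columns:
        pos = tpm[col] > 0
        if pos.sum() < 2:
            raise ValueError(f"experiment {col!r} has < 2 detected genes")
        l = np.log2(tpm.loc[pos, col])
        out.loc[pos, col] = (l - l.mean()) / l.std(ddof=1)
    return out


def expressed_genes(ztpm_mat: pd.DataFrame, threshold: float = -3.0) -> set[str]:
    """Genes with zTPM strictly above ``threshold`` in >= 1 experiment."""
    mask = (ztpm_mat > threshold).any(axis=1)
    return set(ztpm_mat.index[mask])


def merge_nucleolar_db(
    gene_lists: dict[str, list[str]],
    id_mapping: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Union of nucleolar-protein gene lists after symbol updating.

    ``id_mapping`` maps outdated identifiers to current symbols (identifiers
    absent from the mapping are assumed current; identifiers explicitly
    mapped to None/NaN are unmappable). Returns a per-gene table with
    source provenance plus the list of unmappable identifiers.
    """
    if id_mapping is None:
        id_mapping = {}
    sources: dict[str, set[str]] = {}
    unmapped: list[str] = []
    for source, ids in gene_lists.items():
        for raw in ids:
            sym = id_mapping.get(raw, raw)
            if sym is None or (isinstance(sym, float) and np.isnan(sym)):
                unmapped.append(raw)
                continue
            sources.setdefault(sym, set()).add(source)
    table = pd.DataFrame(
        {
            "gene": sorted(sources),
            "sources": [",".join(sorted(sources[g])) for g in sorted(sources)],
        }
    )
    return table, unmapped


def filter_interactions(
    raw: pd.DataFrame,
    expressed: set[str],
    nucleolar: set[str] | None = None,
    rp: set[str] | None = None,
    species: str = "Homo sapiens",
    direction: str = "down",
) -> pd.DataFrame:
    """Filter and annotate a raw interaction table.

    Keeps validated ``species`` rows where the miRNA reduces the mRNA
    (direction ``down``) and the gene is expressed; deduplicates
    (miRNA, gene) pairs keeping an ``evidence`` count. Adds boolean
    ``nucleolar`` / ``rp`` gene annotations. Output is independent of input
    row order and idempotent.
    """
    sub = raw[
        (raw["species"] == species)
        & (raw["direction"] == direction)
        & raw["validated"].astype(bool)
        & raw["gene"].isin(expressed)
    ]
    if "evidence" in sub.columns:
        dedup = (
            sub.groupby(["mirna", "gene"], as_index=False)["evidence"]
            .sum()
        )
    else:
        dedup = (
            sub.groupby(["mirna", "gene"]).size().rename("evidence").reset_index()
        )
    dedup["species"] = species
    dedup["direction"] = direction
    dedup["validated"] = True
    dedup["nucleolar"] = dedup["gene"].isin(nucleolar or set())
    dedup["rp"] = dedup["gene"].isin(rp or set())
    return dedup.sort_values(["mirna", "gene"], ignore_index=True)


@dataclass
class GroupComparison:
    per_mirna: pd.DataFrame
    summary: pd.DataFrame
    t_statistic: float
    pvalue: float


def per_mirna_counts(
    table: pd.DataFrame,
    hit_set: set[str],
    welch: bool = False,
) -> GroupComparison:
    """Per-miRNA target counts and the hit vs non-hit comparison.

    Counts total, nucleolar and RP targets per miRNA, summarizes both groups
    (mean/median of nucleolar-target counts), and runs an unpaired two-sided
    t-test on nucleolar-target counts (equal-variance Student's t by
    default; ``welch=True`` for Welch's). The test is skipped (NaN) when a
    group has fewer than two miRNAs.
    """
    per = (
        table.groupby("mirna")
        .agg(
            n_targets=("gene", "nunique"),
            n_nucleolar=("nucleolar", "sum"),
            n_rp=("rp", "sum"),
        )
        .astype({"n_nucleolar": int, "n_rp": int})
    )
    per["is_hit"] = per.index.isin(hit_set)
    summary = per.groupby("is_hit")["n_nucleolar"].agg(
        ["count", "mean", "median"]
    )
    hit_counts = per.loc[per["is_hit"], "n_nucleolar"]
    non_counts = per.loc[~per["is_hit"], "n_nucleolar"]
    if len(hit_counts) < 2 or len(non_counts) < 2:
        warnings.warn("a group has < 2 miRNAs; t-test skipped", stacklevel=2)
        t, p = np.nan, np.nan
    else:
        t, p = stats.ttest_ind(hit_counts, non_counts, equal_var=not welch)
    return GroupComparison(per, summary, float(t), float(p))


def per_gene_hit_counts(
    table: pd.DataFrame, hit_set: set[str], k: int = 5
) -> tuple[pd.DataFrame, float]:
    """Genes targeted by >= k distinct hit miRNAs, and their percentile.

    Returns a per-gene table (count of distinct hit miRNAs, selected flag)
    restricted to genes with >= 1 hit interaction, plus the selected set's
    share of that universe as a percentage ("top X%").
    """
    hits_only = table[table["mirna"].isin(hit_set)]
    counts = hits_only.groupby("gene")["mirna"].nunique().rename("n_hit_mirnas")
    per_gene = counts.to_frame()
    per_gene["selected"] = per_gene["n_hit_mirnas"] >= k
    pct = (
        100.0 * per_gene["selected"].sum() / len(per_gene)
        if len(per_gene)
        else np.nan
    )
    return per_gene.sort_values("n_hit_mirnas", ascending=False), float(pct)


def overrepresentation(
    query: set[str],
    gene_set_library: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    For each set S (intersected with the universe), computes
    P(X >= |query & S|) for X hypergeometric with population ``|universe|``,
    ``|S|`` successes and ``|query|`` draws, then Benjamini-Hochberg adjusts
    across sets. Gene ratio = overlap / |query|.
    """
    if not query:
        raise ValueError("empty query set")
    extra = query - universe
    if extra:
        raise ValueError(f"query genes outside universe: {sorted(extra)[:5]}")
    m = len(universe)
    n = len(query)
    rows = []
    for name, genes in gene_set_library.items():
        s = genes & universe
        overlap = len(query & s)
        p = float(stats.hypergeom.sf(overlap - 1, m, len(s), n))
        rows.append((name, overlap, len(s), overlap / n, p))
    out = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "gene_ratio", "pvalue"]
    )
    out["adj_pvalue"] = stats.false_discovery_control(out["pvalue"], method="bh")
    return out.sort_values("pvalue", ignore_index=True)
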