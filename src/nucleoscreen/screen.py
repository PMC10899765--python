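"""Primary- and secondary-screen statistics.

Implements plate-adjusted percent effect, the UMVUE strictly standardized
mean difference (SSMD), plate quality metrics (Z' factor, signal-to-
background), dual-cutoff hit calling, hit validation, anchored 5-EU percent
inhibition, cross-cell-line confirmation, the hit-locus chromosome
distribution test, and the five-variable hit PCA.

Percent effect rescales a well's raw phenotype percentage so that the plate's
negative-control median maps to 0 and the phenotype-matched positive-control
median maps to 100; values outside [0, 100] are permitted. The UMVUE SSMD for
k replicate percent effects x_1..x_k is

    beta-hat = c(k) * mean(x) / sd(x),
    c(k) = Gamma((k-1)/2) / Gamma((k-2)/2) * sqrt(2 / (k-1)),

an unbiased estimate of mean/sd under normality; c(3) = 1/sqrt(pi). A mimic
is a hit when its mean percent effect reaches the library's top-q empirical
quantile AND its SSMD is at least tau (default 1.645, "fairly strong").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from sklearn.decomposition import PCA

PHENOTYPE_COLUMNS = {"one-nucleolus": "pct_one", "five-plus": "pct_fiveplus"}
POSITIVE_CONTROLS = {"one-nucleolus": "siNOL11", "five-plus": "siKIF11"}
DEFAULT_QUANTILES = {"one-nucleolus": 0.025, "five-plus": 0.01}
SSMD_CUTOFF = 1.645


def percent_effect(x, neg_values, pos_values) -> np.ndarray | float:
    """Plate-adjusted percent effect: 0 at the negative-control median,
    100 at the positive-control median; may exceed [0, 100]."""
    mn = float(np.median(neg_values))
    mp = float(np.median(pos_values))
    if mp == mn:
        raise ValueError(
            "positive and negative control medians are equal; plate fails QC"
        )
    out = 100.0 * (np.asarray(x, dtype=float) - mn) / (mp - mn)
    return float(out) if np.isscalar(x) else out


def ssmd_umvue(values) -> float:
    """UMVUE SSMD of replicate percent effects (k >= 3 required)."""
    x = np.asarray(values, dtype=float)
    k = x.size
    if k < 3:
        raise ValueError(f"SSMD UMVUE requires k >= 3 replicates, got {k}")
    m = x.mean()
    s = x.std(ddof=1)
    if s == 0.0:
        warnings.warn("zero replicate s.d.; SSMD is signed infinity",
                      stacklevel=2)
        return float(np.sign(m) * np.inf) if m != 0 else 0.0
    c = np.exp(gammaln((k - 1) / 2) - gammaln((k - 2) / 2)) * np.sqrt(
        2.0 / (k - 1)
    )
    return float(c * m / s)


def ssmd_correction(k: int) -> float:
    """The UMVUE bias-correction factor c(k); c(3) = 1/sqrt(pi)."""
    if k < 3:
        raise ValueError("k >= 3 required")
    return float(
        np.exp(gammaln((k - 1) / 2) - gammaln((k - 2) / 2))
        * np.sqrt(2.0 / (k - 1))
    )


def qc_metrics(neg_values, pos_values) -> dict:
    """Z' factor and signal-to-background for one plate's controls.

    Z' = 1 - 3(sd_pos + sd_neg)/|mean_pos - mean_neg|; S/B is the ratio of
    control medians (NaN when the denominator median is 0).
    """
    neg = np.asarray(neg_values, dtype=float)
    pos = np.asarray(pos_values, dtype=float)
    if neg.size < 2 or pos.size < 2:
        raise ValueError("need >= 2 wells per control")
    sep = abs(pos.mean() - neg.mean())
    zprime = -np.inf if sep == 0 else 1.0 - 3.0 * (
        pos.std(ddof=1) + neg.std(ddof=1)
    ) / sep
    mn = np.median(neg)
    sb = np.nan if mn == 0 else float(np.median(pos) / mn)
    return {"zprime": float(zprime), "sb": sb}


def plate_percent_effects(
    wells: pd.DataFrame,
    phenotype: str,
    neg_control: str = "siNT",
    pos_control: str | None = None,
) -> pd.DataFrame:
    """Per-well plate-adjusted percent effects for one phenotype.

    ``wells`` needs columns plate, well, treatment and the raw phenotype
    percentage column (``pct_one`` / ``pct_fiveplus``). Wells with zero
    nuclei (NaN percentage) are flagged and excluded.
    """
    col = PHENOTYPE_COLUMNS[phenotype]
    pos_control = pos_control or POSITIVE_CONTROLS[phenotype]
    out = []
    for plate, grp in wells.groupby("plate", sort=False):
        grp = grp[grp[col].notna()]
        neg = grp.loc[grp["treatment"] == neg_control, col]
        pos = grp.loc[grp["treatment"] == pos_control, col]
        if len(neg) < 2 or len(pos) < 2:
            raise ValueError(
                f"plate {plate}: need >= 2 wells of {neg_control} and "
                f"{pos_control}"
            )
        pe = percent_effect(grp[col].to_numpy(), neg, pos)
        sub = grp[["plate", "well", "treatment"]].copy()
        sub["percent_effect"] = pe
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def mimic_summary(pe_table: pd.DataFrame, library: list[str]) -> pd.DataFrame:
    """Mean percent effect and SSMD per library mimic across replicates."""
    sub = pe_table[pe_table["treatment"].isin(library)]
    rows = [
        (trt, g["percent_effect"].mean(), ssmd_umvue(g["percent_effect"]))
        for trt, g in sub.groupby("treatment", sort=False)
    ]
    return pd.DataFrame(
        rows, columns=["mimic", "mean_pe", "ssmd"]
    ).set_index("mimic")


def call_hits(
    mean_pe: pd.Series,
    ssmd: pd.Series,
    q: float = 0.025,
    tau: float = SSMD_CUTOFF,
) -> pd.Series:
    """Dual-cutoff hit calling over the library mimics.

    hit <=> mean percent effect >= the empirical (1-q) quantile of library
    mean percent effects (linear interpolation, ties included) AND
    SSMD >= tau. Controls must be excluded from the inputs by the caller.
    """
    if mean_pe.empty:
        raise ValueError("empty library")
    cutoff = float(np.quantile(mean_pe.to_numpy(dtype=float), 1.0 - q))
    return (mean_pe >= cutoff) & (ssmd >= tau)


def primary_screen(
    wells: pd.DataFrame,
    library: list[str],
    quantiles: dict[str, float] | None = None,
    tau: float = SSMD_CUTOFF,
) -> pd.DataFrame:
    """Full primary-screen analysis over both phenotypes.

    Computes plate-adjusted percent effects, per-mimic mean PE and SSMD, and
    dual-cutoff hit calls for the one-nucleolus and five-plus phenotypes.
    Returns one row per library mimic with columns ``mean_pe_<ph>``,
    ``ssmd_<ph>``, ``hit_<ph>`` and the combined ``hit`` flag.
    """
    quantiles = quantiles or DEFAULT_QUANTILES
    out = None
    for phenotype, suffix in (("one-nucleolus", "one"), ("five-plus", "five")):
        pe = plate_percent_effects(wells, phenotype)
        summ = mimic_summary(pe, library)
        summ[f"hit_{suffix}"] = call_hits(
            summ["mean_pe"], summ["ssmd"], q=quantiles[phenotype], tau=tau
        )
        summ = summ.rename(
            columns={"mean_pe": f"mean_pe_{suffix}", "ssmd": f"ssmd_{suffix}"}
        )
        out = summ if out is None else out.join(summ)
    out["hit"] = out["hit_one"] | out["hit_five"]
    return out


def validate_hits(
    primary_hits: list[str],
    rescreen_pe: pd.DataFrame,
    tau: float = SSMD_CUTOFF,
) -> tuple[pd.Series, float]:
    """Validation flags for rescreened hits and the overall validation rate.

    A hit passes when its rescreen replicates give SSMD >= tau with positive
    mean percent effect. Hits missing from the rescreen are flagged failed
    (unvalidated) with a warning.
    """
    flags = {}
    grouped = dict(list(rescreen_pe.groupby("treatment", sort=False)))
    for h in primary_hits:
        if h not in grouped:
            warnings.warn(f"hit {h} missing from rescreen", stacklevel=2)
            flags[h] = False
            continue
        pe = grouped[h]["percent_effect"]
        flags[h] = bool(ssmd_umvue(pe) >= tau and pe.mean() > 0)
    s = pd.Series(flags, name="validated")
    rate = float(100.0 * s.mean()) if len(s) else float("nan")
    return s, rate


def inhibition_percent(x, nt_values, pos_values) -> np.ndarray | float:
    """Anchored 5-EU percent inhibition: siNT median -> 0%, siPOLR1A median
    -> 100%; values outside [0, 100] are permitted."""
    mn = float(np.median(nt_values))
    mp = float(np.median(pos_values))
    if mn == mp:
        raise ValueError("anchor control medians are equal; plate fails QC")
    out = 100.0 * (mn - np.asarray(x, dtype=float)) / (mn - mp)
    return float(out) if np.isscalar(x) else out


def plate_inhibitions(
    eu_wells: pd.DataFrame,
    neg_control: str = "siNT",
    pos_control: str = "siPOLR1A",
    value_col: str = "median_nucleolar_EU",
) -> pd.DataFrame:
    """Per-well anchored percent inhibition, computed plate by plate."""
    out = []
    for plate, grp in eu_wells.groupby("plate", sort=False):
        nt = grp.loc[grp["treatment"] == neg_control, value_col]
        pos = grp.loc[grp["treatment"] == pos_control, value_col]
        if nt.empty or pos.empty:
            raise ValueError(f"plate {plate}: missing anchor controls")
        sub = grp[["plate", "well", "treatment"]].copy()
        sub["inhibition"] = inhibition_percent(grp[value_col].to_numpy(), nt, pos)
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def secondary_hits(mean_inhibition: pd.Series, cutoff: float = 50.0) -> pd.Series:
    """Flag mimics whose replicate-mean inhibition is at least ``cutoff``."""
    return mean_inhibition >= cutoff


def cross_line_confirm(
    per_line_means: pd.DataFrame, cutoff: float = 50.0, min_lines: int = 2
) -> pd.Series:
    """Confirm mimics inhibiting by >= ``cutoff`` % in >= ``min_lines`` cell
    lines. ``per_line_means``: mimics x cell-line mean inhibitions."""
    return (per_line_means >= cutoff).sum(axis=1) >= min_lines


@dataclass
class ChromTestResult:
    statistic: float
    df: int
    pvalue: float
    observed: pd.Series
    expected: pd.Series
    residuals: pd.Series = field(init=False)

    def __post_init__(self):
        self.residuals = (self.observed - self.expected) / np.sqrt(self.expected)

    @property
    def most_enriched(self) -> str:
        return str(self.residuals.idxmax())


def chrom_distribution_test(
    hit_chroms, genome_chroms, min_expected: float = 1.0
) -> ChromTestResult:
    """Pearson chi-squared test of hit loci against the genome-wide miRNA
    chromosome distribution, with standardized residuals per chromosome.

    Expected counts are the genome proportions scaled to the hit total;
    chromosomes with expected count below ``min_expected`` are pooled into
    an ``"other"`` category before testing.
    """
    hits = pd.Series(hit_chroms, dtype=str)
    if hits.empty:
        raise ValueError("empty hit set")
    genome = pd.Series(genome_chroms, dtype=str)
    props = genome.value_counts(normalize=True)
    expected = props * len(hits)
    small = expected[expected < min_expected].index
    if len(small):
        keep = expected.drop(small)
        keep["other"] = expected[small].sum()
        expected = keep
    observed = hits.value_counts().reindex(expected.index, fill_value=0)
    pooled = ~hits.isin(expected.index)
    if "other" in expected.index:
        observed["other"] += int(pooled.sum())
    chi2, p = stats.chisquare(observed.to_numpy(), expected.to_numpy())
    return ChromTestResult(
        statistic=float(chi2),
        df=len(expected) - 1,
        pvalue=float(p),
        observed=observed.astype(float),
        expected=expected,
    )


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    dropped: list[str]


def pca_hits(features: pd.DataFrame) -> PCAResult:
    """PCA of the five per-hit screen variables (percent effects, viability,
    inhibition, nucleolar-target count).

    Features are standardized to zero mean / unit variance first; constant
    features are dropped with a warning. Sign convention: the largest-
    magnitude loading of each component is positive.
    """
    X = features.astype(float)
    const = [c for c in X.columns if X[c].std(ddof=0) == 0]
    if const:
        warnings.warn(f"dropping constant feature(s) {const}", stacklevel=2)
        X = X.drop(columns=const)
    Z = (X - X.mean()) / X.std(ddof=0)
    pca = PCA()
    scores = pca.fit_transform(Z.to_numpy())
    loadings = pca.components_
    for i in range(loadings.shape[0]):
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0:
            loadings[i] *= -1
            scores[:, i] *= -1
    comps = [f"PC{i + 1}" for i in range(loadings.shape[0])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=X.index, columns=comps),
        loadings=pd.DataFrame(loadings, index=comps, columns=X.columns),
        explained_variance_ratio=pca.explained_variance_ratio_,
        dropped=const,
    )
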