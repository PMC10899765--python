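"""Downstream molecular-assay normalization and testing.

Comparative-CT qPCR quantification (ddCT with a reference gene and
calibrator sample), dual-luciferase normalization in both orientations
(promoter-activity Fluc/Rluc and UTR-assay Rluc/Fluc), densitometry
normalization, one-way ANOVA with Holm-Sidak-corrected comparisons against
a control, and Welch's t-test.

Every normalization here is invariant to a global rescaling of the raw
readings and anchors the control at 1 (0 on the log2 scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def ddct(
    table: pd.DataFrame,
    reference: str = "7SL",
    calibrator: str = "siNT",
) -> pd.DataFrame:
    """Relative quantification by the comparative-CT (ddCT) method.

    ``table`` has columns sample, target, ct (plus optional replicate/tech
    columns, averaged away on the Ct scale first). Per sample,
    dCt = Ct_target - Ct_reference; ddCt subtracts the calibrator's dCt; the
    fold change is 2**(-ddCt). Samples missing the reference gene are
    dropped with a warning.

    When a replicate column is present, technical replicates are averaged
    within (sample, target, replicate) and a fold change is reported per
    biological replicate (the calibrator dCt is its replicate-mean).
    """
    df = table.copy()
    group_cols = ["sample", "target"]
    if "replicate" in df.columns:
        group_cols.append("replicate")
    ct = df.groupby(group_cols, as_index=False)["ct"].mean()
    keycols = [c for c in group_cols if c != "target"]
    ref = ct[ct["target"] == reference].set_index(keycols)["ct"]
    rows = []
    for key, grp in ct[ct["target"] != reference].groupby(keycols):
        key = key if isinstance(key, tuple) else (key,)
        lookup = key if len(keycols) > 1 else key[0]
        if lookup not in ref.index:
            warnings.warn(f"sample {key}: reference gene missing; dropped",
                          stacklevel=2)
            continue
        for _, r in grp.iterrows():
            rows.append((*key, r["target"], r["ct"] - ref.loc[lookup]))
    cols = keycols + ["target", "dct"]
    d = pd.DataFrame(rows, columns=cols)
    cal = d[d["sample"] == calibrator].groupby("target")["dct"].mean()
    if cal.empty:
        raise ValueError(f"calibrator sample {calibrator!r} absent")
    d["ddct"] = d["dct"] - d["target"].map(cal)
    d["fold"] = 2.0 ** (-d["ddct"])
    d["log2_fold"] = -d["ddct"]
    return d


def promoter_reporter(
    plate: pd.DataFrame, control: str = "siNT", center: str = "mean"
) -> pd.DataFrame:
    """Promoter-activity dual-luciferase normalization (Fluc/Rluc).

    Per well, ratio = fluc/rluc; output is the ratio divided by the control
    wells' mean (or median) ratio. Wells with a zero normalizer are dropped.
    """
    return _reporter(plate, "fluc", "rluc", control, center)


def utr_reporter(
    plate: pd.DataFrame, control: str = "siNT", center: str = "mean"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """UTR-assay dual-luciferase normalization (Rluc/Fluc) per construct,
    with Welch's t-tests between WT and SCR constructs per treatment.

    Normalization is within construct: each construct's control mean maps to
    1 separately. Constructs missing control wells are skipped with a
    warning. Returns (normalized table, Welch test table).
    """
    out = []
    for construct, grp in plate.groupby("construct"):
        if not (grp["sample"] == control).any():
            warnings.warn(
                f"construct {construct}: control missing; skipped", stacklevel=2
            )
            continue
        norm = _reporter(grp, "rluc", "fluc", control, center)
        out.append(norm)
    norm = pd.concat(out, ignore_index=True)
    tests = []
    for sample, grp in norm.groupby("sample"):
        wt = grp.loc[grp["construct"] == "WT", "normalized"]
        scr = grp.loc[grp["construct"] == "SCR", "normalized"]
        if len(wt) < 2 or len(scr) < 2:
            continue
        t, p = stats.ttest_ind(wt, scr, equal_var=False)
        tests.append((sample, float(t), float(p), len(wt), len(scr)))
    return norm, pd.DataFrame(
        tests, columns=["sample", "t", "pvalue", "n_wt", "n_scr"]
    )


def _reporter(df, primary, normalizer, control, center):
    grp = df.copy()
    zero = grp[normalizer] == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} well(s) with zero normalizer dropped",
                      stacklevel=2)
        grp = grp[~zero]
    grp["ratio"] = grp[primary] / grp[normalizer]
    ctrl = grp.loc[grp["sample"] == control, "ratio"]
    if ctrl.empty:
        raise ValueError(f"control sample {control!r} absent")
    anchor = ctrl.mean() if center == "mean" else ctrl.median()
    grp["normalized"] = grp["ratio"] / anchor
    return grp


def densitometry_norm(
    lanes: pd.DataFrame, control: str = "siNT"
) -> pd.DataFrame:
    """Loading-normalized densitometry relative to the control mean.

    ``lanes`` has columns sample, signal, loading. Per lane,
    level = (signal/loading) / mean over control lanes of (signal/loading).
    Lanes with zero loading are dropped with a warning.
    """
    grp = lanes.copy()
    zero = grp["loading"] == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} lane(s) with zero loading dropped",
                      stacklevel=2)
        grp = grp[~zero]
    grp["ratio"] = grp["signal"] / grp["loading"]
    ctrl = grp.loc[grp["sample"] == control, "ratio"]
    if ctrl.empty:
        raise ValueError(f"control sample {control!r} absent")
    grp["normalized"] = grp["ratio"] / ctrl.mean()
    return grp


def holm_sidak(pvalues) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values.

    Order raw p ascending; adjusted p_i = max_{j<=i} 1 - (1 - p_j)^(m-j+1),
    clipped to 1, reported in the input order. Equals single-step Sidak for
    m = 1; always >= the raw p and monotone nondecreasing in rank.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        step = 1.0 - (1.0 - p[idx]) ** (m - i)
        running = max(running, step)
        adj_sorted[i] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


@dataclass
class AnovaResult:
    f_statistic: float
    pvalue: float
    df_between: int
    df_within: int
    mse: float
    comparisons: pd.DataFrame  # index: group; t, pvalue, adj_pvalue


def anova_holm_sidak(
    table: pd.DataFrame, comparator: str = "siNT"
) -> AnovaResult:
    """Ordinary one-way ANOVA with Holm-Sidak comparisons vs ``comparator``.

    ``table`` has columns group, value. Per-comparison t statistics use the
    pooled ANOVA mean-squared error with N - k degrees of freedom; two-sided
    raw p-values are Holm-Sidak adjusted across the m = k - 1 comparisons.
    """
    groups = {g: v["value"].to_numpy(dtype=float)
              for g, v in table.groupby("group")}
    if comparator not in groups:
        raise ValueError(f"comparator {comparator!r} absent")
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups, each with >= 2 values")
    k = len(groups)
    ns = {g: len(v) for g, v in groups.items()}
    n_total = sum(ns.values())
    grand = np.concatenate(list(groups.values())).mean()
    ss_between = sum(
        ns[g] * (v.mean() - grand) ** 2 for g, v in groups.items()
    )
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0:
        raise ValueError("zero within-group variance everywhere; degenerate")
    mse = ss_within / df_w
    f = (ss_between / df_b) / mse
    p_overall = float(stats.f.sf(f, df_b, df_w))
    comp = groups[comparator]
    rows = []
    for g, v in groups.items():
        if g == comparator:
            continue
        se = np.sqrt(mse * (1.0 / len(v) + 1.0 / len(comp)))
        t = (v.mean() - comp.mean()) / se
        rows.append((g, float(t), float(2 * stats.t.sf(abs(t), df_w))))
    comparisons = pd.DataFrame(
        rows, columns=["group", "t", "pvalue"]
    ).set_index("group")
    comparisons["adj_pvalue"] = holm_sidak(comparisons["pvalue"].to_numpy())
    return AnovaResult(float(f), p_overall, df_b, df_w, float(mse), comparisons)


def welch_ttest(a, b) -> tuple[float, float]:
    """Unpaired two-sided Welch's t-test (Satterthwaite df)."""
    t, p = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                           equal_var=False)
    return float(t), float(p)
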