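"""Pre-rRNA processing signatures: RAMP ratios, Ward clustering, LDA,
mature-rRNA ratios and rescue assessment.

RAMP (Ratio Analysis of Multiple Precursors) characterizes a processing
defect by pairwise ratios of precursor band intensities. For precursors i, j
and replicate lane r,

    r_ij = I_i / I_j,   RAMP_ij = r_ij(treatment) / r_ij(control),

and a treatment's signature entry is the mean over replicates of
log2 RAMP_ij. Signatures are antisymmetric in (i, j), identically zero for
the control, and invariant to per-lane loading (multiplying every band in a
lane by a constant cancels in r_ij).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.cluster.hierarchy import fcluster, linkage


def ramp_ratios(
    quants: pd.DataFrame,
    control: str = "siNT",
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Mean log2 RAMP ratios relative to ``control``, per treatment.

    ``quants`` is long-format with columns treatment, replicate, precursor,
    intensity; the control must be present in every replicate batch. The
    default pair set is all ordered pairs of precursors present. Pairs with
    a zero band in a replicate are skipped for that replicate with a warning.
    Returns treatments x pairs (MultiIndex columns (numerator, denominator)).
    """
    wide = quants.pivot_table(
        index=["treatment", "replicate"],
        columns="precursor",
        values="intensity",
        aggfunc="mean",
    )
    precursors = [p for p in quants["precursor"].unique() if p in wide.columns]
    if pairs is None:
        pairs = list(itertools.permutations(precursors, 2))
    treatments = quants["treatment"].unique()
    if control not in treatments:
        raise ValueError(f"control treatment {control!r} absent")
    reps = sorted(quants["replicate"].unique())
    sig = pd.DataFrame(
        index=pd.Index(treatments, name="treatment"),
        columns=pd.MultiIndex.from_tuples(pairs, names=["num", "den"]),
        dtype=float,
    )
    warned = False
    for trt in treatments:
        for i, j in pairs:
            vals = []
            for rep in reps:
                try:
                    ti, tj = wide.loc[(trt, rep), i], wide.loc[(trt, rep), j]
                    ci, cj = wide.loc[(control, rep), i], wide.loc[(control, rep), j]
                except KeyError:
                    continue
                if 0 in (tj, cj) or ci == 0 or np.isnan([ti, tj, ci, cj]).any():
                    if not warned:
                        warnings.warn(
                            "zero/missing band; pair skipped for a replicate",
                            stacklevel=2,
                        )
                        warned = True
                    continue
                vals.append(np.log2((ti / tj) / (ci / cj)))
            sig.loc[trt, (i, j)] = np.mean(vals) if vals else np.nan
    return sig


def ward_cluster(
    signatures: pd.DataFrame, k: int = 4
) -> tuple[pd.Series, np.ndarray]:
    """Agglomerative Ward clustering of signature vectors into k clusters.

    Euclidean distance on the signature rows; returns integer labels (1..k)
    and the scipy linkage matrix (the dendrogram).
    """
    X = signatures.to_numpy(dtype=float)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of treatments {X.shape[0]}")
    Z = linkage(X, method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=signatures.index, name="cluster"), Z


@dataclass
class LDAResult:
    scores: pd.DataFrame
    directions: np.ndarray
    eigenvalues: np.ndarray


def lda_clusters(
    signatures: pd.DataFrame,
    labels: pd.Series,
    regularization: float = 0.0,
) -> LDAResult:
    """Canonical linear discriminant analysis of cluster signatures.

    Maximizes the between/within scatter ratio, returning up to (k-1)
    canonical components. Directions are normalized so scores have unit
    within-class variance, which makes scores invariant (up to sign) to any
    invertible affine transform of the features when ``regularization`` is 0.
    Clusters of size 1 are projected but excluded from scatter estimation,
    with a warning.
    """
    X = signatures.to_numpy(dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need >= 2 clusters")
    usable = classes[counts >= 2]
    if len(usable) < len(classes):
        warnings.warn(
            "cluster(s) of size 1 excluded from scatter estimation",
            stacklevel=2,
        )
    if len(usable) < 2:
        raise ValueError("need >= 2 clusters with >= 2 members")
    mask = np.isin(y, usable)
    grand = X[mask].mean(axis=0)
    p = X.shape[1]
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    for c in usable:
        Xi = X[y == c]
        mu = Xi.mean(axis=0)
        D = Xi - mu
        Sw += D.T @ D
        d = (mu - grand)[:, None]
        Sb += len(Xi) * (d @ d.T)
    if regularization:
        Sw = Sw + regularization * np.eye(p)
    elif np.linalg.matrix_rank(Sw) < p:
        warnings.warn("singular within-class scatter; regularizing",
                      stacklevel=2)
        Sw = Sw + 1e-8 * np.trace(Sw) / p * np.eye(p)
    evals, evecs = linalg.eigh(Sb, Sw)
    order = np.argsort(evals)[::-1][: len(usable) - 1]
    evals = evals[order]
    W = evecs[:, order]
    # unit within-class variance of scores
    n_w = int(mask.sum() - len(usable))
    for j in range(W.shape[1]):
        v = W[:, j]
        scale = np.sqrt(v @ (Sw / max(n_w, 1)) @ v)
        if scale > 0:
            W[:, j] = v / scale
        if np.abs(W[:, j]).max() > 0 and W[np.argmax(np.abs(W[:, j])), j] < 0:
            W[:, j] *= -1
    scores = (X - grand) @ W
    comps = [f"LD{j + 1}" for j in range(W.shape[1])]
    return LDAResult(
        scores=pd.DataFrame(scores, index=signatures.index, columns=comps),
        directions=W,
        eigenvalues=evals,
    )


def mature_ratios(areas: pd.DataFrame) -> pd.DataFrame:
    """28S/18S ratio and 18S/total fraction from electropherogram peak areas.

    ``areas`` needs columns sample, area_18s, area_28s, total. A zero 18S
    area yields a NaN ratio and a ``flagged`` row. Both outputs are invariant
    to the electropherogram's intensity units.
    """
    out = areas.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out["ratio_28s_18s"] = np.where(
            out["area_18s"] > 0, out["area_28s"] / out["area_18s"], np.nan
        )
        out["frac_18s"] = np.where(
            out["total"] > 0, out["area_18s"] / out["total"], np.nan
        )
    out["flagged"] = out["area_18s"] <= 0
    return out


def rescue_assessment(
    ratio_table: pd.DataFrame,
    control: str = "siNT",
    value_col: str = "ratio_28s_18s",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tetracycline-rescue calls from a mimic x induction condition grid.

    ``ratio_table`` needs columns sample, induced (bool), and ``value_col``.
    Within each induction arm, every mimic is compared to the control via
    one-way ANOVA with Holm-Sidak-adjusted comparisons. A mimic is rescued
    when its defect is significant in the uninduced arm and not in the
    induced arm. Missing arms leave the call as NA.
    """
    from .assays import anova_holm_sidak

    arms = {}
    for induced, grp in ratio_table.groupby("induced"):
        sub = grp.rename(columns={"sample": "group", value_col: "value"})
        res = anova_holm_sidak(sub[["group", "value"]], comparator=control)
        arms[bool(induced)] = res.comparisons["adj_pvalue"]
    mimics = sorted(set(ratio_table["sample"]) - {control})
    rows = []
    for m in mimics:
        p_un = arms.get(False, pd.Series(dtype=float)).get(m, np.nan)
        p_in = arms.get(True, pd.Series(dtype=float)).get(m, np.nan)
        if np.isnan(p_un) or np.isnan(p_in):
            rescued = pd.NA
        else:
            rescued = bool(p_un < alpha and p_in >= alpha)
        rows.append((m, p_un, p_in, rescued))
    return pd.DataFrame(
        rows, columns=["mimic", "adj_p_uninduced", "adj_p_induced", "rescued"]
    ).set_index("mimic")
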