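"""Sibling-transcriptome comparison.

Compares per-gene log2 fold-change profiles of two related treatments (e.g.
the MIR-28 sibling mimics) by ordinary least squares, and compares target vs
non-target fold-change distributions by ECDF and the two-sample
Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class LfcRegression:
    slope: float
    intercept: float
    r_squared: float
    pvalue: float
    n: int


def lfc_regression(
    table: pd.DataFrame, col_a: str = "lfc_a", col_b: str = "lfc_b"
) -> LfcRegression:
    """OLS of treatment B's log2 fold changes on treatment A's.

    Genes with a non-finite value in either column are dropped listwise
    (counts logged). R^2 is the squared Pearson correlation; the p-value is
    the two-sided test of zero slope.
    """
    a = table[col_a].to_numpy(dtype=float)
    b = table[col_b].to_numpy(dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    dropped = int((~ok).sum())
    if dropped:
        log.info("lfc_regression: dropped %d genes with non-finite values",
                 dropped)
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ValueError("need >= 3 genes with finite values in both columns")
    if np.ptp(a) == 0:
        raise ValueError("zero variance in predictor column")
    res = stats.linregress(a, b)
    return LfcRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        pvalue=float(res.pvalue),
        n=int(a.size),
    )


@dataclass
class EcdfComparison:
    ks_statistic: float
    pvalue: float
    n_targets: int
    n_non_targets: int
    ecdf_points: pd.DataFrame  # value, F_target, F_non_target


def target_ecdf_compare(
    table: pd.DataFrame, lfc_col: str = "lfc_a", target_col: str = "target"
) -> EcdfComparison:
    """Target vs non-target fold-change distributions (ECDF + two-sample KS).

    Returns the KS statistic D = sup |F_target - F_non_target| with its
    asymptotic p-value, and both right-continuous ECDFs evaluated on the
    pooled sorted values.
    """
    vals = table[lfc_col].to_numpy(dtype=float)
    flags = table[target_col].to_numpy(dtype=bool)
    ok = np.isfinite(vals)
    vals, flags = vals[ok], flags[ok]
    t, n = vals[flags], vals[~flags]
    if t.size < 2 or n.size < 2:
        raise ValueError("need >= 2 genes in each group")
    ks = stats.ks_2samp(t, n, method="asymp")
    grid = np.sort(vals)
    points = pd.DataFrame(
        {
            "value": grid,
            "F_target": stats.ecdf(t).cdf.evaluate(grid),
            "F_non_target": stats.ecdf(n).cdf.evaluate(grid),
        }
    )
    return EcdfComparison(
        ks_statistic=float(ks.statistic),
        pvalue=float(ks.pvalue),
        n_targets=int(t.size),
        n_non_targets=int(n.size),
        ecdf_points=points,
    )
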