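"""Test-retest reliability of graph metrics via ICC(3,1).

Two resting-state recordings taken about two hours apart act as the two
"raters" of a two-way mixed-effects model.  ICC(3,1) is the consistency
form, insensitive to an additive session effect:

    ICC = (MSR - MSE) / (MSR + (k - 1) * MSE)

with MSR the between-subject and MSE the residual mean square of the
subjects x sessions ANOVA, k = number of sessions.  Values are classified
as poor (< 0.5), moderate (0.5-0.75), good (0.75-0.9), excellent (>= 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["IccResult", "icc_3_1", "classify_icc", "reliability_map"]


@dataclass
class IccResult:
    icc: float
    msr: float
    mse: float
    f: float
    df1: int
    df2: int
    p: float
    label: str


def classify_icc(icc: float) -> str:
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


def icc_3_1(session1: np.ndarray, session2: np.ndarray, *more: np.ndarray) -> IccResult:
    """ICC(3,1) for paired measurements (two or more sessions).

    The p-value is one-sided from ``F = MSR / MSE`` on
    ``(n - 1, (n - 1)(k - 1))`` degrees of freedom (H1: ICC > 0).
    """
    data = np.column_stack([session1, session2, *more]).astype(float)
    n, k = data.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite values")
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    df1 = n - 1
    df2 = (n - 1) * (k - 1)
    msr = ss_rows / df1
    mse = ss_err / df2
    if msr <= 0:
        raise ValueError("zero between-subject variance")
    icc = (msr - mse) / (msr + (k - 1) * mse)
    f = msr / mse if mse > 0 else np.inf
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return IccResult(
        icc=float(icc), msr=float(msr), mse=float(mse), f=float(f),
        df1=df1, df2=df2, p=p, label=classify_icc(float(icc)),
    )


def reliability_map(metrics_ec1: pd.DataFrame, metrics_ec2: pd.DataFrame) -> pd.DataFrame:
    """ICC(3,1) per band for global metrics and per band x ROI for nodal ones.

    Inputs are tidy tables with columns (participant, band, metric, roi,
    value); global rows carry roi = -1 by convention (see the metrics
    writer).  Output: one row per (scope, band, metric, roi) with the ICC,
    F, p and qualitative label, for exactly the variables present in both
    sessions.
    """
    key = ["participant", "band", "metric", "roi"]
    for name, df in (("session 1", metrics_ec1), ("session 2", metrics_ec2)):
        missing = set(key + ["value"]) - set(df.columns)
        if missing:
            raise ValueError(f"{name} table lacks columns {sorted(missing)}")
    merged = metrics_ec1.merge(metrics_ec2, on=key, suffixes=("_1", "_2"))
    n1 = metrics_ec1.groupby(["band", "metric", "roi"]).size()
    n_merged = merged.groupby(["band", "metric", "roi"]).size()
    if not n1.align(n_merged, join="inner")[0].equals(n_merged):
        raise ValueError("participant mismatch between sessions")
    rows = []
    for (band, metric, roi), grp in merged.groupby(["band", "metric", "roi"]):
        res = icc_3_1(grp["value_1"].to_numpy(), grp["value_2"].to_numpy())
        rows.append(
            {
                "scope": "global" if roi == -1 else "nodal",
                "band": band,
                "metric": metric,
                "roi": roi,
                "icc": res.icc,
                "F": res.f,
                "p": res.p,
                "label": res.label,
            }
        )
    return pd.DataFrame(rows).sort_values(["scope", "band", "metric", "roi"]).reset_index(drop=True)


def reliability_summary(rel: pd.DataFrame) -> pd.DataFrame:
    """Counts of poor/moderate/good/excellent nodal areas per band x metric."""
    nodal = rel[rel["scope"] == "nodal"]
    counts = (
        nodal.groupby(["band", "metric", "label"]).size().rename("n_rois").reset_index()
    )
    return counts
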