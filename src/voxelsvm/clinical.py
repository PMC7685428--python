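"""ROI gray-matter extraction, clinical correlations and demographic tests.

Covers the clinical side of the analysis: mean preprocessed GM per
region-of-interest, Spearman correlations between ROI means and patient
clinical scores (with BH correction across the whole ROI x variable
family), ROI-ROI correlation matrices, and the summary-statistic
group-comparison tests (pooled two-sample t, 2x2 chi-square).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .volume import VolumeGrid

__all__ = [
    "roi_mean_gm",
    "spearman",
    "correlate_rois_clinical",
    "roi_roi_correlation",
    "t_from_summary",
    "chi2_2x2",
    "DEFAULT_CLINICAL_VARIABLES",
]

DEFAULT_CLINICAL_VARIABLES = (
    "JART",
    "PANSS_total",
    "PANSS_positive",
    "PANSS_negative",
    "onset_age",
    "duration",
    "CPZ_mg",
)


def roi_mean_gm(
    volumes: dict[str, VolumeGrid] | list[VolumeGrid],
    label_volume: VolumeGrid,
    subject_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Mean GM per subject per ROI; ROIs are the nonzero labels of the map."""
    if isinstance(volumes, dict):
        subject_ids = subject_ids or list(volumes)
        vols = [volumes[sid] for sid in subject_ids]
    else:
        vols = list(volumes)
        subject_ids = subject_ids or [str(i) for i in range(len(vols))]
    labels = label_volume.values.astype(int)
    roi_ids = sorted(int(l) for l in np.unique(labels) if l != 0)
    if not roi_ids:
        raise ValueError("label volume contains no ROIs")
    masks = {rid: labels == rid for rid in roi_ids}
    for rid, m in masks.items():
        if not m.any():
            raise ValueError(f"ROI {rid} is empty")
    data = {
        f"ROI_{rid}": [float(v.values[masks[rid]].mean()) for v in vols] for rid in roi_ids
    }
    return pd.DataFrame(data, index=subject_ids)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties.

    Pairs with a missing value in either argument are dropped; needs at
    least 3 complete pairs. The two-sided p comes from the
    t-approximation t = rho * sqrt((n-2)/(1-rho^2)).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"need >= 3 complete pairs, got {len(x)}")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance in a ranked vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def correlate_rois_clinical(
    roi_means: pd.DataFrame,
    participants: pd.DataFrame,
    variables: tuple[str, ...] = DEFAULT_CLINICAL_VARIABLES,
    q: float = 0.05,
) -> pd.DataFrame:
    """All ROI x clinical-variable Spearman correlations for patients.

    Controls are excluded. Missing clinical values are dropped pairwise per
    cell and the per-cell n is reported. Uncorrected p is flagged at 0.05;
    BH q-values are computed across the full ROI x variable family of the
    model (cells that could not be computed are reported with NaN and do
    not enter the family).
    """
    if "diagnosis" in participants.columns:
        participants = participants[participants["diagnosis"] == "patient"]
    roi_means = roi_means.loc[participants["subject_id"]]
    rows = []
    for roi in roi_means.columns:
        for var in variables:
            if var not in participants.columns:
                raise ValueError(f"variable {var!r} absent from participant records")
            x = roi_means[roi].to_numpy(dtype=float)
            yv = participants[var].to_numpy(dtype=float)
            n = int((np.isfinite(x) & np.isfinite(yv)).sum())
            try:
                rho, p = spearman(x, yv)
            except ValueError:
                rho, p = np.nan, np.nan
            rows.append({"roi": roi, "variable": var, "rho": rho, "p": p, "n": n})
    table = pd.DataFrame(rows)
    table["sig_uncorrected"] = table["p"] < 0.05
    table["q"] = np.nan
    ok = table["p"].notna()
    if ok.any():
        from statsmodels.stats.multitest import multipletests

        _, qvals, *_ = multipletests(table.loc[ok, "p"], alpha=q, method="fdr_bh")
        table.loc[ok, "q"] = qvals
    table["sig_fdr"] = table["q"] < q
    return table


def roi_roi_correlation(roi_means: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlations between ROI means, unit diagonal."""
    if roi_means.shape[1] < 2:
        raise ValueError("need at least 2 ROIs")
    cols = list(roi_means.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            rho, _ = spearman(roi_means[a], roi_means[cols[j]])
            out.iloc[i, j] = out.iloc[j, i] = rho
    return out


def t_from_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t test from summary statistics.

    Returns (t, df, two-sided p) with df = n1 + n2 - 2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be >= 0")
    df = n1 + n2 - 2
    if sd1 == 0 and sd2 == 0:
        if m1 == m2:
            return 0.0, df, 1.0
        raise ValueError("zero variance in both groups with unequal means (infinite t)")
    t, p = stats.ttest_ind_from_stats(m1, sd1, n1, m2, sd2, n2, equal_var=True)
    return float(t), df, float(p)


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction."""
    table = np.array([[a, b], [c, d]])
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("all margins must be positive")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)
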