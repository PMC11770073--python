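"""Agreement and accuracy statistics for ICP method comparison.

All differences are defined as estimate minus reference (eICP − ICP), so a
positive bias means overestimation. Bland–Altman limits of agreement use the
sample (n−1) standard deviation and the conventional 1.96 multiplier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ERROR_BAND_EDGES_MMHG = (2.0, 4.0, 6.0)
HI_ICP_THRESHOLD_MMHG = 20.0


@dataclass(frozen=True)
class MetricsReport:
    mae_mmHg: float
    mse_mmHg2: float
    bias_mmHg: float
    sd_mmHg: float
    loa_low_mmHg: float
    loa_high_mmHg: float
    spearman_rho: float
    spearman_p: float
    n_windows: int

    def to_dict(self) -> dict:
        return dict(vars(self))


def _paired(icp, eicp) -> tuple[np.ndarray, np.ndarray]:
    icp = np.asarray(icp, dtype=float)
    eicp = np.asarray(eicp, dtype=float)
    if icp.shape != eicp.shape or icp.ndim != 1 or icp.size == 0:
        raise ValueError("icp and eicp must be equal-length nonempty 1-d arrays")
    if not (np.all(np.isfinite(icp)) and np.all(np.isfinite(eicp))):
        raise ValueError("inputs must be finite")
    return icp, eicp


def regression_metrics(icp, eicp) -> tuple[float, float]:
    """(MAE, MSE) of eICP against reference ICP."""
    icp, eicp = _paired(icp, eicp)
    d = eicp - icp
    return float(np.mean(np.abs(d))), float(np.mean(d**2))


def bland_altman(icp, eicp) -> tuple[float, float, float, float]:
    """(bias, SD, lower limit, upper limit) of the differences eICP − ICP;
    limits are bias ± 1.96·SD with the sample (n−1) SD."""
    icp, eicp = _paired(icp, eicp)
    if icp.size < 2:
        raise ValueError("Bland–Altman needs n >= 2")
    d = eicp - icp
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, sd, bias - 1.96 * sd, bias + 1.96 * sd


def spearman_correlation(icp, eicp) -> tuple[float, float]:
    """Rank correlation (mid-rank ties) with two-sided p value."""
    icp, eicp = _paired(icp, eicp)
    if icp.size < 3:
        raise ValueError("Spearman needs n >= 3")
    if np.std(icp) == 0 or np.std(eicp) == 0:
        raise ValueError("degenerate (constant) input")
    res = stats.spearmanr(icp, eicp)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class ErrorBands:
    """Proportions of |eICP − ICP| in [0,2), [2,4), [4,6) and >= 6 mmHg."""

    proportions: tuple[float, ...]
    edges: tuple[float, ...] = ERROR_BAND_EDGES_MMHG


def error_histogram(icp, eicp, edges=ERROR_BAND_EDGES_MMHG) -> ErrorBands:
    icp, eicp = _paired(icp, eicp)
    d = np.abs(eicp - icp)
    bins = np.concatenate([[0.0], np.asarray(edges, dtype=float), [np.inf]])
    counts, _ = np.histogram(d, bins=bins)
    return ErrorBands(proportions=tuple(counts / d.size), edges=tuple(edges))


@dataclass(frozen=True)
class ThresholdReport:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    npv: float
    ppv: float


def threshold_predictive_values(
    icp, eicp, threshold: float = HI_ICP_THRESHOLD_MMHG
) -> ThresholdReport:
    """Intracranial-hypertension screening at the given threshold (>= is
    positive for both reference and estimate). Undefined ratios (zero
    denominator) are reported as NaN rather than raised."""
    icp, eicp = _paired(icp, eicp)
    truth = icp >= threshold
    pred = eicp >= threshold
    tp = int(np.sum(truth & pred))
    fp = int(np.sum(~truth & pred))
    tn = int(np.sum(~truth & ~pred))
    fn = int(np.sum(truth & ~pred))
    npv = tn / (tn + fn) if (tn + fn) > 0 else float("nan")
    ppv = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    return ThresholdReport(threshold, tp, fp, tn, fn, npv, ppv)


def metrics_report(icp, eicp) -> MetricsReport:
    """Full agreement report for one estimate/reference pairing."""
    mae, mse = regression_metrics(icp, eicp)
    bias, sd, lo, hi = bland_altman(icp, eicp)
    rho, p = spearman_correlation(icp, eicp)
    return MetricsReport(
        mae_mmHg=mae, mse_mmHg2=mse, bias_mmHg=bias, sd_mmHg=sd,
        loa_low_mmHg=lo, loa_high_mmHg=hi,
        spearman_rho=rho, spearman_p=p, n_windows=len(np.asarray(icp)),
    )


def per_patient_summary(predictions: pd.DataFrame) -> pd.DataFrame:
    """Per-patient window-level MAE, mean reference ICP, mean eICP, and mean
    difference (mean eICP − mean ICP). Expects columns ``patient_id``,
    ``reference_icp_mmHg`` and ``eicp_mmHg``."""
    if len(predictions) == 0:
        raise ValueError("no prediction records")
    rows = []
    for pid, grp in predictions.groupby("patient_id", sort=True):
        icp = grp["reference_icp_mmHg"].to_numpy(dtype=float)
        eicp = grp["eicp_mmHg"].to_numpy(dtype=float)
        rows.append(
            {
                "patient_id": pid,
                "mae_mmHg": float(np.mean(np.abs(eicp - icp))),
                "mean_icp_mmHg": float(np.mean(icp)),
                "mean_eicp_mmHg": float(np.mean(eicp)),
                "mean_diff_mmHg": float(np.mean(eicp) - np.mean(icp)),
            }
        )
    return pd.DataFrame(rows)


def aggregate_folds(per_fold: pd.DataFrame, round_decimals: int = 2) -> pd.DataFrame:
    """Column-wise mean and sample SD over cross-validation folds, rounded
    for display. Input: one row per fold, numeric error columns."""
    if len(per_fold) < 2:
        raise ValueError("need >= 2 folds to aggregate")
    numeric = per_fold.select_dtypes(include=[np.number])
    if numeric.isna().any().any():
        raise ValueError("ragged or missing fold values")
    out = pd.DataFrame(
        {"mean": numeric.mean(axis=0), "sd": numeric.std(axis=0, ddof=1)}
    )
    return out.round(round_decimals)
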