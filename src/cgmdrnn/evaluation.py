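"""Forecast evaluation: RMSE, MARD, cross-correlation time lag, t-tests.

RMSE (mg/dL) and MARD (%) measure the error between predicted and actual
glucose; the time lag τ_lag (minutes) measures how slowly a forecaster
reacts to abrupt glucose changes, as the delay maximising the
cross-correlation between the forecast and the actual series.  Paired
two-sided t-tests compare per-subject metric vectors between methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import SLOT_MINUTES

__all__ = [
    "rmse",
    "mard",
    "time_lag",
    "compare_methods",
    "MetricsReport",
]


def _paired(pred, actual) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.shape != actual.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {actual.shape}")
    if pred.size == 0:
        raise ValueError("need at least one paired point")
    return pred, actual


def rmse(pred, actual) -> float:
    """Root mean squared error in mg/dL: sqrt(mean((ŷ - y)²))."""
    pred, actual = _paired(pred, actual)
    return float(np.sqrt(np.mean((pred - actual) ** 2)))


def mard(pred, actual) -> float:
    """Mean absolute relative difference in percent: mean(|ŷ-y| / y) × 100.

    Every actual value must be positive; non-positive actuals are an
    error, never silently skipped.
    """
    pred, actual = _paired(pred, actual)
    if np.any(actual <= 0):
        raise ValueError("MARD requires strictly positive actual values")
    return float(np.mean(np.abs((pred - actual) / actual)) * 100.0)


def time_lag(
    pred,
    actual,
    max_lag_slots: int = 6,
    slot_minutes: int = SLOT_MINUTES,
) -> float:
    """Forecast delay in minutes from the cross-correlation peak.

    For each shift δ ∈ [0, max_lag_slots] the Pearson correlation of
    pred[δ:] against actual[:n-δ] is computed (a forecast that lags the
    truth by δ slots peaks at that shift).  The integer arg-max is
    refined by parabolic interpolation through the peak and its two
    neighbours, giving sub-slot (fractional-minute) resolution; the
    result is clipped to [0, max_lag_slots * slot_minutes].
    """
    pred, actual = _paired(pred, actual)
    n = pred.size
    if n <= max_lag_slots + 2:
        raise ValueError("series too short for the requested lag search")
    corrs = np.empty(max_lag_slots + 1)
    for d in range(max_lag_slots + 1):
        a = pred[d:]
        b = actual[: n - d]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            raise ValueError("zero-variance series: time lag undefined")
        corrs[d] = np.corrcoef(a, b)[0, 1]
    k = int(np.argmax(corrs))
    offset = 0.0
    if 0 < k < max_lag_slots:
        c_m, c_0, c_p = corrs[k - 1], corrs[k], corrs[k + 1]
        denom = c_m - 2.0 * c_0 + c_p
        if denom < 0:  # proper concave peak
            offset = 0.5 * (c_m - c_p) / denom
    lag = (k + offset) * slot_minutes
    return float(np.clip(lag, 0.0, max_lag_slots * slot_minutes))


def compare_methods(metrics_a, metrics_b) -> tuple[float, float, bool]:
    """Paired two-sided t-test between per-subject metric vectors.

    Returns (statistic, p-value, degenerate).  Zero-variance differences
    (including identical vectors) are a degenerate case reported as
    p = 1 with the flag set, never raised mid-pipeline.
    """
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length paired vectors with n >= 2")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        return 0.0, 1.0, True
    t = stats.ttest_rel(a, b)
    return float(t.statistic), float(t.pvalue), False


@dataclass
class MetricsReport:
    """Per-subject metrics for several methods plus pairwise t-tests.

    ``per_subject`` maps method -> {"rmse": [...], "mard": [...],
    "tau_lag": [...]} with one entry per subject, aligned across methods.
    """

    per_subject: dict[str, dict[str, list[float]]]

    METRICS = ("rmse", "mard", "tau_lag")

    def aggregate(self) -> pd.DataFrame:
        """Mean ± SD per method and metric (table layout of the report)."""
        rows = []
        for method, m in self.per_subject.items():
            row = {"method": method}
            for name in self.METRICS:
                vals = np.asarray(m[name], dtype=float)
                row[f"{name}_mean"] = vals.mean()
                row[f"{name}_sd"] = vals.std(ddof=1) if vals.size > 1 else 0.0
            rows.append(row)
        return pd.DataFrame(rows).set_index("method")

    def pairwise_pvalues(self, metric: str = "rmse") -> pd.DataFrame:
        methods = list(self.per_subject)
        out = pd.DataFrame(np.nan, index=methods, columns=methods)
        for i, a in enumerate(methods):
            for b in methods[i + 1 :]:
                _, p, _ = compare_methods(
                    self.per_subject[a][metric], self.per_subject[b][metric]
                )
                out.loc[a, b] = out.loc[b, a] = p
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format per-subject table (method × subject × metric)."""
        rows = []
        for method, m in self.per_subject.items():
            n = len(m["rmse"])
            for i in range(n):
                rows.append(
                    {
                        "method": method,
                        "subject": i,
                        **{name: m[name][i] for name in self.METRICS},
                    }
                )
        return pd.DataFrame(rows)
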