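"""Evaluation: time-series errors, clinical propulsion point metrics,
minimal-detectable-change comparison, and model-comparison statistics.

Propulsion point metrics per stride: peak propulsion (maximum AP GRF, %BW),
its timing as a percentage of stance, and the propulsion impulse (trapezoidal
time integral of the positive AP GRF region over stance, %BW*s).  Propulsion
symmetry is the paretic share of the two-limb total impulse in percent
(50 % = perfect symmetry).  Point-metric RMSEs are compared with published
minimal-detectable-change thresholds for treadmill walking post-stroke.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

# MDC thresholds for treadmill walking in people post-stroke
MDC_PEAK_PCTBW = 0.80       # %BW
MDC_IMPULSE_PCTBW_S = 0.24  # %BW*s
MDC_SYMMETRY_PCT = 3.92     # %


@dataclass
class PropulsionMetrics:
    """Per-stride propulsion point metrics of one leg."""

    stride_id: np.ndarray
    peak: np.ndarray          # %BW
    peak_timing: np.ndarray   # % of stance
    impulse: np.ndarray       # %BW*s

    def __len__(self):
        return len(self.stride_id)

    def mean_impulse(self) -> float:
        return float(np.mean(self.impulse)) if len(self) else float("nan")


@dataclass
class EvalReport:
    rmse: float               # %BW, stance frames
    nrmse: float              # % of test stance range
    r2: float
    metric_rmse: dict = field(default_factory=dict)
    mdc_flags: dict = field(default_factory=dict)
    n_strides: int = 0

    def to_dict(self) -> dict:
        out = {"rmse": self.rmse, "nrmse": self.nrmse, "r2": self.r2,
               "n_strides": self.n_strides}
        out.update({f"rmse_{k}": v for k, v in self.metric_rmse.items()})
        out.update({f"within_mdc_{k}": bool(v) for k, v in self.mdc_flags.items()})
        return out


# ---------------------------------------------------------------------------
# time-series errors

def timeseries_errors(est: np.ndarray, truth: np.ndarray,
                      stance_mask: np.ndarray) -> tuple[float, float, float]:
    """(RMSE %BW, NRMSE %, R^2) over stance frames only."""
    est, truth = np.asarray(est, float), np.asarray(truth, float)
    if est.shape != truth.shape:
        raise ValueError("estimate and truth must have equal length")
    mask = np.asarray(stance_mask, bool)
    if not mask.any():
        raise ValueError("empty stance mask")
    e, t = est[mask], truth[mask]
    rmse = float(np.sqrt(np.mean((e - t) ** 2)))
    rng = float(t.max() - t.min())
    nrmse = 100.0 * rmse / rng if rng > 0 else float("inf")
    ss_res = float(np.sum((e - t) ** 2))
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return rmse, nrmse, r2


# ---------------------------------------------------------------------------
# stride point metrics

def stride_point_metrics(ap_grf: np.ndarray, dt: float = 0.01) -> tuple[float, float, float]:
    """(peak %BW, timing % of stance, impulse %BW*s) of one stride's stance trace.

    Peak = maximum AP GRF (ties broken by the earliest frame); timing = the
    argmax position as a percentage of stance duration; impulse = trapezoidal
    integral of max(AP GRF, 0).
    """
    ap = np.asarray(ap_grf, float)
    if ap.size == 0:
        raise ValueError("empty stride")
    peak = float(ap.max())
    k = int(np.argmax(ap))
    timing = 100.0 * k / max(ap.size - 1, 1)
    impulse = float(np.trapezoid(np.clip(ap, 0.0, None), dx=dt))
    return peak, timing, impulse


def metrics_by_stride(ap: np.ndarray, stride_id: np.ndarray,
                      dt: float = 0.01, min_frames: int = 5) -> PropulsionMetrics:
    """Point metrics for every labelled stride in a stance-frame series."""
    ids = np.unique(stride_id)
    ids = ids[ids >= 0]
    rows = []
    for sid in ids:
        sel = stride_id == sid
        if np.count_nonzero(sel) < min_frames:
            continue
        rows.append((sid, *stride_point_metrics(ap[sel], dt)))
    if not rows:
        return PropulsionMetrics(np.array([], int), np.array([]), np.array([]),
                                 np.array([]))
    arr = np.array(rows)
    return PropulsionMetrics(arr[:, 0].astype(int), arr[:, 1], arr[:, 2], arr[:, 3])


def propulsion_symmetry(paretic_impulse_mean: float,
                        nonparetic_impulse_mean: float) -> float:
    """Paretic share of the two-limb propulsion impulse, percent."""
    p, n = float(paretic_impulse_mean), float(nonparetic_impulse_mean)
    if p < 0 or n < 0:
        raise ValueError("impulse means must be non-negative")
    if p + n <= 0:
        raise ValueError("zero total impulse")
    return 100.0 * p / (p + n)


def metric_rmse(est: PropulsionMetrics, truth: PropulsionMetrics) -> dict:
    """Stride-matched RMSE of each point metric."""
    if not np.array_equal(est.stride_id, truth.stride_id):
        common = np.intersect1d(est.stride_id, truth.stride_id)
        if common.size == 0:
            raise ValueError("mismatched stride sets")
        ei = np.searchsorted(est.stride_id, common)
        ti = np.searchsorted(truth.stride_id, common)
        est = PropulsionMetrics(common, est.peak[ei], est.peak_timing[ei],
                                est.impulse[ei])
        truth = PropulsionMetrics(common, truth.peak[ti], truth.peak_timing[ti],
                                  truth.impulse[ti])

    def rmse(a, b):
        return float(np.sqrt(np.mean((a - b) ** 2)))

    return {"peak": rmse(est.peak, truth.peak),
            "timing": rmse(est.peak_timing, truth.peak_timing),
            "impulse": rmse(est.impulse, truth.impulse)}


def mdc_check(metric_rmses: dict, symmetry_rmse: float | None = None) -> dict:
    """Strictly-below comparison of point-metric RMSEs with MDC thresholds."""
    flags = {"peak": metric_rmses["peak"] < MDC_PEAK_PCTBW,
             "impulse": metric_rmses["impulse"] < MDC_IMPULSE_PCTBW_S}
    if symmetry_rmse is not None:
        flags["symmetry"] = symmetry_rmse < MDC_SYMMETRY_PCT
    return flags


# ---------------------------------------------------------------------------
# model comparison

def paired_model_test(errors_a, errors_b) -> tuple[float, float]:
    """Two-sided paired t-test on per-dataset error values.

    Returns (t, p); raises on fewer than 3 pairs; (nan, nan) with a
    degenerate flag is signalled by ValueError when all differences are 0.
    """
    a = np.asarray(errors_a, float)
    b = np.asarray(errors_b, float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need >= 3 paired error values")
    if np.allclose(a, b):
        raise ValueError("degenerate: all paired differences are zero")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# report assembly

def evaluate_predictions(pred: np.ndarray, truth: np.ndarray,
                         stride_id: np.ndarray, dt: float = 0.01) -> EvalReport:
    """Full report from stance-frame predictions of one leg's test set."""
    rmse, nrmse, r2 = timeseries_errors(pred, truth, np.ones(len(pred), bool))
    m_est = metrics_by_stride(pred, stride_id, dt)
    m_tru = metrics_by_stride(truth, stride_id, dt)
    rmses = metric_rmse(m_est, m_tru)
    return EvalReport(rmse=rmse, nrmse=nrmse, r2=r2, metric_rmse=rmses,
                      mdc_flags=mdc_check(rmses), n_strides=len(m_tru))


def report_table(reports: dict) -> pd.DataFrame:
    """Tabulate {name: EvalReport} as one row per model/report."""
    return pd.DataFrame({name: rep.to_dict() for name, rep in reports.items()}).T
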