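"""Logistic growth fitting of OD600 time series.

Fits the three-parameter logistic N(t) = K / (1 + ((K - N0)/N0) e^{-rt}) by
bounded least squares and reports the growth rate as doublings per hour,
r / ln 2 (equivalently 60 divided by the doubling time in minutes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

_LN2 = float(np.log(2.0))


@dataclass
class GrowthCurve:
    """One well's OD600 time series (times in hours)."""

    sample_id: str
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape or self.times.ndim != 1:
            raise ValueError("times and od must be equal-length vectors")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("OD readings must be non-negative")


@dataclass
class LogisticFit:
    """Fitted logistic parameters; rate conversions are exact identities."""

    sample_id: str
    k: float
    n0: float
    r: float  # per hour
    residual_sd: float
    converged: bool

    @property
    def doubling_time_min(self) -> float:
        if not self.converged or self.r <= 0:
            return float("nan")
        return 60.0 * _LN2 / self.r

    @property
    def doublings_per_hour(self) -> float:
        if not self.converged or self.r <= 0:
            return float("nan")
        return self.r / _LN2


def _logistic(t, k, n0, r):
    return k / (1.0 + ((k - n0) / n0) * np.exp(-r * t))


def _initial_rate(times, od, n0_guess) -> float:
    """Slope of ln(OD) over the earliest quarter of points above baseline."""
    above = np.flatnonzero(od > max(n0_guess, 1e-4))
    if len(above) < 3:
        return 0.5
    early = above[: max(3, len(above) // 4)]
    y = np.log(od[early])
    slope = np.polyfit(times[early], y, 1)[0]
    return float(slope) if np.isfinite(slope) and slope > 0 else 0.5


def fit_logistic(curve: GrowthCurve, blank: str = "none") -> LogisticFit:
    """Least-squares logistic fit; never raises on degenerate series.

    ``blank="first"`` subtracts the first reading (a medium blank) from the
    whole series, flooring at 1e-4; the default assumes the series is
    already blank-corrected.  Returns ``converged=False`` for flat or
    unfittable data.
    """
    times = curve.times
    od = curve.od.astype(float)
    if len(times) < 10:
        raise ValueError("need at least 10 time points to fit")
    if not (np.all(np.isfinite(times)) and np.all(np.isfinite(od))):
        raise ValueError("times and od must be finite")
    if blank == "first":
        od = np.maximum(od - od[0], 1e-4)
    elif blank != "none":
        raise ValueError("blank must be 'none' or 'first'")

    failed = LogisticFit(curve.sample_id, np.nan, np.nan, np.nan, np.nan, False)
    if np.ptp(od) == 0:
        return failed

    k0 = float(od.max())
    positive = od[od > 0]
    n00 = float(positive[0]) if len(positive) else 1e-4
    n00 = min(n00, 0.9 * k0) if k0 > 0 else n00
    bounds = ([max(1e-6, 0.5 * k0), 1e-8, 1e-4], [10.0 * k0, k0, 50.0])
    r0 = _initial_rate(times, od, n00)

    ss_tot0 = float(((od - od.mean()) ** 2).sum())
    best = None
    # a few rate restarts guard against a bad initial log-slope estimate
    for r_init in dict.fromkeys([r0, 0.1, 0.3, 1.0, 3.0]):
        p0 = [
            float(np.clip(k0, bounds[0][0], bounds[1][0])),
            float(np.clip(n00, bounds[0][1], bounds[1][1])),
            float(np.clip(r_init, bounds[0][2], bounds[1][2])),
        ]
        try:
            popt, _ = optimize.curve_fit(
                _logistic, times, od, p0=p0, bounds=bounds, maxfev=10_000
            )
        except (RuntimeError, ValueError):
            continue
        resid = od - _logistic(times, *popt)
        ss = float(resid @ resid)
        if best is None or ss < best[1]:
            best = (popt, ss)
        if best[1] < 1e-3 * (ss_tot0 + 1e-30):
            break  # essentially a perfect fit; stop restarting
    if best is None:
        return failed
    (k, n0, r), ss_res = best
    ss_tot = float(((od - od.mean()) ** 2).sum())
    residual_sd = float(np.sqrt(ss_res / max(len(od) - 3, 1)))
    # a fit that explains less variance than a flat line is no growth curve
    converged = bool(
        np.isfinite([k, n0, r]).all()
        and k > n0 > 0
        and r > bounds[0][2] * (1 + 1e-6)
        and ss_res < 0.9 * ss_tot
    )
    if not converged:
        return LogisticFit(curve.sample_id, float(k), float(n0), float(r),
                           residual_sd, False)
    return LogisticFit(
        curve.sample_id, float(k), float(n0), float(r), residual_sd, True
    )


def doublings_per_hour(fit: LogisticFit) -> float:
    """Growth rate in doublings per hour (r / ln 2); NaN if unconverged."""
    return fit.doublings_per_hour


def compare_growth(mutant_rates: dict, wt_rates) -> pd.DataFrame:
    """Per-strain equal-variance two-sided t vs WT, BH-corrected across strains.

    ``mutant_rates`` maps strain label -> replicate growth rates; ``wt_rates``
    is the WT replicate list.  Identical degenerate groups get p = 1.
    """
    wt = np.asarray(list(wt_rates), dtype=float)
    if len(wt) < 2:
        raise ValueError("need >= 2 WT replicates")
    rows = []
    for strain, values in mutant_rates.items():
        x = np.asarray(list(values), dtype=float)
        if len(x) < 2:
            raise ValueError(f"strain {strain}: need >= 2 replicates")
        if x.std(ddof=1) == 0 and wt.std(ddof=1) == 0:
            if x.mean() == wt.mean():
                t, p = 0.0, 1.0
            else:
                t, p = np.inf * np.sign(x.mean() - wt.mean()), 0.0
        else:
            t, p = stats.ttest_ind(x, wt, equal_var=True)
        rows.append(
            {
                "strain": strain,
                "mean_rate": float(x.mean()),
                "wt_mean_rate": float(wt.mean()),
                "t_statistic": float(t),
                "p_value": float(p),
            }
        )
    frame = pd.DataFrame(rows)
    if len(frame):
        frame["q_value"] = multipletests(frame["p_value"], method="fdr_bh")[1]
    return frame
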