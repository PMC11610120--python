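"""Logistic growth-curve fitting and reciprocal-hemizygote comparison.

Model: N(t) = K / (1 + ((K - N0)/N0) * exp(-r t)) with carrying capacity K,
intrinsic rate r (per hour) and initial density N0.  Derived metrics follow
the conventional growth-curve summaries: Tmid = ln((K - N0)/N0)/r is the
half-capacity time, auc_l = (K/r) * ln((K + N0 (e^{rT} - 1))/K) the exact
integral of the fitted curve over [0, T], auc_e the trapezoidal integral of
the raw data.  Allele groups are compared with a pooled-variance two-sample
Student's t-test on any fitted metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)


@dataclass
class GrowthCurve:
    well: str
    group: str
    times: np.ndarray
    densities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        if self.times.size < 5:
            raise ValueError("need >= 5 time points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if (self.densities < 0).any():
            raise ValueError("densities must be >= 0")


@dataclass
class GrowthFit:
    well: str
    group: str
    K: float
    r: float
    N0: float
    sigma_resid: float
    Tmid: float
    auc_l: float
    auc_e: float
    converged: bool = True

    def metric(self, name: str) -> float:
        if name not in {"K", "r", "N0", "Tmid", "auc_l", "auc_e"}:
            raise KeyError(f"unknown growth metric {name!r}")
        return getattr(self, name)


def logistic(t: np.ndarray, K: float, r: float, N0: float) -> np.ndarray:
    return K / (1.0 + ((K - N0) / N0) * np.exp(-r * np.asarray(t, dtype=float)))


def logistic_auc(K: float, r: float, N0: float, T: float) -> float:
    """Closed-form integral of the logistic curve over [0, T]."""
    if N0 == K:
        return K * T
    return (K / r) * np.log((K + N0 * (np.exp(r * T) - 1.0)) / K)


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    K0 = float(y.max())
    pos = y[y > 0]
    N0_0 = float(pos[0]) if pos.size else 1e-3
    N0_0 = min(N0_0, 0.5 * K0) if K0 > 0 else N0_0
    # early-phase log-linear slope as the rate guess
    early = y > 0
    ne = min(max(int(early.sum() // 2), 3), int(early.sum()))
    te, ye = t[early][:ne], y[early][:ne]
    if ne >= 2 and np.ptp(te) > 0:
        slope = np.polyfit(te, np.log(ye), 1)[0]
        r0 = float(abs(slope)) or 0.1
    else:
        r0 = 0.1
    return K0, r0, N0_0


def fit_logistic(curve: GrowthCurve, max_nfev: int = 10_000) -> GrowthFit:
    """Least-squares logistic fit with derived growth metrics.

    Raises on all-nonpositive data; a fit that fails to converge is
    returned flagged (``converged=False``) rather than raised, so batch
    processing can report diagnostics.
    """
    t, y = curve.times, curve.densities
    if not (y > 0).any():
        raise ValueError(f"well {curve.well}: no positive densities")
    if np.allclose(y, y[0]):
        raise ValueError(f"well {curve.well}: densities are constant")
    K0, r0, N0_0 = _initial_guess(t, y)

    def resid(p: np.ndarray) -> np.ndarray:
        return logistic(t, *p) - y

    sol = optimize.least_squares(
        resid,
        x0=[K0, r0, max(N0_0, 1e-9)],
        bounds=([1e-12, 1e-12, 1e-12], [np.inf, np.inf, np.inf]),
        xtol=1e-8, ftol=1e-12, gtol=1e-12,
        max_nfev=max_nfev,
    )
    K, r, N0 = map(float, sol.x)
    converged = bool(sol.success) and N0 < K
    if not converged:
        logger.warning("well %s: logistic fit did not converge (%s)",
                       curve.well, sol.message)
    T = float(t[-1])
    resid_sd = float(np.std(sol.fun, ddof=min(3, len(t) - 1)))
    tmid = float(np.log((K - N0) / N0) / r) if 0 < N0 < K else np.nan
    return GrowthFit(
        well=curve.well,
        group=curve.group,
        K=K, r=r, N0=N0,
        sigma_resid=resid_sd,
        Tmid=tmid,
        auc_l=float(logistic_auc(K, r, N0, T)),
        auc_e=float(np.trapezoid(y, t)),
        converged=converged,
    )


def fit_table(curves: pd.DataFrame) -> pd.DataFrame:
    """Fit every well in a long-format table (well, group, time_h, od)."""
    rows = []
    for (well, group), sub in curves.groupby(["well", "group"], sort=True):
        sub = sub.sort_values("time_h")
        fit = fit_logistic(
            GrowthCurve(well, group, sub["time_h"].to_numpy(), sub["od"].to_numpy())
        )
        rows.append(vars(fit))
    return pd.DataFrame(rows)


@dataclass
class AlleleComparison:
    metric: str
    t_stat: float
    p_value: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    degenerate: bool = False


def compare_alleles(
    fits_a: list[GrowthFit] | pd.DataFrame,
    fits_b: list[GrowthFit] | pd.DataFrame,
    metric: str = "auc_l",
) -> AlleleComparison:
    """Pooled-variance two-sided Student's t-test on a growth metric.

    Zero pooled variance with equal means yields t = 0, p = 1; with
    unequal means the comparison is flagged degenerate (t infinite).
    """
    va = _metric_values(fits_a, metric)
    vb = _metric_values(fits_b, metric)
    if va.size < 2 or vb.size < 2:
        raise ValueError("need >= 2 fits per group")
    if np.var(va, ddof=1) == 0 and np.var(vb, ddof=1) == 0:
        if va.mean() == vb.mean():
            return AlleleComparison(metric, 0.0, 1.0, float(va.mean()),
                                    float(vb.mean()), va.size, vb.size)
        return AlleleComparison(metric, np.inf if va.mean() > vb.mean() else -np.inf,
                                0.0, float(va.mean()), float(vb.mean()),
                                va.size, vb.size, degenerate=True)
    t_stat, p = stats.ttest_ind(va, vb, equal_var=True)
    return AlleleComparison(
        metric, float(t_stat), float(p),
        float(va.mean()), float(vb.mean()), va.size, vb.size,
    )


def _metric_values(fits, metric: str) -> np.ndarray:
    if isinstance(fits, pd.DataFrame):
        if metric not in fits.columns:
            raise KeyError(f"unknown growth metric {metric!r}")
        return fits[metric].to_numpy(dtype=float)
    return np.array([f.metric(metric) for f in fits], dtype=float)
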