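"""Kaplan-Meier estimation and log-rank comparison for calf survival.

At tied times deaths are processed before censorings (the usual
product-limit convention), so a record censored at an event time still
counts in the at-risk set of that event.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KMCurve",
    "kaplan_meier",
    "survival_at",
    "logrank_test",
    "mortality_table",
    "plot_km",
]

DEFAULT_DAYS = (6, 10, 20, 50, 102, 202, 300)


@dataclass
class KMCurve:
    """Product-limit estimate at each distinct event time."""

    times: np.ndarray
    n_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    greenwood_se: np.ndarray

    def __post_init__(self) -> None:
        s = self.survival
        if s.size and (np.any(np.diff(s) > 1e-12) or s.min() < -1e-12 or s.max() > 1 + 1e-12):
            raise ValueError("survival curve must be non-increasing in [0, 1]")


def _check(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if time.size == 0:
        raise ValueError("need at least one record")
    if time.size != event.size:
        raise ValueError("time/event length mismatch")
    if np.any(time <= 0):
        raise ValueError("times must be positive")
    return time, event


def kaplan_meier(time, event) -> KMCurve:
    """Kaplan-Meier curve from times and death indicators.

    ``event`` is True for a death, False for right-censoring.  Greenwood's
    formula gives the standard error of the survival estimate.
    """
    time, event = _check(time, event)
    n = time.size
    times = np.unique(time[event])
    n_risk = np.empty(times.size, dtype=int)
    n_events = np.empty(times.size, dtype=int)
    for k, t in enumerate(times):
        n_risk[k] = int((time >= t).sum())
        n_events[k] = int(((time == t) & event).sum())
    frac = 1.0 - n_events / n_risk
    survival = np.cumprod(frac)
    # Greenwood: var(S) = S^2 * sum d/(n(n-d))
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = n_events / (n_risk * (n_risk - n_events))
    inc = np.where(np.isfinite(inc), inc, 0.0)
    se = survival * np.sqrt(np.cumsum(inc))
    return KMCurve(
        times=times, n_risk=n_risk, n_events=n_events, survival=survival,
        greenwood_se=se,
    )


def survival_at(curve: KMCurve, t: float) -> float:
    """Right-continuous step evaluation of the curve at time ``t``."""
    if t < 0:
        raise ValueError("t must be >= 0")
    k = np.searchsorted(curve.times, t, side="right")
    return 1.0 if k == 0 else float(curve.survival[k - 1])


def logrank_test(time_a, event_a, time_b, event_b):
    """Two-group log-rank test.

    Returns ``(chi2, p)`` with one degree of freedom.  With no events in
    either group the statistic is 0 and p = 1.  P-values that underflow are
    reported at the smallest positive double rather than 0.
    """
    ta, ea = _check(time_a, event_a)
    tb, eb = _check(time_b, event_b)
    time = np.concatenate([ta, tb])
    event = np.concatenate([ea, eb])
    in_a = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])
    times = np.unique(time[event])
    if times.size == 0:
        return 0.0, 1.0
    u = 0.0
    v = 0.0
    for t in times:
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & in_a).sum())
        d = int(((time == t) & event).sum())
        d1 = int(((time == t) & event & in_a).sum())
        u += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1.0 - n1 / n) * (n - d) / (n - 1)
    if v <= 0:
        return 0.0, 1.0
    chi2 = u * u / v
    p = float(stats.chi2.sf(chi2, df=1))
    p = max(p, np.finfo(float).tiny)
    return float(chi2), p


def mortality_table(curve: KMCurve, days=DEFAULT_DAYS) -> pd.DataFrame:
    """Survival and mortality (1 - S) at each queried day."""
    days = list(days)
    if any(d <= 0 for d in days):
        raise ValueError("days must be positive")
    surv = [survival_at(curve, d) for d in days]
    return pd.DataFrame(
        {"day": days, "survival": surv, "mortality": [1.0 - s for s in surv]}
    )


def records_by_group(records: pd.DataFrame, group: str):
    sub = records[records["group"] == group]
    return sub["time"].to_numpy(), sub["event"].to_numpy(dtype=bool)


def plot_km(curves: dict, path=None):
    """Step plot of one curve per labelled group (optional matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        x = np.concatenate([[0.0], curve.times])
        y = np.concatenate([[1.0], curve.survival])
        ax.step(x, y, where="post", label=label)
    ax.set_xlabel("age (days)")
    ax.set_ylabel("survival")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
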