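"""Turnbull nonparametric MLE of the time-to-surgery distribution.

Each observation is an interval ``(L, U]`` containing the event time (a
surgery on inpatient day N gives ``(N-1, N]``; right censoring at the horizon
gives ``(7, inf)``).  The NPMLE places probability mass only on the "innermost"
(Turnbull) intervals ``(q, p]`` -- ``q`` a left endpoint, ``p`` the smallest
right endpoint above it with no other endpoint strictly between -- and is
found by Turnbull's self-consistency EM, whose log-likelihood is monotone
non-decreasing across iterations.

The cumulative probability is uniquely defined outside the support intervals
and evaluated right-continuously; the day-level probabilities the analysis
reports (surgery within 2, 4, 7 days) fall on support boundaries for day-grid
data, where every interval-censored NPMLE coincides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class NPMLECurve:
    """Turnbull support intervals ``(q, p]`` with probability masses.

    An infinite last support collects the mass of observations censored beyond
    the horizon (``deficit``); interior masses plus the deficit sum to one.
    """

    supports: np.ndarray  # (J, 2) array of (q, p]
    masses: np.ndarray
    label: str | None = None
    n_obs: int = 0
    n_iter: int = 0
    loglik: float = np.nan

    @property
    def deficit(self) -> float:
        inf = np.isinf(self.supports[:, 1])
        return float(self.masses[inf].sum())

    def cdf_dataframe(self, times=None) -> pd.DataFrame:
        """CDF evaluated at integer days (default: horizon day grid)."""
        if times is None:
            hi = self.supports[np.isfinite(self.supports[:, 1]), 1]
            tmax = int(np.ceil(hi.max())) if hi.size else 0
            times = np.arange(0, tmax + 1)
        return pd.DataFrame({"time": times,
                             "cdf": [cdf_at(self, t) for t in times]})


def _as_intervals(lower, upper):
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if lower.size == 0:
        raise ValueError("no observations")
    if np.any(lower > upper):
        raise ValueError("interval bounds must satisfy L <= U")
    exact = lower == upper
    # an exact time t is the degenerate interval (t-, t]
    lower = np.where(exact, np.nextafter(lower, -np.inf), lower)
    return lower, upper


def turnbull_support(lower, upper) -> np.ndarray:
    """Innermost (Turnbull) intervals of the data ``{(L_i, U_i]}``.

    Exact observations may be encoded with ``L == U``.  Returns an ordered
    (J, 2) array of disjoint intervals ``(q, p]``.
    """
    lower, upper = _as_intervals(lower, upper)
    lefts = np.unique(lower)
    rights = np.unique(upper)
    out = []
    for q in lefts:
        above = rights[rights > q]
        if above.size == 0:
            continue
        p = above[0]
        # innermost: no left endpoint strictly inside (q, p)
        if np.any((lefts > q) & (lefts < p)):
            continue
        out.append((q, p))
    if not out:
        raise ValueError("no Turnbull support interval (degenerate data)")
    return np.asarray(out)


def fit_npmle(lower, upper, label: str | None = None, tol: float = 1e-8,
              max_iter: int = 100_000) -> NPMLECurve:
    """Self-consistency EM on the Turnbull supports.

    Iterates until the largest change in any mass is below ``tol``; raises on
    non-convergence with iteration diagnostics.
    """
    lower_a, upper_a = _as_intervals(lower, upper)
    if not np.any(np.isfinite(upper_a)):
        raise ValueError("need at least one non-right-censored observation")
    supports = turnbull_support(lower, upper)
    n = len(lower_a)
    # membership: support (q, p] inside observation (L, U]
    alpha = (supports[None, :, 0] >= lower_a[:, None] - 0.0) & \
            (supports[None, :, 1] <= upper_a[:, None])
    alpha = alpha.astype(float)
    if np.any(alpha.sum(axis=1) == 0):
        raise ValueError("an observation covers no support interval")
    J = len(supports)
    p = np.full(J, 1.0 / J)
    ll = -np.inf
    for it in range(1, max_iter + 1):
        denom = alpha @ p
        ll = float(np.log(denom).sum())
        p_new = p * (alpha / denom[:, None]).mean(axis=0)
        p_new /= p_new.sum()
        delta = np.max(np.abs(p_new - p))
        p = p_new
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"Turnbull EM did not converge in {max_iter} iterations "
            f"(last max mass change {delta:.3e})")
    denom = alpha @ p
    ll = float(np.log(denom).sum())
    return NPMLECurve(supports=supports, masses=p, label=label, n_obs=n,
                      n_iter=it, loglik=ll)


def cdf_at(curve: NPMLECurve, t: float) -> float:
    """Cumulative probability of surgery by time ``t`` (right-continuous).

    Defined as the total mass of supports wholly at or below ``t``; raises if
    ``t`` falls strictly inside a support interval, where the NPMLE is not
    unique (the bounds are reported in the message).
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    inside = (curve.supports[:, 0] < t) & (t < curve.supports[:, 1])
    if np.any(inside):
        q, p = curve.supports[np.where(inside)[0][0]]
        raise ValueError(
            f"CDF is not uniquely defined inside the support interval "
            f"({q:g}, {p:g}]; evaluate at its bounds instead")
    return float(curve.masses[curve.supports[:, 1] <= t].sum())


def npmle_from_days(n_days, horizon: int = 7, label: str | None = None,
                    **kwargs) -> NPMLECurve:
    """Fit the NPMLE from inpatient days of surgery: day N becomes the
    interval ``(N-1, N]``, days beyond the horizon ``(horizon, inf)``."""
    n = np.asarray(n_days, dtype=float)
    if np.any(n < 1):
        raise ValueError("inpatient day of surgery must be >= 1")
    right = n > horizon
    lower = np.where(right, float(horizon), n - 1.0)
    upper = np.where(right, np.inf, n)
    return fit_npmle(lower, upper, label=label, **kwargs)


def curves_by_group(cohort: pd.DataFrame, group_col: str = "demand_category",
                    day_col: str = "surgery_inpatient_day",
                    horizon: int = 7) -> dict[str, NPMLECurve]:
    """One NPMLE curve per demand group (the unadjusted cumulative-probability
    curves of the analysis)."""
    out = {}
    for g, sub in cohort.groupby(group_col, observed=True, sort=True):
        out[str(g)] = npmle_from_days(sub[day_col].to_numpy(), horizon=horizon,
                                      label=str(g))
    return out


def plot_curves(curves: dict[str, NPMLECurve], ax=None, horizon: int = 7):
    """Step plot of the group CDFs at integer days (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    days = np.arange(0, horizon + 1)
    for name, curve in curves.items():
        vals = [cdf_at(curve, t) for t in days]
        ax.step(days, vals, where="post", label=name)
    ax.set_xlabel("days since admission")
    ax.set_ylabel("cumulative probability of surgery")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax
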