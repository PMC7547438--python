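"""Interval-censored log-normal accelerated failure time model.

Time to surgery ``T`` (days since admission) follows

    log T = x'beta + b0 + b1 * d + sigma * eps,     eps ~ N(0, 1),

where ``x`` holds an intercept, indicators for the demand category (reference:
benchmark) and the adjustment covariates; ``b0`` is a hospital random
intercept and ``b1`` a hospital random slope on the ordinal demand score
``d`` in {0,1,2,3}; ``b0``, ``b1`` are independent zero-mean normals with
standard deviations ``tau0``, ``tau1``.

Surgery on inpatient day ``N`` is observed only as ``T`` in the interval
``(N-1, N]``; day 1 gives a left-censored observation (log lower bound is
``-inf``); surgery after the censoring horizon (default 7 days) is
right-censored at the horizon.  Each hospital's marginal likelihood integrates
the product of interval probabilities

    Phi((log U - eta) / sigma) - Phi((log L - eta) / sigma)

over the random effects; the integral is evaluated by (optionally adaptive)
Gauss-Hermite quadrature, tensor-product in two dimensions.

A coefficient ``beta_k`` multiplies the median time by ``exp(beta_k)``; the
percent change in the median is ``(exp(beta_k) - 1) * 100``.  Uncertainty is
reported from the model-based covariance (inverse observed information) and a
hospital-clustered sandwich covariance ``A^{-1} B A^{-1}`` with the small-
sample factor ``G / (G - 1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import log_ndtr, logsumexp

from .demand_metric import CATEGORIES, CATEGORY_SCORE

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))
RANDOM_EFFECTS = ("none", "intercept", "intercept_slope")

#: adjustment covariates of the full model (episode-table column names)
DEFAULT_COVARIATES = [
    "age_group", "sex", "prefracture_status", "admission_timing",
    "admission_status", "preop_transfer", "preop_procedure",
    "medical_reason_for_delay", "hospital_type", "fracture_type",
    "procedure_type", "era", "province",
]


# ---------------------------------------------------------------------------
# censoring intervals
# ---------------------------------------------------------------------------

def build_interval(n_day: int, horizon: int = 7) -> tuple[float, float, str]:
    """Censoring interval ``(L, U]`` in days for surgery on inpatient day N.

    Returns ``(L, U, kind)`` with kind in {"interval", "left", "right"}:
    day 1 is left-censored at 1 (``log 0`` is ``-inf``), days 2..horizon are
    the interval ``(N-1, N]``, later surgery is right-censored at the horizon.
    """
    if n_day < 1:
        raise ValueError("inpatient day of surgery must be >= 1")
    if n_day > horizon:
        return (float(horizon), np.inf, "right")
    if n_day == 1:
        return (0.0, 1.0, "left")
    return (float(n_day - 1), float(n_day), "interval")


def build_intervals(n_days, horizon: int = 7) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised log-scale bounds for inpatient days of surgery.

    Returns ``(log_lower, log_upper)``; ``-inf`` lower bound for day-1
    (left-censored) rows and ``+inf`` upper bound for right-censored rows.
    """
    n = np.asarray(n_days, dtype=float)
    if np.any(~np.isfinite(n)) or np.any(n < 1):
        raise ValueError("inpatient day of surgery must be a finite integer >= 1")
    right = n > horizon
    lower = np.where(right, float(horizon), n - 1.0)
    upper = np.where(right, np.inf, n)
    with np.errstate(divide="ignore"):
        return np.log(lower), np.log(upper)


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignInfo:
    """Covariate coding of a fit: per term, the level list (first = reference)."""

    terms: list[tuple[str, list]]
    names: list[str]

    def encode(self, df: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(df))]
        for col, levels in self.terms:
            vals = df[col]
            unseen = set(pd.unique(vals.dropna())) - set(levels)
            if unseen:
                raise ValueError(f"unseen level(s) {unseen!r} for covariate {col!r}")
            for lev in levels[1:]:
                cols.append((vals == lev).to_numpy(dtype=float))
        return np.column_stack(cols)

    def encode_profile(self, profile: dict) -> np.ndarray:
        row = [1.0]
        for col, levels in self.terms:
            if col not in profile:
                raise ValueError(f"profile is missing covariate {col!r}")
            if profile[col] not in levels:
                raise ValueError(
                    f"unseen level {profile[col]!r} for covariate {col!r}")
            row.extend(float(profile[col] == lev) for lev in levels[1:])
        return np.asarray(row)


def _levels_of(series: pd.Series, fixed: tuple | None = None) -> list:
    if fixed is not None:
        return [lev for lev in fixed if lev in set(series.unique())] or list(fixed)
    vals = pd.unique(series.dropna())
    if series.dtype == bool or set(vals) <= {True, False}:
        return [False, True]
    return sorted(vals, key=str)


def build_design(
    df: pd.DataFrame,
    covariates: list[str] | None = None,
    demand_col: str | None = "demand_category",
) -> DesignInfo:
    """Build the covariate coding: intercept, demand indicators (benchmark
    reference, fixed order), then dummies for each listed covariate with the
    first (sorted) level as reference.  Single-level covariates are dropped."""
    terms: list[tuple[str, list]] = []
    names = ["intercept"]
    if demand_col is not None:
        levels = _levels_of(df[demand_col], fixed=CATEGORIES)
        terms.append((demand_col, levels))
        names += [f"demand[{c}]" for c in levels[1:]]
    for col in covariates or []:
        levels = _levels_of(df[col])
        if df[col].nunique(dropna=True) < 2:
            logger.info("covariate %r has a single level; dropped from design", col)
            continue
        terms.append((col, levels))
        names += [f"{col}[{lev}]" for lev in levels[1:]]
    return DesignInfo(terms=terms, names=names)


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------

@dataclass
class IntervalData:
    """Observations sorted by cluster, ready for likelihood evaluation.

    ``log_lower``/``log_upper`` are log-day bounds (``-inf``/``+inf`` encode
    left/right censoring); rows with ``is_exact`` carry an exactly observed
    log-time in both bounds.  ``cluster`` holds contiguous integer hospital
    codes and ``demand_score`` the ordinal score multiplying the random slope.
    """

    log_lower: np.ndarray
    log_upper: np.ndarray
    is_exact: np.ndarray
    X: np.ndarray
    cluster: np.ndarray
    demand_score: np.ndarray
    names: list[str]
    cluster_labels: np.ndarray
    design: DesignInfo | None = None

    def __post_init__(self):
        self.n_obs = len(self.log_lower)
        self.n_clusters = int(self.cluster.max()) + 1 if self.n_obs else 0
        # rows are sorted by cluster; segment starts for fast per-cluster sums
        self.starts = np.searchsorted(self.cluster, np.arange(self.n_clusters))
        self.has_exact = bool(np.any(self.is_exact))
        bad = ~self.is_exact & (self.log_lower >= self.log_upper)
        if np.any(bad):
            raise ValueError("interval bounds must satisfy L < U")
        const = [self.names[j] for j in range(1, self.X.shape[1])
                 if np.ptp(self.X[:, j]) == 0.0]
        if const:
            raise ValueError(
                f"design column(s) {const} are constant (separation or a "
                "level absent from the data)")

    @classmethod
    def from_arrays(cls, log_lower, log_upper, X, cluster, demand_score=None,
                    is_exact=None, names=None, design=None) -> "IntervalData":
        log_lower = np.asarray(log_lower, dtype=float)
        log_upper = np.asarray(log_upper, dtype=float)
        X = np.asarray(X, dtype=float)
        labels, codes = np.unique(np.asarray(cluster), return_inverse=True)
        order = np.argsort(codes, kind="stable")
        n = len(log_lower)
        demand_score = (np.zeros(n) if demand_score is None
                        else np.asarray(demand_score, dtype=float))
        is_exact = (np.zeros(n, dtype=bool) if is_exact is None
                    else np.asarray(is_exact, dtype=bool))
        return cls(
            log_lower=log_lower[order], log_upper=log_upper[order],
            is_exact=is_exact[order], X=X[order], cluster=codes[order],
            demand_score=demand_score[order],
            names=list(names) if names else [f"x{j}" for j in range(X.shape[1])],
            cluster_labels=labels, design=design)

    @classmethod
    def from_episodes(
        cls,
        cohort: pd.DataFrame,
        covariates: list[str] | None = None,
        demand_col: str | None = "demand_category",
        cluster_col: str = "index_hospital_id",
        day_col: str = "surgery_inpatient_day",
        horizon: int = 7,
    ) -> "IntervalData":
        """Build model data from an episode table carrying the inpatient day
        of surgery, the demand category and the adjustment covariates."""
        design = build_design(cohort, covariates, demand_col)
        X = design.encode(cohort)
        lo, up = build_intervals(cohort[day_col].to_numpy(), horizon=horizon)
        score = (cohort[demand_col].astype(str).map(CATEGORY_SCORE).to_numpy()
                 if demand_col is not None else None)
        return cls.from_arrays(lo, up, X, cohort[cluster_col].to_numpy(),
                               demand_score=score, names=design.names,
                               design=design)


# ---------------------------------------------------------------------------
# observation-level log-probabilities
# ---------------------------------------------------------------------------

def _obs_logp(eta: np.ndarray, sigma: float, data: IntervalData,
              derivs: bool = False):
    """Log interval probability per observation, optionally with first and
    second derivatives with respect to the linear predictor ``eta``."""
    with np.errstate(invalid="ignore"):
        zl = (data.log_lower - eta) / sigma
        zu = (data.log_upper - eta) / sigma
        flip = (zl + zu) > 0  # evaluate in the smaller tail
    a = np.where(flip, -zu, zl)
    b = np.where(flip, -zl, zu)
    la = log_ndtr(a)
    lb = log_ndtr(b)
    with np.errstate(divide="ignore", invalid="ignore"):
        # la = -inf (open lower bound) gives exp(-inf) = 0, i.e. logp = lb
        logp = lb + np.log1p(-np.exp(np.minimum(la - lb, 0.0)))

    if data.has_exact:
        z = zl  # lower == upper == log t for exact rows
        logp = np.where(data.is_exact,
                        -np.log(sigma) - 0.5 * _LOG2PI - 0.5 * z * z, logp)
    if not derivs:
        return logp

    with np.errstate(invalid="ignore", over="ignore"):
        lpdf_l = -0.5 * zl * zl - 0.5 * _LOG2PI
        lpdf_u = -0.5 * zu * zu - 0.5 * _LOG2PI
        el = np.where(np.isfinite(zl), np.exp(lpdf_l - logp), 0.0)
        eu = np.where(np.isfinite(zu), np.exp(lpdf_u - logp), 0.0)
        d1 = (el - eu) / sigma
        tl = np.where(np.isfinite(zl), zl, 0.0) * el
        tu = np.where(np.isfinite(zu), zu, 0.0) * eu
        d2 = (tl - tu) / sigma**2 - d1 * d1
    if data.has_exact:
        d1 = np.where(data.is_exact, zl / sigma, d1)
        d2 = np.where(data.is_exact, -1.0 / sigma**2, d2)
    return logp, d1, d2


# ---------------------------------------------------------------------------
# marginal likelihood (Gauss-Hermite over random effects)
# ---------------------------------------------------------------------------

def _re_dim(random_effects: str) -> int:
    if random_effects not in RANDOM_EFFECTS:
        raise ValueError(f"random_effects must be one of {RANDOM_EFFECTS}")
    return {"none": 0, "intercept": 1, "intercept_slope": 2}[random_effects]


def split_params(theta: np.ndarray, n_beta: int, random_effects: str):
    """Unpack ``theta = (beta, log sigma, log tau...)``."""
    r = _re_dim(random_effects)
    beta = np.asarray(theta[:n_beta], dtype=float)
    sigma = float(np.exp(theta[n_beta]))
    tau = np.exp(np.asarray(theta[n_beta + 1: n_beta + 1 + r], dtype=float))
    return beta, sigma, tau


@lru_cache(maxsize=16)
def _gh_grid(nodes: int, r: int):
    x, w = np.polynomial.hermite.hermgauss(nodes)
    logw = np.log(w)
    if r == 1:
        X = x[:, None]
        lw = logw
    else:
        g0, g1 = np.meshgrid(x, x, indexing="ij")
        X = np.column_stack([g0.ravel(), g1.ravel()])
        lw = (logw[:, None] + logw[None, :]).ravel()
    return X, lw, (X ** 2).sum(axis=1)


def _segsum(arr: np.ndarray, starts: np.ndarray) -> np.ndarray:
    """Per-cluster sums of the (…, n_obs) array (rows sorted by cluster)."""
    return np.add.reduceat(arr, starts, axis=-1)


def _newton_modes(theta_eta0, sigma, Z, tau, data, m0, max_iter=60, gtol=1e-8):
    """Per-cluster posterior modes and curvatures of
    ``h_g(b) = sum_i log f_i(eta0_i + Z_i b) + log N(b; 0, diag(tau^2))``."""
    G, r = m0.shape
    m = m0.copy()
    cl = data.cluster
    st = data.starts
    inv_tau2 = 1.0 / np.maximum(tau, 1e-10) ** 2
    H = None
    for _ in range(max_iter):
        eta = theta_eta0 + (Z * m[cl]).sum(axis=1)
        _, d1, d2 = _obs_logp(eta, sigma, data, derivs=True)
        g = np.column_stack([
            _segsum(d1 * Z[:, j], st) for j in range(r)
        ]) - m * inv_tau2
        if r == 1:
            h00 = _segsum(d2 * Z[:, 0] ** 2, st) - inv_tau2[0]
            H = h00[:, None, None]
            step = (-g[:, 0] / h00)[:, None]
        else:
            h00 = _segsum(d2 * Z[:, 0] ** 2, st) - inv_tau2[0]
            h11 = _segsum(d2 * Z[:, 1] ** 2, st) - inv_tau2[1]
            h01 = _segsum(d2 * Z[:, 0] * Z[:, 1], st)
            det = h00 * h11 - h01 * h01
            step = np.column_stack([
                -(h11 * g[:, 0] - h01 * g[:, 1]) / det,
                -(h00 * g[:, 1] - h01 * g[:, 0]) / det,
            ])
            H = np.empty((G, 2, 2))
            H[:, 0, 0] = h00
            H[:, 1, 1] = h11
            H[:, 0, 1] = H[:, 1, 0] = h01
        step = np.clip(step, -4.0, 4.0)
        m = m + step
        if np.max(np.abs(g)) < gtol:
            break
    return m, H


def cluster_loglik(
    theta: np.ndarray,
    data: IntervalData,
    random_effects: str = "intercept",
    nodes: int = 9,
    adaptive: bool = True,
    mode_cache: dict | None = None,
) -> np.ndarray:
    """Per-hospital marginal log-likelihood contributions at ``theta``."""
    r = _re_dim(random_effects)
    beta, sigma, tau = split_params(theta, data.X.shape[1], random_effects)
    eta0 = data.X @ beta
    G = data.n_clusters
    if r == 0:
        logp = _obs_logp(eta0, sigma, data)
        return _segsum(logp, data.starts)

    Z = np.ones((data.n_obs, 1)) if r == 1 else np.column_stack(
        [np.ones(data.n_obs), data.demand_score])
    grid, logw, sq = _gh_grid(nodes, r)
    tau_safe = np.maximum(tau, 1e-8)

    if adaptive:
        m0 = (mode_cache or {}).get("m")
        if m0 is None or m0.shape != (G, r):
            m0 = np.zeros((G, r))
        m, H = _newton_modes(eta0, sigma, Z, tau_safe, data, m0)
        if mode_cache is not None:
            mode_cache["m"] = m
        if r == 1:
            scale = np.sqrt(-1.0 / H[:, 0, 0])[:, None, None]  # (G,1,1) chol
            L = scale
            logdetL = np.log(L[:, 0, 0])
        else:
            # Cholesky of inv(-H) per cluster, closed form for 2x2
            a = -H[:, 0, 0]
            b = -H[:, 0, 1]
            c = -H[:, 1, 1]
            det = a * c - b * b
            # inv(-H) = [[c, -b], [-b, a]] / det ; chol lower
            i00 = c / det
            i01 = -b / det
            i11 = a / det
            l00 = np.sqrt(i00)
            l10 = i01 / l00
            l11 = np.sqrt(np.maximum(i11 - l10**2, 1e-300))
            L = np.zeros((G, 2, 2))
            L[:, 0, 0] = l00
            L[:, 1, 0] = l10
            L[:, 1, 1] = l11
            logdetL = np.log(l00) + np.log(l11)
    else:
        m = np.zeros((G, r))
        L = np.zeros((G, r, r))
        for j in range(r):
            L[:, j, j] = tau_safe[j]
        logdetL = np.full(G, np.log(tau_safe).sum())

    log_prior_const = -float(np.log(tau_safe).sum()) - 0.5 * r * _LOG2PI
    cl = data.cluster
    # all quadrature points at once: b (K, G, r), eta (K, n_obs)
    b = m[None, :, :] + np.sqrt(2.0) * np.einsum("grs,ks->kgr", L, grid)
    eta = eta0[None, :] + np.einsum("nr,knr->kn", Z, b[:, cl, :])
    logp = _obs_logp(eta, sigma, data)
    lf = _segsum(logp, data.starts)  # (K, G)
    log_prior = log_prior_const - 0.5 * ((b / tau_safe) ** 2).sum(axis=2)
    acc = logw[:, None] + sq[:, None] + lf + log_prior
    return 0.5 * r * np.log(2.0) + logdetL + logsumexp(acc, axis=0)


def loglik(theta, data: IntervalData, random_effects: str = "intercept",
           nodes: int = 9, adaptive: bool = True) -> float:
    """Total marginal log-likelihood at ``theta = (beta, log sigma, log tau)``."""
    lc = cluster_loglik(np.asarray(theta, dtype=float), data, random_effects,
                        nodes, adaptive)
    total = float(lc.sum())
    if not np.isfinite(total):
        bad = np.where(~np.isfinite(lc))[0]
        labels = data.cluster_labels[bad[:5]]
        raise FloatingPointError(
            f"non-finite likelihood in hospital block(s) {list(labels)}")
    return total


# ---------------------------------------------------------------------------
# covariances
# ---------------------------------------------------------------------------

def _num_grad(fun, theta, rel=1e-5):
    theta = np.asarray(theta, dtype=float)
    p = len(theta)
    out = None
    for j in range(p):
        h = rel * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        gp, gm = fun(tp), fun(tm)
        gj = (np.asarray(gp) - np.asarray(gm)) / (2 * h)
        if out is None:
            out = np.empty((p,) + np.shape(gj))
        out[j] = gj
    return out


def observed_information(theta, data, random_effects="intercept", nodes=9,
                         adaptive=True) -> np.ndarray:
    """Numerical observed information ``A = -d^2 loglik / d theta^2``
    (central second differences of the log-likelihood)."""
    cache: dict = {}
    theta = np.asarray(theta, dtype=float)
    p = len(theta)
    h = 1e-4 * np.maximum(1.0, np.abs(theta))

    def f(t):
        return float(cluster_loglik(t, data, random_effects, nodes,
                                    adaptive, cache).sum())

    f0 = f(theta)

    def at(shifts):
        t = theta.copy()
        for j, s in shifts:
            t[j] += s * h[j]
        return f(t)

    fp = np.array([at([(j, 1)]) for j in range(p)])
    fm = np.array([at([(j, -1)]) for j in range(p)])
    H = np.empty((p, p))
    for j in range(p):
        H[j, j] = (fp[j] - 2 * f0 + fm[j]) / h[j] ** 2
        for k in range(j + 1, p):
            fpp = at([(j, 1), (k, 1)])
            fmm = at([(j, -1), (k, -1)])
            H[j, k] = H[k, j] = (
                fpp - fp[j] - fp[k] + 2 * f0 - fm[j] - fm[k] + fmm
            ) / (2 * h[j] * h[k])
    return -H


def cluster_scores(theta, data, random_effects="intercept", nodes=9,
                   adaptive=True) -> np.ndarray:
    """Per-cluster score vectors (G x p) by central differences."""
    cache: dict = {}

    def f(u):
        return cluster_loglik(u, data, random_effects, nodes, adaptive, cache)

    return _num_grad(f, theta).T  # (G, p)


def sandwich_vcov(theta, data, random_effects="intercept", nodes=9,
                  adaptive=True, information: np.ndarray | None = None):
    """Hospital-clustered sandwich covariance ``A^{-1} B A^{-1}`` with the
    small-sample factor ``G / (G - 1)``.  Returns ``(V, A, B)``."""
    G = data.n_clusters
    if G < 2:
        raise ValueError("clustered sandwich estimator needs >= 2 clusters")
    A = (observed_information(theta, data, random_effects, nodes, adaptive)
         if information is None else information)
    S = cluster_scores(theta, data, random_effects, nodes, adaptive)
    B = S.T @ S
    Ainv = np.linalg.pinv(A)
    V = Ainv @ B @ Ainv * (G / (G - 1.0))
    return V, A, B


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class AFTFit:
    """Fitted interval-censored log-normal AFT model."""

    params: np.ndarray
    param_names: list[str]
    sigma: float
    tau: dict
    loglik: float
    vcov_model: np.ndarray
    vcov_sandwich: np.ndarray | None
    n_obs: int
    n_clusters: int
    converged: bool
    message: str
    random_effects: str
    nodes: int
    adaptive: bool
    design: DesignInfo | None = None
    grad_norm: float = np.nan

    @property
    def coef(self) -> pd.Series:
        nb = len(self.param_names) - 1 - len(self.tau)
        return pd.Series(self.params[:nb], index=self.param_names[:nb])

    def beta(self, name: str) -> float:
        return float(self.coef[name])

    def se(self, name: str, kind: str = "sandwich") -> float:
        V = self.vcov_sandwich if kind == "sandwich" else self.vcov_model
        if V is None:
            raise ValueError("requested covariance was not computed")
        j = self.param_names.index(name)
        return float(np.sqrt(V[j, j]))

    def summary(self) -> pd.DataFrame:
        """Coefficient table: estimate, model and sandwich SEs, and the
        percent change in the median with its 95% CI."""
        nb = len(self.coef)
        kind = "sandwich" if self.vcov_sandwich is not None else "model"
        rows = []
        for j, name in enumerate(self.param_names[:nb]):
            se_m = float(np.sqrt(self.vcov_model[j, j]))
            se_s = (float(np.sqrt(self.vcov_sandwich[j, j]))
                    if self.vcov_sandwich is not None else np.nan)
            e = percent_change(self, name, se_kind=kind)
            rows.append({
                "term": name, "coef": self.params[j],
                "se_model": se_m, "se_sandwich": se_s,
                "pct_change": e.pct_change,
                "pct_ci_low": e.ci_low, "pct_ci_high": e.ci_high,
            })
        return pd.DataFrame(rows)


def _start_values(data: IntervalData, r: int) -> np.ndarray:
    lo, up = data.log_lower.copy(), data.log_upper.copy()
    mid = np.where(data.is_exact, lo, 0.5 * (lo + up))
    mid = np.where(np.isneginf(lo), up - 0.5, mid)
    mid = np.where(np.isposinf(up), lo + 0.5, mid)
    beta, *_ = np.linalg.lstsq(data.X, mid, rcond=None)
    resid = mid - data.X @ beta
    sigma0 = max(float(resid.std()), 0.05)
    return np.concatenate([beta, [np.log(sigma0)], np.full(r, np.log(0.1))])


def fit_interval_lognormal(
    data: IntervalData,
    random_effects: str = "intercept",
    nodes: int = 9,
    adaptive: bool = True,
    gtol: float = 1e-5,
    compute_sandwich: bool = True,
    compute_information: bool = True,
    x0: np.ndarray | None = None,
    maxiter: int = 500,
) -> AFTFit:
    """Maximum marginal likelihood fit.

    Optimises ``(beta, log sigma, log tau)`` by BFGS; the unconstrained
    log parameterisation keeps the scale and random-effect SDs positive.
    """
    r = _re_dim(random_effects)
    if r > 0 and data.n_clusters < 2:
        raise ValueError("random effects need at least 2 hospitals")
    if r == 2 and np.ptp(data.demand_score) == 0:
        raise ValueError("random demand slope needs variation in demand score")
    theta0 = _start_values(data, r) if x0 is None else np.asarray(x0, float)
    if x0 is None and r > 0:
        # warm start from a cheap fixed-effects fit: cuts the number of
        # expensive marginal-likelihood iterations substantially
        pre = fit_interval_lognormal(data, random_effects="none", gtol=1e-3,
                                     compute_sandwich=False,
                                     compute_information=False,
                                     x0=theta0[:data.X.shape[1] + 1])
        theta0 = np.concatenate([pre.params, np.full(r, np.log(0.1))])
    cache: dict = {}

    def negll(t):
        return -float(cluster_loglik(t, data, random_effects, nodes, adaptive,
                                     cache).sum())

    def jac(t):
        return _num_grad(negll, t, rel=1e-6)

    res = optimize.minimize(negll, theta0, method="BFGS", jac=jac,
                            options={"gtol": gtol, "maxiter": maxiter})
    theta = res.x
    grad_norm = float(np.max(np.abs(res.jac)))
    # gtol is an absolute gradient bound; accept relative to the data size too
    converged = bool(res.success or grad_norm < gtol * max(1.0, 1e-3 * data.n_obs))
    if not converged:
        logger.warning("optimizer did not converge: %s (|grad|=%.3g)",
                       res.message, grad_norm)

    if compute_information:
        A = observed_information(theta, data, random_effects, nodes, adaptive)
        vcov_model = np.linalg.pinv(A)
    else:
        A = None
        vcov_model = np.full((len(theta), len(theta)), np.nan)
    vcov_sw = None
    if compute_sandwich and data.n_clusters >= 2 and A is not None:
        vcov_sw, _, _ = sandwich_vcov(theta, data, random_effects, nodes,
                                      adaptive, information=A)

    nb = data.X.shape[1]
    names = list(data.names) + ["log_sigma"] + \
        [f"log_tau{i}" for i in range(r)]
    tau = {}
    if r >= 1:
        tau["intercept"] = float(np.exp(theta[nb + 1]))
    if r == 2:
        tau["demand_slope"] = float(np.exp(theta[nb + 2]))
    return AFTFit(
        params=theta, param_names=names, sigma=float(np.exp(theta[nb])),
        tau=tau, loglik=-res.fun, vcov_model=vcov_model, vcov_sandwich=vcov_sw,
        n_obs=data.n_obs, n_clusters=data.n_clusters, converged=converged,
        message=str(res.message), random_effects=random_effects, nodes=nodes,
        adaptive=adaptive, design=data.design, grad_norm=grad_norm)


def fit_aft(
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
    demand_col: str | None = "demand_category",
    random_effects: str = "intercept_slope",
    nodes: int = 9,
    adaptive: bool = True,
    horizon: int = 7,
    **kwargs,
) -> AFTFit:
    """Fit the AFT model from an episode table (see
    :meth:`IntervalData.from_episodes` for the required columns)."""
    data = IntervalData.from_episodes(cohort, covariates=covariates,
                                      demand_col=demand_col, horizon=horizon)
    return fit_interval_lognormal(data, random_effects=random_effects,
                                  nodes=nodes, adaptive=adaptive, **kwargs)


# ---------------------------------------------------------------------------
# effects and medians
# ---------------------------------------------------------------------------

@dataclass
class EffectEstimate:
    """Percent change in median time to surgery for one demand level."""

    term: str
    pct_change: float
    ci_low: float
    ci_high: float
    beta: float
    se: float


def percent_change(fit: AFTFit, term: str, se_kind: str = "sandwich",
                   z: float = 1.96) -> EffectEstimate:
    """Percent change in the median, ``(exp(beta) - 1) * 100``, with a Wald
    CI transformed from the coefficient scale."""
    b = fit.beta(term)
    se = fit.se(term, kind=se_kind)
    return EffectEstimate(
        term=term,
        pct_change=(np.exp(b) - 1.0) * 100.0,
        ci_low=(np.exp(b - z * se) - 1.0) * 100.0,
        ci_high=(np.exp(b + z * se) - 1.0) * 100.0,
        beta=b, se=se)


def predicted_median(fit: AFTFit, profile: dict | None = None,
                     se_kind: str = "sandwich", z: float = 1.96):
    """Median time to surgery ``exp(x' beta)`` in days for a covariate
    profile, with a delta-method CI.  ``profile`` maps each model covariate
    (including the demand column) to a level; an intercept-only model accepts
    ``None``."""
    if fit.design is None:
        if profile:
            raise ValueError("fit carries no design information")
        x = np.zeros(len(fit.coef))
        x[0] = 1.0  # intercept-only prediction
    else:
        x = fit.design.encode_profile(profile or {})
    beta = fit.coef.to_numpy()
    eta = float(x @ beta)
    V = fit.vcov_sandwich if se_kind == "sandwich" else fit.vcov_model
    nb = len(beta)
    # a near-singular information matrix can leave a tiny negative variance
    se_eta = float(np.sqrt(max(x @ V[:nb, :nb] @ x, 0.0)))
    m = float(np.exp(eta))
    return m, m * np.exp(-z * se_eta), m * np.exp(z * se_eta)


def modal_profile(cohort: pd.DataFrame, fit: AFTFit) -> dict:
    """Most frequent level of each model covariate in the cohort (the profile
    at which adjusted medians are reported)."""
    if fit.design is None:
        raise ValueError("fit carries no design information")
    return {col: cohort[col].mode(dropna=True).iloc[0]
            for col, _ in fit.design.terms}
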