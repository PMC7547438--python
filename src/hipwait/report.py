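"""Descriptive and inferential tables of the analysis.

``table_demographics`` tabulates patient, injury and care characteristics
overall and by demand category (counts with column percentages, half-up
rounded to one decimal).  ``analyze_timing`` fits the demand-only and fully
adjusted AFT models -- overall and within the medical-reason-for-delay
subgroups -- and ``table_results`` lays out, per demand level, the number of
surgeries, the median time to surgery with 95% CI, and the unadjusted and
adjusted percent change in the median relative to benchmark demand.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .demand_metric import CATEGORIES
from .interval_model import (DEFAULT_COVARIATES, fit_aft, percent_change,
                             predicted_median, modal_profile)

logger = logging.getLogger(__name__)

#: stratifiers of the descriptive table, in presentation order
DEMOGRAPHIC_VARIABLES = [
    "age_group", "sex", "prefracture_status", "admission_timing",
    "admission_status", "preop_transfer", "preop_procedure",
    "medical_reason_for_delay", "hospital_type", "fracture_type",
    "procedure_type", "era", "province",
]


def round_half_up(x, decimals: int = 1):
    """Decimal rounding with ties away from zero (as in the printed tables)."""
    factor = 10.0 ** decimals
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return float(out) if out.ndim == 0 else out


def _column_block(values: pd.Series, mask: np.ndarray) -> tuple[int, pd.Series]:
    sub = values[mask]
    return len(sub), sub.value_counts()


def table_demographics(
    cohort: pd.DataFrame,
    variables: list[str] | None = None,
    demand_col: str = "demand_category",
) -> pd.DataFrame:
    """Counts and column percentages per stratifier level, overall and by
    demand category.  Percentages are recomputed from the printed counts as a
    consistency audit before the table is returned."""
    variables = DEMOGRAPHIC_VARIABLES if variables is None else variables
    variables = [v for v in variables if v in cohort.columns]
    demand = cohort[demand_col].astype(str)
    groups = {"all": np.ones(len(cohort), dtype=bool)}
    for cat in CATEGORIES:
        mask = (demand == cat).to_numpy()
        if mask.any():
            groups[cat] = mask

    rows = []
    for var in variables:
        vals = cohort[var]
        levels = sorted(pd.unique(vals.dropna()), key=str)
        for lev in levels:
            row = {"variable": var, "level": str(lev)}
            for gname, mask in groups.items():
                n_group = int(mask.sum())
                n = int(((vals == lev) & mask).sum())
                row[f"n_{gname}"] = n
                row[f"pct_{gname}"] = round_half_up(100.0 * n / n_group)
            rows.append(row)
    table = pd.DataFrame(rows)

    # audit: every printed percentage must be recomputable from printed counts
    for gname, mask in groups.items():
        n_group = int(mask.sum())
        expect = round_half_up(100.0 * table[f"n_{gname}"] / n_group)
        if not np.allclose(expect, table[f"pct_{gname}"]):
            raise AssertionError(f"percentage audit failed for column {gname}")
    return table


# ---------------------------------------------------------------------------
# timing models (Table-3-shaped results)
# ---------------------------------------------------------------------------

def analyze_timing(
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
    random_effects: str = "intercept_slope",
    nodes: int = 9,
    adaptive: bool = True,
    horizon: int = 7,
    subgroups: bool = True,
    se_kind: str = "sandwich",
) -> dict:
    """Fit the demand-only and adjusted models overall and, optionally, within
    the with/without medical-reason-for-delay subgroups (which drop the
    medical-reason covariate from the adjustment set)."""
    covariates = DEFAULT_COVARIATES if covariates is None else covariates
    covariates = [c for c in covariates if c in cohort.columns]

    def _one(sub: pd.DataFrame, covs: list[str], label: str):
        if sub["index_hospital_id"].nunique() < 2 and random_effects != "none":
            logger.warning("subgroup %r has <2 hospitals; omitted", label)
            return None
        unadj = fit_aft(sub, covariates=None, random_effects=random_effects,
                        nodes=nodes, adaptive=adaptive, horizon=horizon)
        adj = fit_aft(sub, covariates=covs, random_effects=random_effects,
                      nodes=nodes, adaptive=adaptive, horizon=horizon)
        counts = sub["demand_category"].astype(str).value_counts()
        return {"label": label, "unadjusted": unadj, "adjusted": adj,
                "counts": counts, "cohort": sub, "se_kind": se_kind}

    out = {"overall": _one(cohort, covariates, "overall")}
    if subgroups and "medical_reason_for_delay" in cohort.columns:
        covs_sub = [c for c in covariates if c != "medical_reason_for_delay"]
        flag = cohort["medical_reason_for_delay"].astype(bool)
        for label, mask in (("without_delay_reason", ~flag),
                            ("with_delay_reason", flag)):
            res = _one(cohort.loc[mask], covs_sub, label)
            if res is not None:
                out[label] = res
    return {k: v for k, v in out.items() if v is not None}


def table_results(analyses: dict) -> pd.DataFrame:
    """Per demand level and analysis group: number of surgeries, median days
    (95% CI, from the demand-only model), and unadjusted/adjusted percent
    change in the median versus benchmark demand (reference rows carry 0)."""
    rows = []
    for gname, res in analyses.items():
        unadj, adj = res["unadjusted"], res["adjusted"]
        se_kind = res.get("se_kind", "sandwich")
        demand_levels = [lev for lev in CATEGORIES
                         if lev in set(res["cohort"]["demand_category"].astype(str))]
        ref = demand_levels[0]
        for cat in demand_levels:
            row = {"group": gname, "demand": cat,
                   "n": int(res["counts"].get(cat, 0))}
            m, lo, hi = predicted_median(unadj, {"demand_category": cat},
                                         se_kind=se_kind)
            row.update(median_days=m, median_lo=lo, median_hi=hi)
            if cat == ref:
                row.update(unadj_pct=0.0, unadj_lo=np.nan, unadj_hi=np.nan,
                           adj_pct=0.0, adj_lo=np.nan, adj_hi=np.nan,
                           reference=True)
            else:
                term = f"demand[{cat}]"
                eu = percent_change(unadj, term, se_kind=se_kind)
                ea = percent_change(adj, term, se_kind=se_kind)
                row.update(unadj_pct=eu.pct_change, unadj_lo=eu.ci_low,
                           unadj_hi=eu.ci_high, adj_pct=ea.pct_change,
                           adj_lo=ea.ci_low, adj_hi=ea.ci_high,
                           reference=False)
            rows.append(row)
    return pd.DataFrame(rows)


def format_results_text(table: pd.DataFrame) -> str:
    """Human-readable rendering of :func:`table_results`."""
    lines = []
    for gname, sub in table.groupby("group", sort=False):
        lines.append(f"== {gname} ==")
        for _, r in sub.iterrows():
            med = f"{r.median_days:.1f} ({r.median_lo:.1f} to {r.median_hi:.1f})"
            if r.reference:
                chg = "Reference"
            else:
                chg = (f"unadjusted {r.unadj_pct:+.1f}% "
                       f"({r.unadj_lo:.1f} to {r.unadj_hi:.1f}); "
                       f"adjusted {r.adj_pct:+.1f}% "
                       f"({r.adj_lo:.1f} to {r.adj_hi:.1f})")
            lines.append(f"  {r.demand:<10} n={r.n:<8} median {med} days; {chg}")
    return "\n".join(lines) + "\n"
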