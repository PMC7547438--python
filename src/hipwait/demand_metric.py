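"""Clearance-time demand metric.

Demand for hip fracture surgery at a hospital is summarised, per admission, by
the *clearance time*: the number of days it would take every preoperative
hip-fracture patient present in the hospital on the day of admission to undergo
surgery if the hospital operated at its maximum weekly service rate and no new
patients arrived.  Writing ``Q`` for the preoperative census and ``S`` for the
maximum weekly service rate (largest number of hip fracture surgeries performed
in any single week of the fiscal quarter at that hospital),

    C = Q / (S / 7)     [days].

Clearance time is classified into four demand levels:

    benchmark   C <= 2      (demand clearable within the 2-day benchmark)
    medium      2 < C <= 4
    high        4 < C <= 6
    excessive   C > 6       (7 or more days required)

Fiscal quarters follow the Canadian fiscal year (Q1 = April-June).  Weeks
inside a quarter are consecutive 7-day blocks anchored at the quarter's first
day; the final partial block is counted as a week.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES = ("benchmark", "medium", "high", "excessive")
#: ordinal demand score used for the random-slope term of the AFT model
CATEGORY_SCORE = {c: float(i) for i, c in enumerate(CATEGORIES)}
_BOUNDS = (2.0, 4.0, 6.0)


# ---------------------------------------------------------------------------
# fiscal calendar
# ---------------------------------------------------------------------------

def fiscal_quarter(dates) -> pd.Series:
    """Label each date with its Canadian fiscal quarter, e.g. ``"FY2004Q3"``.

    The fiscal year starts April 1; January-March belong to Q4 of the
    previous fiscal year.
    """
    d = pd.to_datetime(pd.Series(dates))
    month = d.dt.month
    fy = d.dt.year.where(month >= 4, d.dt.year - 1)
    q = (month.where(month >= 4, month + 12) - 4) // 3 + 1
    return "FY" + fy.astype(str) + "Q" + q.astype(str)


def quarter_start(label: str) -> pd.Timestamp:
    """First calendar day of a fiscal-quarter label produced by
    :func:`fiscal_quarter`."""
    fy, q = int(label[2:6]), int(label[-1])
    month = 4 + 3 * (q - 1)
    year = fy
    if month > 12:
        month -= 12
        year += 1
    return pd.Timestamp(year=year, month=month, day=1)


# ---------------------------------------------------------------------------
# maximum weekly service rate
# ---------------------------------------------------------------------------

def hospital_quarter_rates(cohort: pd.DataFrame) -> pd.DataFrame:
    """Maximum weekly service rate ``S`` per hospital and fiscal quarter.

    ``S`` is the largest count of surgeries performed at the hospital within a
    single 7-day week of the quarter (weeks anchored at the quarter start).
    Only hospital-quarters with at least one surgery appear in the table.
    """
    surg = cohort.loc[cohort["surgery_date"].notna()]
    if surg.empty:
        return pd.DataFrame(columns=["hospital_id", "fiscal_quarter", "max_weekly_rate"])
    fq = fiscal_quarter(surg["surgery_date"])
    qstart = fq.map(quarter_start)
    week = ((pd.to_datetime(surg["surgery_date"]) - qstart).dt.days // 7).astype(int)
    counts = (
        pd.DataFrame({
            "hospital_id": surg["index_hospital_id"].to_numpy(),
            "fiscal_quarter": fq.to_numpy(),
            "week": week.to_numpy(),
        })
        .groupby(["hospital_id", "fiscal_quarter", "week"], sort=True)
        .size()
    )
    rates = counts.groupby(level=["hospital_id", "fiscal_quarter"]).max()
    out = rates.rename("max_weekly_rate").reset_index()
    return out


def max_weekly_rate(cohort: pd.DataFrame, hospital_id, fq_label: str) -> int:
    """``S`` for one hospital-quarter.  Raises if no surgery occurred there."""
    table = hospital_quarter_rates(cohort)
    row = table[(table["hospital_id"] == hospital_id) & (table["fiscal_quarter"] == fq_label)]
    if row.empty:
        raise ValueError(
            f"max weekly rate undefined: no surgeries at {hospital_id} in {fq_label}"
        )
    return int(row["max_weekly_rate"].iloc[0])


# ---------------------------------------------------------------------------
# preoperative census
# ---------------------------------------------------------------------------

def preop_census(cohort: pd.DataFrame, hospital_id, day, include_index: bool = True) -> int:
    """Number of preoperative hip-fracture patients present at ``hospital_id``
    on ``day``.

    A patient is present preoperatively on a day ``d`` when
    ``admit_date <= d`` and surgery has not yet happened before ``d``
    (``surgery_date >= d``, or no surgery and ``discharge_date >= d``).
    ``include_index=False`` subtracts the patient admitted that day themself
    (one per call; used for sensitivity analyses).
    """
    day = pd.Timestamp(day)
    sub = cohort[cohort["index_hospital_id"] == hospital_id]
    admit = pd.to_datetime(sub["admit_date"])
    exit_day = pd.to_datetime(sub["surgery_date"]).fillna(pd.to_datetime(sub["discharge_date"]))
    q = int(((admit <= day) & (exit_day >= day)).sum())
    if not include_index:
        q = max(q - 1, 0)
    return q


def _census_for_episodes(cohort: pd.DataFrame, include_index: bool) -> np.ndarray:
    """Vectorised census at each episode's own admission day and hospital."""
    admit = pd.to_datetime(cohort["admit_date"]).to_numpy("datetime64[D]").astype("int64")
    exit_day = (
        pd.to_datetime(cohort["surgery_date"])
        .fillna(pd.to_datetime(cohort["discharge_date"]))
        .to_numpy("datetime64[D]")
        .astype("int64")
    )
    q = np.zeros(len(cohort), dtype=np.int64)
    codes, _ = pd.factorize(cohort["index_hospital_id"], sort=True)
    order = np.argsort(codes, kind="stable")
    bounds = np.searchsorted(codes[order], np.arange(codes.max() + 1 if len(codes) else 0))
    bounds = np.append(bounds, len(order))
    for h in range(len(bounds) - 1):
        idx = order[bounds[h]:bounds[h + 1]]
        if idx.size == 0:
            continue
        a = np.sort(admit[idx])
        e = np.sort(exit_day[idx])
        d = admit[idx]
        # present on d: admitted on or before d, not exited strictly before d
        q[idx] = np.searchsorted(a, d, side="right") - np.searchsorted(e, d, side="left")
    if not include_index:
        q = np.maximum(q - 1, 0)
    return q


# ---------------------------------------------------------------------------
# clearance time
# ---------------------------------------------------------------------------

def categorize(c) -> np.ndarray:
    """Demand category for clearance time(s) ``c`` (boundaries closed on the
    right: C = 2 is still benchmark, C = 4 medium, C = 6 high)."""
    c = np.asarray(c, dtype=float)
    cat = np.select([c <= _BOUNDS[0], c <= _BOUNDS[1], c <= _BOUNDS[2]],
                    CATEGORIES[:3], default=CATEGORIES[3])
    return cat


def clearance_time(q, s):
    """Clearance time ``C = Q / (S/7)`` in days and its demand category.

    ``q`` is the preoperative census; ``s`` the maximum weekly service rate
    (must be >= 1: a hospital-quarter without surgeries has no defined rate).
    Scalars in, scalars out; arrays broadcast.
    """
    q = np.asarray(q, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(s < 1):
        raise ValueError("maximum weekly service rate must be >= 1")
    if np.any(q < 0):
        raise ValueError("census must be nonnegative")
    c = q / (s / 7.0)
    cat = categorize(c)
    if c.ndim == 0:
        return float(c), str(cat)
    return c, cat


def assess_demand(
    cohort: pd.DataFrame,
    include_index: bool = True,
    rates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-episode demand assessment.

    Returns a frame aligned with ``cohort`` holding the census ``Q``, the
    maximum weekly rate ``S`` of the admission hospital in the fiscal quarter
    of admission, the clearance time ``C`` and the demand category.  Episodes
    admitted in a hospital-quarter with no surgeries (rate undefined) get
    missing values and are counted in the log.
    """
    rates = hospital_quarter_rates(cohort) if rates is None else rates
    fq = fiscal_quarter(cohort["admit_date"])
    out = pd.DataFrame(index=cohort.index)
    out["census_q"] = _census_for_episodes(cohort, include_index)
    key = pd.MultiIndex.from_arrays([cohort["index_hospital_id"], fq])
    rate_map = rates.set_index(["hospital_id", "fiscal_quarter"])["max_weekly_rate"]
    out["max_weekly_rate"] = rate_map.reindex(key).to_numpy()
    defined = out["max_weekly_rate"].notna()
    n_undef = int((~defined).sum())
    if n_undef:
        logger.warning(
            "%d episodes admitted in hospital-quarters with no surgeries; "
            "demand undefined for them", n_undef)
    c = np.full(len(out), np.nan)
    c[defined.to_numpy()] = (
        7.0 * out.loc[defined, "census_q"].to_numpy()
        / out.loc[defined, "max_weekly_rate"].to_numpy()
    )
    out["clearance_time"] = c
    cat = np.full(len(out), None, dtype=object)
    cat[defined.to_numpy()] = categorize(c[defined.to_numpy()])
    out["demand_category"] = pd.Categorical(cat, categories=list(CATEGORIES))
    return out
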