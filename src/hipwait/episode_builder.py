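"""Care-episode construction from discharge abstracts and cohort exclusions.

Multiple abstracts with the same patient identifier and contiguous dates --
the next admission on, or within one day of, the previous discharge -- are
combined into one care episode (the hospital-transfer linkage rule; merging is
transitive).  Episode-level covariates come from the abstract containing the
surgery (or the first abstract when none does); the preoperative-transfer flag
is set when the surgery abstract is not the chronologically first one.

The analysis cohort then drops episodes without a surgery date and episodes
treated in a hospital whose annual surgical volume was 24 hip fracture
surgeries or less.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: columns copied to the episode from its representative (surgery) abstract
_CARRIED = [
    "age_group", "sex", "prefracture_status", "admission_timing",
    "admission_status", "preop_procedure", "fracture_type", "procedure_type",
    "hospital_type", "province", "era",
]


def merge_episodes(abstracts: pd.DataFrame, max_gap_days: int = 1) -> pd.DataFrame:
    """Merge same-patient abstracts with contiguous dates into care episodes.

    Two abstracts of one patient belong to the same episode when the later
    admission date is within ``max_gap_days`` of the running latest discharge
    date; the rule chains transitively.  Overlapping stays (an admission
    before the previous discharge) are merged too but logged, as they violate
    the transfer pattern.
    """
    df = abstracts.copy()
    for col in ("admit_date", "discharge_date", "surgery_date"):
        df[col] = pd.to_datetime(df[col])
    if (df["admit_date"] > df["discharge_date"]).any():
        raise ValueError("abstract with admit_date after discharge_date")
    bad_surg = df["surgery_date"].notna() & (
        (df["surgery_date"] < df["admit_date"])
        | (df["surgery_date"] > df["discharge_date"]))
    if bad_surg.any():
        raise ValueError("abstract with surgery_date outside the stay")

    df = df.sort_values(["patient_id", "admit_date", "discharge_date"],
                        kind="mergesort").reset_index(drop=True)
    same_pat = df["patient_id"].eq(df["patient_id"].shift())
    prev_max_disc = (df.groupby("patient_id")["discharge_date"]
                     .cummax().shift())
    gap = (df["admit_date"] - prev_max_disc).dt.days
    n_overlap = int((same_pat & (gap < 0)).sum())
    if n_overlap:
        logger.warning("%d abstracts overlap an earlier stay of the same "
                       "patient; merged, but this is not a transfer pattern",
                       n_overlap)
    new_ep = (~same_pat) | (gap > max_gap_days)
    df["_ep"] = new_ep.cumsum()

    has_surg = df["surgery_date"].notna()
    n_multi_surg = int((has_surg.groupby(df["_ep"]).sum() > 1).sum())
    if n_multi_surg:
        logger.warning("%d episodes contain more than one surgery abstract; "
                       "the earliest surgery is used", n_multi_surg)

    # representative abstract: the (first) one holding the surgery, else first
    rep = (df.assign(_no_surg=~has_surg)
             .sort_values(["_ep", "_no_surg", "admit_date"], kind="mergesort")
             .drop_duplicates("_ep", keep="first")
             .set_index("_ep"))
    agg = df.groupby("_ep").agg(
        patient_id=("patient_id", "first"),
        admit_date=("admit_date", "min"),
        discharge_date=("discharge_date", "max"),
        surgery_date=("surgery_date", "min"),
        n_abstracts=("patient_id", "size"),
        scu_admission=("scu_admission", "any"),
        nice124_condition=("nice124_condition", "any"),
    )
    first_admit = df.groupby("_ep")["admit_date"].min()
    surgery_not_first = rep["admit_date"].gt(first_admit)
    flag_col = (df.groupby("_ep")["preop_transfer"].any()
                if "preop_transfer" in df else False)

    episodes = agg.copy()
    episodes["index_hospital_id"] = rep["hospital_id"]
    for col in _CARRIED:
        if col in rep:
            episodes[col] = rep[col]
    episodes["preop_transfer"] = surgery_not_first | flag_col
    episodes["surgery_inpatient_day"] = (
        (episodes["surgery_date"] - episodes["admit_date"]).dt.days + 1)
    episodes["medical_reason_for_delay"] = (
        episodes["scu_admission"] | episodes["nice124_condition"])
    return episodes.reset_index(drop=True)


def apply_exclusions(
    episodes: pd.DataFrame,
    volume_threshold: int = 24,
) -> tuple[pd.DataFrame, dict]:
    """Apply the cohort exclusions.

    Removes episodes without a surgery date, then episodes whose surgery
    hospital performed ``volume_threshold`` (default 24) or fewer hip fracture
    surgeries in that calendar year.  Returns the analysis cohort and a count
    of each exclusion; cohort size plus exclusions equals the input size.
    """
    log = {"no_surgery": 0, "low_volume_hospital": 0}
    if episodes.empty:
        return episodes.copy(), log
    has_surg = episodes["surgery_date"].notna()
    log["no_surgery"] = int((~has_surg).sum())
    surg = episodes.loc[has_surg].copy()

    year = pd.to_datetime(surg["surgery_date"]).dt.year
    counts = (pd.DataFrame({"h": surg["index_hospital_id"], "y": year})
              .groupby(["h", "y"]).size())
    key = pd.MultiIndex.from_arrays([surg["index_hospital_id"], year])
    vol = counts.reindex(key).to_numpy()
    low = vol <= volume_threshold
    log["low_volume_hospital"] = int(low.sum())
    cohort = surg.loc[~low].reset_index(drop=True)
    logger.info("cohort: %d episodes kept, %d without surgery, %d in "
                "low-volume hospital-years", len(cohort), log["no_surgery"],
                log["low_volume_hospital"])
    return cohort, log


def write_exclusion_log(log: dict, n_input: int, path) -> None:
    """Plain-text exclusion ledger."""
    kept = n_input - sum(log.values())
    lines = [f"episodes in: {n_input}"]
    lines += [f"excluded ({k}): {v}" for k, v in log.items()]
    lines.append(f"analysis cohort: {kept}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
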