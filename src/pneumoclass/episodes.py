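"""Incident pneumonia episode construction.

An admission is a *candidate* when any of its (up to six) discharge diagnoses
matches the pneumonia code set, the discharge falls inside the study window,
the patient is a resident of the region, and the patient is at least 65 years
old at admission.  Candidates are then collapsed into *incident episodes* with
a rolling 30-day rule: only the first of multiple admissions over 30 days for
the same patient is kept — a repeat admitted 30 or fewer days after the most
recent retained episode's admission date belongs to that episode and is
suppressed; 31 days or more starts a new episode.

Eligibility uses the discharge date for the study window (selection is by
discharge) but the admission date for age and for every lookback window.
"""

from __future__ import annotations

import pandas as pd

from .bundle import CohortBundle, split_codes
from .codes import AnalysisConfig, match_series

__all__ = ["find_candidates", "deduplicate", "episode_patient_counts"]


def _whole_year_age(birth: pd.Series, on: pd.Series) -> pd.Series:
    years = on.dt.year - birth.dt.year
    before_birthday = (on.dt.month < birth.dt.month) | (
        (on.dt.month == birth.dt.month) & (on.dt.day < birth.dt.day)
    )
    return years - before_birthday.astype(int)


def find_candidates(bundle: CohortBundle, config: AnalysisConfig) -> pd.DataFrame:
    """Select eligible pneumonia admissions.

    Returns one row per candidate with ``pneumonia_position`` set to
    ``principal`` when the principal diagnosis matches the pneumonia code
    set and ``secondary_only`` otherwise.  Raises ``ValueError`` when a
    candidate's patient record lacks a birth date (age is undefined).
    """
    adm = bundle.admissions
    if adm.empty:
        return _empty_candidates()

    principal_hit = match_series(adm["principal_dx"], config.pneumonia)
    secondary_hit = adm["secondary_dx"].map(
        lambda s: any(config.pneumonia.matches(c) for c in split_codes(s))
    )
    cand = adm[principal_hit | secondary_hit].copy()
    if cand.empty:
        return _empty_candidates()
    cand["pneumonia_position"] = principal_hit[cand.index].map(
        {True: "principal", False: "secondary_only"}
    )

    pats = bundle.patients.set_index("patient_id")
    unknown = sorted(set(cand["patient_id"]) - set(pats.index))
    if unknown:
        raise ValueError(f"candidate admissions reference unknown patients: {unknown}")
    cand = cand.join(pats[["birth_date", "gender", "residence_area", "ses_quintile"]],
                     on="patient_id")
    missing_birth = cand["birth_date"].isna()
    if missing_birth.any():
        bad = cand.loc[missing_birth, "admission_id"].tolist()
        raise ValueError(f"patients without birth_date for admissions: {bad}")

    cand["age_at_admission"] = _whole_year_age(cand["birth_date"], cand["admission_date"])

    start = pd.Timestamp(config.study_start)
    end = pd.Timestamp(config.study_end)
    eligible = (
        (cand["discharge_date"] >= start)
        & (cand["discharge_date"] <= end)
        & (cand["residence_area"] != "outside")
        & (cand["age_at_admission"] >= config.min_age)
    )
    cand = cand[eligible].copy()
    cand["year"] = cand["discharge_date"].dt.year
    cols = [
        "admission_id", "patient_id", "admission_date", "discharge_date", "year",
        "principal_dx", "secondary_dx", "procedures", "discharge_status",
        "icu_contact", "hospital_type", "facility_region", "pneumonia_position",
        "age_at_admission", "gender", "residence_area", "ses_quintile",
    ]
    return cand[cols].reset_index(drop=True)


def _empty_candidates() -> pd.DataFrame:
    cols = [
        "admission_id", "patient_id", "admission_date", "discharge_date", "year",
        "principal_dx", "secondary_dx", "procedures", "discharge_status",
        "icu_contact", "hospital_type", "facility_region", "pneumonia_position",
        "age_at_admission", "gender", "residence_area", "ses_quintile",
    ]
    return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})


def deduplicate(
    candidates: pd.DataFrame, window_days: int = 30
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse candidates into incident episodes with the rolling 30-day rule.

    A candidate is suppressed iff its admission date is ``<= window_days``
    after the admission date of the patient's most recent *retained* episode.
    Same-day ties keep the earlier discharge, then the lexicographically
    smaller admission id, so the result is independent of input row order.

    Returns ``(episodes, suppressed)``; the suppressed frame carries a
    ``suppressed_by`` column naming the retained admission that absorbed it.
    """
    if candidates.empty:
        sup = candidates.copy()
        sup["suppressed_by"] = pd.Series(dtype=object)
        return candidates.copy(), sup

    ordered = candidates.sort_values(
        ["patient_id", "admission_date", "discharge_date", "admission_id"],
        kind="mergesort",
    )
    keep_mask: list[bool] = []
    suppressed_by: list[str | None] = []
    last_pid = None
    last_kept_date = None
    last_kept_id = None
    for pid, adate, aid in zip(
        ordered["patient_id"], ordered["admission_date"], ordered["admission_id"]
    ):
        if pid != last_pid:
            last_pid, last_kept_date, last_kept_id = pid, None, None
        if last_kept_date is not None and (adate - last_kept_date).days <= window_days:
            keep_mask.append(False)
            suppressed_by.append(last_kept_id)
        else:
            keep_mask.append(True)
            suppressed_by.append(None)
            last_kept_date, last_kept_id = adate, aid

    ordered = ordered.assign(_keep=keep_mask, suppressed_by=suppressed_by)
    episodes = (
        ordered[ordered["_keep"]]
        .drop(columns=["_keep", "suppressed_by"])
        .reset_index(drop=True)
    )
    suppressed = (
        ordered[~ordered["_keep"]].drop(columns=["_keep"]).reset_index(drop=True)
    )
    return episodes, suppressed


def episode_patient_counts(episodes: pd.DataFrame) -> tuple[int, int]:
    """(number of episodes, number of distinct patients)."""
    if episodes.empty:
        return 0, 0
    return len(episodes), episodes["patient_id"].nunique()
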