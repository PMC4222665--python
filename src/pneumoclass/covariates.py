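"""Covariate ascertainment, aetiology grouping, outcomes, and cohort summaries.

Lookback conventions:

* comorbidity categories — true iff a matching code appears in any secondary
  diagnosis field of the index admission, or in *any* diagnosis field of a
  prior admission whose admission date lies within the two-year (730-day)
  window before the index admission date;
* COPD and respiratory failure — the same two-year window, prior admissions
  only;
* domiciliary oxygen — any dispensing within 365 days strictly before the
  index admission; influenza vaccination — within 730 days strictly before;
* acute stroke, mechanical ventilation and ICU contact — the index admission
  itself (same-admission severity proxies);
* outcomes — in-hospital death from the discharge status, 30-day death by
  linkage to the mortality register (follow-up starts at the admission
  date), length of stay = discharge (or death) date minus admission date.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bundle import CohortBundle, split_codes, age_band_of
from .codes import AnalysisConfig, COMORBIDITY_CATEGORIES

__all__ = [
    "ascertain_comorbidities",
    "ascertain_exposures",
    "ascertain_severity_and_stroke",
    "assign_aetiology",
    "compute_outcomes",
    "attach_covariates_and_outcomes",
    "summarize_table1",
    "summarize_aetiology",
    "Table1Summary",
    "percent",
    "chi_square",
]


def percent(n: int, total: int, ndigits: int = 1) -> float:
    """A column percentage as printed in cohort tables (one decimal)."""
    if total == 0:
        return float("nan")
    return round(100.0 * n / total, ndigits)


def _dx_long(adm: pd.DataFrame, include_principal: bool) -> pd.DataFrame:
    """Explode an admissions frame into (admission_id, code) rows."""
    rows_id, rows_code = [], []
    for aid, prin, sec in zip(adm["admission_id"], adm["principal_dx"], adm["secondary_dx"]):
        if include_principal and prin:
            rows_id.append(aid)
            rows_code.append(prin)
        for c in split_codes(sec):
            rows_id.append(aid)
            rows_code.append(c)
    return pd.DataFrame({"admission_id": rows_id, "code": rows_code})


def _prior_admissions(
    episodes: pd.DataFrame, bundle: CohortBundle, window_days: int
) -> pd.DataFrame:
    """Prior admissions (any facility) within ``window_days`` before index.

    'Prior' means admission date strictly before the index admission date and
    within the window; all diagnosis fields of such stays count.
    """
    adm = bundle.admissions
    if adm.empty or episodes.empty:
        return pd.DataFrame(columns=["admission_id", "prior_admission_id"])
    m = episodes[["admission_id", "patient_id", "admission_date"]].merge(
        adm[["admission_id", "patient_id", "admission_date", "principal_dx", "secondary_dx"]],
        on="patient_id",
        suffixes=("", "_prior"),
    )
    gap = (m["admission_date"] - m["admission_date_prior"]).dt.days
    m = m[(gap >= 1) & (gap <= window_days)]
    return m.rename(columns={"admission_id_prior": "prior_admission_id"})


def _flags_from_codes(
    episodes: pd.DataFrame,
    prior: pd.DataFrame,
    bundle: CohortBundle,
    codesets: dict,
    include_index_secondary: bool,
) -> pd.DataFrame:
    adm = bundle.admissions.set_index("admission_id")
    flags = pd.DataFrame(False, index=episodes["admission_id"], columns=list(codesets))

    def mark(aid_series: pd.Series, codes: pd.Series) -> None:
        if codes.empty:
            return
        norm = codes.astype(str).str.replace(".", "", regex=False).str.upper()
        for name, cs in codesets.items():
            hit = norm.str.startswith(cs.prefixes)
            hits = set(aid_series[hit])
            if hits:
                flags.loc[flags.index.isin(hits), name] = True

    if include_index_secondary and not episodes.empty:
        idx = adm.loc[episodes["admission_id"]]
        long = _dx_long(idx.reset_index(), include_principal=False)
        mark(long["admission_id"], long["code"])

    if not prior.empty:
        plong = _dx_long(
            prior.rename(
                columns={"principal_dx": "principal_dx", "secondary_dx": "secondary_dx"}
            )[["admission_id", "principal_dx", "secondary_dx"]],
            include_principal=True,
        )
        mark(plong["admission_id"], plong["code"])
    return flags.reset_index(drop=True).set_index(episodes.index)


def ascertain_comorbidities(
    episodes: pd.DataFrame, bundle: CohortBundle, config: AnalysisConfig
) -> pd.DataFrame:
    """Boolean flags for the 14 comorbidity categories plus COPD and
    respiratory failure over the two-year lookback."""
    prior = _prior_admissions(episodes, bundle, config.comorbidity_window_days)
    com = _flags_from_codes(
        episodes, prior, bundle, dict(config.comorbidities), include_index_secondary=True
    )
    # COPD / respiratory failure: previous two years, prior admissions only
    hist = _flags_from_codes(
        episodes,
        prior,
        bundle,
        {"copd_2y": config.copd, "respiratory_failure_2y": config.respiratory_failure},
        include_index_secondary=False,
    )
    com["copd_2y"] = hist["copd_2y"]
    com["respiratory_failure_2y"] = hist["respiratory_failure_2y"]
    com["any_comorbidity"] = com[list(COMORBIDITY_CATEGORIES)].any(axis=1)
    return com


def ascertain_exposures(
    episodes: pd.DataFrame, bundle: CohortBundle, config: AnalysisConfig
) -> pd.DataFrame:
    """Oxygen-therapy (1 year) and influenza-vaccination (2 years) flags."""
    out = pd.DataFrame(index=episodes.index)
    disp = bundle.dispensings
    oxy = disp[disp["drug_class"] == "domiciliary_oxygen"]
    vac = bundle.vaccinations
    flu = vac[vac["vaccine_kind"] == "influenza"]

    def _within(events: pd.DataFrame, date_col: str, window: int) -> pd.Series:
        if events.empty or episodes.empty:
            return pd.Series(False, index=episodes.index)
        m = episodes[["admission_id", "patient_id", "admission_date"]].merge(
            events[["patient_id", date_col]], on="patient_id"
        )
        delta = (m["admission_date"] - m[date_col]).dt.days
        ok = set(m.loc[(delta >= 1) & (delta <= window), "admission_id"])
        return episodes["admission_id"].isin(ok)

    out["oxygen_therapy_1y"] = _within(oxy, "dispensing_date", config.oxygen_window_days)
    out["influenza_vaccination_2y"] = _within(flu, "vaccination_date", config.vaccination_window_days)
    return out


def ascertain_severity_and_stroke(
    episodes: pd.DataFrame, config: AnalysisConfig
) -> pd.DataFrame:
    """Same-admission severity proxies and acute stroke.

    Ventilation comes from the procedure code set (continuous invasive
    mechanical ventilation, 96.7x by default) on the index admission; ICU is
    the admission's ICU-contact flag; acute stroke matches the stroke code
    set in *any* diagnosis field of the index admission.
    """
    out = pd.DataFrame(index=episodes.index)
    out["ventilation_same_admission"] = episodes["procedures"].map(
        lambda s: any(config.ventilation_procedures.matches(c) for c in split_codes(s))
    )
    out["icu_same_admission"] = episodes["icu_contact"].astype(bool)
    out["acute_stroke_same_admission"] = episodes.apply(
        lambda r: (bool(r["principal_dx"]) and config.stroke.matches(r["principal_dx"]))
        or any(config.stroke.matches(c) for c in split_codes(r["secondary_dx"])),
        axis=1,
    ) if not episodes.empty else pd.Series(dtype=bool)
    return out


def assign_aetiology(episodes: pd.DataFrame, config: AnalysisConfig) -> pd.Series:
    """One aetiology category per episode, first match in priority order.

    Specific organisms beat unspecified categories; an episode whose
    diagnoses match no aetiology set at all is labelled ``other`` (a warning
    reports how many such episodes were seen).
    """
    labels = []
    unmatched = 0
    for prin, sec in zip(episodes["principal_dx"], episodes["secondary_dx"]):
        codes = ([prin] if prin else []) + split_codes(sec)
        label = None
        for name, cs in config.aetiology_priority:
            if any(cs.matches(c) for c in codes):
                label = name
                break
        if label is None:
            label = "other"
            unmatched += 1
        labels.append(label)
    if unmatched:
        warnings.warn(
            f"{unmatched} episode(s) matched no aetiology code set; labelled 'other'",
            stacklevel=2,
        )
    return pd.Series(labels, index=episodes.index, dtype=object, name="aetiology")


def compute_outcomes(episodes: pd.DataFrame, bundle: CohortBundle,
                     followup_days: int = 30) -> pd.DataFrame:
    """In-hospital death, death within 30 days of admission, length of stay.

    Raises ``ValueError`` if a linked death date precedes the index
    admission date (a data inconsistency: the patient was admitted after
    death).
    """
    out = pd.DataFrame(index=episodes.index)
    out["in_hospital_death"] = episodes["discharge_status"] == "died"
    out["length_of_stay"] = (
        episodes["discharge_date"] - episodes["admission_date"]
    ).dt.days

    deaths = bundle.deaths.drop_duplicates("patient_id").set_index("patient_id")["death_date"]
    ddate = episodes["patient_id"].map(deaths)
    delta = (ddate - episodes["admission_date"]).dt.days
    bad = delta.notna() & (delta < 0)
    if bad.any():
        ids = episodes.loc[bad, "admission_id"].tolist()
        raise ValueError(f"death date before admission date for admissions: {ids}")
    out["death_within_30d"] = delta.notna() & (delta <= followup_days)
    return out


def attach_covariates_and_outcomes(
    labeled: pd.DataFrame, bundle: CohortBundle, config: AnalysisConfig
) -> pd.DataFrame:
    """Full covariate/outcome vector for a labelled episode frame."""
    parts = [
        labeled,
        ascertain_comorbidities(labeled, bundle, config),
        ascertain_exposures(labeled, bundle, config),
        ascertain_severity_and_stroke(labeled, config),
        compute_outcomes(labeled, bundle, config.death_followup_days),
    ]
    out = pd.concat(parts, axis=1)
    out["aetiology"] = assign_aetiology(labeled, config)
    out["age_band"] = out["age_at_admission"].map(age_band_of)
    out["age_group"] = np.where(out["age_at_admission"] >= 80, "80+", "65-79")
    return out


def chi_square(table: np.ndarray | pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-square on a contingency table, no continuity correction.

    Returns (statistic, dof, p).  For the 2x2 table this is
    n(ad-bc)^2 / (r1 r2 c1 c2).
    """
    stat, p, dof, _ = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(stat), int(dof), float(p)


@dataclass
class Table1Summary:
    """Per-subtype cohort description (counts, column %, chi-square, LOS)."""

    n_by_subtype: dict
    rows: pd.DataFrame          # section, characteristic, per-subtype n/pct, chi2, dof, p
    length_of_stay: pd.DataFrame  # subtype, mean, median
    any_comorbidity_pct: float


_BOOL_ROWS = [
    ("Respiratory conditions", "oxygen_therapy_1y"),
    ("Respiratory conditions", "copd_2y"),
    ("Respiratory conditions", "respiratory_failure_2y"),
    ("Respiratory conditions", "influenza_vaccination_2y"),
    ("Acute stroke (same admission)", "acute_stroke_same_admission"),
    ("Severity (same admission)", "ventilation_same_admission"),
    ("Severity (same admission)", "icu_same_admission"),
    ("Mortality", "in_hospital_death"),
    ("Mortality", "death_within_30d"),
]

_CATEGORICAL_ROWS = [
    ("Gender", "gender"),
    ("Residence", "residence_area"),
    ("Age", "age_band"),
    ("Socioeconomic position", "ses_quintile"),
    ("Type of hospital", "hospital_type"),
]


def _lower_median(values: pd.Series) -> float:
    """Median taking the lower of the two middle values for even counts."""
    v = np.sort(values.to_numpy())
    if len(v) == 0:
        return float("nan")
    return float(v[(len(v) - 1) // 2])


def summarize_table1(cohort: pd.DataFrame, subtypes=("HCAP", "PNP", "CAP")) -> Table1Summary:
    """Per-subtype description of a labelled, covariate-attached cohort.

    Percentages are within-subtype column percentages; chi-square tests the
    subtype x category contingency table (no continuity correction) and is
    skipped with a warning when a subtype column is empty.  Mortality rows
    carry no test, as in the conventional presentation.
    """
    n_by = {s: int((cohort["subtype"] == s).sum()) for s in subtypes}
    some_empty = any(n == 0 for n in n_by.values())
    if some_empty:
        warnings.warn("at least one subtype has no episodes; chi-square skipped", stacklevel=2)

    records = []

    def add_row(section, characteristic, counts, test_counts=None):
        rec = {"section": section, "characteristic": characteristic}
        for s in subtypes:
            rec[f"{s}_n"] = counts[s]
            rec[f"{s}_pct"] = percent(counts[s], n_by[s]) if n_by[s] else float("nan")
        rec["chi2"], rec["dof"], rec["p"] = test_counts if test_counts else (
            float("nan"), 0, float("nan")
        )
        records.append(rec)

    for section, col in _CATEGORICAL_ROWS:
        sub = cohort[cohort[col].notna()]
        levels = sorted(sub[col].unique(), key=str)
        table = np.array(
            [[int(((sub["subtype"] == s) & (sub[col] == lv)).sum()) for s in subtypes]
             for lv in levels]
        )
        test = None
        if not some_empty and table.shape[0] >= 2 and table.sum(axis=1).all() and table.sum(axis=0).all():
            test = chi_square(table)
        for i, lv in enumerate(levels):
            counts = {s: int(table[i, j]) for j, s in enumerate(subtypes)}
            add_row(section, f"{col}={lv}", counts, test if i == 0 else None)

    comorb_sections = [("Comorbidities (previous two years)", c) for c in COMORBIDITY_CATEGORIES]
    for section, col in _BOOL_ROWS + comorb_sections:
        counts = {s: int(((cohort["subtype"] == s) & cohort[col]).sum()) for s in subtypes}
        test = None
        if not some_empty and col not in ("in_hospital_death", "death_within_30d"):
            table = np.array(
                [[counts[s] for s in subtypes], [n_by[s] - counts[s] for s in subtypes]]
            )
            if table.sum(axis=1).all():
                test = chi_square(table)
        add_row(section, col, counts, test)

    los = pd.DataFrame(
        {
            "subtype": list(subtypes),
            "mean": [
                round(float(cohort.loc[cohort["subtype"] == s, "length_of_stay"].mean()), 1)
                if n_by[s] else float("nan")
                for s in subtypes
            ],
            "median": [
                _lower_median(cohort.loc[cohort["subtype"] == s, "length_of_stay"])
                for s in subtypes
            ],
        }
    )
    total = sum(n_by.values())
    any_pct = percent(int(cohort["any_comorbidity"].sum()), total) if total else float("nan")
    return Table1Summary(
        n_by_subtype=n_by,
        rows=pd.DataFrame.from_records(records),
        length_of_stay=los,
        any_comorbidity_pct=any_pct,
    )


def summarize_aetiology(cohort: pd.DataFrame, subtypes=("HCAP", "PNP", "CAP")) -> pd.DataFrame:
    """Aetiology category counts and column percentages per subtype."""
    n_by = {s: int((cohort["subtype"] == s).sum()) for s in subtypes}
    cats = list(dict.fromkeys(cohort["aetiology"])) if not cohort.empty else []
    recs = []
    for cat in cats:
        rec = {"aetiology": cat}
        for s in subtypes:
            n = int(((cohort["subtype"] == s) & (cohort["aetiology"] == cat)).sum())
            rec[f"{s}_n"] = n
            rec[f"{s}_pct"] = percent(n, n_by[s]) if n_by[s] else float("nan")
        recs.append(rec)
    return pd.DataFrame.from_records(recs)
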