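"""The linked multi-registry cohort: tables, CSV round-trip and validation.

A :class:`CohortBundle` holds the seven flat tables that emulate a regional
health-information environment:

* ``patients`` — demographics (birth date, gender, residence area, an
  area-based socio-economic quintile available for the regional capital only);
* ``admissions`` — hospital discharge abstracts with up to six ICD-9-CM
  diagnoses and up to six procedures, discharge status, ICU contact flag,
  hospital type, and a facility-region flag for out-of-region mobility rows;
* ``outpatient`` — dialysis / chemotherapy service dates;
* ``dispensings`` — drug dispensings (domiciliary oxygen is the class used);
* ``vaccinations`` — influenza vaccination dates;
* ``deaths`` — the mortality register (at most one record per person);
* ``population`` — census resident counts per (year, 5-year age band, gender),
  the denominators for incidence rates.

Record linkage across tables is exact on ``patient_id``.  Dates are ISO-8601
calendar dates; all intervals in the pipeline are whole-day differences.
Multi-valued fields (secondary diagnoses, procedures) are pipe-delimited
strings inside one CSV column.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, fields as dc_fields

import pandas as pd

__all__ = [
    "CohortBundle",
    "read_bundle",
    "write_bundle",
    "validate_bundle",
    "split_codes",
    "join_codes",
    "AGE_BANDS",
    "age_band_of",
    "BundleFormatError",
]

GENDERS = ("male", "female")
RESIDENCE_AREAS = ("rome", "province_of_rome", "rest_of_lazio", "outside")
DISCHARGE_STATUSES = ("alive", "died")
HOSPITAL_TYPES = ("public", "teaching", "private")
FACILITY_REGIONS = ("lazio", "other")
SERVICE_KINDS = ("dialysis", "chemotherapy", "other")
DRUG_CLASSES = ("domiciliary_oxygen", "other")
VACCINE_KINDS = ("influenza", "other")
AGE_BANDS = ("65-69", "70-74", "75-79", "80-84", "85-89", "90+")

_SCHEMAS: dict[str, list[str]] = {
    "patients": ["patient_id", "birth_date", "gender", "residence_area", "ses_quintile"],
    "admissions": [
        "admission_id", "patient_id", "admission_date", "discharge_date",
        "principal_dx", "secondary_dx", "procedures", "discharge_status",
        "icu_contact", "hospital_type", "facility_region",
    ],
    "outpatient": ["patient_id", "service_date", "service_kind"],
    "dispensings": ["patient_id", "dispensing_date", "drug_class"],
    "vaccinations": ["patient_id", "vaccination_date", "vaccine_kind"],
    "deaths": ["patient_id", "death_date", "cause_code"],
    "population": ["year", "age_band", "gender", "resident_count"],
}

_DATE_COLS: dict[str, list[str]] = {
    "patients": ["birth_date"],
    "admissions": ["admission_date", "discharge_date"],
    "outpatient": ["service_date"],
    "dispensings": ["dispensing_date"],
    "vaccinations": ["vaccination_date"],
    "deaths": ["death_date"],
    "population": [],
}


class BundleFormatError(ValueError):
    """A registry CSV is structurally unusable (missing column, bad date)."""


def split_codes(cell) -> list[str]:
    """Split a pipe-delimited code field into a list (empty cell -> [])."""
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return []
    s = str(cell).strip()
    return [c for c in s.split("|") if c] if s else []


def join_codes(codes) -> str:
    return "|".join(str(c).strip() for c in codes if str(c).strip())


def age_band_of(age: int) -> str | None:
    """Map a whole-year age to its 5-year band (None below 65)."""
    if age < 65:
        return None
    if age >= 90:
        return "90+"
    lo = 65 + 5 * ((age - 65) // 5)
    return f"{lo}-{lo + 4}"


@dataclass
class CohortBundle:
    """Seven linked registry tables treated as one unit."""

    patients: pd.DataFrame
    admissions: pd.DataFrame
    outpatient: pd.DataFrame
    dispensings: pd.DataFrame
    vaccinations: pd.DataFrame
    deaths: pd.DataFrame
    population: pd.DataFrame

    def tables(self):
        for f in dc_fields(self):
            yield f.name, getattr(self, f.name)

    @classmethod
    def empty(cls) -> "CohortBundle":
        kw = {}
        for name, cols in _SCHEMAS.items():
            df = pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
            kw[name] = _coerce_table(name, df)
        return cls(**kw)


def _coerce_table(name: str, df: pd.DataFrame, source: str = "<memory>") -> pd.DataFrame:
    cols = _SCHEMAS[name]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise BundleFormatError(f"{source}: table {name!r} is missing mandatory column(s) {missing}")
    df = df[cols].copy()
    for c in _DATE_COLS[name]:
        raw = df[c]
        parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            i = int(bad.idxmax())
            raise BundleFormatError(
                f"{source}: table {name!r} column {c!r} has unparseable date "
                f"{raw[i]!r} at row {i + 2} (1-based, counting the header)"
            )
        df[c] = parsed
    if name == "patients":
        df["ses_quintile"] = pd.to_numeric(df["ses_quintile"], errors="coerce").astype("Int64")
    if name == "admissions":
        df["icu_contact"] = df["icu_contact"].map(
            {True: True, False: False, "1": True, "0": False, 1: True, 0: False,
             "true": True, "false": False, "True": True, "False": False}
        )
        for c in ("secondary_dx", "procedures"):
            df[c] = df[c].fillna("").astype(str).replace("nan", "")
    if name == "population":
        df["year"] = pd.to_numeric(df["year"], errors="raise").astype(int)
        df["resident_count"] = pd.to_numeric(df["resident_count"], errors="raise").astype(int)
    for c in df.columns:
        if df[c].dtype == object:
            df[c] = df[c].where(df[c].notna(), None)
    return df.reset_index(drop=True)


def read_bundle(directory) -> CohortBundle:
    """Read the seven registry CSVs from ``directory`` into a bundle.

    Missing mandatory columns and unparseable dates raise
    :class:`BundleFormatError` with file and row context.
    """
    kw = {}
    for name in _SCHEMAS:
        path = os.path.join(directory, f"{name}.csv")
        if not os.path.exists(path):
            raise BundleFormatError(f"missing registry file: {path}")
        df = pd.read_csv(path, dtype=str, keep_default_na=True)
        kw[name] = _coerce_table(name, df, source=path)
    return CohortBundle(**kw)


def _format_table(name: str, df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in _DATE_COLS[name]:
        out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
    if name == "patients":
        out["ses_quintile"] = out["ses_quintile"].astype(object).where(
            out["ses_quintile"].notna(), ""
        ).map(lambda v: "" if v == "" else str(int(v)))
    if name == "admissions":
        out["icu_contact"] = out["icu_contact"].map(lambda v: "1" if v else "0")
    return out


def write_bundle(bundle: CohortBundle, directory) -> dict[str, str]:
    """Write the bundle as seven CSVs; returns the paths written.

    The on-disk form is canonical (fixed column order, ISO dates, ``1``/``0``
    booleans), so write -> read -> write is byte-stable.
    """
    os.makedirs(directory, exist_ok=True)
    paths = {}
    for name, df in bundle.tables():
        path = os.path.join(directory, f"{name}.csv")
        _format_table(name, df).to_csv(path, index=False, lineterminator="\n")
        paths[name] = path
    return paths


def _check_enum(violations, df, table, col, allowed, id_col=None):
    bad = ~df[col].isin(allowed) & df[col].notna()
    for i in df.index[bad]:
        ident = f" ({id_col}={df.at[i, id_col]})" if id_col else ""
        violations.append(
            f"{table}.{col}: invalid value {df.at[i, col]!r} at row {i}{ident}"
        )


def validate_bundle(bundle: CohortBundle) -> list[str]:
    """Check type invariants and referential integrity; never mutates.

    Returns a list of human-readable violation strings (empty iff clean).
    Violations are data, not exceptions: a dirty bundle is reportable.
    """
    v: list[str] = []
    pat = bundle.patients
    adm = bundle.admissions

    dup = pat["patient_id"][pat["patient_id"].duplicated()]
    for pid in dup:
        v.append(f"patients: duplicate patient_id {pid!r}")
    _check_enum(v, pat, "patients", "gender", GENDERS, "patient_id")
    _check_enum(v, pat, "patients", "residence_area", RESIDENCE_AREAS, "patient_id")
    bad_ses = pat["ses_quintile"].notna() & ~pat["ses_quintile"].isin([1, 2, 3, 4, 5])
    for i in pat.index[bad_ses]:
        v.append(f"patients: ses_quintile out of 1..5 (patient_id={pat.at[i, 'patient_id']})")

    dup = adm["admission_id"][adm["admission_id"].duplicated()]
    for aid in dup:
        v.append(f"admissions: duplicate admission_id {aid!r}")
    bad_dates = adm["discharge_date"] < adm["admission_date"]
    for i in adm.index[bad_dates.fillna(False)]:
        v.append(
            f"admissions: discharge before admission (admission_id={adm.at[i, 'admission_id']})"
        )
    _check_enum(v, adm, "admissions", "discharge_status", DISCHARGE_STATUSES, "admission_id")
    _check_enum(v, adm, "admissions", "hospital_type", HOSPITAL_TYPES, "admission_id")
    _check_enum(v, adm, "admissions", "facility_region", FACILITY_REGIONS, "admission_id")
    for i in adm.index:
        sec = split_codes(adm.at[i, "secondary_dx"])
        proc = split_codes(adm.at[i, "procedures"])
        aid = adm.at[i, "admission_id"]
        if len(sec) > 5:
            v.append(f"admissions: more than 6 diagnoses in total (admission_id={aid})")
        if len(proc) > 6:
            v.append(f"admissions: more than 6 procedures (admission_id={aid})")
        p = adm.at[i, "principal_dx"]
        if p is None or not str(p).strip():
            v.append(f"admissions: empty principal diagnosis (admission_id={aid})")

    _check_enum(v, bundle.outpatient, "outpatient", "service_kind", SERVICE_KINDS)
    _check_enum(v, bundle.dispensings, "dispensings", "drug_class", DRUG_CLASSES)
    _check_enum(v, bundle.vaccinations, "vaccinations", "vaccine_kind", VACCINE_KINDS)

    dd = bundle.deaths["patient_id"][bundle.deaths["patient_id"].duplicated()]
    for pid in dd:
        v.append(f"deaths: more than one death record for patient_id {pid!r}")

    pop = bundle.population
    _check_enum(v, pop, "population", "age_band", AGE_BANDS)
    _check_enum(v, pop, "population", "gender", GENDERS)
    dup = pop[["year", "age_band", "gender"]].duplicated()
    for i in pop.index[dup]:
        v.append(
            f"population: duplicate stratum (year={pop.at[i, 'year']}, "
            f"age_band={pop.at[i, 'age_band']}, gender={pop.at[i, 'gender']})"
        )
    if (pop["resident_count"] < 0).any():
        v.append("population: negative resident_count")

    known = set(pat["patient_id"])
    for name in ("admissions", "outpatient", "dispensings", "vaccinations", "deaths"):
        df = getattr(bundle, name)
        orphans = sorted(set(df["patient_id"]) - known)
        for pid in orphans:
            v.append(f"{name}: references unknown patient_id {pid!r}")
    return v
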