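import pandas as pd
import pytest

from pneumoclass import CohortBundle, GeneratorConfig, default_config, generate


@pytest.fixture(scope="session")
def config():
    return default_config()


def make_patient(pid="P1", birth="1935-06-15", gender="male",
                 residence="rome", ses=3):
    return {
        "patient_id": pid,
        "birth_date": pd.Timestamp(birth),
        "gender": gender,
        "residence_area": residence,
        "ses_quintile": ses,
    }


def make_admission(aid="A1", pid="P1", admission="2007-03-01", discharge="2007-03-10",
                   principal="486", secondary="", procedures="",
                   status="alive", icu=False, hospital="public", region="lazio"):
    return {
        "admission_id": aid,
        "patient_id": pid,
        "admission_date": pd.Timestamp(admission),
        "discharge_date": pd.Timestamp(discharge),
        "principal_dx": principal,
        "secondary_dx": secondary,
        "procedures": procedures,
        "discharge_status": status,
        "icu_contact": icu,
        "hospital_type": hospital,
        "facility_region": region,
    }


def make_bundle(patients=(), admissions=(), outpatient=(), dispensings=(),
                vaccinations=(), deaths=(), population=()) -> CohortBundle:
    """Assemble a bundle from row dicts, filling empty tables with schemas."""
    empty = CohortBundle.empty()

    def frame(rows, template):
        if not rows:
            return template.copy()
        df = pd.DataFrame.from_records(list(rows))
        for c in template.columns:
            if c not in df.columns:
                df[c] = None
        return df[template.columns]

    b = CohortBundle(
        patients=frame(patients, empty.patients),
        admissions=frame(admissions, empty.admissions),
        outpatient=frame(outpatient, empty.outpatient),
        dispensings=frame(dispensings, empty.dispensings),
        vaccinations=frame(vaccinations, empty.vaccinations),
        deaths=frame(deaths, empty.deaths),
        population=frame(population, empty.population),
    )
    b.patients["ses_quintile"] = pd.to_numeric(
        b.patients["ses_quintile"], errors="coerce"
    ).astype("Int64")
    return b


@pytest.fixture(scope="session")
def small_cohort():
    """A 2000-patient generated cohort shared by recovery-style tests."""
    cfg = GeneratorConfig(seed=11, n_patients=2000)
    bundle, truth = generate(cfg)
    return cfg, bundle, truth
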