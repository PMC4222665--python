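"""Synthetic multi-registry cohort generator with planted ground truth.

The generator emulates the registry environment the pipeline consumes —
hospital discharge abstracts, outpatient dialysis/chemotherapy services,
oxygen dispensings, influenza vaccinations, a mortality register, patient
demographics and census denominators — for a cohort of elderly pneumonia
hospitalisations with a configurable subtype mixture.

Subtype is planted as *mechanism*, not label: an intended
healthcare-associated (HCAP) episode receives a qualifying exposure (a
dialysis or chemotherapy service within 30 days, or a prior >= 2-day stay —
or a surgical day stay — discharged within 180 days) and no structure that
would fire a sibling rule; an intended probable-nosocomial (PNP) episode
carries pneumonia only as a secondary diagnosis under a non-excluded
principal diagnosis and no healthcare-contact exposure; an intended
community-acquired (CAP) episode carries principal pneumonia and no
exposure.  Comorbidity evidence planted on earlier stays is always
discharged more than 180 days before the index admission, so it can never
leak into the healthcare-contact rule.  The classifier is therefore tested
against causally planted structure, and cross-mechanism contamination (an
exposure added to a PNP-structured episode) is injectable at a configured
rate to exercise the precedence rules.

Default mixtures, outcome probabilities, length-of-stay means, comorbidity
prevalences and aetiology shares follow the published per-subtype cohort
profile of elderly pneumonia hospitalisations in a large central-Italian
region (2006-2008; 8.6% HCAP / 25.8% PNP / 65.2% CAP, in-hospital mortality
32.3/24.6/13.3%, census denominator 1,056,000 residents aged 65+).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import isclose

import numpy as np
import pandas as pd

from .bundle import CohortBundle, join_codes, AGE_BANDS

__all__ = ["GeneratorConfig", "GeneratorConfigError", "generate", "plant_repeat_admissions"]

SUBTYPES = ("HCAP", "PNP", "CAP")

_BAND_RANGES = {
    "65-69": (65, 69), "70-74": (70, 74), "75-79": (75, 79),
    "80-84": (80, 84), "85-89": (85, 89), "90+": (90, 99),
}

# Representative planted code per comorbidity category.  Cerebrovascular is
# planted on prior stays only so the same-admission acute-stroke flag stays
# under the generator's separate control.
_COMORBIDITY_PLANT = {
    "heart_failure": "4280",
    "diabetes": "25000",
    "chronic_kidney": "5859",
    "malignant_tumours": "1629",
    "hypertension": "4019",
    "ischemic_heart": "41401",
    "other_heart": "4240",
    "arrhythmias": "42731",
    "cerebrovascular": "43491",
    "digestive": "53081",
    "anaemias_coagulopathies": "2859",
    "neurological": "3310",
    "psychiatric": "3004",
    "chronic_respiratory_other": "515",
}
_PRIOR_ONLY_CATEGORIES = {"cerebrovascular"}

# Planted diagnosis per aetiology category.  The chemical-inhalation group
# rides as a secondary code next to unspecified pneumonia (506.x alone is
# not a pneumonia case-definition code); "other" uses viral pneumonia 480.0,
# which belongs to the case definition but to no tabulated aetiology group.
_AETIOLOGY_PLANT = {
    "bronchopneumonia_unspecified": ("485", None),
    "pneumonia_unspecified": ("486", None),
    "bacterial_unspecified": ("4829", None),
    "pseudomonas": ("4821", None),
    "other_specified_bacteria": ("48289", None),
    "pneumococcal": ("481", None),
    "mssa": ("48241", None),
    "klebsiella": ("4820", None),
    "other_gram_negative": ("48283", None),
    "staphylococcus_unspecified": ("48240", None),
    "e_coli": ("48282", None),
    "chemical_fumes": ("486", "5060"),
    "other": ("4800", None),
}

_FILLER_PRINCIPAL = "78060"  # fever/symptom code: in no analysis code set
_SURGERY_PROC = "8151"       # hip replacement: operative-chapter procedure
_STROKE_PLANT = "43411"
_VENT_PROC = "9671"


def _sub(d: dict, s: str) -> float:
    return float(d[s])


class GeneratorConfigError(ValueError):
    """The generator configuration is internally inconsistent."""


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    ``n_patients`` counts *eligible* cohort members (aged 65+, regional
    residents); under-65 and out-of-region decoys are added on top at the
    configured fractions purely to exercise the eligibility filter.
    Probabilities are per subtype in the order the keys state.
    """

    seed: int = 0
    n_patients: int = 26239
    study_years: tuple[int, ...] = (2006, 2007, 2008)

    # count-derived shares, normalised over the three subtype counts
    subtype_mixture: dict = field(
        default_factory=lambda: {
            "HCAP": 2257 / 26139, "PNP": 6775 / 26139, "CAP": 17107 / 26139,
        }
    )
    in_hospital_death: dict = field(
        default_factory=lambda: {"HCAP": 0.323, "PNP": 0.246, "CAP": 0.133}
    )
    death_within_30d: dict = field(
        default_factory=lambda: {"HCAP": 0.382, "PNP": 0.283, "CAP": 0.158}
    )
    los_mean_days: dict = field(
        default_factory=lambda: {"HCAP": 27.1, "PNP": 16.8, "CAP": 13.2}
    )
    los_log_sigma: float = 0.8
    late_death_prob: float = 0.10

    hcap_mechanisms: dict = field(
        default_factory=lambda: {"dialysis30": 0.18, "chemo30": 0.12, "prior_stay180": 0.70}
    )
    hcap_within10_share: float = 0.519  # of all HCAP episodes
    surgery_day_stay_frac: float = 0.2  # of prior-stay mechanisms: day stay + surgery

    male_share: dict = field(
        default_factory=lambda: {"HCAP": 0.584, "PNP": 0.522, "CAP": 0.550}
    )
    age_band_probs: dict = field(
        default_factory=lambda: {
            "HCAP": (0.170, 0.215, 0.248, 0.176, 0.127, 0.0625),
            "PNP": (0.107, 0.155, 0.211, 0.235, 0.173, 0.119),
            "CAP": (0.126, 0.169, 0.222, 0.223, 0.154, 0.107),
        }
    )
    residence_probs: dict = field(
        default_factory=lambda: {"rome": 0.593, "province_of_rome": 0.217, "rest_of_lazio": 0.190}
    )
    under65_fraction: float = 0.05
    outside_fraction: float = 0.02

    comorbidity_prevalence: dict = field(
        default_factory=lambda: {
            "heart_failure": {"HCAP": 0.244, "PNP": 0.306, "CAP": 0.202},
            "diabetes": {"HCAP": 0.184, "PNP": 0.133, "CAP": 0.130},
            "chronic_kidney": {"HCAP": 0.280, "PNP": 0.165, "CAP": 0.135},
            "malignant_tumours": {"HCAP": 0.319, "PNP": 0.206, "CAP": 0.126},
            "hypertension": {"HCAP": 0.366, "PNP": 0.251, "CAP": 0.253},
            "ischemic_heart": {"HCAP": 0.258, "PNP": 0.232, "CAP": 0.227},
            "other_heart": {"HCAP": 0.234, "PNP": 0.190, "CAP": 0.166},
            "arrhythmias": {"HCAP": 0.267, "PNP": 0.293, "CAP": 0.249},
            "cerebrovascular": {"HCAP": 0.330, "PNP": 0.299, "CAP": 0.248},
            "digestive": {"HCAP": 0.062, "PNP": 0.080, "CAP": 0.058},
            "anaemias_coagulopathies": {"HCAP": 0.179, "PNP": 0.130, "CAP": 0.115},
            "neurological": {"HCAP": 0.158, "PNP": 0.135, "CAP": 0.114},
            "psychiatric": {"HCAP": 0.096, "PNP": 0.093, "CAP": 0.100},
            "chronic_respiratory_other": {"HCAP": 0.050, "PNP": 0.056, "CAP": 0.057},
        }
    )
    copd_2y_prevalence: dict = field(
        default_factory=lambda: {"HCAP": 0.219, "PNP": 0.166, "CAP": 0.208}
    )
    respiratory_failure_2y_prevalence: dict = field(
        default_factory=lambda: {"HCAP": 0.107, "PNP": 0.067, "CAP": 0.095}
    )
    oxygen_1y_prevalence: dict = field(
        default_factory=lambda: {"HCAP": 0.123, "PNP": 0.112, "CAP": 0.130}
    )
    vaccination_2y_prevalence: dict = field(
        default_factory=lambda: {"HCAP": 0.540, "PNP": 0.564, "CAP": 0.407}
    )
    stroke_prevalence: dict = field(
        default_factory=lambda: {"HCAP": 0.043, "PNP": 0.085, "CAP": 0.008}
    )
    ventilation_prevalence: dict = field(
        default_factory=lambda: {"HCAP": 0.185, "PNP": 0.031, "CAP": 0.028}
    )
    icu_prevalence: dict = field(
        default_factory=lambda: {"HCAP": 0.257, "PNP": 0.054, "CAP": 0.028}
    )
    hospital_type_probs: dict = field(
        default_factory=lambda: {
            "HCAP": (0.603, 0.265, 0.132),
            "PNP": (0.662, 0.205, 0.133),
            "CAP": (0.660, 0.173, 0.166),
        }
    )
    pnp_principal_probs: dict = field(
        default_factory=lambda: {"82000": 0.40, "0389": 0.30, "5990": 0.30}
    )
    aetiology_mixture: dict = field(
        default_factory=lambda: {
            "HCAP": {
                "bronchopneumonia_unspecified": 0.400, "pneumonia_unspecified": 0.282,
                "bacterial_unspecified": 0.146, "pseudomonas": 0.036,
                "other_specified_bacteria": 0.026, "pneumococcal": 0.020, "mssa": 0.014,
                "klebsiella": 0.007, "other_gram_negative": 0.007,
                "staphylococcus_unspecified": 0.007, "e_coli": 0.006,
                "chemical_fumes": 0.006, "other": 0.043,
            },
            "PNP": {
                "bronchopneumonia_unspecified": 0.514, "pneumonia_unspecified": 0.270,
                "bacterial_unspecified": 0.127, "pseudomonas": 0.006,
                "other_specified_bacteria": 0.016, "pneumococcal": 0.016, "mssa": 0.002,
                "klebsiella": 0.004, "other_gram_negative": 0.001,
                "staphylococcus_unspecified": 0.003, "e_coli": 0.001,
                "chemical_fumes": 0.013, "other": 0.026,
            },
            "CAP": {
                "bronchopneumonia_unspecified": 0.476, "pneumonia_unspecified": 0.286,
                "bacterial_unspecified": 0.134, "pseudomonas": 0.012,
                "other_specified_bacteria": 0.014, "pneumococcal": 0.017, "mssa": 0.006,
                "klebsiella": 0.005, "other_gram_negative": 0.005,
                "staphylococcus_unspecified": 0.007, "e_coli": 0.003,
                "chemical_fumes": 0.001, "other": 0.032,
            },
        }
    )

    decoy_service_prob: float = 0.05   # out-of-window dialysis/chemo on non-HCAP
    decoy_short_stay_prob: float = 0.04  # non-qualifying <2-day prior stay
    mobility_fraction: float = 0.03    # index admissions at out-of-region facilities
    contamination_rate: float = 0.0    # exposure added to PNP-structured episodes

    total_population: int = 1_056_000
    population_band_shares: tuple[float, ...] = (0.28, 0.25, 0.21, 0.14, 0.08, 0.04)
    population_female_shares: tuple[float, ...] = (0.53, 0.54, 0.56, 0.60, 0.65, 0.70)
    population_year_scale: dict = field(
        default_factory=lambda: {2006: 0.98, 2007: 0.99, 2008: 1.00}
    )

    def replace(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)

    def validate(self) -> None:
        if self.n_patients < 0:
            raise GeneratorConfigError("n_patients must be non-negative")
        if not isclose(sum(self.subtype_mixture.values()), 1.0, abs_tol=1e-9):
            raise GeneratorConfigError("subtype_mixture must sum to 1")
        if not isclose(sum(self.hcap_mechanisms.values()), 1.0, abs_tol=1e-9):
            raise GeneratorConfigError("hcap_mechanisms must sum to 1")
        prob_dicts = [
            self.subtype_mixture, self.in_hospital_death, self.death_within_30d,
            self.male_share, self.copd_2y_prevalence, self.respiratory_failure_2y_prevalence,
            self.oxygen_1y_prevalence, self.vaccination_2y_prevalence,
            self.stroke_prevalence, self.ventilation_prevalence, self.icu_prevalence,
        ] + list(self.comorbidity_prevalence.values())
        for d in prob_dicts:
            for p in d.values():
                if not 0.0 <= p <= 1.0:
                    raise GeneratorConfigError(f"probability {p} outside [0, 1]")
        for s in SUBTYPES:
            if self.in_hospital_death[s] > self.death_within_30d[s]:
                raise GeneratorConfigError(
                    "in-hospital death probability cannot exceed 30-day death probability"
                )
            if self.los_mean_days[s] <= 0:
                raise GeneratorConfigError("length-of-stay means must be positive")
        if len(self.population_band_shares) != len(AGE_BANDS):
            raise GeneratorConfigError("population_band_shares must cover all six age bands")
        for band, share, probs in zip(
            AGE_BANDS, self.population_band_shares,
            zip(*[self.age_band_probs[s] for s in SUBTYPES]),
        ):
            if share <= 0 and any(p > 0 for p in probs):
                raise GeneratorConfigError(
                    f"age band {band} is generated but has zero population denominator"
                )
        for y in self.study_years:
            if y not in self.population_year_scale:
                raise GeneratorConfigError(f"population_year_scale missing study year {y}")


class _Builder:
    """Accumulates registry rows and ground-truth bookkeeping."""

    def __init__(self, config: GeneratorConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.patients: list[dict] = []
        self.admissions: list[dict] = []
        self.outpatient: list[dict] = []
        self.dispensings: list[dict] = []
        self.vaccinations: list[dict] = []
        self.deaths: list[dict] = []
        self.truth: list[dict] = []
        self._pid = 0
        self._aid = 0
        y0, y1 = min(config.study_years), max(config.study_years)
        self.window_start = pd.Timestamp(y0, 1, 1)
        self.window_end = pd.Timestamp(y1, 12, 31)
        self.window_days = (self.window_end - self.window_start).days + 1
        ps = config.hcap_mechanisms["prior_stay180"]
        self.p10_given_prior = min(1.0, config.hcap_within10_share / ps) if ps > 0 else 0.0

    def next_pid(self) -> str:
        self._pid += 1
        return f"P{self._pid:06d}"

    def next_aid(self) -> str:
        self._aid += 1
        return f"A{self._aid:06d}"

    def _birth_date(self, admission: pd.Timestamp, age: int) -> pd.Timestamp:
        m, d = admission.month, admission.day
        if m == 2 and d == 29:
            d = 28
        anniversary = pd.Timestamp(admission.year - age, m, d)
        return anniversary - pd.Timedelta(days=int(self.rng.integers(0, 365)))

    def _choice(self, options, probs):
        p = np.asarray(list(probs), dtype=float)
        return list(options)[int(self.rng.choice(len(p), p=p / p.sum()))]

    def add_subject(self, *, eligible_kind: str = "eligible") -> None:
        """One cohort member: index pneumonia admission plus planted registry rows.

        ``eligible_kind`` is ``eligible``, ``under65`` or ``outside``.
        """
        cfg, rng = self.cfg, self.rng
        pid = self.next_pid()
        subtype = self._choice(SUBTYPES, [cfg.subtype_mixture[s] for s in SUBTYPES])

        # outcome draws (in-hospital deaths nested inside 30-day deaths)
        mean = cfg.los_mean_days[subtype]
        sigma = cfg.los_log_sigma
        mu = np.log(mean) - sigma * sigma / 2.0
        los = int(round(float(rng.lognormal(mu, sigma))))
        los = max(0, los)
        status = "alive"
        death_offset: int | None = None
        u = rng.random()
        if u < cfg.in_hospital_death[subtype]:
            death_offset = int(rng.integers(0, 31))
            los = death_offset
            status = "died"
        elif u < cfg.death_within_30d[subtype]:
            death_offset = int(rng.integers(1, 31))
            if los >= death_offset:
                los = int(rng.integers(0, death_offset))
        elif rng.random() < cfg.late_death_prob:
            death_offset = int(rng.integers(31, 366))

        discharge = self.window_start + pd.Timedelta(days=int(rng.integers(0, self.window_days)))
        admission = discharge - pd.Timedelta(days=los)

        if eligible_kind == "under65":
            age = int(rng.integers(50, 65))
        else:
            band = self._choice(AGE_BANDS, cfg.age_band_probs[subtype])
            lo, hi = _BAND_RANGES[band]
            age = int(rng.integers(lo, hi + 1))
        if eligible_kind == "outside":
            residence = "outside"
        else:
            residence = self._choice(
                list(cfg.residence_probs), list(cfg.residence_probs.values())
            )
        ses = int(rng.integers(1, 6)) if residence == "rome" else None
        gender = "male" if rng.random() < cfg.male_share[subtype] else "female"

        self.patients.append(
            {
                "patient_id": pid,
                "birth_date": self._birth_date(admission, age),
                "gender": gender,
                "residence_area": residence,
                "ses_quintile": ses,
            }
        )

        # diagnosis structure
        aet = self._choice(
            list(cfg.aetiology_mixture[subtype]),
            list(cfg.aetiology_mixture[subtype].values()),
        )
        pneu_code, extra_code = _AETIOLOGY_PLANT[aet]
        structural_secondary: list[str] = []
        if subtype == "PNP":
            principal = self._choice(
                list(cfg.pnp_principal_probs), list(cfg.pnp_principal_probs.values())
            )
            structural_secondary.append(pneu_code)
        else:
            principal = pneu_code
        if extra_code is not None:
            structural_secondary.append(extra_code)
        stroke = rng.random() < cfg.stroke_prevalence[subtype]
        if stroke:
            structural_secondary.append(_STROKE_PLANT)

        # comorbidity planting: index secondary slots or a safely distant prior stay
        index_comorb: list[str] = []
        prior_codes: list[str] = []
        for cat, prev in cfg.comorbidity_prevalence.items():
            if rng.random() < prev[subtype]:
                code = _COMORBIDITY_PLANT[cat]
                if cat in _PRIOR_ONLY_CATEGORIES or rng.random() >= 0.5:
                    prior_codes.append(code)
                else:
                    index_comorb.append(code)
        if rng.random() < cfg.copd_2y_prevalence[subtype]:
            prior_codes.append("4912")
        if rng.random() < cfg.respiratory_failure_2y_prevalence[subtype]:
            prior_codes.append("51881")

        secondary = structural_secondary + index_comorb
        if len(secondary) > 5:  # abstracts hold at most 6 diagnoses in total
            spill = secondary[5:]
            secondary = secondary[:5]
            prior_codes.extend(spill)

        procedures: list[str] = []
        if rng.random() < cfg.ventilation_prevalence[subtype]:
            procedures.append(_VENT_PROC)
        icu = rng.random() < cfg.icu_prevalence[subtype]
        hosp = self._choice(("public", "teaching", "private"), cfg.hospital_type_probs[subtype])
        region = "other" if rng.random() < cfg.mobility_fraction else "lazio"

        aid = self.next_aid()
        self.admissions.append(
            {
                "admission_id": aid,
                "patient_id": pid,
                "admission_date": admission,
                "discharge_date": discharge,
                "principal_dx": principal,
                "secondary_dx": join_codes(secondary),
                "procedures": join_codes(procedures),
                "discharge_status": status,
                "icu_contact": icu,
                "hospital_type": hosp,
                "facility_region": region,
            }
        )

        # healthcare-contact mechanism (HCAP) or decoy non-qualifying contact
        mechanism = "none"
        if subtype == "HCAP":
            mechanism = self._choice(
                list(cfg.hcap_mechanisms), list(cfg.hcap_mechanisms.values())
            )
            if mechanism == "dialysis30":
                self.outpatient.append(
                    {
                        "patient_id": pid,
                        "service_date": admission - pd.Timedelta(days=int(rng.integers(1, 31))),
                        "service_kind": "dialysis",
                    }
                )
            elif mechanism == "chemo30":
                self.outpatient.append(
                    {
                        "patient_id": pid,
                        "service_date": admission - pd.Timedelta(days=int(rng.integers(1, 31))),
                        "service_kind": "chemotherapy",
                    }
                )
            else:
                if rng.random() < self.p10_given_prior:
                    gap = int(rng.integers(1, 11))
                else:
                    gap = int(rng.integers(11, 181))
                if rng.random() < cfg.surgery_day_stay_frac:
                    prior_los, prior_procs = int(rng.integers(0, 2)), [_SURGERY_PROC]
                else:
                    prior_los, prior_procs = int(rng.integers(2, 15)), []
                p_dis = admission - pd.Timedelta(days=gap)
                self.admissions.append(
                    {
                        "admission_id": self.next_aid(),
                        "patient_id": pid,
                        "admission_date": p_dis - pd.Timedelta(days=prior_los),
                        "discharge_date": p_dis,
                        "principal_dx": _FILLER_PRINCIPAL,
                        "secondary_dx": "",
                        "procedures": join_codes(prior_procs),
                        "discharge_status": "alive",
                        "icu_contact": False,
                        "hospital_type": hosp,
                        "facility_region": "lazio",
                    }
                )
        else:
            mechanism = "secondary_dx_structure" if subtype == "PNP" else "none"
            if rng.random() < cfg.decoy_service_prob:  # exposure outside the 30-day window
                self.outpatient.append(
                    {
                        "patient_id": pid,
                        "service_date": admission - pd.Timedelta(days=int(rng.integers(35, 366))),
                        "service_kind": "dialysis" if rng.random() < 0.5 else "chemotherapy",
                    }
                )
            if rng.random() < cfg.decoy_short_stay_prob:  # <2-day stay, no surgery
                gap = int(rng.integers(5, 171))
                prior_los = int(rng.integers(0, 2))
                p_dis = admission - pd.Timedelta(days=gap)
                self.admissions.append(
                    {
                        "admission_id": self.next_aid(),
                        "patient_id": pid,
                        "admission_date": p_dis - pd.Timedelta(days=prior_los),
                        "discharge_date": p_dis,
                        "principal_dx": _FILLER_PRINCIPAL,
                        "secondary_dx": "",
                        "procedures": "",
                        "discharge_status": "alive",
                        "icu_contact": False,
                        "hospital_type": hosp,
                        "facility_region": "lazio",
                    }
                )

        # prior stays carrying the spilled comorbidity evidence (discharged
        # 181+ days before index: outside the healthcare-contact window,
        # inside the two-year comorbidity window)
        for i in range(0, len(prior_codes), 6):
            chunk = prior_codes[i: i + 6]
            prior_los = int(rng.integers(1, 10))
            gap_dis = int(rng.integers(181, 730 - prior_los))
            p_adm = admission - pd.Timedelta(days=gap_dis + prior_los)
            self.admissions.append(
                {
                    "admission_id": self.next_aid(),
                    "patient_id": pid,
                    "admission_date": p_adm,
                    "discharge_date": p_adm + pd.Timedelta(days=prior_los),
                    "principal_dx": chunk[0],
                    "secondary_dx": join_codes(chunk[1:]),
                    "procedures": "",
                    "discharge_status": "alive",
                    "icu_contact": False,
                    "hospital_type": hosp,
                    "facility_region": "lazio",
                }
            )

        if rng.random() < cfg.oxygen_1y_prevalence[subtype]:
            self.dispensings.append(
                {
                    "patient_id": pid,
                    "dispensing_date": admission - pd.Timedelta(days=int(rng.integers(1, 366))),
                    "drug_class": "domiciliary_oxygen",
                }
            )
        if rng.random() < cfg.vaccination_2y_prevalence[subtype]:
            self.vaccinations.append(
                {
                    "patient_id": pid,
                    "vaccination_date": admission - pd.Timedelta(days=int(rng.integers(1, 731))),
                    "vaccine_kind": "influenza",
                }
            )
        if death_offset is not None:
            self.deaths.append(
                {
                    "patient_id": pid,
                    "death_date": admission + pd.Timedelta(days=death_offset),
                    "cause_code": "486",
                }
            )

        self.truth.append(
            {
                "admission_id": aid,
                "patient_id": pid,
                "intended_subtype": subtype,
                "mechanism": mechanism,
                "dedup_fate": "index" if eligible_kind == "eligible" else "ineligible",
                "eligible": eligible_kind == "eligible",
                "aetiology": aet,
                "contaminated": False,
                "in_hospital_death": status == "died",
                "death_within_30d": death_offset is not None and death_offset <= 30,
            }
        )

    def apply_contamination(self) -> None:
        """Add a 30-day dialysis exposure to a sampled share of PNP episodes."""
        cfg, rng = self.cfg, self.rng
        if cfg.contamination_rate <= 0:
            return
        adm_date = {t["admission_id"]: None for t in self.truth}
        for a in self.admissions:
            if a["admission_id"] in adm_date:
                adm_date[a["admission_id"]] = a["admission_date"]
        for t in self.truth:
            if t["intended_subtype"] == "PNP" and rng.random() < cfg.contamination_rate:
                self.outpatient.append(
                    {
                        "patient_id": t["patient_id"],
                        "service_date": adm_date[t["admission_id"]]
                        - pd.Timedelta(days=int(rng.integers(1, 31))),
                        "service_kind": "dialysis",
                    }
                )
                t["contaminated"] = True

    def population_table(self) -> pd.DataFrame:
        cfg = self.cfg
        shares = np.asarray(cfg.population_band_shares, dtype=float)
        shares = shares / shares.sum()
        rows = []
        for year in cfg.study_years:
            scale = cfg.population_year_scale[year]
            for band, share, fem in zip(AGE_BANDS, shares, cfg.population_female_shares):
                total = cfg.total_population * share * scale
                for gender, gshare in (("male", 1.0 - fem), ("female", fem)):
                    rows.append(
                        {
                            "year": int(year),
                            "age_band": band,
                            "gender": gender,
                            "resident_count": int(round(total * gshare)),
                        }
                    )
        return pd.DataFrame.from_records(rows)

    def to_bundle(self) -> tuple[CohortBundle, pd.DataFrame]:
        def frame(rows, cols):
            if rows:
                return pd.DataFrame.from_records(rows)[cols]
            return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})

        bundle = CohortBundle(
            patients=frame(
                self.patients,
                ["patient_id", "birth_date", "gender", "residence_area", "ses_quintile"],
            ),
            admissions=frame(
                self.admissions,
                ["admission_id", "patient_id", "admission_date", "discharge_date",
                 "principal_dx", "secondary_dx", "procedures", "discharge_status",
                 "icu_contact", "hospital_type", "facility_region"],
            ),
            outpatient=frame(self.outpatient, ["patient_id", "service_date", "service_kind"]),
            dispensings=frame(self.dispensings, ["patient_id", "dispensing_date", "drug_class"]),
            vaccinations=frame(
                self.vaccinations, ["patient_id", "vaccination_date", "vaccine_kind"]
            ),
            deaths=frame(self.deaths, ["patient_id", "death_date", "cause_code"]),
            population=self.population_table(),
        )
        bundle.patients["ses_quintile"] = pd.to_numeric(
            bundle.patients["ses_quintile"], errors="coerce"
        ).astype("Int64")
        truth_cols = [
            "admission_id", "patient_id", "intended_subtype", "mechanism", "dedup_fate",
            "eligible", "aetiology", "contaminated", "in_hospital_death", "death_within_30d",
        ]
        truth = frame(self.truth, truth_cols)
        return bundle, truth


def generate(config: GeneratorConfig) -> tuple[CohortBundle, pd.DataFrame]:
    """Generate a cohort bundle and its ground-truth table.

    Deterministic given ``config.seed``.  Every intended-HCAP index
    admission has exactly one planted qualifying exposure; intended-PNP
    admissions carry secondary-only pneumonia under a non-excluded principal
    diagnosis; intended-CAP admissions carry principal pneumonia and no
    exposure.  The returned bundle passes ``validate_bundle``.
    """
    config.validate()
    b = _Builder(config)
    for _ in range(config.n_patients):
        b.add_subject(eligible_kind="eligible")
    for _ in range(int(round(config.n_patients * config.under65_fraction))):
        b.add_subject(eligible_kind="under65")
    for _ in range(int(round(config.n_patients * config.outside_fraction))):
        b.add_subject(eligible_kind="outside")
    b.apply_contamination()
    return b.to_bundle()


def plant_repeat_admissions(
    bundle: CohortBundle,
    truth: pd.DataFrame,
    rate: float,
    seed: int,
    k_range: tuple[int, int] = (10, 60),
) -> tuple[CohortBundle, pd.DataFrame]:
    """Add repeat pneumonia admissions straddling the 30-day dedup boundary.

    For a sampled subset of eligible index admissions of patients who left
    hospital alive and have no death record, a second pneumonia admission is
    planted ``k`` days after the index admission date, with ``k`` drawn
    uniformly from ``k_range`` (which straddles 30).  Ground truth records
    the dedup fate: ``suppressed`` when ``k <= 30``, ``index`` (a new
    episode) when ``k > 30``.  A surviving repeat has, by construction, a
    qualifying prior stay (the index stay) when that stay lasted >= 2 days,
    so its intended subtype is recorded accordingly.

    Returns new (bundle, truth); inputs are not mutated.
    """
    rng = np.random.default_rng(seed)
    k_lo, k_hi = k_range
    adm = bundle.admissions.set_index("admission_id")
    dead = set(bundle.deaths["patient_id"])
    window_end = adm["discharge_date"].max()

    new_adm_rows: list[dict] = []
    new_truth_rows: list[dict] = []
    n_rep = 0
    for t in truth.itertuples(index=False):
        if t.dedup_fate != "index" or not t.eligible or t.patient_id in dead:
            continue
        if t.intended_subtype == "HCAP":
            # an HCAP patient's planted mechanism stay may still fall inside
            # the 180-day window of the repeat, which would make the repeat's
            # intended subtype ambiguous; repeats are planted on CAP/PNP
            # patients, whose only in-window qualifying stay is the index stay
            continue
        if rng.random() >= rate:
            continue
        row = adm.loc[t.admission_id]
        if row["discharge_status"] != "alive":
            continue
        los_index = (row["discharge_date"] - row["admission_date"]).days
        k = int(rng.integers(k_lo, k_hi + 1))
        if k <= los_index:
            continue  # the repeat must start after the index discharge
        adm2 = row["admission_date"] + pd.Timedelta(days=k)
        los2 = int(rng.integers(3, 11))
        dis2 = adm2 + pd.Timedelta(days=los2)
        if dis2 > window_end:
            continue
        n_rep += 1
        rid = f"R{n_rep:06d}"
        new_adm_rows.append(
            {
                "admission_id": rid,
                "patient_id": t.patient_id,
                "admission_date": adm2,
                "discharge_date": dis2,
                "principal_dx": "486",
                "secondary_dx": "",
                "procedures": "",
                "discharge_status": "alive",
                "icu_contact": False,
                "hospital_type": row["hospital_type"],
                "facility_region": "lazio",
            }
        )
        suppressed = k <= 30
        if suppressed:
            intended, mech = t.intended_subtype, "none"
        elif los_index >= 2:
            intended, mech = "HCAP", "prior_stay180"
        else:
            intended, mech = "CAP", "none"
        new_truth_rows.append(
            {
                "admission_id": rid,
                "patient_id": t.patient_id,
                "intended_subtype": intended,
                "mechanism": mech,
                "dedup_fate": "suppressed" if suppressed else "index",
                "eligible": True,
                "aetiology": "pneumonia_unspecified",
                "contaminated": False,
                "in_hospital_death": False,
                "death_within_30d": False,
            }
        )

    out_bundle = CohortBundle(
        patients=bundle.patients.copy(),
        admissions=pd.concat(
            [bundle.admissions, pd.DataFrame.from_records(new_adm_rows)],
            ignore_index=True,
        )
        if new_adm_rows
        else bundle.admissions.copy(),
        outpatient=bundle.outpatient.copy(),
        dispensings=bundle.dispensings.copy(),
        vaccinations=bundle.vaccinations.copy(),
        deaths=bundle.deaths.copy(),
        population=bundle.population.copy(),
    )
    out_truth = (
        pd.concat([truth, pd.DataFrame.from_records(new_truth_rows)], ignore_index=True)
        if new_truth_rows
        else truth.copy()
    )
    return out_bundle, out_truth
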