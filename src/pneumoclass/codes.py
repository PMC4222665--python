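"""ICD-9-CM code sets and analysis configuration.

Diagnosis and procedure codes in hospital discharge abstracts are matched by
*dotless prefix*: ``"480.1"`` normalises to ``"4801"`` and matches a code set
containing the prefix ``"480"``.  Three-digit prefixes therefore capture all
fourth/fifth-digit children, which is the standard convention when phenotyping
from claims data at the category level.

Every code list used by the pipeline (pneumonia case definition, subtype
exclusions, comorbidity categories, aetiology groups, surgery and ventilation
procedures) lives in an :class:`AnalysisConfig` together with the lookback
window lengths, so the algorithm itself is exact while the lists remain
swappable via a YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "normalize_code",
    "CodeSet",
    "code_matches",
    "match_series",
    "AnalysisConfig",
    "default_config",
    "load_config",
    "save_config",
    "AETIOLOGY_CATEGORIES",
    "COMORBIDITY_CATEGORIES",
]


def normalize_code(code: str) -> str:
    """Normalise an ICD-9-CM code: strip whitespace and dots, upper-case.

    Idempotent.  Raises ``ValueError`` on an empty code so malformed records
    are surfaced rather than silently unmatched.
    """
    c = str(code).strip()
    if not c:
        raise ValueError("empty diagnosis/procedure code")
    return c.replace(".", "").upper()


@dataclass(frozen=True)
class CodeSet:
    """A named collection of dotless code prefixes.

    A code belongs to the set iff its normalisation starts with any prefix.
    """

    name: str
    prefixes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.prefixes:
            raise ValueError(f"code set {self.name!r} has no prefixes")
        object.__setattr__(
            self, "prefixes", tuple(normalize_code(p) for p in self.prefixes)
        )

    def matches(self, code: str) -> bool:
        return normalize_code(code).startswith(self.prefixes)

    def with_prefixes(self, extra: Iterable[str]) -> "CodeSet":
        return CodeSet(self.name, self.prefixes + tuple(extra))


def code_matches(code: str, cs: CodeSet) -> bool:
    """True iff ``code`` belongs to code set ``cs`` (prefix semantics)."""
    return cs.matches(code)


def match_series(codes: pd.Series, cs: CodeSet) -> pd.Series:
    """Vectorised membership test for a Series of raw code strings."""
    norm = codes.fillna("").astype(str).str.strip().str.replace(".", "", regex=False).str.upper()
    return norm.str.startswith(cs.prefixes)


def _span(lo: int, hi: int) -> list[str]:
    return [str(i) for i in range(lo, hi + 1)]


# The 14 comorbidity categories tabulated per subtype, with conventional
# claims groupings (the category-level lists are configuration, not doctrine).
_DEFAULT_COMORBIDITIES: dict[str, list[str]] = {
    "heart_failure": ["428"],
    "diabetes": ["250"],
    "chronic_kidney": ["585", "586"],
    "malignant_tumours": _span(140, 208),
    "hypertension": _span(401, 405),
    "ischemic_heart": _span(410, 414),
    "other_heart": ["420", "421", "422", "423", "424", "425", "429"],
    "arrhythmias": ["426", "427"],
    "cerebrovascular": _span(430, 438),
    "digestive": _span(530, 537) + ["555", "556", "557", "558", "560", "562", "571", "577"],
    "anaemias_coagulopathies": _span(280, 287),
    "neurological": ["330", "331", "332", "333", "334", "335", "340", "341", "342",
                     "343", "344", "345", "348"],
    "psychiatric": ["290", "295", "296", "297", "298", "300", "311"],
    "chronic_respiratory_other": ["493", "495", "500", "501", "502", "503", "504",
                                  "505", "515", "516", "517"],
}

COMORBIDITY_CATEGORIES: tuple[str, ...] = tuple(_DEFAULT_COMORBIDITIES)

# Aetiology groups in assignment priority order: specific organisms beat
# unspecified categories; the chemical-inhalation group beats the residual
# unspecified pneumonia codes; anything unmatched falls through to "other".
_DEFAULT_AETIOLOGY: list[tuple[str, list[str]]] = [
    ("pseudomonas", ["4821"]),
    ("klebsiella", ["4820"]),
    ("mssa", ["48241"]),
    ("e_coli", ["48282"]),
    ("other_gram_negative", ["48283"]),
    ("staphylococcus_unspecified", ["48240"]),
    ("pneumococcal", ["481"]),
    ("other_specified_bacteria", ["4828"]),
    ("chemical_fumes", ["506"]),
    ("bacterial_unspecified", ["4829"]),
    ("bronchopneumonia_unspecified", ["485"]),
    ("pneumonia_unspecified", ["486"]),
]

AETIOLOGY_CATEGORIES: tuple[str, ...] = tuple(name for name, _ in _DEFAULT_AETIOLOGY) + ("other",)


@dataclass(frozen=True)
class AnalysisConfig:
    """All code sets, lookback windows and rule switches of the pipeline.

    Window lengths are whole days, measured backward from the index
    admission date; ``precedence`` orders the healthcare-associated versus
    probable-nosocomial rules when both fire on the same episode.
    """

    pneumonia: CodeSet
    pneumonia_complications: CodeSet
    copd: CodeSet
    trauma: CodeSet
    surgery_procedures: CodeSet
    ventilation_procedures: CodeSet
    stroke: CodeSet
    respiratory_failure: CodeSet
    comorbidities: Mapping[str, CodeSet]
    aetiology_priority: tuple[tuple[str, CodeSet], ...]

    # study window & eligibility
    study_start: str = "2006-01-01"
    study_end: str = "2008-12-31"
    min_age: int = 65

    # rule windows (days)
    dedup_window_days: int = 30
    dialysis_chemo_window_days: int = 30
    prior_stay_window_days: int = 180
    min_prior_stay_los: int = 2
    comorbidity_window_days: int = 730
    oxygen_window_days: int = 365
    vaccination_window_days: int = 730
    death_followup_days: int = 30

    precedence: str = "hcap_first"  # or "pnp_first"

    def __post_init__(self) -> None:
        if self.precedence not in ("hcap_first", "pnp_first"):
            raise ValueError(f"unknown precedence {self.precedence!r}")

    def replace(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)

    # -- serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "code_sets": {
                "pneumonia": list(self.pneumonia.prefixes),
                "pneumonia_complications": list(self.pneumonia_complications.prefixes),
                "copd": list(self.copd.prefixes),
                "trauma": list(self.trauma.prefixes),
                "surgery_procedures": list(self.surgery_procedures.prefixes),
                "ventilation_procedures": list(self.ventilation_procedures.prefixes),
                "stroke": list(self.stroke.prefixes),
                "respiratory_failure": list(self.respiratory_failure.prefixes),
                "comorbidities": {k: list(v.prefixes) for k, v in self.comorbidities.items()},
                "aetiology_priority": [[name, list(cs.prefixes)] for name, cs in self.aetiology_priority],
            },
            "study_start": self.study_start,
            "study_end": self.study_end,
            "min_age": self.min_age,
            "windows": {
                "dedup": self.dedup_window_days,
                "dialysis_chemo": self.dialysis_chemo_window_days,
                "prior_stay": self.prior_stay_window_days,
                "min_prior_stay_los": self.min_prior_stay_los,
                "comorbidity": self.comorbidity_window_days,
                "oxygen": self.oxygen_window_days,
                "vaccination": self.vaccination_window_days,
                "death_followup": self.death_followup_days,
            },
            "precedence": self.precedence,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        cs = d["code_sets"]
        w = d.get("windows", {})
        return cls(
            pneumonia=CodeSet("pneumonia", tuple(cs["pneumonia"])),
            pneumonia_complications=CodeSet("pneumonia_complications", tuple(cs["pneumonia_complications"])),
            copd=CodeSet("copd", tuple(cs["copd"])),
            trauma=CodeSet("trauma", tuple(cs["trauma"])),
            surgery_procedures=CodeSet("surgery_procedures", tuple(cs["surgery_procedures"])),
            ventilation_procedures=CodeSet("ventilation_procedures", tuple(cs["ventilation_procedures"])),
            stroke=CodeSet("stroke", tuple(cs["stroke"])),
            respiratory_failure=CodeSet("respiratory_failure", tuple(cs["respiratory_failure"])),
            comorbidities={k: CodeSet(k, tuple(v)) for k, v in cs["comorbidities"].items()},
            aetiology_priority=tuple((name, CodeSet(name, tuple(p))) for name, p in cs["aetiology_priority"]),
            study_start=d.get("study_start", "2006-01-01"),
            study_end=d.get("study_end", "2008-12-31"),
            min_age=d.get("min_age", 65),
            dedup_window_days=w.get("dedup", 30),
            dialysis_chemo_window_days=w.get("dialysis_chemo", 30),
            prior_stay_window_days=w.get("prior_stay", 180),
            min_prior_stay_los=w.get("min_prior_stay_los", 2),
            comorbidity_window_days=w.get("comorbidity", 730),
            oxygen_window_days=w.get("oxygen", 365),
            vaccination_window_days=w.get("vaccination", 730),
            death_followup_days=w.get("death_followup", 30),
            precedence=d.get("precedence", "hcap_first"),
        )

    def describe_codesets(self) -> str:
        """Human-readable dump of every code set (the --show-codesets output)."""
        lines = []
        simple = [
            self.pneumonia, self.pneumonia_complications, self.copd, self.trauma,
            self.surgery_procedures, self.ventilation_procedures, self.stroke,
            self.respiratory_failure,
        ]
        for cs in simple:
            lines.append(f"{cs.name}: {', '.join(cs.prefixes)}")
        lines.append("comorbidities:")
        for k, cs in self.comorbidities.items():
            lines.append(f"  {k}: {', '.join(cs.prefixes)}")
        lines.append("aetiology priority (first match wins):")
        for name, cs in self.aetiology_priority:
            lines.append(f"  {name}: {', '.join(cs.prefixes)}")
        return "\n".join(lines)


def default_config() -> AnalysisConfig:
    """The documented default configuration.

    Pneumonia case definition 480-486 plus 487.0; complications of pneumonia
    (empyema / pleurisy with effusion / abscess of lung); COPD 490-492, 494,
    496; trauma 800-959; surgery = any operative-chapter procedure (01-86);
    continuous invasive mechanical ventilation 96.7x; acute stroke 430-434
    and 436.
    """
    return AnalysisConfig(
        pneumonia=CodeSet("pneumonia", tuple(_span(480, 486) + ["4870"])),
        pneumonia_complications=CodeSet(
            "pneumonia_complications", ("5100", "5109", "5111", "5119", "5130")
        ),
        copd=CodeSet("copd", ("490", "491", "492", "494", "496")),
        trauma=CodeSet("trauma", tuple(_span(800, 959))),
        surgery_procedures=CodeSet(
            "surgery_procedures", tuple(f"{i:02d}" for i in range(1, 87))
        ),
        ventilation_procedures=CodeSet("ventilation_procedures", ("967",)),
        stroke=CodeSet("stroke", ("430", "431", "432", "433", "434", "436")),
        respiratory_failure=CodeSet("respiratory_failure", ("5185", "5188", "7991")),
        comorbidities={k: CodeSet(k, tuple(v)) for k, v in _DEFAULT_COMORBIDITIES.items()},
        aetiology_priority=tuple(
            (name, CodeSet(name, tuple(p))) for name, p in _DEFAULT_AETIOLOGY
        ),
    )


def load_config(path) -> AnalysisConfig:
    with open(path) as fh:
        return AnalysisConfig.from_dict(yaml.safe_load(fh))


def save_config(config: AnalysisConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
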