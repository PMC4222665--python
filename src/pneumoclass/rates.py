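"""Stratified hospitalisation incidence rates with exact Poisson intervals.

Rates are events per 1000 resident-years.  The *average annual* rate over a
multi-year study deliberately reuses a single census year's resident counts
for every study year (person-years = residents x number of years), the
convention of the source surveillance design; *per-year* rates divide each
year's new cases by that year's own resident count.

Confidence intervals are exact Poisson (Garwood) intervals obtained from
chi-square quantiles:

    low  = qchisq(alpha/2, 2k) / 2,          (0 when k = 0)
    high = qchisq(1 - alpha/2, 2k + 2) / 2,

divided by person-years and scaled to 1000.  They are asymmetric for small
counts, matching the behaviour of small-stratum intervals in surveillance
tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StratumRate",
    "rate_per_1000",
    "poisson_ci_counts",
    "rate_ci",
    "average_annual_rates",
    "per_year_rates",
    "trend_report",
]

FINE_BANDS = ("65-69", "70-74", "75-79", "80-84", "85-89", "90+")
COARSE_OF_BAND = {b: ("65-79" if b in ("65-69", "70-74", "75-79") else "80+") for b in FINE_BANDS}


@dataclass(frozen=True)
class StratumRate:
    """Events, person-years, rate per 1000 and 95% CI for one stratum."""

    subtype: str
    age_group: str
    gender: str
    year: object  # calendar year or "average-annual"
    events: int
    person_years: float
    rate_per_1000: float
    ci_low: float
    ci_high: float


def rate_per_1000(events: int, person_years: float) -> float:
    """Events per 1000 person-years (full precision; round for display)."""
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    return 1000.0 * events / person_years


def poisson_ci_counts(events: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) interval for a Poisson count."""
    if events < 0:
        raise ValueError("events must be non-negative")
    alpha = 1.0 - level
    low = 0.0 if events == 0 else float(stats.chi2.ppf(alpha / 2.0, 2 * events) / 2.0)
    high = float(stats.chi2.ppf(1.0 - alpha / 2.0, 2 * events + 2) / 2.0)
    return low, high


def rate_ci(events: int, person_years: float, level: float = 0.95) -> tuple[float, float]:
    """Exact Poisson CI for a rate, per 1000 person-years."""
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    lo, hi = poisson_ci_counts(events, level)
    return 1000.0 * lo / person_years, 1000.0 * hi / person_years


def _stratum(subtype, age_group, gender, year, events, py) -> StratumRate:
    if py <= 0:
        if events > 0:
            raise ValueError(
                f"stratum ({subtype}, {age_group}, {gender}, {year}) has "
                f"{events} events but no person-years"
            )
        return StratumRate(subtype, age_group, gender, year, 0, py, 0.0, 0.0, float("nan"))
    lo, hi = rate_ci(events, py)
    return StratumRate(
        subtype, age_group, gender, year, int(events), float(py),
        rate_per_1000(events, py), lo, hi,
    )


def _rates_frame(strata: list[StratumRate]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in strata])


def average_annual_rates(
    episodes: pd.DataFrame,
    population: pd.DataFrame,
    denominator_year: int = 2008,
    n_years: int = 3,
    subtypes=("HCAP", "PNP", "CAP"),
) -> pd.DataFrame:
    """Average annual rates per 1000 residents, by subtype x age group x gender.

    Person-years are the ``denominator_year`` resident counts multiplied by
    ``n_years``; age groups are 65-79, 80+, and total; gender is male,
    female, and total.  Raises if the population table lacks the denominator
    year.
    """
    pop = population[population["year"] == denominator_year]
    if pop.empty:
        raise ValueError(f"population table has no rows for year {denominator_year}")
    pop = pop.assign(age_group=pop["age_band"].map(COARSE_OF_BAND))

    def residents(age_group, gender):
        sel = pop
        if age_group != "total":
            sel = sel[sel["age_group"] == age_group]
        if gender != "total":
            sel = sel[sel["gender"] == gender]
        return float(sel["resident_count"].sum())

    ep = episodes.assign(
        age_group=np.where(episodes["age_at_admission"] >= 80, "80+", "65-79")
    )
    strata = []
    for subtype in subtypes:
        for gender in ("male", "female", "total"):
            for age_group in ("65-79", "80+", "total"):
                sel = ep[ep["subtype"] == subtype]
                if gender != "total":
                    sel = sel[sel["gender"] == gender]
                if age_group != "total":
                    sel = sel[sel["age_group"] == age_group]
                py = residents(age_group, gender) * n_years
                strata.append(
                    _stratum(subtype, age_group, gender, "average-annual", len(sel), py)
                )
    return _rates_frame(strata)


def per_year_rates(
    episodes: pd.DataFrame,
    population: pd.DataFrame,
    subtypes=("HCAP", "PNP", "CAP"),
    years=None,
) -> pd.DataFrame:
    """Per-year rates by fine age band and subtype (genders combined).

    Each year's new cases are divided by that year's resident count for the
    band.  Raises a configuration error naming any requested year missing
    from the population table.
    """
    if years is None:
        years = sorted(episodes["year"].unique()) if not episodes.empty else []
    have = set(population["year"].unique())
    missing = [y for y in years if y not in have]
    if missing:
        raise ValueError(f"population table lacks denominators for year(s) {missing}")

    strata = []
    for year in years:
        pop_y = population[population["year"] == year]
        for band in FINE_BANDS:
            py = float(pop_y.loc[pop_y["age_band"] == band, "resident_count"].sum())
            in_band = episodes[
                (episodes["year"] == year)
                & (episodes["age_at_admission"].map(lambda a: _band_of(a)) == band)
            ]
            for subtype in subtypes:
                n = int((in_band["subtype"] == subtype).sum())
                strata.append(_stratum(subtype, band, "total", int(year), n, py))
    return _rates_frame(strata)


def _band_of(age) -> str | None:
    if age < 65:
        return None
    if age >= 90:
        return "90+"
    lo = 65 + 5 * ((int(age) - 65) // 5)
    return f"{lo}-{lo + 4}"


def trend_report(per_year: pd.DataFrame) -> pd.DataFrame:
    """Year-over-year rate listing per (subtype, age band) with CI flags.

    ``monotone_increase`` marks strata whose rates never decrease across the
    years and end above where they started; ``ci_nonoverlap`` marks strata
    whose first-year and last-year 95% intervals do not overlap (the informal
    significance screen used for small-stratum trends).
    """
    recs = []
    for (subtype, band), g in per_year.groupby(["subtype", "age_group"], sort=True):
        g = g.sort_values("year")
        years = g["year"].tolist()
        r = g["rate_per_1000"].to_numpy()
        lo = g["ci_low"].to_numpy()
        hi = g["ci_high"].to_numpy()
        monotone = bool(len(r) >= 2 and np.all(np.diff(r) >= 0) and r[-1] > r[0])
        nonoverlap = bool(
            len(r) >= 2 and (lo[-1] > hi[0] or lo[0] > hi[-1])
        )
        recs.append(
            {
                "subtype": subtype,
                "age_group": band,
                "years": years,
                "rates": [round(float(x), 3) for x in r],
                "monotone_increase": monotone,
                "ci_nonoverlap": nonoverlap,
            }
        )
    return pd.DataFrame.from_records(recs)
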