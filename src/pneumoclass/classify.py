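"""HCAP / PNP / CAP subtype assignment.

The three subtypes follow the healthcare-contact taxonomy used in
claims-based pneumonia surveillance:

* **HCAP** (healthcare-associated): the patient had dialysis or chemotherapy
  in the 30 days before the index admission, or a prior acute-care stay of at
  least two days — or any stay with a surgical procedure — discharged within
  the previous 180 days.  (The nursing-home residence criterion of the
  original clinical definition requires a residence registry and is not part
  of this algorithm.)
* **PNP** (probable nosocomial): pneumonia coded only as a secondary
  diagnosis, with a principal diagnosis other than pneumonia, complications
  of pneumonia, or COPD; a trauma principal diagnosis is the classic example
  and is flagged separately.
* **CAP** (community-acquired): the residual — any incident episode that is
  neither HCAP nor PNP.

All exposure windows are inclusive at the stated bound and end the day
before the index admission (day counts are >= 1: the index admission can
never be its own qualifying prior stay).  When an episode satisfies both the
HCAP and the PNP rules, precedence is configurable; the default puts HCAP
first.
"""

from __future__ import annotations

import pandas as pd

from .bundle import CohortBundle, split_codes
from .codes import AnalysisConfig

__all__ = [
    "build_exposure_profiles",
    "is_hcap",
    "is_pnp",
    "classify_episodes",
    "hcap_within_days_share",
]

SUBTYPES = ("HCAP", "PNP", "CAP")


def _min_days_since(episodes: pd.DataFrame, events: pd.DataFrame, date_col: str) -> pd.Series:
    """Per episode, the smallest whole-day gap to a strictly prior event."""
    if events.empty or episodes.empty:
        return pd.Series(dtype="float64")
    m = episodes[["admission_id", "patient_id", "admission_date"]].merge(
        events[["patient_id", date_col]], on="patient_id", how="inner"
    )
    m["delta"] = (m["admission_date"] - m[date_col]).dt.days
    m = m[m["delta"] >= 1]
    return m.groupby("admission_id")["delta"].min()


def build_exposure_profiles(
    episodes: pd.DataFrame, bundle: CohortBundle, config: AnalysisConfig
) -> pd.DataFrame:
    """Healthcare-contact exposures for each episode.

    Returns a frame indexed like ``episodes`` with columns
    ``days_since_last_dialysis`` / ``days_since_last_chemo`` (NaN when no
    strictly prior service exists), ``prior_stay_admission_id`` and
    ``days_since_prior_discharge`` for the most recent *qualifying* prior
    stay (>= 2-day stay or any surgical procedure, discharged within the
    prior-stay window before the index admission date).
    """
    out = episodes[["admission_id", "patient_id", "admission_date"]].copy()
    op = bundle.outpatient
    dial = _min_days_since(out, op[op["service_kind"] == "dialysis"], "service_date")
    chemo = _min_days_since(out, op[op["service_kind"] == "chemotherapy"], "service_date")
    out["days_since_last_dialysis"] = out["admission_id"].map(dial)
    out["days_since_last_chemo"] = out["admission_id"].map(chemo)

    adm = bundle.admissions
    out["prior_stay_admission_id"] = None
    out["days_since_prior_discharge"] = float("nan")
    if not adm.empty and not out.empty:
        m = out[["admission_id", "patient_id", "admission_date"]].merge(
            adm[["admission_id", "patient_id", "admission_date", "discharge_date", "procedures"]],
            on="patient_id",
            how="inner",
            suffixes=("", "_prior"),
        )
        m = m[m["discharge_date"] < m["admission_date"]]
        m["gap"] = (m["admission_date"] - m["discharge_date"]).dt.days
        m = m[m["gap"] <= config.prior_stay_window_days]
        if not m.empty:
            los = (m["discharge_date"] - m["admission_date_prior"]).dt.days
            surgery = m["procedures"].map(
                lambda s: any(config.surgery_procedures.matches(c) for c in split_codes(s))
            )
            m = m[(los >= config.min_prior_stay_los) | surgery]
        if not m.empty:
            m = m.sort_values(["admission_id", "gap", "admission_id_prior"], kind="mergesort")
            best = m.groupby("admission_id").first()
            out["prior_stay_admission_id"] = out["admission_id"].map(best["admission_id_prior"])
            out["days_since_prior_discharge"] = out["admission_id"].map(best["gap"])
    out.index = episodes.index
    return out.drop(columns=["patient_id", "admission_date"])


def is_hcap(profile_row, window_days: int = 30) -> bool:
    """True iff any healthcare-contact criterion fires for one profile row."""
    d = profile_row.get("days_since_last_dialysis")
    c = profile_row.get("days_since_last_chemo")
    return (
        (pd.notna(d) and d <= window_days)
        or (pd.notna(c) and c <= window_days)
        or pd.notna(profile_row.get("days_since_prior_discharge"))
    )


def is_pnp(principal_dx: str, pneumonia_position: str, config: AnalysisConfig) -> bool:
    """Probable-nosocomial rule for one episode (HCAP not yet considered)."""
    if pneumonia_position != "secondary_only":
        return False
    excluded = (
        config.pneumonia.matches(principal_dx)
        or config.pneumonia_complications.matches(principal_dx)
        or config.copd.matches(principal_dx)
    )
    return not excluded


def classify_episodes(
    episodes: pd.DataFrame, bundle: CohortBundle, config: AnalysisConfig
) -> pd.DataFrame:
    """Attach subtype labels and exposure columns to the episode frame.

    Adds ``subtype`` ({HCAP, PNP, CAP}), ``qualifying_reason``
    ({dialysis30, chemo30, prior_stay180, secondary_dx_rule, residual}),
    ``trauma_principal`` (the trauma special case of the PNP rule), and the
    exposure-profile columns.  Exactly one label per episode; the
    HCAP-versus-PNP precedence follows ``config.precedence``.
    """
    prof = build_exposure_profiles(episodes, bundle, config)
    out = episodes.copy()
    for c in prof.columns:
        out[c] = prof[c]

    w = config.dialysis_chemo_window_days
    dial = out["days_since_last_dialysis"].notna() & (out["days_since_last_dialysis"] <= w)
    chemo = out["days_since_last_chemo"].notna() & (out["days_since_last_chemo"] <= w)
    prior = out["days_since_prior_discharge"].notna()
    hcap = dial | chemo | prior

    pnp = out.apply(
        lambda r: is_pnp(r["principal_dx"], r["pneumonia_position"], config), axis=1
    ) if not out.empty else pd.Series(dtype=bool)

    subtype = []
    reason = []
    for h, p, d, ch in zip(hcap, pnp, dial, chemo):
        first_pnp = config.precedence == "pnp_first"
        if h and not (first_pnp and p):
            subtype.append("HCAP")
            # reason precedence mirrors the listed criteria: dialysis, chemo, prior stay
            reason.append("dialysis30" if d else ("chemo30" if ch else "prior_stay180"))
        elif p:
            subtype.append("PNP")
            reason.append("secondary_dx_rule")
        else:
            subtype.append("CAP")
            reason.append("residual")
    out["subtype"] = pd.Series(subtype, index=out.index, dtype=object)
    out["qualifying_reason"] = pd.Series(reason, index=out.index, dtype=object)
    out["trauma_principal"] = out["principal_dx"].map(
        lambda c: bool(c) and config.trauma.matches(c)
    ) & (out["subtype"] == "PNP") if not out.empty else pd.Series(dtype=bool)
    return out


def hcap_within_days_share(labeled: pd.DataFrame, days: int = 10) -> float:
    """Share of HCAP episodes whose qualifying prior stay ended within ``days``.

    The denominator is *all* HCAP episodes; episodes qualifying only through
    dialysis/chemotherapy (no prior stay) contribute to the denominator only.
    Returns NaN when there are no HCAP episodes.
    """
    h = labeled[labeled["subtype"] == "HCAP"]
    if h.empty:
        return float("nan")
    close = h["days_since_prior_discharge"].notna() & (h["days_since_prior_discharge"] <= days)
    return float(close.sum()) / float(len(h))
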