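import math

import pandas as pd
import pytest

from pneumoclass import (
    build_exposure_profiles,
    classify_episodes,
    deduplicate,
    default_config,
    find_candidates,
    hcap_within_days_share,
)

from conftest import make_admission, make_bundle, make_patient


def _episodes(bundle, config):
    eps, _ = deduplicate(find_candidates(bundle, config), config.dedup_window_days)
    return eps


def _classify_one(config, *, outpatient=(), extra_admissions=(), principal="486",
                  secondary="486"):
    """One index admission on 2007-06-01 plus optional exposure rows."""
    adm = [make_admission("IDX", admission="2007-06-01", discharge="2007-06-08",
                          principal=principal, secondary=secondary)]
    adm += list(extra_admissions)
    b = make_bundle(patients=[make_patient("P1")], admissions=adm, outpatient=outpatient)
    labeled = classify_episodes(_episodes(b, config), b, config)
    assert len(labeled) == 1
    return labeled.iloc[0]


def _service(kind, days_before, date="2007-06-01"):
    return {
        "patient_id": "P1",
        "service_date": pd.Timestamp(date) - pd.Timedelta(days=days_before),
        "service_kind": kind,
    }


def _prior_stay(gap_days, los, procedures="", aid="PRIOR", index_date="2007-06-01"):
    dis = pd.Timestamp(index_date) - pd.Timedelta(days=gap_days)
    return make_admission(
        aid, admission=dis - pd.Timedelta(days=los), discharge=dis,
        principal="78060", procedures=procedures,
    )


class TestExposureProfile:
    def test_dialysis_days_counted_to_admission(self, config):
        row = _classify_one(config, outpatient=[_service("dialysis", 12)])
        assert row["days_since_last_dialysis"] == 12

    def test_same_day_service_does_not_count(self, config):
        row = _classify_one(config, outpatient=[_service("dialysis", 0)])
        assert math.isnan(row["days_since_last_dialysis"])

    def test_qualifying_prior_stay_170_days(self, config):
        row = _classify_one(config, extra_admissions=[_prior_stay(170, 5)])
        assert row["days_since_prior_discharge"] == 170
        assert row["prior_stay_admission_id"] == "PRIOR"

    def test_one_day_stay_without_surgery_does_not_qualify(self, config):
        row = _classify_one(config, extra_admissions=[_prior_stay(10, 1)])
        assert math.isnan(row["days_since_prior_discharge"])

    def test_day_stay_with_surgery_qualifies(self, config):
        row = _classify_one(config, extra_admissions=[_prior_stay(10, 0, procedures="81.51")])
        assert row["days_since_prior_discharge"] == 10

    def test_stay_discharged_181_days_before_does_not_qualify(self, config):
        row = _classify_one(config, extra_admissions=[_prior_stay(181, 5)])
        assert math.isnan(row["days_since_prior_discharge"])
        row = _classify_one(config, extra_admissions=[_prior_stay(180, 5)])
        assert row["days_since_prior_discharge"] == 180

    def test_most_recent_qualifying_stay_wins(self, config):
        row = _classify_one(
            config,
            extra_admissions=[_prior_stay(90, 5, aid="OLD"), _prior_stay(20, 5, aid="NEW")],
        )
        assert row["prior_stay_admission_id"] == "NEW"
        assert row["days_since_prior_discharge"] == 20


class TestHcapBoundaries:
    def test_dialysis_30_days_inclusive(self, config):
        assert _classify_one(config, outpatient=[_service("dialysis", 30)])["subtype"] == "HCAP"

    def test_dialysis_31_days_is_not_hcap(self, config):
        assert _classify_one(config, outpatient=[_service("dialysis", 31)])["subtype"] == "CAP"

    def test_reason_precedence_dialysis_chemo_prior_stay(self, config):
        row = _classify_one(
            config,
            outpatient=[_service("chemotherapy", 5)],
            extra_admissions=[_prior_stay(60, 5)],
        )
        assert row["subtype"] == "HCAP"
        assert row["qualifying_reason"] == "chemo30"


class TestPnpRule:
    def test_trauma_principal_with_secondary_pneumonia(self, config):
        row = _classify_one(config, principal="820.0", secondary="486")
        assert row["subtype"] == "PNP"
        assert bool(row["trauma_principal"])

    def test_copd_principal_goes_to_cap(self, config):
        row = _classify_one(config, principal="491.21", secondary="486")
        assert row["subtype"] == "CAP"

    def test_pneumonia_complication_principal_goes_to_cap(self, config):
        row = _classify_one(config, principal="510.9", secondary="486")
        assert row["subtype"] == "CAP"

    def test_principal_pneumonia_is_not_pnp(self, config):
        row = _classify_one(config, principal="486", secondary="")
        assert row["subtype"] == "CAP"
        assert row["qualifying_reason"] == "residual"

    def test_hcap_beats_pnp_by_default(self, config):
        row = _classify_one(
            config, principal="428.0", secondary="486", outpatient=[_service("dialysis", 7)]
        )
        assert row["subtype"] == "HCAP"

    def test_pnp_first_precedence_flag(self, config):
        cfg = config.replace(precedence="pnp_first")
        row = _classify_one(
            cfg, principal="428.0", secondary="486", outpatient=[_service("dialysis", 7)]
        )
        assert row["subtype"] == "PNP"


# ---------------------------------------------------------------------------
# Exhaustive micro-cohort grid against an independently coded truth table.
# Factors: exposure x principal diagnosis x where the pneumonia code sits.
# ---------------------------------------------------------------------------

EXPOSURES = ("none", "dialysis15", "dialysis45", "prior_stay90")
PRINCIPALS = ("486", "491", "820", "428")
POSITIONS = ("principal", "secondary")


def _oracle(exposure: str, principal: str, position: str) -> str:
    """Truth table written straight from the subtype definitions."""
    if exposure in ("dialysis15", "prior_stay90"):
        return "HCAP"
    # pneumonia as a secondary diagnosis only, principal not pneumonia (486),
    # not a complication of pneumonia, not COPD (491): probable nosocomial
    if position == "secondary" and principal in ("820", "428"):
        return "PNP"
    return "CAP"


@pytest.mark.parametrize("exposure", EXPOSURES)
@pytest.mark.parametrize("principal", PRINCIPALS)
@pytest.mark.parametrize("position", POSITIONS)
def test_truth_table_grid(config, exposure, principal, position):
    if position == "principal":
        prin, sec = "486", ("" if principal == "486" else principal)
    else:
        prin, sec = principal, "486"
    outpatient = []
    extra = []
    if exposure == "dialysis15":
        outpatient = [_service("dialysis", 15)]
    elif exposure == "dialysis45":
        outpatient = [_service("dialysis", 45)]
    elif exposure == "prior_stay90":
        extra = [_prior_stay(90, 5)]
    row = _classify_one(config, principal=prin, secondary=sec, outpatient=outpatient,
                        extra_admissions=extra)
    effective_position = "principal" if prin == "486" else "secondary"
    assert row["subtype"] == _oracle(exposure, prin, effective_position)


def test_partition_and_monotonicity(small_cohort):
    """Every episode gets exactly one label; adding an exposure to a CAP
    episode can only move it to HCAP."""
    cfg, bundle, _ = small_cohort
    config = default_config()
    eps = _episodes(bundle, config)
    labeled = classify_episodes(eps, bundle, config)
    assert labeled["subtype"].isin(("HCAP", "PNP", "CAP")).all()
    assert labeled["subtype"].value_counts().sum() == len(eps)

    cap = labeled[labeled["subtype"] == "CAP"].head(20)
    extra = pd.DataFrame(
        {
            "patient_id": cap["patient_id"],
            "service_date": cap["admission_date"] - pd.Timedelta(days=3),
            "service_kind": "dialysis",
        }
    )
    bundle2 = type(bundle)(
        patients=bundle.patients, admissions=bundle.admissions,
        outpatient=pd.concat([bundle.outpatient, extra], ignore_index=True),
        dispensings=bundle.dispensings, vaccinations=bundle.vaccinations,
        deaths=bundle.deaths, population=bundle.population,
    )
    relabeled = classify_episodes(eps, bundle2, config)
    moved = relabeled.set_index("admission_id").loc[cap["admission_id"], "subtype"]
    assert (moved == "HCAP").all()


class TestWithinTenDays:
    def test_half_within_ten_days(self, config):
        b = make_bundle(
            patients=[make_patient("P1"), make_patient("P2", birth="1930-01-01")],
            admissions=[
                make_admission("A1", "P1", admission="2007-06-01", discharge="2007-06-08"),
                _prior_stay(7, 5, aid="S1"),
                make_admission("A2", "P2", admission="2007-06-01", discharge="2007-06-08"),
            ],
            outpatient=[dict(_service("dialysis", 4), patient_id="P2")],
        )
        labeled = classify_episodes(_episodes(b, config), b, config)
        assert set(labeled["subtype"]) == {"HCAP"}
        assert hcap_within_days_share(labeled) == 0.5

    def test_none_within_ten_days(self, config):
        row_bundle = make_bundle(
            patients=[make_patient("P1")],
            admissions=[
                make_admission("A1", "P1", admission="2007-06-01", discharge="2007-06-08"),
                _prior_stay(60, 5, aid="S1"),
            ],
        )
        labeled = classify_episodes(_episodes(row_bundle, config), row_bundle, config)
        assert hcap_within_days_share(labeled) == 0.0

    def test_printed_counts_reproduce_the_share(self):
        # 1172 of 2257 healthcare-associated episodes -> 51.9%
        assert round(100 * 1172 / 2257, 1) == 51.9
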