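import numpy as np
import pandas as pd
import pytest

from pneumoclass import (
    classify_episodes,
    deduplicate,
    find_candidates,
    run_pipeline,
    summarize_aetiology,
    summarize_table1,
)
from pneumoclass.covariates import (
    ascertain_comorbidities,
    ascertain_exposures,
    ascertain_severity_and_stroke,
    assign_aetiology,
    chi_square,
    compute_outcomes,
    percent,
)

from conftest import make_admission, make_bundle, make_patient


def _cohort_one(config, *, index_kw=None, extra_admissions=(), dispensings=(),
                vaccinations=(), deaths=()):
    index_kw = dict(
        dict(admission="2007-06-01", discharge="2007-06-08", principal="486"),
        **(index_kw or {}),
    )
    b = make_bundle(
        patients=[make_patient("P1")],
        admissions=[make_admission("IDX", **index_kw)] + list(extra_admissions),
        dispensings=dispensings,
        vaccinations=vaccinations,
        deaths=deaths,
    )
    eps, _ = deduplicate(find_candidates(b, config), config.dedup_window_days)
    labeled = classify_episodes(eps, b, config)
    return b, labeled


def _prior(aid, gap_admission_days, codes, index="2007-06-01", los=3):
    adm = pd.Timestamp(index) - pd.Timedelta(days=gap_admission_days)
    return make_admission(
        aid, admission=adm, discharge=adm + pd.Timedelta(days=los),
        principal=codes[0], secondary="|".join(codes[1:]),
    )


class TestComorbidityLookback:
    def test_prior_admission_within_two_years_counts(self, config):
        b, labeled = _cohort_one(config, extra_admissions=[_prior("H1", 400, ["428"])])
        com = ascertain_comorbidities(labeled, b, config)
        assert bool(com.loc[0, "heart_failure"])

    def test_prior_admission_outside_two_years_ignored(self, config):
        b, labeled = _cohort_one(config, extra_admissions=[_prior("H1", 800, ["428"])])
        com = ascertain_comorbidities(labeled, b, config)
        assert not com.loc[0, "heart_failure"]

    def test_index_secondary_diagnosis_counts(self, config):
        b, labeled = _cohort_one(config, index_kw={"secondary": "250.00"})
        com = ascertain_comorbidities(labeled, b, config)
        assert bool(com.loc[0, "diabetes"])

    def test_index_principal_does_not_count_for_comorbidity(self, config):
        # comorbidity from the index admission reads secondary fields only
        b, labeled = _cohort_one(config, index_kw={"principal": "428.0", "secondary": "486"})
        com = ascertain_comorbidities(labeled, b, config)
        assert not com.loc[0, "heart_failure"]

    def test_copd_history_needs_a_prior_admission(self, config):
        b, labeled = _cohort_one(config, index_kw={"secondary": "491.21"})
        com = ascertain_comorbidities(labeled, b, config)
        assert not com.loc[0, "copd_2y"]
        b, labeled = _cohort_one(config, extra_admissions=[_prior("H1", 300, ["491.21"])])
        com = ascertain_comorbidities(labeled, b, config)
        assert bool(com.loc[0, "copd_2y"])

    def test_widening_the_window_is_monotone(self, config):
        b, labeled = _cohort_one(config, extra_admissions=[_prior("H1", 700, ["428"])])
        narrow = ascertain_comorbidities(labeled, b, config.replace(comorbidity_window_days=365))
        wide = ascertain_comorbidities(labeled, b, config)
        for col in narrow.columns:
            assert not (narrow[col] & ~wide[col]).any(), col


class TestRegistryExposures:
    def _disp(self, days_before):
        return {
            "patient_id": "P1",
            "dispensing_date": pd.Timestamp("2007-06-01") - pd.Timedelta(days=days_before),
            "drug_class": "domiciliary_oxygen",
        }

    def _vacc(self, days_before):
        return {
            "patient_id": "P1",
            "vaccination_date": pd.Timestamp("2007-06-01") - pd.Timedelta(days=days_before),
            "vaccine_kind": "influenza",
        }

    def test_oxygen_within_year(self, config):
        b, labeled = _cohort_one(config, dispensings=[self._disp(100)])
        assert bool(ascertain_exposures(labeled, b, config).loc[0, "oxygen_therapy_1y"])

    def test_oxygen_outside_year(self, config):
        b, labeled = _cohort_one(config, dispensings=[self._disp(400)])
        assert not ascertain_exposures(labeled, b, config).loc[0, "oxygen_therapy_1y"]

    def test_vaccination_on_admission_day_is_strictly_prior(self, config):
        b, labeled = _cohort_one(config, vaccinations=[self._vacc(0)])
        assert not ascertain_exposures(labeled, b, config).loc[0, "influenza_vaccination_2y"]
        b, labeled = _cohort_one(config, vaccinations=[self._vacc(1)])
        assert bool(ascertain_exposures(labeled, b, config).loc[0, "influenza_vaccination_2y"])


class TestSeverityAndStroke:
    def test_ventilation_procedure(self, config):
        _, labeled = _cohort_one(config, index_kw={"procedures": "96.71"})
        sev = ascertain_severity_and_stroke(labeled, config)
        assert bool(sev.loc[0, "ventilation_same_admission"])

    def test_no_flags_by_default(self, config):
        _, labeled = _cohort_one(config)
        sev = ascertain_severity_and_stroke(labeled, config)
        assert not sev.loc[0, ["ventilation_same_admission", "icu_same_admission",
                               "acute_stroke_same_admission"]].any()

    def test_stroke_from_secondary_dx(self, config):
        _, labeled = _cohort_one(config, index_kw={"secondary": "434.11"})
        sev = ascertain_severity_and_stroke(labeled, config)
        assert bool(sev.loc[0, "acute_stroke_same_admission"])


class TestAetiology:
    @pytest.mark.parametrize(
        "principal,secondary,expected",
        [
            ("482.1", "", "pseudomonas"),
            ("486", "", "pneumonia_unspecified"),
            ("485", "482.0", "klebsiella"),       # specific beats unspecified
            ("486", "506.0", "chemical_fumes"),
            ("482.41", "", "mssa"),
            ("482.89", "", "other_specified_bacteria"),
            ("480.0", "", "other"),               # case code outside all groups
        ],
    )
    def test_priority_assignment(self, config, principal, secondary, expected):
        import warnings

        # every principal here belongs to the pneumonia case definition, so
        # the episode stays a principal-position candidate
        _, labeled = _cohort_one(
            config, index_kw={"principal": principal, "secondary": secondary}
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aet = assign_aetiology(labeled, config)
        assert aet.iloc[0] == expected

    def test_every_episode_gets_exactly_one_label(self, config, small_cohort):
        _, bundle, _ = small_cohort
        cohort, _ = run_pipeline(bundle, config, check=False)
        assert cohort["aetiology"].notna().all()
        tab = summarize_aetiology(cohort)
        for s in ("HCAP", "PNP", "CAP"):
            assert tab[f"{s}_n"].sum() == (cohort["subtype"] == s).sum()


class TestOutcomes:
    def _death(self, offset_days):
        return {
            "patient_id": "P1",
            "death_date": pd.Timestamp("2007-06-01") + pd.Timedelta(days=offset_days),
            "cause_code": "486",
        }

    def test_discharged_alive_then_death_within_30_days(self, config):
        b, labeled = _cohort_one(
            config,
            index_kw={"admission": "2007-06-01", "discharge": "2007-06-13"},
            deaths=[self._death(25)],
        )
        out = compute_outcomes(labeled, b)
        assert not out.loc[0, "in_hospital_death"]
        assert bool(out.loc[0, "death_within_30d"])
        assert out.loc[0, "length_of_stay"] == 12

    def test_in_hospital_death_day_8(self, config):
        b, labeled = _cohort_one(
            config,
            index_kw={"admission": "2007-06-01", "discharge": "2007-06-09", "status": "died"},
            deaths=[self._death(8)],
        )
        out = compute_outcomes(labeled, b)
        assert bool(out.loc[0, "in_hospital_death"])
        assert bool(out.loc[0, "death_within_30d"])
        assert out.loc[0, "length_of_stay"] == 8

    def test_death_day_31_not_thirty_day(self, config):
        b, labeled = _cohort_one(config, deaths=[self._death(31)])
        out = compute_outcomes(labeled, b)
        assert not out.loc[0, "death_within_30d"]

    def test_no_death_record(self, config):
        b, labeled = _cohort_one(config)
        out = compute_outcomes(labeled, b)
        assert not out.loc[0, "death_within_30d"]

    def test_death_before_admission_is_an_error(self, config):
        b, labeled = _cohort_one(config, deaths=[self._death(-10)])
        with pytest.raises(ValueError, match="death date before admission"):
            compute_outcomes(labeled, b)


class TestSummaries:
    def test_percent_matches_printed_rounding(self):
        assert percent(729, 2257) == 32.3
        assert percent(863, 2257) == 38.2

    def test_chi_square_2x2_without_continuity_correction(self):
        # hand computation: n(ad-bc)^2 / (r1 r2 c1 c2)
        #  = 100 * (10*40 - 20*30)^2 / (30*70*40*60) = 0.79365
        stat, dof, p = chi_square([[10, 20], [30, 40]])
        assert stat == pytest.approx(0.79365, abs=1e-4)
        assert dof == 1

    def test_table1_percentages_sum_to_100_within_rows(self, config, small_cohort):
        _, bundle, _ = small_cohort
        cohort, _ = run_pipeline(bundle, config, check=False)
        t1 = summarize_table1(cohort)
        rows = t1.rows
        gender = rows[rows["section"] == "Gender"]
        for s in ("HCAP", "PNP", "CAP"):
            assert gender[f"{s}_n"].sum() == t1.n_by_subtype[s]
            assert gender[f"{s}_pct"].sum() == pytest.approx(100.0, abs=0.2)
        # the in-hospital mortality invariant: deaths within LOS<=30 are 30-day deaths
        short = cohort[cohort["length_of_stay"] <= 30]
        assert (~short["in_hospital_death"] | short["death_within_30d"]).all()

    def test_empty_subtype_skips_chi_square(self, config):
        _, labeled = _cohort_one(config)
        b, _ = _cohort_one(config)
        cohort, _ = run_pipeline(b, config, check=False)
        with pytest.warns(UserWarning, match="chi-square skipped"):
            t1 = summarize_table1(cohort)
        assert t1.n_by_subtype["HCAP"] == 0
        assert np.isnan(t1.rows["chi2"]).all()

    def test_lower_median_for_even_counts(self, config):
        from pneumoclass.covariates import _lower_median

        assert _lower_median(pd.Series([1, 2, 3, 4])) == 2
        assert _lower_median(pd.Series([5])) == 5
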