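"""Cohort summaries, estimators, and the two-cohort comparison machinery."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cahscreen import (
    PatientRecord,
    clinical_recognition_rate,
    compare_cohorts,
    estimate_sw_mortality_from_deficit,
    first_tier_fp_rate,
    frame_to_records,
    params_from_cohorts,
    read_cohort_csv,
    records_to_frame,
    screened_incidence_denominator,
    summarize_cohort,
    write_cohort_csv,
    generate_cohort,
    paper_truth_presets,
)
from cahscreen.synthetic import with_size


def make_record(**overrides) -> PatientRecord:
    base = dict(
        cohort="unscreened", form="SW", sex_karyotype="46XY", birth_group="post1999",
        recognized_early=False, dehydrated=True, hospitalized=False, icu=False,
        icu_days=0.0, sodium=125.0, age_at_diagnosis=30.0,
        gh_treated=False, gh_years=0.0, gnrha_treated=False, gnrha_years=0.0,
        reared_male_46xx=False,
    )
    base.update(overrides)
    return PatientRecord(**base)


class TestPatientRecordInvariants:
    def test_icu_requires_hospitalized(self):
        with pytest.raises(ValueError, match="icu implies hospitalized"):
            make_record(icu=True, hospitalized=False)

    def test_hospitalized_requires_dehydrated(self):
        with pytest.raises(ValueError, match="hospitalized implies dehydrated"):
            make_record(dehydrated=False, hospitalized=True)

    def test_therapy_years_require_flag(self):
        with pytest.raises(ValueError, match="gh_years"):
            make_record(gh_years=2.0)


class TestSummarize:
    def test_hospitalized_fraction_from_published_counts(self):
        """11 hospitalized of 19 screened SW patients reports as 58%."""
        records = [make_record(cohort="screened", hospitalized=i < 11) for i in range(19)]
        s = summarize_cohort(records)
        assert s.prop_hospitalized == pytest.approx(11 / 19)
        assert round(s.prop_hospitalized, 2) == 0.58

    def test_toy_sodium_ci_from_t_quantile(self):
        """{120, 121, 122}: mean 121, CI half-width t(2) * s / sqrt(3) with s = 1."""
        records = [make_record(sodium=v) for v in (120.0, 121.0, 122.0)]
        s = summarize_cohort(records)
        half = stats.t.ppf(0.975, 2) / math.sqrt(3)
        assert s.mean_sodium.mean == pytest.approx(121.0)
        assert s.mean_sodium.ci_low == pytest.approx(121.0 - half)
        assert s.mean_sodium.ci_high == pytest.approx(121.0 + half)
        assert half == pytest.approx(4.302652 / math.sqrt(3), abs=1e-4)

    def test_single_record_mean_defined_ci_unavailable(self):
        s = summarize_cohort([make_record(sodium=130.0)])
        assert s.mean_sodium.mean == 130.0
        assert s.mean_sodium.ci_low is None and s.mean_sodium.ci_high is None

    def test_empty_subset_statistics_unavailable_not_zero(self):
        s = summarize_cohort([make_record()], subset="form == 'SV'")
        assert s.n == 0
        assert s.mean_sodium is None
        assert s.prop_hospitalized is None

    def test_subset_query(self):
        records = [make_record(form="SW"), make_record(form="SV", dehydrated=False)]
        assert summarize_cohort(records, subset="form == 'SW'").n == 1


class TestEstimators:
    @pytest.mark.parametrize("screened, unscreened, expected",
                             [(0.75, 0.64, 0.11), (0.75, 0.75, 0.0), (0.75, 0.43, 0.32)])
    def test_mortality_deficit(self, screened, unscreened, expected):
        assert estimate_sw_mortality_from_deficit(screened, unscreened) == pytest.approx(expected)

    def test_deficit_floored_at_zero(self):
        assert estimate_sw_mortality_from_deficit(0.5, 0.9) == 0.0

    def test_deficit_antitone_in_unscreened_fraction(self):
        values = [estimate_sw_mortality_from_deficit(0.75, x) for x in np.linspace(0, 1, 21)]
        assert values == sorted(values, reverse=True)

    def test_sw_recognition_is_crisis_complement(self):
        records = [make_record(dehydrated=i < 84, recognized_early=i >= 84) for i in range(100)]
        assert clinical_recognition_rate(records, "SW") == pytest.approx(0.16)

    def test_sv_recognition_neonatal_window(self):
        records = [make_record(form="SV", dehydrated=False,
                               age_at_diagnosis=20.0 if i < 11 else 400.0)
                   for i in range(100)]
        assert clinical_recognition_rate(records, "SV") == pytest.approx(0.11)

    def test_all_recognized(self):
        records = [make_record(dehydrated=False, recognized_early=True) for _ in range(5)]
        assert clinical_recognition_rate(records, "SW") == 1.0

    def test_empty_form_rejected(self):
        with pytest.raises(ValueError, match="SV"):
            clinical_recognition_rate([make_record(form="SW")], "SV")

    def test_screened_program_descriptives(self):
        assert screened_incidence_denominator(25, 378_379) == 15_135
        assert round(100 * first_tier_fp_rate(843, 378_379), 2) == 0.22


class TestCompareCohorts:
    def test_self_comparison_zero_differences(self):
        cohort = generate_cohort(with_size(paper_truth_presets("unscreened"), seed=7))
        table = compare_cohorts(cohort, cohort)
        diffs = table["difference"].dropna()
        assert (diffs.abs() < 1e-12).all()

    def test_chi_square_matches_closed_form_2x2(self):
        """Hospitalization 96/106 vs 30/50 against the hand 2x2 formula
        chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
        a_rec = [make_record(hospitalized=i < 96) for i in range(106)]
        b_rec = [make_record(cohort="screened", hospitalized=i < 30) for i in range(50)]
        table = compare_cohorts(a_rec, b_rec)
        row = table[table["variable"] == "hospitalized"].iloc[0]
        a, b, c, d = 96, 10, 30, 20
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert row["test"] == "chi_square"
        assert row["statistic"] == pytest.approx(expected)

    def test_fisher_used_when_expected_cell_below_five(self):
        # 96/106 vs 11/19: the smallest expected cell is 19 x 18 / 125 < 5
        a_rec = [make_record(hospitalized=i < 96) for i in range(106)]
        b_rec = [make_record(cohort="screened", hospitalized=i < 11) for i in range(19)]
        table = compare_cohorts(a_rec, b_rec)
        assert table[table["variable"] == "hospitalized"].iloc[0]["test"] == "fisher_exact"

    def test_symmetry_up_to_sign(self):
        a_rec = generate_cohort(with_size(paper_truth_presets("unscreened"), seed=1))
        b_rec = generate_cohort(with_size(paper_truth_presets("screened"), seed=2))
        ab = compare_cohorts(a_rec, b_rec).set_index("variable")
        ba = compare_cohorts(b_rec, a_rec).set_index("variable")
        for var in ab.index:
            da, db = ab.loc[var, "difference"], ba.loc[var, "difference"]
            if da is not None and not (isinstance(da, float) and math.isnan(da)):
                assert da == pytest.approx(-db)
                assert ab.loc[var, "p_value"] == pytest.approx(ba.loc[var, "p_value"], abs=1e-9)

    def test_type_i_error_uniform_under_null(self):
        """With both cohorts drawn from identical truth, Welch-t p-values for
        sodium are uniform on (0, 1): Kolmogorov-Smirnov over 200 replicates."""
        truth = paper_truth_presets("unscreened")
        pvals = []
        for rep in range(200):
            a_rec = generate_cohort(with_size(truth, n_sw=40, n_sv=0, seed=10_000 + 2 * rep))
            b_rec = generate_cohort(with_size(truth, n_sw=40, n_sv=0, seed=10_001 + 2 * rep))
            table = compare_cohorts(a_rec, b_rec).set_index("variable")
            pvals.append(table.loc["sodium", "p_value"])
        _, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 0.001


@pytest.fixture(scope="module")
def cohorts():
    unscreened = generate_cohort(with_size(paper_truth_presets("unscreened"),
                                           n_sw=4000, n_sv=4000, seed=3))
    screened = generate_cohort(with_size(paper_truth_presets("screened"),
                                         n_sw=4000, n_sv=1000, seed=4))
    return unscreened, screened


class TestParamsFromCohorts:
    def test_raw_cohort_values(self, cohorts):
        unscreened, screened = cohorts
        est = params_from_cohorts(unscreened, screened)
        assert est["epidemiology.clinical_recognition_sw"] == pytest.approx(0.16, abs=0.03)
        assert est["epidemiology.clinical_recognition_sv"] == pytest.approx(0.11, abs=0.03)
        assert est["sw.hosp_rate_unscreened"] == pytest.approx(0.91, abs=0.03)
        assert est["sw.hosp_rate_screened"] == pytest.approx(0.58, abs=0.03)

    def test_partner_averaging(self, cohorts):
        unscreened, screened = cohorts
        raw = params_from_cohorts(unscreened, screened)
        avg = params_from_cohorts(
            unscreened, screened,
            averaging_partner={"epidemiology.clinical_recognition_sw": 0.56})
        # averaged field moves halfway to the partner value; others are raw
        expected = (raw["epidemiology.clinical_recognition_sw"] + 0.56) / 2
        assert avg["epidemiology.clinical_recognition_sw"] == pytest.approx(expected)
        assert avg["epidemiology.clinical_recognition_sv"] == raw[
            "epidemiology.clinical_recognition_sv"]
        # with the published 16% cohort value this is the base-case 36% average
        assert (0.16 + 0.56) / 2 == pytest.approx(0.36)

    def test_mortality_deficit_path(self, cohorts):
        unscreened, screened = cohorts
        est = params_from_cohorts(unscreened, screened, assumed_sw_fraction_screened=0.75)
        frame = records_to_frame(unscreened)
        observed_sw = (frame["form"] == "SW").mean()
        assert est["epidemiology.sw_mortality_unscreened"] == pytest.approx(
            max(0.75 - observed_sw, 0.0), abs=1e-9)


def test_cohort_csv_round_trip(tmp_path):
    records = generate_cohort(with_size(paper_truth_presets("screened"), seed=5))
    path = tmp_path / "cohort.csv"
    write_cohort_csv(records, path)
    back = read_cohort_csv(path)
    pd.testing.assert_frame_equal(records_to_frame(back), records_to_frame(records),
                                  check_exact=False, rtol=1e-12)


def test_csv_missing_column_rejected(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("cohort,form\nscreened,SW\n")
    with pytest.raises(ValueError, match="missing columns"):
        read_cohort_csv(path)
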