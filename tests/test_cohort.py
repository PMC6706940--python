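"""Phenotype transforms, classification, published-count tabulation and the
interaction regression."""

import numpy as np
import pandas as pd
import pytest

from cpeparch import (CPeptideRegression, SyntheticConfig, antibody_positive,
                      classify_possible_t2, abneg_by_duration_cpeptide,
                      fit_cpeptide_regression, loess_surface,
                      prevalence_by_onset_duration, simulate_study,
                      transform_cpeptide)
from cpeparch import datasets
from cpeparch.cohort import REGRESSION_TERMS
from cpeparch.exceptions import AlignmentError, ConfigurationError
from cpeparch.loess import loess_fit_grid


class TestTransform:
    @pytest.mark.parametrize("value,expect", [
        (100.0, 2.0), (2.0, 0.0), (1.0, 0.0), (3.0, np.log10(3.0)),
        (0.0, 0.0), (1000.0, 3.0),
    ])
    def test_log10_with_censoring(self, value, expect):
        assert transform_cpeptide(value) == pytest.approx(expect)

    def test_negative_is_error(self):
        with pytest.raises(ValueError):
            transform_cpeptide(-1.0)

    def test_monotone_above_lod(self):
        x = np.linspace(3.0, 1000.0, 200)
        y = transform_cpeptide(x)
        assert np.all(np.diff(y) >= 0)


class TestAntibodyPositive:
    @pytest.mark.parametrize("analyte,titre,age,expect", [
        ("GAD", 12.0, 40.0, True), ("GAD", 11.0, 40.0, False),
        ("IA2", 8.0, 40.0, True), ("IA2", 0.0, 40.0, False),
        ("ZnT8", 20.0, 25.0, False), ("ZnT8", 20.0, 35.0, True),
        ("ZnT8", 66.0, 25.0, True), ("ZnT8", 9.0, 35.0, False),
    ])
    def test_thresholds(self, analyte, titre, age, expect):
        assert antibody_positive(analyte, titre, age) is expect

    def test_unknown_analyte_errors(self):
        with pytest.raises(ConfigurationError):
            antibody_positive("IAA", 1.0, 30.0)


class TestClassification:
    def _rec(self, cpep, gad=0.0, ia2=0.0, znt8=0.0, age=40.0):
        return pd.DataFrame([{"cpeptide": cpep, "gad": gad, "ia2": ia2,
                              "znt8": znt8, "age_sampling": age}])

    def test_high_cpeptide_all_negative_is_possible_t2(self):
        assert classify_possible_t2(self._rec(700.0)).iloc[0] == "possible_t2"

    def test_any_positive_antibody_is_definite_t1(self):
        assert classify_possible_t2(self._rec(700.0, gad=20.0)).iloc[0] == "definite_t1"

    def test_boundary_600_is_definite_t1(self):
        assert classify_possible_t2(self._rec(600.0)).iloc[0] == "definite_t1"

    def test_missing_titre_flagged_not_classified(self):
        out = classify_possible_t2(self._rec(700.0, gad=np.nan))
        assert out.isna().iloc[0]

    def test_partition_over_fixture(self):
        recs = datasets.expand_autoantibody_records()
        labels = classify_possible_t2(recs)
        assert set(labels.unique()) == {"definite_t1", "possible_t2"}
        assert labels.notna().all()


class TestPrevalenceTables:
    def test_reproduces_published_detectable_percentages(self):
        recs = datasets.expand_prevalence_records()
        table = prevalence_by_onset_duration(recs).with_margins()
        pct = table.to_frame()
        assert pct.loc["15 or more", "0 to 15"] == 19
        assert pct.loc["0 to 5", "35 or more"] == 92
        expected = datasets.expected_percent(datasets.CPEPTIDE_PREVALENCE_COUNTS)
        for (dbin, obin), want in expected.items():
            assert pct.loc[dbin, obin] == want
        # margins equal sums of the printed counts
        assert table.denominators[-1, 0] == 17 + 128 + 237 + 1643
        assert table.numerators[-1, 0] == 469
        assert pct.loc["All", "0 to 15"] == 23
        assert pct.loc["All", "35 or more"] == 64

    def test_reproduces_published_abneg_percentages(self):
        recs = datasets.expand_autoantibody_records()
        table = abneg_by_duration_cpeptide(recs).with_margins()
        pct = table.to_frame()
        expected = datasets.expected_percent(datasets.AUTOANTIBODY_NEGATIVE_COUNTS)
        for (dbin, cbin), want in expected.items():
            assert pct.loc[dbin, cbin] == want
        assert pct.loc["15 or more", "(600, 7000]"] == 80
        assert table.numerators[-1, -1] == 1148 + 175 + 145 + 203
        assert pct.loc["All", "[0, 30]"] == 27

    def test_possible_t2_count_matches_published(self):
        recs = datasets.expand_autoantibody_records()
        labels = classify_possible_t2(recs)
        assert int((labels == "possible_t2").sum()) == 203

    def test_empty_bin_renders_blank(self):
        recs = pd.DataFrame([{"age_onset": 5.0, "duration": 2.0,
                              "cpeptide": 100.0, "individual_id": "x"}])
        table = prevalence_by_onset_duration(recs)
        frame = table.to_frame(formatted=True)
        assert frame.loc["15 or more", "35 or more"] == ""
        assert np.isnan(table.percent[3, 3])

    def test_all_positive_fixture_gives_zero_percent_cells(self):
        recs = datasets.expand_autoantibody_records().copy()
        recs["gad"] = 50.0
        table = abneg_by_duration_cpeptide(recs)
        assert np.nansum(table.numerators) == 0
        assert np.all(table.percent[table.denominators > 0] == 0)


def _recovery_config(**kw):
    """Low-censoring regime where OLS is the generative model's estimator."""
    base = dict(seed=21, n_cohort=5000, intercept=2.0, lod=1e-6,
                h2_cpep=0.0, serotype_cpep_effect=0.0)
    # the generative model covers the whole simulated cohort, so recovery
    # fits keep every individual (no possible-type-2 exclusion)
    base.update(kw)
    return SyntheticConfig(**base)


def _scores_frame(study):
    return pd.DataFrame(
        {"t1_score": study.phenotypes["true_t1_score"].to_numpy(),
         "t2_score": study.phenotypes["true_t2_score"].to_numpy()},
        index=study.phenotypes["individual_id"])


class TestRegression:
    def test_recovers_generating_coefficients_within_2se(self):
        study = simulate_study(_recovery_config())
        res = fit_cpeptide_regression(study.phenotypes, _scores_frame(study),
                                      lod=study.config.lod,
                                      exclude_possible_t2=False)
        truth = study.truth.regression_truth
        for term in REGRESSION_TERMS:
            z = abs(res.loc[term, "estimate"] - truth[term]) / res.loc[term, "se"]
            assert z < 2.0, term

    def test_zero_noise_exact_recovery(self):
        study = simulate_study(_recovery_config(n_cohort=1000, resid_sd=0.0))
        res = fit_cpeptide_regression(study.phenotypes, _scores_frame(study),
                                      lod=study.config.lod,
                                      exclude_possible_t2=False)
        truth = study.truth.regression_truth
        for term in REGRESSION_TERMS:
            assert res.loc[term, "estimate"] == pytest.approx(truth[term], abs=1e-8)
        assert res.loc["const", "estimate"] == pytest.approx(2.0, abs=1e-8)

    def test_centering_invariance_of_interactions(self):
        study = simulate_study(_recovery_config(n_cohort=800))
        base = fit_cpeptide_regression(study.phenotypes, _scores_frame(study),
                                       lod=study.config.lod,
                                       exclude_possible_t2=False)
        shifted = study.phenotypes.copy()
        shifted["bmi"] = shifted["bmi"] + 7.0
        shifted["duration"] = shifted["duration"] + 3.0
        res = fit_cpeptide_regression(shifted, _scores_frame(study),
                                      lod=study.config.lod,
                                      exclude_possible_t2=False)
        for term in REGRESSION_TERMS:
            if term.startswith("sqrt_onset:"):
                assert res.loc[term, "estimate"] == pytest.approx(
                    base.loc[term, "estimate"], abs=1e-10)

    def test_rank_deficiency_names_collinear_terms(self):
        study = simulate_study(_recovery_config(n_cohort=300))
        ph = study.phenotypes.copy()
        sc = _scores_frame(study)
        sc["t2_score"] = sc["t1_score"]  # duplicate score column
        with pytest.raises(AlignmentError, match="t2_score"):
            fit_cpeptide_regression(ph, sc, lod=study.config.lod)

    def test_estimator_wrapper_matches_function(self):
        study = simulate_study(_recovery_config(n_cohort=500))
        est = CPeptideRegression(lod=study.config.lod,
                                 exclude_possible_t2=False).fit(
            study.phenotypes, _scores_frame(study))
        res = fit_cpeptide_regression(study.phenotypes, _scores_frame(study),
                                      lod=study.config.lod,
                                      exclude_possible_t2=False)
        np.testing.assert_allclose(
            est.coef_, res.loc[REGRESSION_TERMS, "estimate"].to_numpy())
        assert est.get_params()["lod"] == study.config.lod


class TestLoess:
    def test_constant_surface(self):
        rng = np.random.default_rng(0)
        onset = rng.uniform(5, 50, 300)
        duration = rng.uniform(1, 40, 300)
        logc = np.full(300, 1.5)
        _, _, surface = loess_surface(onset, duration, logc,
                                      grid_onset=[10, 30], grid_duration=[5, 20])
        np.testing.assert_allclose(surface, 10 ** 1.5, rtol=1e-10)

    def test_planar_data_reproduced_exactly(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 400)
        y = rng.uniform(0, 10, 400)
        z = 0.5 + 0.2 * x - 0.1 * y
        g1 = np.array([3.0, 5.0, 7.0])
        g2 = np.array([4.0, 6.0])
        fit = loess_fit_grid(x, y, z, g1, g2, degree=2, span=0.25)
        expect = 0.5 + 0.2 * g1[:, None] - 0.1 * g2[None, :]
        np.testing.assert_allclose(fit, expect, atol=1e-6)

    def test_monotone_truth_gives_monotone_fit(self):
        rng = np.random.default_rng(2)
        onset = rng.uniform(5, 50, 600)
        duration = rng.uniform(0, 40, 600)
        logc = 2.0 - 0.04 * duration + 0.01 * onset + rng.normal(0, 0.02, 600)
        grid_d = np.linspace(5, 35, 7)
        _, _, surface = loess_surface(onset, duration, logc,
                                      grid_onset=[20.0, 35.0],
                                      grid_duration=grid_d, span=0.4)
        assert np.all(np.diff(surface, axis=1) < 0)

    def test_span_too_small_errors(self):
        with pytest.raises(ConfigurationError):
            loess_fit_grid(np.arange(10.0), np.arange(10.0), np.arange(10.0),
                           [1.0], [1.0], span=0.2)
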