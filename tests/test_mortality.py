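"""Gompertz-family hazards, likelihoods, fitting, model selection and group tests."""

import numpy as np
import pytest
from scipy import integrate, stats

from rapalife.mortality import (
    CohortSurvival,
    GompertzFamilyModel,
    compare_groups,
    fit_model,
    hazard,
    log_likelihood,
    select_model,
    survival,
)
from rapalife.synthetic_data import sample_death_times


def random_model(family, rng):
    return GompertzFamilyModel(
        family,
        a=float(rng.uniform(1e-4, 5e-3)),
        b=float(rng.uniform(0.05, 0.3)),
        c=float(rng.uniform(1e-4, 2e-3)) if family.endswith("makeham") else None,
        s=float(rng.uniform(0.1, 2.0)) if family.startswith("logistic") else None,
    )


class TestHazardSurvival:
    def test_gompertz_hazard_at_origin(self):
        m = GompertzFamilyModel("gompertz", a=0.001, b=0.2)
        assert hazard(m, 0.0) == pytest.approx(0.001)

    def test_makeham_hazard_at_origin(self):
        m = GompertzFamilyModel("gompertz_makeham", a=0.001, b=0.2, c=0.0005)
        assert hazard(m, 0.0) == pytest.approx(0.0015)

    def test_logistic_hazard_plateaus_at_b_over_s(self):
        m = GompertzFamilyModel("logistic", a=0.001, b=0.2, s=0.5)
        assert hazard(m, 200.0) == pytest.approx(0.2 / 0.5, rel=1e-6)

    def test_survival_is_one_at_origin(self):
        rng = np.random.default_rng(0)
        for fam in ("gompertz", "gompertz_makeham", "logistic", "logistic_makeham"):
            assert survival(random_model(fam, rng), 0.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("family", ["gompertz", "gompertz_makeham",
                                        "logistic", "logistic_makeham"])
    def test_survival_matches_hazard_quadrature(self, family):
        """S(x) equals exp(−∫u) computed by adaptive quadrature, within 1e-8."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            m = random_model(family, rng)
            for x in (2.0, 10.0, 25.0):
                H, _ = integrate.quad(lambda t: hazard(m, t), 0.0, x,
                                      epsabs=1e-12, epsrel=1e-12)
                assert survival(m, x) == pytest.approx(np.exp(-H), abs=1e-8)

    def test_makeham_reduces_to_exponential_when_a_vanishes(self):
        m = GompertzFamilyModel("gompertz_makeham", a=1e-12, b=0.2, c=0.05)
        assert survival(m, 10.0) == pytest.approx(np.exp(-0.5), rel=1e-6)

    def test_negative_age_rejected(self):
        m = GompertzFamilyModel("gompertz", a=0.001, b=0.2)
        with pytest.raises(ValueError):
            hazard(m, -1.0)

    def test_invalid_parameters_name_the_parameter(self):
        with pytest.raises(ValueError, match="a"):
            GompertzFamilyModel("gompertz", a=-0.1, b=0.2)
        with pytest.raises(ValueError, match="s"):
            GompertzFamilyModel("logistic", a=0.001, b=0.2, s=-1.0)


class TestLogLikelihood:
    def test_single_early_death_equals_log_hazard(self):
        m = GompertzFamilyModel("gompertz", a=0.01, b=0.2)
        c = CohortSurvival(np.array([1e-10]), np.array([True]))
        assert log_likelihood(m, c) == pytest.approx(np.log(0.01), abs=1e-6)

    def test_additive_over_disjoint_cohorts(self):
        m = GompertzFamilyModel("gompertz", a=0.001, b=0.15)
        a = CohortSurvival(np.array([5.0, 10.0]), np.array([True, False]))
        b = CohortSurvival(np.array([15.0, 20.0, 25.0]), np.array([True, True, True]))
        assert log_likelihood(m, a.concat(b)) == pytest.approx(
            log_likelihood(m, a) + log_likelihood(m, b), abs=1e-10)

    def test_printed_ages_match_quadrature_oracle(self):
        """logL of deaths at 5,10,15,20,25 months under (a=0.001, b=0.15)."""
        m = GompertzFamilyModel("gompertz", a=0.001, b=0.15)
        ages = np.array([5.0, 10.0, 15.0, 20.0, 25.0])
        expected = 0.0
        for x in ages:
            H, _ = integrate.quad(lambda t: hazard(m, t), 0.0, x,
                                  epsabs=1e-13, epsrel=1e-13)
            expected += np.log(hazard(m, x)) - H
        c = CohortSurvival(ages, np.ones(5, dtype=bool))
        assert log_likelihood(m, c) == pytest.approx(expected, abs=1e-8)

    def test_logistic_small_s_reproduces_gompertz(self, large_gompertz_cohort):
        g = GompertzFamilyModel("gompertz", a=0.001, b=0.2)
        l = GompertzFamilyModel("logistic", a=0.001, b=0.2, s=1e-6)
        c = large_gompertz_cohort
        assert log_likelihood(l, c) == pytest.approx(log_likelihood(g, c), abs=1e-4)


class TestFitting:
    def test_mle_beats_generating_parameters(self, gompertz_model, large_gompertz_cohort):
        fit = fit_model(large_gompertz_cohort, "gompertz")
        assert fit.converged
        assert fit.log_likelihood >= log_likelihood(gompertz_model, large_gompertz_cohort)

    def test_mle_agrees_with_grid_search_oracle(self):
        """On a 20-death sample the MLE lands within one cell of a dense grid."""
        rng = np.random.default_rng(3)
        m = GompertzFamilyModel("gompertz", a=0.002, b=0.18)
        t = sample_death_times(m, 20, rng)
        c = CohortSurvival(t, np.ones(20, dtype=bool))
        fit = fit_model(c, "gompertz")
        a_grid = np.exp(np.linspace(np.log(1e-5), np.log(0.1), 120))
        b_grid = np.exp(np.linspace(np.log(0.01), np.log(1.0), 120))
        ll = np.array([[log_likelihood(GompertzFamilyModel("gompertz", a=a, b=b), c)
                        for b in b_grid] for a in a_grid])
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        # within one grid cell on the log scale
        da = np.log(a_grid[1] / a_grid[0])
        db = np.log(b_grid[1] / b_grid[0])
        assert abs(np.log(fit.model.a / a_grid[i])) <= da
        assert abs(np.log(fit.model.b / b_grid[j])) <= db
        assert fit.log_likelihood >= ll[i, j]

    def test_parameter_recovery_at_n5000(self, large_gompertz_cohort):
        fit = fit_model(large_gompertz_cohort, "gompertz")
        assert fit.model.a == pytest.approx(0.001, rel=0.10)
        assert fit.model.b == pytest.approx(0.2, rel=0.10)

    def test_too_few_events_rejected(self):
        c = CohortSurvival(np.array([1.0, 2.0, 3.0]), np.ones(3, dtype=bool))
        with pytest.raises(ValueError, match="events"):
            fit_model(c, "gompertz")

    def test_extended_families_never_fall_below_gompertz(self, large_gompertz_cohort):
        base = fit_model(large_gompertz_cohort, "gompertz")
        for fam in ("gompertz_makeham", "logistic", "logistic_makeham"):
            ext = fit_model(large_gompertz_cohort, fam, n_starts=3)
            assert ext.converged
            assert ext.log_likelihood >= base.log_likelihood - 1e-6


class TestModelSelection:
    def test_chi_square_tail_example(self):
        """2·(−98 − (−100)) = 4 on 1 df gives p ≈ 0.0455."""
        assert stats.chi2.sf(4.0, 1) == pytest.approx(0.0455, abs=2e-4)

    def test_equal_likelihood_retains_base(self, large_gompertz_cohort):
        sel = select_model(large_gompertz_cohort, n_starts=3)
        row = sel.lrt_table.set_index(["base", "extension"])
        assert sel.chosen == "gompertz"
        assert (row["statistic"] >= 0).all()

    def test_lrt_invariant_to_time_rescaling(self):
        """Switching months to days rescales a and b but not the statistic."""
        rng = np.random.default_rng(5)
        m1 = GompertzFamilyModel("gompertz", a=0.002, b=0.15)
        m2 = GompertzFamilyModel("gompertz", a=0.002, b=0.11)
        t1 = sample_death_times(m1, 300, rng)
        t2 = sample_death_times(m2, 300, rng)
        ev = np.ones(300, dtype=bool)
        r_months = compare_groups(CohortSurvival(t1, ev), CohortSurvival(t2, ev), "b")
        r_days = compare_groups(CohortSurvival(t1 * 30.44, ev),
                                CohortSurvival(t2 * 30.44, ev), "b")
        assert r_days.statistic == pytest.approx(r_months.statistic, abs=1e-4)


class TestGroupComparison:
    def test_cohort_against_itself_is_null(self, large_gompertz_cohort):
        c = large_gompertz_cohort.subset(np.arange(500))
        for par in ("a", "b", "both"):
            r = compare_groups(c, c, par)
            assert r.statistic == pytest.approx(0.0, abs=1e-6)
            assert r.p == pytest.approx(1.0, abs=1e-6)
            assert r.df == (2 if par == "both" else 1)

    def test_power_against_reduced_rate_of_aging(self):
        """b lowered 30% in group 2, n=1,000/arm: detected in >= 90% of runs."""
        rng = np.random.default_rng(8)
        m1 = GompertzFamilyModel("gompertz", a=0.001, b=0.2)
        m2 = GompertzFamilyModel("gompertz", a=0.001, b=0.14)
        hits = 0
        n_reps = 50
        for _ in range(n_reps):
            c1 = CohortSurvival(sample_death_times(m1, 1000, rng), np.ones(1000, bool))
            c2 = CohortSurvival(sample_death_times(m2, 1000, rng), np.ones(1000, bool))
            hits += compare_groups(c1, c2, "b").p < 0.05
        assert hits / n_reps >= 0.90

    def test_invalid_parameter_name_rejected(self, large_gompertz_cohort):
        c = large_gompertz_cohort.subset(np.arange(100))
        with pytest.raises(ValueError):
            compare_groups(c, c, "c")
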