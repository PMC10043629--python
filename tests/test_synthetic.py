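import math

import numpy as np
import pandas as pd
import pytest

from ltcincidence import (
    AgeGroup,
    GompertzTruth,
    LogitLinearTruth,
    PFLEGESTATISTIK_GROUPS,
    PrevalenceSurface,
    RecoverySettings,
    ScenarioConfig,
    ValidationError,
    default_logitlinear_truths,
    default_truths,
    emit_tables,
    estimate_incidence,
    fit_logit_linear,
    microsimulate,
    recovery_experiment,
    run_scenarios,
    solve_cohort,
    solve_prevalence_forward,
    synthesize_tables,
)
from ltcincidence.synthetic import SINGLE_AGE_GROUPS, _simulate_cohort


class TestForwardSolver:
    def test_zero_incidence_keeps_prevalence_zero(self):
        truth = GompertzTruth(i0=0.0, beta_i=0.0)
        surface = solve_prevalence_forward(truth, [2015], np.arange(0, 100, 10.0))
        assert np.all(surface.p == 0.0)

    def test_constant_incidence_closed_form(self):
        # with R = 1 and no background mortality, p' = i (1 - p): p(a) = 1 - exp(-i a)
        truth = GompertzTruth(i0=0.01, beta_i=0.0, alpha=0.0, gamma=0.0, R=1.0)
        p, _m, _alive = solve_cohort(truth, 1965, [50.0], step=0.05)
        assert p[0] == pytest.approx(1 - math.exp(-0.5), abs=1e-8)

    def test_mixture_bounds_on_total_mortality(self, gompertz_truths):
        truth = gompertz_truths["male"]
        surface = solve_prevalence_forward(truth, [2013, 2015], np.arange(1.0, 100.0, 7.0))
        for iy, year in enumerate(surface.years):
            m0 = truth.mortality_free(year, surface.ages)
            assert np.all(surface.m_total[iy] >= m0 * (1 - 1e-12))
            assert np.all(surface.m_total[iy] <= truth.R * m0 * (1 + 1e-12))
        assert np.all((surface.p >= 0) & (surface.p < 1))

    def test_fourth_order_step_convergence(self, gompertz_truths):
        truth = gompertz_truths["male"]
        ages = np.arange(0.0, 100.0, 5.0)
        p1 = solve_prevalence_forward(truth, [2015], ages, step=0.05).p
        p2 = solve_prevalence_forward(truth, [2015], ages, step=0.025).p
        p3 = solve_prevalence_forward(truth, [2015], ages, step=0.0125).p
        d12 = np.max(np.abs(p1 - p2))
        d23 = np.max(np.abs(p2 - p3))
        assert d12 < 1e-8  # halving the default step barely moves the surface
        assert 8 < d12 / d23 < 32  # error shrinks ~16x per halving: 4th order

    def test_large_step_rejected(self, gompertz_truths):
        with pytest.raises(ValidationError, match="step"):
            solve_prevalence_forward(gompertz_truths["male"], [2015], [50.0], step=0.5)

    def test_logitlinear_truth_reproduces_its_surface(self):
        truth = default_logitlinear_truths()["female"]
        ages = np.array([20.0, 50.0, 70.0, 90.0])
        surface = solve_prevalence_forward(truth, [2015], ages)
        np.testing.assert_allclose(surface.p[0], truth.prevalence(2015.0, ages), rtol=1e-7)
        np.testing.assert_allclose(
            surface.m_total[0], truth.mortality_total(2015.0, ages), rtol=1e-7
        )


class TestExactInversionFromSurface:
    @pytest.mark.parametrize("sex", ["female", "male"])
    def test_estimator_recovers_truth_without_regression(self, sex, gompertz_truths):
        """With p, dp, m taken exactly from the solved surface (dp by central
        difference along the cohort), the transport-equation inversion returns
        the generating incidence to numerical precision -- isolating estimator
        error from regression error."""
        truth = gompertz_truths[sex]
        h = 1e-3
        for age in range(55, 96, 10):
            p, m, _ = solve_cohort(truth, 2015 - age, [age - h, age, age + h])
            dp = (p[2] - p[0]) / (2 * h)
            i_est = estimate_incidence(p[1], dp, m[1], truth.R, truth.r)
            i_true = float(truth.incidence(2015.0, float(age)))
            assert abs(i_est - i_true) / i_true <= 1e-6


class TestMicrosimulation:
    def test_empty_population_gives_empty_counts(self, gompertz_truths):
        counts = microsimulate(gompertz_truths["male"], n=0, seed=1, years=(2015,), ages=[70])
        assert (counts.df[["n_alive", "n_ill", "deaths"]].to_numpy() == 0).all()

    def test_zero_incidence_means_no_ill_person_time(self):
        truth = GompertzTruth(i0=0.0, beta_i=0.0)
        counts = microsimulate(truth, n=5000, seed=2, years=(2015,), ages=[60])
        assert counts.py_ill == 0.0
        assert (counts.df.n_ill == 0).all()

    def test_reproducible_given_seed(self, gompertz_truths):
        a = microsimulate(gompertz_truths["female"], n=2000, seed=42, years=(2015,), ages=[70, 80])
        b = microsimulate(gompertz_truths["female"], n=2000, seed=42, years=(2015,), ages=[70, 80])
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_event_history_conservation(self, gompertz_truths):
        """Every person is either alive at the end or has exactly one death
        age inside the simulated span; ill episodes lie within life spans."""
        truth = gompertz_truths["male"]
        rng = np.random.default_rng(7)
        n, a_max = 5000, 90.0
        death_age, episodes = _simulate_cohort(truth, 1930.0, n, rng, a_max, 0.05)
        finite = np.isfinite(death_age)
        assert np.all(death_age[finite] > 0) and np.all(death_age[finite] <= a_max)
        for idx, onset, end in episodes:
            assert np.all(onset <= end + 1e-12)
            capped = np.minimum(death_age[idx], a_max)
            assert np.all(end <= capped + 1e-9)

    def test_cohort_attrition_is_monotone(self, gompertz_truths):
        # the same birth cohort observed in successive years can only shrink
        counts = microsimulate(
            gompertz_truths["male"], n=20000, seed=3,
            years=(2011, 2013, 2015), ages=[76, 78, 80],
        )
        df = counts.df
        df = df.assign(birth=df.year - df.age)
        for _, cohort in df.groupby("birth"):
            cohort = cohort.sort_values("age")
            if len(cohort) > 1:
                assert np.all(np.diff(cohort.n_alive.to_numpy()) <= 0)
                assert np.all(cohort.n_ill <= cohort.n_alive)

    def test_grouped_prevalence_agrees_with_solver(self, gompertz_truths):
        # fast variant of the full-scale oracle agreement (3 binomial SE)
        truth = gompertz_truths["female"]
        ages = range(60, 90)
        counts = microsimulate(truth, n=30000, seed=11, years=(2015,), ages=ages)
        groups = [AgeGroup(lo, lo + 5) for lo in range(60, 90, 5)]
        prev_ms, _ = emit_tables(counts, "female", groups=groups)
        surface = solve_prevalence_forward(truth, [2015], np.asarray(list(ages), float))
        for g in groups:
            sel = np.array([g.contains(a) for a in surface.ages])
            w = surface.alive[0, sel]
            p_ode = float(np.sum(w * surface.p[0, sel]) / np.sum(w))
            row = prev_ms.df[prev_ms.df.age_lo == g.lower].iloc[0]
            se = math.sqrt(p_ode * (1 - p_ode) / row.n_pop)
            assert abs(row.prevalence - p_ode) <= 3 * se


class TestEmitTables:
    def surface(self, ages, p, alive=None):
        ages = np.asarray(ages, float)
        p = np.asarray(p, float)[None, :]
        alive = np.ones_like(p) if alive is None else np.asarray(alive, float)[None, :]
        return PrevalenceSurface(
            years=np.array([2015.0]), ages=ages, p=p,
            m_total=np.full_like(p, 0.02), alive=alive,
        )

    def test_identity_grouping_reproduces_surface(self):
        surf = self.surface([60.0, 61.0], [0.10, 0.20])
        groups = (AgeGroup(60, 61), AgeGroup(61, 62))
        prev, mort = emit_tables(surf, "male", groups=groups, cohort_size=10**6)
        assert prev.df.prevalence.tolist() == pytest.approx([0.10, 0.20])
        assert mort.df.m.tolist() == pytest.approx([0.02, 0.02])

    def test_equal_weight_mean(self):
        surf = self.surface([60.0, 61.0], [0.10, 0.20])
        prev, _ = emit_tables(surf, "male", groups=(AgeGroup(60, 62),), cohort_size=10**6)
        assert prev.df.prevalence.iloc[0] == pytest.approx(0.15, abs=1e-6)

    def test_person_weighted_mean(self):
        surf = self.surface([60.0, 61.0], [0.10, 0.20], alive=[0.75, 0.25])
        prev, _ = emit_tables(surf, "male", groups=(AgeGroup(60, 62),), cohort_size=10**6)
        assert prev.df.prevalence.iloc[0] == pytest.approx(0.125, abs=1e-6)

    def test_default_grouping_covers_all_ages_disjointly(self, gompertz_tables):
        prev, _mort, _ = gompertz_tables
        sub = prev.df[(prev.df.year == 2015) & (prev.df.sex == "male")]
        assert len(sub) == 9
        groups = [AgeGroup(int(lo), float(hi)) for lo, hi in zip(sub.age_lo, sub.age_hi)]
        covered = sorted((g.lower, g.upper) for g in groups)
        assert covered[0][0] == 0 and math.isinf(covered[-1][1])
        for (lo1, hi1), (lo2, _) in zip(covered, covered[1:]):
            assert hi1 == lo2  # contiguous, non-overlapping

    def test_uncovered_surface_age_rejected(self):
        surf = self.surface([60.0, 61.0], [0.1, 0.2])
        with pytest.raises(ValidationError, match="cover"):
            emit_tables(surf, "male", groups=(AgeGroup(60, 61),))

    def test_emitted_tables_pass_validation_and_layout(self, gompertz_tables):
        prev, mort, _ = gompertz_tables
        assert prev.years == [2011, 2013, 2015, 2017, 2019]
        assert sorted(mort.df.year.unique()) == [2011, 2013, 2015, 2017, 2019]
        # single contiguous ages 0..99 per year and sex
        sub = mort.df[(mort.df.year == 2015) & (mort.df.sex == "female")]
        assert sub.age.tolist() == list(range(100))


class TestRecovery:
    def test_well_specified_pipeline_recovers_incidence(self):
        settings = RecoverySettings(groups=SINGLE_AGE_GROUPS, eval_ages=tuple(range(50, 91)))
        report = recovery_experiment(default_logitlinear_truths(), settings)
        assert report["max_rel_error"] <= 0.005

    def test_misspecified_regime_is_much_worse_but_bounded(self):
        settings = RecoverySettings(min_fit_age=60, eval_ages=tuple(range(60, 86)))
        report = recovery_experiment(default_truths(), settings)
        assert 0.01 <= report["max_rel_error"] <= 0.30

    def test_underestimating_R_biases_incidence_down_at_high_age(self, gompertz_tables):
        """Estimating with R = 1.17 when the data arose under R = 3.2 removes
        most of the mortality correction, so the high-age incidence must be
        systematically underestimated."""
        prev, mort, _ = gompertz_tables
        truth = default_truths()["male"]
        from ltcincidence import FitOptions

        model = fit_logit_linear(
            prev, "male", FitOptions(include_groups=lambda g: g.lower >= 60 and not g.is_open)
        )
        ages = tuple(float(a) for a in range(80, 91))
        wrong = run_scenarios(
            {"male": model}, mort, ScenarioConfig(R=(1.17,), year=2015, ages=ages, sexes=("male",))
        ).sorted()
        i_wrong = wrong.incidence_per_1000py.to_numpy() / 1000
        i_true = np.asarray(truth.incidence(2015.0, np.asarray(ages)))
        assert np.all(i_wrong < i_true)

    def test_ignoring_remission_underestimates_incidence(self):
        """With true remission r > 0, estimating under r = 0 gives a strict
        lower bound on the incidence at every age."""
        truth = LogitLinearTruth(r=0.01)
        settings = RecoverySettings(groups=SINGLE_AGE_GROUPS, eval_ages=tuple(range(60, 86)))
        prev, mort, _ = synthesize_tables(
            {"female": truth},
            years=settings.years,
            ages=settings.table_ages,
            groups=settings.groups,
        )
        from ltcincidence import FitOptions

        model = fit_logit_linear(
            prev, "female", FitOptions(include_groups=lambda g: g.lower >= 40 and not g.is_open)
        )
        ages = tuple(float(a) for a in settings.eval_ages)
        est = run_scenarios(
            {"female": model}, mort,
            ScenarioConfig(R=(truth.R,), r=0.0, year=2015, ages=ages, sexes=("female",)),
        ).sorted()
        i_est = est.incidence_per_1000py.to_numpy() / 1000
        i_true = np.asarray(truth.incidence(2015.0, np.asarray(ages)))
        assert np.all(i_est < i_true)
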