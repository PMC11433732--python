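import math

import numpy as np
import pytest

from ehrpk.metrics import (
    CtSeries,
    aape,
    auc_model,
    auc_to_inf,
    auc_trapezoid,
    dose_normalize,
    fold_change,
    interval_half_life,
    naive_pool,
    summarize,
)


def series(t, c, analyte="NAL", dose=162.0, lloq=0.0, censored=None, **kw):
    return CtSeries(analyte=analyte, t=np.asarray(t, float),
                    conc=np.asarray(c, float), dose_mg=dose, lloq=lloq,
                    censored=censored, **kw)


class TestCtSeries:
    def test_rejects_unknown_analyte(self):
        with pytest.raises(ValueError, match="analyte"):
            series([0, 1], [1, 1], analyte="M6")

    def test_rejects_non_increasing_times(self):
        with pytest.raises(ValueError, match="increasing"):
            series([1, 1], [1, 1])

    def test_rejects_negative_uncensored(self):
        with pytest.raises(ValueError):
            series([0, 1], [1, -1])


class TestAucTrapezoid:
    def test_constant_profile(self):
        s = series(np.arange(0, 25, 1.0), np.full(25, 10.0))
        assert auc_trapezoid(s, 0, 24) == pytest.approx(240.0)

    def test_two_points(self):
        s = series([0.0, 2.0], [0.0, 10.0])
        assert auc_trapezoid(s, 0, 2) == pytest.approx(10.0)

    def test_against_exponential_integral(self):
        # closed-form integral of C0*exp(-k t); trapezoid on a fine grid
        # must agree within its discretization error bound (h^2/12 * max|f''|*T)
        k, c0 = 0.2, 100.0
        t = np.arange(0.0, 48.0001, 0.25)
        s = series(t, c0 * np.exp(-k * t))
        exact = c0 / k * (1.0 - math.exp(-k * 48.0))
        bound = 0.25**2 / 12.0 * c0 * k**2 * 48.0
        assert abs(auc_trapezoid(s, 0, 48) - exact) < bound

    def test_interval_subset_with_interpolation(self):
        s = series([0.0, 2.0, 4.0], [0.0, 10.0, 0.0])
        assert auc_trapezoid(s, 1.0, 3.0) == pytest.approx(15.0)

    def test_outside_range_raises(self):
        s = series([0.0, 2.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="outside"):
            auc_trapezoid(s, 0.0, 5.0)

    def test_censoring_conventions(self):
        # interior censored -> LLOQ/2; trailing censored -> 0
        s = series([0.0, 1.0, 2.0, 3.0], [10.0, 0.01, 10.0, 0.02],
                   lloq=0.05, censored=[False, True, False, True])
        # segments: (10 + 0.025)/2 + (0.025 + 10)/2 + (10 + 0)/2
        assert auc_trapezoid(s, 0, 3) == pytest.approx(10.025 + 5.0)


class TestAucModel:
    def test_matches_trapezoid_on_dense_grid(self, healthy_sim):
        s = series(healthy_sim.t, np.maximum(healthy_sim.conc["NAL"], 0.0))
        am = auc_model(healthy_sim, "NAL", 0.0, 96.0)
        at = auc_trapezoid(s, 0.0, 96.0)
        assert am == pytest.approx(at, rel=1e-4)

    def test_zero_profile(self, healthy_sim):
        import copy

        r = copy.copy(healthy_sim)
        r.conc = dict(r.conc)
        r.conc["M4"] = np.zeros_like(r.t)
        assert auc_model(r, "M4", 0.0, 120.0) == 0.0

    def test_unknown_analyte(self, healthy_sim):
        with pytest.raises(ValueError):
            auc_model(healthy_sim, "M6", 0.0, 24.0)


class TestIntervalHalfLife:
    def test_exact_exponential(self):
        t = np.arange(0.0, 48.1, 2.0)
        s = series(t, 50.0 * np.exp(-np.log(2.0) / 12.0 * t))
        assert interval_half_life(s, 12, 24) == pytest.approx(12.0, rel=1e-9)

    def test_constant_profile_not_computable(self):
        s = series(np.arange(0.0, 48.0, 2.0), np.full(24, 5.0))
        assert math.isnan(interval_half_life(s, 12, 24))

    def test_too_few_points(self):
        s = series([0.0, 30.0], [10.0, 1.0])
        assert math.isnan(interval_half_life(s, 12, 24))

    def test_scale_invariance(self):
        t = np.arange(0.0, 48.1, 2.0)
        c = np.exp(-0.1 * t) * (1.0 + 0.05 * np.sin(t))
        s1 = series(t, c)
        s2 = series(t, 1000.0 * c)
        assert interval_half_life(s1, 12, 36) == pytest.approx(
            interval_half_life(s2, 12, 36), rel=1e-12)

    def test_two_point_option(self):
        t = np.array([10.0, 20.0, 30.0])
        s = series(t, [8.0, 5.0, 2.0])
        hl = interval_half_life(s, 10, 30, method="two-point")
        expected = math.log(2.0) / (math.log(8.0 / 2.0) / 20.0)
        assert hl == pytest.approx(expected)

    def test_healthy_m3_window(self, healthy_sim):
        # soft, model-dependent check anchored at the observed ~12 h
        s = series(healthy_sim.t, np.maximum(healthy_sim.conc["M3"], 0.0),
                   analyte="M3")
        assert interval_half_life(s, 24, 36) == pytest.approx(12.0, rel=0.25)


class TestDoseNormalize:
    def test_27_to_162(self):
        s = series([0.0, 1.0], [1.0, 2.0], dose=27.0, lloq=0.05)
        out = dose_normalize(s, 162.0)
        np.testing.assert_allclose(out.conc, [6.0, 12.0])
        assert out.dose_mg == 162.0
        assert out.lloq == pytest.approx(0.3)

    def test_identity(self):
        s = series([0.0, 1.0], [1.0, 2.0], dose=162.0)
        out = dose_normalize(s, 162.0)
        np.testing.assert_allclose(out.conc, s.conc)

    def test_commutes_with_auc(self):
        s = series(np.arange(0.0, 10.0), np.arange(10.0), dose=27.0)
        a1 = auc_trapezoid(dose_normalize(s, 162.0), 0, 9)
        a2 = auc_trapezoid(s, 0, 9) * 6.0
        assert a1 == pytest.approx(a2)


class TestNaivePool:
    def test_identical_subjects(self):
        subj = [series([0.0, 1.0, 2.0], [1.0, 2.0, 3.0]) for _ in range(4)]
        mean, sd = naive_pool(subj)
        np.testing.assert_allclose(mean.conc, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(sd, 0.0)

    def test_two_subject_sd(self):
        subj = [series([0.0], [0.0]), series([0.0], [10.0])]
        mean, sd = naive_pool(subj)
        assert mean.conc[0] == pytest.approx(5.0)
        assert sd[0] == pytest.approx(math.sqrt(50.0))  # sample SD

    def test_mismatched_schedules(self):
        with pytest.raises(ValueError, match="schedule"):
            naive_pool([series([0.0, 1.0], [1.0, 1.0]),
                        series([0.0, 2.0], [1.0, 1.0])])

    def test_majority_censoring_rule(self):
        cen = [False, False, True, True]
        subj = [series([0.0], [c], lloq=0.5, censored=[cen[i]])
                for i, c in enumerate([1.0, 2.0, 0.1, 0.2])]
        mean, _ = naive_pool(subj)
        assert mean.censored[0]  # only half quantifiable: not trusted
        assert mean.conc[0] == pytest.approx(1.5)  # mean of quantifiable

    def test_lognormal_mean_exceeds_median(self):
        # pooled arithmetic mean of a lognormal cohort lies above the
        # profile at the median parameters
        rng = np.random.default_rng(5)
        t = np.arange(0.0, 10.0)
        median = np.exp(-0.3 * t) * 100.0
        subj = [series(t, median * np.exp(0.4 * rng.standard_normal()))
                for _ in range(2000)]
        mean, _ = naive_pool(subj)
        assert np.all(mean.conc > median)
        # and it converges to the CV-inflated expectation exp(sigma^2/2)
        np.testing.assert_allclose(mean.conc / median,
                                   np.exp(0.4**2 / 2.0), rtol=0.03)


class TestAape:
    def test_perfect(self):
        assert aape([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_uniform_overprediction(self):
        obs = [10.0, 20.0, 30.0]
        pred = [1.07 * o for o in obs]
        assert aape(pred, obs) == pytest.approx(7.0)

    def test_mixed(self):
        assert aape([110.0, 95.0], [100.0, 100.0]) == pytest.approx(7.5)

    def test_zero_observed(self):
        with pytest.raises(ValueError):
            aape([1.0], [0.0])


class TestFoldChange:
    def test_values(self):
        assert fold_change(310.0, 100.0) == pytest.approx(3.1)
        assert fold_change(740.0, 100.0) == pytest.approx(7.4)
        assert fold_change(5.0, 5.0) == 1.0

    def test_invalid(self):
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)


class TestAucToInf:
    def test_exponential_tail(self):
        k = np.log(2.0) / 10.0
        t = np.arange(0.0, 72.1, 2.0)
        s = series(t, 100.0 * np.exp(-k * t))
        exact = 100.0 / k
        assert auc_to_inf(s) == pytest.approx(exact, rel=0.01)


class TestSummarize:
    def test_panel(self, healthy_sim):
        s = series(healthy_sim.t, np.maximum(healthy_sim.conc["NAL"], 0.0),
                   group="healthy")
        out = summarize(s)
        assert 3.0 <= out.t_max <= 6.0
        assert out.auc > 0
        assert out.t_half_24_36 > out.t_half_12_24 * 0  # computable
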