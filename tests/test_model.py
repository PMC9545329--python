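"""Core-model mathematics: latent trajectories, hazards, joint likelihood."""
import numpy as np
import pytest
from scipy import integrate

from serialjm import (
    LongitudinalSpec,
    ModelSpec,
    RandomEffects,
    cumulative_hazard,
    hazard,
    latent_m1,
    latent_m2,
    log_baseline_hazard,
    subject_loglik,
)

from conftest import SIM_SPEC, make_baseline, make_params, make_subject

B0 = RandomEffects()


class TestLatentTrajectories:
    def test_intercept_only_at_zero(self):
        p = make_params()
        s = make_subject(intervention=0)
        assert latent_m1(0.0, p, s, B0)[0] == pytest.approx(0.07)

    def test_zero_coefficients_give_zero(self):
        p = make_params(beta1=(0, 0, 0))
        s = make_subject(intervention=1)
        t = np.array([0.0, 0.7, 3.0])
        assert np.all(latent_m1(t, p, s, B0) == 0)

    def test_treated_subject_at_two_years(self):
        # 0.07 + 2(-0.25) + 2(0.12) with the treatment-by-time interaction
        p = make_params()
        s = make_subject(intervention=1)
        assert latent_m1(2.0, p, s, B0)[0] == pytest.approx(-0.19)

    def test_m2_zero_when_all_zero(self):
        p = make_params(beta2=(0, 0, 0), xi=0.0)
        s = make_subject()
        assert np.all(latent_m2(np.linspace(0, 3, 7), p, s, B0) == 0)

    def test_m2_linear_in_m1(self):
        # m1 == 2 via a random intercept; beta2 = 0, xi = -0.5 -> m2 = -1
        p = make_params(beta1=(0, 0, 0), beta2=(0, 0, 0), xi=-0.5)
        b = RandomEffects(b1=np.array([2.0, 0.0]))
        s = make_subject()
        assert latent_m2(1.3, p, s, b)[0] == pytest.approx(-1.0)

    def test_control_subject_chain_at_one_year(self):
        p = make_params()
        s = make_subject(intervention=0)
        assert latent_m1(1.0, p, s, B0)[0] == pytest.approx(-0.18)
        assert latent_m2(1.0, p, s, B0)[0] == pytest.approx(0.69)

    def test_m2_slope_in_m1_is_exactly_xi(self):
        rng = np.random.default_rng(0)
        p = make_params(xi=-0.73)
        s = make_subject(intervention=1)
        t = rng.uniform(0, 3, 5)
        for shift in (0.5, 2.0):
            b_lo = RandomEffects(b1=np.array([0.1, 0.0]))
            b_hi = RandomEffects(b1=np.array([0.1 + shift, 0.0]))
            dm2 = latent_m2(t, p, s, b_hi) - latent_m2(t, p, s, b_lo)
            dm1 = latent_m1(t, p, s, b_hi) - latent_m1(t, p, s, b_lo)
            np.testing.assert_allclose(dm2, p.xi * dm1, rtol=1e-12)

    def test_missing_covariate_named_in_error(self):
        spec = ModelSpec(
            long1=LongitudinalSpec(("intercept", "time", "bmmse")),
            long2=LongitudinalSpec(
                ("intercept", "time"), includes_upstream_latent=True
            ),
            survival_terms=("intervention",),
        )
        p = make_params(beta1=(0.1, 0.1, 0.1), beta2=(0.0, 0.0), spec=spec)
        s = make_subject()  # no bmmse recorded
        with pytest.raises(KeyError, match="bmmse"):
            latent_m1(1.0, p, s, B0)


def _de_boor(t, knots, degree, j):
    """Textbook Cox-de Boor recursion for one basis function."""
    if degree == 0:
        # half-open intervals, closed at the right boundary
        if knots[j] <= t < knots[j + 1]:
            return 1.0
        if t == knots[-1] and knots[j] < knots[j + 1] == knots[-1]:
            return 1.0
        return 0.0
    left = 0.0
    if knots[j + degree] > knots[j]:
        left = (t - knots[j]) / (knots[j + degree] - knots[j]) * _de_boor(
            t, knots, degree - 1, j
        )
    right = 0.0
    if knots[j + degree + 1] > knots[j + 1]:
        right = (
            (knots[j + degree + 1] - t)
            / (knots[j + degree + 1] - knots[j + 1])
            * _de_boor(t, knots, degree - 1, j + 1)
        )
    return left + right


class TestBaselineHazard:
    def test_zero_coefficients(self):
        base = make_baseline(coefs=None)
        t = np.linspace(0, 3.2, 9)
        assert np.all(log_baseline_hazard(t, 1, base) == 0)

    def test_partition_of_unity(self):
        base = make_baseline(coefs=np.log(0.25))
        t = np.linspace(0, 3.2, 33)
        for k in (1, 2):
            np.testing.assert_allclose(
                log_baseline_hazard(t, k, base), np.log(0.25), rtol=1e-12
            )

    def test_agrees_with_de_boor_recursion(self):
        rng = np.random.default_rng(12)
        coefs = rng.normal(0, 1, (2, 7))
        base = make_baseline(coefs=coefs[0], n_interior=3)
        base = base.__class__(
            degree=3,
            boundary_knots=base.boundary_knots,
            interior_knots=base.interior_knots,
            coefficients_per_risk=coefs,
        )
        knots = base.knots
        for t in rng.uniform(0, 3.2, 50):
            expected = sum(
                coefs[0, j] * _de_boor(t, knots, 3, j)
                for j in range(base.n_basis)
            )
            assert log_baseline_hazard(t, 1, base)[0] == pytest.approx(
                expected, abs=1e-10
            )

    def test_no_extrapolation(self):
        base = make_baseline()
        with pytest.raises(ValueError, match="extrapolate"):
            log_baseline_hazard(3.5, 1, base)
        with pytest.raises(ValueError, match="extrapolate"):
            log_baseline_hazard(-0.1, 1, base)


class TestHazard:
    def test_unit_hazard_when_everything_zero(self):
        p = make_params(gamma=((0,), (0,)), alpha=((0, 0), (0, 0)),
                        beta1=(0, 0, 0), beta2=(0, 0, 0), xi=0.0)
        s = make_subject(intervention=1)
        t = np.linspace(0, 3.2, 11)
        for k in (1, 2):
            np.testing.assert_allclose(hazard(t, k, p, s, B0), 1.0)

    def test_intervention_multiplies_hazard_by_exp_gamma(self):
        p = make_params(beta1=(0, 0, 0), beta2=(0, 0, 0), xi=0.0)
        h1 = hazard(1.5, 1, p, make_subject(intervention=1), B0)[0]
        h0 = hazard(1.5, 1, p, make_subject(intervention=0), B0)[0]
        assert h1 / h0 == pytest.approx(np.exp(-0.2), rel=1e-12)

    def test_positive_for_extreme_parameters(self):
        p = make_params(alpha=((-5, 4), (3, -6)), gamma=((2,), (-3,)))
        b = RandomEffects(b1=np.array([1.5, -2.0]), b2=np.array([-1.0, 2.0]))
        s = make_subject(intervention=1)
        h = hazard(np.linspace(0, 3.2, 20), 2, p, s, b)
        assert np.all(h > 0) and np.all(np.isfinite(h))

    @pytest.mark.parametrize(
        "alpha_val,reduction", [(-0.416, 0.34), (-1.073, 0.66)]
    )
    def test_one_sd_latent_increase_risk_reduction(self, alpha_val, reduction):
        """A one-SD latent increase scales the hazard by exp(alpha)."""
        p = make_params(beta1=(0, 0, 0), beta2=(0, 0, 0), xi=0.0,
                        gamma=((0,), (0,)),
                        alpha=((alpha_val, 0), (0, 0)))
        s = make_subject()
        h_base = hazard(1.0, 1, p, s, B0)[0]
        h_up = hazard(1.0, 1, p, s, RandomEffects(b1=np.array([1.0, 0.0])))[0]
        assert round(1 - h_up / h_base, 2) == reduction


class TestCumulativeHazard:
    def test_zero_at_time_zero(self):
        p = make_params()
        assert cumulative_hazard(0.0, 1, p, make_subject(), B0) == 0.0

    def test_constant_hazard_closed_form(self):
        rate = 0.37
        p = make_params(
            beta1=(0, 0, 0), beta2=(0, 0, 0), xi=0.0,
            gamma=((0,), (0,)), alpha=((0, 0), (0, 0)),
            baseline=make_baseline(coefs=np.log(rate)),
        )
        s = make_subject()
        for t in (0.3, 1.7, 3.2):
            assert cumulative_hazard(t, 1, p, s, B0) == pytest.approx(
                rate * t, rel=1e-10
            )

    def test_monotone_nondecreasing(self):
        p = make_params()
        s = make_subject(intervention=1)
        b = RandomEffects(b1=np.array([0.4, -0.2]), b2=np.array([0.1, 0.3]))
        vals = [cumulative_hazard(t, 1, p, s, b) for t in np.linspace(0, 3.2, 15)]
        assert np.all(np.diff(vals) >= 0)

    def test_matches_adaptive_quadrature(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            coefs = rng.normal(-1.5, 0.5, (2, 7))
            p = make_params(
                beta1=rng.normal(0, 0.3, 3),
                beta2=rng.normal(0, 0.3, 3),
                xi=rng.normal(0, 0.5),
                gamma=rng.normal(0, 0.3, (2, 1)),
                alpha=rng.normal(0, 0.4, (2, 2)),
                baseline=make_baseline().__class__(
                    degree=3,
                    boundary_knots=(0.0, 3.2),
                    interior_knots=make_baseline().interior_knots,
                    coefficients_per_risk=coefs,
                ),
            )
            b = RandomEffects(rng.normal(0, 0.4, 2), rng.normal(0, 0.4, 2))
            s = make_subject(intervention=int(rng.integers(2)))
            t_up = float(rng.uniform(0.5, 3.2))
            k = int(rng.integers(1, 3))
            oracle, err = integrate.quad(
                lambda t: hazard(t, k, p, s, b)[0], 0, t_up, limit=200
            )
            got = cumulative_hazard(t_up, k, p, s, b)
            assert got == pytest.approx(oracle, rel=1e-6)


class TestSubjectLoglik:
    def test_survival_only_subject(self):
        p = make_params(gamma=((0,), (0,)), alpha=((0, 0), (0, 0)),
                        beta1=(0, 0, 0), beta2=(0, 0, 0), xi=0.0,
                        baseline=make_baseline(coefs=np.log(0.3)))
        s = make_subject(observed_time=2.0, event=0)
        # no measurements, censored: loglik reduces to -sum_k Lambda_k(T)
        assert subject_loglik(s, p, B0) == pytest.approx(-2 * 0.3 * 2.0)

    def test_single_measurement_at_the_mean(self):
        p = make_params(
            gamma=((0,), (0,)), alpha=((0, 0), (0, 0)), sigma=0.5,
        )
        s = make_subject(intervention=0, series_1=[(1.0, -0.18)],
                         observed_time=1.5, event=0)
        base = subject_loglik(
            make_subject(observed_time=1.5, event=0), p, B0
        )
        got = subject_loglik(s, p, B0)
        assert got - base == pytest.approx(np.log(1 / (0.5 * np.sqrt(2 * np.pi))))

    def test_matches_sum_of_pieces(self):
        rng = np.random.default_rng(9)
        p = make_params()
        for i in range(10):
            T = float(rng.uniform(0.5, 3.2))
            times = np.sort(rng.uniform(0, T, 4))
            s = make_subject(
                intervention=int(rng.integers(2)),
                series_1=[(float(t), float(rng.normal())) for t in times],
                series_2=[(float(t), float(rng.normal())) for t in times],
                observed_time=T,
                event=int(rng.integers(0, 3)),
            )
            b = RandomEffects(rng.normal(0, 0.4, 2), rng.normal(0, 0.4, 2))
            # recompute every term separately
            expect = 0.0
            for t, v in s.series_1:
                m = latent_m1(t, p, s, b)[0]
                expect += -0.5 * np.log(2 * np.pi) - np.log(p.sigma1) \
                    - 0.5 * ((v - m) / p.sigma1) ** 2
            for t, v in s.series_2:
                m = latent_m2(t, p, s, b)[0]
                expect += -0.5 * np.log(2 * np.pi) - np.log(p.sigma2) \
                    - 0.5 * ((v - m) / p.sigma2) ** 2
            if s.event:
                expect += np.log(hazard(T, s.event, p, s, b)[0])
            expect -= cumulative_hazard(T, 1, p, s, b)
            expect -= cumulative_hazard(T, 2, p, s, b)
            assert subject_loglik(s, p, b) == pytest.approx(expect, rel=1e-12)

    def test_outcome2_drops_out_of_survival_when_unlinked(self):
        """With xi=0 and alpha_k2=0, changing outcome-2 data moves the
        log-likelihood only through the outcome-2 Gaussian terms."""
        p = make_params(xi=0.0, alpha=((-0.6, 0.0), (-0.1, 0.0)))
        common = dict(intervention=1, series_1=[(0.5, 0.2)],
                      observed_time=2.0, event=1)
        s_a = make_subject(series_2=[(1.0, 0.3)], **common)
        s_b = make_subject(series_2=[(1.0, 1.1)], **common)
        b = RandomEffects(np.array([0.2, 0.1]), np.array([-0.1, 0.2]))
        m2 = latent_m2(1.0, p, s_a, b)[0]

        def normal_term(v):
            return -0.5 * np.log(2 * np.pi) - np.log(p.sigma2) \
                - 0.5 * ((v - m2) / p.sigma2) ** 2

        diff = subject_loglik(s_a, p, b) - subject_loglik(s_b, p, b)
        assert diff == pytest.approx(
            normal_term(0.3) - normal_term(1.1), rel=1e-10
        )

    def test_measurement_after_observed_time_rejected(self):
        p = make_params()
        s = make_subject(series_1=[(2.5, 0.0)], observed_time=2.0)
        with pytest.raises(ValueError, match="s1"):
            subject_loglik(s, p, B0)
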