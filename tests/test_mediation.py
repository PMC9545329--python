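"""Mediation decomposition: paths, additivity identity, plug-in arithmetic."""
import numpy as np
import pytest

from serialjm import (
    LongitudinalSpec,
    ModelSpec,
    PosteriorDraws,
    decompose,
    intervention_profile,
    plot_decomposition,
    total_effect_draws,
)

from conftest import make_params

TRIAL_SPEC = ModelSpec(
    long1=LongitudinalSpec(
        ("intercept", "time", "intervention", "intervention:time")
    ),
    long2=LongitudinalSpec(
        ("intercept", "time", "intervention", "intervention:time"),
        includes_upstream_latent=True,
    ),
    survival_terms=("intervention",),
)


def trial_params(**kwargs):
    """Parameter values with both a main intervention effect and an
    interaction with time, as in the real-trial configuration."""
    defaults = dict(
        beta1=(0.0, -0.183, -0.064, 0.071),
        beta2=(0.0, -0.088, 0.060, 0.051),
        xi=0.354,
        gamma=((0.153,), (-0.241,)),
        alpha=((-0.416, -1.073), (0.047, -0.242)),
        spec=TRIAL_SPEC,
    )
    defaults.update(kwargs)
    return make_params(**defaults)


def draws_from(values: dict, meta_terms=None, n_rep=1) -> PosteriorDraws:
    meta = {
        "long1_terms": ["intercept", "time", "intervention",
                        "intervention:time"],
        "long2_terms": ["intercept", "time", "intervention",
                        "intervention:time"],
        "survival_terms": ["intervention"],
        "has_outcome2": True,
    }
    if meta_terms:
        meta.update(meta_terms)
    return PosteriorDraws(
        draws={
            k: np.broadcast_to(np.asarray(v, float), (1, n_rep)).copy()
            for k, v in values.items()
        },
        meta=meta,
    )


TRIAL_POSTERIOR_MEANS = {
    "beta1[intervention]": -0.064,
    "beta1[intervention:time]": 0.071,
    "beta2[intervention]": 0.060,
    "beta2[intervention:time]": 0.051,
    "xi": 0.354,
    "gamma1[intervention]": 0.153,
    "gamma2[intervention]": -0.241,
    "alpha_11": -0.416,
    "alpha_12": -1.073,
    "alpha_21": 0.047,
    "alpha_22": -0.242,
}


def random_draws(seed=0, n=500):
    rng = np.random.default_rng(seed)
    return draws_from(
        {k: rng.normal(0, 0.5, n) for k in TRIAL_POSTERIOR_MEANS}, n_rep=n
    )


class TestInterventionProfile:
    def test_trial_point_estimates(self):
        p = trial_params()
        assert intervention_profile(p, 1, 0.0) == pytest.approx(-0.064)
        assert intervention_profile(p, 1, 1.0) == pytest.approx(0.007)

    def test_zero_coefficients(self):
        p = trial_params(beta1=(0.5, -0.2, 0.0, 0.0))
        t = np.linspace(0, 3, 4)
        assert np.all(intervention_profile(p, 1, t) == 0)

    def test_no_intervention_terms_is_an_error(self):
        spec = ModelSpec(
            long1=LongitudinalSpec(("intercept", "time")),
            long2=LongitudinalSpec(
                ("intercept", "time"), includes_upstream_latent=True
            ),
            survival_terms=("intervention",),
        )
        p = make_params(beta1=(0.1, 0.1), beta2=(0.1, 0.1), spec=spec)
        with pytest.raises(ValueError, match="intervention"):
            intervention_profile(p, 1, 0.0)


class TestDecompose:
    def test_degenerate_reduction_to_direct_effect(self):
        vals = dict(TRIAL_POSTERIOR_MEANS)
        for k in ("alpha_11", "alpha_12", "alpha_21", "alpha_22", "xi"):
            vals[k] = 0.0
        curves = decompose(draws_from(vals), np.linspace(0, 3, 7))
        np.testing.assert_allclose(
            curves.hazard_ratio("total"), np.exp(0.153), rtol=1e-12
        )
        for comp in ("indirect_1", "indirect_2", "indirect_3"):
            np.testing.assert_allclose(curves.curves[comp], 0.0)

    def test_trial_posterior_mean_plugin_at_baseline(self):
        """Plug-in decomposition at the published posterior means gives a
        total hazard ratio of about 1.150 at t = 0."""
        curves = decompose(draws_from(TRIAL_POSTERIOR_MEANS), np.array([0.0]))
        assert curves.hazard_ratio("total")[0, 0] == pytest.approx(
            1.150, abs=1e-3
        )

    def test_additivity_identity_machine_exact(self):
        curves = decompose(random_draws(3), np.linspace(0, 3, 61))
        total = curves.curves["total"]
        parts = (
            curves.curves["direct"]
            + curves.curves["indirect_1"]
            + curves.curves["indirect_2"]
            + curves.curves["indirect_3"]
        )
        assert np.array_equal(total, parts)

    def test_combined_path_through_outcome1(self):
        d = random_draws(4, n=200)
        grid = np.linspace(0, 3, 13)
        curves = decompose(d, grid)
        B1 = (
            d.flat("beta1[intervention]")[:, None]
            + d.flat("beta1[intervention:time]")[:, None] * grid
        )
        expected = B1 * (
            d.flat("alpha_11")[:, None]
            + d.flat("xi")[:, None] * d.flat("alpha_12")[:, None]
        )
        np.testing.assert_allclose(
            curves.curves["combined_via_outcome1"], expected, rtol=1e-12
        )

    def test_constant_profile_gives_time_constant_curves(self):
        vals = dict(TRIAL_POSTERIOR_MEANS)
        vals["beta1[intervention:time]"] = 0.0
        vals["beta2[intervention:time]"] = 0.0
        curves = decompose(draws_from(vals), np.linspace(0, 3, 10))
        for arr in curves.curves.values():
            np.testing.assert_allclose(
                arr, np.broadcast_to(arr[:, [0]], arr.shape), rtol=1e-12
            )

    def test_second_risk_uses_symmetric_formula(self):
        curves = decompose(draws_from(TRIAL_POSTERIOR_MEANS), np.array([0.0]), risk=2)
        expect = (
            -0.241
            + 0.047 * (-0.064)
            + (-0.242) * 0.060
            + 0.354 * (-0.242) * (-0.064)
        )
        assert curves.curves["total"][0, 0] == pytest.approx(expect)

    def test_missing_parameter_reported(self):
        vals = {k: v for k, v in TRIAL_POSTERIOR_MEANS.items() if k != "alpha_12"}
        with pytest.raises(KeyError, match="alpha_12"):
            decompose(draws_from(vals), np.array([0.0]))

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            decompose(draws_from(TRIAL_POSTERIOR_MEANS), np.array([]))

    def test_univariate_overall_effect(self):
        vals = {
            "beta1[intervention]": -0.064,
            "beta1[intervention:time]": 0.071,
            "gamma1[intervention]": 0.153,
            "alpha_11": -0.416,
        }
        d = draws_from(
            vals,
            meta_terms={
                "long2_terms": None, "has_outcome2": False,
                "long1_terms": ["intercept", "time", "intervention",
                                "intervention:time"],
            },
        )
        grid = np.array([0.0, 1.0])
        curve = total_effect_draws(d, grid)
        np.testing.assert_allclose(
            curve[0],
            [0.153 + (-0.416) * (-0.064), 0.153 + (-0.416) * 0.007],
            rtol=1e-10,
        )


class TestPlot:
    def test_writes_nonempty_file_and_is_deterministic(self, tmp_path):
        curves = decompose(random_draws(8, n=100), np.linspace(0, 3, 10))
        out = tmp_path / "decomp.png"
        plot_decomposition(curves, out)
        assert out.exists() and out.stat().st_size > 0
        again = decompose(random_draws(8, n=100), np.linspace(0, 3, 10))
        for comp in curves.curves:
            np.testing.assert_array_equal(
                curves.curves[comp], again.curves[comp]
            )

    def test_empty_grid_rejected(self):
        curves = decompose(random_draws(1, n=50), np.linspace(0, 3, 5))
        curves.time_grid = np.array([])
        with pytest.raises(ValueError):
            plot_decomposition(curves, "unused.png")
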