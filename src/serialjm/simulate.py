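"""Data simulation from the multivariate competing-risk joint model.

The generative design mirrors a two-arm trial with two serially linked
longitudinal outcomes: per subject, random effects are drawn independently
per outcome, an event time is sampled by inverting the all-cause survival
function under the two time-varying cause-specific hazards, the cause is
drawn from the cause-specific hazard ratio at the event time, and an
independent exponential censoring time plus an administrative horizon
truncate follow-up.  Visits are equally spaced over the follow-up window and
kept only while the subject is still at risk.

Latent trajectories are affine in time for the supported model
specifications (terms are at most linear in t), which the vectorised
event-time sampler exploits.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model import gauss_legendre_nodes
from .types import (
    BaselineHazardSpec,
    JointModelParameters,
    LongitudinalSpec,
    ModelSpec,
    RandomEffects,
    SubjectRecord,
)

__all__ = [
    "SimScenario",
    "default_truth",
    "scenario_registry",
    "sample_event_time",
    "simulate_dataset",
]

#: bisection tolerance for event-time inversion (years)
_ROOT_TOL = 1e-8


@dataclass(frozen=True)
class SimScenario:
    """A complete generating configuration for one simulation scenario."""

    name: str
    n_subjects: int
    n_visits: int
    max_followup: float
    censoring_mean: float
    params_truth: JointModelParameters
    treatment_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_visits < 2:
            raise ValueError("n_visits must be >= 2")
        if self.max_followup <= 0 or self.censoring_mean <= 0:
            raise ValueError("max_followup and censoring_mean must be > 0")

    def replace(self, **kwargs) -> "SimScenario":
        return replace(self, **kwargs)


# The published simulation design: intercept, linear time, and a
# treatment-by-time interaction in both longitudinal submodels; the
# intervention indicator as the only survival covariate.
_SIM_SPEC = ModelSpec(
    long1=LongitudinalSpec(("intercept", "time", "intervention:time")),
    long2=LongitudinalSpec(
        ("intercept", "time", "intervention:time"), includes_upstream_latent=True
    ),
    survival_terms=("intervention",),
)


def default_truth(
    xi: float,
    *,
    sigma: float = 0.5,
    re_sd: tuple[float, float] = (0.5, 0.25),
    re_corr: float = 0.2,
    baseline_rate: float = 0.25,
    max_followup: float = 3.2,
) -> JointModelParameters:
    """Generating parameters of the simulation studies for a given ``xi``.

    Regression, association, and survival coefficients are the published
    design values; error SDs, random-effect covariances, and the (constant)
    baseline hazard level are documented package defaults, since the design
    leaves them unstated.  Equal spline coefficients give a constant baseline
    by the partition-of-unity property, identical for both risks.
    """
    sd_i, sd_s = re_sd
    Sigma = np.array(
        [
            [sd_i**2, re_corr * sd_i * sd_s],
            [re_corr * sd_i * sd_s, sd_s**2],
        ]
    )
    interior = tuple(np.linspace(0.0, max_followup, 5)[1:-1])
    baseline = BaselineHazardSpec(
        degree=3,
        boundary_knots=(0.0, max_followup),
        interior_knots=interior,
        coefficients_per_risk=np.full((2, len(interior) + 4), np.log(baseline_rate)),
    )
    return JointModelParameters(
        spec=_SIM_SPEC,
        beta1=np.array([0.07, -0.25, 0.12]),
        beta2=np.array([0.15, 0.45, -0.10]),
        xi=xi,
        sigma1=sigma,
        sigma2=sigma,
        Sigma_b1=Sigma.copy(),
        Sigma_b2=Sigma.copy(),
        gamma=np.array([[-0.2], [0.1]]),
        alpha=np.array([[-0.6, 0.4], [-0.1, 0.1]]),
        baseline=baseline,
    )


def scenario_registry() -> dict[str, SimScenario]:
    """Named scenarios of the two simulation studies.

    ``study1`` uses xi = -0.5; ``study2_I`` through ``study2_IV`` sweep
    xi over -0.01, -1, -2, -3 with all other parameters shared.
    """
    common = dict(
        n_subjects=500,
        n_visits=10,
        max_followup=3.2,
        censoring_mean=5.0,
        treatment_prob=0.5,
        seed=0,
    )
    xis = {
        "study1": -0.5,
        "study2_I": -0.01,
        "study2_II": -1.0,
        "study2_III": -2.0,
        "study2_IV": -3.0,
    }
    return {
        name: SimScenario(name=name, params_truth=default_truth(xi), **common)
        for name, xi in xis.items()
    }


def get_scenario(name: str) -> SimScenario:
    registry = scenario_registry()
    try:
        return registry[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(registry)}"
        ) from None


class _AffineLatents:
    """Vectorised latent processes m_j(t) = u_j + v_j t across subjects.

    Valid because all supported fixed/random terms are at most linear in t.
    """

    def __init__(
        self,
        params: JointModelParameters,
        intervention: np.ndarray,
        covariates: dict[str, np.ndarray],
        b1: np.ndarray,
        b2: np.ndarray,
    ):
        self.params = params
        n = intervention.shape[0]

        def affine(terms, beta):
            u = np.zeros(n)
            v = np.zeros(n)
            for coef, term in zip(beta, terms):
                if term == "intercept":
                    u += coef
                elif term == "time":
                    v += coef
                elif term == "intervention":
                    u += coef * intervention
                elif term == "intervention:time":
                    v += coef * intervention
                else:
                    u += coef * covariates[term]
            return u, v

        spec = params.spec
        self.u1, self.v1 = affine(spec.long1.fixed_terms, params.beta1)
        self.u1 = self.u1 + b1[:, 0]
        self.v1 = self.v1 + b1[:, 1]
        if spec.has_outcome2:
            u2, v2 = affine(spec.long2.fixed_terms, params.beta2)
            self.u2 = u2 + b2[:, 0] + params.xi * self.u1
            self.v2 = v2 + b2[:, 1] + params.xi * self.v1
        else:
            self.u2 = self.v2 = None
        # survival covariate linear predictor per risk
        W = np.zeros((n, len(spec.survival_terms)))
        for j, term in enumerate(spec.survival_terms):
            if term == "intercept":
                W[:, j] = 1.0
            elif term == "intervention":
                W[:, j] = intervention
            else:
                W[:, j] = covariates[term]
        self.surv_lp = params.gamma @ W.T  # (2, n)

    def m1(self, t: np.ndarray) -> np.ndarray:
        return self.u1 + self.v1 * t

    def log_hazards(self, t: np.ndarray) -> np.ndarray:
        """(2, ...) log cause-specific hazards at per-subject times ``t``."""
        base = self.params.baseline
        flat = np.ravel(t)
        logh0 = base.basis(flat) @ self.params.baseline.coefficients_per_risk.T
        logh0 = logh0.T.reshape((2,) + np.shape(t))  # (2, ...)
        alpha = self.params.alpha
        m1 = self.u1[..., None] + self.v1[..., None] * t if t.ndim > 1 else (
            self.u1 + self.v1 * t
        )
        out = logh0 + self.surv_lp.reshape(
            (2,) + (len(self.u1),) + (1,) * (t.ndim - 1)
        )
        out = out + alpha[:, 0].reshape((2,) + (1,) * t.ndim) * m1
        if self.u2 is not None:
            m2 = (
                self.u2[..., None] + self.v2[..., None] * t
                if t.ndim > 1
                else self.u2 + self.v2 * t
            )
            out = out + alpha[:, 1].reshape((2,) + (1,) * t.ndim) * m2
        return out

    def total_cumulative_hazard(self, t: np.ndarray, order: int = 15) -> np.ndarray:
        """Sum over risks of the cumulative hazard at per-subject times t."""
        x, w = np.polynomial.legendre.leggauss(order)
        nodes = 0.5 * t[:, None] * (x + 1.0)  # (n, G)
        wts = 0.5 * t[:, None] * w
        logh = self.log_hazards(nodes)  # (2, n, G)
        return np.einsum("ng,kng->n", wts, np.exp(logh))


def _invert_survival(
    lat: _AffineLatents, target: np.ndarray, max_followup: float
) -> np.ndarray:
    """Solve total cumulative hazard(t) = target per subject by bisection.

    Returns +inf where no solution exists below ``max_followup``
    (administrative censoring).
    """
    n = target.shape[0]
    lo = np.zeros(n)
    hi = np.full(n, max_followup)
    lam_max = lat.total_cumulative_hazard(hi)
    unsolved = lam_max >= target
    # bisect simultaneously; inactive rows just carry their bounds along
    n_iter = int(np.ceil(np.log2(max_followup / _ROOT_TOL))) + 1
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        lam = lat.total_cumulative_hazard(np.maximum(mid, 1e-300))
        go_right = lam < target
        lo = np.where(go_right, mid, lo)
        hi = np.where(go_right, hi, mid)
    t_star = 0.5 * (lo + hi)
    return np.where(unsolved, t_star, np.inf)


def sample_event_time(
    subject: SubjectRecord,
    params_truth: JointModelParameters,
    b: RandomEffects,
    u: float,
    max_followup: float,
    u_cause: float = 0.5,
) -> tuple[float, int] | None:
    """Invert exp{-sum_k Lambda_k(t)} = u for one subject.

    Returns ``(time, cause)`` or ``None`` when the subject survives past
    ``max_followup`` (administrative censoring).  The cause is 1 when
    ``u_cause`` falls below h1(t*)/(h1(t*)+h2(t*)) and 2 otherwise.
    """
    if not 0.0 < u < 1.0:
        raise ValueError("u must lie strictly inside (0, 1)")
    lat = _AffineLatents(
        params_truth,
        np.array([float(subject.intervention)]),
        {k: np.array([v]) for k, v in subject.baseline_covariates.items()},
        b.b1[None, :],
        b.b2[None, :],
    )
    t_star = _invert_survival(lat, np.array([-np.log(u)]), max_followup)[0]
    if not np.isfinite(t_star):
        return None
    logh = lat.log_hazards(np.array([t_star]))[:, 0]
    p1 = 1.0 / (1.0 + np.exp(logh[1] - logh[0]))
    cause = 1 if u_cause < p1 else 2
    return float(t_star), cause


def simulate_dataset(
    scenario: SimScenario, seed: int | None = None
) -> list[SubjectRecord]:
    """Generate one dataset of :class:`SubjectRecord` from a scenario.

    Randomness is fully determined by ``seed`` (falling back to
    ``scenario.seed``): the same seed yields a bit-identical dataset.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    n = scenario.n_subjects
    params = scenario.params_truth
    spec = params.spec

    intervention = (rng.uniform(size=n) < scenario.treatment_prob).astype(float)
    b1 = rng.multivariate_normal(np.zeros(2), params.Sigma_b1, size=n)
    if spec.has_outcome2:
        b2 = rng.multivariate_normal(np.zeros(2), params.Sigma_b2, size=n)
    else:
        b2 = np.zeros((n, 2))
    lat = _AffineLatents(params, intervention, {}, b1, b2)

    u = rng.uniform(size=n)
    t_event = _invert_survival(lat, -np.log(u), scenario.max_followup)
    u_cause = rng.uniform(size=n)
    finite = np.isfinite(t_event)
    cause = np.ones(n, dtype=int)
    if finite.any():
        logh = lat.log_hazards(np.where(finite, t_event, 0.0))  # (2, n)
        p1 = 1.0 / (1.0 + np.exp(logh[1] - logh[0]))
        cause = np.where(u_cause < p1, 1, 2)

    c_time = rng.exponential(scenario.censoring_mean, size=n)
    c_time = np.minimum(c_time, scenario.max_followup)
    observed = np.where(finite, np.minimum(t_event, c_time), c_time)
    # tie between event and censoring time (measure zero): the event wins
    delta = np.where(finite & (t_event <= c_time), cause, 0)

    visit_times = np.linspace(0.0, scenario.max_followup, scenario.n_visits)
    subjects: list[SubjectRecord] = []
    for i in range(n):
        keep = visit_times <= observed[i] + 1e-12
        times = visit_times[keep]
        mean1 = lat.u1[i] + lat.v1[i] * times
        y1 = mean1 + rng.normal(0.0, params.sigma1, size=times.size)
        series_1 = list(zip(times.tolist(), y1.tolist()))
        if spec.has_outcome2:
            mean2 = lat.u2[i] + lat.v2[i] * times
            y2 = mean2 + rng.normal(0.0, params.sigma2, size=times.size)
            series_2 = list(zip(times.tolist(), y2.tolist()))
        else:
            series_2 = []
        subjects.append(
            SubjectRecord(
                subject_id=f"s{i + 1:04d}",
                intervention=int(intervention[i]),
                baseline_covariates={},
                series_1=series_1,
                series_2=series_2,
                observed_time=float(observed[i]),
                event=int(delta[i]),
            )
        )
    return subjects
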