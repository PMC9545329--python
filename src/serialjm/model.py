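"""Model mathematics: latent trajectories, hazards, and the joint likelihood.

All functions here are per-subject reference implementations, written for
clarity and used directly by the simulator and the tests.  The MCMC engine
(:mod:`serialjm.inference`) re-expresses the same quantities as vectorised
array operations across subjects; agreement between the two routes is part of
the test suite.
"""
from __future__ import annotations

import numpy as np

from .types import (
    BaselineHazardSpec,
    JointModelParameters,
    RandomEffects,
    SubjectRecord,
    design_matrix,
)

__all__ = [
    "latent_m1",
    "latent_m2",
    "log_baseline_hazard",
    "hazard",
    "cumulative_hazard",
    "subject_loglik",
    "gauss_legendre_nodes",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

#: Gauss-Legendre order for cumulative hazards (standard joint-model choice)
QUADRATURE_ORDER = 15


def latent_m1(
    t: float | np.ndarray,
    params: JointModelParameters,
    subject: SubjectRecord,
    b: RandomEffects,
) -> np.ndarray:
    """True (error-free) trajectory m1(t) = x1(t)'beta1 + z1(t)'b1."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    X = design_matrix(params.spec.long1.fixed_terms, subject, t)
    Z = np.column_stack([np.ones_like(t), t])
    return X @ params.beta1 + Z @ b.b1


def latent_m2(
    t: float | np.ndarray,
    params: JointModelParameters,
    subject: SubjectRecord,
    b: RandomEffects,
) -> np.ndarray:
    """m2(t) = x2(t)'beta2 + z2(t)'b2 + xi * m1(t).

    The first outcome's latent process enters as a time-varying covariate;
    ``xi`` is the change in m2 per unit increase in m1.
    """
    if not params.spec.has_outcome2:
        raise ValueError("model specification has no second outcome")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    X = design_matrix(params.spec.long2.fixed_terms, subject, t)
    Z = np.column_stack([np.ones_like(t), t])
    return X @ params.beta2 + Z @ b.b2 + params.xi * latent_m1(
        t, params, subject, b
    )


def log_baseline_hazard(
    t: float | np.ndarray, k: int, spec: BaselineHazardSpec
) -> np.ndarray:
    """log h0k(t): B-spline basis at t dotted with the risk-k coefficients."""
    if k not in (1, 2):
        raise ValueError("risk index k must be 1 or 2")
    return spec.basis(t) @ spec.coefficients_per_risk[k - 1]


def hazard(
    t: float | np.ndarray,
    k: int,
    params: JointModelParameters,
    subject: SubjectRecord,
    b: RandomEffects,
) -> np.ndarray:
    """Cause-specific hazard h_k(t) = h0k(t) exp{gamma_k'w + a_k1 m1 + a_k2 m2}.

    Strictly positive for all finite parameters.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    W = design_matrix(params.spec.survival_terms, subject, np.zeros(1))[0]
    lp = log_baseline_hazard(t, k, params.baseline) + params.gamma[k - 1] @ W
    lp = lp + params.alpha[k - 1, 0] * latent_m1(t, params, subject, b)
    if params.spec.has_outcome2:
        lp = lp + params.alpha[k - 1, 1] * latent_m2(t, params, subject, b)
    return np.exp(lp)


def gauss_legendre_nodes(
    upper: float, order: int = QUADRATURE_ORDER
) -> tuple[np.ndarray, np.ndarray]:
    """Nodes and weights of Gauss-Legendre quadrature on [0, upper]."""
    x, w = np.polynomial.legendre.leggauss(order)
    half = 0.5 * upper
    return half * (x + 1.0), half * w


def cumulative_hazard(
    t: float,
    k: int,
    params: JointModelParameters,
    subject: SubjectRecord,
    b: RandomEffects,
    order: int = QUADRATURE_ORDER,
    composite: bool = True,
) -> float:
    """Integral of the cause-k hazard over [0, t] by Gauss-Legendre quadrature.

    Zero at t = 0 and nondecreasing in t (the integrand is positive).  By
    default the integral is split at the baseline spline's interior knots,
    where the integrand is only C^(degree-1); per-segment Gauss-Legendre then
    converges at the full rate.  ``composite=False`` applies one rule on
    [0, t] — the cheaper variant used inside the vectorised likelihood, whose
    error is far below statistical relevance.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0.0:
        return 0.0
    t = float(t)
    if composite:
        cuts = [u for u in params.baseline.interior_knots if 0.0 < u < t]
        edges = np.concatenate([[0.0], cuts, [t]])
    else:
        edges = np.array([0.0, t])
    x, w = np.polynomial.legendre.leggauss(order)
    total = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        half = 0.5 * (hi - lo)
        nodes = lo + half * (x + 1.0)
        total += half * float(w @ hazard(nodes, k, params, subject, b))
    return total


def subject_loglik(
    subject: SubjectRecord,
    params: JointModelParameters,
    b: RandomEffects,
) -> float:
    """Joint log-likelihood of one subject's data given its random effects.

    Sum of the two Gaussian longitudinal terms, the log cause-specific hazard
    at the observed time for the realised event (if any), and minus both
    cumulative hazards at the observed time.  The random-effects density is
    deliberately excluded: this is the data likelihood conditional on ``b``.
    """
    subject.validate()
    total = 0.0

    def _normal_terms(series, mean_fn, sigma, label):
        if not series:
            return 0.0
        times = np.array([t for t, _ in series], dtype=float)
        values = np.array([v for _, v in series], dtype=float)
        resid = values - mean_fn(times)
        out = float(
            np.sum(
                -0.5 * _LOG_2PI - np.log(sigma) - 0.5 * (resid / sigma) ** 2
            )
        )
        if not np.isfinite(out):
            raise FloatingPointError(
                f"non-finite longitudinal log-likelihood (outcome {label}) "
                f"for subject {subject.subject_id}"
            )
        return out

    total += _normal_terms(
        subject.series_1,
        lambda t: latent_m1(t, params, subject, b),
        params.sigma1,
        "1",
    )
    if params.spec.has_outcome2:
        total += _normal_terms(
            subject.series_2,
            lambda t: latent_m2(t, params, subject, b),
            params.sigma2,
            "2",
        )

    T = subject.observed_time
    if subject.event in (1, 2):
        h = hazard(T, subject.event, params, subject, b)[0]
        if not (np.isfinite(h) and h > 0):
            raise FloatingPointError(
                f"non-finite event hazard for subject {subject.subject_id}"
            )
        total += float(np.log(h))
    for k in (1, 2):
        lam = cumulative_hazard(T, k, params, subject, b)
        if not np.isfinite(lam):
            raise FloatingPointError(
                f"non-finite cumulative hazard (risk {k}) for subject "
                f"{subject.subject_id}"
            )
        total -= lam
    return total
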