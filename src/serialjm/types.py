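"""Core data structures for the multivariate competing-risk joint model.

The model couples two linear mixed-effects submodels — the latent process of
the first longitudinal outcome enters the second outcome's mixed model as a
time-varying covariate with coefficient ``xi`` — with two cause-specific
proportional-hazards submodels whose log-baseline hazards are B-splines and
whose linear predictors load on both latent processes through the association
matrix ``alpha``.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "SubjectRecord",
    "LongitudinalSpec",
    "BaselineHazardSpec",
    "JointModelParameters",
    "RandomEffects",
    "ModelSpec",
    "design_matrix",
]

#: term names with built-in meaning; anything else is looked up in
#: ``SubjectRecord.baseline_covariates``
_BUILTIN_TERMS = ("intercept", "time", "intervention", "intervention:time")


@dataclass
class SubjectRecord:
    """One subject: covariates, two measurement series, and survival data.

    ``series_1``/``series_2`` are sequences of ``(time, value)`` pairs, timed
    independently per outcome.  ``event`` is 0 for censoring and 1 or 2 for
    the two competing events.
    """

    subject_id: str
    intervention: int
    baseline_covariates: dict[str, float]
    series_1: list[tuple[float, float]]
    series_2: list[tuple[float, float]]
    observed_time: float
    event: int

    def validate(self) -> None:
        if self.observed_time < 0:
            raise ValueError(
                f"subject {self.subject_id}: observed_time must be >= 0"
            )
        if self.event not in (0, 1, 2):
            raise ValueError(
                f"subject {self.subject_id}: event must be in {{0, 1, 2}}, "
                f"got {self.event}"
            )
        for label, series in (("1", self.series_1), ("2", self.series_2)):
            for t, _ in series:
                if t < 0:
                    raise ValueError(
                        f"subject {self.subject_id}: outcome-{label} "
                        f"measurement at negative time {t}"
                    )
                if t > self.observed_time + 1e-12:
                    raise ValueError(
                        f"subject {self.subject_id}: outcome-{label} "
                        f"measurement at t={t} after observed_time="
                        f"{self.observed_time}"
                    )


@dataclass(frozen=True)
class LongitudinalSpec:
    """Fixed/random-effects structure of one longitudinal submodel.

    ``fixed_terms`` is an ordered tuple drawn from ``intercept``, ``time``,
    ``intervention``, ``intervention:time`` and names of baseline covariates.
    Random effects are always a random intercept and a random slope.
    ``includes_upstream_latent`` is True only for the second outcome, whose
    mean adds ``xi * m1(t)``.
    """

    fixed_terms: tuple[str, ...]
    includes_upstream_latent: bool = False

    def __post_init__(self) -> None:
        if len(set(self.fixed_terms)) != len(self.fixed_terms):
            raise ValueError("duplicate fixed terms")

    @property
    def n_fixed(self) -> int:
        return len(self.fixed_terms)


def _term_value(term: str, subject: SubjectRecord, t: np.ndarray) -> np.ndarray:
    if term == "intercept":
        return np.ones_like(t)
    if term == "time":
        return t
    if term == "intervention":
        return np.full_like(t, float(subject.intervention))
    if term == "intervention:time":
        return float(subject.intervention) * t
    try:
        return np.full_like(t, float(subject.baseline_covariates[term]))
    except KeyError:
        raise KeyError(
            f"subject {subject.subject_id} is missing covariate {term!r} "
            f"required by the model specification"
        ) from None


def design_matrix(
    terms: Sequence[str], subject: SubjectRecord, t: np.ndarray | float
) -> np.ndarray:
    """Design matrix (len(t) x len(terms)) for one subject at times ``t``."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    return np.column_stack([_term_value(term, subject, t) for term in terms])


@dataclass(frozen=True)
class BaselineHazardSpec:
    """B-spline log-baseline hazards, shared knots across the two risks.

    The basis is evaluated on the log-hazard scale so the baseline hazard is
    positive for any coefficient values.  Evaluation outside the boundary
    knots is an error: hazards are never extrapolated.
    """

    degree: int
    boundary_knots: tuple[float, float]
    interior_knots: tuple[float, ...]
    coefficients_per_risk: np.ndarray  # (2, n_basis)

    def __post_init__(self) -> None:
        lo, hi = self.boundary_knots
        if not lo < hi:
            raise ValueError("boundary knots must satisfy lo < hi")
        interior = np.asarray(self.interior_knots, dtype=float)
        if interior.size and not (
            np.all(np.diff(interior) > 0)
            and interior[0] > lo
            and interior[-1] < hi
        ):
            raise ValueError("interior knots must be ordered and strictly "
                             "inside the boundary knots")
        coefs = np.atleast_2d(np.asarray(self.coefficients_per_risk, float))
        object.__setattr__(self, "coefficients_per_risk", coefs)
        if coefs.shape[1] != self.n_basis:
            raise ValueError(
                f"expected {self.n_basis} coefficients per risk, "
                f"got {coefs.shape[1]}"
            )

    @property
    def n_basis(self) -> int:
        return len(self.interior_knots) + self.degree + 1

    @property
    def knots(self) -> np.ndarray:
        """Full (clamped) knot vector."""
        lo, hi = self.boundary_knots
        return np.concatenate(
            [
                np.repeat(lo, self.degree + 1),
                np.asarray(self.interior_knots, dtype=float),
                np.repeat(hi, self.degree + 1),
            ]
        )

    def basis(self, t: np.ndarray | float) -> np.ndarray:
        """B-spline basis matrix at times ``t`` (len(t) x n_basis)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        lo, hi = self.boundary_knots
        if np.any(t < lo - 1e-12) or np.any(t > hi + 1e-12):
            raise ValueError(
                f"time outside baseline-hazard support [{lo}, {hi}]; "
                "refusing to extrapolate the baseline hazard"
            )
        t = np.clip(t, lo, hi)
        return BSpline.design_matrix(
            t, self.knots, self.degree, extrapolate=False
        ).toarray()


@dataclass(frozen=True)
class ModelSpec:
    """Structure of the full joint model (no parameter values)."""

    long1: LongitudinalSpec
    long2: LongitudinalSpec | None
    survival_terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.long1.includes_upstream_latent:
            raise ValueError("outcome 1 cannot include an upstream latent "
                             "process")
        if self.long2 is not None and not self.long2.includes_upstream_latent:
            raise ValueError("outcome 2 must include the upstream latent "
                             "process in this model family")

    @property
    def has_outcome2(self) -> bool:
        return self.long2 is not None


@dataclass
class RandomEffects:
    """Random intercept and slope per outcome for one subject."""

    b1: np.ndarray = field(default_factory=lambda: np.zeros(2))
    b2: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.b1 = np.asarray(self.b1, dtype=float)
        self.b2 = np.asarray(self.b2, dtype=float)
        if not (np.all(np.isfinite(self.b1)) and np.all(np.isfinite(self.b2))):
            raise ValueError("random effects must be finite")


@dataclass
class JointModelParameters:
    """Every parameter of the joint model, tied to a :class:`ModelSpec`.

    ``alpha`` is the 2x2 association matrix with rows indexed by risk k and
    columns by longitudinal outcome j: ``alpha[k-1, j-1]`` is the log hazard
    ratio for event k per unit increase of outcome j's latent process.
    ``gamma`` has one row of survival covariate coefficients per risk.
    """

    spec: ModelSpec
    beta1: np.ndarray
    beta2: np.ndarray | None
    xi: float
    sigma1: float
    sigma2: float | None
    Sigma_b1: np.ndarray
    Sigma_b2: np.ndarray | None
    gamma: np.ndarray  # (2, n_survival_terms)
    alpha: np.ndarray  # (2, 2); column 2 ignored without outcome 2
    baseline: BaselineHazardSpec

    def __post_init__(self) -> None:
        self.beta1 = np.asarray(self.beta1, dtype=float)
        if self.beta1.shape != (self.spec.long1.n_fixed,):
            raise ValueError("beta1 length does not match outcome-1 terms")
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        self.alpha = np.atleast_2d(np.asarray(self.alpha, dtype=float))
        if self.alpha.shape != (2, 2):
            raise ValueError("alpha must be a 2x2 matrix (risk x outcome)")
        self.Sigma_b1 = _check_cov(np.asarray(self.Sigma_b1, float), "Sigma_b1")
        if self.sigma1 <= 0:
            raise ValueError("sigma1 must be positive")
        if self.spec.has_outcome2:
            self.beta2 = np.asarray(self.beta2, dtype=float)
            if self.beta2.shape != (self.spec.long2.n_fixed,):
                raise ValueError("beta2 length does not match outcome-2 terms")
            if self.sigma2 is None or self.sigma2 <= 0:
                raise ValueError("sigma2 must be positive")
            self.Sigma_b2 = _check_cov(
                np.asarray(self.Sigma_b2, float), "Sigma_b2"
            )

    def replace(self, **kwargs) -> "JointModelParameters":
        return replace(self, **kwargs)


def _check_cov(S: np.ndarray, name: str) -> np.ndarray:
    if S.shape != (2, 2) or not np.allclose(S, S.T):
        raise ValueError(f"{name} must be 2x2 symmetric")
    if np.any(np.linalg.eigvalsh(S) <= 0):
        raise ValueError(f"{name} must be positive definite")
    return S
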