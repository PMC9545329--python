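import numpy as np
import pytest

from serialjm import (
    BaselineHazardSpec,
    JointModelParameters,
    LongitudinalSpec,
    ModelSpec,
    SubjectRecord,
)

SIM_SPEC = ModelSpec(
    long1=LongitudinalSpec(("intercept", "time", "intervention:time")),
    long2=LongitudinalSpec(
        ("intercept", "time", "intervention:time"),
        includes_upstream_latent=True,
    ),
    survival_terms=("intervention",),
)


def make_baseline(coefs=None, n_interior=3, t_max=3.2, degree=3):
    interior = tuple(np.linspace(0, t_max, n_interior + 2)[1:-1])
    nb = n_interior + degree + 1
    if coefs is None:
        coefs = np.zeros((2, nb))
    else:
        coefs = np.broadcast_to(np.asarray(coefs, float), (2, nb)).copy()
    return BaselineHazardSpec(
        degree=degree,
        boundary_knots=(0.0, t_max),
        interior_knots=interior,
        coefficients_per_risk=coefs,
    )


def make_params(
    beta1=(0.07, -0.25, 0.12),
    beta2=(0.15, 0.45, -0.10),
    xi=-0.5,
    sigma=0.5,
    gamma=((-0.2,), (0.1,)),
    alpha=((-0.6, 0.4), (-0.1, 0.1)),
    baseline=None,
    spec=SIM_SPEC,
):
    Sigma = np.array([[0.25, 0.025], [0.025, 0.0625]])
    return JointModelParameters(
        spec=spec,
        beta1=np.asarray(beta1, float),
        beta2=np.asarray(beta2, float) if spec.has_outcome2 else None,
        xi=xi,
        sigma1=sigma,
        sigma2=sigma if spec.has_outcome2 else None,
        Sigma_b1=Sigma.copy(),
        Sigma_b2=Sigma.copy() if spec.has_outcome2 else None,
        gamma=np.asarray(gamma, float),
        alpha=np.asarray(alpha, float),
        baseline=baseline if baseline is not None else make_baseline(),
    )


def make_subject(
    intervention=0,
    covariates=None,
    series_1=(),
    series_2=(),
    observed_time=3.2,
    event=0,
    subject_id="s1",
):
    return SubjectRecord(
        subject_id=subject_id,
        intervention=intervention,
        baseline_covariates=dict(covariates or {}),
        series_1=list(series_1),
        series_2=list(series_2),
        observed_time=observed_time,
        event=event,
    )


@pytest.fixture
def sim_spec():
    return SIM_SPEC
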