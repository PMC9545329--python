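"""Bayesian estimation of the joint model by Markov chain Monte Carlo.

The sampler is a blocked Metropolis-within-Gibbs scheme:

* Random effects are proposed from their exact Gaussian full conditional
  given the longitudinal data and the random-effects prior (both outcomes
  contribute to ``b1`` because the latent process of outcome 1 enters
  outcome 2's mean with coefficient ``xi``), with a Metropolis correction
  for the survival factor of the likelihood.  Because the proposal matches
  the dominant part of the conditional, acceptance is high and mixing of the
  random effects is close to independent sampling.
* Structural parameters are updated in small blocks by adaptive random-walk
  Metropolis; proposal covariances are learned from the warm-up history and
  frozen afterwards so the sampling phase is a valid Markov chain.

Likelihood evaluations are fully vectorised across subjects; cumulative
hazards use fixed-order Gauss-Legendre quadrature on [0, T_i].
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import QUADRATURE_ORDER
from .types import (
    BaselineHazardSpec,
    ModelSpec,
    SubjectRecord,
)

__all__ = [
    "PriorSpec",
    "McmcConfig",
    "PosteriorDraws",
    "PosteriorSummary",
    "fit",
    "fit_univariate",
    "summarize",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative default priors, all scales overridable.

    Normal(0, coef_scale^2) on fixed effects, gamma, alpha and xi;
    half-t(sd_df, sd_scale) on the error SDs and random-effect SDs;
    LKJ(lkj_eta) on the within-outcome random-effect correlation;
    Normal(0, spline_scale^2) ridge on the log-baseline spline coefficients.
    """

    coef_scale: float = 10.0
    sd_scale: float = 2.5
    sd_df: float = 3.0
    lkj_eta: float = 2.0
    spline_scale: float = 5.0

    def __post_init__(self) -> None:
        for name in ("coef_scale", "sd_scale", "sd_df", "spline_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class McmcConfig:
    """Chain-length settings. ``n_iterations`` counts warm-up + retained."""

    n_iterations: int = 3000
    n_burnin: int = 1000
    n_chains: int = 2
    seed: int = 0
    thinning: int = 1

    def __post_init__(self) -> None:
        if not self.n_burnin < self.n_iterations:
            raise ValueError("n_burnin must be < n_iterations")
        if self.n_chains < 1 or self.thinning < 1:
            raise ValueError("n_chains and thinning must be >= 1")


#: preset mirroring the published analysis (100k iterations, 50k burn-in)
FULL_MCMC = McmcConfig(n_iterations=100_000, n_burnin=50_000, n_chains=2)


@dataclass
class PosteriorDraws:
    """Named posterior draws, one (chain, draw) matrix per parameter."""

    draws: dict[str, np.ndarray]
    meta: dict

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.draws.values()}
        if len(shapes) > 1:
            raise ValueError("all parameters must have equal draw counts")

    @property
    def names(self) -> list[str]:
        return list(self.draws)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def flat(self, name: str) -> np.ndarray:
        """All retained draws of one parameter, chains concatenated."""
        try:
            return self.draws[name].reshape(-1)
        except KeyError:
            raise KeyError(
                f"parameter {name!r} not in draws; available: {self.names}"
            ) from None


@dataclass
class PosteriorSummary:
    """Per-parameter posterior mean, SD, central 95% interval, diagnostics."""

    table: pd.DataFrame

    def param(self, name: str) -> pd.Series:
        return self.table.loc[name]

    @property
    def max_rhat(self) -> float:
        return float(self.table["rhat"].max())


def summarize(draws: PosteriorDraws) -> PosteriorSummary:
    """Posterior mean, SD, 2.5/97.5% quantiles, split R-hat and bulk ESS."""
    if draws.n_draws < 100:
        raise ValueError("need at least 100 retained draws to summarize")
    import arviz as az

    # split each chain in two so R-hat/ESS are the split versions and remain
    # defined for single-chain runs
    half = draws.n_draws // 2
    split = {
        k: np.concatenate([v[:, :half], v[:, half:2 * half]], axis=0)
        for k, v in draws.draws.items()
    }
    idata = az.from_dict(split)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rows = {}
    for name, arr in draws.draws.items():
        flat = arr.reshape(-1)
        rows[name] = {
            "mean": float(np.mean(flat)),
            "sd": float(np.std(flat, ddof=1)) if flat.size > 1 else 0.0,
            "q2.5": float(np.quantile(flat, 0.025)),
            "q97.5": float(np.quantile(flat, 0.975)),
            "rhat": float(rhat[name].values),
            "ess": float(ess[name].values),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    return PosteriorSummary(table=table)


# --------------------------------------------------------------------------
# vectorised data container
# --------------------------------------------------------------------------


def _design_rows(terms, w, cov, t):
    """Stacked design values for per-row subject attributes ``w``/``cov``.

    ``w`` and covariates are row-aligned with ``t`` (any shape).
    """
    cols = []
    for term in terms:
        if term == "intercept":
            cols.append(np.ones_like(t))
        elif term == "time":
            cols.append(t)
        elif term == "intervention":
            cols.append(np.broadcast_to(w, t.shape).copy())
        elif term == "intervention:time":
            cols.append(w * t)
        else:
            cols.append(np.broadcast_to(cov[term], t.shape).copy())
    return np.stack(cols, axis=-1)


class _ModelData:
    """Dataset reorganised into flat arrays for vectorised likelihoods."""

    def __init__(
        self,
        subjects: list[SubjectRecord],
        spec: ModelSpec,
        n_interior_knots: int = 5,
        spline_degree: int = 3,
        quad_order: int = QUADRATURE_ORDER,
    ):
        if not subjects:
            raise ValueError("dataset is empty")
        for s in subjects:
            s.validate()
        self.spec = spec
        n = self.n = len(subjects)
        self.ids = [s.subject_id for s in subjects]

        self.w = np.array([float(s.intervention) for s in subjects])
        cov_names = sorted(
            {k for s in subjects for k in s.baseline_covariates}
        )
        self.cov = {}
        for name in cov_names:
            try:
                self.cov[name] = np.array(
                    [float(s.baseline_covariates[name]) for s in subjects]
                )
            except KeyError:
                missing = [
                    s.subject_id for s in subjects
                    if name not in s.baseline_covariates
                ]
                raise KeyError(
                    f"covariate {name!r} missing for subjects {missing[:5]}"
                ) from None
        needed = set(spec.long1.fixed_terms) | set(spec.survival_terms)
        if spec.has_outcome2:
            needed |= set(spec.long2.fixed_terms)
        for term in needed - {"intercept", "time", "intervention",
                              "intervention:time"}:
            if term not in self.cov:
                raise KeyError(
                    f"model specification requires covariate {term!r} which "
                    "no subject carries"
                )

        self.T = np.array([s.observed_time for s in subjects])
        self.delta = np.array([s.event for s in subjects], dtype=int)

        def stack_series(attr):
            idx, times, values = [], [], []
            for i, s in enumerate(subjects):
                for t, v in getattr(s, attr):
                    idx.append(i)
                    times.append(t)
                    values.append(v)
            return (
                np.array(idx, dtype=int),
                np.array(times, dtype=float),
                np.array(values, dtype=float),
            )

        self.idx1, t1, self.y1 = stack_series("series_1")
        self.t1 = t1
        self.X1 = _design_rows(
            spec.long1.fixed_terms, self.w[self.idx1],
            {k: v[self.idx1] for k, v in self.cov.items()}, t1
        )
        self.Z1 = np.column_stack([np.ones_like(t1), t1])

        if spec.has_outcome2:
            self.idx2, t2, self.y2 = stack_series("series_2")
            self.t2 = t2
            cov2 = {k: v[self.idx2] for k, v in self.cov.items()}
            self.X2 = _design_rows(
                spec.long2.fixed_terms, self.w[self.idx2], cov2, t2
            )
            self.Z2 = np.column_stack([np.ones_like(t2), t2])
            self.X1a2 = _design_rows(
                spec.long1.fixed_terms, self.w[self.idx2], cov2, t2
            )
            self.Z1a2 = self.Z2

        # survival design
        self.W = _design_rows(
            spec.survival_terms, self.w, self.cov, np.zeros(n)
        ) if spec.survival_terms else np.zeros((n, 0))
        # replace time-dependent placeholders: survival covariates are
        # baseline-only, so 'time' terms are not allowed there
        if any(t in ("time", "intervention:time") for t in spec.survival_terms):
            raise ValueError("survival covariates must be baseline-only")

        # baseline-hazard knots: interior at equally spaced quantiles of the
        # observed event times, boundary at 0 and the largest observed time
        t_max = float(self.T.max())
        event_times = self.T[self.delta > 0]
        pool = event_times if event_times.size >= n_interior_knots + 2 else self.T
        qs = np.linspace(0, 1, n_interior_knots + 2)[1:-1]
        interior = np.quantile(pool, qs)
        interior = np.unique(np.clip(interior, 1e-6 * t_max, (1 - 1e-6) * t_max))
        self.baseline_template = BaselineHazardSpec(
            degree=spline_degree,
            boundary_knots=(0.0, t_max),
            interior_knots=tuple(interior.tolist()),
            coefficients_per_risk=np.zeros((2, interior.size + spline_degree + 1)),
        )
        nb = self.n_basis = self.baseline_template.n_basis

        # Gauss-Legendre nodes on [0, T_i]
        x, wq = np.polynomial.legendre.leggauss(quad_order)
        self.glw = wq
        self.nodes = 0.5 * self.T[:, None] * (x + 1.0)  # (n, G)
        self.wts = 0.5 * self.T[:, None] * wq
        G = quad_order
        basis = self.baseline_template.basis
        self.B_nodes = basis(self.nodes.ravel()).reshape(n, G, nb)
        self.B_nodes_flat = self.B_nodes.reshape(n * G, nb)
        self.B_T = basis(self.T)
        covn = {k: v[:, None] for k, v in self.cov.items()}
        self.X1n = _design_rows(
            spec.long1.fixed_terms, self.w[:, None], covn, self.nodes
        )
        self.X1n_flat = self.X1n.reshape(n * G, -1)
        self.X1T = _design_rows(spec.long1.fixed_terms, self.w, self.cov, self.T)
        if spec.has_outcome2:
            self.X2n = _design_rows(
                spec.long2.fixed_terms, self.w[:, None], covn, self.nodes
            )
            self.X2n_flat = self.X2n.reshape(n * G, -1)
            self.X2T = _design_rows(
                spec.long2.fixed_terms, self.w, self.cov, self.T
            )

        # per-subject random-effect cross products for conjugate proposals
        def ztz(Z, idx):
            out = np.zeros((n, 2, 2))
            for a in range(2):
                for b in range(a, 2):
                    v = np.bincount(idx, weights=Z[:, a] * Z[:, b], minlength=n)
                    out[:, a, b] = v
                    out[:, b, a] = v
            return out

        # per-subject affine decomposition of the fixed designs: every
        # supported term is a + c*t per subject, so x(t)'delta = A@delta +
        # (C@delta)*t.  Used by the translation moves that shift a fixed
        # effect and counter-shift the random effects.
        def affine_terms(terms):
            A = np.zeros((n, len(terms)))
            C = np.zeros((n, len(terms)))
            for j, term in enumerate(terms):
                if term == "intercept":
                    A[:, j] = 1.0
                elif term == "time":
                    C[:, j] = 1.0
                elif term == "intervention":
                    A[:, j] = self.w
                elif term == "intervention:time":
                    C[:, j] = self.w
                else:
                    A[:, j] = self.cov[term]
            return A, C

        self.A1, self.C1 = affine_terms(spec.long1.fixed_terms)
        if spec.has_outcome2:
            self.A2, self.C2 = affine_terms(spec.long2.fixed_terms)

        self.Z1tZ1 = ztz(self.Z1, self.idx1)
        if spec.has_outcome2:
            self.Z2tZ2 = ztz(self.Z2, self.idx2)
            self.Z1a2tZ1a2 = self.Z2tZ2  # same design

        self.is_event = [self.delta == 1, self.delta == 2]


# --------------------------------------------------------------------------
# batched 2x2 linear algebra helpers
# --------------------------------------------------------------------------


def _inv2(A):
    a, b, d = A[..., 0, 0], A[..., 0, 1], A[..., 1, 1]
    det = a * d - b * b
    out = np.empty_like(A)
    out[..., 0, 0] = d / det
    out[..., 1, 1] = a / det
    out[..., 0, 1] = out[..., 1, 0] = -b / det
    return out


def _chol2(V):
    l11 = np.sqrt(V[..., 0, 0])
    l21 = V[..., 0, 1] / l11
    l22 = np.sqrt(np.maximum(V[..., 1, 1] - l21**2, 1e-300))
    return l11, l21, l22


def _cov_from_eta(eta):
    sd1, sd2 = np.exp(eta[0]), np.exp(eta[1])
    rho = np.tanh(eta[2])
    return np.array(
        [[sd1**2, rho * sd1 * sd2], [rho * sd1 * sd2, sd2**2]]
    )


# --------------------------------------------------------------------------
# adaptive random-walk block
# --------------------------------------------------------------------------


class _AdaptiveBlock:
    def __init__(self, name, init_scale, dim):
        self.name = name
        self.dim = dim
        self.log_s = np.log(init_scale)
        self.mean = np.zeros(dim)
        self.m2 = np.zeros((dim, dim))
        self.count = 0
        self.chol = np.eye(dim)

    def propose(self, x, rng):
        eps = rng.standard_normal(self.dim)
        return x + np.exp(self.log_s) * (self.chol @ eps)

    def adapt(self, x, accepted, iteration, warmup):
        if iteration >= warmup:
            return
        rate = 0.234 if self.dim > 1 else 0.44
        self.log_s += (float(accepted) - rate) / (1.0 + 0.1 * iteration) ** 0.6
        self.count += 1
        d = x - self.mean
        self.mean += d / self.count
        self.m2 += np.outer(d, x - self.mean)
        if self.count > 50 and self.count % 25 == 0:
            cov = self.m2 / (self.count - 1) + 1e-9 * np.eye(self.dim)
            try:
                self.chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                pass


# --------------------------------------------------------------------------
# the sampler
# --------------------------------------------------------------------------


class _Sampler:
    def __init__(self, data: _ModelData, priors: PriorSpec, rng):
        self.d = data
        self.pr = priors
        self.rng = rng
        self._glw = data.glw
        self.has2 = data.spec.has_outcome2
        self.q = len(data.spec.survival_terms)
        self.n_alpha = 2 if self.has2 else 1
        self._init_state()
        self._refresh_all()
        lp = self._total_loglik()
        if not np.isfinite(lp):
            raise FloatingPointError(
                "non-finite log-posterior at initialization; state: "
                + repr({k: np.round(v, 3) for k, v in self.state.items()})
            )

    # -- initialization ----------------------------------------------------
    def _init_state(self):
        d = self.d
        st = {}
        beta1, *_ = np.linalg.lstsq(d.X1, d.y1, rcond=None)
        resid1 = d.y1 - d.X1 @ beta1
        st["beta1"] = beta1
        st["log_sigma1"] = np.array(
            [np.log(max(np.std(resid1), 1e-3)) ]
        )
        if self.has2:
            m1hat = d.X1a2 @ beta1
            X = np.column_stack([d.X2, m1hat])
            coef, *_ = np.linalg.lstsq(X, d.y2, rcond=None)
            st["beta2"] = coef[:-1]
            st["xi"] = np.array([coef[-1]])
            resid2 = d.y2 - X @ coef
            st["log_sigma2"] = np.array(
                [np.log(max(np.std(resid2), 1e-3))]
            )
        st["eta1"] = np.array([np.log(0.3), np.log(0.2), 0.0])
        if self.has2:
            st["eta2"] = st["eta1"].copy()
        exposure = max(float(d.T.sum()), 1e-6)
        for k in (1, 2):
            n_ev = max(int((d.delta == k).sum()), 1)
            st[f"ga{k}"] = np.zeros(self.q + self.n_alpha)
            st[f"phi{k}"] = np.full(d.n_basis, np.log(n_ev / exposure))
        # jitter for chain dispersion
        for key, val in st.items():
            st[key] = val + 0.01 * self.rng.standard_normal(val.shape)
        self.state = st
        self.b1 = np.zeros((d.n, 2))
        self.b2 = np.zeros((d.n, 2))

    # -- cache management --------------------------------------------------
    # the random-effect design is always (1, t), so z'b = b0 + b1 * t
    def _m1_pieces(self, beta1, b1):
        d = self.d
        fit1 = d.X1 @ beta1 + b1[d.idx1, 0] + b1[d.idx1, 1] * d.t1
        m1n = (
            (d.X1n_flat @ beta1).reshape(d.nodes.shape)
            + b1[:, 0, None]
            + b1[:, 1, None] * d.nodes
        )
        m1T = d.X1T @ beta1 + b1[:, 0] + b1[:, 1] * d.T
        m1a2 = (
            d.X1a2 @ beta1 + b1[d.idx2, 0] + b1[d.idx2, 1] * d.t2
            if self.has2
            else None
        )
        return fit1, m1n, m1T, m1a2

    def _m2_pieces(self, beta2, xi, b2, m1n, m1T):
        d = self.d
        m2n = (
            (d.X2n_flat @ beta2).reshape(d.nodes.shape)
            + b2[:, 0, None]
            + b2[:, 1, None] * d.nodes
            + xi * m1n
        )
        m2T = d.X2T @ beta2 + b2[:, 0] + b2[:, 1] * d.T + xi * m1T
        return m2n, m2T

    def _surv_vec(self, k, m1n, m1T, m2n, m2T, ga=None, phi=None):
        """Per-subject survival log-likelihood contribution for risk k.

        ``ga``/``phi`` default to the cached current-state linear predictors;
        pass a value to evaluate a proposal for that block.
        """
        d = self.d
        if ga is None:
            wlp = self.wlp[k]
            alpha = self.state[f"ga{k}"][self.q:]
        else:
            gamma = ga[: self.q]
            alpha = ga[self.q:]
            wlp = d.W @ gamma if self.q else np.zeros(d.n)
        if phi is None:
            logh0T = self.logh0T[k]
            logh0n = self.logh0n[k]
        else:
            logh0T = d.B_T @ phi
            logh0n = (d.B_nodes_flat @ phi).reshape(d.nodes.shape)
        lpT = logh0T + wlp + alpha[0] * m1T
        lpn = logh0n + wlp[:, None] + alpha[0] * m1n
        if self.has2:
            lpT = lpT + alpha[1] * m2T
            lpn = lpn + alpha[1] * m2n
        with np.errstate(over="ignore"):
            lam = np.exp(lpn) @ self._glw  # weights via wts = glw * T/2
            lam = lam * (0.5 * d.T)
        return np.where(d.is_event[k - 1], lpT, 0.0) - lam

    @staticmethod
    def _gauss_ll(ssr, n_obs, log_sigma):
        return -n_obs * (0.5 * _LOG_2PI + log_sigma) - 0.5 * ssr * np.exp(
            -2.0 * log_sigma
        )

    def _re_prior(self, b, eta):
        S = _cov_from_eta(eta)
        P = _inv2(S)
        quad = np.einsum("ni,ij,nj->n", b, P, b)
        logdet = float(np.log(S[0, 0] * S[1, 1] - S[0, 1] ** 2))
        return -b.shape[0] * (_LOG_2PI + 0.5 * logdet) - 0.5 * float(quad.sum())

    def _refresh_all(self):
        st = self.state
        d = self.d
        self.fit1, self.m1n, self.m1T, self.m1a2 = self._m1_pieces(
            st["beta1"], self.b1
        )
        self.r1 = d.y1 - self.fit1
        self.ssr1 = float(self.r1 @ self.r1)
        self.ll1 = self._gauss_ll(self.ssr1, d.y1.size, st["log_sigma1"][0])
        if self.has2:
            self.m2n, self.m2T = self._m2_pieces(
                st["beta2"], st["xi"][0], self.b2, self.m1n, self.m1T
            )
            self.r2 = (
                d.y2
                - d.X2 @ st["beta2"]
                - np.sum(d.Z2 * self.b2[d.idx2], axis=1)
                - st["xi"][0] * self.m1a2
            )
            self.ssr2 = float(self.r2 @ self.r2)
            self.ll2 = self._gauss_ll(self.ssr2, d.y2.size, st["log_sigma2"][0])
        else:
            self.m2n = self.m2T = None
            self.ll2 = 0.0
        # cached survival linear-predictor pieces, invalidated only by the
        # block that owns them
        self.wlp = {
            k: (d.W @ st[f"ga{k}"][: self.q] if self.q else np.zeros(d.n))
            for k in (1, 2)
        }
        self.logh0T = {k: d.B_T @ st[f"phi{k}"] for k in (1, 2)}
        self.logh0n = {
            k: (d.B_nodes_flat @ st[f"phi{k}"]).reshape(d.nodes.shape)
            for k in (1, 2)
        }
        self.sv = {
            k: self._surv_vec(k, self.m1n, self.m1T, self.m2n, self.m2T)
            for k in (1, 2)
        }
        self.re1 = self._re_prior(self.b1, st["eta1"])
        self.re2 = self._re_prior(self.b2, st["eta2"]) if self.has2 else 0.0

    def _total_loglik(self):
        total = self.ll1 + self.ll2 + self.re1 + self.re2
        total += float(self.sv[1].sum() + self.sv[2].sum())
        for name in self.state:
            total += self._block_prior(name, self.state[name])
        return total

    # -- priors ------------------------------------------------------------
    def _block_prior(self, name, value):
        pr = self.pr
        if name.startswith("surv"):
            n_ga = self.q + self.n_alpha
            return float(
                -0.5 * np.sum((value[:n_ga] / pr.coef_scale) ** 2)
                - 0.5 * np.sum((value[n_ga:] / pr.spline_scale) ** 2)
            )
        if name.startswith(("beta", "xi", "ga")):
            # "beta2xi" concatenates beta2 and xi; the iid normal prior
            # factorises, so one expression covers all coefficient blocks
            return float(-0.5 * np.sum((value / pr.coef_scale) ** 2))
        if name.startswith("phi"):
            return float(-0.5 * np.sum((value / pr.spline_scale) ** 2))
        if name.startswith("log_sigma"):
            sigma = np.exp(value[0])
            return self._half_t(sigma) + value[0]
        if name.startswith("eta"):
            sd1, sd2 = np.exp(value[0]), np.exp(value[1])
            rho = np.tanh(value[2])
            lp = self._half_t(sd1) + value[0] + self._half_t(sd2) + value[1]
            # LKJ(eta) on rho plus the tanh Jacobian log(1 - rho^2)
            lp += self.pr.lkj_eta * np.log1p(-(rho**2))
            return float(lp)
        raise KeyError(name)

    def _half_t(self, sigma):
        df, scale = self.pr.sd_df, self.pr.sd_scale
        return float(-0.5 * (df + 1.0) * np.log1p((sigma / scale) ** 2 / df))

    # -- random-effects updates --------------------------------------------
    def _update_b1(self):
        d, st = self.d, self.state
        sig1sq = np.exp(2.0 * st["log_sigma1"][0])
        P0 = _inv2(_cov_from_eta(st["eta1"]))
        A = P0[None] + d.Z1tZ1 / sig1sq
        e1 = d.y1 - d.X1 @ st["beta1"]
        rhs = np.column_stack(
            [
                np.bincount(d.idx1, weights=d.Z1[:, 0] * e1, minlength=d.n),
                np.bincount(d.idx1, weights=d.Z1[:, 1] * e1, minlength=d.n),
            ]
        ) / sig1sq
        if self.has2:
            xi = st["xi"][0]
            sig2sq = np.exp(2.0 * st["log_sigma2"][0])
            A = A + (xi**2 / sig2sq) * d.Z1a2tZ1a2
            e2p = (
                d.y2
                - d.X2 @ st["beta2"]
                - np.sum(d.Z2 * self.b2[d.idx2], axis=1)
                - xi * (d.X1a2 @ st["beta1"])
            )
            rhs = rhs + (xi / sig2sq) * np.column_stack(
                [
                    np.bincount(d.idx2, weights=d.Z1a2[:, 0] * e2p, minlength=d.n),
                    np.bincount(d.idx2, weights=d.Z1a2[:, 1] * e2p, minlength=d.n),
                ]
            )
        V = _inv2(A)
        mu = np.einsum("nij,nj->ni", V, rhs)
        l11, l21, l22 = _chol2(V)
        eps = self.rng.standard_normal((d.n, 2))
        prop = mu + np.column_stack(
            [l11 * eps[:, 0], l21 * eps[:, 0] + l22 * eps[:, 1]]
        )

        fit1_p, m1n_p, m1T_p, m1a2_p = self._m1_pieces(st["beta1"], prop)
        if self.has2:
            xi = st["xi"][0]
            m2n_p = self.m2n + xi * (m1n_p - self.m1n)
            m2T_p = self.m2T + xi * (m1T_p - self.m1T)
        else:
            m2n_p = m2T_p = None
        sv_p = {
            k: self._surv_vec(
                k, m1n_p, m1T_p, m2n_p, m2T_p
            )
            for k in (1, 2)
        }
        delta_ll = (sv_p[1] + sv_p[2]) - (self.sv[1] + self.sv[2])
        delta_ll = np.where(np.isfinite(delta_ll), delta_ll, -np.inf)
        acc = np.log(self.rng.uniform(size=d.n)) < delta_ll

        self.b1 = np.where(acc[:, None], prop, self.b1)
        rows1 = acc[d.idx1]
        self.fit1 = np.where(rows1, fit1_p, self.fit1)
        self.r1 = d.y1 - self.fit1
        self.ssr1 = float(self.r1 @ self.r1)
        self.ll1 = self._gauss_ll(self.ssr1, d.y1.size, st["log_sigma1"][0])
        self.m1n = np.where(acc[:, None], m1n_p, self.m1n)
        self.m1T = np.where(acc, m1T_p, self.m1T)
        if self.has2:
            rows2 = acc[d.idx2]
            old_m1a2 = self.m1a2
            self.m1a2 = np.where(rows2, m1a2_p, self.m1a2)
            self.r2 = self.r2 - st["xi"][0] * (self.m1a2 - old_m1a2)
            self.ssr2 = float(self.r2 @ self.r2)
            self.ll2 = self._gauss_ll(
                self.ssr2, d.y2.size, st["log_sigma2"][0]
            )
            self.m2n = np.where(acc[:, None], m2n_p, self.m2n)
            self.m2T = np.where(acc, m2T_p, self.m2T)
        for k in (1, 2):
            self.sv[k] = np.where(acc, sv_p[k], self.sv[k])
        self.re1 = self._re_prior(self.b1, st["eta1"])
        return float(acc.mean())

    def _update_b2(self):
        if not self.has2:
            return 1.0
        d, st = self.d, self.state
        sig2sq = np.exp(2.0 * st["log_sigma2"][0])
        P0 = _inv2(_cov_from_eta(st["eta2"]))
        A = P0[None] + d.Z2tZ2 / sig2sq
        e2q = (
            d.y2 - d.X2 @ st["beta2"] - st["xi"][0] * self.m1a2
        )
        rhs = np.column_stack(
            [
                np.bincount(d.idx2, weights=d.Z2[:, 0] * e2q, minlength=d.n),
                np.bincount(d.idx2, weights=d.Z2[:, 1] * e2q, minlength=d.n),
            ]
        ) / sig2sq
        V = _inv2(A)
        mu = np.einsum("nij,nj->ni", V, rhs)
        l11, l21, l22 = _chol2(V)
        eps = self.rng.standard_normal((d.n, 2))
        prop = mu + np.column_stack(
            [l11 * eps[:, 0], l21 * eps[:, 0] + l22 * eps[:, 1]]
        )

        db = prop - self.b2
        m2n_p = self.m2n + db[:, 0, None] + db[:, 1, None] * d.nodes
        m2T_p = self.m2T + db[:, 0] + db[:, 1] * d.T
        sv_p = {
            k: self._surv_vec(
                k, self.m1n, self.m1T, m2n_p, m2T_p,
            )
            for k in (1, 2)
        }
        delta_ll = (sv_p[1] + sv_p[2]) - (self.sv[1] + self.sv[2])
        delta_ll = np.where(np.isfinite(delta_ll), delta_ll, -np.inf)
        acc = np.log(self.rng.uniform(size=d.n)) < delta_ll

        self.b2 = np.where(acc[:, None], prop, self.b2)
        rows2 = acc[d.idx2]
        db_rows = np.sum(d.Z2 * db[d.idx2], axis=1)
        self.r2 = np.where(rows2, self.r2 - db_rows, self.r2)
        self.ssr2 = float(self.r2 @ self.r2)
        self.ll2 = self._gauss_ll(self.ssr2, d.y2.size, st["log_sigma2"][0])
        self.m2n = np.where(acc[:, None], m2n_p, self.m2n)
        self.m2T = np.where(acc, m2T_p, self.m2T)
        for k in (1, 2):
            self.sv[k] = np.where(acc, sv_p[k], self.sv[k])
        self.re2 = self._re_prior(self.b2, st["eta2"])
        return float(acc.mean())

    # -- interweaved (non-centered) covariance moves -------------------------
    def _try_eta_nc(self, j, prop):
        """Joint move of (eta_j, b_j) keeping the whitened effects fixed.

        b' = L(eta') L(eta)^{-1} b; the random-effects prior and the Jacobian
        of the rescaling cancel exactly, so the acceptance ratio reduces to
        the data-likelihood ratio times the prior ratio on eta.  This
        interweaving breaks the funnel-shaped coupling between the
        random-effect scales and the effects themselves.
        """
        st, d = self.state, self.d
        name = f"eta{j}"
        cur = st[name]
        dprior = self._block_prior(name, prop) - self._block_prior(name, cur)

        def lower_chol(eta):
            S = _cov_from_eta(eta)
            return np.linalg.cholesky(S)

        L_cur = lower_chol(cur)
        L_new = lower_chol(prop)
        M = L_new @ np.linalg.inv(L_cur)

        if j == 1:
            b1p = self.b1 @ M.T
            fit1_p, m1n_p, m1T_p, m1a2_p = self._m1_pieces(st["beta1"], b1p)
            r1_p = d.y1 - fit1_p
            ssr1_p = float(r1_p @ r1_p)
            ll1_p = self._gauss_ll(ssr1_p, d.y1.size, st["log_sigma1"][0])
            if self.has2:
                xi = st["xi"][0]
                m2n_p = self.m2n + xi * (m1n_p - self.m1n)
                m2T_p = self.m2T + xi * (m1T_p - self.m1T)
                r2_p = self.r2 - xi * (m1a2_p - self.m1a2)
                ssr2_p = float(r2_p @ r2_p)
                ll2_p = self._gauss_ll(ssr2_p, d.y2.size, st["log_sigma2"][0])
            else:
                m2n_p = m2T_p = r2_p = None
                ssr2_p, ll2_p = 0.0, 0.0
            sv_p = {
                k: self._surv_vec(
                    k, m1n_p, m1T_p, m2n_p, m2T_p
                )
                for k in (1, 2)
            }
            delta = (
                dprior
                + (ll1_p - self.ll1)
                + (ll2_p - self.ll2)
                + float((sv_p[1] - self.sv[1]).sum())
                + float((sv_p[2] - self.sv[2]).sum())
            )

            def commit():
                st[name] = prop
                self.b1 = b1p
                self.fit1, self.m1n, self.m1T, self.m1a2 = (
                    fit1_p, m1n_p, m1T_p, m1a2_p,
                )
                self.r1, self.ssr1, self.ll1 = r1_p, ssr1_p, ll1_p
                if self.has2:
                    self.m2n, self.m2T = m2n_p, m2T_p
                    self.r2, self.ssr2, self.ll2 = r2_p, ssr2_p, ll2_p
                self.sv = sv_p
                self.re1 = self._re_prior(self.b1, prop)

            return delta, commit

        b2p = self.b2 @ M.T
        db = b2p - self.b2
        m2n_p = self.m2n + db[:, 0, None] + db[:, 1, None] * d.nodes
        m2T_p = self.m2T + db[:, 0] + db[:, 1] * d.T
        r2_p = self.r2 - np.sum(d.Z2 * db[d.idx2], axis=1)
        ssr2_p = float(r2_p @ r2_p)
        ll2_p = self._gauss_ll(ssr2_p, d.y2.size, st["log_sigma2"][0])
        sv_p = {
            k: self._surv_vec(
                k, self.m1n, self.m1T, m2n_p, m2T_p,
            )
            for k in (1, 2)
        }
        delta = (
            dprior
            + (ll2_p - self.ll2)
            + float((sv_p[1] - self.sv[1]).sum())
            + float((sv_p[2] - self.sv[2]).sum())
        )

        def commit():
            st[name] = prop
            self.b2 = b2p
            self.m2n, self.m2T = m2n_p, m2T_p
            self.r2, self.ssr2, self.ll2 = r2_p, ssr2_p, ll2_p
            self.sv = sv_p
            self.re2 = self._re_prior(self.b2, prop)

        return delta, commit

    # -- translation (ancillary) moves ---------------------------------------
    def _try_translation(self, name, delta):
        """Shift a location parameter and counter-shift the random effects.

        The fitted values — hence the whole data likelihood — are invariant,
        so acceptance involves only the random-effects prior and the
        parameter prior.  Together with the centered block updates this is an
        interweaving scheme for the location parameters, removing the slow
        random-walk behaviour along the flat fixed-effect/random-effect
        direction.
        """
        st, d = self.state, self.d
        if name == "tr_beta1":
            prop = st["beta1"] + delta
            shift = np.column_stack([d.A1 @ delta, d.C1 @ delta])
            b1p = self.b1 - shift
            re_p = self._re_prior(b1p, st["eta1"])
            dlt = (
                self._block_prior("beta1", prop)
                - self._block_prior("beta1", st["beta1"])
                + re_p
                - self.re1
            )

            def commit():
                st["beta1"] = prop
                self.b1 = b1p
                self.re1 = re_p

            return dlt, commit

        if name == "tr_beta2":
            prop = st["beta2"] + delta
            shift = np.column_stack([d.A2 @ delta, d.C2 @ delta])
            b2p = self.b2 - shift
            re_p = self._re_prior(b2p, st["eta2"])
            dlt = (
                self._block_prior("beta2", prop)
                - self._block_prior("beta2", st["beta2"])
                + re_p
                - self.re2
            )

            def commit():
                st["beta2"] = prop
                self.b2 = b2p
                self.re2 = re_p

            return dlt, commit

        if name == "tr_xi":
            # m2 gains delta*m1; absorb it into b2 via m1's per-subject
            # affine coefficients so m2 stays fixed
            dxi = float(delta[0])
            prop = st["xi"] + dxi
            u1 = d.A1 @ st["beta1"] + self.b1[:, 0]
            v1 = d.C1 @ st["beta1"] + self.b1[:, 1]
            b2p = self.b2 - dxi * np.column_stack([u1, v1])
            re_p = self._re_prior(b2p, st["eta2"])
            dlt = (
                self._block_prior("xi", prop)
                - self._block_prior("xi", st["xi"])
                + re_p
                - self.re2
            )

            def commit():
                st["xi"] = prop
                self.b2 = b2p
                self.re2 = re_p

            return dlt, commit

        raise KeyError(name)

    # -- structural block updates -------------------------------------------
    def _try_block(self, name, prop):
        """Return (delta log-posterior, cache-update callable) for a block."""
        st, d = self.state, self.d
        if name == "beta2xi":
            cur = np.concatenate([st["beta2"], st["xi"]])
        elif name.startswith("surv"):
            k = name[-1]
            cur = np.concatenate([st[f"ga{k}"], st[f"phi{k}"]])
        else:
            cur = st[name]
        dprior = self._block_prior(name, prop) - self._block_prior(name, cur)

        if name == "beta1":
            fit1_p, m1n_p, m1T_p, m1a2_p = self._m1_pieces(prop, self.b1)
            r1_p = d.y1 - fit1_p
            ssr1_p = float(r1_p @ r1_p)
            ll1_p = self._gauss_ll(ssr1_p, d.y1.size, st["log_sigma1"][0])
            if self.has2:
                xi = st["xi"][0]
                m2n_p = self.m2n + xi * (m1n_p - self.m1n)
                m2T_p = self.m2T + xi * (m1T_p - self.m1T)
                r2_p = self.r2 - xi * (m1a2_p - self.m1a2)
                ssr2_p = float(r2_p @ r2_p)
                ll2_p = self._gauss_ll(ssr2_p, d.y2.size, st["log_sigma2"][0])
            else:
                m2n_p = m2T_p = r2_p = None
                ssr2_p, ll2_p = 0.0, 0.0
            sv_p = {
                k: self._surv_vec(
                    k, m1n_p, m1T_p, m2n_p, m2T_p
                )
                for k in (1, 2)
            }
            delta = (
                dprior
                + (ll1_p - self.ll1)
                + (ll2_p - self.ll2)
                + float((sv_p[1] - self.sv[1]).sum())
                + float((sv_p[2] - self.sv[2]).sum())
            )

            def commit():
                self.fit1, self.m1n, self.m1T, self.m1a2 = (
                    fit1_p, m1n_p, m1T_p, m1a2_p,
                )
                self.r1, self.ssr1, self.ll1 = r1_p, ssr1_p, ll1_p
                if self.has2:
                    self.m2n, self.m2T = m2n_p, m2T_p
                    self.r2, self.ssr2, self.ll2 = r2_p, ssr2_p, ll2_p
                self.sv = sv_p

            return delta, commit

        if name == "beta2xi":
            beta2_p, xi_p = prop[:-1], prop[-1]
            m2n_p, m2T_p = self._m2_pieces(
                beta2_p, xi_p, self.b2, self.m1n, self.m1T
            )
            r2_p = (
                d.y2
                - d.X2 @ beta2_p
                - np.sum(d.Z2 * self.b2[d.idx2], axis=1)
                - xi_p * self.m1a2
            )
            ssr2_p = float(r2_p @ r2_p)
            ll2_p = self._gauss_ll(ssr2_p, d.y2.size, st["log_sigma2"][0])
            sv_p = {
                k: self._surv_vec(
                    k, self.m1n, self.m1T, m2n_p, m2T_p,
                )
                for k in (1, 2)
            }
            delta = (
                dprior
                + (ll2_p - self.ll2)
                + float((sv_p[1] - self.sv[1]).sum())
                + float((sv_p[2] - self.sv[2]).sum())
            )

            def commit():
                st["beta2"], st["xi"] = beta2_p, np.array([xi_p])
                self.m2n, self.m2T = m2n_p, m2T_p
                self.r2, self.ssr2, self.ll2 = r2_p, ssr2_p, ll2_p
                self.sv = sv_p

            return delta, commit

        if name == "log_sigma1":
            ll1_p = self._gauss_ll(self.ssr1, d.y1.size, prop[0])
            delta = dprior + (ll1_p - self.ll1)

            def commit():
                self.ll1 = ll1_p

            return delta, commit

        if name == "log_sigma2":
            ll2_p = self._gauss_ll(self.ssr2, d.y2.size, prop[0])
            delta = dprior + (ll2_p - self.ll2)

            def commit():
                self.ll2 = ll2_p

            return delta, commit

        if name == "eta1":
            re_p = self._re_prior(self.b1, prop)
            delta = dprior + (re_p - self.re1)

            def commit():
                self.re1 = re_p

            return delta, commit

        if name == "eta2":
            re_p = self._re_prior(self.b2, prop)
            delta = dprior + (re_p - self.re2)

            def commit():
                self.re2 = re_p

            return delta, commit

        if name in ("surv1", "surv2"):
            # one joint block per risk: (gamma_k, alpha_k, phi_k).  The
            # association parameters and the baseline level are strongly
            # correlated a posteriori; updating them jointly with a learned
            # proposal covariance avoids the zigzag of separate blocks.
            k = int(name[-1])
            n_ga = self.q + self.n_alpha
            ga_p, phi_p = prop[:n_ga], prop[n_ga:]
            sv_p = self._surv_vec(
                k, self.m1n, self.m1T, self.m2n, self.m2T,
                ga=ga_p, phi=phi_p,
            )
            delta = dprior + float((sv_p - self.sv[k]).sum())

            def commit():
                st[f"ga{k}"], st[f"phi{k}"] = ga_p, phi_p
                self.sv[k] = sv_p
                self.wlp[k] = (
                    d.W @ ga_p[: self.q] if self.q else np.zeros(d.n)
                )
                self.logh0T[k] = d.B_T @ phi_p
                self.logh0n[k] = (d.B_nodes_flat @ phi_p).reshape(
                    d.nodes.shape
                )

            return delta, commit

        raise KeyError(name)

    def run(self, n_iterations, n_burnin, thinning, record):
        st = self.state
        block_names = ["beta1"]
        if self.has2:
            block_names.append("beta2xi")
        block_names += ["log_sigma1"]
        if self.has2:
            block_names.append("log_sigma2")
        block_names += ["eta1"]
        if self.has2:
            block_names.append("eta2")
        block_names += ["surv1", "surv2"]

        def block_value(name):
            if name == "beta2xi":
                return np.concatenate([st["beta2"], st["xi"]])
            if name.startswith("surv"):
                k = name[-1]
                return np.concatenate([st[f"ga{k}"], st[f"phi{k}"]])
            return st[name]

        init_scales = {
            "beta1": 0.02, "beta2xi": 0.02, "log_sigma1": 0.02,
            "log_sigma2": 0.02, "eta1": 0.08, "eta2": 0.08,
            "surv1": 0.08, "surv2": 0.08,
        }
        blocks = {
            name: _AdaptiveBlock(
                name, init_scales[name], block_value(name).size
            )
            for name in block_names
        }
        # extra within-sweep repeats for the slowest-mixing blocks
        repeats = {"surv1": 3, "surv2": 3, "beta2xi": 3}
        self_setting = {"beta2xi", "surv1", "surv2"}  # commit sets state

        nc_blocks = {1: _AdaptiveBlock("nceta1", 0.08, 3)}
        if self.has2:
            nc_blocks[2] = _AdaptiveBlock("nceta2", 0.08, 3)

        trans_names = ["tr_beta1"]
        if self.has2:
            trans_names += ["tr_beta2", "tr_xi"]
        trans_dims = {
            "tr_beta1": st["beta1"].size,
            "tr_beta2": st["beta2"].size if self.has2 else 0,
            "tr_xi": 1,
        }
        trans_blocks = {
            name: _AdaptiveBlock(name, 0.05, trans_dims[name])
            for name in trans_names
        }

        def trans_value(name):
            if name == "tr_beta1":
                return st["beta1"]
            if name == "tr_beta2":
                return st["beta2"]
            return st["xi"]

        for it in range(n_iterations):
            self._update_b1()
            self._update_b2()
            for name in block_names:
                for _ in range(repeats.get(name, 1)):
                    cur = block_value(name)
                    prop = blocks[name].propose(cur, self.rng)
                    delta, commit = self._try_block(name, prop)
                    ok = np.isfinite(delta) and (
                        delta >= 0 or np.log(self.rng.uniform()) < delta
                    )
                    if ok:
                        if name not in self_setting:
                            st[name] = prop
                        commit()
                    blocks[name].adapt(block_value(name), ok, it, n_burnin)
            for name in trans_names:
                block = trans_blocks[name]
                delta_step = block.propose(
                    np.zeros(block.dim), self.rng
                )
                dlt, commit = self._try_translation(name, delta_step)
                ok = np.isfinite(dlt) and (
                    dlt >= 0 or np.log(self.rng.uniform()) < dlt
                )
                if ok:
                    commit()
                block.adapt(trans_value(name).copy(), ok, it, n_burnin)
            for j, block in nc_blocks.items():
                cur = st[f"eta{j}"]
                prop = block.propose(cur, self.rng)
                delta, commit = self._try_eta_nc(j, prop)
                ok = np.isfinite(delta) and (
                    delta >= 0 or np.log(self.rng.uniform()) < delta
                )
                if ok:
                    commit()
                block.adapt(st[f"eta{j}"], ok, it, n_burnin)
            if it >= n_burnin and (it - n_burnin) % thinning == 0:
                record(self)


# --------------------------------------------------------------------------
# public fitting API
# --------------------------------------------------------------------------


def _param_names(data: _ModelData) -> list[str]:
    spec = data.spec
    names = [f"beta1[{t}]" for t in spec.long1.fixed_terms]
    if spec.has_outcome2:
        names += [f"beta2[{t}]" for t in spec.long2.fixed_terms]
        names += ["xi"]
    names += ["sigma1"]
    if spec.has_outcome2:
        names += ["sigma2"]
    names += ["sd_b1[intercept]", "sd_b1[slope]", "cor_b1"]
    if spec.has_outcome2:
        names += ["sd_b2[intercept]", "sd_b2[slope]", "cor_b2"]
    for k in (1, 2):
        names += [f"gamma{k}[{t}]" for t in spec.survival_terms]
        names += [f"alpha_{k}1"]
        if spec.has_outcome2:
            names += [f"alpha_{k}2"]
    for k in (1, 2):
        names += [f"phi{k}[{s}]" for s in range(data.n_basis)]
    return names


def _record_vector(s: _Sampler) -> np.ndarray:
    st = s.state
    parts = [st["beta1"]]
    if s.has2:
        parts += [st["beta2"], st["xi"]]
    parts += [np.exp(st["log_sigma1"])]
    if s.has2:
        parts += [np.exp(st["log_sigma2"])]
    e = st["eta1"]
    parts += [np.array([np.exp(e[0]), np.exp(e[1]), np.tanh(e[2])])]
    if s.has2:
        e = st["eta2"]
        parts += [np.array([np.exp(e[0]), np.exp(e[1]), np.tanh(e[2])])]
    for k in (1, 2):
        parts += [st[f"ga{k}"]]
    for k in (1, 2):
        parts += [st[f"phi{k}"]]
    return np.concatenate(parts)


def fit(
    dataset: list[SubjectRecord],
    model_config: ModelSpec,
    priors: PriorSpec | None = None,
    mcmc: McmcConfig | None = None,
    n_interior_knots: int = 5,
    quad_order: int = QUADRATURE_ORDER,
) -> PosteriorDraws:
    """Sample the posterior of the full multivariate competing-risk model.

    Returns draws of every structural parameter (fixed effects of both
    longitudinal submodels, xi, error SDs, random-effect SDs/correlations,
    survival coefficients gamma, association matrix alpha, and both risks'
    baseline-spline coefficients).  Random effects are marginalised by
    sampling; they are not retained.
    """
    priors = priors or PriorSpec()
    mcmc = mcmc or McmcConfig()
    data = _ModelData(
        dataset, model_config, n_interior_knots=n_interior_knots,
        quad_order=quad_order,
    )
    names = _param_names(data)
    n_keep = (mcmc.n_iterations - mcmc.n_burnin + mcmc.thinning - 1) // mcmc.thinning
    out = np.empty((mcmc.n_chains, n_keep, len(names)))
    seed_seq = np.random.SeedSequence(mcmc.seed)
    for c, child in enumerate(seed_seq.spawn(mcmc.n_chains)):
        rng = np.random.default_rng(child)
        sampler = _Sampler(data, priors, rng)
        kept = []
        sampler.run(
            mcmc.n_iterations, mcmc.n_burnin, mcmc.thinning,
            lambda s: kept.append(_record_vector(s)),
        )
        out[c] = np.asarray(kept)
    draws = {name: out[:, :, j].copy() for j, name in enumerate(names)}
    meta = {
        "long1_terms": list(model_config.long1.fixed_terms),
        "long2_terms": (
            list(model_config.long2.fixed_terms)
            if model_config.has_outcome2
            else None
        ),
        "survival_terms": list(model_config.survival_terms),
        "has_outcome2": model_config.has_outcome2,
        "baseline_degree": data.baseline_template.degree,
        "baseline_boundary": list(data.baseline_template.boundary_knots),
        "baseline_interior": list(data.baseline_template.interior_knots),
        "n_subjects": data.n,
        "seed": mcmc.seed,
        "n_chains": mcmc.n_chains,
        "n_iterations": mcmc.n_iterations,
        "n_burnin": mcmc.n_burnin,
    }
    return PosteriorDraws(draws=draws, meta=meta)


def fit_univariate(
    dataset: list[SubjectRecord],
    model_config: ModelSpec,
    priors: PriorSpec | None = None,
    mcmc: McmcConfig | None = None,
    **kwargs,
) -> PosteriorDraws:
    """Fit the restricted model that ignores the second longitudinal outcome.

    Identical to :func:`fit` with outcome 2, xi and the alpha_k2 associations
    removed — the misspecified comparator of the second simulation study.
    """
    restricted = ModelSpec(
        long1=model_config.long1, long2=None,
        survival_terms=model_config.survival_terms,
    )
    stripped = [
        SubjectRecord(
            subject_id=s.subject_id,
            intervention=s.intervention,
            baseline_covariates=s.baseline_covariates,
            series_1=s.series_1,
            series_2=[],
            observed_time=s.observed_time,
            event=s.event,
        )
        for s in dataset
    ]
    return fit(stripped, restricted, priors=priors, mcmc=mcmc, **kwargs)
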