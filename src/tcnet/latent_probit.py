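"""Dyadic probit GLMM with crossed random effects and a latent factor term.

Model
-----
For an ordered dyad (i, j) on day t,

    P(tie) = Phi(eta),   eta = x' beta + a_i + b_j + c_t + m(i, j)

with sender effects a ~ N(0, sigma_a^2), receiver effects b ~ N(0,
sigma_b^2), day effects c ~ N(0, sigma_c^2), and a latent factor term
m(i, j) = u_i . v_j (multiplicative, default) or -||u_i - u_j|| (distance)
absorbing residual dyadic dependence beyond the covariates.

Estimation is by Gibbs sampling with truncated-normal data augmentation of
the probit outcomes: conditional updates of the augmented outcomes, beta,
the three random-effect sets, the latent positions, and inverse-gamma
updates of the variance components are all in closed form (the distance
form updates positions by random-walk Metropolis).  Sender, receiver, and
day effects are re-centred each sweep, their means folded into the
intercept, so the intercept stays interpretable as the baseline tie
propensity.  Latent positions are reported only through
rotation/translation-invariant summaries, never as raw coordinates.

Priors (weakly informative, conjugate): beta ~ N(0, 5^2) iid; variance
components ~ Inverse-Gamma(2, 1); latent positions ~ N(0, I).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import ndtr, ndtri

from .covariates import REPORT_LABELS, VARIANCE_LABELS, VARIANCE_NAMES
from .event_data import ValidationError

MULTIPLICATIVE = "multiplicative"
DISTANCE = "distance"


@dataclass
class ModelSpec:
    """Covariate list, latent-term configuration, priors, and MCMC settings."""

    covariates: Sequence[str]
    latent_dim: int = 2
    latent_form: str = MULTIPLICATIVE
    prior_beta_sd: float = 5.0
    prior_var_shape: float = 2.0
    prior_var_rate: float = 1.0
    latent_prior_sd: float = 1.0
    fixed_re_variance: float | None = None  # pin all three variance components
    iterations: int = 1500
    burn_in: int = 500
    thinning: int = 2
    chains: int = 1
    seed: int = 0
    mh_step: float = 0.15  # proposal sd for distance-form position updates

    def __post_init__(self):
        self.covariates = list(self.covariates)
        if self.latent_dim < 0:
            raise ValidationError("latent_dim must be >= 0")
        if self.latent_form not in (MULTIPLICATIVE, DISTANCE):
            raise ValidationError(f"unknown latent_form {self.latent_form!r}")
        if self.chains < 1:
            raise ValidationError("need at least one chain")
        if self.burn_in >= self.iterations:
            raise ValidationError("burn_in must be smaller than iterations")


@dataclass
class ModelState:
    """One full set of model parameters (used for prediction and simulation)."""

    beta: dict[str, float]
    a: dict = field(default_factory=dict)  # sender effects by actor
    b: dict = field(default_factory=dict)  # receiver effects by actor
    c: dict = field(default_factory=dict)  # day effects by day
    U: dict = field(default_factory=dict)  # latent positions (rows) by actor
    V: dict = field(default_factory=dict)
    latent_form: str = MULTIPLICATIVE


def latent_term(state: ModelState, i, j) -> float:
    if state.latent_form == MULTIPLICATIVE:
        u = np.asarray(state.U.get(i, 0.0))
        v = np.asarray(state.V.get(j, 0.0))
        return float(np.sum(u * v))
    u = np.asarray(state.U.get(i, 0.0))
    v = np.asarray(state.U.get(j, 0.0))
    return -float(np.linalg.norm(u - v))


def linear_predictor(state: ModelState, row, i, j, t) -> float:
    """eta = x'beta + a_i + b_j + c_t + latent term, from named covariates."""
    eta = sum(coef * float(row[name]) for name, coef in state.beta.items())
    eta += float(state.a.get(i, 0.0)) + float(state.b.get(j, 0.0)) + float(state.c.get(t, 0.0))
    eta += latent_term(state, i, j)
    return eta


def predict_prob(state: ModelState, row, i, j, t) -> float:
    """Posterior-predictive tie probability Phi(eta) for one dyad-day."""
    return float(ndtr(linear_predictor(state, row, i, j, t)))


@dataclass
class PosteriorDraws:
    """Retained post-burn-in draws: (chains, draws, ...) arrays."""

    beta: np.ndarray  # (chains, draws, p)
    sigma2: np.ndarray  # (chains, draws, 3): sender, receiver, day
    covariates: list[str]
    spec: ModelSpec
    n_obs: int

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    def stacked_beta(self) -> np.ndarray:
        return self.beta.reshape(-1, self.beta.shape[-1])

    def stacked_sigma2(self) -> np.ndarray:
        return self.sigma2.reshape(-1, 3)


def _sample_truncated_normal(rng, eta, y):
    """z ~ N(eta, 1) truncated to (0, inf) where y, (-inf, 0] otherwise."""
    u = rng.random(eta.shape[0])
    F0 = ndtr(-eta)  # mass below zero
    arg = np.where(y, F0 + u * (1.0 - F0), u * F0)
    return eta + ndtri(np.clip(arg, 1e-16, 1.0 - 1e-16))


def _draw_invgamma(rng, shape, rate):
    return rate / rng.gamma(shape)


def fit(design: pd.DataFrame, spec: ModelSpec, outcome_col: str = "tie") -> PosteriorDraws:
    """Gibbs sampler for the latent-factor probit GLMM.

    ``design`` needs columns sender, receiver, day, the outcome, and every
    covariate named in ``spec.covariates``.  Fully reproducible given
    ``spec.seed``; refuses degenerate outcomes (all zero or all one).
    """
    for c in spec.covariates:
        if c not in design.columns:
            raise ValidationError(f"design is missing covariate column {c!r}")
    X = design[list(spec.covariates)].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValidationError("non-finite covariate values in design")
    y = design[outcome_col].to_numpy().astype(bool)
    if y.all() or not y.any():
        raise ValidationError(
            "outcomes are all-zero or all-one; the probit intercept is not identified"
        )
    actors = np.unique(np.concatenate([design["sender"].to_numpy(), design["receiver"].to_numpy()]))
    amap = {aid: k for k, aid in enumerate(actors)}
    s_code = design["sender"].map(amap).to_numpy()
    r_code = design["receiver"].map(amap).to_numpy()
    days = np.unique(design["day"].to_numpy())
    dmap = {d: k for k, d in enumerate(days)}
    d_code = design["day"].map(dmap).to_numpy()

    chains_beta, chains_sig = [], []
    for chain in range(spec.chains):
        rng = np.random.default_rng([int(spec.seed), chain])
        b_draws, s_draws = _run_chain(rng, X, y, s_code, r_code, d_code, len(actors), len(days), spec)
        chains_beta.append(b_draws)
        chains_sig.append(s_draws)
    return PosteriorDraws(
        beta=np.stack(chains_beta),
        sigma2=np.stack(chains_sig),
        covariates=list(spec.covariates),
        spec=spec,
        n_obs=len(y),
    )


def _run_chain(rng, X, y, s_code, r_code, d_code, R, D, spec: ModelSpec):
    n, p = X.shape
    d = spec.latent_dim
    icpt = spec.covariates.index("intercept") if "intercept" in spec.covariates else None

    prior_prec = 1.0 / spec.prior_beta_sd**2
    A = X.T @ X + prior_prec * np.eye(p)
    cho = cho_factor(A)
    L = np.linalg.cholesky(A)

    n_s = np.bincount(s_code, minlength=R).astype(float)
    n_r = np.bincount(r_code, minlength=R).astype(float)
    n_d = np.bincount(d_code, minlength=D).astype(float)
    rows_by_sender = [np.flatnonzero(s_code == i) for i in range(R)]
    rows_by_receiver = [np.flatnonzero(r_code == i) for i in range(R)]

    beta = np.zeros(p)
    a = np.zeros(R)
    b = np.zeros(R)
    c = np.zeros(D)
    fixed = spec.fixed_re_variance
    s2 = np.full(3, fixed if fixed is not None else 0.5)
    if d > 0:
        U = 0.1 * rng.standard_normal((R, d))
        V = 0.1 * rng.standard_normal((R, d)) if spec.latent_form == MULTIPLICATIVE else None
    lat = np.zeros(n)

    keep = max((spec.iterations - spec.burn_in) // spec.thinning, 0)
    beta_out = np.empty((keep, p))
    sig_out = np.empty((keep, 3))
    kept = 0

    lam_prior = 1.0 / spec.latent_prior_sd**2

    for it in range(spec.iterations):
        if d > 0:
            if spec.latent_form == MULTIPLICATIVE:
                lat = np.einsum("ij,ij->i", U[s_code], V[r_code])
            else:
                lat = -np.linalg.norm(U[s_code] - U[r_code], axis=1)
        eta = X @ beta + a[s_code] + b[r_code] + c[d_code] + lat
        z = _sample_truncated_normal(rng, eta, y)

        re_part = a[s_code] + b[r_code] + c[d_code] + lat
        mean_beta = cho_solve(cho, X.T @ (z - re_part))
        beta = mean_beta + solve_triangular(L.T, rng.standard_normal(p), lower=False)
        xb = X @ beta

        # sender effects
        resid = z - xb - b[r_code] - c[d_code] - lat
        prec = n_s + 1.0 / s2[0]
        a = np.bincount(s_code, weights=resid, minlength=R) / prec
        a += rng.standard_normal(R) / np.sqrt(prec)
        # receiver effects
        resid = z - xb - a[s_code] - c[d_code] - lat
        prec = n_r + 1.0 / s2[1]
        b = np.bincount(r_code, weights=resid, minlength=R) / prec
        b += rng.standard_normal(R) / np.sqrt(prec)
        # day effects
        resid = z - xb - a[s_code] - b[r_code] - lat
        prec = n_d + 1.0 / s2[2]
        c = np.bincount(d_code, weights=resid, minlength=D) / prec
        c += rng.standard_normal(D) / np.sqrt(prec)

        # re-centre; fold means into the intercept so eta is unchanged
        if icpt is not None:
            for v in (a, b, c):
                m = v.mean()
                v -= m
                beta[icpt] += m
            xb = X @ beta

        if fixed is None:
            s2[0] = _draw_invgamma(rng, spec.prior_var_shape + R / 2, spec.prior_var_rate + 0.5 * a @ a)
            s2[1] = _draw_invgamma(rng, spec.prior_var_shape + R / 2, spec.prior_var_rate + 0.5 * b @ b)
            s2[2] = _draw_invgamma(rng, spec.prior_var_shape + D / 2, spec.prior_var_rate + 0.5 * c @ c)

        if d > 0:
            resid_all = z - xb - a[s_code] - b[r_code] - c[d_code]
            if spec.latent_form == MULTIPLICATIVE:
                for i in range(R):
                    rows = rows_by_sender[i]
                    if len(rows):
                        Vi = V[r_code[rows]]
                        Ai = Vi.T @ Vi + lam_prior * np.eye(d)
                        Li = np.linalg.cholesky(Ai)
                        mu = cho_solve((Li, True), Vi.T @ resid_all[rows])
                        U[i] = mu + solve_triangular(Li.T, rng.standard_normal(d), lower=False)
                    else:
                        U[i] = spec.latent_prior_sd * rng.standard_normal(d)
                for j in range(R):
                    rows = rows_by_receiver[j]
                    if len(rows):
                        Uj = U[s_code[rows]]
                        Aj = Uj.T @ Uj + lam_prior * np.eye(d)
                        Lj = np.linalg.cholesky(Aj)
                        mu = cho_solve((Lj, True), Uj.T @ resid_all[rows])
                        V[j] = mu + solve_triangular(Lj.T, rng.standard_normal(d), lower=False)
                    else:
                        V[j] = spec.latent_prior_sd * rng.standard_normal(d)
            else:
                _mh_distance_update(rng, U, resid_all, s_code, r_code,
                                    rows_by_sender, rows_by_receiver, spec, lam_prior)

        if it >= spec.burn_in and (it - spec.burn_in) % spec.thinning == 0 and kept < keep:
            beta_out[kept] = beta
            sig_out[kept] = s2
            kept += 1
    return beta_out[:kept], sig_out[:kept]


def _mh_distance_update(rng, U, resid, s_code, r_code, rows_s, rows_r, spec, lam_prior):
    """Random-walk Metropolis on each actor's position (distance form)."""
    R, d = U.shape
    for i in range(R):
        rows = np.concatenate([rows_s[i], rows_r[i]])
        prop = U[i] + spec.mh_step * rng.standard_normal(d)
        if len(rows):
            other = np.where(s_code[rows] == i, r_code[rows], s_code[rows])
            cur_m = -np.linalg.norm(U[i] - U[other], axis=1)
            new_m = -np.linalg.norm(prop - U[other], axis=1)
            ll_cur = -0.5 * np.sum((resid[rows] - cur_m) ** 2)
            ll_new = -0.5 * np.sum((resid[rows] - new_m) ** 2)
        else:
            ll_cur = ll_new = 0.0
        lp = ll_new - ll_cur - 0.5 * lam_prior * (prop @ prop - U[i] @ U[i])
        if np.log(rng.random()) < lp:
            U[i] = prop


def summarize(draws: PosteriorDraws, min_draws: int = 100) -> pd.DataFrame:
    """Posterior summary table: mean, equal-tailed 95% interval, sig flag.

    Rows follow the covariate order of the fit, then the three variance
    components (on the variance scale).  ``sig`` marks intervals excluding
    zero (variance components are positive by construction, so their flag
    reads as "distinguishable from zero" trivially).
    """
    if draws.n_draws < min_draws:
        raise ValidationError(
            f"only {draws.n_draws} retained draws; need at least {min_draws} to summarise"
        )
    rows = []
    B = draws.stacked_beta()
    for k, name in enumerate(draws.covariates):
        lo, hi = np.quantile(B[:, k], [0.025, 0.975])
        rows.append((name, REPORT_LABELS.get(name, name), B[:, k].mean(), lo, hi))
    S = draws.stacked_sigma2()
    for k, name in enumerate(VARIANCE_NAMES):
        lo, hi = np.quantile(S[:, k], [0.025, 0.975])
        rows.append((name, VARIANCE_LABELS[name], S[:, k].mean(), lo, hi))
    df = pd.DataFrame(rows, columns=["variable", "label", "mean", "lower", "upper"])
    df["sig"] = (df["lower"] > 0) | (df["upper"] < 0)
    return df


def diagnostics(draws: PosteriorDraws, rhat_warn: float = 1.05, ess_warn: float = 100.0) -> pd.DataFrame:
    """Split-chain potential-scale-reduction (R-hat) and effective sample size."""
    import arviz as az

    names = list(draws.covariates) + VARIANCE_NAMES
    arr = np.concatenate([draws.beta, draws.sigma2], axis=2)
    idata = az.from_dict(posterior={"param": arr})
    rhat = np.atleast_1d(az.rhat(idata)["param"].to_numpy())
    ess = np.atleast_1d(az.ess(idata)["param"].to_numpy())
    df = pd.DataFrame({"variable": names, "rhat": rhat, "ess": ess})
    bad = df[(df["rhat"] > rhat_warn) | (df["ess"] < ess_warn)]
    if len(bad):
        warnings.warn(
            "possible non-convergence for: " + ", ".join(bad["variable"]), stacklevel=2
        )
    return df
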