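"""Beta-Binomial observation model and null-model fits.

The observation model for maternal counts ``a_i`` out of totals ``d_i`` is

    a_i | mu_i, d_i ~ BetaBinom(mu_i / theta, (1 - mu_i) / theta)

with mean rate ``mu_i = sigmoid(eta_i)`` on a logit linear predictor
``eta_i = logit(r_base) + alpha + x_iᵀ beta`` and overdispersion ``theta``
capturing extra-binomial variance.  Null models (no cell-state random effect)
are fitted by Fisher scoring: Newton updates for the regression coefficients
alternated with safeguarded Newton steps for ``log theta``, with step-halving
on the exact log-likelihood so it is non-decreasing across iterations.

Everything is implemented batched over regions: ``a``/``d`` may be
``(n_regions, n_cells)`` arrays sharing one design matrix, which is what makes
genome-scale testing and parametric bootstraps cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, expit, gammaln, logit

THETA_MIN = 1e-8
THETA_MAX = 1e3
_MU_EPS = 1e-12


@dataclass
class NullModelSpec:
    """Specification of a Beta-Binomial null model.

    ``base_rate`` is the expected allelic rate absent any imbalance (0.5 for
    autosomes in a diploid).  ``free_intercept`` controls whether the
    homogeneous imbalance ``alpha`` is estimated (heterogeneity-test null) or
    pinned to zero (homogeneous/joint-test nulls).
    """

    base_rate: float = 0.5
    free_intercept: bool = True
    covariates: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.base_rate < 1.0:
            raise ValueError("base_rate must lie in (0, 1)")
        if self.covariates is not None:
            X = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if X.size == 0:
                X = None
            self.covariates = X

    def design(self, n_cells: int) -> np.ndarray:
        """Null design matrix Z (intercept column first if free)."""
        cols = []
        if self.free_intercept:
            cols.append(np.ones((n_cells, 1)))
        if self.covariates is not None:
            if self.covariates.shape[0] != n_cells:
                raise ValueError("covariate rows must match cells")
            cols.append(self.covariates)
        if not cols:
            return np.zeros((n_cells, 0))
        return np.hstack(cols)


@dataclass
class NullFit:
    """A fitted Beta-Binomial null model for one region."""

    alpha_hat: float | None
    beta_hat: np.ndarray
    theta_hat: float
    mu_hat: np.ndarray
    score_residuals: np.ndarray
    info: np.ndarray
    converged: bool
    n_iter: int
    spec: NullModelSpec = field(repr=False, default=None)
    mask: np.ndarray = field(repr=False, default=None)
    eta: np.ndarray = field(repr=False, default=None)
    loglik: float = np.nan

    def to_dict(self) -> dict:
        """JSON-serialisable record of the fitted parameters."""
        return {
            "alpha_hat": None if self.alpha_hat is None else float(self.alpha_hat),
            "beta_hat": [float(b) for b in np.atleast_1d(self.beta_hat)],
            "theta_hat": float(self.theta_hat),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "n_observed": int(self.mask.sum()) if self.mask is not None else None,
        }


def _validate_counts(a, d):
    a = np.asarray(a)
    d = np.asarray(d)
    if np.any(a < 0) or np.any(d < 0) or np.any(a > d):
        raise ValueError("counts must satisfy 0 <= a <= d")
    if np.any(a != np.floor(a)) or np.any(d != np.floor(d)):
        raise ValueError("counts must be integer-valued")
    return a.astype(float), d.astype(float)


def betabinom_logpmf(a, d, mu, theta):
    """Log pmf of BetaBinom(d; mu/theta, (1-mu)/theta).

    The shape parameterisation keeps the mean at ``mu`` for any overdispersion
    ``theta``; as ``theta -> 0`` the pmf converges to Binomial(d, mu).
    """
    a, d = _validate_counts(a, d)
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(mu <= 0.0) or np.any(mu >= 1.0):
        raise ValueError("mu must lie in (0, 1)")
    if np.any(theta <= 0.0):
        raise ValueError("theta must be positive")
    a, d, mu, theta = np.broadcast_arrays(a, d, mu, theta)
    small = theta < 1e-7
    out = np.where(small, _binom_logpmf(a, d, mu), _bb_logpmf_raw(a, d, mu, np.maximum(theta, 1e-7)))
    if out.ndim == 0:
        return float(out)
    return out


def _binom_logpmf(a, d, mu):
    return (
        gammaln(d + 1.0)
        - gammaln(a + 1.0)
        - gammaln(d - a + 1.0)
        + a * np.log(mu)
        + (d - a) * np.log1p(-mu)
    )


def _bb_logpmf_raw(a, d, mu, theta):
    A = mu / theta
    B = (1.0 - mu) / theta
    N = 1.0 / theta
    return (
        gammaln(d + 1.0)
        - gammaln(a + 1.0)
        - gammaln(d - a + 1.0)
        + gammaln(a + A)
        - gammaln(A)
        + gammaln(d - a + B)
        - gammaln(B)
        - gammaln(d + N)
        + gammaln(N)
    )


def _loglik_rows(a, d, mu, theta, mask, include_const=True):
    """Summed Beta-Binomial log-likelihood per region row.

    ``include_const=False`` drops the parameter-free binomial coefficient,
    which is sufficient (and cheaper) inside the optimisation loop.
    """
    mu = np.clip(mu, _MU_EPS, 1.0 - _MU_EPS)
    th = np.broadcast_to(np.asarray(theta, dtype=float)[..., None], a.shape)
    ths = np.maximum(th, 1e-7)
    A = mu / ths
    B = (1.0 - mu) / ths
    N = 1.0 / ths
    core_bb = (
        gammaln(a + A) - gammaln(A) + gammaln(d - a + B) - gammaln(B)
        - gammaln(d + N) + gammaln(N)
    )
    core_bin = a * np.log(mu) + (d - a) * np.log1p(-mu)
    ll = np.where(th < 1e-7, core_bin, core_bb)
    if include_const:
        ll = ll + gammaln(d + 1.0) - gammaln(a + 1.0) - gammaln(d - a + 1.0)
    return np.where(mask, ll, 0.0).sum(axis=-1)


def score_eta(a, d, mu, theta):
    """Exact score of the Beta-Binomial log-likelihood w.r.t. the linear predictor.

    In the Binomial limit (theta -> 0) this reduces to the working residual
    ``a - d * mu``.
    """
    mu = np.clip(mu, _MU_EPS, 1.0 - _MU_EPS)
    th = np.asarray(theta, dtype=float)
    if th.ndim and th.shape != np.shape(mu):
        th = np.broadcast_to(th[..., None], np.shape(mu))
    small = th < 1e-7
    ths = np.maximum(th, 1e-7)
    A = mu / ths
    B = (1.0 - mu) / ths
    bracket = digamma(a + A) - digamma(A) - digamma(d - a + B) + digamma(B)
    exact = mu * (1.0 - mu) / ths * bracket
    return np.where(small, a - d * mu, exact)


def _dll_dtheta(a, d, mu, theta):
    """Per-cell derivative of the log-likelihood w.r.t. theta."""
    mu = np.clip(mu, _MU_EPS, 1.0 - _MU_EPS)
    th = np.asarray(theta, dtype=float)
    if th.ndim and th.shape != np.shape(mu):
        th = np.broadcast_to(th[..., None], np.shape(mu))
    th = np.maximum(th, 1e-10)
    A = mu / th
    B = (1.0 - mu) / th
    N = 1.0 / th
    return (
        -(A / th) * (digamma(a + A) - digamma(A))
        - (B / th) * (digamma(d - a + B) - digamma(B))
        + (N / th) * (digamma(d + N) - digamma(N))
    )


def expected_information(d, mu, theta, mask=None, include_theta=True, _chunk=4_000_000):
    """Exact per-cell Fisher information by enumerating the count support.

    Returns ``(V, c, i_tt)`` where ``V_i = E[s_i^2]`` is the information of the
    linear predictor, ``c_i = E[s_i t_i]`` the cross-information with theta and
    ``i_tt_i = E[t_i^2]`` the theta information (``t_i`` = per-cell theta
    score).  Enumeration is grouped by the (few) unique total counts.
    """
    d = np.asarray(d, dtype=float)
    mu = np.clip(np.asarray(mu, dtype=float), _MU_EPS, 1.0 - _MU_EPS)
    th = np.asarray(theta, dtype=float)
    if th.ndim < d.ndim:
        th = np.broadcast_to(th[..., None], d.shape)
    if mask is None:
        mask = d > 0
    V = np.zeros(d.shape)
    c = np.zeros(d.shape)
    i_tt = np.zeros(d.shape)
    d_flat = d.ravel()
    mu_flat = mu.ravel()
    th_flat = np.broadcast_to(th, d.shape).ravel()
    m_flat = np.asarray(mask).ravel()
    V_f, c_f, t_f = V.ravel(), c.ravel(), i_tt.ravel()
    for du in np.unique(d_flat[m_flat & (d_flat > 0)]):
        sel = np.flatnonzero(m_flat & (d_flat == du))
        du_i = int(du)
        step = max(1, _chunk // (du_i + 1))
        ag = np.arange(du_i + 1, dtype=float)[None, :]
        for lo in range(0, sel.size, step):
            idx = sel[lo : lo + step]
            mu_s = mu_flat[idx][:, None]
            th_s = th_flat[idx][:, None]
            pm = np.exp(_bb_logpmf_raw(ag, du, mu_s, np.maximum(th_s, 1e-7)))
            u = score_eta(ag, du, mu_s, np.maximum(th_s, 1e-7))
            V_f[idx] = np.sum(pm * u * u, axis=1)
            if include_theta:
                t = _dll_dtheta(ag, du, mu_s, th_s)
                c_f[idx] = np.sum(pm * u * t, axis=1)
                t_f[idx] = np.sum(pm * t * t, axis=1)
    return V, c, i_tt


def _quasi_weights(d, mu, theta, mask):
    """Quasi information of eta (exact for the Binomial, BB-variance based)."""
    th = np.asarray(theta, dtype=float)[..., None]
    w = d * mu * (1.0 - mu) * (1.0 + th) / (1.0 + d * th)
    return np.where(mask, w, 0.0)


def _theta_mom(a, d, mask):
    """Method-of-moments initial overdispersion per region row."""
    with np.errstate(invalid="ignore", divide="ignore"):
        n_obs = mask.sum(axis=-1)
        sum_d = np.where(mask, d, 0.0).sum(axis=-1)
        rbar = (np.where(mask, a, 0.0).sum(axis=-1) + 0.5) / (sum_d + 1.0)
        r = np.where(mask, a / np.where(d > 0, d, 1.0), 0.0)
        v = np.where(mask, (r - rbar[..., None]) ** 2, 0.0).sum(axis=-1) / np.maximum(n_obs, 1)
        m1 = np.where(mask, 1.0 / np.where(d > 0, d, 1.0), 0.0).sum(axis=-1) / np.maximum(n_obs, 1)
        rho = (v / np.maximum(rbar * (1.0 - rbar), 1e-8) - m1) / np.maximum(1.0 - m1, 1e-8)
    rho = np.clip(np.nan_to_num(rho, nan=0.2), 1e-3, 0.99)
    return np.clip(rho / (1.0 - rho), 1e-2, 50.0)


class BatchedNullFit:
    """Null fits for a batch of regions sharing one design matrix.

    Thin container produced by :func:`fit_null_batched`; exposes per-region
    parameter arrays and the working quantities the score tests consume.
    """

    def __init__(self, coef, theta, mu, eta, loglik, converged, n_iter, Z, offset, mask, free_intercept, theta_fixed):
        self.coef = coef
        self.theta = theta
        self.mu = mu
        self.eta = eta
        self.loglik = loglik
        self.converged = converged
        self.n_iter = n_iter
        self.Z = Z
        self.offset = offset
        self.mask = mask
        self.free_intercept = free_intercept
        self.theta_fixed = theta_fixed

    @property
    def n_regions(self):
        return self.mu.shape[0]

    def score_residuals(self, a, d):
        s = score_eta(a, d, self.mu, self.theta)
        return np.where(self.mask, s, 0.0)


def fit_null_batched(
    a,
    d,
    spec: NullModelSpec | None = None,
    theta_fixed: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> BatchedNullFit:
    """Fisher-scoring fit of the Beta-Binomial null for a batch of regions.

    ``a`` and ``d`` are ``(n_regions, n_cells)`` (a single region may be passed
    as 1-D).  Cells with ``d = 0`` carry no information about allelic rates and
    are excluded from the likelihood.  ``theta_fixed`` pins the overdispersion
    (e.g. near zero for the Binomial variant).
    """
    spec = spec or NullModelSpec()
    a = np.atleast_2d(np.asarray(a, dtype=float))
    d = np.atleast_2d(np.asarray(d, dtype=float))
    a, d = _validate_counts(a, d)
    if a.shape != d.shape:
        raise ValueError("a and d must have matching shapes")
    R, n = a.shape
    mask = d > 0
    if not mask.any(axis=1).all():
        bad = np.flatnonzero(~mask.any(axis=1))
        raise ValueError(f"regions {bad[:5].tolist()} have no cells with d > 0")
    Z = spec.design(n)
    q = Z.shape[1]
    offset = float(logit(spec.base_rate))

    # --- initialisation -----------------------------------------------------
    coef = np.zeros((R, q))
    if spec.free_intercept:
        sum_a = np.where(mask, a, 0.0).sum(axis=1)
        sum_d = np.where(mask, d, 0.0).sum(axis=1)
        rbar = (sum_a + 0.5) / (sum_d + 1.0)
        coef[:, 0] = np.clip(logit(rbar) - offset, -10.0, 10.0)
    if theta_fixed is not None:
        theta = np.full(R, float(theta_fixed))
    else:
        theta = _theta_mom(a, d, mask)
    log_theta = np.log(theta)

    def eta_of(cf):
        e = offset + (cf @ Z.T if q else np.zeros((R, n)))
        return np.clip(e, -30.0, 30.0)

    eta = eta_of(coef)
    mu = expit(eta)
    ll = _loglik_rows(a, d, mu, theta, mask, include_const=False)
    converged = np.zeros(R, dtype=bool)
    n_iter = 0
    eps_phi = 1e-4

    for it in range(max_iter):
        n_iter = it + 1
        ll_prev = ll.copy()

        # Newton step for the regression coefficients (quasi-information
        # curvature, exact score), with per-region step-halving on the exact
        # log-likelihood.
        if q:
            s = np.where(mask, score_eta(a, d, mu, theta), 0.0)
            g = s @ Z
            w = _quasi_weights(d, mu, theta, mask)
            H = np.einsum("rn,ni,nj->rij", w, Z, Z)
            H += 1e-10 * np.eye(q)
            try:
                step = np.linalg.solve(H, g[..., None])[..., 0]
            except np.linalg.LinAlgError:
                step = g / (np.einsum("rii->ri", H) + 1e-8)
            coef, eta, mu, ll = _accept_step(
                lambda cf: cf, coef, step, a, d, theta, mask, ll, eta_of
            )

        # Safeguarded Newton step for log(theta).
        if theta_fixed is None:
            t = np.where(mask, _dll_dtheta(a, d, mu, theta), 0.0).sum(axis=1)
            g_phi = theta * t
            theta_eps = np.exp(log_theta + eps_phi)
            t_eps = np.where(mask, _dll_dtheta(a, d, mu, theta_eps), 0.0).sum(axis=1)
            h_phi = (theta_eps * t_eps - g_phi) / eps_phi
            h_phi = np.where(h_phi < -1e-12, h_phi, -np.maximum(np.abs(g_phi), 1.0))
            step_phi = np.clip(-g_phi / h_phi, -2.0, 2.0)
            scale = np.ones(R)
            accepted = np.zeros(R, dtype=bool)
            for _ in range(15):
                trial_phi = np.clip(log_theta + scale * step_phi, np.log(THETA_MIN), np.log(THETA_MAX))
                ll_t = _loglik_rows(a, d, mu, np.exp(trial_phi), mask, include_const=False)
                ok = np.isfinite(ll_t) & (ll_t >= ll - 1e-12) & ~accepted
                log_theta = np.where(ok, trial_phi, log_theta)
                ll = np.where(ok, ll_t, ll)
                accepted |= ok
                if accepted.all():
                    break
                scale = np.where(accepted, scale, scale * 0.5)
            theta = np.exp(log_theta)

        rel = np.abs(ll - ll_prev) / (np.abs(ll) + 1.0)
        converged = rel < tol
        if converged.all():
            break

    ll_full = _loglik_rows(a, d, mu, theta, mask, include_const=True)
    return BatchedNullFit(
        coef, theta, mu, eta, ll_full, converged, n_iter, Z, offset, mask,
        spec.free_intercept, theta_fixed,
    )


def _accept_step(transform, coef, step, a, d, theta, mask, ll, eta_of):
    """Vectorised step-halving: accept per-region Newton steps only if the
    exact log-likelihood does not decrease."""
    R = coef.shape[0]
    scale = np.ones(R)
    accepted = np.zeros(R, dtype=bool)
    best = coef.copy()
    for _ in range(15):
        trial = coef + scale[:, None] * step
        eta_t = eta_of(trial)
        ll_t = _loglik_rows(a, d, expit(eta_t), theta, mask, include_const=False)
        ok = np.isfinite(ll_t) & (ll_t >= ll - 1e-12) & ~accepted
        best[ok] = trial[ok]
        ll = np.where(ok, ll_t, ll)
        accepted |= ok
        if accepted.all():
            break
        scale = np.where(accepted, scale, scale * 0.5)
    eta = eta_of(best)
    return best, eta, expit(eta), ll


def fit_null(a, d, spec: NullModelSpec | None = None, **kwargs) -> NullFit:
    """Fit the Beta-Binomial null model for a single region.

    Cells with ``d = 0`` are excluded from the likelihood; the returned
    ``mu_hat`` still covers all cells (prediction from the linear predictor).
    Non-convergence is flagged on the result, not raised.
    """
    spec = spec or NullModelSpec()
    a = np.asarray(a, dtype=float).ravel()
    d = np.asarray(d, dtype=float).ravel()
    if not (d > 0).any():
        raise ValueError("need at least one cell with d > 0")
    fit = fit_null_batched(a[None, :], d[None, :], spec=spec, **kwargs)
    # working residuals a - d*mu, the score of the mean model in the
    # Binomial limit and the statistic the score tests are built on
    s = np.where(fit.mask, a[None, :] - d[None, :] * fit.mu, 0.0)[0]
    V, _, _ = expected_information(d[None, :], fit.mu, fit.theta, fit.mask)
    Z = fit.Z
    info = Z.T @ (V[0][:, None] * Z) if Z.shape[1] else np.zeros((0, 0))
    alpha_hat = float(fit.coef[0, 0]) if spec.free_intercept else None
    beta0 = 1 if spec.free_intercept else 0
    if not fit.converged[0]:
        warnings.warn("null fit did not converge", RuntimeWarning, stacklevel=2)
    return NullFit(
        alpha_hat=alpha_hat,
        beta_hat=fit.coef[0, beta0:].copy(),
        theta_hat=float(fit.theta[0]),
        mu_hat=fit.mu[0].copy(),
        score_residuals=s,
        info=info,
        converged=bool(fit.converged[0]),
        n_iter=fit.n_iter,
        spec=spec,
        mask=fit.mask[0],
        eta=fit.eta[0].copy(),
        loglik=float(fit.loglik[0]),
    )


def loglik(fit: NullFit, a, d) -> float:
    """Summed Beta-Binomial log-likelihood of a fit over cells with d > 0."""
    a = np.asarray(a, dtype=float).ravel()
    d = np.asarray(d, dtype=float).ravel()
    if a.shape != d.shape or a.size != fit.mu_hat.size:
        raise ValueError("shape mismatch between counts and fit")
    mask = d > 0
    if not mask.any():
        return 0.0
    return float(
        np.sum(
            betabinom_logpmf(
                a[mask], d[mask], np.clip(fit.mu_hat[mask], _MU_EPS, 1 - _MU_EPS), fit.theta_hat
            )
        )
    )
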