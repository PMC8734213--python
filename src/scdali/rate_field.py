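"""Per-cell allelic rate estimation across the cell-state space.

For regions with heterogeneous imbalance, the Beta-Binomial observation model
is replaced by a Gaussian likelihood on empirical rates ``r_i = a_i / d_i``
so that the latent rate field ``u`` (mean ``alpha + X beta`` plus a
kernel-structured deviation) can be estimated in closed form by sparse
variational Gaussian-process regression.  The field lives on the rate scale;
noise is heteroscedastic with variance proportional to ``1 / d_i`` (rates
from deeper cells are more precise).  Cells with ``d = 0`` receive posterior
predictions but do not enter the likelihood.

With a linear kernel ``k(x, x') = s_k^2 xᵀx'`` on a rank-k factor, any
inducing set whose rows span the factor's column space makes the variational
posterior exactly equal to the dense Gaussian-process posterior; inducing
points (k-means centers in cell-state space, at most 1000) therefore mainly
bound the cost of the general code path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.cluster import KMeans

from .kernels import ClusterLabels, KernelFactor

_JITTER = 1e-8


@dataclass
class RatePosterior:
    """Posterior over the latent per-cell allelic rate field."""

    mean: np.ndarray
    variance: np.ndarray
    alpha_hat: float
    inducing_count: int
    observed_mask: np.ndarray
    mean_raw: np.ndarray = field(repr=False, default=None)
    kernel_scale: float = np.nan
    noise_scale: float = np.nan
    elbo_trace: np.ndarray = field(repr=False, default=None)


@dataclass
class EffectSize:
    """Heterogeneity effect size: spread of the estimated rate field."""

    qdiff10: float
    mean_rate: float


class _SGPR:
    """Collapsed sparse variational GP with linear kernel and 1/d noise."""

    def __init__(self, Eobs, y, dobs, Z, Xobs):
        self.Eobs, self.y, self.dobs, self.Z, self.Xobs = Eobs, y, dobs, Z, Xobs
        self.n, self.k = Eobs.shape
        self.m = Z.shape[0]

    def _unpack(self, params):
        alpha = params[0]
        p = self.Xobs.shape[1]
        beta = params[1 : 1 + p]
        s2k = np.exp(params[1 + p])
        s2n = np.exp(params[2 + p])
        return alpha, beta, s2k, s2n

    def _matrices(self, s2k, s2n):
        Kmm = s2k * (self.Z @ self.Z.T) + _JITTER * np.eye(self.m)
        Knm = s2k * (self.Eobs @ self.Z.T)
        lam = s2n / self.dobs  # heteroscedastic noise variances
        return Kmm, Knm, lam

    def neg_elbo(self, params):
        alpha, beta, s2k, s2n = self._unpack(params)
        Kmm, Knm, lam = self._matrices(s2k, s2n)
        resid = self.y - alpha - self.Xobs @ beta
        # log N(resid; 0, Qnn + diag(lam)) via Woodbury with Lm = chol(Kmm)
        Lm = np.linalg.cholesky(Kmm)
        A = np.linalg.solve(Lm, Knm.T) / np.sqrt(lam)[None, :]  # m x n
        B = np.eye(self.m) + A @ A.T
        LB = np.linalg.cholesky(B)
        c = np.linalg.solve(LB, A @ (resid / np.sqrt(lam)))
        quad = resid @ (resid / lam) - c @ c
        logdet = 2 * np.sum(np.log(np.diag(LB))) + np.sum(np.log(lam))
        # trace term: sum_i (K_ii - Q_ii) / lam_i
        Kdiag = s2k * np.sum(self.Eobs**2, axis=1)
        Qdiag = np.sum(np.linalg.solve(Lm, Knm.T) ** 2, axis=0)
        trace = np.sum((Kdiag - Qdiag) / lam)
        return 0.5 * (quad + logdet + self.n * np.log(2 * np.pi) + trace)

    def posterior(self, params, Eall, Xall):
        alpha, beta, s2k, s2n = self._unpack(params)
        Kmm, Knm, lam = self._matrices(s2k, s2n)
        Sigma = Kmm + Knm.T @ (Knm / lam[:, None])
        resid = self.y - alpha - self.Xobs @ beta
        Ls = np.linalg.cholesky(Sigma)
        rhs = Knm.T @ (resid / lam)
        w = np.linalg.solve(Ls.T, np.linalg.solve(Ls, rhs))  # Sigma^-1 Kmn lam^-1 resid
        Ksm = s2k * (Eall @ self.Z.T)
        mean_f = Ksm @ w
        Lm = np.linalg.cholesky(Kmm)
        V1 = np.linalg.solve(Lm, Ksm.T)
        V2 = np.linalg.solve(Ls, Kmm @ np.linalg.solve(Lm.T, np.linalg.solve(Lm, Ksm.T)))
        Kss = s2k * np.sum(Eall**2, axis=1)
        var = Kss - np.sum(V1**2, axis=0) + np.sum(V2**2, axis=0)
        mean = alpha + Xall @ beta + mean_f
        return mean, np.maximum(var, 0.0)


def estimate_rates(
    a,
    d,
    factor: KernelFactor,
    covariates: np.ndarray | None = None,
    n_inducing: int = 1000,
    seed: int = 0,
) -> RatePosterior:
    """Estimate the latent allelic rate field from sparse empirical rates.

    Fits mean parameters (alpha, covariate effects), the kernel scale and the
    noise scale by maximising the collapsed variational bound, then returns
    the posterior mean and variance of the rate field at *all* cells,
    including unobserved ones.  Reported means are clipped to [0, 1]
    (``mean_raw`` keeps the unclipped field).
    """
    a = np.asarray(a, dtype=float).ravel()
    d = np.asarray(d, dtype=float).ravel()
    n = d.size
    if factor.n_cells != n:
        raise ValueError("factor rows must match cells")
    obs = d > 0
    if obs.sum() < 2:
        raise ValueError("need at least 2 cells with d > 0")
    n_inducing = int(min(n_inducing, 1000, obs.sum()))
    E = factor.E
    X = np.zeros((n, 0)) if covariates is None else np.atleast_2d(np.asarray(covariates, dtype=float))
    y = a[obs] / d[obs]
    Eobs, Xobs, dobs = E[obs], X[obs], d[obs]

    if n_inducing >= obs.sum():
        Z = Eobs.copy()
    else:
        km = KMeans(n_clusters=n_inducing, n_init=3, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            km.fit(Eobs)
        Z = km.cluster_centers_
    model = _SGPR(Eobs, y, dobs, Z, Xobs)

    p = Xobs.shape[1]
    x0 = np.concatenate([[np.mean(y)], np.zeros(p), [np.log(0.05)], [np.log(0.25)]])
    trace: list[float] = []

    def cb(xk):
        trace.append(-model.neg_elbo(xk))

    res = optimize.minimize(
        model.neg_elbo, x0, method="L-BFGS-B", callback=cb,
        bounds=[(None, None)] * (1 + p) + [(np.log(1e-8), np.log(10.0))] * 2,
    )
    params = res.x
    mean, var = model.posterior(params, E, X)
    alpha, beta, s2k, s2n = model._unpack(params)
    return RatePosterior(
        mean=np.clip(mean, 0.0, 1.0),
        variance=var,
        alpha_hat=float(alpha),
        inducing_count=n_inducing,
        observed_mask=obs,
        mean_raw=mean,
        kernel_scale=float(s2k),
        noise_scale=float(s2n),
        elbo_trace=np.asarray(trace),
    )


def qdiff10(posterior: RatePosterior) -> EffectSize:
    """Effect size of heterogeneity: 90% minus 10% quantile of the rate field."""
    q10, q90 = np.quantile(posterior.mean, [0.1, 0.9])
    return EffectSize(qdiff10=float(q90 - q10), mean_rate=float(np.mean(posterior.mean)))


def lineage_rate_summary(
    posterior: RatePosterior, labels: ClusterLabels | np.ndarray,
    quantiles=(0.1, 0.25, 0.5, 0.75, 0.9),
) -> pd.DataFrame:
    """Mean and quantiles of the estimated rate field per lineage."""
    if not isinstance(labels, ClusterLabels):
        labels = ClusterLabels(np.asarray(labels))
    if labels.n_cells != posterior.mean.size:
        raise ValueError("labels must match cells")
    rows = []
    for lineage in labels.categories:
        sel = labels.labels == lineage
        if not sel.any():
            warnings.warn(f"lineage {lineage!r} is empty; omitted", RuntimeWarning, stacklevel=2)
            continue
        vals = posterior.mean[sel]
        row = {"lineage": lineage, "n_cells": int(sel.sum()), "mean_rate": float(vals.mean())}
        for q in quantiles:
            row[f"q{int(q * 100)}"] = float(np.quantile(vals, q))
        rows.append(row)
    return pd.DataFrame(rows)


def correlate_activity(posterior: RatePosterior, activity: np.ndarray, names=None) -> pd.DataFrame:
    """Pearson correlation of the rate field with per-cell activity scores.

    One row per activity factor (e.g. transcription-factor deviation scores),
    ranked by absolute correlation; zero-variance factors report NA.
    """
    act = np.atleast_2d(np.asarray(activity, dtype=float))
    if act.shape[0] != posterior.mean.size:
        raise ValueError("activity rows must match cells")
    if names is None:
        names = [f"factor{j}" for j in range(act.shape[1])]
    m = posterior.mean
    mc = m - m.mean()
    denom_m = np.sqrt(np.sum(mc**2))
    out = []
    for j, name in enumerate(names):
        v = act[:, j]
        vc = v - v.mean()
        denom_v = np.sqrt(np.sum(vc**2))
        if denom_v == 0.0 or denom_m == 0.0:
            r = np.nan
        else:
            r = float(mc @ vc / (denom_m * denom_v))
        out.append({"factor": name, "pearson_r": r})
    df = pd.DataFrame(out)
    return df.reindex(df["pearson_r"].abs().sort_values(ascending=False, na_position="last").index).reset_index(drop=True)


def export_rates(path, posterior: RatePosterior, cell_ids=None) -> None:
    """Write per-cell posterior means/variances as TSV keyed by cell id."""
    n = posterior.mean.size
    if cell_ids is None:
        cell_ids = [f"cell{i}" for i in range(n)]
    pd.DataFrame(
        {
            "cell": cell_ids,
            "rate_mean": posterior.mean,
            "rate_variance": posterior.variance,
            "observed": posterior.observed_mask.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)
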