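"""Variational autoencoder for binarized chromatin accessibility.

The generative model for a binary peak-by-cell matrix is

    z_i ~ N(0, I),   rho_i = f_rho(z_i, c_i) in [0,1]^m,
    x_ij | rho_ij, l_i ~ Bernoulli(1 - (1 - rho_ij)^{l_i})

where ``c_i`` is the batch identity and ``l_i`` a per-cell size factor on the
reads scale: if ``l_i`` were the true read count, ``1 - (1 - rho)^l`` is the
probability of seeing at least one read in a peak.  Batch one-hots are fed to
both encoder and decoder so the latent space integrates batches.  Coarse
collection-time labels ``y_i in {1..t}`` couple to the latent space through
an ordinal probit likelihood

    p(y | z) = Phi(w_y - f_y(z)) - Phi(w_{y-1} - f_y(z)),

with ``w_0 = -inf < w_1 < ... < w_{t-1} < w_t = +inf`` and a linear
pseudotime map ``f_y``; threshold ordering is enforced by parameterising gaps
as exponentials.  ``f_y(z)`` provides a continuous developmental ordering
from few discrete labels.

Implementation notes: the size factor is treated as observed (the per-cell
total count), with the per-batch log-normal prior estimated by
:func:`size_factor_mle`; peak activities are independent sigmoids (no
sum-to-one constraint); inference is amortised variational inference with the
reparameterisation trick, hand-derived gradients and Adam (two hidden layers
of width 128 in encoder and decoder).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

_EPS = 1e-7


@dataclass
class VaeConfig:
    latent_dim: int = 8
    hidden: int = 128
    n_epochs: int = 30
    learning_rate: float = 1e-3
    seed: int = 0
    time_categories: int = 3
    time_weight: float = 1.0
    batch_size: int = 128

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.time_categories < 2:
            raise ValueError("need at least 2 time categories for the ordinal loss")


@dataclass
class SizeFactorPrior:
    """Per-batch log-normal prior parameters for the size factor."""

    mu_l: np.ndarray
    sigma2_l: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.sigma2_l) <= 0):
            raise ValueError("sigma2_l must be positive")


def size_factor_mle(totals, batch_ids, var_floor: float = 1e-6) -> SizeFactorPrior:
    """Maximum-likelihood log-normal prior from total reads per cell per batch."""
    totals = np.asarray(totals, dtype=float)
    if np.any(totals <= 0):
        raise ValueError("totals must be positive")
    batch_ids = np.asarray(batch_ids)
    cats = np.unique(batch_ids)
    mu = np.zeros(cats.size)
    s2 = np.zeros(cats.size)
    logt = np.log(totals)
    for i, c in enumerate(cats):
        sel = batch_ids == c
        mu[i] = logt[sel].mean()
        v = logt[sel].var()
        if sel.sum() < 2 or v < var_floor:
            if sel.sum() < 2:
                warnings.warn(f"batch {c!r} has a single cell; variance floored", RuntimeWarning, stacklevel=2)
            v = var_floor
        s2[i] = v
    return SizeFactorPrior(mu_l=mu, sigma2_l=s2)


def decode_prob(rho, l):
    """Bernoulli parameter 1 - (1 - rho)^l; monotone in both arguments."""
    rho = np.asarray(rho, dtype=float)
    l = np.asarray(l, dtype=float)
    if np.any(rho < 0) or np.any(rho > 1):
        raise ValueError("rho must lie in [0, 1]")
    if np.any(l <= 0):
        raise ValueError("size factor l must be positive")
    return -np.expm1(l * np.log1p(-np.clip(rho, 0.0, 1.0 - 1e-12)))


def ordinal_logprob(y, f, thresholds):
    """Log probability of ordinal category y under the probit model.

    ``thresholds`` are the finite cut points w_1 < ... < w_{t-1}; categories
    are 1..t.  Probabilities over all categories sum to one for any f.
    """
    th = np.asarray(thresholds, dtype=float)
    if th.size and np.any(np.diff(th) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    y = np.asarray(y, dtype=int)
    f = np.asarray(f, dtype=float)
    t = th.size + 1
    if np.any(y < 1) or np.any(y > t):
        raise ValueError("categories must lie in 1..t")
    full = np.concatenate([[-np.inf], th, [np.inf]])
    hi = norm.cdf(full[y] - f)
    lo = norm.cdf(full[y - 1] - f)
    return np.log(np.maximum(hi - lo, 1e-300))


class OrdinalHead:
    """Linear pseudotime map with ordered probit thresholds.

    Threshold ordering is maintained by construction: ``w_1 = base`` and
    subsequent thresholds add exponentiated gap parameters.
    """

    def __init__(self, latent_dim: int, t: int, rng):
        self.w = 0.01 * rng.normal(size=latent_dim)
        self.b = 0.0
        self.base = -1.0
        self.log_gaps = np.zeros(max(t - 2, 0))

    @property
    def thresholds(self) -> np.ndarray:
        return self.base + np.concatenate([[0.0], np.cumsum(np.exp(self.log_gaps))])

    def f(self, z):
        return z @ self.w + self.b


def _init_layer(rng, n_in, n_out):
    return rng.normal(0.0, np.sqrt(2.0 / (n_in + n_out)), size=(n_in, n_out)), np.zeros(n_out)


class _Adam:
    def __init__(self, params, lr):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mh = self.m[i] / (1 - b1**self.t)
            vh = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + eps)


class CellStateVAE:
    """Amortised VAE with batch integration and ordinal pseudotime."""

    def __init__(self, config: VaeConfig | None = None):
        self.config = config or VaeConfig()
        self.elbo_trace: np.ndarray | None = None

    # ---------------- forward pieces ----------------
    def _encode(self, xb):
        h1 = np.tanh(xb @ self.We1 + self.be1)
        h2 = np.tanh(h1 @ self.We2 + self.be2)
        mu = h2 @ self.Wmu + self.bmu
        lv = np.clip(h2 @ self.Wlv + self.blv, -8.0, 8.0)
        return h1, h2, mu, lv

    def _decode(self, zb):
        g1 = np.tanh(zb @ self.Wd1 + self.bd1)
        g2 = np.tanh(g1 @ self.Wd2 + self.bd2)
        logits = g2 @ self.Wout + self.bout
        return g1, g2, logits

    def _params(self):
        head = self.head
        return [
            self.We1, self.be1, self.We2, self.be2, self.Wmu, self.bmu, self.Wlv, self.blv,
            self.Wd1, self.bd1, self.Wd2, self.bd2, self.Wout, self.bout,
            head.w, np.atleast_1d(head.b), np.atleast_1d(head.base), head.log_gaps,
        ]

    def fit(self, x, batch_ids, time_labels, totals=None):
        """Train on a binary cells x peaks matrix.

        ``time_labels`` are ordinal categories 1..t; ``totals`` (size factors)
        default to the per-cell number of accessible peaks.  Returns self;
        the latent means, pseudotime and activities are then available via
        :meth:`transform`.
        """
        cfg = self.config
        x = np.asarray(x, dtype=float)
        if x.size == 0 or not x.any():
            raise ValueError("input matrix is degenerate (all zeros)")
        if not np.isin(x, (0.0, 1.0)).all():
            raise ValueError("x must be binary")
        n, m = x.shape
        batch_ids = np.asarray(batch_ids)
        cats = np.unique(batch_ids)
        bcode = np.searchsorted(cats, batch_ids)
        nb = cats.size
        onehot = np.zeros((n, nb))
        onehot[np.arange(n), bcode] = 1.0
        if totals is None:
            totals = np.maximum(x.sum(axis=1), 1.0)
        totals = np.asarray(totals, dtype=float)
        self.size_prior = size_factor_mle(totals, batch_ids)
        y = np.asarray(time_labels, dtype=int)

        rng = np.random.default_rng(cfg.seed)
        k, h = cfg.latent_dim, cfg.hidden
        self.We1, self.be1 = _init_layer(rng, m + nb, h)
        self.We2, self.be2 = _init_layer(rng, h, h)
        self.Wmu, self.bmu = _init_layer(rng, h, k)
        self.Wlv, self.blv = _init_layer(rng, h, k)
        self.Wd1, self.bd1 = _init_layer(rng, k + nb, h)
        self.Wd2, self.bd2 = _init_layer(rng, h, h)
        self.Wout, self.bout = _init_layer(rng, h, m)
        self.bout -= 4.0  # activities start small: p(open) ~ l * rho
        self.head = OrdinalHead(k, cfg.time_categories, rng)
        self._batch_cats = cats
        self._n_batches = nb

        params = self._params()
        opt = _Adam(params, cfg.learning_rate)
        trace = []
        for epoch in range(cfg.n_epochs):
            order = rng.permutation(n)
            ep_elbo = 0.0
            for lo in range(0, n, cfg.batch_size):
                idx = order[lo : lo + cfg.batch_size]
                elbo = self._step(x[idx], onehot[idx], totals[idx], y[idx], opt, rng)
                ep_elbo += elbo * idx.size
            trace.append(ep_elbo / n)
        self.elbo_trace = np.asarray(trace)
        self._onehot_all = onehot
        self._x = x
        self._totals = totals
        return self

    def _step(self, xb, ob, lb, yb, opt, rng):
        B, m = xb.shape
        head = self.head
        xin = np.hstack([xb, ob])
        h1, h2, mu, lv = self._encode(xin)
        eps = rng.normal(size=mu.shape)
        z = mu + eps * np.exp(0.5 * lv)
        zin = np.hstack([z, ob])
        g1, g2, logits = self._decode(zin)
        rho = 1.0 / (1.0 + np.exp(-logits))
        log1mrho = np.log1p(-np.clip(rho, 0.0, 1.0 - 1e-12))
        p = np.clip(-np.expm1(lb[:, None] * log1mrho), _EPS, 1.0 - _EPS)
        recon = np.sum(xb * np.log(p) + (1.0 - xb) * np.log1p(-p))
        kl = 0.5 * np.sum(mu**2 + np.exp(lv) - 1.0 - lv)
        f = head.f(z)
        th = head.thresholds
        full = np.concatenate([[-np.inf], th, [np.inf]])
        hi_arg = full[yb] - f
        lo_arg = full[yb - 1] - f
        P = np.maximum(norm.cdf(hi_arg) - norm.cdf(lo_arg), 1e-12)
        ord_ll = np.sum(np.log(P))
        elbo = (recon - kl + self.config.time_weight * ord_ll) / B

        # ---- backward (gradients of the negative ELBO) ----
        dL_dp = -(xb / p - (1.0 - xb) / (1.0 - p))
        dp_drho = lb[:, None] * np.exp((lb[:, None] - 1.0) * log1mrho)
        dL_dlogits = dL_dp * dp_drho * rho * (1.0 - rho)
        gWout = g2.T @ dL_dlogits
        gbout = dL_dlogits.sum(0)
        dg2 = (dL_dlogits @ self.Wout.T) * (1.0 - g2**2)
        gWd2 = g1.T @ dg2
        gbd2 = dg2.sum(0)
        dg1 = (dg2 @ self.Wd2.T) * (1.0 - g1**2)
        gWd1 = zin.T @ dg1
        gbd1 = dg1.sum(0)
        dz = (dg1 @ self.Wd1.T)[:, : mu.shape[1]]

        phi_hi = norm.pdf(hi_arg)
        phi_lo = norm.pdf(lo_arg)
        w_t = self.config.time_weight
        dL_df = w_t * (phi_hi - phi_lo) / P
        dz += dL_df[:, None] * head.w[None, :]
        gw_head = z.T @ dL_df
        gb_head = np.array([dL_df.sum()])
        t_cats = th.size + 1
        dL_dw = np.zeros(th.size)
        for kk in range(1, t_cats):
            sel_hi = yb == kk  # w_kk is upper bound of category kk
            sel_lo = yb == kk + 1
            dL_dw[kk - 1] = -w_t * (np.sum(phi_hi[sel_hi] / P[sel_hi]) - np.sum(phi_lo[sel_lo] / P[sel_lo]))
        gbase = np.array([dL_dw.sum()])
        glog_gaps = np.array(
            [np.sum(dL_dw[i + 1 :]) * np.exp(head.log_gaps[i]) for i in range(head.log_gaps.size)]
        )

        # KL gradients + reparameterisation
        dmu = dz + mu
        dlv = dz * eps * 0.5 * np.exp(0.5 * lv) + 0.5 * (np.exp(lv) - 1.0)
        dh2 = (dmu @ self.Wmu.T + dlv @ self.Wlv.T) * (1.0 - h2**2)
        gWmu = h2.T @ dmu
        gbmu = dmu.sum(0)
        gWlv = h2.T @ dlv
        gblv = dlv.sum(0)
        gWe2 = h1.T @ dh2
        gbe2 = dh2.sum(0)
        dh1 = (dh2 @ self.We2.T) * (1.0 - h1**2)
        gWe1 = xin.T @ dh1
        gbe1 = dh1.sum(0)

        grads = [
            gWe1, gbe1, gWe2, gbe2, gWmu, gbmu, gWlv, gblv,
            gWd1, gbd1, gWd2, gbd2, gWout, gbout,
            gw_head, gb_head, gbase, glog_gaps,
        ]
        grads = [g / B for g in grads]
        params = self._params()
        opt.step(params, grads)
        # scalars stored as arrays need writing back
        self.head.b = float(params[15][0])
        self.head.base = float(params[16][0])
        return elbo

    def transform(self, x=None, batch_ids=None):
        """Latent means, pseudotime f_y(z) and activities rho per cell."""
        if x is None:
            xin = np.hstack([self._x, self._onehot_all])
            onehot = self._onehot_all
        else:
            x = np.asarray(x, dtype=float)
            bcode = np.searchsorted(self._batch_cats, np.asarray(batch_ids))
            onehot = np.zeros((x.shape[0], self._n_batches))
            onehot[np.arange(x.shape[0]), bcode] = 1.0
            xin = np.hstack([x, onehot])
        _, _, mu, _ = self._encode(xin)
        _, _, logits = self._decode(np.hstack([mu, onehot]))
        rho = 1.0 / (1.0 + np.exp(-logits))
        return mu, self.head.f(mu), rho


def fit(x, batch_ids, time_labels, config: VaeConfig | None = None, totals=None):
    """Convenience wrapper: train a VAE and return (latent, pseudotime, model)."""
    model = CellStateVAE(config).fit(x, batch_ids, time_labels, totals=totals)
    latent, pseudotime, _ = model.transform()
    return latent, pseudotime, model
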