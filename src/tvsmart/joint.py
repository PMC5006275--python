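"""Joint model: the TVMEM longitudinal submodels plus a relative-risk model
for the time to intermediate response, linked by the shared random intercept.

The hazard of responding at time ``t`` is

    h_i(t) = h0(t) * exp{ gamma1 * A1_i + alpha * m_i(0) },

with ``m_i(0) = beta00 + b_i`` the latent (error-free) baseline outcome, so
the event submodel depends on the random intercept only through a fixed
linear map and the integral over ``b`` is one-dimensional.  The baseline
hazard ``h0`` is Weibull by default (shape estimated, log-scale absorbed into
an intercept ``gamma0``) with a piecewise-constant alternative.

The marginal likelihood integrates ``b`` out by Gauss-Hermite quadrature,
by default adaptively recentred at each subject's empirical-Bayes posterior
mode under the longitudinal part (where that posterior is exactly Gaussian);
during optimization the centres are frozen at the warm start so the
objective is smooth and its analytic gradient exact.  All node
accumulations are done in log space.

Note on parameter scales: the simulator draws ``T1`` from a Weibull whose
*scale* is ``exp{g0 + g1*A1 + a*m(0)}``; the relative-risk model above
multiplies the *hazard*.  For shape k these parameterizations are related by
``(gamma1, alpha) = -k * (g1, a)``, which is what a correctly specified fit
to simulator output recovers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .design import DesignSpec
from .tvmem import (
    SIGMA_TERMS,
    DataError,
    TvmemFit,
    _numerical_hessian,
    _wald,
    empirical_bayes_b,
    fit_tvmem,
    mean_design,
)

__all__ = [
    "JointFit",
    "event_loglik_given_b",
    "joint_loglik",
    "fit_joint",
]

EVENT_TERMS_WEIBULL = ["gamma0", "gamma1", "alpha", "weibull_shape"]


def event_loglik_given_b(
    T1,
    delta,
    A1,
    b,
    params,
    truncate_at_t00: bool = False,
    t00: float = 0.0,
):
    """Log-likelihood of ``(T1, delta)`` given the random intercept.

    Weibull baseline: ``h(t) = k t^(k-1) exp{gamma0 + gamma1*A1 +
    alpha*(beta00 + b)}``; returns ``delta*log h(T1) - H(T1)`` with the
    integrated hazard ``H(t) = t^k exp{...}`` taken from 0, or from ``t00``
    when ``truncate_at_t00`` (the conditional, left-truncated likelihood).
    Vectorized over all arguments.
    """
    T1 = np.asarray(T1, float)
    delta = np.asarray(delta, float)
    k = float(params["weibull_shape"])
    if k <= 0:
        raise ValueError("weibull_shape must be > 0")
    eta = (
        float(params["gamma0"])
        + float(params["gamma1"]) * np.asarray(A1, float)
        + float(params["alpha"]) * (float(params["beta00"]) + np.asarray(b, float))
    )
    out = delta * (np.log(k) + (k - 1.0) * np.log(T1) + eta) - T1**k * np.exp(eta)
    if truncate_at_t00:
        out = out + t00**k * np.exp(eta)
    return out


def _gh_nodes(n: int):
    x, w = np.polynomial.hermite.hermgauss(n)
    return x, w


def _longitudinal_terms(params, data, include_interactions):
    Xs, labels, _ = mean_design(data, include_interactions, drop_constant_time=False)
    betas = [np.array([float(params[l]) for l in lab]) for lab in labels]
    y = data[["Y0", "Y1", "Y2"]].to_numpy(float)
    r0 = np.column_stack([y[:, j] - Xs[j] @ betas[j] for j in range(3)])
    sigmas = np.array([float(params[s]) for s in ("sigma0", "sigma1", "sigma2")])
    return r0, sigmas


def joint_loglik(
    params,
    data: pd.DataFrame,
    nodes: int = 15,
    include_interactions: bool = False,
    adaptive: bool = True,
    truncate_at_t00: bool = False,
    t00: float = 0.0,
) -> float:
    """Marginal joint log-likelihood at labeled parameter values.

    *params* maps the TVMEM labels plus ``gamma0``, ``gamma1``, ``alpha``
    and ``weibull_shape`` to values on the natural scale.  The integral over
    the random intercept uses *nodes* Gauss-Hermite points, recentred per
    subject when *adaptive* (exact for the Gaussian longitudinal factor).
    """
    if nodes < 5:
        raise ValueError("need at least 5 quadrature nodes")
    r0, sigmas = _longitudinal_terms(params, data, include_interactions)
    sb = float(params["sigma_b"])
    x, w = _gh_nodes(nodes)
    a1 = data["A1"].to_numpy(float)
    t1 = data["T1"].to_numpy(float)
    delta = data["delta"].to_numpy(float)

    if sb <= 0.0:  # degenerate mixing distribution: plug in b = 0
        lon = np.sum(
            -0.5 * np.log(2 * np.pi * sigmas**2) - r0**2 / (2 * sigmas**2), axis=1
        )
        ev = event_loglik_given_b(t1, delta, a1, 0.0, params, truncate_at_t00, t00)
        return float(np.sum(lon + ev))

    if adaptive:
        tau = 1.0 / sb**2 + np.sum(1.0 / sigmas**2)
        mu = (r0 / sigmas**2).sum(axis=1) / tau
        s = 1.0 / np.sqrt(tau)
        B = mu[:, None] + np.sqrt(2.0) * s * x[None, :]
        logw = np.log(np.sqrt(2.0) * s * w)[None, :] + x[None, :] ** 2
        prior = -0.5 * np.log(2 * np.pi * sb**2) - B**2 / (2 * sb**2)
    else:
        B = np.broadcast_to(np.sqrt(2.0) * sb * x, (len(data), nodes))
        logw = np.broadcast_to(np.log(w / np.sqrt(np.pi)), (len(data), nodes))
        prior = 0.0  # absorbed in the Gauss-Hermite weight

    lon = np.zeros_like(B)
    for j in range(3):
        rj = r0[:, j][:, None] - B
        lon += -0.5 * np.log(2 * np.pi * sigmas[j] ** 2) - rj**2 / (2 * sigmas[j] ** 2)
    ev = event_loglik_given_b(
        t1[:, None], delta[:, None], a1[:, None], B, params, truncate_at_t00, t00
    )
    g = logw + lon + prior + ev
    gmax = g.max(axis=1, keepdims=True)
    li = gmax[:, 0] + np.log(np.exp(g - gmax).sum(axis=1))
    return float(li.sum())


@dataclass
class JointFit(TvmemFit):
    """TVMEM fields plus the event submodel (see :class:`TvmemFit`)."""

    nodes: int = 15
    baseline: str = "weibull"
    tvmem_start: TvmemFit | None = None


class _JointObjective:
    """Negative joint log-likelihood with analytic gradient, on a frozen
    adaptive quadrature grid.

    Parameter vector: stage coefficients, then log sigma_b, log sigma0..2,
    then gamma0, gamma1, alpha, log shape (Weibull baseline) or the log
    piecewise baseline heights followed by gamma1, alpha.
    """

    def __init__(self, data, include_interactions, nodes, centers, scales,
                 truncate_at_t00, t00, baseline="weibull", breaks=None):
        self.data = data
        self.Xs, self.labels, _ = mean_design(
            data, include_interactions, drop_constant_time=False
        )
        self.beta_labels = self.labels[0] + self.labels[1] + self.labels[2]
        self.y = data[["Y0", "Y1", "Y2"]].to_numpy(float)
        self.a1 = data["A1"].to_numpy(float)
        self.t1 = data["T1"].to_numpy(float)
        self.delta = data["delta"].to_numpy(float)
        self.trunc = truncate_at_t00
        self.t00 = t00
        self.baseline = baseline
        x, w = _gh_nodes(nodes)
        self.B = centers[:, None] + np.sqrt(2.0) * scales[:, None] * x[None, :]
        self.logw = (
            np.log(np.sqrt(2.0) * scales)[:, None] + np.log(w)[None, :] + x[None, :] ** 2
        )
        self.logT = np.log(self.t1)
        if baseline == "piecewise":
            if breaks is None:
                raise ValueError("piecewise baseline needs break points")
            self.breaks = np.asarray(breaks, float)  # increasing, first >= 0
            edges = self.breaks
            # time each subject spends in each piece before T1 (from 0 or t00)
            lo = self.t00 if truncate_at_t00 else 0.0
            starts = np.maximum(edges[:-1], lo)
            self.occupancy = np.clip(
                self.t1[:, None] - starts[None, :], 0.0,
                np.maximum(edges[1:] - starts, 0.0)[None, :],
            )
            self.piece_of_t1 = np.clip(
                np.searchsorted(edges, self.t1, side="right") - 1, 0, len(edges) - 2
            )
            self.event_labels = [f"log_h0_{j + 1}" for j in range(len(edges) - 1)] + [
                "gamma1", "alpha",
            ]
        else:
            self.event_labels = ["gamma0", "gamma1", "alpha", "log_shape"]
        self.param_labels = (
            self.beta_labels
            + ["log_sigma_b", "log_sigma0", "log_sigma1", "log_sigma2"]
            + self.event_labels
        )
        self.n_beta = len(self.beta_labels)
        self.splits = np.cumsum([len(l) for l in self.labels])

    def unpack(self, theta):
        nb = self.n_beta
        betas = np.split(theta[:nb], self.splits[:-1])
        sb = np.exp(theta[nb])
        sigmas = np.exp(theta[nb + 1: nb + 4])
        event = theta[nb + 4:]
        return betas, sb, sigmas, event

    def __call__(self, theta):
        betas, sb, sigmas, event = self.unpack(theta)
        B, n, K = self.B, *self.B.shape
        r = [self.y[:, j] - self.Xs[j] @ betas[j] for j in range(3)]

        lon = np.zeros((n, K))
        for j in range(3):
            rj = r[j][:, None] - B
            lon += -0.5 * np.log(2 * np.pi * sigmas[j] ** 2) - rj**2 / (
                2 * sigmas[j] ** 2
            )
        prior = -0.5 * np.log(2 * np.pi * sb**2) - B**2 / (2 * sb**2)

        beta00 = betas[0][0]
        if self.baseline == "weibull":
            gamma0, gamma1, alpha, logk = event
            k = np.exp(logk)
            eta = gamma0 + gamma1 * self.a1[:, None] + alpha * (beta00 + B)
            H0 = self.t1[:, None] ** k  # baseline cumulative (gamma0 inside eta)
            log_h = np.log(k) + (k - 1.0) * self.logT[:, None] + eta
            H = H0 * np.exp(eta)
            if self.trunc:
                H = H - self.t00**k * np.exp(eta)
        else:
            m = len(self.event_labels) - 2
            lam, gamma1, alpha = event[:m], event[m], event[m + 1]
            eta = gamma1 * self.a1[:, None] + alpha * (beta00 + B)
            log_h = lam[self.piece_of_t1][:, None] + eta
            H0 = self.occupancy @ np.exp(lam)
            H = H0[:, None] * np.exp(eta)
        ev = self.delta[:, None] * log_h - H

        g = self.logw + lon + prior + ev
        gmax = g.max(axis=1, keepdims=True)
        eg = np.exp(g - gmax)
        seg = eg.sum(axis=1)
        li = gmax[:, 0] + np.log(seg)
        pi = eg / seg[:, None]

        # gradient: posterior-weighted node-wise score
        grad = np.zeros(len(theta))
        G = pi * (self.delta[:, None] - H)  # d(ev)/d(eta), weighted
        Gsum_i = G.sum(axis=1)
        off = 0
        for j in range(3):
            rj = r[j][:, None] - B
            ebar = (pi * rj).sum(axis=1) / sigmas[j] ** 2
            grad[off:off + len(betas[j])] = self.Xs[j].T @ ebar
            off += len(betas[j])
        grad[0] += alpha * Gsum_i.sum()  # beta00 enters the hazard via m(0)
        nb = self.n_beta
        grad[nb] = (pi * (B**2 / sb**2 - 1.0)).sum()
        for j in range(3):
            rj = r[j][:, None] - B
            grad[nb + 1 + j] = (pi * (rj**2 / sigmas[j] ** 2 - 1.0)).sum()
        e0 = nb + 4
        if self.baseline == "weibull":
            grad[e0 + 0] = Gsum_i.sum()
            grad[e0 + 1] = (self.a1 * Gsum_i).sum()
            grad[e0 + 2] = (G * (beta00 + B)).sum()
            dk = (
                self.delta[:, None] * (1.0 + k * self.logT[:, None])
                - k * self.logT[:, None] * H0 * np.exp(eta)
            )
            if self.trunc and self.t00 > 0:
                dk += k * np.log(self.t00) * self.t00**k * np.exp(eta)
            grad[e0 + 3] = (pi * dk).sum()
        else:
            expeta = np.exp(eta)
            for jp in range(m):
                at = (self.piece_of_t1 == jp).astype(float)
                dl = self.delta[:, None] * at[:, None] - np.exp(
                    lam[jp]
                ) * self.occupancy[:, jp][:, None] * expeta
                grad[e0 + jp] = (pi * dl).sum()
            grad[e0 + m] = (self.a1 * Gsum_i).sum()
            grad[e0 + m + 1] = (G * (beta00 + B)).sum()

        return -float(li.sum()), -grad


def _event_warm_start(data, beta00, b_hat, truncate_at_t00, t00):
    """Constant-hazard (shape 1) censored regression on T1 with plug-in m(0)."""
    a1 = data["A1"].to_numpy(float)
    t1 = data["T1"].to_numpy(float)
    delta = data["delta"].to_numpy(float)
    m0 = beta00 + b_hat
    dur = t1 - (t00 if truncate_at_t00 else 0.0)

    def nll(g):
        eta = g[0] + g[1] * a1 + g[2] * m0
        ll = delta * eta - dur * np.exp(eta)
        de = delta - dur * np.exp(eta)
        return -ll.sum(), -np.array([de.sum(), (a1 * de).sum(), (m0 * de).sum()])

    res = optimize.minimize(nll, np.zeros(3), jac=True, method="L-BFGS-B")
    return res.x


def fit_joint(
    data: pd.DataFrame,
    include_interactions: bool = False,
    level: float = 0.95,
    nodes: int = 15,
    truncate_at_t00: bool = False,
    t00: float = 0.1,
    baseline: str = "weibull",
    n_pieces: int = 3,
    maxiter: int = 400,
) -> JointFit:
    """Maximum-likelihood joint fit with Wald inference.

    Warm-started from the TVMEM fit (longitudinal block) and a censored
    constant-hazard regression with plug-in empirical-Bayes ``m(0)`` (event
    block); then the full likelihood is maximized by L-BFGS with analytic
    gradients on the frozen adaptive quadrature grid.
    """
    if data["delta"].min() == data["delta"].max():
        raise DataError("need at least one responder and one censored subject")
    start = fit_tvmem(data, include_interactions, level=level, drop_constant_time=False)
    mu, s = empirical_bayes_b(start.params, data, include_interactions)

    breaks = None
    if baseline == "piecewise":
        t1r = np.sort(data.loc[data["delta"] == 1, "T1"].to_numpy(float))
        qs = np.quantile(t1r, np.linspace(0, 1, n_pieces + 1)[1:-1])
        breaks = np.concatenate([[0.0], qs, [data["T1"].max() + 1e-9]])

    obj = _JointObjective(
        data, include_interactions, nodes, mu, s, truncate_at_t00, t00,
        baseline=baseline, breaks=breaks,
    )
    g_warm = _event_warm_start(
        data, float(start.params["beta00"]), mu, truncate_at_t00, t00
    )
    theta0 = list(start.params[obj.beta_labels].to_numpy())
    theta0 += list(np.log(np.maximum(start.params[SIGMA_TERMS].to_numpy(), 1e-3)))
    if baseline == "weibull":
        theta0 += [g_warm[0], g_warm[1], g_warm[2], 0.0]
    else:
        theta0 += [g_warm[0]] * (len(obj.event_labels) - 2) + [g_warm[1], g_warm[2]]
    theta0 = np.asarray(theta0, float)

    # keep the variance components within e^±3 of the warm start: under a
    # degenerate generator (an exactly deterministic Y1 link) the joint
    # likelihood has a sigma -> 0 spike that a gradient optimizer would chase
    bounds: list[tuple] = [(None, None)] * theta0.size
    for i in range(obj.n_beta, obj.n_beta + 4):
        bounds[i] = (theta0[i] - 3.0, theta0[i] + 3.0)
    path = [-obj(theta0)[0]]
    res = optimize.minimize(
        obj,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        callback=lambda xk: path.append(-obj(xk)[0]),
        options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 5e-9},
    )
    theta_hat = res.x
    betas, sb, sigmas, event = obj.unpack(theta_hat)

    values = dict(zip(obj.beta_labels, theta_hat[: obj.n_beta]))
    values["sigma_b"] = sb
    for j, lab in enumerate(("sigma0", "sigma1", "sigma2")):
        values[lab] = sigmas[j]
    if baseline == "weibull":
        values["gamma0"] = event[0]
        values["gamma1"] = event[1]
        values["alpha"] = event[2]
        values["weibull_shape"] = float(np.exp(event[3]))
        event_report = EVENT_TERMS_WEIBULL
    else:
        m = len(obj.event_labels) - 2
        for jp in range(m):
            values[f"log_h0_{jp + 1}"] = event[jp]
        values["gamma1"] = event[m]
        values["alpha"] = event[m + 1]
        event_report = obj.event_labels
    order = obj.beta_labels + SIGMA_TERMS + event_report
    params = pd.Series({k: values[k] for k in order})

    # observed information via finite differences of the analytic gradient
    p = theta_hat.size
    h = 1e-5 * np.maximum(1.0, np.abs(theta_hat))
    H = np.empty((p, p))
    for i in range(p):
        tp = theta_hat.copy(); tp[i] += h[i]
        tm = theta_hat.copy(); tm[i] -= h[i]
        H[i] = (obj(tp)[1] - obj(tm)[1]) / (2 * h[i])
    H = 0.5 * (H + H.T)
    eigmin = float(np.linalg.eigvalsh(H).min())
    hess_pd = eigmin > 0
    cov = np.linalg.pinv(H)

    log_scale_sigma = ["sigma_b", "sigma0", "sigma1", "sigma2"]
    cov_labels = obj.beta_labels + log_scale_sigma + event_report
    cov_df = pd.DataFrame(cov, index=cov_labels, columns=cov_labels)
    log_scale = list(log_scale_sigma)
    if baseline == "weibull":
        log_scale.append("weibull_shape")  # estimated as log k
    se, ci = _wald(params.reindex(cov_labels), cov, level, log_scale=log_scale)

    fit = JointFit(
        params=params,
        se=se.reindex(order),
        conf_int=ci.reindex(order),
        cov=cov_df,
        loglik=-res.fun,
        converged=bool(res.success) and hess_pd,
        n_iter=int(res.nit),
        n=len(data),
        level=level,
        include_interactions=include_interactions,
        dropped_terms=[],
        loglik_path=path,
        nodes=nodes,
        baseline=baseline,
        tvmem_start=start,
    )
    if not hess_pd:
        fit.dropped_terms = [f"hessian_min_eigenvalue={eigmin:.3g}"]
    return fit
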