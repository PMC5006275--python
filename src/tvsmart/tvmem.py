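"""Time-varying mixed effects model (TVMEM): maximum likelihood for the three
stacked longitudinal submodels sharing one subject-level random intercept.

Marginally, each subject's outcome vector ``(Y0, Y1, Y2)`` is trivariate
normal with mean given by the stage-specific linear predictors and covariance
``sigma_b^2 * J + diag(sigma0^2, sigma1^2, sigma2^2)`` (J the all-ones
matrix).  The intervention durations ``T1`` and ``T2`` enter as fixed, known
covariates — the stance this model takes, and the one the joint model in
:mod:`tvsmart.joint` relaxes.

Fitting maximizes the exact marginal Gaussian likelihood: the mean
coefficients are profiled out by generalized least squares at each variance
iterate, and the four log-SD parameters are optimized by quasi-Newton
iteration from a method-of-moments start.  Standard errors come from the
inverse observed information (numerical Hessian of the full likelihood).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import DesignSpec

__all__ = [
    "DataError",
    "TvmemFit",
    "mean_design",
    "tvmem_loglik",
    "fit_tvmem",
    "empirical_bayes_b",
]


class DataError(ValueError):
    """The data cannot identify the requested model (e.g. an empty arm)."""


STAGE_TERMS = {
    0: ["beta00"],
    1: ["beta01", "beta11", "beta31"],
    2: ["beta02", "beta12", "beta22", "beta23", "beta32", "beta41", "beta42"],
}
SIGMA_TERMS = ["sigma_b", "sigma0", "sigma1", "sigma2"]


def mean_design(
    data: pd.DataFrame,
    include_interactions: bool = False,
    drop_constant_time: bool = True,
):
    """Stage design matrices ``(X0, X1, X2)`` and their coefficient labels.

    In standard-SMART data ``T1`` (and hence ``T2``) is the same for every
    subject, which makes the time columns collinear with the intercepts;
    with ``drop_constant_time`` they are dropped and reported in the fourth
    return value so callers can flag them as not estimable.
    """
    n = len(data)
    one = np.ones(n)
    a1 = data["A1"].to_numpy(float)
    a2r = data["A2R"].to_numpy(float)
    a2nr = data["A2NR"].to_numpy(float)
    t1 = data["T1"].to_numpy(float)
    t2 = data["T2"].to_numpy(float)

    cols1 = [("beta01", one), ("beta11", a1), ("beta31", t1)]
    cols2 = [
        ("beta02", one),
        ("beta12", a1),
        ("beta22", a2r),
        ("beta23", a2nr),
        ("beta32", t2),
    ]
    if include_interactions:
        cols2 += [("beta41", a1 * a2r), ("beta42", a1 * a2nr)]

    dropped: list[str] = []
    if drop_constant_time:
        if np.ptp(t1) == 0.0:
            cols1 = [c for c in cols1 if c[0] != "beta31"]
            dropped.append("beta31")
        if np.ptp(t2) == 0.0:
            cols2 = [c for c in cols2 if c[0] != "beta32"]
            dropped.append("beta32")
    # columns that are identically zero cannot be identified (e.g. A2R and
    # its interaction when the design never re-randomizes responders)
    for name, col in list(cols2):
        if name != "beta02" and not np.any(col):
            cols2 = [c for c in cols2 if c[0] != name]
            dropped.append(name)

    X0 = one[:, None]
    X1 = np.column_stack([c[1] for c in cols1])
    X2 = np.column_stack([c[1] for c in cols2])
    labels = (["beta00"], [c[0] for c in cols1], [c[0] for c in cols2])
    return (X0, X1, X2), labels, dropped


def _check_identifiable(data: pd.DataFrame) -> None:
    a1 = data["A1"].to_numpy()
    delta = data["delta"].to_numpy()
    if len(np.unique(a1)) < 2:
        raise DataError("both first-stage arms must be present")
    if delta.min() == delta.max():
        which = "non-responders" if delta.min() == 1 else "responders"
        raise DataError(f"no {which} in the data; the stage-2 model is singular")


def _omega(sigma_b: float, sigmas: np.ndarray):
    """Inverse and log-determinant of ``sigma_b^2 J + diag(sigmas^2)``."""
    d = 1.0 / sigmas**2
    c = d.sum()
    denom = 1.0 + sigma_b**2 * c
    omega = np.diag(d) - (sigma_b**2 / denom) * np.outer(d, d)
    logdet = float(np.sum(np.log(sigmas**2)) + np.log(denom))
    return omega, logdet


def _resid(Xs, betas_by_stage, data) -> np.ndarray:
    y = data[["Y0", "Y1", "Y2"]].to_numpy(float)
    r = np.empty_like(y)
    for j in range(3):
        r[:, j] = y[:, j] - Xs[j] @ betas_by_stage[j]
    return r


def _loglik_from_resid(r: np.ndarray, sigma_b: float, sigmas: np.ndarray) -> float:
    omega, logdet = _omega(sigma_b, sigmas)
    n = r.shape[0]
    quad = float(np.einsum("ij,jk,ik->", r, omega, r))
    return -0.5 * (3 * n * np.log(2 * np.pi) + n * logdet + quad)


def tvmem_loglik(params, data: pd.DataFrame, include_interactions: bool = False) -> float:
    """Exact marginal log-likelihood at labeled parameter values.

    *params* maps coefficient labels (``beta00`` ... ``beta42``, ``sigma_b``,
    ``sigma0..2``) to values on the natural scale (sigmas as SDs).  Labels
    absent from the mean model are ignored.
    """
    Xs, labels, dropped = mean_design(data, include_interactions, drop_constant_time=False)
    betas = [np.array([float(params[l]) for l in lab]) for lab in labels]
    r = _resid(Xs, betas, data)
    sigmas = np.array([float(params[s]) for s in ("sigma0", "sigma1", "sigma2")])
    if not np.all(np.isfinite(np.concatenate(betas))) or not np.all(np.isfinite(sigmas)):
        raise ValueError("non-finite parameter values")
    return _loglik_from_resid(r, float(params["sigma_b"]), sigmas)


def _gls(Xs, omega, y):
    """Profile GLS solve for the stage coefficients at a fixed covariance."""
    ps = [X.shape[1] for X in Xs]
    p = sum(ps)
    A = np.zeros((p, p))
    c = np.zeros(p)
    off = np.cumsum([0] + ps)
    for j in range(3):
        for l in range(3):
            blk = omega[j, l] * (Xs[j].T @ Xs[l])
            A[off[j]:off[j + 1], off[l]:off[l + 1]] += blk
            c[off[j]:off[j + 1]] += omega[j, l] * (Xs[j].T @ y[:, l])
    try:
        beta = np.linalg.solve(A, c)
    except np.linalg.LinAlgError as exc:
        raise DataError(f"singular mean design: {exc}") from exc
    return beta, off


def _moment_start(Xs, y):
    """Per-stage OLS coefficients and method-of-moments variance components."""
    betas = []
    resid = np.empty_like(y)
    for j in range(3):
        b, *_ = np.linalg.lstsq(Xs[j], y[:, j], rcond=None)
        betas.append(b)
        resid[:, j] = y[:, j] - Xs[j] @ b
    cov = np.cov(resid, rowvar=False)
    v = np.diag(cov)
    # clip so that no stage starts with a near-zero residual SD even when
    # the shared intercept explains almost all marginal variance
    sb2 = float(np.clip(np.mean([cov[0, 1], cov[0, 2], cov[1, 2]]), 1e-4, 0.9 * v.min()))
    s2 = np.maximum(v - sb2, 0.05 * v)
    return betas, np.sqrt(sb2), np.sqrt(s2), resid


@dataclass
class TvmemFit:
    """Result of a TVMEM (or joint-model) maximum-likelihood fit."""

    params: pd.Series
    se: pd.Series
    conf_int: pd.DataFrame
    cov: pd.DataFrame
    loglik: float
    converged: bool
    n_iter: int
    n: int
    level: float
    include_interactions: bool
    dropped_terms: list[str] = field(default_factory=list)
    loglik_path: list[float] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.params.index,
                "estimate": self.params.to_numpy(),
                "se": self.se.reindex(self.params.index).to_numpy(),
                "ci_low": self.conf_int["low"].reindex(self.params.index).to_numpy(),
                "ci_high": self.conf_int["high"].reindex(self.params.index).to_numpy(),
            }
        )

    def write_summary(self, path) -> None:
        self.summary_frame().to_csv(path, index=False)


def _wald(params: pd.Series, cov: np.ndarray, level: float, log_scale: list[str]):
    """SEs and Wald intervals; labels in *log_scale* were estimated as logs."""
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    est = params.to_numpy().astype(float)
    low = np.empty_like(est)
    high = np.empty_like(est)
    se_nat = np.empty_like(est)
    for i, lab in enumerate(params.index):
        if lab in log_scale:
            # delta method back to the SD scale; CI transformed from logs
            se_nat[i] = est[i] * se[i]
            low[i] = est[i] * np.exp(-z * se[i])
            high[i] = est[i] * np.exp(z * se[i])
        else:
            se_nat[i] = se[i]
            low[i] = est[i] - z * se[i]
            high[i] = est[i] + z * se[i]
    return (
        pd.Series(se_nat, index=params.index),
        pd.DataFrame({"low": low, "high": high}, index=params.index),
    )


def _numerical_hessian(f, x0: np.ndarray, step: float = 1e-4) -> np.ndarray:
    p = x0.size
    h = step * np.maximum(1.0, np.abs(x0))
    H = np.empty((p, p))
    f0 = f(x0)
    for i in range(p):
        for j in range(i, p):
            if i == j:
                xp = x0.copy(); xp[i] += h[i]
                xm = x0.copy(); xm[i] -= h[i]
                H[i, i] = (f(xp) - 2 * f0 + f(xm)) / h[i] ** 2
            else:
                xpp = x0.copy(); xpp[[i, j]] += [h[i], h[j]]
                xpm = x0.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
                xmp = x0.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
                xmm = x0.copy(); xmm[[i, j]] -= [h[i], h[j]]
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (
                    4 * h[i] * h[j]
                )
    return H


def fit_tvmem(
    data: pd.DataFrame,
    include_interactions: bool = False,
    level: float = 0.95,
    shared_resid_var: bool = False,
    fix_sigma_b: float | None = None,
    drop_constant_time: bool = True,
) -> TvmemFit:
    """Maximum-likelihood TVMEM fit with Wald inference.

    Parameters
    ----------
    data
        Trial data frame (one row per subject; see
        :data:`tvsmart.simulate.TRIALDATA_COLUMNS`).
    include_interactions
        Include the ``A1*A2R`` and ``A1*A2NR`` terms in the final-outcome
        submodel.
    shared_resid_var
        Collapse the three stage residual SDs to a single parameter.
    fix_sigma_b
        Fix the random-intercept SD instead of estimating it (0 gives
        independent per-stage regressions, which then reduce to OLS).
    """
    _check_identifiable(data)
    Xs, labels, dropped = mean_design(data, include_interactions, drop_constant_time)
    y = data[["Y0", "Y1", "Y2"]].to_numpy(float)
    betas0, sb0, s0, _ = _moment_start(Xs, y)

    estimate_sb = fix_sigma_b is None
    n_resid = 1 if shared_resid_var else 3

    def unpack(psi):
        k = 0
        if estimate_sb:
            sb = np.exp(psi[0]); k = 1
        else:
            sb = float(fix_sigma_b)
        s = np.exp(psi[k:k + n_resid])
        sigmas = np.repeat(s, 3) if shared_resid_var else s
        return sb, sigmas

    def profile_nll(psi):
        sb, sigmas = unpack(psi)
        omega, logdet = _omega(sb, sigmas)
        beta, off = _gls(Xs, omega, y)
        r = _resid(Xs, [beta[off[j]:off[j + 1]] for j in range(3)], data)
        return -_loglik_from_resid(r, sb, sigmas)

    psi0 = []
    if estimate_sb:
        psi0.append(np.log(max(sb0, 1e-3)))
    psi0 += list(np.log(np.maximum([np.mean(s0)] if shared_resid_var else s0, 1e-3)))
    psi0 = np.asarray(psi0)

    path: list[float] = [-profile_nll(psi0)]
    bounds = [(-7.0, 7.0)] * psi0.size
    opts = {"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8}
    res = optimize.minimize(
        profile_nll,
        psi0,
        method="L-BFGS-B",
        bounds=bounds,
        callback=lambda xk: path.append(-profile_nll(xk)),
        options=opts,
    )
    if not res.success:
        # restart from an even split of the marginal variances
        v = np.log(np.sqrt(np.maximum(y.var(axis=0), 1e-6) / 2.0))
        psi1 = ([np.mean(v)] if estimate_sb else []) + list(
            [np.mean(v)] if shared_resid_var else v
        )
        res2 = optimize.minimize(
            profile_nll, np.asarray(psi1), method="L-BFGS-B", bounds=bounds,
            callback=lambda xk: path.append(-profile_nll(xk)), options=opts,
        )
        if res2.success or res2.fun < res.fun:
            res = res2
    sb_hat, sigmas_hat = unpack(res.x)
    omega, _ = _omega(sb_hat, sigmas_hat)
    beta_hat, off = _gls(Xs, omega, y)

    beta_labels = labels[0] + labels[1] + labels[2]
    values = dict(zip(beta_labels, beta_hat))
    values["sigma_b"] = sb_hat
    for j, lab in enumerate(("sigma0", "sigma1", "sigma2")):
        values[lab] = sigmas_hat[j]
    order = beta_labels + SIGMA_TERMS
    params = pd.Series({k: values[k] for k in order})

    # observed information over the full parameter vector (log-SD scale for
    # the variance components; sigma_b excluded when fixed)
    free_sigma = ([] if not estimate_sb else ["sigma_b"]) + ["sigma0", "sigma1", "sigma2"]
    if shared_resid_var:
        free_sigma = ([] if not estimate_sb else ["sigma_b"]) + ["sigma0"]

    def full_nll(theta):
        bet = theta[: len(beta_labels)]
        rest = theta[len(beta_labels):]
        k = 0
        sb = float(fix_sigma_b) if not estimate_sb else np.exp(rest[0])
        if estimate_sb:
            k = 1
        s = np.exp(rest[k:])
        sigmas = np.repeat(s, 3) if shared_resid_var else s
        r = _resid(Xs, [bet[off[j]:off[j + 1]] for j in range(3)], data)
        return -_loglik_from_resid(r, sb, sigmas)

    theta_hat = np.concatenate(
        [beta_hat, np.log(np.maximum(
            [sb_hat] * estimate_sb + list(sigmas_hat[: n_resid]), 1e-10))]
    )
    H = _numerical_hessian(full_nll, theta_hat)
    cov_labels = beta_labels + free_sigma
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((len(cov_labels), len(cov_labels)), np.nan)

    # expand to the reported labels (shared residual SD repeats its column)
    cov_df = pd.DataFrame(cov, index=cov_labels, columns=cov_labels)
    se, ci = _wald(
        params.reindex(cov_labels), cov, level, log_scale=free_sigma
    )
    se = se.reindex(order)
    ci = ci.reindex(order)
    if shared_resid_var:
        for lab in ("sigma1", "sigma2"):
            se[lab] = se["sigma0"]
            ci.loc[lab] = ci.loc["sigma0"]
    if not estimate_sb:
        se["sigma_b"] = 0.0
        ci.loc["sigma_b"] = [fix_sigma_b, fix_sigma_b]

    return TvmemFit(
        params=params,
        se=se,
        conf_int=ci,
        cov=cov_df,
        loglik=-res.fun,
        converged=bool(res.success),
        n_iter=int(res.nit),
        n=len(data),
        level=level,
        include_interactions=include_interactions,
        dropped_terms=dropped,
        loglik_path=path,
    )


def empirical_bayes_b(params, data: pd.DataFrame, include_interactions: bool = False):
    """Posterior mean and SD of the random intercept given the outcomes.

    The posterior of ``b | (Y0, Y1, Y2)`` is Gaussian with precision
    ``1/sigma_b^2 + sum_j 1/sigma_j^2`` and mean proportional to the
    precision-weighted residual sum.  Used to warm-start and recentre the
    joint model's quadrature.
    """
    Xs, labels, _ = mean_design(data, include_interactions, drop_constant_time=False)
    betas = [np.array([float(params[l]) for l in lab]) for lab in labels]
    r = _resid(Xs, betas, data)
    sigmas = np.array([float(params[s]) for s in ("sigma0", "sigma1", "sigma2")])
    sb = float(params["sigma_b"])
    if sb <= 0:
        return np.zeros(len(data)), np.zeros(len(data))
    tau = 1.0 / sb**2 + np.sum(1.0 / sigmas**2)
    mean = (r / sigmas**2).sum(axis=1) / tau
    sd = np.full(len(data), 1.0 / np.sqrt(tau))
    return mean, sd
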