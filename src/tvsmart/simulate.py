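"""Trial data generators for time-varying and standard SMART designs.

Two mechanisms produce the first-stage duration ``T1``:

* :func:`simulate_trial_weibull` — ``T1`` is drawn from a left-truncated
  Weibull whose scale depends on the first-stage arm and the subject's latent
  baseline level ``m(0) = beta00 + b``; the intermediate residual is then
  rejection-sampled so the observed outcomes honour the responder rule.
* :func:`simulate_trial_boundary` — the intermediate outcome trajectory is
  monitored and ``T1`` is the first time it crosses a relative-improvement
  boundary (solved in closed form for the linear trajectory).

Both write one row per subject with columns
``id, Y0, A1, T1, delta, Y1, A2R, A2NR, T2, Y2`` (+ the latent intercept
``b``, kept for testing and dropped on export by default).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .design import DesignSpec

__all__ = [
    "GenParams",
    "TRIALDATA_COLUMNS",
    "sample_truncated_weibull",
    "simulate_trial",
    "simulate_trial_weibull",
    "simulate_trial_boundary",
    "write_trialdata",
    "read_trialdata",
    "validate_trialdata",
]

TRIALDATA_COLUMNS = ["id", "Y0", "A1", "T1", "delta", "Y1", "A2R", "A2NR", "T2", "Y2"]


@dataclass(frozen=True)
class GenParams:
    """Generative parameters for the three outcome submodels and the
    event-time model.

    Longitudinal means (shared random intercept ``b ~ N(0, sigma_b^2)``)::

        Y0 = beta00                                              + b + e0
        Y1 = beta01 + beta11*A1 + beta31*T1                      + b + e1
        Y2 = beta02 + beta12*A1 + beta22*A2R + beta23*A2NR
             + beta32*T2 + beta41*A1*A2R + beta42*A1*A2NR        + b + e2

    with ``e_j ~ N(0, sigma_j^2)``.  The event-time generator draws ``T1``
    from a Weibull with shape ``weibull_shape`` and *scale*
    ``exp{gamma0 + gamma1*A1 + alpha*m(0)}`` left-truncated at ``t00``,
    where ``m(0) = beta00 + b`` is the latent (error-free) baseline.
    """

    beta00: float = 10.0
    beta01: float = 1.0
    beta11: float = 0.2
    beta31: float = 0.1
    beta02: float = 0.0
    beta12: float = 0.4
    beta22: float = 0.5
    beta23: float = 0.5
    beta32: float = 2.0
    beta41: float = 0.0
    beta42: float = 0.0
    sigma_b: float = 5.0
    sigma0: float = 4.0
    sigma1: float = 5.0
    sigma2: float = 5.0
    gamma0: float = -1.5
    gamma1: float = 0.4
    alpha: float = 0.25
    weibull_shape: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sigma_b", "sigma0", "sigma1", "sigma2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be > 0")

    def truth(self, include_interactions: bool) -> dict[str, float]:
        """Generating values keyed by coefficient label (for MSE/coverage)."""
        out = {
            "beta00": self.beta00,
            "beta01": self.beta01,
            "beta11": self.beta11,
            "beta31": self.beta31,
            "beta02": self.beta02,
            "beta12": self.beta12,
            "beta22": self.beta22,
            "beta23": self.beta23,
            "beta32": self.beta32,
            "sigma_b": self.sigma_b,
            "sigma0": self.sigma0,
            "sigma1": self.sigma1,
            "sigma2": self.sigma2,
        }
        if include_interactions:
            out["beta41"] = self.beta41
            out["beta42"] = self.beta42
        return out


def sample_truncated_weibull(shape, scale, t00, rng, size=None):
    """Draw from Weibull(shape, scale) conditioned on exceeding ``t00``.

    The scale convention is ``S(t) = exp{-(t/scale)^shape}``.  Uses the
    inverse CDF of the conditional distribution:
    ``T = scale * ((t00/scale)^shape - log(1-U))^(1/shape)``.

    ``shape`` and ``scale`` may be arrays (broadcast against ``size``).
    """
    shape = np.asarray(shape, dtype=float)
    scale = np.asarray(scale, dtype=float)
    if np.any(shape <= 0) or np.any(scale <= 0):
        raise ValueError("shape and scale must be positive")
    if t00 < 0:
        raise ValueError("t00 must be >= 0")
    u = rng.uniform(size=size)
    # conditional survival: S(t)/S(t00) = exp{ (t00/scale)^shape - (t/scale)^shape }
    return scale * ((t00 / scale) ** shape - np.log1p(-u)) ** (1.0 / shape)


def _second_stage(delta, design: DesignSpec, rng) -> tuple[np.ndarray, np.ndarray]:
    """Draw (A2R, A2NR) given response status under *design*."""
    n = delta.size
    a2r = np.zeros(n, dtype=int)
    a2nr = np.zeros(n, dtype=int)
    resp = delta == 1
    if design.rerandomizes_responders:
        a2r[resp] = np.where(rng.uniform(size=int(resp.sum())) < design.p_stage2_resp, 1, -1)
    a2nr[~resp] = np.where(
        rng.uniform(size=int((~resp).sum())) < design.p_stage2_nonresp, 1, -1
    )
    return a2r, a2nr


def _assemble(design, params, b, y0, a1, t1, delta, y1, rng) -> pd.DataFrame:
    a2r, a2nr = _second_stage(delta, design, rng)
    t2 = t1 + design.delta_t
    n = b.size
    eps2 = rng.normal(0.0, params.sigma2, size=n)
    y2 = (
        params.beta02
        + params.beta12 * a1
        + params.beta22 * a2r
        + params.beta23 * a2nr
        + params.beta32 * t2
        + params.beta41 * a1 * a2r
        + params.beta42 * a1 * a2nr
        + b
        + eps2
    )
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "Y0": y0,
            "A1": a1,
            "T1": t1,
            "delta": delta,
            "Y1": y1,
            "A2R": a2r,
            "A2NR": a2nr,
            "T2": t2,
            "Y2": y2,
            "b": b,
        }
    )


def _responder_ok(y0, y1, delta, design: DesignSpec) -> np.ndarray:
    """Does (Y0, Y1) satisfy the responder rule implied by delta?"""
    if design.responder_rule == "absolute_drop":
        responded = y0 - y1 >= design.threshold
    else:
        responded = y1 <= (1.0 - design.threshold) * y0
    return np.where(delta == 1, responded, ~responded)


def simulate_trial_weibull(
    design: DesignSpec,
    params: GenParams,
    n: int,
    rng: np.random.Generator,
    max_rejection: int = 1_000_000,
) -> pd.DataFrame:
    """Simulate a complete trial with Weibull first-stage durations.

    Per subject: ``b ~ N(0, sigma_b^2)``; ``Y0`` from its submodel; ``A1``
    randomized; ``T1`` from the left-truncated Weibull with scale
    ``exp{gamma0 + gamma1*A1 + alpha*(beta00 + b)}``, censored at ``t10``
    (``delta = 1{T1 < t10}``); the intermediate residual ``e1`` is
    rejection-sampled until the responder rule matches ``delta``; second
    stage randomized per *design*; ``Y2`` from its submodel with fresh noise.

    For *standard* variants ``T1 = t10`` for everyone, ``e1`` is drawn once
    and ``delta`` comes from applying the responder rule at ``t10``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    b = rng.normal(0.0, params.sigma_b, size=n)
    y0 = params.beta00 + b + rng.normal(0.0, params.sigma0, size=n)
    a1 = np.where(rng.uniform(size=n) < design.p_stage1, 1, -1)
    m0 = params.beta00 + b

    if design.time_varying:
        scale = np.exp(params.gamma0 + params.gamma1 * a1 + params.alpha * m0)
        t1_star = sample_truncated_weibull(
            params.weibull_shape, scale, design.t00, rng, size=n
        )
        delta = (t1_star < design.t10).astype(int)
        t1 = np.where(delta == 1, t1_star, design.t10)
        y1_mean = params.beta01 + params.beta11 * a1 + params.beta31 * t1 + b
        eps1 = rng.normal(0.0, params.sigma1, size=n)
        ok = _responder_ok(y0, y1_mean + eps1, delta, design)
        tries = 1
        while not ok.all():
            if tries >= max_rejection:
                raise RuntimeError(
                    "rejection sampling of the intermediate residual did not "
                    f"accept within {max_rejection} tries; the responder "
                    "threshold is infeasible for these variances"
                )
            bad = ~ok
            eps1[bad] = rng.normal(0.0, params.sigma1, size=int(bad.sum()))
            ok[bad] = _responder_ok(y0[bad], y1_mean[bad] + eps1[bad], delta[bad], design)
            tries += 1
        y1 = y1_mean + eps1
    else:
        t1 = np.full(n, design.t10)
        y1 = (
            params.beta01
            + params.beta11 * a1
            + params.beta31 * design.t10
            + b
            + rng.normal(0.0, params.sigma1, size=n)
        )
        if design.responder_rule == "absolute_drop":
            delta = (y0 - y1 >= design.threshold).astype(int)
        else:
            delta = (y1 <= (1.0 - design.threshold) * y0).astype(int)

    return _assemble(design, params, b, y0, a1, t1, delta, y1, rng)


def simulate_trial_boundary(
    design: DesignSpec,
    params: GenParams,
    n: int,
    rng: np.random.Generator,
    literal_clamp: bool = False,
) -> pd.DataFrame:
    """Simulate a trial where ``T1`` is the boundary-crossing time of the
    monitored intermediate trajectory.

    The responder rule must be ``relative_drop`` with fraction ``f``; the
    crossing time solves ``beta01 + beta11*A1 + beta31*T1* + b + e1 =
    (1-f)*Y0`` for a single draw of ``e1``.  Crossings before ``t00`` are
    moved to ``t00`` (still responders); trajectories that have not crossed
    by ``t10`` are censored there (``T1 = t10``, ``delta = 0``).

    ``literal_clamp=True`` reproduces the printed-but-inconsistent rule that
    also maps late crossings to ``t00`` (audit only; it breaks the
    ``delta``/``T1`` invariant deliberately).
    """
    if design.responder_rule != "relative_drop":
        raise ValueError("boundary generator requires responder_rule='relative_drop'")
    if params.beta31 == 0:
        raise ValueError("beta31 must be nonzero for a boundary crossing to exist")
    if n < 1:
        raise ValueError("n must be >= 1")
    b = rng.normal(0.0, params.sigma_b, size=n)
    y0 = params.beta00 + b + rng.normal(0.0, params.sigma0, size=n)
    a1 = np.where(rng.uniform(size=n) < design.p_stage1, 1, -1)
    eps1 = rng.normal(0.0, params.sigma1, size=n)
    target = (1.0 - design.threshold) * y0
    t1_star = (target - params.beta01 - params.beta11 * a1 - b - eps1) / params.beta31

    if design.time_varying:
        late = t1_star > design.t10
        t1 = np.clip(t1_star, design.t00, design.t10)
        if literal_clamp:
            t1 = np.where(late, design.t00, t1)
        delta = np.where(late, 0, 1).astype(int)
    else:
        t1 = np.full(n, design.t10)
        delta = (t1_star <= design.t10).astype(int)

    y1 = params.beta01 + params.beta11 * a1 + params.beta31 * t1 + b + eps1
    return _assemble(design, params, b, y0, a1, t1, delta, y1, rng)


def simulate_trial(
    design: DesignSpec,
    params: GenParams,
    n: int,
    rng: np.random.Generator,
    mechanism: str = "weibull",
    **kwargs,
) -> pd.DataFrame:
    """Dispatch to the Weibull or boundary-crossing generator."""
    if mechanism == "weibull":
        return simulate_trial_weibull(design, params, n, rng, **kwargs)
    if mechanism == "boundary":
        return simulate_trial_boundary(design, params, n, rng, **kwargs)
    raise ValueError(f"unknown mechanism {mechanism!r}")


def validate_trialdata(data: pd.DataFrame, design: DesignSpec) -> None:
    """Raise if *data* violates a structural trial-data invariant."""
    missing = [c for c in TRIALDATA_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"trial data missing columns {missing}")
    delta = data["delta"].to_numpy()
    t1 = data["T1"].to_numpy()
    if not np.array_equal(np.isin(delta, [0, 1]), np.ones(len(data), bool)):
        raise ValueError("delta must be 0/1")
    if np.any((delta == 0) & (t1 != design.t10)):
        raise ValueError("non-responders must have T1 = t10")
    if np.any((delta == 1) & (t1 >= design.t10)) and design.time_varying:
        raise ValueError("responders must have T1 < t10 in a time-varying design")
    if np.any((delta == 1) & (data["A2NR"].to_numpy() != 0)):
        raise ValueError("responders must have A2NR = 0")
    if np.any((delta == 0) & (data["A2R"].to_numpy() != 0)):
        raise ValueError("non-responders must have A2R = 0")
    if not design.rerandomizes_responders and np.any(data["A2R"].to_numpy() != 0):
        raise ValueError("nonresp_rerand designs must have A2R = 0 everywhere")
    if not np.allclose(data["T2"].to_numpy(), t1 + design.delta_t):
        raise ValueError("T2 must equal T1 + delta_t")


def write_trialdata(data: pd.DataFrame, path, keep_latent: bool = False) -> None:
    cols = TRIALDATA_COLUMNS + (["b"] if keep_latent and "b" in data.columns else [])
    data[cols].to_csv(path, index=False)


def read_trialdata(path) -> pd.DataFrame:
    data = pd.read_csv(path)
    missing = [c for c in TRIALDATA_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"{path}: missing trial-data columns {missing}")
    return data
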