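"""Trial designs for two-stage SMARTs with subject-specific re-randomization times.

Two families of designs are supported, each in a *time-varying* and a
*standard* flavour:

* ``full_rerand``: every participant is re-randomized at the end of the first
  stage — responders between "continue" (+1) and "reduce intensity" (-1),
  non-responders between "intensify" (+1) and "augment with the other
  intervention" (-1).
* ``nonresp_rerand``: only non-responders are re-randomized; responders
  always continue their first-stage intervention.

In the time-varying flavour a responder moves to the second stage at the
random time ``T1`` at which the intermediate outcome first satisfies the
responder rule (monitoring starts at ``t00``); non-responders are censored at
``t10``.  In the standard flavour everyone is re-randomized at the fixed time
``t10`` and response status is assessed there.

Arm coding: ``A1 = -1`` medication (M), ``+1`` behavioral (B).  ``A2R`` codes
the responder options (+1 continue / -1 reduce), ``A2NR`` the non-responder
options (+1 intensify / -1 augment); 0 means "not applicable" (``A2R = 0``
for non-responders and vice versa).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "DesignSpec",
    "EmbeddedAI",
    "VARIANTS",
    "enumerate_embedded_ais",
    "subject_consistent_with_ai",
]

VARIANTS = (
    "full_rerand_timevarying",
    "nonresp_rerand_timevarying",
    "full_rerand_standard",
    "nonresp_rerand_standard",
)

RESPONDER_RULES = ("absolute_drop", "relative_drop")


@dataclass(frozen=True)
class DesignSpec:
    """Configuration of one SMART design.

    Parameters
    ----------
    variant
        One of :data:`VARIANTS`.
    p_stage1
        Probability that ``A1 = +1`` (behavioral arm) at the first
        randomization.
    p_stage2_resp
        Probability that ``A2R = +1`` among responders (ignored for
        ``nonresp_rerand`` variants, where responders keep ``A2R = 0``).
    p_stage2_nonresp
        Probability that ``A2NR = +1`` among non-responders.
    t00, t10
        Monitoring start and maximum first-stage duration (the censoring /
        fixed re-randomization time), ``0 < t00 < t10``.
    delta_t
        Fixed second-stage duration; ``T2 = T1 + delta_t``.
    responder_rule
        ``absolute_drop``: responder iff ``Y0 - Y1 >= threshold``;
        ``relative_drop``: responder iff ``Y1 <= (1 - threshold) * Y0``.
    threshold
        Drop size C (outcome units) for ``absolute_drop``; fraction in (0,1)
        for ``relative_drop``.
    """

    variant: str = "full_rerand_timevarying"
    p_stage1: float = 0.5
    p_stage2_resp: float = 0.5
    p_stage2_nonresp: float = 0.5
    t00: float = 0.1
    t10: float = 1.0
    delta_t: float = 1.0
    responder_rule: str = "absolute_drop"
    threshold: float = 9.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown design variant {self.variant!r}; expected one of {VARIANTS}")
        if self.responder_rule not in RESPONDER_RULES:
            raise ValueError(f"unknown responder_rule {self.responder_rule!r}")
        for name in ("p_stage1", "p_stage2_resp", "p_stage2_nonresp"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {p}")
        if not 0.0 < self.t00 < self.t10:
            raise ValueError(f"need 0 < t00 < t10, got t00={self.t00}, t10={self.t10}")
        if self.delta_t <= 0.0:
            raise ValueError(f"delta_t must be > 0, got {self.delta_t}")
        if self.responder_rule == "relative_drop" and not 0.0 < self.threshold < 1.0:
            raise ValueError("relative_drop threshold must be a fraction in (0, 1)")

    @property
    def rerandomizes_responders(self) -> bool:
        return self.variant.startswith("full_rerand")

    @property
    def time_varying(self) -> bool:
        return self.variant.endswith("timevarying")

    def standard_analog(self) -> "DesignSpec":
        """The standard SMART with the same arms, probabilities and times."""
        base = self.variant.split("_timevarying")[0].split("_standard")[0]
        return DesignSpec(
            variant=f"{base}_standard",
            p_stage1=self.p_stage1,
            p_stage2_resp=self.p_stage2_resp,
            p_stage2_nonresp=self.p_stage2_nonresp,
            t00=self.t00,
            t10=self.t10,
            delta_t=self.delta_t,
            responder_rule=self.responder_rule,
            threshold=self.threshold,
        )


@dataclass(frozen=True, order=True)
class EmbeddedAI:
    """One adaptive intervention embedded in a SMART design.

    ``a1`` is the first-stage arm; ``a2r`` the responder option (``None``
    when the design never re-randomizes responders); ``a2nr`` the
    non-responder option.
    """

    a1: int
    a2r: Optional[int] = field(default=None)
    a2nr: int = field(default=1)

    def __post_init__(self) -> None:
        if self.a1 not in (-1, 1) or self.a2nr not in (-1, 1):
            raise ValueError("a1 and a2nr must be -1 or +1")
        if self.a2r is not None and self.a2r not in (-1, 1):
            raise ValueError("a2r must be -1, +1 or None")

    def astuple(self) -> tuple:
        if self.a2r is None:
            return (self.a1, self.a2nr)
        return (self.a1, self.a2r, self.a2nr)

    def __str__(self) -> str:  # e.g. "(-1,+1,+1)"
        return "(" + ",".join(f"{v:+d}" for v in self.astuple()) + ")"


def enumerate_embedded_ais(design: DesignSpec) -> list[EmbeddedAI]:
    """All adaptive interventions embedded in *design*, in a fixed order.

    ``full_rerand`` variants embed the 8 combinations of
    ``(a1, a2r, a2nr)``; ``nonresp_rerand`` variants embed the 4 combinations
    of ``(a1, a2nr)``.  Order is lexicographic with -1 before +1, keys
    ordered ``(a1, a2r, a2nr)``.
    """
    out: list[EmbeddedAI] = []
    if design.rerandomizes_responders:
        for a1 in (-1, 1):
            for a2r in (-1, 1):
                for a2nr in (-1, 1):
                    out.append(EmbeddedAI(a1, a2r, a2nr))
    else:
        for a1 in (-1, 1):
            for a2nr in (-1, 1):
                out.append(EmbeddedAI(a1, None, a2nr))
    return out


def subject_consistent_with_ai(record, ai: EmbeddedAI, design: DesignSpec) -> bool:
    """Whether a subject's realized path is consistent with *ai*.

    A record is consistent when its first-stage arm matches ``a1`` and the
    second-stage option it actually received matches the option *ai* dictates
    for its response status.  The counterfactual branch (the option for the
    status the subject did not have) is unconstrained, so under a
    ``full_rerand`` design every record is consistent with exactly two of the
    eight embedded AIs.

    *record* is any mapping with keys ``A1``, ``delta``, ``A2R``, ``A2NR``
    (e.g. a DataFrame row).
    """
    if design.rerandomizes_responders == (ai.a2r is None):
        raise ValueError(
            f"AI arity {ai} does not match design variant {design.variant!r}"
        )
    if int(record["A1"]) != ai.a1:
        return False
    if int(record["delta"]) == 1:  # responder
        if ai.a2r is None:
            return True  # responders always continue; no constraint
        return int(record["A2R"]) == ai.a2r
    return int(record["A2NR"]) == ai.a2nr
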