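"""Mediation E-value: sensitivity of an effect to unmeasured confounding.

The E-value is the minimum strength of association, on the risk-ratio scale,
that an unmeasured confounder would need with both the exposure (or
mediator) and the outcome to explain away an observed association. A
continuous-outcome effect in log-outcome units is first converted to an
approximate risk ratio through the standardized difference d = beta / sd(Y)
and RR = exp(0.91 d), the standard conversion of the E-value methodology for
continuous outcomes; RR < 1 is inverted before evaluating

    E = RR + sqrt(RR * (RR - 1)),   RR >= 1.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["EvalueResult", "effect_to_rr", "evalue", "mediation_evalue"]


@dataclass(frozen=True)
class EvalueResult:
    rr: float
    evalue_point: float
    evalue_ci: float  # E-value for the CI bound closer to the null


def effect_to_rr(beta: float, sd_y: float) -> float:
    """Approximate risk ratio for a continuous-outcome effect: exp(0.91 beta/sd)."""
    if sd_y <= 0:
        raise ValueError("outcome standard deviation must be positive")
    return math.exp(0.91 * beta / sd_y)


def evalue(rr: float) -> float:
    """E-value of a risk ratio; RR < 1 is inverted first."""
    if rr <= 0:
        raise ValueError(f"risk ratio must be positive, got {rr}")
    if rr < 1.0:
        rr = 1.0 / rr
    return rr + math.sqrt(rr * (rr - 1.0))


def mediation_evalue(
    beta: float, se: float, sd_y: float, z: float = 1.959963984540054
) -> EvalueResult:
    """E-values for a point estimate and its CI bound closer to the null.

    If the confidence interval crosses the null the CI E-value is 1 (no
    unmeasured confounding is needed to move the interval to the null).
    """
    rr = effect_to_rr(beta, sd_y)
    lo, hi = beta - z * se, beta + z * se
    if lo <= 0.0 <= hi:
        e_ci = 1.0
    else:
        bound = lo if beta > 0 else hi
        e_ci = evalue(effect_to_rr(bound, sd_y))
    return EvalueResult(rr=rr, evalue_point=evalue(rr), evalue_ci=e_ci)
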