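"""Sample-size estimation for a paired diagnostic design.

Both indices are applied to the same subjects, so the calculation is the
McNemar-type paired-proportions formula driven by the discordant mass
psi = p1 + p2 - 2p, with effect d = p1 - p2 derived from a pilot 2x2
table (index-positive vs outcome-positive)."""
from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats as _st

from .afs import ValidationError
from .roc import TwoByTwoTable

__all__ = ["SampleSizeInput", "derived_quantities", "required_n"]


@dataclass(frozen=True)
class SampleSizeInput:
    pilot: TwoByTwoTable
    alpha: float = 0.05
    power: float = 0.90

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")
        if not 0.0 < self.power < 1.0:
            raise ValidationError("power must be in (0, 1)")
        if self.pilot.n == 0:
            raise ValidationError("pilot table is empty")


def derived_quantities(pilot: TwoByTwoTable) -> dict[str, float]:
    """Proportions derived from the pilot table.

    p1 = (a+b)/N (index-positive), p2 = (a+c)/N (outcome-positive),
    p = a/N (both), p_bar = (p1 + p2 - 2p)/2, d = p1 - p2,
    psi = p1 + p2 - 2p (the discordant mass, = 2 p_bar).
    """
    n = pilot.n
    p1 = (pilot.a + pilot.b) / n
    p2 = (pilot.a + pilot.c) / n
    p = pilot.a / n
    psi = p1 + p2 - 2.0 * p
    return {
        "p1": p1,
        "p2": p2,
        "p": p,
        "p_bar": psi / 2.0,
        "d": p1 - p2,
        "psi": psi,
    }


def required_n(inp: SampleSizeInput) -> int:
    """Required paired sample size, ceiled to an integer.

    n = ceil( (z_{1-a/2} sqrt(psi) + z_{1-b} sqrt(psi - d^2))^2 / d^2 ).
    z-quantiles are used at full double precision.
    """
    q = derived_quantities(inp.pilot)
    d, psi = q["d"], q["psi"]
    if d == 0.0:
        raise ValidationError("p1 == p2: effect size is zero")
    if psi <= d * d:
        raise ValidationError(
            "formula domain violated: discordant mass psi <= d^2"
        )
    z_alpha = float(_st.norm.ppf(1.0 - inp.alpha / 2.0))
    z_beta = float(_st.norm.ppf(inp.power))
    n = (z_alpha * math.sqrt(psi) + z_beta * math.sqrt(psi - d * d)) ** 2 / (
        d * d
    )
    return math.ceil(n)
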