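"""Closed-form Schoenfeld sample-size / minimum-detectable-HR comparator.

For a binary covariate with prevalence ``p`` in a proportional-hazards model,
the events requirement at two-sided level ``alpha`` and power ``1 - beta`` is

    d = (z_{1-alpha/2} + z_power)^2 / (p (1-p) (log HR)^2)

and, inverted at a fixed number of events, the minimum detectable hazard
ratio is

    MDHR = exp( (z_{1-alpha/2} + z_power) / sqrt(d p (1-p)) ).

This conventional calculation assumes continuous event-time ascertainment,
no measurement error and no unmeasured heterogeneity; its MDHR is therefore
a lower bound on what the simulation engine reports for matched scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

from scipy import stats

__all__ = [
    "SchoenfeldInputs",
    "schoenfeld_required_events",
    "schoenfeld_mdhr",
]


@dataclass(frozen=True)
class SchoenfeldInputs:
    events: float
    prevalence: float
    alpha: float
    power: float

    def __post_init__(self) -> None:
        if not self.events > 0:
            raise ValueError("events must be > 0")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")


def _z_sum(alpha: float, power: float) -> float:
    # isf keeps full double precision for tiny alpha (e.g. 5e-8 two-sided)
    return float(stats.norm.isf(alpha / 2) + stats.norm.isf(1 - power))


def schoenfeld_required_events(
    log_hr: float, prevalence: float, alpha: float, power: float
) -> float:
    """Required number of events to detect ``log_hr`` for a binary covariate."""
    if log_hr == 0:
        raise ValueError("log_hr must be nonzero (null effect needs infinite events)")
    SchoenfeldInputs(1.0, prevalence, alpha, power)  # validate shared fields
    z = _z_sum(alpha, power)
    return z**2 / (prevalence * (1 - prevalence) * log_hr**2)


def schoenfeld_mdhr(inputs: SchoenfeldInputs) -> float:
    """Minimum detectable hazard ratio at a fixed expected event count."""
    z = _z_sum(inputs.alpha, inputs.power)
    return math.exp(z / math.sqrt(inputs.events * inputs.prevalence * (1 - inputs.prevalence)))
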