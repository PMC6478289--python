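"""Decompose sexual size dimorphism into rate vs duration contributions.

Under free larval growth, cube-root mass increases linearly:
m(d) = (m0^(1/3) + g·d)^3 with allometric rate g.  Two counterfactual
projections quantify how much of the female:male mass ratio a small
rate difference versus one extra day of growth can generate:

* rate scenario — both sexes start at a common mass m0 and grow for the
  same number of days, but at their own rates g_F and g_M;
* duration scenario — a single rate g, with the female growing
  ``extra_days`` longer.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class DecompositionResult:
    """Projected female:male mass ratios from the two scenarios."""

    ratio_from_rate_diff: float
    ratio_from_extra_day: float
    m0: float
    g_F: float
    g_M: float
    days: float
    extra_days: float


def project_mass(m0: float, g: float, days: float) -> float:
    """Mass after ``days`` of cubic-scale growth: (m0^(1/3) + g·days)^3."""
    if m0 <= 0:
        raise ValueError("m0 must be strictly positive")
    if days < 0:
        raise ValueError("days must be non-negative")
    return (m0 ** (1.0 / 3.0) + g * days) ** 3


def ratio_from_rate_difference(m0: float, g_F: float, g_M: float,
                               days: float) -> float:
    """Mass ratio generated by a rate difference over a shared period."""
    if g_F <= 0 or g_M <= 0:
        raise ValueError("rates must be strictly positive")
    return project_mass(m0, g_F, days) / project_mass(m0, g_M, days)


def ratio_from_extra_day(m0: float, g: float, days: float,
                         extra_days: float) -> float:
    """Mass ratio generated by growing ``extra_days`` longer at rate g."""
    if g <= 0:
        raise ValueError("rate must be strictly positive")
    if extra_days < 0:
        raise ValueError("extra_days must be non-negative")
    return project_mass(m0, g, days + extra_days) / project_mass(m0, g, days)


def decompose_ssd(m0: float = 25.30, g_F: float = 0.279, g_M: float = 0.270,
                  days: float = 5, extra_days: float = 1) -> DecompositionResult:
    """Both scenario ratios at once.

    Defaults: the male mean initial mass as the common start, the
    sex-specific allometric rates, five free-growth days, one extra day.
    """
    return DecompositionResult(
        ratio_from_rate_diff=ratio_from_rate_difference(m0, g_F, g_M, days),
        ratio_from_extra_day=ratio_from_extra_day(m0, g_M, days, extra_days),
        m0=m0, g_F=g_F, g_M=g_M, days=days, extra_days=extra_days,
    )
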