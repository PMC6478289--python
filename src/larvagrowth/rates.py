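"""Differential (instantaneous) growth-rate indices, plus integral ones.

Three indices are computed from the two masses bounding a 24 h period:

* absolute — the raw increment, m_end − m_start (mg·day^-1), strongly
  size-dependent;
* relative — log10(m_end / m_start) (day^-1), assumes exponential
  growth and declines with larval size;
* allometric — m_end^(1/3) − m_start^(1/3) (mg^(1/3)·day^-1), constant
  across sizes under cubic growth and hence the index that separates
  sex from size.

Day-specific rates are computed over the free-growth window (days 2–5
by default; day 1 is excluded because its gain is dominated by gut
filling).  Each rate record carries a size covariate: the mass recorded
one day *before* the 24 h period, so regression of rate on size shares
no measurement with the rate itself.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .features import FeatureRow
from .trajectory import TrajectoryTable

MEASURES = ("absolute", "relative", "allometric")
DEFAULT_WINDOW = (2, 3, 4, 5)
INTEGRAL_VARIANTS = ("pupa_over_total_time", "pupa_over_instar_time",
                     "log_pupa_over_total_time")


def _check_masses(m_start: float, m_end: float) -> None:
    if m_start <= 0 or m_end <= 0:
        raise ValueError("masses must be strictly positive")


def absolute_rate(m_start: float, m_end: float) -> float:
    """Absolute 24 h mass increment (mg·day^-1)."""
    _check_masses(m_start, m_end)
    return m_end - m_start


def relative_rate(m_start: float, m_end: float, base: str = "log10") -> float:
    """Relative growth rate over 24 h (day^-1).

    log10 by default; ``base="ln"`` gives the natural-log variant.
    """
    _check_masses(m_start, m_end)
    if base == "log10":
        return math.log10(m_end / m_start)
    if base == "ln":
        return math.log(m_end / m_start)
    raise ValueError(f"unknown log base {base!r}")


def allometric_rate(m_start: float, m_end: float) -> float:
    """Allometric growth rate: 24 h gain in cube-root mass (mg^(1/3)·day^-1)."""
    _check_masses(m_start, m_end)
    return m_end ** (1.0 / 3.0) - m_start ** (1.0 / 3.0)


_RATE_FUNCS = {"absolute": absolute_rate,
               "relative": relative_rate,
               "allometric": allometric_rate}


def rate_table(table: TrajectoryTable,
               window=DEFAULT_WINDOW,
               measures=MEASURES) -> pd.DataFrame:
    """Long table of day-specific rate records.

    One row per (individual, day, measure) for which both bounding
    masses exist.  ``covariate_mass`` is the mass of day d−2 (the
    initial mass for d = 2), NaN when unrecorded.
    """
    window = sorted(set(int(d) for d in window))
    if not window:
        raise ValueError("window must contain at least one day")
    if window[0] < 1:
        raise ValueError("window days must be >= 1")
    bad = set(measures) - set(MEASURES)
    if bad:
        raise ValueError(f"unknown measures: {sorted(bad)}")
    rows = []
    for t in table:
        for d in window:
            m_start, m_end = t.mass_on_day(d - 1), t.mass_on_day(d)
            if math.isnan(m_start) or math.isnan(m_end):
                continue
            cov = t.mass_on_day(d - 2)
            for meas in measures:
                rows.append({
                    "individual_id": t.individual_id, "sex": t.sex,
                    "brood_id": t.brood_id, "host": t.host, "day": d,
                    "measure": meas, "value": _RATE_FUNCS[meas](m_start, m_end),
                    "covariate_mass": cov,
                })
    return pd.DataFrame(rows, columns=["individual_id", "sex", "brood_id",
                                       "host", "day", "measure", "value",
                                       "covariate_mass"])


def integral_rate(feature: FeatureRow, variant: str) -> float:
    """Whole-phase growth rate from a feature row.

    ``pupa_over_total_time`` — pupal mass over (time to the last instar
    + instar duration); ``pupa_over_instar_time`` — pupal mass over the
    instar duration; ``log_pupa_over_total_time`` — log10 pupal mass
    over total time.
    """
    if variant not in INTEGRAL_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    total = feature.time_to_instar5 + feature.instar_duration
    if variant == "pupa_over_total_time":
        denom = total
    elif variant == "pupa_over_instar_time":
        denom = feature.instar_duration
    else:
        denom = total
    if denom <= 0:
        raise ValueError("development time must be strictly positive")
    if variant == "log_pupa_over_total_time":
        return math.log10(feature.pupal_mass) / denom
    return feature.pupal_mass / denom


def mean_daily_mass_factor(records: pd.DataFrame, how: str = "arithmetic") -> pd.Series:
    """Per-sex average daily fold-change in mass over the rate window.

    ``arithmetic`` averages the daily ratios 10**rate directly;
    ``geometric`` back-transforms the mean relative rate.  Expects a
    rate table filtered to measure == "relative".
    """
    rel = records[records["measure"] == "relative"]
    if rel.empty:
        raise ValueError("no relative-rate records")
    if how == "arithmetic":
        return (10.0 ** rel["value"]).groupby(rel["sex"]).mean()
    if how == "geometric":
        return 10.0 ** rel.groupby("sex")["value"].mean()
    raise ValueError(f"unknown summary {how!r}")
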