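"""Growth-curve descriptors of the last instar, summarized by sex.

The descriptor set mirrors the classical description of a larval growth
trajectory: initial mass at the moult, maximal mass and the day it was
reached, final feeding-stage mass, pupal mass, instar duration, the mass
ratios linking them, and the absolute 24 h mass increments of days 2–9.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import Trajectory, TrajectoryTable

INCREMENT_DAYS = range(2, 10)  # absolute increments reported for days 2..9


@dataclass
class FeatureRow:
    """Growth-curve descriptors for one larva."""

    individual_id: str
    sex: str
    brood_id: str
    host: str
    time_to_instar5: float
    initial_mass: float
    maximal_mass: float
    pupal_mass: float
    final_larval_mass: float
    instar_duration: int
    ratio_pupa_initial: float
    ratio_max_initial: float
    ratio_max_final: float
    time_to_max: int
    abs_increments: dict[int, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "abs_increments"}
        for day in INCREMENT_DAYS:
            d[f"abs_increment_day_{day}"] = self.abs_increments.get(day, math.nan)
        return d


def extract_features(traj: Trajectory) -> FeatureRow:
    """Compute the descriptor vector for one trajectory.

    The maximal mass is taken over the initial mass and all recorded
    daily masses; ties resolve to the earliest day (day 0 being the
    initial mass).  Increment for day d is m_d − m_{d−1}, missing when
    either mass is missing.
    """
    if len(traj.daily_masses) < 1:
        raise ValueError(f"{traj.individual_id}: no daily masses")
    masses = [traj.initial_mass] + list(traj.daily_masses)
    observed = [(d, m) for d, m in enumerate(masses) if not math.isnan(m)]
    maximal_mass = max(m for _, m in observed)
    time_to_max = next(d for d, m in observed if m == maximal_mass)
    increments = {}
    for day in INCREMENT_DAYS:
        if day < len(masses):
            a, b = masses[day - 1], masses[day]
            if not (math.isnan(a) or math.isnan(b)):
                increments[day] = b - a
    return FeatureRow(
        individual_id=traj.individual_id,
        sex=traj.sex,
        brood_id=traj.brood_id,
        host=traj.host,
        time_to_instar5=traj.time_to_instar5,
        initial_mass=traj.initial_mass,
        maximal_mass=maximal_mass,
        pupal_mass=traj.pupal_mass,
        final_larval_mass=traj.final_larval_mass,
        instar_duration=traj.instar_duration,
        ratio_pupa_initial=traj.pupal_mass / traj.initial_mass,
        ratio_max_initial=maximal_mass / traj.initial_mass,
        ratio_max_final=maximal_mass / traj.final_larval_mass,
        time_to_max=time_to_max,
        abs_increments=increments,
    )


def feature_table(table: TrajectoryTable) -> pd.DataFrame:
    """One descriptor row per individual, as a DataFrame."""
    return pd.DataFrame([extract_features(t).as_dict() for t in table])


_ID_COLS = {"individual_id", "sex", "brood_id", "host"}


def summarize_by_sex(features: pd.DataFrame) -> pd.DataFrame:
    """Per-sex mean ± SE (sd/√n) of every numeric descriptor.

    Missing values are excluded per variable; returns a tidy table with
    columns variable, sex, n, mean, se.
    """
    present = set(features["sex"].unique())
    for sx in ("F", "M"):
        if sx not in present:
            raise ValueError(f"no rows for sex {sx!r}")
    counts = features["sex"].value_counts()
    if counts.min() < 2:
        raise ValueError("need at least 2 rows per sex")
    rows = []
    variables = [c for c in features.columns if c not in _ID_COLS]
    for var in variables:
        if not pd.api.types.is_numeric_dtype(features[var]):
            continue
        for sx, grp in features.groupby("sex"):
            vals = grp[var].dropna().to_numpy(dtype=float)
            n = len(vals)
            mean = float(np.mean(vals)) if n else math.nan
            se = float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1 else math.nan
            rows.append({"variable": var, "sex": sx, "n": n,
                         "mean": mean, "se": se})
    return pd.DataFrame(rows, columns=["variable", "sex", "n", "mean", "se"])


def ssd_ratio(mean_F: float, mean_M: float) -> float:
    """Sexual size dimorphism as the female:male ratio of mean size."""
    if mean_F <= 0 or mean_M <= 0:
        raise ValueError("means must be strictly positive")
    return mean_F / mean_M


def sdi(ratio: float) -> float:
    """Sexual dimorphism index: the SSD ratio minus one."""
    if ratio <= 0:
        raise ValueError("ratio must be strictly positive")
    return ratio - 1.0
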