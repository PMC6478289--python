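"""Core containers: one larva's growth record and collections thereof."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence


def _is_missing(x: float | None) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass
class Trajectory:
    """Full growth record of one larva through its last instar.

    ``initial_mass`` is the mass recorded at the intermolt growth stasis
    just before the final moult and is treated as the day-0 mass of the
    instar.  ``daily_masses[d-1]`` is the mass on day ``d`` (d = 1..n);
    entries may be NaN for missed weighings.  ``final_larval_mass`` is
    the mass on the last feeding day (before the wandering stage), and
    is distinct from ``pupal_mass``.
    """

    individual_id: str
    brood_id: str
    host: str  # "host1" | "host2"
    sex: str   # "F" | "M"
    time_to_instar5: float
    initial_mass: float
    daily_masses: list[float]
    final_larval_mass: float
    pupal_mass: float
    censored: bool = False

    @property
    def instar_duration(self) -> int:
        """Number of daily records (days 1..n of the instar)."""
        return len(self.daily_masses)

    def mass_on_day(self, day: int) -> float:
        """Mass on day ``day`` (0 = initial mass); NaN if not recorded."""
        if day == 0:
            return self.initial_mass
        if 1 <= day <= len(self.daily_masses):
            return self.daily_masses[day - 1]
        return math.nan

    def validate(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"{self.individual_id}: unknown sex code {self.sex!r}")
        if self.host not in ("host1", "host2"):
            raise ValueError(f"{self.individual_id}: unknown host {self.host!r}")
        if not self.brood_id:
            raise ValueError(f"{self.individual_id}: empty brood_id")
        if len(self.daily_masses) < 1:
            raise ValueError(f"{self.individual_id}: needs at least one daily mass")
        observed = [m for m in self.daily_masses if not _is_missing(m)]
        for name, value in (("initial_mass", self.initial_mass),
                            ("final_larval_mass", self.final_larval_mass),
                            ("pupal_mass", self.pupal_mass)):
            if _is_missing(value) or value <= 0:
                raise ValueError(f"{self.individual_id}: {name} must be a positive mass")
        if any(m <= 0 for m in observed):
            raise ValueError(f"{self.individual_id}: non-positive daily mass")
        if observed:
            peak = max(observed)
            if peak < self.initial_mass:
                raise ValueError(
                    f"{self.individual_id}: maximal daily mass below initial mass")
            if self.pupal_mass > peak * (1 + 1e-9):
                raise ValueError(
                    f"{self.individual_id}: pupal_mass exceeds maximal daily mass")
            if self.final_larval_mass > peak * (1 + 1e-9):
                raise ValueError(
                    f"{self.individual_id}: final_larval_mass exceeds maximal daily mass")
        if self.time_to_instar5 <= 0:
            raise ValueError(f"{self.individual_id}: time_to_instar5 must be positive")


@dataclass
class TrajectoryTable:
    """A validated collection of trajectories plus provenance metadata."""

    trajectories: list[Trajectory]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories)

    def validate(self) -> None:
        seen: set[str] = set()
        for t in self.trajectories:
            if t.individual_id in seen:
                raise ValueError(f"duplicate individual_id {t.individual_id!r}")
            seen.add(t.individual_id)
            t.validate()
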