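"""Generative parameters for simulated larval growth trajectories.

The defaults describe the last (5th) instar of a geometrid moth population
with moderate female-biased size dimorphism: females enter the instar
heavier (29.18 vs 25.30 mg on average), grow slightly faster on the
cube-root ("allometric") scale (0.279 vs 0.270 mg^(1/3) per day), peak
later (day 9.75 vs 8.67) and pupate later (instar duration 11.46 vs
10.10 days).  The rearing design is 109 broods with 12 larvae on the
first host plant and 3 on the second.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace, asdict

#: Per-sex descriptor means (mg, days) the default parameters are
#: calibrated against.  These anchor the simulator's central tendencies;
#: see :mod:`larvagrowth.params` defaults for how they enter the model.
CALIBRATION_MEANS = {
    "initial_mass": {"F": 29.18, "M": 25.30},
    "maximal_mass": {"F": 120.24, "M": 98.91},
    "pupal_mass": {"F": 73.57, "M": 63.28},
    "time_to_instar5": {"F": 18.17, "M": 17.58},
    "instar_duration": {"F": 11.46, "M": 10.10},
}


@dataclass(frozen=True)
class SimParams:
    """Parameter set for the stochastic growth-trajectory simulator.

    All masses are in mg, times in days, and growth rates on the
    cube-root-of-mass scale (mg^(1/3) per day).  Variance components are
    standard deviations on the same scales.
    """

    # development time from hatching to the start of the last instar
    mean_time_to_instar5_F: float = 18.17
    mean_time_to_instar5_M: float = 17.58
    sd_time_to_instar5: float = 1.7

    # mass at the intermolt stasis preceding the last instar (= day-0 mass)
    mean_initial_mass_F: float = 29.18
    mean_initial_mass_M: float = 25.30
    sd_initial_cuberoot: float = 0.13

    # allometric differential growth rate during free growth
    rate_F: float = 0.279
    rate_M: float = 0.270
    sd_rate_brood: float = 0.09
    sd_rate_individual: float = 0.02
    sd_rate_day: float = 0.064
    host_effect_on_rate: float = 0.0

    # day-1 mass gain is inflated by gut filling after the moult
    gutfill_factor: float = 1.5

    # growth taper and instar end
    taper_start_F: int = 6
    taper_start_M: int = 6
    peak_day_F: float = 9.75
    peak_day_M: float = 8.67
    sd_peak_day: float = 1.4
    instar_duration_F: float = 11.46
    instar_duration_M: float = 10.10
    sd_instar_duration: float = 1.0

    # pre-pupal mass loss: maximal mass over final feeding-stage mass,
    # and maximal mass over pupal mass
    max_over_final_F: float = 1.39
    max_over_final_M: float = 1.37
    max_over_pupa_F: float = 120.24 / 73.57
    max_over_pupa_M: float = 98.91 / 63.28
    sd_pupa_lognoise: float = 0.02

    # rearing design
    n_broods: int = 109
    larvae_per_brood_host1: int = 12
    larvae_per_brood_host2: int = 3
    sex_ratio: float = 0.5
    dropout_rate: float = 0.0

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        pos = [
            "mean_time_to_instar5_F", "mean_time_to_instar5_M",
            "mean_initial_mass_F", "mean_initial_mass_M",
            "rate_F", "rate_M", "peak_day_F", "peak_day_M",
            "instar_duration_F", "instar_duration_M",
        ]
        for name in pos:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        nonneg = [
            "sd_time_to_instar5", "sd_initial_cuberoot", "sd_rate_brood",
            "sd_rate_individual", "sd_rate_day", "sd_peak_day",
            "sd_instar_duration", "sd_pupa_lognoise", "dropout_rate",
        ]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.gutfill_factor < 1:
            raise ValueError("gutfill_factor must be >= 1")
        for sx in "FM":
            if getattr(self, f"max_over_final_{sx}") < 1:
                raise ValueError("max_over_final must be >= 1")
            if getattr(self, f"max_over_pupa_{sx}") < 1:
                raise ValueError("max_over_pupa must be >= 1")
            if not getattr(self, f"peak_day_{sx}") < getattr(self, f"instar_duration_{sx}"):
                raise ValueError("peak_day must precede instar_duration")
            if getattr(self, f"taper_start_{sx}") < 2:
                raise ValueError("taper_start must be >= 2")
        if self.n_broods < 1:
            raise ValueError("n_broods must be >= 1")
        if self.larvae_per_brood_host1 < 0 or self.larvae_per_brood_host2 < 0:
            raise ValueError("larvae_per_brood counts must be >= 0")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must lie in [0, 1]")

    def with_(self, **overrides) -> "SimParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **overrides)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimParams fields: {sorted(unknown)}")
        return cls(**d)


def default_params(seed: int = 0) -> SimParams:
    """The default parameter set, calibrated to the reference rearing design."""
    return SimParams(seed=seed)
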