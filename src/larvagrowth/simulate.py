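"""Stochastic simulator for last-instar larval growth trajectories.

The generative model works on the cube-root-of-mass scale c = m^(1/3),
on which free larval growth is approximately linear: each free-growth
day adds an allometric increment g (mg^(1/3)·day^-1).  The trajectory of
one larva is built as

* day 0: c0 drawn normal on the cube-root scale, centred so that the
  mg-scale mean equals the sex-specific mean initial mass;
* day 1: c1 = c0 + gutfill_factor · g_i — the first day's apparent gain
  is inflated by the larva refilling its gut after the moult;
* free-growth days 2 .. taper_start−1: c_d = c_{d-1} + g_i + ε_d, where
  g_i = g_sex + host shift + brood effect + individual effect and ε_d is
  day-level noise;
* taper days taper_start .. peak: the increment is multiplied by a
  factor decaying linearly from 1 (at taper_start − 1) to 0 at the
  individual's peak day, so mass peaks there;
* post-peak days: mass declines geometrically toward
  max(daily masses)/max_over_final on the last feeding day (the
  pre-pupal wandering-stage mass loss);
* pupal mass = maximal mass / max_over_pupa with small multiplicative
  noise.

Randomness is organised as one ``numpy`` seed sequence per population,
spawned deterministically per brood and then per individual, so adding
broods or individuals never perturbs earlier draws.
"""

from __future__ import annotations

import math

import numpy as np

from .params import SimParams, default_params
from .trajectory import Trajectory, TrajectoryTable

__all__ = ["default_params", "simulate_trajectory", "simulate_population"]

_MAX_REDRAWS = 20
_EFFECT_TRUNC = 2.5  # rate random effects truncated at +-2.5 sd so that
_MIN_RATE = 5e-3     # a larva's allometric rate stays positive (larvae grow)


def _truncated_normal(rng: np.random.Generator, sd: float,
                      cap: float = _EFFECT_TRUNC) -> float:
    if sd == 0:
        return 0.0
    for _ in range(100):
        z = rng.normal(0.0, 1.0)
        if abs(z) <= cap:
            return sd * z
    return 0.0


def _mean_preserving_cuberoot_mean(mean_mass: float, sd: float) -> float:
    """Location mu such that E[(mu + sd*Z)^3] = mean_mass for Z ~ N(0,1).

    E[c^3] = mu^3 + 3*mu*sd^2, a depressed cubic in mu solved with
    numpy's polynomial roots (unique real root for sd >= 0).
    """
    if sd == 0:
        return mean_mass ** (1.0 / 3.0)
    roots = np.roots([1.0, 0.0, 3.0 * sd**2, -mean_mass])
    real = roots[np.abs(roots.imag) < 1e-9].real
    return float(real[real > 0][0])


def _sex_field(params: SimParams, stem: str, sex: str) -> float:
    return getattr(params, f"{stem}_{sex}")


def _draw_trajectory_once(
    params: SimParams,
    sex: str,
    brood_effect: float,
    host: str,
    rng: np.random.Generator,
) -> tuple[float, list[float], float, float, float]:
    g_sex = _sex_field(params, "rate", sex)
    host_shift = params.host_effect_on_rate if host == "host2" else 0.0
    indiv_effect = _truncated_normal(rng, params.sd_rate_individual)
    g_i = g_sex + host_shift + brood_effect + indiv_effect
    if g_i < _MIN_RATE:
        raise FloatingPointError("non-positive allometric rate draw")

    mu0 = _mean_preserving_cuberoot_mean(
        _sex_field(params, "mean_initial_mass", sex), params.sd_initial_cuberoot)
    c0 = rng.normal(mu0, params.sd_initial_cuberoot)

    taper_start = int(_sex_field(params, "taper_start", sex))
    peak = int(round(rng.normal(_sex_field(params, "peak_day", sex),
                                params.sd_peak_day)))
    peak = max(peak, 2)  # taper is simply skipped when taper_start > peak
    duration = int(round(rng.normal(_sex_field(params, "instar_duration", sex),
                                    params.sd_instar_duration)))
    duration = max(duration, peak + 1)

    c = [c0, c0 + params.gutfill_factor * g_i]
    for day in range(2, peak + 1):
        inc = g_i + rng.normal(0.0, params.sd_rate_day)
        if day >= taper_start:
            # linear decay from 1 at taper_start-1 to 0 at peak
            inc *= (peak - day) / (peak - (taper_start - 1))
        c.append(c[-1] + inc)

    carr = np.asarray(c)
    if not np.all(np.isfinite(carr)) or np.any(carr <= 0):
        raise FloatingPointError("degenerate cube-root mass draw")

    masses = (carr**3).tolist()
    initial_mass = masses[0]
    daily = masses[1:]

    peak_mass = max([initial_mass] + daily)
    final_target = peak_mass / _sex_field(params, "max_over_final", sex)
    n_decline = duration - peak
    m_peak_day = daily[-1]
    for k in range(1, n_decline + 1):
        daily.append(m_peak_day * (final_target / m_peak_day) ** (k / n_decline))

    final_larval_mass = daily[-1]
    pupal = peak_mass / _sex_field(params, "max_over_pupa", sex)
    pupal *= math.exp(rng.normal(0.0, params.sd_pupa_lognoise))
    pupal = min(pupal, peak_mass)

    time_to_5 = rng.normal(_sex_field(params, "mean_time_to_instar5", sex),
                           params.sd_time_to_instar5)
    if time_to_5 <= 0:
        raise FloatingPointError("non-positive development time draw")
    return initial_mass, daily, final_larval_mass, pupal, time_to_5


def simulate_trajectory(
    params: SimParams,
    sex: str,
    brood_effect: float,
    host: str,
    rng: np.random.Generator,
    individual_id: str = "ind-0",
    brood_id: str = "brood-0",
) -> Trajectory:
    """Simulate one larva's last-instar growth record.

    ``brood_effect`` is the brood's random shift of the allometric rate
    (drawn once per brood by :func:`simulate_population`); ``rng`` is the
    individual's own random stream.
    """
    if sex not in ("F", "M"):
        raise ValueError(f"sex must be 'F' or 'M', got {sex!r}")
    if host not in ("host1", "host2"):
        raise ValueError(f"host must be 'host1' or 'host2', got {host!r}")
    last_err: Exception | None = None
    for _ in range(_MAX_REDRAWS):
        try:
            init, daily, final, pupal, t5 = _draw_trajectory_once(
                params, sex, brood_effect, host, rng)
            break
        except FloatingPointError as err:  # reject and redraw
            last_err = err
    else:
        raise ValueError(
            f"could not draw a valid trajectory after {_MAX_REDRAWS} attempts; "
            f"parameters look degenerate ({last_err})")
    censored = bool(params.dropout_rate > 0
                    and rng.random() < params.dropout_rate)
    traj = Trajectory(
        individual_id=individual_id,
        brood_id=brood_id,
        host=host,
        sex=sex,
        time_to_instar5=t5,
        initial_mass=init,
        daily_masses=daily,
        final_larval_mass=final,
        pupal_mass=pupal,
        censored=censored,
    )
    traj.validate()
    return traj


def simulate_population(params: SimParams) -> TrajectoryTable:
    """Simulate the full rearing design.

    ``n_broods`` broods each contribute ``larvae_per_brood_host1`` larvae
    on the first host and ``larvae_per_brood_host2`` on the second; sex
    is assigned independently per individual with probability
    ``sex_ratio`` of being female.
    """
    per_brood = params.larvae_per_brood_host1 + params.larvae_per_brood_host2
    if params.n_broods * per_brood == 0:
        raise ValueError("design contains zero larvae")

    root = np.random.SeedSequence(params.seed)
    brood_seeds = root.spawn(params.n_broods)
    trajectories: list[Trajectory] = []
    for b, bseq in enumerate(brood_seeds):
        brood_id = f"b{b + 1:03d}"
        child_seqs = bseq.spawn(per_brood + 1)
        brood_rng = np.random.Generator(np.random.PCG64(child_seqs[0]))
        brood_effect = _truncated_normal(brood_rng, params.sd_rate_brood)
        hosts = (["host1"] * params.larvae_per_brood_host1
                 + ["host2"] * params.larvae_per_brood_host2)
        for i, (host, iseq) in enumerate(zip(hosts, child_seqs[1:])):
            rng = np.random.Generator(np.random.PCG64(iseq))
            sex = "F" if rng.random() < params.sex_ratio else "M"
            trajectories.append(simulate_trajectory(
                params, sex, brood_effect, host, rng,
                individual_id=f"{brood_id}-i{i + 1:02d}",
                brood_id=brood_id,
            ))
    return TrajectoryTable(
        trajectories,
        metadata={"source": "simulated", "seed": params.seed,
                  "params": params.to_dict()},
    )
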