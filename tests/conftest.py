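import numpy as np
import pytest

import larvagrowth as lg


def deterministic_params(**overrides):
    """Noise-free parameter set on which growth is exactly cubic.

    All variance components are zero, gut-fill is off, and the taper
    window starts after the peak, so daily masses follow
    m_d = (m0^(1/3) + g*d)^3 until the single post-peak decline day.
    """
    base = dict(
        sd_time_to_instar5=0.0, sd_initial_cuberoot=0.0,
        sd_rate_brood=0.0, sd_rate_individual=0.0, sd_rate_day=0.0,
        sd_peak_day=0.0, sd_instar_duration=0.0, sd_pupa_lognoise=0.0,
        gutfill_factor=1.0,
        taper_start_F=11, taper_start_M=11,
        peak_day_F=10, peak_day_M=10,
        instar_duration_F=11, instar_duration_M=11,
        mean_initial_mass_F=27.0, mean_initial_mass_M=27.0,
        rate_F=0.3, rate_M=0.3,
        max_over_final_F=1.39, max_over_final_M=1.39,
    )
    base.update(overrides)
    return lg.default_params().with_(**base)


@pytest.fixture(scope="session")
def default_population():
    """One full default population (109 broods x 15 larvae), reused."""
    return lg.simulate_population(lg.default_params(seed=20240601))


@pytest.fixture(scope="session")
def small_population():
    params = lg.default_params(seed=7).with_(
        n_broods=12, larvae_per_brood_host1=4, larvae_per_brood_host2=2)
    return lg.simulate_population(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
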