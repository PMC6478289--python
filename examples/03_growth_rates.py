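"""Three growth-rate indices and why the choice matters.

Absolute daily gain, relative (log-ratio) rate, and the allometric rate
(daily gain in cube-root mass) describe the same trajectories but scale
differently with body size.  On near-cubic growth the allometric rate
is size-independent, while the relative rate declines mechanically with
mass and makes the larger sex look slower.

To isolate that artefact we simulate a population whose larvae differ
only in initial size, not in growth rate: regressing each day's rate on
the previous day's mass then shows a flat allometric slope and a
negative relative slope.  (In a population with real between-larva rate
variation the picture blurs, because faster growers are also heavier —
rate heterogeneity and the size artefact pull the slope in opposite
directions.)
"""

import larvagrowth as lg

pop = lg.simulate_population(lg.default_params(seed=33))
recs = lg.rate_table(pop, window=(2, 3, 4, 5))
print("mean rate by sex and measure (free-growth window, days 2-5):")
print(recs.groupby(["measure", "sex"])["value"].mean().unstack()
      .to_string(float_format="%.4f"))

# same design, but all rate variation switched off
uniform = lg.default_params(seed=33).with_(
    sd_rate_brood=0.0, sd_rate_individual=0.0, sd_rate_day=0.0)
urecs = lg.rate_table(lg.simulate_population(uniform), window=(2, 3, 4, 5))
fits = lg.size_dependence(urecs, days=(2, 3),
                          measures=("relative", "allometric"))
print("\nrate-on-previous-mass slopes, size variation only (+- SE):")
for f in fits:
    print(f"  {f.measure:10s} day {f.day} {f.sex}: "
          f"{f.slope:+.2e} +- {f.slope_se:.2e}  (n={f.n})")
print("\nallometric slopes are ~0; relative slopes are clearly negative.")
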