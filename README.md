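# larvagrowth

Simulation and analysis of sexual size dimorphism (SSD) ontogeny in
larval growth trajectories.

In many insects females are the larger sex, and the dimorphism must be
built during a shared larval period. This package provides a complete,
reproducible pipeline for studying *how*: a stochastic simulator of
daily larval mass trajectories under a split-brood rearing design, and
the analysis chain that turns those trajectories into answers — growth
curve descriptors, size-corrected growth-rate indices, mixed-model
ANOVA with brood as a random factor, and a cubic-scale decomposition of
dimorphism into growth-*rate* and growth-*duration* contributions.

The central methodological point is the choice of rate index. The
conventional relative growth rate, `log10(m_end / m_start)` per day,
declines mechanically with body size, so the larger sex looks slower
even when it is not. The allometric rate — the daily gain in cube-root
mass, `Δ(m^(1/3))` — is size-independent under near-cubic larval
growth. On that scale a small but real female rate advantage becomes
detectable (0.279 vs 0.270 mg^(1/3)/day in the calibrated defaults),
yet it projects to only a ~3% mass ratio over the free-growth window,
while a single extra day of growth projects to ~20%: growth duration,
not growth rate, is the dominant proximate source of SSD.

## Quick start

```python
import larvagrowth as lg

# simulate the default rearing design: 109 broods, 12 + 3 larvae each
pop = lg.simulate_population(lg.default_params(seed=1))

# per-larva growth-curve descriptors and per-sex summaries
feats = lg.feature_table(pop)
means = feats.groupby("sex")["pupal_mass"].mean()
ratio = lg.ssd_ratio(means["F"], means["M"])   # ~1.18
sdi = lg.sdi(ratio)                            # ratio - 1

# daily growth rates over the free-growth window (days 2-5)
recs = lg.rate_table(pop, measures=("allometric", "relative"))

# mixed-model ANOVA: sex * day * host plant, brood random
from larvagrowth.inference import repeated_anova, anova_frame
print(anova_frame(repeated_anova(recs, measure="allometric")))

# decompose SSD into rate vs duration contributions
res = lg.decompose_ssd()       # m0=25.30, rates 0.279/0.270, 5 days
print(res.ratio_from_rate_diff)   # 1.0318  -> ~3% from rate
print(res.ratio_from_extra_day)   # 1.2012  -> ~20% from one extra day
```

The same pipeline is available from the command line:

```sh
larvagrowth simulate --seed 1 --out traj.tsv
larvagrowth features --in traj.tsv --out feats.tsv --summary sums.tsv
larvagrowth rates    --in traj.tsv --out rates.tsv
larvagrowth test     --rates rates.tsv --out anova.tsv
larvagrowth decompose --json
```

Identical seeds produce byte-identical outputs; adding broods to a
design does not perturb the trajectories of existing broods.

## Package layout

| module | contents |
|---|---|
| `params` | `SimParams` (all generative parameters), `CALIBRATION_MEANS` |
| `simulate` | stochastic trajectory simulator on the cube-root scale |
| `trajectory`, `io` | data model plus wide/long TSV/CSV readers and writers |
| `features` | growth-curve descriptors, per-sex summaries, `ssd_ratio`/`sdi` |
| `rates` | absolute / relative / allometric daily rates, integral rates |
| `inference` | REML mixed-model ANOVA, size-dependence regressions |
| `decompose` | cubic projection of rate-vs-duration SSD contributions |
| `cli` | thin `larvagrowth` command-line wrapper |

Narrative walkthroughs live in `examples/`; the model and its
assumptions are documented in `docs/methods.md`.

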