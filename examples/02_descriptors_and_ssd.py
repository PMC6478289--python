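"""Growth-curve descriptors and the size dimorphism they imply.

Each trajectory is reduced to scalar descriptors (initial, maximal,
final and pupal mass; timing of the peak; mass ratios).  Per-sex means
of those descriptors quantify sexual size dimorphism (SSD), reported
both as the female:male ratio and as the sexual dimorphism index
(SDI = ratio - 1).
"""

import larvagrowth as lg

pop = lg.simulate_population(lg.default_params(seed=22))
feats = lg.feature_table(pop)
summary = lg.summarize_by_sex(feats)

print(summary[summary.variable.isin(
    ["initial_mass", "maximal_mass", "pupal_mass", "instar_duration"])]
    .to_string(index=False))

means = feats.groupby("sex")["pupal_mass"].mean()
ratio = lg.ssd_ratio(means["F"], means["M"])
print(f"\npupal-mass SSD ratio {ratio:.3f}, SDI {lg.sdi(ratio):.3f}")

# the descriptor means the simulator is calibrated against imply:
pupa = lg.CALIBRATION_MEANS["pupal_mass"]
print(f"calibration anchor SDI: "
      f"{lg.sdi(lg.ssd_ratio(pupa['F'], pupa['M'])):.3f}")
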