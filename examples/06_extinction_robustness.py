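"""Simulated habitat loss: extinction curves, robustness, z-scores.

Locations are removed one per step, either in random order or habitat by
habitat (orchard first, then grassland, forest, arable — the intensification
scenario); a species goes extinct with its last occupied location.
Robustness is the normalized area under the persistence curve.
"""

import habnet as hn

ds = hn.generate_dataset(hn.GeneratorConfig(seed=1))
locations = hn.exclude_settlement_locations(ds.locations)
lid = "L14"  # the most diverse landscape
lm = hn.build_location_matrix(locations, ds.bees, lid)

for scenario in (hn.RANDOMIZED, hn.HABITAT_ORDER):
    run = hn.simulate_extinction(lm, scenario, n_rep=1000, seed=5)
    print(f"{lid} {scenario.name}: rob_obs = {run.rob_obs:.3f}")
    print("  persistence:", [round(p, 2) for p in run.persistence_curve])
    print(hn.per_step_species_loss(run).round(3).to_string(index=False))

ens = hn.robustness_zscore(lm, hn.RANDOMIZED, n_null=200, n_rep=200, seed=6)
print(f"\nrobustness z-score vs Patefield nulls: {ens.z:+.2f} "
      f"(null mean {ens.null_mean:.3f}, sd {ens.null_sd:.3f})")
# Higher per-step losses concentrate in the habitats that hold the most
# species exclusively; z near 0 means the observed curve is what fixed
# margins alone would produce.
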