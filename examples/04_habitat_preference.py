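"""Habitat preference/avoidance of wild bees, with the probabilistic variant.

The deviation statistic compares the share of a landscape's bees caught in a
habitat with the habitat's share of the landscape area; deviations are
aggregated over landscapes with 95% t-CIs. The probabilistic variant re-draws
each location's habitat from its 100-m cover mix to address ambiguous
mixed-cover locations.
"""

import habnet as hn

cfg = hn.GeneratorConfig(
    seed=1, effort=60.0,
    preference_matrix=hn.habitat_boost_preference(75, "orchard", 2.0),
)
ds = hn.generate_dataset(cfg)
locations = hn.exclude_settlement_locations(ds.locations)
networks = hn.build_all_networks(locations, ds.bees)

dev = hn.all_landscape_deviations(networks, ds.landscapes)
print(hn.aggregate_preference(dev).round(3).to_string(index=False))

ensembles = {
    lid: hn.probabilistic_networks(locations, ds.bees, lid, n_rep=200,
                                   seed=10 + i)
    for i, lid in enumerate(sorted(networks))
}
print("\nprobabilistic assignment:")
print(hn.probabilistic_preference(ensembles, ds.landscapes)
      .round(3).to_string(index=False))
# The planted orchard attraction (multiplier 2) surfaces as a positive mean
# deviation with a CI above zero — classification 'preference'.
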