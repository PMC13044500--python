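"""Chao1 sampling completeness for species and for interactions.

Singletons (count 1) and doubletons (count 2) drive the bias-corrected
asymptote S_obs + F1(F1-1)/(2(F2+1)); completeness is S_obs over that.
"""

import habnet as hn

ds = hn.generate_dataset(hn.GeneratorConfig(seed=1))
locations = hn.exclude_settlement_locations(ds.locations)
networks = hn.build_all_networks(locations, ds.bees)

table = hn.completeness_table(ds.bees, locations, networks)
summary = table.groupby("entity")["completeness"].agg(["mean", "std"])
print(table.head(6).round(3).to_string(index=False))
print("\nmean completeness:")
print((100 * summary).round(1).to_string())
# Interaction completeness sits below species completeness: the habitat x
# species cells are harder to sample exhaustively than the species list.
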