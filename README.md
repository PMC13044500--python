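# habnet

Species–habitat network analysis for wild bee communities in agricultural
landscapes.

Grid-based surveys sample bees at locations spread across all major habitat
types of a landscape (arable land, forest, grassland, orchard, plus minor
settlement/road/hedgerow cover). `habnet` turns such surveys into bipartite
**species–habitat networks** — habitat × species abundance matrices, one per
landscape, with each location assigned to the habitat of dominant cover in
its 100-m radius — and computes the emergent properties ecologists use to
reason about habitat complementarity and landscape-level conservation:

* **Habitat preference / avoidance** — per landscape–habitat pair the
  deviation `p_bees − p_cover` between the share of bees caught in a habitat
  and the habitat's share of landscape area, aggregated over landscapes with
  95% t-CIs (CI above 0 → preference, below → avoidance); plus a
  probabilistic variant that re-draws each location's habitat from its local
  cover mix to handle ambiguous mixed-cover locations.
* **Sampling completeness** — bias-corrected Chao1,
  `S_chao1 = S_obs + F1(F1−1)/(2(F2+1))`, for species per landscape and for
  habitat–species interactions per network.
* **Modularity** — Barber's bipartite modularity
  `Q = (1/m) Σ_ij (A_ij − k_i d_j/m) δ(g_i, h_j)`, maximized exactly for the
  small habitat dimension of these networks, standardized as z-scores
  against Patefield fixed-margin null matrices (curveball nulls for the
  binary sensitivity variant).
* **Robustness to habitat loss** — sequential removal of sampling locations
  (fully random, or orchard → grassland → forest → arable, the
  intensification scenario), secondary species extinctions, per-step
  species-loss attributions, extinction curves, robustness as the
  normalized area under the curve, and robustness z-scores.
* **Inference layer** — OLS / mixed models relating the indices to
  landscape Shannon diversity with deterministic backward selection, the
  log(loss + 0.01) species-loss model with back-transformed per-habitat
  predictions, and Pearson correlations.

A seeded synthetic landscape generator emulates the full study design
(diversity gradient, proportional grid allocation of locations, log-series
species abundances, tunable habitat preference, Poisson/multinomial count
sampling), so every stage is testable end-to-end without field data.

## Worked example

Plant a community-wide orchard attraction (multiplier 2) and recover it:

```python
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
```

```
  habitat  n_landscapes  mean_deviation  ci_low  ci_high classification  reliable
   arable            14           0.016  -0.002    0.034        neutral      True
   forest            13          -0.001  -0.019    0.017        neutral      True
grassland            13          -0.001  -0.018    0.016        neutral      True
  orchard            13           0.076   0.050    0.102     preference      True
```

Orchards hold 7.6 percentage points more of each landscape's bees than
their area share predicts, with a CI excluding zero — the planted
preference is classified `preference`, while the other habitats stay
neutral. The `examples/` directory has one
narrative script per capability (generator, networks and metanetworks,
completeness, preference, modularity, extinction/robustness, full
pipeline); `habnet --help` exposes the same stages as a thin CLI.

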