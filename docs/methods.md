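# Methods

This note documents the models behind `habnet`, the assumptions of the
synthetic survey generator, and the numerical and design choices made where
the problem was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model

A survey consists of landscapes (1-km² units with proportional habitat
cover over up to seven classes: arable, forest, grassland, orchard,
hedgerow, road, settlement), sampling locations (16 per landscape, each
with a 100-m-radius cover composition), and pooled bee counts per
(location, species). Landscape diversity is the Shannon entropy
H = −Σ p ln p of the cover composition, in nats; zero-cover classes
contribute nothing. Covers arrive precomputed — there is no GIS layer —
and coordinates, if present, are never used.

Each location is assigned the habitat of maximal local cover. Ties are
broken lexicographically with a logged warning: deterministic and
auditable, and the probabilistic-assignment variant (below) is the proper
treatment of genuinely ambiguous mixes. Locations dominated by settlement
are removed from every analysis — too few to support a network row.
Honeybee exclusion is the data producer's responsibility; the validator
only warns when *Apis mellifera* appears.

## Networks

A landscape's network is the habitat × species matrix of summed abundances
over locations per dominant habitat; rows and columns are alphabetical so
outputs diff cleanly. Network size is `n_habitats × n_species`. The
location × species matrix is retained for the extinction simulation and
collapses to the network exactly (a tested invariant). Probabilistic
ensembles re-draw each location's habitat per replicate with probability
equal to its local cover, renormalized over the four focal habitats:
settlement is excluded from all analyses and the minor linear classes
carry no network row, so their cover is redistributed proportionally
(documented per run in the ensemble's provenance rather than guessed as a
seventh row).

## Habitat preference

For landscape L and habitat h, `deviation = p_bees − p_cover`, where
`p_bees` is h's share of L's bees and `p_cover` is h's share of the *full*
mapped landscape (all classes, not a focal-four renormalization — the
statistic compares bee share against true area share). Consequently the
four focal deviations sum to the minor-habitat cover (a small positive
constant) by construction when minor classes are present. Deviations are
aggregated per habitat across landscapes as mean ± 95% Student-t CI
(n−1 df) — with 13–14 landscape-level observations a t-interval is the
standard choice; a bootstrap would be defensible but adds a tuning knob
for no gain at this n. Classification: `preference` if the CI lies above
0, `avoidance` below, `neutral` otherwise. Landscapes where a habitat has
zero cover *and* zero bees are excluded from that habitat's aggregation;
zero cover with bees present contributes (possible under 100-m mixing at
landscape edges). In the probabilistic variant the per-landscape deviation
is the mean over replicates, then aggregated identically.

## Sampling completeness

Bias-corrected Chao1, `S_chao1 = S_obs + F1(F1−1)/(2(F2+1))`, with
completeness `S_obs / S_chao1`. Entities are species (pooled abundances
per landscape — the abundance-based asymptote, not incidence) or nonzero
network cells (interaction richness, with cell weight as the count). The
classic `F1²/(2F2)` variant is deliberately not offered, to avoid silent
divergence between runs. One quirk worth knowing: completeness is not
monotone under adding individuals — resolving a doubleton into a tripleton
lowers F2 and *raises* the estimate; the tests pin this down.

## Modularity and null models

Barber's bipartite modularity for matrix A with row sums k, column sums d,
total m:

    Q = (1/m) Σ_ij (A_ij − k_i d_j / m) δ(g_i, h_j)

Only row–column pairs contribute, so for any fixed partition of the rows
each column independently joins the module with the largest summed
null-corrected weight (or stays alone when all are negative). Exhaustive
search over row set-partitions is therefore exact, and with ≤ 7 habitats
per network it is also fast — every habitat network uses this exact path.
Larger matrices fall back to seeded label propagation with agglomerative
module merging and 20 restarts (DIRT-LPA-wb+ style); the fallback is
tested against the exact path. Single-row or single-column matrices have
no between-module structure: Q = 0 with a degenerate flag, and such
landscapes are excluded from z-score statistics (present in observed
modularity output only).

Weighted null model: Patefield draws — uniform over integer matrices with
the observed margins — generated row by row from the multivariate
hypergeometric of remaining column capacities, which is the exact
conditional law of that uniform model; margins are conserved bit-exactly.
Binary sensitivity variant: curveball trades (degree-preserving), the
standard binary analogue of fixed margins. z = (observed − null mean)/null
sd over 1000 nulls by default; a zero null sd yields a flagged non-finite
z. Independent child RNG streams per landscape make results independent of
iteration order.

## Extinction simulation and robustness

Input is the location × species matrix. Per repetition the removal order
is either a uniform permutation (`randomized`) or grouped by the habitat
sequence orchard → grassland → forest → arable with random order within
each habitat (`habitat_order`, the intensification scenario; the sequence
must cover all habitats present). A species survives while any remaining
location holds ≥ 1 individual — no abundance threshold, since persistence
is about occupancy. The proportional species loss at each step is
attributed to the removed location and its habitat; curves and
attributions average over 1000 repetitions by default. Landscapes with
fewer locations (after settlement exclusion) simply run to their own
location count, and the step axis normalizes by that count.

Robustness is the area under the mean persistence curve at integer steps
0..n (starting at 1.0 at step 0 — including the origin keeps the AUC on
[0, 1]), interpolated with a cubic spline, *clamped to [0, 1]* before
integration (Simpson on a dense grid, 64 points per step), divided by n.
The clamp guards against spline overshoot on steep curves; on monotone
fixtures the spline AUC stays within 0.02 of the trapezoid. Robustness
z-scores run Patefield nulls of the location × species matrix (location
and species totals fixed, habitat labels of rows retained — the only
margin-preserving null the pipeline uses, applied to the same protocol)
through the identical simulation.

## Inference layer

Per-landscape indices (Shannon H, network size, richness, completeness,
Q_obs, Mod_z) feed: OLS of Q_obs and Mod_z on H; mixed models with a
landscape random intercept for rob_obs and rob_z on scenario × H (and
variants replacing H with modularity); the species-loss model
log(mean per-location loss + 0.01) ~ habitat + scenario + H fitted by OLS
on location × scenario rows, with per-habitat predictions back-transformed
as exp(fit) − 0.01 (the constant subtracted after exponentiation, so
predictions land on the proportion scale actually reported). Backward
selection removes the least significant term — interactions before their
main effects — until everything remaining has p < 0.05, via
likelihood-ratio χ² for mixed models and F-tests for the loss model; term
order is fixed, so selection is deterministic. When the random-intercept
variance collapses to zero (singular Hessian), the grouping carries no
information and that response's whole selection path falls back to OLS,
flagged in the result. Singular or degenerate fits are reported, never
silently dropped.

## Synthetic survey generator

The generator emulates the study design the analysis assumes, and its
defaults are the study's conditions:

* **14 landscapes, 16 locations each.** Landscape covers are a
  deterministic function of a diversity gradient g ∈ [0, 1] (one value per
  landscape, default evenly spaced): focal composition
  (1−g)·(all arable) + g·(even quarter split), scaled by the fixed minor
  covers (settlement 2.5%, road 4.5%, hedgerow 1.5% — combined minor cover
  is capped at 10%).
* **Grid allocation.** Locations per habitat are proportional to cover
  with unbiased systematic rounding (realized counts within one location
  of the target), mirroring grid-based sampling; each location then draws
  its 100-m mix from a Dirichlet (concentration 10) centred on a blend of
  its habitat and the landscape composition, resampled so the intended
  habitat is dominant. Road and hedgerow are narrow linear elements and
  never dominate a location.
* **Species pool.** 75 species; base abundance weights are log-series
  (shape 0.99), reproducing the dominance of a few species typical of bee
  communities. By default each species prefers one random focal habitat
  with multiplier 3 (niche differentiation, which is what makes diverse
  landscapes modular); `uniform_preference` removes all preference and
  `habitat_boost_preference` plants a community-wide one.
* **Counts.** Location totals are Poisson with mean
  effort × attractiveness, where attractiveness is the abundance-weighted
  mean of cover-weighted preference (exactly 1 for a neutral community);
  species identities are multinomial in base weight × preference. Default
  effort 4.3 bees per location matches the scale of a two-round
  pan-trap-plus-sweep-net season.
* **Null configuration.** `GeneratorConfig.neutral()` sets all preference
  multipliers to 1 *and* minor covers to zero. Both matter for
  calibration: with unmapped minor cover the focal deviations sum to a
  positive constant by construction, so an unbiased null requires the
  focal classes to exhaust the landscape. Under the null configuration the
  expected deviation is exactly zero and the 95% CI covers zero at its
  nominal rate (a tested property).
* **Reproducibility.** One root seed spawns per-landscape child streams;
  identical config + seed gives byte-identical tables.

What the generator does **not** emulate: spatial geometry and
autocorrelation, phenology and the two-round structure, honeybee
contamination, observer effects, and any real species' identity. Passing
tests therefore demonstrate that the pipeline recovers structure *of the
kinds planted* at field-realistic sample sizes — not that field data meet
the generator's independence assumptions.

### Experiment sizes used in tests

Recovery and calibration experiments run at: preference recovery —
multiplier 2, 14 landscapes, effort 60, 50 replicates; CI calibration —
neutral configuration, effort 30, 200 replicates; modularity–diversity
slope — default preference (strength 3), effort 30, 200 replicates;
extinction geometry — 14 landscapes at 1000 repetitions. The acceptance
script runs the default study at 1000 repetitions with 300-replicate null
ensembles (200 repetitions inside each null), sizes chosen so a full rerun
stays at desk scale while Monte-Carlo error remains well below the effect
sizes of interest.

## Known limitations

* Exact numerical parity with other modularity optimizers is not
  guaranteed in the label-propagation regime (> 7 habitats); for the
  networks this package targets, the exact path makes the optimum
  reproducible by construction.
* The binary null scheme (curveball) is a design choice; fixed-degree is
  the standard binary analogue of fixed margins, but other schemes exist
  and would shift binary z-scores.
* The t-based CI treats landscape-level deviations as independent;
  spatial autocorrelation between nearby landscapes would narrow it
  unduly. No multiple-testing correction is applied across habitats.
* Backward selection's path under near-ties depends on the fixed term
  order; borderline terms may resolve differently than in other
  implementations.
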