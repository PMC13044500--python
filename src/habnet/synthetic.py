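"""Synthetic survey generator.

Emulates the grid-based study design the analysis assumes: a set of 1-km²
agricultural landscapes spanning a diversity gradient (from arable-dominated
to an even mix of arable, forest, grassland and orchard, plus minor
settlement/road/hedgerow cover), a fixed grid of sampling locations per
landscape whose 100-m cover mixes vary around the landscape composition, a
species pool with heavy-tailed (log-series) abundances and tunable habitat
preference, and Poisson/multinomial count sampling at each location.

The generator gives every downstream stage — network construction, sampling
completeness, preference statistics, modularity and robustness — a testable
input with known planted structure. It is deliberately non-spatial: there is
no geometry, no phenology and no between-round structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .survey import (
    FOCAL_HABITATS,
    SurveyDataError,
    assign_dominant_habitats,
    shannon_diversity,
)

#: Default minor-habitat covers; combined cover is capped at 10% of a landscape.
DEFAULT_MINOR_COVERS: dict[str, float] = {
    "settlement": 0.025,
    "road": 0.045,
    "hedgerow": 0.015,
}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic survey.

    ``diversity_gradient`` holds one mixing parameter in [0, 1] per landscape:
    0 means a single dominant focal habitat (arable), 1 an even split of the
    four focal habitats. ``preference_matrix`` (species × focal habitat,
    nonnegative multipliers) encodes relative attraction; if None, each
    species is assigned one preferred habitat at random and given multiplier
    ``preference_strength`` there (1 elsewhere). ``effort`` is the expected
    number of individuals sampled per location for a neutral community.
    """

    n_landscapes: int = 14
    n_locations_per_landscape: int = 16
    focal_habitats: tuple[str, ...] = FOCAL_HABITATS
    minor_covers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MINOR_COVERS)
    )
    diversity_gradient: tuple[float, ...] | None = None
    n_species: int = 75
    abundance_shape: float = 0.99  # log-series parameter, in (0, 1)
    preference_strength: float = 3.0
    preference_matrix: pd.DataFrame | None = None
    effort: float = 4.3
    location_concentration: float = 10.0
    seed: int = 0

    def gradient(self) -> np.ndarray:
        if self.diversity_gradient is not None:
            g = np.asarray(self.diversity_gradient, dtype=float)
            if len(g) != self.n_landscapes:
                raise SurveyDataError(
                    "diversity_gradient length must equal n_landscapes"
                )
        else:
            g = np.linspace(0.0, 1.0, self.n_landscapes)
        if ((g < 0) | (g > 1)).any():
            raise SurveyDataError("diversity gradient values must lie in [0, 1]")
        return g

    def validate(self) -> None:
        if self.n_landscapes < 1 or self.n_locations_per_landscape < 1:
            raise SurveyDataError("need at least one landscape and one location")
        if self.n_species < 1:
            raise SurveyDataError("need at least one species")
        if not 0.0 < self.abundance_shape < 1.0:
            raise SurveyDataError("abundance_shape must be in (0, 1)")
        minor_total = sum(self.minor_covers.values())
        if minor_total > 0.10 + 1e-9:
            raise SurveyDataError("combined minor-habitat cover is capped at 10%")
        if any(v < 0 for v in self.minor_covers.values()):
            raise SurveyDataError("minor covers must be nonnegative")
        if self.effort < 0:
            raise SurveyDataError("effort must be nonnegative")
        self.gradient()
        if self.preference_matrix is not None:
            pm = self.preference_matrix
            if (pm.to_numpy() < 0).any():
                raise SurveyDataError("preference multipliers must be nonnegative")
            if (pm.sum(axis=1) <= 0).any():
                raise SurveyDataError(
                    "each species needs at least one positive preference multiplier"
                )
            unknown = set(pm.columns) - set(self.focal_habitats)
            if unknown:
                raise SurveyDataError(f"unknown habitats in preference matrix: {unknown}")

    def neutral(self) -> "GeneratorConfig":
        """Copy of this config with no habitat preference and no minor cover.

        This is the null configuration used for calibration experiments: with
        all preference multipliers equal and the full landscape mapped by the
        four focal habitats, expected preference deviations are exactly zero.
        """
        cfg = GeneratorConfig(**{**self.__dict__})
        cfg.minor_covers = {}
        cfg.preference_matrix = uniform_preference(cfg.n_species, cfg.focal_habitats)
        return cfg


def uniform_preference(
    n_species: int, habitats: tuple[str, ...] = FOCAL_HABITATS
) -> pd.DataFrame:
    """Preference matrix of all ones: no habitat preference."""
    names = _species_names(n_species)
    return pd.DataFrame(1.0, index=names, columns=list(habitats))


def habitat_boost_preference(
    n_species: int,
    habitat: str,
    multiplier: float,
    habitats: tuple[str, ...] = FOCAL_HABITATS,
) -> pd.DataFrame:
    """All species share a single boosted habitat (multiplier elsewhere 1).

    Used in recovery experiments that plant a community-wide preference."""
    pm = uniform_preference(n_species, habitats)
    pm[habitat] = float(multiplier)
    return pm


def _species_names(n: int) -> list[str]:
    return [f"sp{i + 1:03d}" for i in range(n)]


@dataclass
class SurveyDataset:
    """A complete synthetic (or ingested) survey: the four tidy tables."""

    landscapes: pd.DataFrame
    locations: pd.DataFrame
    bees: pd.DataFrame
    traits: pd.DataFrame | None = None

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.landscapes.to_csv(directory / "landscapes.csv", index=False)
        self.locations.to_csv(directory / "locations.csv", index=False)
        self.bees.to_csv(directory / "bees.csv", index=False)
        if self.traits is not None:
            self.traits.to_csv(directory / "traits.csv", index=False)


def generate_landscapes(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the landscape cover table and the location table.

    Landscape covers are a deterministic function of the diversity gradient:
    at gradient g the focal composition is (1-g)·(all arable) + g·(even
    split), scaled down by the fixed minor-habitat cover. Each location draws
    an "intended" habitat with probability proportional to landscape cover
    (focal types plus settlement), then a 100-m cover mix from a Dirichlet
    centred on a blend of that habitat and the landscape composition,
    resampled so the intended habitat is dominant. Location counts per
    dominant habitat are therefore binomial with success probability equal to
    the habitat's cover share — the proportionality the grid design targets.
    """
    config.validate()
    focal = list(config.focal_habitats)
    minor = dict(config.minor_covers)
    minor_total = sum(minor.values())
    gradient = config.gradient()

    ss = np.random.SeedSequence(config.seed)
    land_seeds = ss.spawn(config.n_landscapes)

    all_habitats = sorted(set(focal) | set(minor))
    land_rows = []
    loc_rows = []
    for i, g in enumerate(gradient):
        lid = f"L{i + 1:02d}"
        target = np.full(len(focal), g / len(focal))
        target[focal.index("arable")] += 1.0 - g
        cover = {h: float(target[k] * (1.0 - minor_total)) for k, h in enumerate(focal)}
        cover.update(minor)
        cover_series = pd.Series({h: cover.get(h, 0.0) for h in all_habitats})
        land_rows.append(
            {"landscape_id": lid, **cover_series.to_dict(),
             "shannon_h": shannon_diversity(cover_series)}
        )

        rng = np.random.default_rng(land_seeds[i])
        loc_rows.extend(
            _generate_locations(lid, cover_series, config, rng)
        )

    landscapes = pd.DataFrame(land_rows)
    locations = pd.DataFrame(loc_rows)
    locations = assign_dominant_habitats(locations)
    return landscapes, locations


def _systematic_counts(targets: np.ndarray, rng) -> np.ndarray:
    """Round fractional location targets to integers, unbiasedly.

    Grid-based sampling allocates locations proportionally to habitat cover;
    fractional remainders are resolved by systematic (PPS) sampling, so
    E[count_h] equals the target exactly while the realized count never
    deviates from it by more than one location.
    """
    base = np.floor(targets).astype(int)
    frac = targets - base
    k = int(round(frac.sum()))
    if k > 0:
        cum = np.concatenate([[0.0], np.cumsum(frac)])
        points = rng.random() + np.arange(k)
        extra = np.searchsorted(cum, points, side="right") - 1
        np.add.at(base, extra, 1)
    return base


def _generate_locations(lid, cover: pd.Series, config: GeneratorConfig, rng):
    habitats = list(cover.index)
    cov = cover.to_numpy(dtype=float)
    # road/hedgerow are narrow linear elements: they never dominate a 100-m disc
    dominance_ok = np.array(
        [h in config.focal_habitats or h == "settlement" for h in habitats]
    )
    p_intend = np.where(dominance_ok, cov, 0.0)
    p_intend = p_intend / p_intend.sum()
    conc = config.location_concentration

    # grid design: locations per habitat proportional to cover
    counts = _systematic_counts(p_intend * config.n_locations_per_landscape, rng)
    intended_seq = np.repeat(np.arange(len(habitats)), counts)
    rng.shuffle(intended_seq)

    rows = []
    for j in range(config.n_locations_per_landscape):
        intended = int(intended_seq[j])
        e = np.zeros(len(habitats))
        e[intended] = 1.0
        center = 0.55 * e + 0.45 * cov
        local = None
        for _ in range(20):
            draw = np.zeros(len(habitats))
            pos = center > 0
            draw[pos] = rng.dirichlet(conc * center[pos])
            if draw.argmax() == intended:
                local = draw
                break
        if local is None:  # fall back to a mix that guarantees dominance
            local = 0.6 * e + 0.4 * cov
            local = local / local.sum()
        rows.append(
            {"location_id": f"{lid}-{j + 1:02d}", "landscape_id": lid,
             **{h: float(local[k]) for k, h in enumerate(habitats)}}
        )
    return rows


def generate_species_pool(config: GeneratorConfig) -> pd.DataFrame:
    """Species pool: base abundance weights, preference row, and traits.

    Base weights follow a log-series distribution (parameter
    ``abundance_shape``), reproducing the dominance of a few species typical
    of bee communities. Traits (sociality, diet breadth, endangerment, body
    size) are attached for downstream demonstrations only.
    """
    config.validate()
    names = _species_names(config.n_species)
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(config.n_landscapes + 1)[-1])

    weights = stats.logser.rvs(
        config.abundance_shape, size=config.n_species, random_state=rng
    ).astype(float)

    if config.preference_matrix is not None:
        pref = config.preference_matrix.reindex(names)
        if pref.isna().any().any():
            raise SurveyDataError(
                "preference_matrix must cover all species sp001..spNNN"
            )
    else:
        pref = uniform_preference(config.n_species, config.focal_habitats)
        preferred = rng.integers(0, len(config.focal_habitats), config.n_species)
        for k, h in enumerate(config.focal_habitats):
            pref.loc[np.asarray(preferred) == k, h] = config.preference_strength

    pool = pd.DataFrame({"species": names, "weight": weights})
    for h in pref.columns:
        pool[f"pref_{h}"] = pref[h].to_numpy()
    pool["sociality"] = np.where(rng.random(config.n_species) < 0.35,
                                 "social", "solitary")
    pool["diet"] = np.where(rng.random(config.n_species) < 0.10,
                            "oligolectic", "polylectic")
    pool["endangered"] = rng.random(config.n_species) < 0.30
    pool["body_size_mm"] = np.round(rng.lognormal(np.log(9.0), 0.35,
                                                  config.n_species), 1)
    return pool


def sample_bees(
    locations: pd.DataFrame,
    pool: pd.DataFrame,
    effort: float,
    seed: int,
) -> pd.DataFrame:
    """Sample bee counts at every location.

    The total at a location is Poisson with mean ``effort`` scaled by the
    location's attractiveness (abundance-weighted mean of cover-weighted
    preference, equal to 1 for a neutral community); species identities are
    multinomial with weights base abundance × preference for the local cover
    mix. Zero-count rows are omitted.
    """
    if effort < 0:
        raise SurveyDataError("effort must be nonnegative")
    pref_cols = [c for c in pool.columns if c.startswith("pref_")]
    habitats = [c.removeprefix("pref_") for c in pref_cols]
    missing = [h for h in habitats if h not in locations.columns]
    if missing:
        raise SurveyDataError(f"preference matrix names unknown habitats: {missing}")

    base = pool["weight"].to_numpy(dtype=float)
    pref = pool[pref_cols].to_numpy(dtype=float)  # species x habitat
    species = pool["species"].to_numpy()

    ss = np.random.SeedSequence(seed)
    land_ids = pd.unique(locations["landscape_id"])
    land_rngs = {
        lid: np.random.default_rng(s)
        for lid, s in zip(land_ids, ss.spawn(len(land_ids)))
    }

    records = []
    for _, loc in locations.iterrows():
        rng = land_rngs[loc["landscape_id"]]
        cover = loc[habitats].to_numpy(dtype=float)
        if cover.sum() <= 0:
            raise SurveyDataError(
                f"location {loc['location_id']!r} has zero focal-habitat cover"
            )
        cover = cover / cover.sum()
        w = base * (pref @ cover)  # species sampling weights at this mix
        attract = w.sum() / base.sum()
        total = rng.poisson(effort * attract)
        if total == 0:
            continue
        counts = rng.multinomial(total, w / w.sum())
        for s_idx in np.nonzero(counts)[0]:
            records.append(
                {"location_id": loc["location_id"], "species": species[s_idx],
                 "abundance": int(counts[s_idx])}
            )
    return pd.DataFrame(records, columns=["location_id", "species", "abundance"])


def generate_dataset(config: GeneratorConfig) -> SurveyDataset:
    """Run the full generator: landscapes, locations, bee records, traits."""
    landscapes, locations = generate_landscapes(config)
    pool = generate_species_pool(config)
    # distinct stream for sampling, derived from the root seed
    bees = sample_bees(locations, pool, config.effort, seed=config.seed + 1_000_003)
    traits = pool[["species", "sociality", "diet", "endangered", "body_size_mm"]].copy()
    return SurveyDataset(landscapes=landscapes, locations=locations,
                         bees=bees, traits=traits)
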