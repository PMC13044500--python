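"""Bipartite species-habitat network construction.

A landscape's network is a habitat × species abundance matrix: bees sampled
at all locations sharing a dominant habitat are aggregated into that
habitat's row. The location × species matrix underlying it is kept for the
extinction simulation. Metanetworks aggregate over all landscapes, and the
probabilistic-assignment ensemble re-draws each location's habitat from its
local cover fractions to address ambiguous mixed-cover locations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survey import (
    FOCAL_HABITATS,
    SurveyDataError,
    habitat_cover_columns,
)


class EmptyNetworkError(SurveyDataError):
    """Raised when a landscape has no bee records to build a network from."""


@dataclass
class HabitatNetwork:
    """Habitat × species abundance matrix for one landscape.

    ``matrix`` is a DataFrame with habitats as rows and species as columns,
    both sorted alphabetically; entries are nonnegative integer counts and no
    species column is all-zero.
    """

    landscape_id: str
    matrix: pd.DataFrame

    @property
    def habitats(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def species(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def network_size(self) -> int:
        return network_size(self)

    @property
    def total_abundance(self) -> int:
        return int(self.matrix.to_numpy().sum())

    def to_edge_list(self) -> pd.DataFrame:
        long = self.matrix.stack().rename("weight").reset_index()
        long.columns = ["habitat", "species", "weight"]
        return long[long["weight"] > 0].reset_index(drop=True)


@dataclass
class LocationMatrix:
    """Location × species abundance matrix with per-row habitat identity.

    Collapsing rows by habitat reproduces the landscape's HabitatNetwork
    exactly; rows are the (non-excluded) sampling locations, including
    locations where no bees were caught.
    """

    landscape_id: str
    matrix: pd.DataFrame           # locations x species
    habitats: pd.Series            # habitat identity per location row

    def collapse(self) -> HabitatNetwork:
        collapsed = self.matrix.groupby(self.habitats).sum()
        collapsed = collapsed.sort_index()
        collapsed = collapsed[sorted(collapsed.columns)]
        collapsed.index.name = None
        return HabitatNetwork(self.landscape_id, collapsed.astype(int))


def network_size(net: HabitatNetwork) -> int:
    """Number of bee species multiplied by the number of habitat types."""
    n_hab, n_sp = net.matrix.shape
    if n_hab == 0 or n_sp == 0:
        raise EmptyNetworkError(f"empty network for landscape {net.landscape_id!r}")
    return n_hab * n_sp


def build_location_matrix(
    locations: pd.DataFrame, bees: pd.DataFrame, landscape_id
) -> LocationMatrix:
    """Location × species matrix for one landscape.

    Expects settlement exclusion and dominant-habitat assignment to have been
    applied to ``locations``. Species with zero total abundance in the
    landscape are dropped; locations without bees keep an all-zero row.
    """
    locs = locations.loc[locations["landscape_id"] == landscape_id]
    if locs.empty:
        raise SurveyDataError(f"no locations for landscape {landscape_id!r}")
    if "dominant_habitat" not in locs.columns:
        raise SurveyDataError("dominant habitats must be assigned first")

    loc_ids = list(locs["location_id"])
    recs = bees.loc[bees["location_id"].isin(loc_ids)]
    if recs.empty or recs["abundance"].sum() == 0:
        raise EmptyNetworkError(f"landscape {landscape_id!r} has no bee records")

    mat = (
        recs.pivot_table(index="location_id", columns="species",
                         values="abundance", aggfunc="sum", fill_value=0)
        .reindex(loc_ids, fill_value=0)
    )
    mat = mat[sorted(mat.columns)].astype(int)
    mat = mat.loc[:, mat.sum(axis=0) > 0]
    habitats = locs.set_index("location_id")["dominant_habitat"].reindex(mat.index)
    mat.columns.name = None
    mat.index.name = None
    return LocationMatrix(str(landscape_id), mat, habitats)


def build_network(
    locations: pd.DataFrame, bees: pd.DataFrame, landscape_id
) -> HabitatNetwork:
    """Habitat × species network: aggregate bees over locations per habitat."""
    return build_location_matrix(locations, bees, landscape_id).collapse()


def build_all_networks(
    locations: pd.DataFrame, bees: pd.DataFrame
) -> dict[str, HabitatNetwork]:
    """Networks for every landscape present in ``locations``."""
    out = {}
    for lid in pd.unique(locations["landscape_id"]):
        out[str(lid)] = build_network(locations, bees, lid)
    return out


def build_metanetworks(
    locations: pd.DataFrame, bees: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate across landscapes.

    Returns ``(species_meta, location_meta)``: the habitat × species
    abundance metanetwork summed over all landscapes, and the habitat ×
    landscape matrix of sampling-location counts.
    """
    nets = build_all_networks(locations, bees)
    species_meta = None
    for net in nets.values():
        species_meta = net.matrix if species_meta is None else (
            species_meta.add(net.matrix, fill_value=0)
        )
    species_meta = species_meta.fillna(0).astype(int)
    species_meta = species_meta.sort_index()[sorted(species_meta.columns)]

    location_meta = (
        locations.groupby(["dominant_habitat", "landscape_id"])
        .size()
        .unstack(fill_value=0)
        .sort_index()
    )
    location_meta.index.name = None
    location_meta.columns.name = None
    return species_meta, location_meta


def metanetwork_totals(species_meta: pd.DataFrame) -> pd.DataFrame:
    """Per-habitat totals of the species metanetwork: abundance and richness."""
    return pd.DataFrame(
        {
            "abundance": species_meta.sum(axis=1).astype(int),
            "species_richness": (species_meta > 0).sum(axis=1).astype(int),
        }
    )


def probabilistic_networks(
    locations: pd.DataFrame,
    bees: pd.DataFrame,
    landscape_id,
    n_rep: int = 1000,
    seed: int = 0,
    habitats: tuple[str, ...] = FOCAL_HABITATS,
) -> list[HabitatNetwork]:
    """Ensemble of networks with habitat assignment drawn from local cover.

    Per replicate, each location's habitat is drawn independently with
    probability equal to its 100-m cover fraction, renormalized over the
    focal habitat types (settlement and the minor linear types carry no
    network row, so their cover is redistributed proportionally). Expected
    assignment counts over replicates therefore match cover × n_rep.
    """
    if n_rep < 1:
        raise SurveyDataError("n_rep must be >= 1")
    locs = locations.loc[locations["landscape_id"] == landscape_id]
    if locs.empty:
        raise SurveyDataError(f"no locations for landscape {landscape_id!r}")
    cover_cols = [h for h in habitat_cover_columns(locs) if h in habitats]
    probs = locs[cover_cols].to_numpy(dtype=float)
    row_sums = probs.sum(axis=1)
    if (row_sums <= 0).any():
        bad = locs.loc[row_sums <= 0, "location_id"].tolist()
        raise SurveyDataError(f"zero focal cover at locations {bad}")
    probs = probs / row_sums[:, None]

    base = build_location_matrix(locations, bees, landscape_id)
    loc_order = list(base.matrix.index)
    probs = pd.DataFrame(probs, index=list(locs["location_id"]),
                         columns=cover_cols).reindex(loc_order).to_numpy()

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cum = probs.cumsum(axis=1)
    nets = []
    for _ in range(n_rep):
        u = rng.random(len(loc_order))
        idx = (u[:, None] > cum).sum(axis=1)
        assigned = pd.Series([cover_cols[i] for i in idx], index=loc_order)
        lm = LocationMatrix(str(landscape_id), base.matrix, assigned)
        nets.append(lm.collapse())
    return nets
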