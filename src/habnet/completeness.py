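"""Chao1 sampling completeness for species and habitat-species interactions.

Uses the bias-corrected Chao1 asymptotic richness estimator

    S_chao1 = S_obs + F1 (F1 - 1) / (2 (F2 + 1)),

where F1 and F2 are the numbers of singletons and doubletons (entities
observed exactly once or twice). Completeness is S_obs / S_chao1. Entities
are species (with pooled abundances per landscape) or nonzero cells of a
habitat × species matrix (with cell weights as counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .networks import HabitatNetwork
from .survey import SurveyDataError


@dataclass(frozen=True)
class Chao1Estimate:
    """Observed richness, singleton/doubleton counts, asymptote, completeness."""

    s_obs: int
    f1: int
    f2: int
    s_chao1: float
    completeness: float


def chao1(counts) -> Chao1Estimate:
    """Bias-corrected Chao1 estimate from a multiset of positive counts."""
    arr = np.asarray(list(counts))
    if arr.size == 0:
        raise SurveyDataError("chao1 requires at least one observed entity")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise SurveyDataError("chao1 counts must be positive integers")
        arr = np.round(arr).astype(int)
    if (arr <= 0).any():
        raise SurveyDataError("chao1 counts must be positive integers")

    s_obs = int(arr.size)
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    s_hat = s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))
    return Chao1Estimate(
        s_obs=s_obs, f1=f1, f2=f2, s_chao1=float(s_hat),
        completeness=float(s_obs / s_hat),
    )


def species_completeness(
    bees: pd.DataFrame, locations: pd.DataFrame
) -> pd.DataFrame:
    """Per-landscape species sampling completeness from pooled abundances."""
    merged = bees.merge(
        locations[["location_id", "landscape_id"]], on="location_id", how="inner"
    )
    rows = []
    for lid, grp in merged.groupby("landscape_id", sort=True):
        pooled = grp.groupby("species")["abundance"].sum()
        if pooled.empty:
            raise SurveyDataError(f"landscape {lid!r} has no bee records")
        est = chao1(pooled.to_numpy())
        rows.append({"landscape_id": lid, **est.__dict__})
    return pd.DataFrame(rows)


def interaction_completeness(net: HabitatNetwork) -> Chao1Estimate:
    """Chao1 completeness of habitat-species interactions for one network.

    Entities are the nonzero cells of the matrix; a cell with weight 1 is a
    singleton interaction, weight 2 a doubleton.
    """
    cells = net.matrix.to_numpy().ravel()
    cells = cells[cells > 0]
    if cells.size == 0:
        raise SurveyDataError(
            f"network for landscape {net.landscape_id!r} has no interactions"
        )
    return chao1(cells)


def completeness_table(
    bees: pd.DataFrame,
    locations: pd.DataFrame,
    networks: dict[str, HabitatNetwork],
) -> pd.DataFrame:
    """Species and interaction completeness for every landscape, long format."""
    sp = species_completeness(bees, locations)
    sp.insert(1, "entity", "species")
    rows = []
    for lid in sorted(networks):
        est = interaction_completeness(networks[lid])
        rows.append({"landscape_id": lid, "entity": "interaction", **est.__dict__})
    return pd.concat([sp, pd.DataFrame(rows)], ignore_index=True)
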