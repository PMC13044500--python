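"""Survey data model: landscapes, sampling locations, bee records.

The analysis consumes three tidy tables (plus an optional trait table):

* ``landscapes`` — one row per 1-km² landscape with the proportional cover of
  each habitat type and its Shannon diversity;
* ``locations`` — one row per sampling location with the proportional habitat
  cover within a 100-m radius, the assigned dominant habitat and an exclusion
  flag;
* ``bees`` — one row per (location, species) with the pooled abundance.

Habitat covers arrive precomputed (no GIS work happens here). Coordinates, if
present, are carried through untouched and never used in computation.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The four focal habitat types of the study system (alphabetical).
FOCAL_HABITATS: tuple[str, ...] = ("arable", "forest", "grassland", "orchard")

#: Minor habitat classes: small covers, never carrying a network row.
MINOR_HABITATS: tuple[str, ...] = ("hedgerow", "road", "settlement")

ALL_HABITATS: tuple[str, ...] = tuple(sorted(FOCAL_HABITATS + MINOR_HABITATS))

#: Columns of the locations table that are not habitat cover fractions.
LOCATION_META_COLUMNS = ("location_id", "landscape_id", "dominant_habitat", "excluded")


class SurveyDataError(ValueError):
    """Raised for survey tables that violate referential or cover constraints."""


def shannon_diversity(cover: Mapping[str, float] | pd.Series) -> float:
    """Shannon entropy H = -sum p ln p of a cover composition, in nats.

    Zero-cover classes contribute nothing. Raises on negative proportions or
    an all-zero composition; proportions must sum to ~1 (±0.01).
    """
    p = pd.Series(cover, dtype=float)
    if (p < 0).any():
        raise SurveyDataError(f"negative cover proportion in {dict(p[p < 0])}")
    total = float(p.sum())
    if total <= 0:
        raise SurveyDataError("all-zero cover composition")
    if not 0.99 <= total <= 1.01:
        raise SurveyDataError(f"cover proportions sum to {total:.4f}, expected ~1")
    p = p[p > 0] / total
    return float(-(p * np.log(p)).sum())


def assign_dominant_habitat(local_cover: Mapping[str, float] | pd.Series) -> str:
    """Habitat with the largest cover fraction in the 100-m radius.

    Ties are broken by lexicographic habitat order, with a logged warning, so
    the assignment is deterministic and auditable.
    """
    cov = pd.Series(local_cover, dtype=float)
    if cov.empty:
        raise SurveyDataError("empty cover map")
    if (cov < 0).any():
        raise SurveyDataError("negative local cover")
    top = cov.max()
    winners = sorted(cov.index[cov == top])
    if len(winners) > 1:
        logger.warning(
            "dominant-habitat tie between %s at cover %.3f; lexicographic pick %r",
            winners, top, winners[0],
        )
        warnings.warn(
            f"dominant-habitat tie between {winners}; picking {winners[0]!r}",
            stacklevel=2,
        )
    return winners[0]


def habitat_cover_columns(locations: pd.DataFrame) -> list[str]:
    """Columns of a locations table holding cover fractions."""
    return [c for c in locations.columns if c not in LOCATION_META_COLUMNS]


def assign_dominant_habitats(locations: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of ``locations`` with a ``dominant_habitat`` column."""
    out = locations.copy()
    cover_cols = habitat_cover_columns(out)
    out["dominant_habitat"] = [
        assign_dominant_habitat(row) for _, row in out[cover_cols].iterrows()
    ]
    return out


def exclude_settlement_locations(
    locations: pd.DataFrame, habitat: str = "settlement"
) -> pd.DataFrame:
    """Drop locations whose dominant habitat is ``habitat`` (default settlement).

    Settlement-dominated locations are too few to support a network row and
    are removed from every downstream analysis. The number of removals is
    logged; the returned table carries ``excluded=False`` for all rows.
    """
    if "dominant_habitat" not in locations.columns:
        raise SurveyDataError("dominant habitats must be assigned before exclusion")
    mask = locations["dominant_habitat"] == habitat
    n = int(mask.sum())
    if n:
        logger.info("excluding %d %s-dominant sampling location(s)", n, habitat)
    out = locations.loc[~mask].copy()
    out["excluded"] = False
    return out


@dataclass
class ValidationReport:
    """Outcome of dataset validation: violations found and the cleaned tables."""

    violations: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    landscapes: pd.DataFrame | None = None
    locations: pd.DataFrame | None = None
    bees: pd.DataFrame | None = None

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_dataset(
    landscapes: pd.DataFrame,
    locations: pd.DataFrame,
    bees: pd.DataFrame,
) -> ValidationReport:
    """Check referential integrity and cover sums; merge duplicate bee rows.

    Fatal violations (broken references, bad cover sums, nonpositive
    abundances) are listed in ``violations``; duplicate (location, species)
    rows are merged by summation with a warning. Raises ``SurveyDataError``
    when violations are fatal.
    """
    report = ValidationReport()

    known_landscapes = set(landscapes["landscape_id"])
    bad_ls = locations.loc[~locations["landscape_id"].isin(known_landscapes)]
    for _, row in bad_ls.iterrows():
        report.violations.append(
            f"location {row['location_id']!r} references unknown landscape "
            f"{row['landscape_id']!r}"
        )

    known_locations = set(locations["location_id"])
    bad_loc = bees.loc[~bees["location_id"].isin(known_locations)]
    for _, row in bad_loc.iterrows():
        report.violations.append(
            f"bee record ({row['location_id']!r}, {row['species']!r}) references "
            "an unknown location"
        )

    cover_cols = habitat_cover_columns(locations)
    sums = locations[cover_cols].sum(axis=1)
    for loc_id, s in zip(locations["location_id"], sums):
        if not 0.99 <= s <= 1.01:
            report.violations.append(
                f"location {loc_id!r} cover fractions sum to {s:.4f}"
            )

    if (bees["abundance"] <= 0).any():
        n = int((bees["abundance"] <= 0).sum())
        report.violations.append(f"{n} bee record(s) with nonpositive abundance")

    if (bees["species"] == "Apis mellifera").any():
        report.warnings.append(
            "honeybee records (Apis mellifera) present; the producer is expected "
            "to exclude managed honeybees before analysis"
        )

    clean = bees
    dup = bees.duplicated(subset=["location_id", "species"], keep=False)
    if dup.any():
        report.warnings.append(
            f"{int(dup.sum())} duplicate (location, species) rows merged by summation"
        )
        clean = (
            bees.groupby(["location_id", "species"], as_index=False)["abundance"]
            .sum()
        )

    report.landscapes = landscapes
    report.locations = locations
    report.bees = clean
    if report.violations:
        raise SurveyDataError(
            "dataset validation failed:\n  " + "\n  ".join(report.violations)
        )
    return report


# ---------------------------------------------------------------------------
# CSV readers. UTF-8, header row, dot decimal. `columns` maps our canonical
# names to the names used in the file, to tolerate external table dialects.
# ---------------------------------------------------------------------------

def _read(path, columns: Mapping[str, str] | None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if columns:
        df = df.rename(columns={v: k for k, v in columns.items()})
    return df


def read_landscapes_csv(path, columns: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read the landscape cover table: landscape_id, one column per habitat,
    optionally a precomputed ``shannon_h`` (recomputed if absent)."""
    df = _read(path, columns)
    if "landscape_id" not in df.columns:
        raise SurveyDataError("landscapes table needs a landscape_id column")
    cover_cols = [c for c in df.columns if c not in ("landscape_id", "shannon_h")]
    if len(cover_cols) < 2:
        raise SurveyDataError("landscapes table needs at least two habitat columns")
    if "shannon_h" not in df.columns:
        df["shannon_h"] = [
            shannon_diversity(row) for _, row in df[cover_cols].iterrows()
        ]
    return df


def read_locations_csv(path, columns: Mapping[str, str] | None = None) -> pd.DataFrame:
    df = _read(path, columns)
    for col in ("location_id", "landscape_id"):
        if col not in df.columns:
            raise SurveyDataError(f"locations table needs a {col} column")
    return df


def read_bees_csv(path, columns: Mapping[str, str] | None = None) -> pd.DataFrame:
    df = _read(path, columns)
    for col in ("location_id", "species", "abundance"):
        if col not in df.columns:
            raise SurveyDataError(f"bees table needs a {col} column")
    return df


def read_traits_csv(path, columns: Mapping[str, str] | None = None) -> pd.DataFrame:
    df = _read(path, columns)
    if "species" not in df.columns:
        raise SurveyDataError("traits table needs a species column")
    return df


def landscape_cover(landscapes: pd.DataFrame, landscape_id) -> pd.Series:
    """Cover composition of one landscape as a Series indexed by habitat."""
    row = landscapes.loc[landscapes["landscape_id"] == landscape_id]
    if row.empty:
        raise SurveyDataError(f"unknown landscape {landscape_id!r}")
    cover_cols = [c for c in landscapes.columns if c not in ("landscape_id", "shannon_h")]
    return row.iloc[0][cover_cols].astype(float)
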