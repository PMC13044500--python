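"""Habitat preference and avoidance statistics.

For each landscape-habitat pair the deviation statistic is

    deviation = p_bees - p_cover,

where p_bees is the proportion of the landscape's bees caught in locations
assigned to the habitat and p_cover the habitat's proportional cover of the
full mapped landscape. Positive deviations indicate preference (more bees
than expected from area alone), negative ones avoidance. Deviations are
aggregated across landscapes per habitat as a mean with a two-sided 95%
Student-t confidence interval; a habitat is classified as preferred if the
CI lies above zero, avoided if below, neutral otherwise.

Note p_cover uses the habitat's share of the *entire* mapped landscape (all
habitat classes), while p_bees is computed over the focal network rows only;
with nonzero minor-habitat cover the focal deviations therefore sum to a
small positive constant by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .networks import HabitatNetwork
from .survey import FOCAL_HABITATS, SurveyDataError, landscape_cover


def landscape_deviations(
    net: HabitatNetwork,
    landscapes: pd.DataFrame,
    habitats: tuple[str, ...] = FOCAL_HABITATS,
) -> pd.DataFrame:
    """Preference deviations for one landscape's network.

    A habitat absent from both the landscape (zero cover) and the network is
    omitted; zero cover with bees present still contributes (possible under
    100-m mixing at landscape edges).
    """
    total = net.total_abundance
    if total <= 0:
        raise SurveyDataError(
            f"landscape {net.landscape_id!r} has zero total abundance"
        )
    cover = landscape_cover(landscapes, net.landscape_id)
    row_sums = net.matrix.sum(axis=1)

    rows = []
    for h in habitats:
        p_cover = float(cover.get(h, 0.0))
        p_bees = float(row_sums.get(h, 0)) / total
        if p_cover == 0.0 and p_bees == 0.0:
            continue
        rows.append(
            {"landscape_id": net.landscape_id, "habitat": h,
             "p_bees": p_bees, "p_cover": p_cover,
             "deviation": p_bees - p_cover}
        )
    return pd.DataFrame(rows, columns=["landscape_id", "habitat",
                                       "p_bees", "p_cover", "deviation"])


def all_landscape_deviations(
    networks: dict[str, HabitatNetwork],
    landscapes: pd.DataFrame,
    habitats: tuple[str, ...] = FOCAL_HABITATS,
) -> pd.DataFrame:
    """Deviation table over every landscape (one row per landscape-habitat)."""
    parts = [
        landscape_deviations(networks[lid], landscapes, habitats)
        for lid in sorted(networks)
    ]
    return pd.concat(parts, ignore_index=True)


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    n = len(values)
    mean = float(np.mean(values))
    if n < 2:
        return mean, np.nan, np.nan
    sem = float(np.std(values, ddof=1)) / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + level / 2, df=n - 1)
    return mean, mean - tcrit * sem, mean + tcrit * sem


def classify(ci_low: float, ci_high: float) -> str:
    if np.isnan(ci_low) or np.isnan(ci_high):
        return "neutral"
    if ci_low > 0:
        return "preference"
    if ci_high < 0:
        return "avoidance"
    return "neutral"


def aggregate_preference(deviations: pd.DataFrame) -> pd.DataFrame:
    """Per-habitat mean deviation with 95% t-CI and classification.

    Habitats contributed by fewer than two landscapes are flagged
    unreliable (CI undefined, classification neutral).
    """
    rows = []
    for h, grp in deviations.groupby("habitat", sort=True):
        vals = grp["deviation"].to_numpy(dtype=float)
        mean, lo, hi = _t_ci(vals)
        rows.append(
            {"habitat": h, "n_landscapes": len(vals), "mean_deviation": mean,
             "ci_low": lo, "ci_high": hi,
             "classification": classify(lo, hi),
             "reliable": len(vals) >= 2}
        )
    return pd.DataFrame(rows)


def probabilistic_deviations(
    ensembles: dict[str, list[HabitatNetwork]],
    landscapes: pd.DataFrame,
    habitats: tuple[str, ...] = FOCAL_HABITATS,
) -> pd.DataFrame:
    """Mean deviation over replicate networks per landscape-habitat pair.

    ``ensembles`` maps landscape id to the replicate networks produced by
    probabilistic habitat assignment; deviations are averaged over replicates
    before cross-landscape aggregation, exactly as for the deterministic
    assignment. Habitats with zero cover and zero bees in every replicate of
    a landscape are omitted for that landscape.
    """
    rows = []
    for lid in sorted(ensembles):
        reps = ensembles[lid]
        if not reps:
            raise SurveyDataError(f"empty ensemble for landscape {lid!r}")
        acc: dict[str, list[float]] = {}
        covers: dict[str, float] = {}
        for net in reps:
            dev = landscape_deviations(net, landscapes, habitats)
            for _, r in dev.iterrows():
                acc.setdefault(r["habitat"], []).append(r["deviation"])
                covers[r["habitat"]] = r["p_cover"]
        for h in sorted(acc):
            vals = acc[h]
            # absent replicates contribute deviation -p_cover (no bees there)
            missing = len(reps) - len(vals)
            mean_dev = (sum(vals) + missing * (-covers[h])) / len(reps)
            rows.append({"landscape_id": lid, "habitat": h,
                         "deviation": mean_dev})
    return pd.DataFrame(rows, columns=["landscape_id", "habitat", "deviation"])


def probabilistic_preference(
    ensembles: dict[str, list[HabitatNetwork]],
    landscapes: pd.DataFrame,
    habitats: tuple[str, ...] = FOCAL_HABITATS,
) -> pd.DataFrame:
    """Aggregate the probabilistic-assignment deviations across landscapes."""
    return aggregate_preference(
        probabilistic_deviations(ensembles, landscapes, habitats)
    )
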