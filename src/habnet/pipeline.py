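"""End-to-end analysis pipeline.

Runs the full chain — simulate (or ingest) → validate → exclude settlement →
build networks → completeness → preference → modularity → extinction →
regression layer — and collects every result table in one bundle. Each stage
is seeded from one root seed through named child streams, so a rerun with
the same inputs and seed reproduces the bundle bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .completeness import completeness_table
from .extinction import (
    HABITAT_ORDER,
    RANDOMIZED,
    extinction_analysis,
)
from .models import (
    ModelResult,
    correlations,
    fit_modularity_models,
    fit_robustness_models,
    fit_species_loss_model,
)
from .modularity import modularity_zscores
from .networks import (
    build_all_networks,
    build_location_matrix,
    build_metanetworks,
    metanetwork_totals,
    network_size,
    probabilistic_networks,
)
from .preference import (
    aggregate_preference,
    all_landscape_deviations,
    probabilistic_preference,
)
from .survey import (
    exclude_settlement_locations,
    validate_dataset,
)
from .synthetic import GeneratorConfig, SurveyDataset, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """All tables produced by one pipeline run."""

    dataset: SurveyDataset
    networks: dict
    indices: pd.DataFrame
    completeness: pd.DataFrame
    deviations: pd.DataFrame
    preference: pd.DataFrame
    preference_probabilistic: pd.DataFrame | None
    modularity: pd.DataFrame
    robustness: pd.DataFrame
    losses: pd.DataFrame
    models: dict[str, ModelResult]
    correlations: pd.DataFrame
    species_meta: pd.DataFrame
    location_meta: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.dataset.write(directory / "input")
        self.indices.to_csv(directory / "indices.csv", index=False)
        self.completeness.to_csv(directory / "completeness.csv", index=False)
        self.deviations.to_csv(directory / "preference_deviations.csv", index=False)
        self.preference.to_csv(directory / "preference_summary.csv", index=False)
        if self.preference_probabilistic is not None:
            self.preference_probabilistic.to_csv(
                directory / "preference_probabilistic.csv", index=False
            )
        self.modularity.to_csv(directory / "modularity.csv", index=False)
        self.robustness.to_csv(directory / "robustness.csv", index=False)
        self.losses.to_csv(directory / "species_losses.csv", index=False)
        self.correlations.to_csv(directory / "correlations.csv", index=False)
        self.species_meta.to_csv(directory / "metanetwork_species.csv")
        self.location_meta.to_csv(directory / "metanetwork_locations.csv")
        coef_rows = []
        for name, res in self.models.items():
            for term in res.params.index:
                coef_rows.append(
                    {"model": name, "term": term,
                     "estimate": res.params[term],
                     "se": res.bse.get(term, np.nan),
                     "p": res.pvalues.get(term, np.nan),
                     "n": res.n, "formula": res.formula,
                     "dropped": ";".join(res.dropped_terms)}
                )
        pd.DataFrame(coef_rows).to_csv(directory / "models.csv", index=False)
        for name, res in self.models.items():
            if res.predictions is not None:
                res.predictions.to_csv(
                    directory / f"predictions_{name}.csv", index=False
                )
        (directory / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, default=str)
        )


def run_pipeline(
    config: GeneratorConfig | None = None,
    dataset: SurveyDataset | None = None,
    seed: int = 0,
    n_prob_rep: int = 1000,
    n_null: int = 1000,
    n_rep: int = 1000,
    n_rep_null: int | None = None,
    probabilistic: bool = True,
) -> PipelineResult:
    """Execute every analysis stage and return the result bundle.

    Provide either a generator ``config`` (synthetic run) or an ingested
    ``dataset``. Stage-level failures raise with the stage named.
    ``n_prob_rep``, ``n_rep``, ``n_null`` control the probabilistic-network,
    extinction-repetition and null-ensemble sizes.
    """
    t0 = time.time()
    stages: dict[str, float] = {}

    def mark(stage: str):
        stages[stage] = round(time.time() - t0, 2)

    if (config is None) == (dataset is None):
        raise ValueError("provide exactly one of config or dataset")
    if config is not None:
        dataset = generate_dataset(config)
    mark("simulate/ingest")

    report = validate_dataset(dataset.landscapes, dataset.locations, dataset.bees)
    bees = report.bees
    locations = exclude_settlement_locations(dataset.locations)
    mark("validate")

    networks = build_all_networks(locations, bees)
    loc_matrices = {
        lid: build_location_matrix(locations, bees, lid) for lid in networks
    }
    species_meta, location_meta = build_metanetworks(locations, bees)
    mark("build")

    comp = completeness_table(bees, locations, networks)
    mark("completeness")

    deviations = all_landscape_deviations(networks, dataset.landscapes)
    pref = aggregate_preference(deviations)
    pref_prob = None
    if probabilistic:
        ss = np.random.SeedSequence(seed).spawn(len(networks))
        ensembles = {
            lid: probabilistic_networks(
                locations, bees, lid, n_rep=n_prob_rep,
                seed=int(s.generate_state(1)[0] % (2**31)),
            )
            for lid, s in zip(sorted(networks), ss)
        }
        pref_prob = probabilistic_preference(ensembles, dataset.landscapes)
    mark("preference")

    mod = modularity_zscores(networks, n_null=n_null, seed=seed + 1)
    mark("modularity")

    robustness, losses = extinction_analysis(
        loc_matrices, scenarios=(RANDOMIZED, HABITAT_ORDER),
        n_rep=n_rep, n_null=n_null, n_rep_null=n_rep_null, seed=seed + 2,
    )
    mark("extinction")

    indices = _index_table(dataset, networks, comp, mod, bees, locations)
    fits: dict[str, ModelResult] = {}
    fits.update(fit_modularity_models(indices))
    fits.update(fit_robustness_models(robustness, indices))
    fits["species_loss"] = fit_species_loss_model(losses, indices)
    corr = correlations(indices)
    mark("models")

    manifest = {
        "habnet_version": __version__,
        "seed": seed,
        "n_rep": n_rep, "n_null": n_null, "n_prob_rep": n_prob_rep,
        "n_rep_null": n_rep_null if n_rep_null is not None else n_rep,
        "synthetic": config is not None,
        "generator_seed": config.seed if config is not None else None,
        "stage_seconds": stages,
    }
    return PipelineResult(
        dataset=dataset, networks=networks, indices=indices,
        completeness=comp, deviations=deviations, preference=pref,
        preference_probabilistic=pref_prob, modularity=mod,
        robustness=robustness, losses=losses, models=fits,
        correlations=corr, species_meta=species_meta,
        location_meta=location_meta, manifest=manifest,
    )


def _index_table(dataset, networks, comp, mod, bees, locations) -> pd.DataFrame:
    """One row per landscape: diversity, size, completeness, modularity."""
    merged = bees.merge(locations[["location_id", "landscape_id"]],
                        on="location_id")
    richness = merged.groupby("landscape_id")["species"].nunique()
    sp = comp[comp["entity"] == "species"].set_index("landscape_id")
    ia = comp[comp["entity"] == "interaction"].set_index("landscape_id")
    rows = []
    for lid in sorted(networks):
        land = dataset.landscapes.loc[
            dataset.landscapes["landscape_id"] == lid
        ].iloc[0]
        mrow = mod.loc[mod["landscape_id"] == lid].iloc[0]
        rows.append(
            {"landscape_id": lid,
             "shannon_h": float(land["shannon_h"]),
             "network_size": network_size(networks[lid]),
             "species_richness": int(richness.get(lid, 0)),
             "total_abundance": networks[lid].total_abundance,
             "q_obs": mrow["q_obs"], "mod_z": mrow["mod_z"],
             "species_completeness": float(sp.loc[lid, "completeness"]),
             "interaction_completeness": float(ia.loc[lid, "completeness"])}
        )
    return pd.DataFrame(rows)


def comparison_report(
    computed: dict[str, float],
    reference: dict[str, float],
    tolerance: dict[str, float] | float = 0.05,
) -> pd.DataFrame:
    """Compare computed statistics against user-supplied reference values.

    Intended for replication runs against an external deposit: the caller
    supplies the published values; nothing is bundled with the package. A
    scalar ``tolerance`` applies to every key; a dict sets per-key absolute
    tolerances.
    """
    rows = []
    for key, ref in reference.items():
        got = computed.get(key)
        tol = tolerance.get(key, np.inf) if isinstance(tolerance, dict) else tolerance
        ok = got is not None and np.isfinite(got) and abs(got - ref) <= tol
        rows.append({"statistic": key, "computed": got, "reference": ref,
                     "abs_diff": np.nan if got is None else abs(got - ref),
                     "tolerance": tol, "within_tolerance": bool(ok)})
    return pd.DataFrame(rows)
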