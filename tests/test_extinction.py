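"""Habitat-loss simulation: persistence curves, AUC robustness, z-scores."""

import numpy as np
import pandas as pd
import pytest

import habnet as hn
from habnet.extinction import _removal_ranks
from habnet.survey import SurveyDataError


def make_lm(matrix, habitats, lid="L"):
    n_loc, n_sp = np.asarray(matrix).shape
    df = pd.DataFrame(
        np.asarray(matrix),
        index=[f"loc{i}" for i in range(n_loc)],
        columns=[f"sp{j}" for j in range(n_sp)],
    )
    return hn.LocationMatrix(lid, df, pd.Series(list(habitats), index=df.index))


class TestSimulateExtinction:
    def test_exclusive_species_collapse_with_their_location(self):
        # every species only at location 0: all lost at whichever step removes it
        lm = make_lm([[1, 2, 3], [0, 0, 0]], ["arable", "arable"])
        with pytest.raises(SurveyDataError):
            # all-zero species columns are rejected, build a valid variant
            hn.simulate_extinction(make_lm([[1, 0], [0, 0]], ["a", "a"]))
        run = hn.simulate_extinction(lm, n_rep=200, seed=0, keep_rep_curves=True)
        for curve in run.per_rep_curves:
            assert curve[0] == 1.0
            assert curve[-1] == 0.0
            assert (np.diff(curve) <= 1e-12).all()

    def test_symmetric_exclusive_species_mean_persistence(self):
        """4 species exclusive to 4 locations: E[persistence after k] = (4-k)/4."""
        lm = make_lm(np.eye(4, dtype=int), ["arable"] * 4)
        run = hn.simulate_extinction(lm, n_rep=5000, seed=3)
        expected = np.array([1.0, 0.75, 0.5, 0.25, 0.0])
        assert np.allclose(run.persistence_curve, expected, atol=0.02)

    def test_habitat_order_never_violated(self):
        habitats = ["orchard", "grassland", "forest", "arable",
                    "orchard", "forest"]
        ranks = _removal_ranks(
            np.array(habitats), hn.HABITAT_ORDER, n_rep=1000,
            rng=np.random.default_rng(0),
        )
        order = {"orchard": 0, "grassland": 1, "forest": 2, "arable": 3}
        hab_rank = np.array([order[h] for h in habitats])
        for rep in ranks:
            removal_habitats = hab_rank[np.argsort(rep)]
            assert (np.diff(removal_habitats) >= 0).all()

    def test_unknown_habitat_in_sequence_rejected(self):
        lm = make_lm([[1], [1]], ["arable", "wetland"])
        with pytest.raises(SurveyDataError, match="wetland"):
            hn.simulate_extinction(lm, hn.HABITAT_ORDER, n_rep=5, seed=0)

    def test_scenarios_identical_on_single_habitat_landscape(self):
        """With one habitat, habitat-order shuffling equals the random shuffle."""
        rng_mat = np.random.default_rng(5).integers(0, 3, size=(6, 8))
        rng_mat[:, rng_mat.sum(0) == 0] = 1
        lm = make_lm(rng_mat, ["arable"] * 6)
        a = hn.simulate_extinction(lm, hn.RANDOMIZED, n_rep=400, seed=9)
        b = hn.simulate_extinction(lm, hn.HABITAT_ORDER, n_rep=400, seed=9)
        assert np.allclose(a.persistence_curve, b.persistence_curve)

    def test_per_run_losses_telescope_to_one(self):
        mat = np.random.default_rng(2).integers(0, 4, (5, 7))
        mat[:, mat.sum(0) == 0] = 1
        lm = make_lm(mat, ["arable", "forest", "orchard", "forest", "arable"])
        run = hn.simulate_extinction(lm, n_rep=100, seed=1)
        assert run.per_location_loss["mean_prop_loss"].sum() == pytest.approx(1.0)
        assert run.persistence_curve[0] == 1.0
        assert run.persistence_curve[-1] == 0.0

    def test_redundant_community_loses_everything_last(self):
        """Every species everywhere: no loss until the final location goes."""
        lm = make_lm(np.ones((4, 5), dtype=int), ["arable"] * 4)
        run = hn.simulate_extinction(lm, n_rep=50, seed=0)
        assert np.allclose(run.persistence_curve[:-1], 1.0)
        assert run.persistence_curve[-1] == 0.0
        table = hn.per_step_species_loss(run)
        assert table["mean_prop_loss"].sum() == pytest.approx(1 / 4)

    def test_concentrated_habitat_attracts_largest_loss(self):
        """Species packed into orchard locations: orchard shows the top loss."""
        mat = np.zeros((6, 8), dtype=int)
        mat[0, :4] = 3
        mat[1, 4:] = 3
        mat[2:, :] = 0
        mat[2:, 0] = 1  # other locations share one common species
        habitats = ["orchard", "orchard", "arable", "arable", "forest", "forest"]
        run = hn.simulate_extinction(make_lm(mat, habitats), n_rep=400, seed=2)
        table = hn.per_step_species_loss(run).set_index("habitat")
        assert table["mean_prop_loss"].idxmax() == "orchard"


class TestRobustnessAUC:
    def test_linear_decline_gives_half(self):
        curve = np.linspace(1, 0, 17)
        assert hn.robustness_auc(curve) == pytest.approx(0.5, abs=0.02)

    def test_late_collapse_near_one(self):
        curve = np.concatenate([np.ones(16), [0.0]])
        assert hn.robustness_auc(curve) >= 15 / 16 - 0.02

    def test_immediate_collapse_near_zero(self):
        curve = np.concatenate([[1.0], np.zeros(16)])
        assert hn.robustness_auc(curve) <= 1 / 16 + 0.02

    def test_spline_close_to_trapezoid_on_monotone_curves(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            drops = rng.random(16)
            curve = np.concatenate([[1.0], 1 - np.cumsum(drops) / drops.sum()])
            curve = np.clip(curve, 0, 1)
            trap = np.trapezoid(curve) / 16
            assert abs(hn.robustness_auc(curve) - trap) <= 0.02

    def test_short_curve_rejected(self):
        with pytest.raises(SurveyDataError):
            hn.robustness_auc([1.0])


class TestRobustnessZScore:
    def test_same_seed_identical(self):
        mat = np.random.default_rng(4).integers(0, 3, (6, 10))
        mat[:, mat.sum(0) == 0] = 1
        lm = make_lm(mat, ["arable", "forest", "orchard"] * 2)
        a = hn.robustness_zscore(lm, n_null=30, n_rep=100, seed=5)
        b = hn.robustness_zscore(lm, n_null=30, n_rep=100, seed=5)
        assert a.z == b.z
        assert np.array_equal(a.values, b.values)

    def test_redundant_community_above_null_mean(self):
        """All species everywhere is maximally robust; margin-fixed nulls
        fragment occurrences, so the observed AUC sits above the null mean."""
        lm = make_lm(np.full((5, 6), 2, dtype=int), ["arable"] * 5)
        ens = hn.robustness_zscore(lm, n_null=50, n_rep=150, seed=8)
        assert ens.observed > ens.null_mean

    def test_margin_random_input_has_small_z(self):
        base = np.random.default_rng(11).integers(0, 4, (6, 12))
        base[:, base.sum(0) == 0] = 1
        hits = 0
        for i in range(20):
            null = hn.patefield_null(base, np.random.default_rng(600 + i))
            keep = null.sum(axis=0) > 0
            lm = make_lm(null[:, keep], ["arable", "forest"] * 3)
            ens = hn.robustness_zscore(lm, n_null=60, n_rep=120, seed=i)
            if abs(ens.z) < 2:
                hits += 1
        assert hits >= 16


class TestRedundancyMonotonicity:
    def test_duplicating_locations_never_lowers_robustness(self):
        rng = np.random.default_rng(13)
        for trial in range(20):
            mat = rng.integers(0, 3, (5, 6))
            mat[:, mat.sum(0) == 0] = 1
            habs = ["arable", "forest", "orchard", "grassland", "arable"]
            base = hn.simulate_extinction(make_lm(mat, habs),
                                          n_rep=300, seed=trial)
            doubled = hn.simulate_extinction(
                make_lm(np.vstack([mat, mat]), habs * 2),
                n_rep=300, seed=trial,
            )
            assert doubled.rob_obs >= base.rob_obs - 0.02


def test_extinction_analysis_table_shapes(small_dataset, small_analysis):
    locations, networks = small_analysis
    lms = {lid: hn.build_location_matrix(locations, small_dataset.bees, lid)
           for lid in list(networks)[:2]}
    rob, losses = hn.extinction_analysis(lms, n_rep=100, n_null=20,
                                         n_rep_null=50, seed=1)
    assert len(rob) == 4  # 2 landscapes x 2 scenarios
    assert set(rob["scenario"]) == {"randomized", "habitat_order"}
    assert ((rob["rob_obs"] >= 0) & (rob["rob_obs"] <= 1)).all()
    n_locs = sum(len(lm.matrix) for lm in lms.values())
    assert len(losses) == 2 * n_locs
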