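"""Neighborhood profiles, K-means niches, ratio comparisons, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score

from tmeniche import CellMap, clinical_panel
from tmeniche.niche import (
    ISOLATED,
    cluster_units_by_niches,
    compare_group_ratios,
    fit_niches,
    neighborhood_profile,
    niche_ratios,
)
from tmeniche.synthetic_data import NicheSpec, simulate_cell_map

from conftest import make_random_map


def map_from_points(points, types, panel=None, roi="r0", patient="p0"):
    panel = panel or clinical_panel()
    pts = np.asarray(points, dtype=float)
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(len(pts))],
            "roi_id": roi, "patient_id": patient,
            "x": pts[:, 0], "y": pts[:, 1], "cell_type": list(types),
        }
    )
    return CellMap(cells, panel)


def brute_force_profiles(cell_map, radius):
    """O(n^2) oracle for neighbor-type fractions."""
    categories = list(cell_map.panel.types) + ["other"]
    cells = cell_map.cells
    out = np.zeros((len(cells), len(categories)))
    n_count = np.zeros(len(cells), dtype=int)
    for roi, sub in cells.groupby("roi_id", sort=False):
        pts = sub[["x", "y"]].to_numpy(float)
        d = cdist(pts, pts)
        idx = sub.index.to_numpy()
        for a in range(len(idx)):
            nbr = np.flatnonzero((d[a] <= radius) & (np.arange(len(idx)) != a))
            n_count[idx[a]] = len(nbr)
            for b in nbr:
                t = sub.iloc[b]["cell_type"]
                out[idx[a], categories.index(t)] += 1
    with np.errstate(invalid="ignore"):
        frac = np.where(n_count[:, None] > 0, out / n_count[:, None], 0.0)
    return frac, n_count


class TestProfiles:
    def test_collinear_hand_geometry(self):
        cm = map_from_points([(0, 0), (10, 0), (20, 0)], ["Th", "CTL", "Th"])
        prof = neighborhood_profile(cm, radius=15.0)
        assert prof.loc[1, "Th"] == 1.0 and prof.loc[1, "neighbor_count"] == 2
        assert prof.loc[0, "CTL"] == 1.0 and prof.loc[0, "neighbor_count"] == 1
        assert prof.loc[2, "CTL"] == 1.0

    def test_isolated_cell_zero_vector(self):
        cm = map_from_points([(0, 0), (500, 500)], ["Th", "CTL"])
        prof = neighborhood_profile(cm, radius=15.0)
        assert prof["neighbor_count"].tolist() == [0, 0]
        assert prof.drop(columns="neighbor_count").to_numpy().sum() == 0

    def test_matches_bruteforce_oracle(self):
        cm = make_random_map(5, n_cells=2000, bounds=(0, 0, 800, 800))
        prof = neighborhood_profile(cm, radius=50.0)
        frac, n_count = brute_force_profiles(cm, 50.0)
        np.testing.assert_array_equal(
            prof["neighbor_count"].to_numpy(), n_count
        )
        np.testing.assert_allclose(
            prof.drop(columns="neighbor_count").to_numpy(), frac, atol=1e-12
        )

    def test_neighbor_count_monotone_in_radius(self):
        cm = make_random_map(6, n_cells=400)
        prev = None
        for radius in (10.0, 25.0, 50.0, 100.0):
            n = neighborhood_profile(cm, radius)["neighbor_count"]
            if prev is not None:
                assert (n >= prev).all()
            prev = n

    def test_untyped_cells_rejected(self, panel7):
        cm = make_random_map(0, n_cells=10)
        cm.cells.loc[3, "cell_type"] = None
        with pytest.raises(ValueError, match="typed"):
            neighborhood_profile(cm, 15.0)


class TestFitNiches:
    def test_single_cluster_centroid_is_mean_profile(self):
        cm = make_random_map(1, n_cells=300)
        prof = neighborhood_profile(cm, 50.0)
        model = fit_niches(prof, K=1, seed=0)
        fitted = prof[prof["neighbor_count"] > 0].drop(columns="neighbor_count")
        np.testing.assert_allclose(
            model.centroids.iloc[0].to_numpy(), fitted.mean(axis=0).to_numpy()
        )

    def test_two_planted_archetypes_recovered_exactly(self):
        """Disjoint pure-CTL and pure-Tumor blobs split with ARI 1.0."""
        a, _ = simulate_cell_map(
            [NicheSpec("ctl", {"CTL": 1.0}, blob_radius=20, cells_per_blob=150)],
            0.0, bounds=(0, 0, 200, 200), seed=0, roi_id="rA",
        )
        b, _ = simulate_cell_map(
            [NicheSpec("fb", {"Tumor": 1.0}, blob_radius=20, cells_per_blob=150)],
            0.0, bounds=(0, 0, 200, 200), seed=1, roi_id="rB",
        )
        cells = pd.concat([a.cells, b.cells], ignore_index=True)
        cells["patient_id"] = "p0"
        cm = CellMap(cells, a.panel, {**a.roi_bounds, **b.roi_bounds})
        prof = neighborhood_profile(cm, 60.0)
        model = fit_niches(prof, K=2, seed=0)
        truth = (cells["roi_id"] == "rA").astype(int)
        keep = model.assignments != ISOLATED
        ari = adjusted_rand_score(truth[keep], model.assignments[keep])
        assert ari == 1.0

    def test_same_seed_identical_assignments(self):
        cm = make_random_map(2, n_cells=500)
        prof = neighborhood_profile(cm, 50.0)
        m1 = fit_niches(prof, K=4, seed=7)
        m2 = fit_niches(prof, K=4, seed=7)
        pd.testing.assert_series_equal(m1.assignments, m2.assignments)

    def test_relabeling_descending_size(self):
        cm = make_random_map(3, n_cells=600)
        prof = neighborhood_profile(cm, 50.0)
        model = fit_niches(prof, K=4, seed=0)
        sizes = model.assignments[model.assignments != ISOLATED].value_counts()
        assert list(sizes.index) == sorted(sizes.index)  # 0 is largest
        assert (sizes.sort_index().diff().dropna() <= 0).all()

    def test_k_exceeding_distinct_profiles_raises(self):
        cm = map_from_points([(0, 0), (5, 0), (500, 500)], ["Th", "Th", "Th"])
        prof = neighborhood_profile(cm, 15.0)
        with pytest.raises(ValueError, match="distinct"):
            fit_niches(prof, K=5, seed=0)


class TestRatios:
    def test_hand_ratios_and_row_sums(self):
        cm = map_from_points(
            [(i * 100.0, 0.0) for i in range(10)], ["Th"] * 10
        )
        assignments = pd.Series([0] * 2 + [1] * 3 + [2] * 5, name="niche")
        from tmeniche.niche import NicheModel
        model = NicheModel(K=3, centroids=pd.DataFrame(),
                           assignments=assignments, inertia=0.0, seed=0)
        ratios = niche_ratios(model, cm, unit="roi")
        np.testing.assert_allclose(ratios.loc["r0"].to_numpy(), [0.2, 0.3, 0.5])

    def test_unknown_unit_rejected(self, planted_products, planted_cohort):
        with pytest.raises(ValueError, match="unit"):
            niche_ratios(
                planted_products["niche_model"],
                planted_cohort["cell_map"], unit="slide",
            )


class TestCompare:
    def test_identical_groups_no_signal(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        out = compare_group_ratios(df, ["a"] * 3 + ["b"] * 3, adjust=False)
        assert out.loc["v", "difference"] == 0.0
        assert out.loc["v", "pvalue"] > 0.99

    def test_welch_toy_numbers(self):
        """{1,2,3} vs {4,5,6}: t = -3/sqrt(2/3) = -3.674, p ~ 0.021."""
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
        out = compare_group_ratios(
            df, ["a"] * 3 + ["b"] * 3, method="welch", adjust=False
        )
        assert out.loc["v", "statistic"] == pytest.approx(-3.674, abs=1e-3)
        assert out.loc["v", "pvalue"] == pytest.approx(0.0214, abs=2e-3)

    def test_small_group_rejected(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="at least 2"):
            compare_group_ratios(df, ["a", "b", "b"])

    def test_bh_adjustment_monotone(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(20, 6)),
                          columns=[f"v{i}" for i in range(6)])
        df["v0"] += np.repeat([0, 3], 10)  # one real effect
        out = compare_group_ratios(df, ["a"] * 10 + ["b"] * 10)
        assert (out["p_adjusted"] >= out["pvalue"] - 1e-15).all()
        assert out.loc["v0", "p_adjusted"] < 0.05


class TestUnitClustering:
    def test_two_identical_groups_split_exactly(self):
        rows = [[1.0, 0.0, 0.0]] * 4 + [[0.0, 0.0, 1.0]] * 4
        table = pd.DataFrame(rows, index=[f"u{i}" for i in range(8)],
                             columns=["IN-0", "IN-1", "IN-2"])
        out = cluster_units_by_niches(table, k=2)
        labels = out["clusters"]
        assert labels.iloc[:4].nunique() == 1
        assert labels.iloc[4:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_flat_clusters_invariant_to_row_order(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(
            rng.dirichlet(np.ones(4), size=12),
            index=[f"u{i:02d}" for i in range(12)],
        )
        out1 = cluster_units_by_niches(table, k=3)
        shuffled = table.sample(frac=1.0, random_state=1)
        out2 = cluster_units_by_niches(shuffled, k=3)
        pd.testing.assert_series_equal(out1["clusters"], out2["clusters"])

    def test_single_unit_rejected(self):
        with pytest.raises(ValueError, match="2 units"):
            cluster_units_by_niches(pd.DataFrame([[1.0, 0.0]]))
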