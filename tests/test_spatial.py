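import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from spatialtme import qc, spatial
from spatialtme.errors import ConfigError

from conftest import make_dataset, toy_cells


def brute_force_knn(coords, k):
    """O(n²) kNN oracle: ties broken by ascending index."""
    n = len(coords)
    d = squareform(pdist(coords))
    out = np.empty((n, k), dtype=int)
    for i in range(n):
        order = sorted((d[i, j], j) for j in range(n) if j != i)
        out[i] = [j for _, j in order[:k]]
    return out


def univariate_moran_oracle(x, neighbors):
    """Double-loop univariate Moran's I over binary kNN lists."""
    x = np.asarray(x, dtype=float)
    n, k = neighbors.shape
    xc = x - x.mean()
    num = 0.0
    for i in range(n):
        for j in neighbors[i]:
            num += xc[i] * xc[j]
    return n / (n * k) * num / (xc**2).sum()


class TestKnnWeights:
    def test_collinear_hand_fixture_ties_to_lower_index(self):
        coords = np.array([[0.0, 0], [1, 0], [2, 0], [3, 0]])
        w = spatial.knn_weights(coords, k=1)
        np.testing.assert_array_equal(w.neighbors.ravel(), [1, 0, 1, 2])

    def test_k3_of_four_cells_is_complete_graph(self):
        coords = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]])
        w = spatial.knn_weights(coords, k=3)
        for i in range(4):
            assert set(w.neighbors[i]) == set(range(4)) - {i}
        assert w.s0 == 12

    @pytest.mark.parametrize("n", [50, 500, 2500])
    def test_matches_brute_force_oracle(self, n, rng):
        coords = rng.uniform(0, 100, size=(n, 2))
        w = spatial.knn_weights(coords, k=3)
        np.testing.assert_array_equal(w.neighbors, brute_force_knn(coords, 3))

    def test_too_few_cells_rejected(self):
        with pytest.raises(ConfigError):
            spatial.knn_weights(np.zeros((3, 2)), k=3)


class TestRipleyK:
    def test_two_cells_within_radius(self):
        coords = np.array([[0.0, 0], [10.0, 0]])
        assert spatial.ripley_k(coords, None, r=27.0, area=1.0) == pytest.approx(1.0)

    def test_zero_radius_counts_nothing(self, rng):
        coords = rng.uniform(0, 10, size=(30, 2))
        assert spatial.ripley_k(coords, None, r=0.0, area=100.0) == 0.0

    def test_pair_counting_matches_quadratic_oracle(self, rng):
        coords = rng.uniform(0, 200, size=(300, 2))
        r, area = 30.0, 200.0 * 200.0
        d = squareform(pdist(coords))
        np.fill_diagonal(d, np.inf)
        oracle = area * (d <= r).sum() / (300 * 299)
        assert spatial.ripley_k(coords, None, r, area) == pytest.approx(oracle, abs=1e-12)

    def test_csr_mean_matches_poisson_expectation(self):
        # interior-dominated regime: mean K(27) within 5% of pi*27^2
        r, w, h = 27.0, 900.0, 700.0
        vals = []
        for rep in range(100):
            rng = np.random.default_rng(rep)
            coords = rng.uniform([0, 0], [w, h], size=(1000, 2))
            vals.append(spatial.ripley_k(coords, None, r, w * h))
        assert np.mean(vals) == pytest.approx(np.pi * r**2, rel=0.05)

    def test_singleton_subset_is_missing(self, rng):
        coords = rng.uniform(0, 10, size=(5, 2))
        assert spatial.ripley_k(coords, np.array([1, 0, 0, 0, 0], bool), 5.0, 100.0) is None


class TestDoce:
    def test_whole_population_has_doce_exactly_zero(self, rng):
        coords = rng.uniform(0, 100, size=(200, 2))
        labels = np.array(["all"] * 200, dtype=object)
        res = spatial.doce(coords, labels, "all", r=20.0, area=10_000.0)
        assert res.doce == 0.0

    def test_random_thinning_is_centered_at_zero(self):
        # a CSR-thinned subset has the same K as the full pattern in expectation
        vals = []
        for rep in range(100):
            rng = np.random.default_rng(rep)
            coords = rng.uniform(0, 500, size=(400, 2))
            labels = np.where(rng.random(400) < 0.3, "sub", "rest")
            res = spatial.doce(coords, labels, "sub", r=27.0, area=500.0**2)
            vals.append(res.doce)
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se + 1e-9

    def test_unit_rescaling_changes_doce_by_exactly_c_squared(self, rng):
        # K carries units of area, so rescaling coords by c (r by c, area by c²)
        # multiplies DOCE by exactly c²; the pair counts themselves are identical
        coords = rng.uniform(0, 100, size=(150, 2))
        labels = rng.choice(["a", "b"], 150)
        c = 5.5
        r1 = spatial.doce(coords, labels, "a", r=20.0, area=100.0**2)
        r2 = spatial.doce(coords * c, labels, "a", r=20.0 * c, area=(100.0 * c) ** 2)
        assert r2.doce == pytest.approx(r1.doce * c**2, rel=1e-12)

    def test_absent_phenotype_recorded_as_missing(self, rng):
        coords = rng.uniform(0, 10, size=(20, 2))
        res = spatial.doce(coords, np.array(["x"] * 20, dtype=object), "ghost", area=100.0)
        assert res.doce is None and res.reason


class TestGeneSetScore:
    def test_single_present_gene_gives_its_zscore(self, rng):
        expr = rng.normal(size=(40, 3))
        s = spatial.score_gene_set(expr, ["a", "b", "c"], ["b", "MISSING1", "MISSING2"])
        assert s is None  # only 1 present gene → skipped
        s = spatial.score_gene_set(expr, ["a", "b", "c"], ["b", "c"])
        z = (expr[:, 1] - expr[:, 1].mean()) / expr[:, 1].std()
        z2 = (expr[:, 2] - expr[:, 2].mean()) / expr[:, 2].std()
        np.testing.assert_allclose(s, (z + z2) / 2, atol=1e-12)

    def test_identical_cells_score_zero(self):
        expr = np.ones((10, 4))
        s = spatial.score_gene_set(expr, list("abcd"), ["a", "b"])
        np.testing.assert_array_equal(s, 0.0)


class TestSpatialEnrichment:
    def test_constant_scores_are_skipped(self, rng):
        coords = rng.uniform(0, 10, size=(20, 2))
        res = spatial.spatial_enrichment(np.ones(20), coords, n_perm=19, rng=rng)
        assert res.p_empirical is None and "variance" in res.reason

    def test_too_few_high_cells_reports_reason(self, rng):
        scores = np.zeros(30)
        scores[0] = 100.0
        res = spatial.spatial_enrichment(scores, rng.uniform(0, 10, (30, 2)), n_perm=19, rng=rng)
        assert res.p_empirical is None and "too few" in res.reason

    def test_maximally_dispersed_high_cells_give_p_one(self):
        # the two high cells sit at opposite corners: no permutation is farther
        coords = np.vstack([[0, 0], [100, 100], np.random.default_rng(0).uniform(40, 60, (20, 2))])
        scores = np.zeros(22)
        scores[:2] = 10.0
        res = spatial.spatial_enrichment(scores, coords, n_perm=99, min_high=2,
                                         rng=np.random.default_rng(1))
        assert res.p_empirical == 1.0

    def test_p_respects_permutation_bounds(self, rng):
        scores = rng.normal(size=100)
        res = spatial.spatial_enrichment(scores, rng.uniform(0, 50, (100, 2)), n_perm=49, rng=rng)
        assert 1 / 50 <= res.p_empirical <= 1.0

    def test_invariant_to_rigid_motion(self, rng):
        scores = np.random.default_rng(5).normal(size=80)
        coords = np.random.default_rng(6).uniform(0, 100, (80, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = coords @ R.T + [55.0, -20.0]
        r1 = spatial.spatial_enrichment(scores, coords, n_perm=99, rng=np.random.default_rng(9))
        r2 = spatial.spatial_enrichment(scores, moved, n_perm=99, rng=np.random.default_rng(9))
        assert r1.p_empirical == pytest.approx(r2.p_empirical)
        assert r1.observed_sum_distance == pytest.approx(r2.observed_sum_distance)


class TestBivariateMoran:
    def test_alternating_collinear_fixture_is_minus_one(self):
        w = spatial.knn_weights(np.array([[0.0, 0], [1, 0], [2, 0], [3, 0]]), k=1)
        x = np.array([1.0, -1.0, 1.0, -1.0])
        assert spatial.bivariate_moran(x, x, w) == pytest.approx(-1.0)

    @pytest.mark.parametrize("k", [1, 3, 6])
    def test_x_equals_y_matches_univariate_oracle(self, k, rng):
        coords = rng.uniform(0, 100, size=(300, 2))
        x = rng.normal(size=300)
        w = spatial.knn_weights(coords, k=k)
        ours = spatial.bivariate_moran(x, x, w)
        oracle = univariate_moran_oracle(x, w.neighbors)
        assert ours == pytest.approx(oracle, abs=1e-12)

    def test_permutation_null_is_centered(self):
        rng = np.random.default_rng(17)
        coords = rng.uniform(0, 100, size=(200, 2))
        w = spatial.knn_weights(coords, k=3)
        base_x = rng.normal(size=200)
        base_y = rng.normal(size=200)
        vals = [
            spatial.bivariate_moran(rng.permutation(base_x), rng.permutation(base_y), w)
            for _ in range(1000)
        ]
        assert abs(np.mean(vals)) < 0.01

    def test_zero_variance_is_missing(self, rng):
        coords = rng.uniform(0, 10, size=(10, 2))
        w = spatial.knn_weights(coords, k=2)
        assert spatial.bivariate_moran(np.ones(10), rng.normal(size=10), w) is None


class TestMoranPairScan:
    def _dataset(self, rng):
        n = 60
        cells = toy_cells(n, rng=rng)
        counts = rng.integers(0, 8, size=(n, 4))
        adata = make_dataset(cells, counts, ["LIG", "REC", "FLAT", "OTHER"])
        qc.normalize(adata)
        layer = np.asarray(adata.layers["normalized"]).copy()
        layer[:, 2] = 0.0  # zero-variance gene
        adata.layers["normalized"] = layer
        return adata

    def test_missing_gene_and_zero_variance_reported(self, rng):
        adata = self._dataset(rng)
        pairs = pd.DataFrame(
            {"ligand": ["LIG", "LIG", "FLAT"], "receptor": ["ABSENT", "REC", "OTHER"],
             "source_set": ""}
        )
        out = spatial.moran_pair_scan(adata, pairs, k=3)
        by = out.set_index("receptor")
        assert by.loc["ABSENT", "reason"] == "gene absent from panel"
        assert np.isfinite(by.loc["REC", "I"])
        assert by.loc["OTHER", "reason"] == "zero variance"
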