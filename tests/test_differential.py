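import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from spatialtme import differential as D
from spatialtme.errors import ConfigError, IntegrityError


def bh_oracle(p):
    """Reference BH step-up: sort, m*p/i, enforce monotonicity from the top."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestBhFdr:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(D.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert D.bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_adjusted_never_below_raw(self, rng):
        p = rng.random(50)
        assert (D.bh_fdr(p) >= p - 1e-15).all()

    def test_matches_reference_step_up_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.random(rng.integers(1, 20))
            np.testing.assert_allclose(D.bh_fdr(p), bh_oracle(p), atol=1e-12)


class TestBetaBinom:
    def _fixture(self):
        # overdispersed 6-FOV fixture (drawn once from BetaBinomial(mu={0.12,0.35}, rho=0.1))
        y = np.array([1.0, 1, 2, 46, 21, 20])
        n = np.array([60.0, 55, 70, 80, 75, 90])
        g = np.array(["ctl"] * 3 + ["trt"] * 3, dtype=object)
        return y, n, g

    def test_rho_zero_limit_equals_binomial_loglik(self):
        y, n, g = self._fixture()
        gi = (g == "trt").astype(float)
        params = np.array([-1.2, 0.8, -30.0])  # logit rho → rho ≈ 0
        from scipy.special import expit

        mu = expit(params[0] + params[1] * gi)
        assert D.betabinom_loglik(params, y, n, gi) == pytest.approx(
            st.binom.logpmf(y, n, mu).sum(), abs=1e-8
        )

    def test_ml_matches_zooming_grid_oracle(self):
        y, n, g = self._fixture()
        fit = D.betabinom_abundance(y, n, g)
        gi = (g == "trt").astype(float)
        # independent oracle: iteratively refined dense grid over (b0, b1, logit rho)
        center = np.array([0.0, 0.0, -2.0])
        widths = np.array([3.0, 3.0, 4.0])
        for _ in range(6):
            axes = [np.linspace(c - w, c + w, 13) for c, w in zip(center, widths)]
            best = None
            for b0, b1, lr in itertools.product(*axes):
                ll = D.betabinom_loglik(np.array([b0, b1, lr]), y, n, gi)
                if best is None or ll > best[0]:
                    best = (ll, np.array([b0, b1, lr]))
            center, widths = best[1], widths / 6.0
        assert fit.b0 == pytest.approx(center[0], abs=1e-3)
        assert fit.b1 == pytest.approx(center[1], abs=1e-3)
        assert fit.loglik >= best[0] - 1e-6

    def test_all_zero_group_is_flagged_boundary(self):
        y = np.array([0.0, 0, 0, 5, 6, 7])
        n = np.array([30.0] * 6)
        g = np.array(["a"] * 3 + ["b"] * 3, dtype=object)
        fit = D.betabinom_abundance(y, n, g)
        assert fit.boundary

    def test_requires_two_fovs_per_group(self):
        with pytest.raises(IntegrityError):
            D.betabinom_abundance(
                np.array([1.0, 2, 3]), np.array([10.0, 10, 10]),
                np.array(["a", "b", "b"], dtype=object),
            )

    def test_lrt_agrees_with_wald_in_magnitude(self):
        y, n, g = self._fixture()
        fit = D.betabinom_abundance(y, n, g, lrt=True)
        assert fit.p < 0.01 and fit.p_lrt < 0.01


class TestPseudobulk:
    def _cells(self, n_fov=8, cells_per_fov=20):
        rows = []
        for f in range(n_fov):
            grp = "A" if f < n_fov // 2 else "B"
            rows += [{"fov_id": f"F{f}", "cohort": grp}] * cells_per_fov
        return pd.DataFrame(rows)

    def test_identical_groups_give_t_zero_p_one(self, rng):
        cells = self._cells()
        base = rng.normal(size=(160, 5))
        # make group B's cells an exact copy of group A's
        X = np.vstack([base[:80], base[:80]])
        out = D.pseudobulk_de(X, [f"g{i}" for i in range(5)], cells, ("A", "B"))
        np.testing.assert_array_equal(out["statistic"], 0.0)
        np.testing.assert_array_equal(out["p"], 1.0)

    def test_fov_averaging_identity(self, rng):
        cells = self._cells(n_fov=2, cells_per_fov=10)
        X = rng.normal(size=(20, 3))
        means, grps = D._fov_means(X, cells["fov_id"].to_numpy(), cells["cohort"].to_numpy(dtype=object))
        np.testing.assert_allclose(means[0], X[:10].sum(axis=0) / 10, atol=1e-12)

    def test_welch_t_matches_scipy_on_fov_means(self, rng):
        cells = self._cells()
        X = rng.normal(size=(160, 4))
        out = D.pseudobulk_de(X, list("abcd"), cells, ("A", "B"))
        means, grps = D._fov_means(X, cells["fov_id"].to_numpy(), cells["cohort"].to_numpy(dtype=object))
        t_ref, p_ref = st.ttest_ind(means[grps == "A"], means[grps == "B"], equal_var=False)
        np.testing.assert_allclose(out["statistic"], t_ref)
        np.testing.assert_allclose(out["p"], p_ref)


class TestMixedModel:
    def _design(self, rng, n_fov=8, cells_per_fov=25, icc_sd=0.0, effect=0.0):
        rows, vals = [], []
        for f in range(n_fov):
            grp = "A" if f < n_fov // 2 else "B"
            fov_eff = rng.normal(scale=icc_sd)
            for _ in range(cells_per_fov):
                rows.append({"fov_id": f"F{f}", "cohort": grp})
                vals.append(rng.normal() + fov_eff + (effect if grp == "B" else 0.0))
        return pd.DataFrame(rows), np.asarray(vals)[:, None]

    def test_zero_fov_variance_reduces_to_ols(self, rng):
        import statsmodels.api as sm

        cells, X = self._design(rng, icc_sd=0.0)
        out = D.mixedmodel_de(X, ["g"], cells, ("A", "B"))
        g = (cells["cohort"] == "B").astype(float).to_numpy()
        ols = sm.OLS(X[:, 0], sm.add_constant(g)).fit()
        assert out["estimate"][0] == pytest.approx(ols.params[1], abs=1e-6)

    def test_balanced_design_estimate_is_difference_of_fov_mean_means(self, rng):
        cells, X = self._design(rng, icc_sd=0.8, effect=0.5)
        out = D.mixedmodel_de(X, ["g"], cells, ("A", "B"))
        fm = pd.DataFrame({"fov": cells["fov_id"], "g": cells["cohort"], "y": X[:, 0]})
        fov_means = fm.groupby(["g", "fov"], observed=True)["y"].mean()
        expected = fov_means["B"].mean() - fov_means["A"].mean()
        assert out["estimate"][0] == pytest.approx(expected, abs=1e-6)

    def test_requires_two_fovs_per_group(self, rng):
        cells, X = self._design(rng, n_fov=2)
        with pytest.raises(IntegrityError):
            D.mixedmodel_de(X, ["g"], cells, ("A", "B"))


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        v = np.array([1.0, 2, 3, 1, 2, 3])
        lab = np.array(["a"] * 3 + ["b"] * 3, dtype=object)
        stat, p = D.wilcoxon_groups(v, lab)
        assert p == pytest.approx(1.0)

    def test_u_statistic_matches_pair_counting(self, rng):
        for _ in range(20):
            x = rng.integers(0, 10, 30).astype(float)  # heavy ties
            y = rng.integers(0, 10, 20).astype(float)
            vals = np.concatenate([x, y])
            labs = np.array(["a"] * 30 + ["b"] * 20, dtype=object)
            stat, _ = D.wilcoxon_groups(vals, labs)
            u_brute = sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)
            assert stat == pytest.approx(u_brute)


class TestCompareDoce:
    def test_mirrored_groups_give_zero_slope(self):
        doce_df = pd.DataFrame(
            {"fov_id": ["F1", "F2", "F3", "F4"], "phenotype": "T cell",
             "doce": [1.0, -1.0, 1.0, -1.0]}
        )
        groups = pd.Series({"F1": "A", "F2": "A", "F3": "B", "F4": "B"})
        out = D.compare_doce(doce_df, groups, ("A", "B"))
        assert out["estimate"][0] == pytest.approx(0.0, abs=1e-12)

    def test_slope_equals_group_mean_difference(self, rng):
        vals = rng.normal(size=10)
        doce_df = pd.DataFrame(
            {"fov_id": [f"F{i}" for i in range(10)], "phenotype": "x", "doce": vals}
        )
        groups = pd.Series({f"F{i}": ("A" if i < 5 else "B") for i in range(10)})
        out = D.compare_doce(doce_df, groups, ("A", "B"))
        assert out["estimate"][0] == pytest.approx(vals[5:].mean() - vals[:5].mean(), abs=1e-12)


class TestCompareMoranAndEnrichment:
    def test_single_fov_per_group_is_missing(self):
        df = pd.DataFrame(
            {"fov_id": ["F1", "F2"], "ligand": "L", "receptor": "R", "I": [0.1, 0.2]}
        )
        groups = pd.Series({"F1": "A", "F2": "B"})
        out = D.compare_moran(df, groups, ("A", "B"))
        assert out["reason"][0] == "needs >=2 FOVs per group"
        assert np.isnan(out["p"][0])

    def test_all_null_pvalues_count_zero_samples(self):
        enrich = pd.DataFrame(
            {"fov_id": ["F1", "F2"], "set_name": "EMT", "p_empirical": [1.0, 1.0]}
        )
        meta = pd.DataFrame(
            {"fov_id": ["F1", "F2"], "sample_id": ["S1", "S2"], "cohort": ["A", "B"]}
        )
        out = D.compare_enrichment(enrich, meta, ("A", "B"), alpha=0.05)
        assert (out["n_enriched"] == 0).all()

    def test_exactly_two_groups_enforced(self):
        with pytest.raises(ConfigError):
            D.wilcoxon_groups(np.arange(6.0), np.array(["a", "b", "c"] * 2, dtype=object))
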