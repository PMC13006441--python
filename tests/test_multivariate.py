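import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from serumscape import multivariate, synth
from serumscape.types import IntensityMatrix


def _matrix(arr):
    arr = np.asarray(arr, dtype=float)
    return IntensityMatrix(pd.DataFrame(
        np.exp2(arr), index=[f"S{i}" for i in range(arr.shape[0])],
        columns=[f"A{j}" for j in range(arr.shape[1])]))


class TestPca:
    def test_identical_samples_equal_scores(self):
        rng = np.random.default_rng(0)
        row = rng.normal(10, 1, 5)
        arr = np.vstack([row, row, rng.normal(10, 1, (3, 5))])
        pca = multivariate.pca_project(_matrix(arr), k=1)
        assert pca.scores.iloc[0, 0] == pytest.approx(pca.scores.iloc[1, 0])

    def test_rank_one_explains_everything(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        v = np.array([0.5, 1.0, 1.5])
        arr = 10 + np.outer(u, v)
        pca = multivariate.pca_project(_matrix(arr), k=1)
        assert pca.explained[0] == pytest.approx(1.0)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(1)
        arr = rng.normal(10, 1, (6, 4))
        m = _matrix(arr)
        pca = multivariate.pca_project(m, k=4)
        centered = arr - arr.mean(axis=0)
        recon = pca.scores.to_numpy() @ pca.loadings.to_numpy().T
        np.testing.assert_allclose(recon, centered, atol=1e-8)

    def test_k_too_large_errors(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="exceeds"):
            multivariate.pca_project(_matrix(rng.normal(10, 1, (4, 6))), k=5)

    def test_scores_centered_and_explained_monotone(self):
        rng = np.random.default_rng(3)
        pca = multivariate.pca_project(_matrix(rng.normal(10, 1, (8, 5))), k=4)
        np.testing.assert_allclose(pca.scores.mean(axis=0), 0, atol=1e-10)
        assert (np.diff(pca.explained) <= 1e-12).all()
        assert pca.explained.sum() <= 1 + 1e-12


class TestPermanova:
    def test_hand_computed_four_sample_example(self):
        # 1-D points 0, 1 | 10, 11: SS_total = 404/4 = 101, SS_within = 1,
        # F = 100 / (1/2) = 200; enumeration of the 6 assignments -> p = 2/6
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        D = np.abs(X - X.T)
        labels = ["a", "a", "b", "b"]
        res = multivariate.permanova(D, labels, method="exact")
        assert res.f == pytest.approx(200.0)
        assert res.p == pytest.approx(1 / 3)
        assert res.r2 == pytest.approx(100.0 / 101.0)

    def test_single_group_errors(self):
        D = np.zeros((4, 4))
        with pytest.raises(ValueError, match="2 distinct groups"):
            multivariate.permanova(D, ["a"] * 4)

    def test_singleton_group_errors(self):
        D = np.zeros((3, 3))
        with pytest.raises(ValueError, match="2 members"):
            multivariate.permanova(D, ["a", "a", "b"])

    def test_p_floor_and_reorder_invariance(self):
        rng = np.random.default_rng(4)
        arr = rng.normal(10, 1, (12, 6))
        arr[:6] += 2.0
        m = _matrix(arr)
        labels = np.array(["g1"] * 6 + ["g2"] * 6)
        res = multivariate.permanova(m, labels, permutations=99, seed=0)
        assert res.p >= 1 / 100
        perm = rng.permutation(12)
        m2 = IntensityMatrix(m.values.iloc[perm])
        res2 = multivariate.permanova(m2, labels[perm], permutations=99, seed=0)
        assert res2.f == pytest.approx(res.f)

    def test_null_p_distribution_uniform(self):
        rng = np.random.default_rng(5)
        pvals = []
        for rep in range(200):
            arr = rng.normal(0, 1, (12, 4))
            m = _matrix(10 + arr)
            labels = ["a"] * 6 + ["b"] * 6
            res = multivariate.permanova(m, labels, permutations=99, seed=rep)
            pvals.append(res.p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestEnvfit:
    def _pca(self, seed=0, n=30):
        rng = np.random.default_rng(seed)
        return multivariate.pca_project(_matrix(rng.normal(10, 1, (n, 10))), k=3)

    def _md(self, n, **cols):
        base = {"group": ["ME"] * (n // 2) + ["HC"] * (n - n // 2),
                "sex": ["F"] * n, "age": np.linspace(20, 60, n),
                "bmi": np.full(n, 24.0), "fasting": [False] * n}
        base.update(cols)
        return pd.DataFrame(base, index=[f"S{i}" for i in range(n)])

    def test_covariate_equal_to_pc1(self):
        pca = self._pca()
        md = self._md(30, age=pca.scores["PC1"].to_numpy())
        res = multivariate.envfit_covariates(pca, md, permutations=99, seed=0,
                                             covariates=("age",))
        row = res.table.loc["age"]
        assert abs(row["pc1"]) == pytest.approx(1.0, abs=1e-9)
        assert row["pc2"] == pytest.approx(0.0, abs=1e-9)
        assert row["r2"] == pytest.approx(1.0)

    def test_direction_invariant_to_rescaling(self):
        pca = self._pca(seed=1)
        md1 = self._md(30, age=np.linspace(20, 60, 30))
        md2 = self._md(30, age=5.0 * np.linspace(20, 60, 30) + 100.0)
        r1 = multivariate.envfit_covariates(pca, md1, permutations=9, seed=0,
                                            covariates=("age",)).table
        r2 = multivariate.envfit_covariates(pca, md2, permutations=9, seed=0,
                                            covariates=("age",)).table
        np.testing.assert_allclose(r1[["pc1", "pc2"]], r2[["pc1", "pc2"]], atol=1e-12)

    def test_independent_covariate_small_r2(self):
        rng = np.random.default_rng(6)
        r2s, ps = [], []
        for rep in range(30):
            pca = self._pca(seed=100 + rep)
            md = self._md(30, age=rng.normal(40, 10, 30))
            res = multivariate.envfit_covariates(pca, md, permutations=49,
                                                 seed=rep, covariates=("age",))
            r2s.append(res.table.loc["age", "r2"])
            ps.append(res.table.loc["age", "p"])
        assert np.mean(r2s) < 0.2
        assert 0.2 < np.mean(ps) < 0.8

    def test_constant_covariate_skipped(self):
        pca = self._pca(seed=2)
        md = self._md(30)
        with pytest.warns(UserWarning, match="constant"):
            res = multivariate.envfit_covariates(pca, md, permutations=9, seed=0,
                                                 covariates=("bmi",))
        assert len(res.table) == 0


class TestVariancePartition:
    def _setup(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        md = pd.DataFrame({
            "group": ["ME"] * (n // 2) + ["HC"] * (n - n // 2),
            "sex": rng.choice(["F", "M"], n), "age": rng.normal(40, 10, n),
            "bmi": rng.normal(24, 4, n),
            "fasting": rng.choice([True, False], n),
        }, index=[f"S{i}" for i in range(n)])
        return rng, md

    def test_group_indicator_aptamer_fully_explained(self):
        # covariates exactly balanced across groups (orthogonal construction)
        rng = np.random.default_rng(0)
        n = 40
        md = pd.DataFrame({
            "group": ["ME"] * 20 + ["HC"] * 20,
            "sex": ["F", "M"] * 20,
            "age": np.tile(np.linspace(30, 50, 20), 2),
            "bmi": np.tile(np.random.default_rng(1).permutation(
                np.linspace(20, 28, 20)), 2),
            "fasting": [True, True, False, False] * 10,
        }, index=[f"S{i}" for i in range(n)])
        group = (md["group"] == "ME").astype(float).to_numpy()
        arr = np.column_stack([10 + group, rng.normal(10, 1, (n, 2))])
        m = _matrix(arr)
        vp = multivariate.variance_partition(m, md)
        assert vp.iloc[0]["ME"] > 0.95
        assert vp.iloc[0]["residual"] < 0.05

    def test_pure_noise_fractions_near_zero(self):
        fracs = []
        for seed in range(20):
            rng, md = self._setup(seed=seed, n=79)
            m = _matrix(rng.normal(10, 1, (79, 10)))
            vp = multivariate.variance_partition(m, md)
            fracs.append(vp["ME"].mean())
        assert np.mean(fracs) < 0.08

    def test_matches_all_subsets_oracle(self):
        rng, md = self._setup(seed=3, n=25)
        m = _matrix(rng.normal(10, 1, (25, 3)))
        vp = multivariate.variance_partition(m, md)
        # brute-force oracle: R^2 from explicit subset regressions
        from serumscape.diff import build_design
        X = build_design(md, ("sex", "age", "bmi", "fasting"))
        Y = m.log2().to_numpy()

        def r2(cols, j):
            Xa = X[cols].to_numpy()
            beta, *_ = np.linalg.lstsq(Xa, Y[:, j], rcond=None)
            resid = Y[:, j] - Xa @ beta
            tss = ((Y[:, j] - Y[:, j].mean()) ** 2).sum()
            return 1 - (resid ** 2).sum() / tss

        all_cols = list(X.columns)
        for j in range(3):
            full = r2(all_cols, j)
            for term, name in [("group", "ME"), ("sex", "sex"), ("age", "age"),
                               ("bmi", "bmi"), ("fasting", "fasting")]:
                reduced = r2([c for c in all_cols if c != term], j)
                assert vp.iloc[j][name] == pytest.approx(max(full - reduced, 0.0),
                                                         abs=1e-10)
            assert vp.iloc[j]["residual"] == pytest.approx(1 - full, abs=1e-10)

    def test_me_fraction_tracks_planted_effect(self):
        cfg = synth.GeneratorConfig(
            seed=31, n_me=40, n_hc=39, n_proteins=500, duplication_rate=0.0,
            noise_sd=0.4,
            effect_model={"intracellular": (0.0, 0.35), "membrane": (0.0, 0.35),
                          "secreted": (0.0, 0.35), "unannotated": (0.0, 0.35)})
        matrix, _, metadata, truth = synth.generate_dataset(cfg)
        vp = multivariate.variance_partition(matrix, metadata)
        rho = stats.spearmanr(vp["ME"].to_numpy(),
                              np.abs(truth["log2fc"].to_numpy())).statistic
        assert rho > 0.8
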