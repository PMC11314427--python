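import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import nichecol as nc
from nichecol.ordination import anosim, pcoa, permanova, permdisp, rda

from conftest import make_bundle


def planar_cloud(seed, n=20):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 2))
    return pts, squareform(pdist(pts))


class TestPcoa:
    def test_two_points_half_distance(self):
        d = 1.8
        res = pcoa(np.array([[0.0, d], [d, 0.0]]))
        coords = np.sort(res.coordinates.iloc[:, 0].to_numpy())
        assert coords == pytest.approx([-d / 2, d / 2])

    def test_euclidean_embedding_reproduces_distances(self):
        pts, D = planar_cloud(3)
        res = pcoa(D, n_axes=2)
        rec = squareform(pdist(res.coordinates.to_numpy()))
        assert np.abs(rec - D).max() < 1e-8

    def test_bray_matrix_reports_negative_eigenvalues(self, random_count_matrices):
        from conftest import to_counts_df

        seen_negative = 0
        for mat in random_count_matrices[:10]:
            cdf = to_counts_df(mat)
            meta = pd.DataFrame(
                {"day": [3] * 6, "replicate": range(1, 7)}, index=cdf.columns
            )
            b = nc.validate_bundle(cdf, meta, None, None)
            res = pcoa(nc.bray_curtis(b))
            assert (res.negative_eigenvalues < 0).all()
            seen_negative += len(res.negative_eigenvalues) > 0
        # Bray-Curtis is non-Euclidean: negative eigenvalues are typical
        assert seen_negative > 0

    def test_matches_skbio(self):
        from skbio.stats.ordination import pcoa as sk_pcoa

        _, D = planar_cloud(7, n=12)
        mine = pcoa(D)
        ref = sk_pcoa(D, method="eigh")
        assert np.allclose(
            np.sort(mine.eigenvalues)[::-1][:5], ref.eigvals.values[:5], atol=1e-8
        )

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestPermanova:
    def test_statistic_matches_skbio(self):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import permanova as sk_permanova

        _, D = planar_cloud(11, n=14)
        labels = np.array(["a"] * 7 + ["b"] * 7)
        mine = permanova(D, labels, n_perm=99, seed=0)
        ref = sk_permanova(SkDM(D), labels, permutations=99)
        assert mine.statistic == pytest.approx(ref["test statistic"])

    def test_separated_clouds_minimal_p(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.1, (8, 2)), rng.normal(50, 0.1, (8, 2))])
        D = squareform(pdist(pts))
        labels = ["a"] * 8 + ["b"] * 8
        t = permanova(D, labels, n_perm=199, seed=1)
        assert t.pvalue == pytest.approx(1 / 200)

    def test_degenerate_zero_matrix_flagged(self):
        t = permanova(np.zeros((6, 6)), ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0)
        assert t.extras.get("degenerate")
        assert np.isnan(t.pvalue)

    def test_reproducible_given_seed(self):
        _, D = planar_cloud(5, n=12)
        labels = ["a"] * 6 + ["b"] * 6
        t1 = permanova(D, labels, n_perm=199, seed=42)
        t2 = permanova(D, labels, n_perm=199, seed=42)
        assert (t1.statistic, t1.pvalue) == (t2.statistic, t2.pvalue)

    def test_singleton_group_rejected(self):
        _, D = planar_cloud(5, n=5)
        with pytest.raises(ValueError, match="size 1"):
            permanova(D, ["a"] * 4 + ["b"], n_perm=99, seed=0)


class TestAnosim:
    def test_statistic_matches_skbio(self):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import anosim as sk_anosim

        _, D = planar_cloud(13, n=14)
        labels = np.array(["a"] * 7 + ["b"] * 7)
        mine = anosim(D, labels, n_perm=99, seed=0)
        ref = sk_anosim(SkDM(D), labels, permutations=99)
        assert mine.statistic == pytest.approx(ref["test statistic"])

    def test_complete_separation_r_one(self):
        rng = np.random.default_rng(2)
        pts = np.vstack([rng.normal(0, 0.1, (6, 2)), rng.normal(10, 0.1, (6, 2))])
        D = squareform(pdist(pts))
        t = anosim(D, ["a"] * 6 + ["b"] * 6, n_perm=99, seed=0)
        assert t.statistic == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        _, D = planar_cloud(17, n=12)
        la = np.array(["a"] * 6 + ["b"] * 6)
        lb = np.array(["b"] * 6 + ["a"] * 6)
        assert anosim(D, la, 99, 0).statistic == pytest.approx(
            anosim(D, lb, 99, 0).statistic
        )


class TestPermdisp:
    def test_translated_copies_equal_dispersion(self):
        rng = np.random.default_rng(4)
        cloud = rng.normal(size=(8, 2))
        pts = np.vstack([cloud, cloud + 100.0])
        D = squareform(pdist(pts))
        t = permdisp(D, ["a"] * 8 + ["b"] * 8, n_perm=199, seed=0)
        assert t.statistic == pytest.approx(0.0, abs=1e-8)
        assert t.pvalue > 0.5

    def test_scaled_group_detected(self):
        rng = np.random.default_rng(6)
        cloud = rng.normal(size=(10, 2))
        pts = np.vstack([cloud, (cloud - cloud.mean(0)) * 10 + 100.0])
        D = squareform(pdist(pts))
        t = permdisp(D, ["a"] * 10 + ["b"] * 10, n_perm=999, seed=0)
        assert t.pvalue < 0.01

    def test_identical_points_zero_dispersion(self):
        pts = np.vstack([np.zeros((4, 2)), np.random.default_rng(0).normal(5, 1, (4, 2))])
        D = squareform(pdist(pts))
        t = permdisp(D, ["a"] * 4 + ["b"] * 4, n_perm=99, seed=0)
        assert t.extras["mean_dispersion"]["a"] == pytest.approx(0.0, abs=1e-9)

    def test_statistic_matches_skbio_centroid(self):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import permdisp as sk_permdisp

        _, D = planar_cloud(19, n=14)
        labels = np.array(["a"] * 7 + ["b"] * 7)
        mine = permdisp(D, labels, n_perm=99, seed=0)
        ref = sk_permdisp(SkDM(D), labels, permutations=99, test="centroid")
        assert mine.statistic == pytest.approx(ref["test statistic"], abs=1e-6)


class TestRda:
    def env_and_counts(self, seed, n=20, linear=True):
        rng = np.random.default_rng(seed)
        env = pd.DataFrame(
            {"x": rng.normal(size=n), "noise": rng.normal(size=n)},
            index=[f"s{i}" for i in range(n)],
        )
        if linear:
            Y = np.outer(np.arange(1, 7), env["x"].to_numpy()) + 20.0
        else:
            Y = rng.poisson(20, size=(6, n)).astype(float)
        counts = pd.DataFrame(Y, index=[f"sp{i}" for i in range(6)], columns=env.index)
        return counts, env

    def test_planted_linear_dependence(self):
        counts, env = self.env_and_counts(0)
        res = rda(counts, env[["x"]], transform="raw", n_perm=199, seed=1)
        assert res.constrained_proportion == pytest.approx(1.0, abs=1e-9)
        assert res.ordination.proportion_explained[0] == pytest.approx(1.0, abs=1e-9)
        assert res.test.pvalue == pytest.approx(1 / 200)

    def test_variance_additivity(self):
        counts, env = self.env_and_counts(3, linear=False)
        res = rda(counts, env, n_perm=99, seed=0)
        assert (
            res.constrained_variance + res.unconstrained_variance
            == pytest.approx(res.total_variance, abs=1e-9)
        )

    def test_collinear_variable_dropped(self, caplog):
        counts, env = self.env_and_counts(4, linear=False)
        env["x2"] = 2.0 * env["x"] + 1.0
        with caplog.at_level("WARNING"):
            res = rda(counts, env, n_perm=99, seed=0)
        assert res.dropped_variables
        assert len(res.env_scores.index) == 2

    def test_pure_noise_env_not_significant_typically(self):
        pvals = []
        for seed in range(10):
            counts, env = self.env_and_counts(100 + seed, linear=False)
            pvals.append(rda(counts, env[["noise"]], n_perm=99, seed=seed).test.pvalue)
        # roughly uniform: most runs give unremarkable p-values
        assert np.mean(np.array(pvals) < 0.05) <= 0.3

    def test_too_many_variables_rejected(self):
        counts, env = self.env_and_counts(5, n=3, linear=False)
        counts = counts.iloc[:, :3]
        env = env.iloc[:3]
        env["a"] = 1.0
        env["b"] = 2.0
        with pytest.raises(ValueError, match="fewer environmental"):
            rda(counts, env, n_perm=99, seed=0)
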