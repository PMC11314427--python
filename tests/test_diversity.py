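import numpy as np
import pandas as pd
import pytest

import nichecol as nc
from nichecol.diversity import (
    alpha_diversity,
    beta_multisite,
    beta_pair,
    bray_curtis,
    env_summary,
    euclidean_env,
    normalized_dissimilarity,
)
from nichecol.stages import StagePartition

from conftest import make_bundle


class TestBray:
    def test_identical_samples_zero(self):
        b = make_bundle({"a": [3, 3], "b": [1, 1]})
        assert bray_curtis(b).matrix[0, 1] == pytest.approx(0.0)

    def test_disjoint_samples_one(self):
        b = make_bundle({"a": [2, 0], "b": [0, 2]})
        assert bray_curtis(b).matrix[0, 1] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        b = make_bundle({"a": [6, 2], "b": [2, 2]})
        assert bray_curtis(b).matrix[0, 1] == pytest.approx(4 / 12)

    def test_both_empty_pair_warns_zero(self, caplog):
        b = make_bundle({"a": [0, 0, 1]})
        with caplog.at_level("WARNING"):
            d = bray_curtis(b)
        assert d.matrix[0, 1] == 0.0
        assert "both-empty" in caplog.text

    def test_relative_abundance_mode(self):
        b = make_bundle({"a": [6, 3], "b": [2, 1]})  # same composition, 2x depth
        assert bray_curtis(b, relative=True).matrix[0, 1] == pytest.approx(0.0)


class TestEuclidean:
    def test_identical_rows_zero(self):
        env = pd.DataFrame({"x": [1.0, 1.0], "y": [2.0, 2.0]}, index=["s1", "s2"])
        assert euclidean_env(env, standardize=False).matrix[0, 1] == 0.0

    def test_one_dimensional_distance(self):
        env = pd.DataFrame({"x": [1.0, 4.0]}, index=["s1", "s2"])
        assert euclidean_env(env, standardize=False).matrix[0, 1] == pytest.approx(3.0)

    def test_pythagorean_triangle(self):
        env = pd.DataFrame({"x": [0.0, 3.0], "y": [0.0, 4.0]}, index=["s1", "s2"])
        assert euclidean_env(env, standardize=False).matrix[0, 1] == pytest.approx(5.0)

    def test_zero_variance_variable_dropped(self, caplog):
        env = pd.DataFrame(
            {"x": [1.0, 2.0, 3.0], "flat": [7.0, 7.0, 7.0]},
            index=["s1", "s2", "s3"],
        )
        with caplog.at_level("WARNING"):
            d = euclidean_env(env, standardize=True)
        assert "flat" in caplog.text
        assert np.isfinite(d.matrix).all()


class TestNormalizedDissimilarity:
    def test_global_max_normalization(self):
        # pair achieving global max 0.5 -> 0.5 / 0.501
        b = make_bundle({"a": [6, 2, 4], "b": [2, 2, 4]}, days=[3, 3, 6])
        dm = bray_curtis(b)
        part = StagePartition(labels={"s01": "T1", "s02": "T1", "s03": "T2"})
        out = normalized_dissimilarity(dm, part)
        gmax = dm.max
        assert out.loc["T1", "mean"] == pytest.approx(
            dm.matrix[0, 1] / (gmax + 0.001)
        )

    def test_exact_substitution(self):
        d = np.array([[0.0, 0.5], [0.5, 0.0]])
        dm = nc.DistanceMatrix(["a", "b"], d, "bray")
        part = StagePartition(labels={"a": "T1", "b": "T1"})
        out = normalized_dissimilarity(dm, part)
        assert out.loc["T1", "mean"] == pytest.approx(0.5 / 0.501)

    def test_identical_communities_zero(self):
        b = make_bundle({"a": [3, 3], "b": [1, 1]})
        part = StagePartition(labels={"s01": "T1", "s02": "T1"})
        out = normalized_dissimilarity(bray_curtis(b), part)
        assert out.loc["T1", "mean"] == 0.0

    def test_invariant_to_sample_order_and_below_one(self, random_count_matrices):
        from conftest import to_counts_df

        mat = random_count_matrices[0]
        cdf = to_counts_df(mat)
        meta = pd.DataFrame(
            {"day": [3, 3, 6, 6, 9, 9], "replicate": [1, 2] * 3}, index=cdf.columns
        )
        b = nc.validate_bundle(cdf, meta, None, None)
        part = nc.assign_stages(b.meta, {"T1": (3, 6), "T2": (9, 9)})
        out1 = normalized_dissimilarity(bray_curtis(b), part)
        # reversed column order
        b2 = nc.validate_bundle(cdf[cdf.columns[::-1]], meta, None, None)
        out2 = normalized_dissimilarity(bray_curtis(b2), part)
        pd.testing.assert_frame_equal(out1, out2)
        norm = bray_curtis(b).matrix / (bray_curtis(b).max + 0.001)
        assert norm.max() < 1.0


class TestAlpha:
    def test_chao1_hand_example(self):
        b = make_bundle({"a": [5], "b": [1], "c": [1], "d": [2]}, days=[3])
        out = alpha_diversity(b)
        row = out.iloc[0]
        assert row["Sobs"] == 4
        assert row["F1"] == 2 and row["F2"] == 1
        assert row["Chao1"] == pytest.approx(4.5)

    def test_uniform_abundance_maximal_evenness(self):
        b = make_bundle({c: [7] for c in "abcde"}, days=[3])
        assert alpha_diversity(b)["J"].iloc[0] == pytest.approx(1.0)

    def test_no_singletons_or_doubletons(self):
        b = make_bundle({"a": [5], "b": [4], "c": [3]}, days=[3])
        row = alpha_diversity(b).iloc[0]
        assert row["Chao1"] == row["Sobs"]

    def test_single_species_evenness_undefined(self):
        b = make_bundle({"a": [5], "b": [0]}, days=[3])
        assert np.isnan(alpha_diversity(b)["J"].iloc[0])

    def test_against_skbio(self, random_count_matrices):
        from skbio.diversity.alpha import chao1, shannon

        for mat in random_count_matrices[:10]:
            col = mat[:, 0]
            b = make_bundle({f"sp{i}": [int(v)] for i, v in enumerate(col)}, days=[3])
            row = alpha_diversity(b).iloc[0]
            assert row["Chao1"] == pytest.approx(chao1(col, bias_corrected=True))
            assert row["Shannon"] == pytest.approx(shannon(col, base=np.e))

    def test_stage_level_pooling(self):
        b = make_bundle({"a": [1, 0], "b": [0, 1]}, days=[3, 6])
        part = nc.assign_stages(b.meta, {"T1": (3, 6)})
        out = alpha_diversity(b, level="stage", partition=part)
        assert out.loc["T1", "Sobs"] == 2


class TestBetaPartition:
    def test_hand_example(self):
        # sites {A,B,C} vs {A,D}: a=1, b=2, c=1
        x = np.array([1, 1, 1, 0])
        y = np.array([1, 0, 0, 1])
        r = beta_pair(x, y)
        assert r["beta_sor"] == pytest.approx(0.6)
        assert r["beta_sim"] == pytest.approx(0.5)
        assert r["beta_sne"] == pytest.approx(0.1)

    def test_identical_composition_zero(self):
        x = np.array([2, 3, 0])
        r = beta_pair(x, x)
        assert r["beta_sor"] == r["beta_sim"] == r["beta_sne"] == 0.0

    def test_perfect_nesting_is_pure_nestedness(self):
        x = np.array([1, 1, 1])
        y = np.array([1, 0, 0])
        r = beta_pair(x, y)
        assert r["beta_sim"] == 0.0
        assert r["beta_sor"] == pytest.approx(0.5)
        assert r["beta_sne"] == pytest.approx(0.5)

    def test_both_empty_undefined(self):
        r = beta_pair(np.zeros(3), np.zeros(3))
        assert np.isnan(r["beta_sor"])

    def test_multisite_reduces_to_pairwise_for_two_sites(self, random_count_matrices):
        for mat in random_count_matrices[:10]:
            counts = pd.DataFrame(mat[:, :2], columns=["s1", "s2"])
            ms = beta_multisite(counts)
            pw = beta_pair(mat[:, 0], mat[:, 1])
            assert ms["beta_SOR"] == pytest.approx(pw["beta_sor"])
            assert ms["beta_SIM"] == pytest.approx(pw["beta_sim"])
            assert ms["beta_SNE"] == pytest.approx(pw["beta_sne"])

    def test_partition_shares_sum_to_one(self, random_count_matrices):
        from conftest import to_counts_df

        cdf = to_counts_df(random_count_matrices[1])
        meta = pd.DataFrame({"day": [3] * 6, "replicate": range(1, 7)}, index=cdf.columns)
        b = nc.validate_bundle(cdf, meta, None, None)
        part = StagePartition(labels={s: "T1" for s in cdf.columns})
        out = nc.beta_partition(b, part, scope="multisite")
        row = out.loc["T1"]
        assert row["turnover_share"] + row["nestedness_share"] == pytest.approx(1.0)


class TestEnvSummary:
    def test_constant_variable_cv_zero(self):
        env = pd.DataFrame({"x": [1.0, 1.0, 1.0]}, index=["a", "b", "c"])
        part = StagePartition(labels={"a": "T1", "b": "T1", "c": "T1"})
        out = env_summary(env, part)
        assert out["cv_pct"].iloc[0] == 0.0

    def test_hand_computed_cv(self):
        env = pd.DataFrame({"x": [1.0, 3.0]}, index=["a", "b"])
        part = StagePartition(labels={"a": "T1", "b": "T1"})
        out = env_summary(env, part)
        assert out["cv_pct"].iloc[0] == pytest.approx(100 * np.sqrt(2) / 2, abs=0.01)

    def test_zero_mean_flagged(self):
        env = pd.DataFrame({"x": [-1.0, 1.0]}, index=["a", "b"])
        part = StagePartition(labels={"a": "T1", "b": "T1"})
        out = env_summary(env, part)
        assert np.isnan(out["cv_pct"].iloc[0])
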