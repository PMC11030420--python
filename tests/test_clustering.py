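"""Leiden stability selection, enrichment, feature modules, distances."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from opspheno.clustering import (
    cluster_enrichment,
    cluster_leiden,
    feature_modules,
    phenotype_distance,
    select_resolution,
)


def _grouped_coords(n_groups=3, per_group=30, sep=8.0, seed=0):
    rng = np.random.default_rng(seed)
    blocks, truth = [], []
    for g in range(n_groups):
        center = sep * np.array([np.cos(2 * np.pi * g / n_groups), np.sin(2 * np.pi * g / n_groups)])
        blocks.append(rng.normal(0, 0.5, (per_group, 2)) + center)
        truth += [g] * per_group
    ids = [f"G{i:03d}" for i in range(n_groups * per_group)]
    return pd.DataFrame(np.vstack(blocks), index=ids, columns=["x", "y"]), np.array(truth)


class TestLeiden:
    def test_planted_clusters_recovered(self):
        coords, truth = _grouped_coords()
        res = select_resolution(coords, [0.1, 1.0, 10.0], seed=3, knn_graph_k=10)
        assert res.n_clusters == 3
        assert adjusted_rand_score(truth, res.labels) >= 0.95
        assert res.resolution in set(res.stability_curve["resolution"])
        assert res.stability_curve.loc[
            res.stability_curve["resolution"] == res.resolution, "mean_ars"
        ].iloc[0] >= 0.95

    def test_stability_curve_reproducible(self):
        coords, _ = _grouped_coords(seed=1)
        r1 = select_resolution(coords, [0.3, 1.0], seed=5, knn_graph_k=8)
        r2 = select_resolution(coords, [0.3, 1.0], seed=5, knn_graph_k=8)
        pd.testing.assert_frame_equal(r1.stability_curve, r2.stability_curve)
        pd.testing.assert_series_equal(r1.labels, r2.labels)

    def test_label_invariants(self):
        coords, _ = _grouped_coords(seed=2)
        labels = cluster_leiden(coords, resolution=1.0, knn_graph_k=10, seed=0)
        assert set(labels.index) == set(coords.index)
        assert labels.nunique() == len(set(labels))
        with pytest.raises(ValueError):
            cluster_leiden(coords, 1.0, knn_graph_k=len(coords), seed=0)


class TestEnrichment:
    def test_exact_hypergeometric_value(self):
        """A 10-gene cluster made entirely of hits out of a 100-gene
        background with 20 hits: p = C(20,10)/C(100,10)."""
        genes = [f"G{i}" for i in range(100)]
        labels = pd.Series([0] * 10 + [1] * 90, index=genes)
        flags = pd.Series([True] * 20 + [False] * 80, index=genes)
        out = cluster_enrichment(labels, flags)
        expect = math.comb(20, 10) / math.comb(100, 10)
        got = out.loc[out["cluster"] == 0, "p"].iloc[0]
        assert got == pytest.approx(expect, rel=1e-12)
        assert out.loc[out["cluster"] == 1, "p"].iloc[0] == pytest.approx(1.0)

    def test_matches_enumeration_oracle_small(self):
        """Brute-force enumeration over all draws for N <= 30."""
        rng = np.random.default_rng(3)
        N, K, n = 12, 5, 4
        genes = [f"G{i}" for i in range(N)]
        labels = pd.Series([0] * n + [1] * (N - n), index=genes)
        flags = pd.Series(rng.permutation([True] * K + [False] * (N - K)), index=genes)
        k = int(flags.iloc[:n].sum())
        brute = sum(
            math.comb(K, j) * math.comb(N - K, n - j) / math.comb(N, n) for j in range(k, min(K, n) + 1)
        )
        out = cluster_enrichment(labels, flags)
        assert out.loc[out["cluster"] == 0, "p"].iloc[0] == pytest.approx(brute, rel=1e-12)

    def test_null_fraction_not_significant(self):
        genes = [f"G{i}" for i in range(100)]
        labels = pd.Series([0] * 20 + [1] * 80, index=genes)
        flags = pd.Series(([True] * 5 + [False] * 20) * 4, index=genes)
        out = cluster_enrichment(labels, flags)
        assert (out["p"] > 0.2).all()  # hit fraction matches background

    def test_ranksum_mode(self):
        genes = [f"G{i}" for i in range(40)]
        labels = pd.Series([0] * 10 + [1] * 30, index=genes)
        scores = pd.Series(np.r_[np.full(10, 5.0), np.zeros(30)], index=genes)
        out = cluster_enrichment(labels, gene_flags=None, scores=scores, mode="ranksum")
        assert out.loc[out["cluster"] == 0, "p"].iloc[0] < 1e-4


class TestFeatureModules:
    def test_perfect_pairs_recovered(self):
        """40 features as 20 near-duplicate pairs: module assignment
        reproduces the pairs exactly (ARI = 1)."""
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, (100, 20))
        X = np.empty((100, 40))
        X[:, ::2] = base
        X[:, 1::2] = base + rng.normal(0, 1e-3, base.shape)
        df = pd.DataFrame(X, columns=[f"f{i:02d}" for i in range(40)])
        mapping, scores = feature_modules(df, n_modules=20)
        truth = np.repeat(np.arange(20), 2)
        assert adjusted_rand_score(truth, mapping.to_numpy()) == 1.0
        assert scores.shape == (100, 20)

    def test_identity_and_singleton(self):
        df = pd.DataFrame(np.random.default_rng(6).normal(size=(30, 5)),
                          columns=list("abcde"))
        mapping, scores = feature_modules(df, n_modules=5)
        assert sorted(mapping) == [1, 2, 3, 4, 5]  # identity partition
        single_col = mapping.index[mapping == mapping["a"]]
        assert np.allclose(scores.iloc[:, mapping["a"] - 1], df[single_col].mean(axis=1))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        base = rng.normal(0, 1, (50, 6))
        X = np.hstack([base, base + rng.normal(0, 1e-4, base.shape)])
        cols = [f"f{i}" for i in range(12)]
        df = pd.DataFrame(X, columns=cols)
        _, s1 = feature_modules(df, 6)
        perm = rng.permutation(cols)
        _, s2 = feature_modules(df[perm], 6)
        a = np.sort(s1.to_numpy(), axis=1)
        b = np.sort(s2.to_numpy(), axis=1)
        assert np.allclose(a, b)

    def test_nan_rejected(self):
        df = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            feature_modules(df, 2)


class TestPhenotypeDistance:
    def test_arithmetic_and_invariance(self):
        coords = pd.DataFrame(
            {"x": [3.0, 0.0, 0.0], "y": [4.0, 0.0, 0.0]}, index=["g", "n1", "n2"]
        )
        assert phenotype_distance(coords, "g", ["n1", "n2"]) == pytest.approx(5.0)
        assert phenotype_distance(coords, "n1", ["n1", "n2"]) == 0.0
        shifted = coords + 10.0
        assert phenotype_distance(shifted, "g", ["n1", "n2"]) == pytest.approx(5.0)
        with pytest.raises(ValueError):
            phenotype_distance(coords, "g", [])
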