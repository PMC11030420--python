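"""Classifier scores, bootstrap nulls, p-value machinery, hit calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import opspheno as op
from opspheno.classify import (
    ClassifierParams,
    ConditionClassifier,
    MeanDecisionScorer,
    NullBank,
    NullDistribution,
    bootstrap_null,
    call_hits,
    score_guide_condition,
    score_guide_perturbed,
    score_screen,
    train_condition_classifier,
)

RNG = np.random.default_rng(0)


def _cloud(n, mean, d=6, rng=RNG):
    return rng.normal(0, 1, (n, d)) + np.asarray(mean)


def _table(X):
    return pd.DataFrame(X, columns=[f"feature_{i:03d}" for i in range(X.shape[1])])


class TestConditionClassifier:
    def test_separable_clouds_high_separation(self):
        """4-SD separated clouds: held-out decision values rank the two
        populations nearly perfectly (the pipeline consumes decision
        values against a bootstrap null, never a 0-threshold)."""
        rng = np.random.default_rng(1)
        a, b = _cloud(400, [4, 0, 0, 0, 0, 0], rng=rng), _cloud(400, [0] * 6, rng=rng)
        clf = train_condition_classifier(_table(a), _table(b))
        d_a = clf.decision_function(_cloud(300, [4, 0, 0, 0, 0, 0], rng=rng))
        d_b = clf.decision_function(_cloud(300, [0] * 6, rng=rng))
        auc = (d_a[:, None] > d_b[None, :]).mean()
        assert auc >= 0.99

    def test_null_case_chance_accuracy(self):
        rng = np.random.default_rng(2)
        clf = train_condition_classifier(_table(_cloud(400, [0] * 6, rng=rng)), _table(_cloud(400, [0] * 6, rng=rng)))
        held = _cloud(1000, [0] * 6, rng=rng)
        assert abs((clf.predict(held) == 1).mean() - 0.5) < 0.15

    def test_deterministic_given_seed(self):
        a, b = _cloud(100, [1, 0, 0, 0, 0, 0]), _cloud(100, [0] * 6)
        w1 = train_condition_classifier(_table(a), _table(b)).coef_
        w2 = train_condition_classifier(_table(a), _table(b)).coef_
        assert np.array_equal(w1, w2)

    def test_single_condition_rejected(self):
        X = _cloud(10, [0] * 6)
        with pytest.raises(ValueError):
            ConditionClassifier().fit(X, np.zeros(10))

    def test_orientation_toward_target(self):
        """Cells at the target archetype score above reference cells."""
        rng = np.random.default_rng(3)
        target, ref = _cloud(300, [3, 0, 0, 0, 0, 0], rng=rng), _cloud(300, [0] * 6, rng=rng)
        clf = train_condition_classifier(_table(target), _table(ref))
        s_t = score_guide_condition(clf, _table(_cloud(50, [3, 0, 0, 0, 0, 0], rng=rng)))
        s_r = score_guide_condition(clf, _table(_cloud(50, [0] * 6, rng=rng)))
        assert s_t > s_r

    def test_boundary_and_duplication(self):
        clf = ConditionClassifier().fit(
            np.vstack([_cloud(50, [1] * 6), _cloud(50, [-1] * 6)]),
            np.r_[np.ones(50), np.zeros(50)],
            feature_names=[f"feature_{i:03d}" for i in range(6)],
        )
        b = clf.intercept_
        # shift a point onto the hyperplane: d(x) = w.x + b = 0
        x = -b * clf.coef_ / (clf.coef_ @ clf.coef_)
        assert clf.decision_function(x[None, :])[0] == pytest.approx(0.0, abs=1e-12)
        cells = _table(_cloud(30, [1] * 6))
        doubled = pd.concat([cells, cells], ignore_index=True)
        assert score_guide_condition(clf, cells) == pytest.approx(
            score_guide_condition(clf, doubled)
        )


class TestPerturbedScore:
    def test_too_few_cells_unscorable(self):
        assert np.isnan(score_guide_perturbed(np.zeros((4, 6)), np.zeros((50, 6))))

    def test_strong_effect_beats_null(self):
        rng = np.random.default_rng(4)
        ntc = _cloud(400, [0] * 6, rng=rng)
        guide = _cloud(50, [4, 0, 0, 0, 0, 0], rng=rng)
        s = score_guide_perturbed(guide, ntc, rng=np.random.default_rng(0))
        null_scores = [
            score_guide_perturbed(ntc[rng.integers(0, 400, 50)], ntc, rng=np.random.default_rng(i))
            for i in range(100)
        ]
        assert s > np.quantile(null_scores, 0.999)

    def test_same_seed_same_score(self):
        rng = np.random.default_rng(5)
        guide, ntc = _cloud(30, [1] * 6, rng=rng), _cloud(200, [0] * 6, rng=rng)
        s1 = score_guide_perturbed(guide, ntc, rng=np.random.default_rng(9))
        s2 = score_guide_perturbed(guide, ntc, rng=np.random.default_rng(9))
        assert s1 == s2


class TestBootstrapNull:
    def test_clt_mean_and_width(self):
        """Mean-of-feature scorer: null mean ~ 0 and SD ~ sigma/sqrt(n)."""
        rng = np.random.default_rng(6)
        ntc = rng.normal(0, 1, (4000, 1))

        class FeatureMean:
            is_mean = True

            def per_cell(self, X):
                return X[:, 0]

            def __call__(self, X):
                return float(X[:, 0].mean())

        null = bootstrap_null(ntc, 100, 2000, FeatureMean(), seed=1)
        # bootstrap scores center on the NTC sample mean with SD sigma/sqrt(n)
        assert null.scores.mean() == pytest.approx(ntc[:, 0].mean(), abs=0.01)
        assert null.scores.std() == pytest.approx(0.1, rel=0.1)
        wide = bootstrap_null(ntc, 10, 2000, FeatureMean(), seed=1)
        narrow = bootstrap_null(ntc, 4000, 2000, FeatureMean(), seed=1)
        assert narrow.scores.std() < wide.scores.std() / 2

    def test_determinism_and_validation(self):
        ntc = np.random.default_rng(7).normal(0, 1, (200, 2))
        scorer = lambda X: float(X.mean())
        n1 = bootstrap_null(ntc, 20, 100, scorer, seed=3)
        n2 = bootstrap_null(ntc, 20, 100, scorer, seed=3)
        assert np.array_equal(n1.scores, n2.scores)
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_null(ntc, 20, 99, scorer, seed=3)
        with pytest.raises(ValueError, match="group_size"):
            bootstrap_null(ntc, 201, 100, scorer, seed=3)


class TestEmpiricalP:
    def test_forced_values(self):
        null = NullDistribution("m", 10, np.sort(np.arange(100.0)))
        assert op.empirical_pvalue(1000.0, null, "greater") == pytest.approx(1 / 101)
        assert op.empirical_pvalue(49.5, null, "greater") == pytest.approx(51 / 101)

    def test_monotone_in_score(self):
        null = NullDistribution("m", 10, np.sort(np.random.default_rng(8).normal(size=500)))
        scores = np.linspace(-3, 3, 50)
        ps = [op.empirical_pvalue(s, null, "greater") for s in scores]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    @given(st.floats(-5, 5))
    @settings(max_examples=50, derandomize=True)
    def test_oracle_equivalence(self, score):
        null_scores = np.sort(np.random.default_rng(9).normal(size=333))
        null = NullDistribution("m", 5, null_scores)
        brute_greater = (1 + (null_scores >= score).sum()) / 334
        brute_less = (1 + (null_scores <= score).sum()) / 334
        assert op.empirical_pvalue(score, null, "greater") == pytest.approx(brute_greater, abs=1e-15)
        assert op.empirical_pvalue(score, null, "two_sided") == pytest.approx(
            min(1.0, 2 * min(brute_greater, brute_less)), abs=1e-15
        )


class TestCombining:
    def test_stouffer_known_values(self):
        assert op.stouffer_combine([0.5, 0.5]) == pytest.approx(0.5, abs=1e-12)
        assert op.stouffer_combine([0.123]) == pytest.approx(0.123, abs=1e-12)
        # two p-values at z=2 combine to z = 2*sqrt(2)
        p2 = float(stats.norm.sf(2.0))
        assert op.stouffer_combine([p2, p2]) == pytest.approx(
            float(stats.norm.sf(2 * np.sqrt(2))), abs=1e-12
        )

    @given(st.lists(st.floats(1e-6, 1 - 1e-6), min_size=1, max_size=8))
    @settings(max_examples=100, derandomize=True)
    def test_stouffer_matches_scipy(self, ps):
        ours = op.stouffer_combine(ps)
        ref = stats.combine_pvalues(ps, method="stouffer").pvalue
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_bh_known_values(self):
        assert np.allclose(op.bh_correct([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        assert np.allclose(op.bh_correct([1.0]), [1.0])
        assert np.allclose(op.bh_correct([0.05, 1.0]), [0.10, 1.0])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, derandomize=True)
    def test_bh_matches_bruteforce(self, ps):
        q = op.bh_correct(ps)
        m = len(ps)
        order = np.argsort(ps, kind="stable")
        brute = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, m * ps[i] / rank)
            brute[i] = running
        assert np.allclose(q, brute, atol=1e-12)


class TestNullBank:
    def test_bucket_interpolation_brackets_exact(self):
        rng = np.random.default_rng(10)
        ntc = rng.normal(0, 1, (3000, 1))

        class FeatureMean:
            is_mean = True

            def per_cell(self, X):
                return X[:, 0]

        bank = NullBank(ntc, FeatureMean(), n_boot=4000, seed=1)
        exact = NullBank(ntc, FeatureMean(), n_boot=4000, seed=1, exact=True)
        for size, score in [(50, 0.2), (100, 0.15), (70, 0.25)]:
            p_b = bank.pvalue(score, size)
            p_e = exact.pvalue(score, size)
            assert p_b == pytest.approx(p_e, abs=0.05)


def test_call_hits_union_and_degenerate():
    rows = []
    for model in ("unstimulated", "increased_stim"):
        for gene, p in [("A", 1e-6), ("B", 0.8)]:
            rows.append((model, gene, f"{gene}_g1", 50, 1.0, p if model == "unstimulated" else 0.9))
    gs = pd.DataFrame(rows, columns=["model", "gene", "guide_id", "n_cells", "mean_score", "empirical_p"])
    hits = call_hits(gs, q_threshold=0.001)
    assert bool(hits.loc["A", "hit_unstimulated"])
    assert not bool(hits.loc["A", "hit_increased_stim"])
    assert bool(hits.loc["A", "hit_any"])  # union of the per-model flags
    all_one = gs.assign(empirical_p=1.0)
    assert not call_hits(all_one)["hit_any"].any()


def test_score_screen_recovers_planted_hits(normalized_effect_cells):
    """3 planted 4-SD hits among 12 genes; the union call finds them all
    and flags no null gene."""
    gs, hits = score_screen(
        normalized_effect_cells, n_boot=1000, seed=5, exact_nulls=True
    )
    planted = {"GENE0001", "GENE0002", "GENE0003"}
    called = set(hits.index[hits["hit_any"]])
    assert planted <= called
    assert len(called - planted) == 0
    # determinism of the whole path
    gs2, hits2 = score_screen(normalized_effect_cells, n_boot=1000, seed=5, exact_nulls=True)
    pd.testing.assert_frame_equal(hits, hits2)
    pd.testing.assert_frame_equal(gs, gs2)
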