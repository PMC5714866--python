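"""Selection/optimization: CV comparison, PCA, importance, mtry tuning,
OOB grid, hybrid sets, and the rank-sum screen."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from moltox import (
    build_hybrid,
    crossval_compare,
    oob_grid,
    pca_project,
    rank_importance,
    subset_topk,
    tune_mtry,
    wilcoxon_screen,
)
from moltox.select_opt import ImportanceRanking, ranksum_pvalue
from moltox.synthdata import PlantedSpec, make_classification_table

from conftest import manual_table


def exact_ranksum_twosided(a, b):
    """Enumeration oracle: two-sided rank-sum p over all C(n1+n2, n1)
    assignments of the pooled ranks (no ties assumed)."""
    pooled = np.concatenate([a, b])
    ranks = pd.Series(pooled).rank().to_numpy()
    n1 = len(a)
    obs = ranks[:n1].sum()
    stats = [sum(c) for c in itertools.combinations(ranks, n1)]
    mean = np.mean(stats)
    extreme = sum(abs(s - mean) >= abs(obs - mean) - 1e-9 for s in stats)
    return extreme / len(stats)


class TestCrossvalCompare:
    def test_planted_signal_rf_auc_high(self):
        spec = PlantedSpec(n_pos=60, n_neg=40, n_informative=5, n_noise=45,
                           effect_size=2.0, seed=3)
        table, _ = make_classification_table(spec)
        aucs = crossval_compare(table, algorithms=("RF",), folds=5, seed=0)
        assert aucs["RF"] > 0.9

    def test_permuted_labels_near_half(self):
        spec = PlantedSpec(n_pos=60, n_neg=40, n_informative=5, n_noise=45,
                           effect_size=2.0, seed=5)
        table, _ = make_classification_table(spec)
        rng = np.random.default_rng(0)
        table.labels = pd.Series(rng.permutation(table.labels.to_numpy()),
                                 index=table.X.index)
        aucs = crossval_compare(table, algorithms=("RF", "CART"), folds=5, seed=0)
        for auc in aucs.values():
            assert abs(auc - 0.5) < 0.15

    def test_unknown_algorithm(self, small_planted):
        with pytest.raises(ValueError):
            crossval_compare(small_planted[0], algorithms=("MLP",), folds=3)


class TestPca:
    def test_isotropic_cloud_equal_fractions(self, rng):
        Z = rng.normal(size=(4000, 2))
        t = manual_table({"a": Z[:, 0], "b": Z[:, 1]}, kind="fingerprint")
        r = pca_project(t, 2)
        assert r.explained_variance_ratio[0] == pytest.approx(0.5, abs=0.05)

    def test_exact_line_one_component(self):
        x = np.linspace(-1, 1, 50)
        t = manual_table({"x": x, "y": 2 * x}, kind="fingerprint")
        r = pca_project(t, 2)
        assert r.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_known_covariance_eigen_ratio(self, rng):
        Z = rng.multivariate_normal([0, 0], [[2, 1], [1, 2]], size=30000)
        t = manual_table({"a": Z[:, 0], "b": Z[:, 1]}, kind="fingerprint")
        r = pca_project(t, 2)
        ratio = r.explained_variance_ratio[0] / r.explained_variance_ratio[1]
        assert ratio == pytest.approx(3.0, rel=0.05)

    def test_orthonormal_loadings_and_reconstruction(self, rng):
        Z = rng.normal(size=(40, 4))
        t = manual_table({f"f{i}": Z[:, i] for i in range(4)}, kind="fingerprint")
        r = pca_project(t, 4)
        L = r.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(4), atol=1e-10)
        centered = Z - Z.mean(axis=0)
        assert np.allclose(r.scores.to_numpy() @ L.T, centered, atol=1e-10)

    def test_zero_variance_rejected(self):
        t = manual_table({"a": [1.0, 1.0, 1.0], "b": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError):
            pca_project(t, 1)


class TestTuneMtry:
    def test_single_feature_returns_one(self):
        spec = PlantedSpec(n_pos=30, n_neg=30, n_informative=1, n_noise=0, seed=0)
        t, _ = make_classification_table(spec)
        assert tune_mtry(t, ntree=50) == 1

    def test_start_wider_than_table_rejected(self, small_planted):
        with pytest.raises(ValueError):
            tune_mtry(small_planted[0], start=10_000)

    def test_regression_defaults_accepted(self):
        from moltox.synthdata import make_regression_table

        t, _ = make_regression_table(80, [2.0, -1.0], 0.0, n_noise=18,
                                     noise_sd=0.5, seed=0)
        m = tune_mtry(t, start=14, step_factor=0.5, improve=1e-5, ntree=100)
        assert 1 <= m <= len(t.feature_names)

    def test_returns_minimum_visited(self, small_planted):
        table, _ = small_planted
        m = tune_mtry(table, start=5, ntree=50, seed=0)
        assert 1 <= m <= len(table.feature_names)


class TestImportance:
    def test_sorted_and_ties_lexicographic(self, small_planted):
        table, _ = small_planted
        r = rank_importance(table, ntree=100, seed=0, mtry=5)
        scores = [s for _, s in r.entries]
        assert scores == sorted(scores, reverse=True)
        for (n1, s1), (n2, s2) in zip(r.entries, r.entries[1:]):
            if s1 == s2:
                assert n1 < n2

    def test_constant_feature_near_zero(self):
        spec = PlantedSpec(n_pos=50, n_neg=50, n_informative=3, n_noise=10,
                           effect_size=2.0, seed=7)
        table, _ = make_classification_table(spec)
        table.X["constant"] = 1.0
        table.kinds["constant"] = "descriptor"
        r = rank_importance(table, ntree=100, seed=0, mtry=3)
        assert abs(r.scores["constant"]) < 0.01

    def test_informative_features_outrank_noise(self, small_planted):
        table, informative = small_planted
        r = rank_importance(table, ntree=200, seed=0, mtry=5)
        top = set(subset_topk(r, k=len(informative)))
        assert len(top & set(informative)) >= len(informative) - 1

    def test_single_class_rejected(self, small_planted):
        table, _ = small_planted
        pos = list(table.labels[table.labels == 1].index)
        with pytest.raises(ValueError):
            rank_importance(table.subset_rows(pos), ntree=20)


class TestSubsetTopk:
    def _ranking(self, n):
        return ImportanceRanking(tuple((f"f{i:05d}", float(n - i)) for i in range(n)))

    def test_fraction_rounding(self):
        assert len(subset_topk(self._ranking(10208), fraction=0.10)) == 1021

    def test_k_and_identity(self):
        r = self._ranking(150)
        assert len(subset_topk(r, k=100)) == 100
        assert subset_topk(r, k=150) == r.names

    def test_prefix_property(self):
        r = self._ranking(30)
        for k in range(1, 30):
            assert subset_topk(r, k=k) == subset_topk(r, k=k + 1)[:k]

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            subset_topk(self._ranking(5), k=6)


@pytest.fixture(scope="module")
def planted():
    spec = PlantedSpec(n_pos=60, n_neg=40, n_informative=4, n_noise=16,
                       effect_size=2.0, seed=0)
    return make_classification_table(spec)


class TestOobGrid:
    def test_cardinality(self, planted):
        table, inf = planted
        subsets = {"a": table.feature_names[:5], "b": table.feature_names[:10]}
        g = oob_grid(table, subsets, [2, 3], [50, 100], seed=0)
        assert len(g.points) == 8

    def test_informative_subset_beats_noise(self, planted):
        table, informative = planted
        noise = [f for f in table.feature_names if f not in informative][: len(informative)]
        g = oob_grid(table, {"inf": informative, "noise": noise}, [2], [100], seed=0)
        err = {p.subset_name: p.oob_error for p in g.points}
        assert err["inf"] < err["noise"]

    def test_best_is_min_and_order_invariant(self, planted):
        table, _ = planted
        subsets = {"a": table.feature_names[:6], "b": table.feature_names[:12]}
        g1 = oob_grid(table, subsets, [2, 4], [50], seed=0)
        g2 = oob_grid(table, dict(reversed(list(subsets.items()))), [4, 2], [50], seed=0)
        assert g1.best == g2.best
        assert g1.best.oob_error == min(p.oob_error for p in g1.points)

    def test_empty_grid_rejected(self, planted):
        with pytest.raises(ValueError):
            oob_grid(planted[0], {}, [2], [50])


class TestBuildHybrid:
    def test_published_sizes(self):
        desc = [f"d{i}" for i in range(100)]
        fp = [f"fp{i}" for i in range(1021)]
        combined = build_hybrid(desc, fp)
        assert len(combined) == 1121
        assert combined[:100] == desc and combined[100:] == fp

    def test_minimal(self):
        assert build_hybrid(["d"], ["f"]) == ["d", "f"]

    def test_duplicate_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_hybrid(["d", "d"], ["f"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_hybrid([], ["f"])


class TestWilcoxonScreen:
    def test_identical_distributions_no_hits(self):
        vals = [1.0, 2.0, 3.0, 4.0] * 2
        t = manual_table({"f": vals}, labels=[1, 1, 1, 1, 0, 0, 0, 0])
        assert wilcoxon_screen(t, alpha=0.05) == []

    def test_fully_separated_exact_p(self):
        t = manual_table({"f": [10, 11, 12, 13, 1, 2, 3, 4]},
                         labels=[1, 1, 1, 1, 0, 0, 0, 0])
        (hit,) = wilcoxon_screen(t)
        assert hit.p_value == pytest.approx(2 / 70)
        assert hit.direction == "higher-in-toxin"

    def test_alpha_boundary_inclusive(self):
        t = manual_table({"f": [10, 11, 12, 13, 1, 2, 3, 4]},
                         labels=[1, 1, 1, 1, 0, 0, 0, 0])
        assert wilcoxon_screen(t, alpha=2 / 70) != []

    def test_tiny_class_rejected(self):
        t = manual_table({"f": [1.0, 2.0, 3.0]}, labels=[1, 0, 0])
        with pytest.raises(ValueError):
            wilcoxon_screen(t)

    def test_exact_p_matches_enumeration(self, rng):
        """Exact rank-sum p equals the all-assignments oracle for every
        no-tie layout with n1 + n2 <= 10."""
        for n1 in range(2, 6):
            for n2 in range(2, 11 - n1):
                for _ in range(3):
                    vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
                    a, b = vals[:n1], vals[n1:]
                    assert ranksum_pvalue(a, b) == pytest.approx(
                        exact_ranksum_twosided(a, b), abs=1e-12
                    )
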