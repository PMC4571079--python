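import numpy as np
import pytest

import cytoscreen as cs
from cytoscreen import cart_partition as cp
from cytoscreen.cart_partition import fit_cart, gini
from cytoscreen.screening import SearchConfig

from conftest import make_cohort


def brute_force_root_split(X, y):
    """Independent exhaustive scan of all (variable, observed value) splits.

    Pure-Python re-derivation of the maximal Gini-decrease split; ties
    broken by (variable index == name order here, value).
    """
    n = len(y)
    n1 = sum(y)
    parent = 1 - (n1 / n) ** 2 - ((n - n1) / n) ** 2
    best = None
    for j in range(X.shape[1]):
        for value in sorted(set(X[:, j])):
            left = [i for i in range(n) if X[i, j] < value]
            right = [i for i in range(n) if X[i, j] >= value]
            if not left or not right:
                continue
            def g(rows):
                m = len(rows)
                m1 = sum(y[i] for i in rows)
                return 1 - (m1 / m) ** 2 - ((m - m1) / m) ** 2
            dec = parent - len(left) / n * g(left) - len(right) / n * g(right)
            if best is None or dec > best[0] + 1e-12:
                best = (dec, j, value)
            elif dec > best[0] - 1e-12 and (j, value) < (best[1], best[2]):
                best = (max(dec, best[0]), j, value)
    return None if best is None or best[0] <= 1e-15 else (best[1], best[2])


def two_regime_cohort(seed, n=300):
    """Two strata split by a bimodal variable, with opposite threshold
    rules on the same marker in each stratum."""
    rng = np.random.default_rng(seed)
    half = n // 2
    v0 = np.concatenate([rng.normal(-3, 1, half), rng.normal(3, 1, half)])
    v1 = rng.standard_normal(n)
    v2 = rng.standard_normal(n)
    y = np.where(np.arange(n) < half, v1 > 0.1, v1 < -1.5).astype(int)
    return make_cohort(np.column_stack([v0, v1, v2]), y,
                       names=["v0", "v1", "v2"])


class TestFitCart:
    def test_root_gini_at_study_counts(self):
        # 38 cases / 41 controls
        assert gini(38, 41) == pytest.approx(1 - (38 / 79) ** 2
                                             - (41 / 79) ** 2)
        assert gini(38, 41) == pytest.approx(0.4993, abs=5e-5)

    def test_pure_node_is_leaf(self):
        cohort = make_cohort([[0.0], [1.0], [2.0], [3.0]], [1, 1, 0, 0])
        tree = fit_cart(cohort, max_depth=3)
        for nid in (tree.nodes[0].left, tree.nodes[0].right):
            nd = tree.node(nid)
            assert nd.is_leaf and nd.gini == 0.0

    def test_single_class_rejected(self):
        cohort = make_cohort([[0.0], [1.0]], [1, 1])
        with pytest.raises(ValueError):
            fit_cart(cohort)

    @pytest.mark.parametrize("seed", range(10))
    def test_root_split_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(8, 3)).round(2)
        y = rng.integers(0, 2, 8)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        cohort = make_cohort(X, y)
        tree = fit_cart(cohort, max_depth=1)
        expect = brute_force_root_split(X, y)
        root = tree.nodes[0]
        if expect is None:
            assert root.is_leaf
        else:
            j, value = expect
            assert root.feature == cohort.variables[j]
            assert root.threshold == pytest.approx(value)

    def test_split_values_are_observed_data_values(self):
        cohort, _ = cs.generate_cohort(cs.SyntheticSpec(
            n_patients=100, n_vars=4, informative=[(0, 1.5)],
            latent_blocks=[], rho=0.0, prevalence=0.5, seed=3))
        tree = fit_cart(cohort, max_depth=3)
        for nd in tree.nodes:
            if not nd.is_leaf:
                col = cohort.column(nd.feature)
                assert np.any(col == nd.threshold)


class TestAssignGroups:
    def test_level_zero_is_single_group(self):
        cohort = two_regime_cohort(0)
        tree = fit_cart(cohort, max_depth=2)
        groups = cp.assign_groups(tree, cohort, level=0)
        assert groups.n_groups == 1
        (rows,) = groups.group_rows.values()
        assert rows.size == cohort.n_patients

    def test_level_one_splits_at_root_threshold(self):
        cohort = two_regime_cohort(0)
        tree = fit_cart(cohort, max_depth=2)
        groups = cp.assign_groups(tree, cohort, level=1)
        root = tree.nodes[0]
        left = cohort.column(root.feature) < root.threshold
        assert groups.n_groups == 2
        sizes = sorted(rows.size for rows in groups.group_rows.values())
        assert sizes == sorted([int(left.sum()), int((~left).sum())])

    def test_training_membership_matches_tree_records(self):
        cohort = two_regime_cohort(1)
        tree = fit_cart(cohort, max_depth=3)
        for level in range(tree.depth + 1):
            groups = cp.assign_groups(tree, cohort, level)
            covered = np.concatenate(list(groups.group_rows.values()))
            assert sorted(covered) == list(range(cohort.n_patients))
            for nid, rows in groups.group_rows.items():
                np.testing.assert_array_equal(np.sort(rows),
                                              np.sort(tree.node(nid).members))


class TestPerGroupSearch:
    def test_level_zero_reduces_to_flat_search(self):
        cohort = two_regime_cohort(2, n=120)
        params = cs.fit_standardization(cohort)
        z = cs.standardize(cohort, params)
        cfg = SearchConfig(pool=["v0", "v1", "v2"], sizes=[1, 2],
                           realizations=100, seed=4, keep_leaderboard=False)
        flat = cs.search(z, params, cfg)
        tree = fit_cart(cohort, max_depth=1)
        groups = cp.assign_groups(tree, cohort, level=0)
        res = cp.per_group_search(groups, cohort, cfg, tree)
        assert res.pooled_omr == pytest.approx(flat.best_metrics.omr)

    def test_children_of_perfect_parent_inherit(self):
        # a rule-generated phenotype lets the parent reach OMR 0, so both
        # children must inherit without a fresh search
        rule = cs.PlantedRule(var_idx=[0], lower=[-0.8], upper=[0.9])
        spec = cs.SyntheticSpec(n_patients=150, n_vars=3, threshold_rule=rule,
                                seed=5)
        cohort, _ = cs.generate_cohort(spec)
        tree = fit_cart(cohort, max_depth=1)
        cfg = SearchConfig(pool=list(cohort.variables), sizes=[1, 2],
                           realizations=4000, seed=6, keep_leaderboard=False)
        lvl0 = cp.per_group_search(cp.assign_groups(tree, cohort, 0),
                                   cohort, cfg, tree)
        assert lvl0.pooled_omr == 0.0
        lvl1 = cp.per_group_search(cp.assign_groups(tree, cohort, 1),
                                   cohort, cfg, tree,
                                   {g.node_id: g for g in lvl0.groups})
        assert all(g.inherited for g in lvl1.groups)
        assert lvl1.pooled_omr == 0.0

    def test_two_regime_partition_improves_pooled_omr(self):
        cohort = two_regime_cohort(0)
        train, valid = cs.split_cohort(cohort, 200, seed=0)
        tree = fit_cart(train, max_depth=1)
        cfg = SearchConfig(pool=["v0", "v1", "v2"], sizes=[1, 2, 3],
                           realizations=500, seed=0, keep_leaderboard=False)
        curves = cp.level_curves(train, valid, tree, cfg)
        assert curves.train_omr[1] < curves.train_omr[0]
        assert curves.valid_omr[1] < curves.valid_omr[0]
        assert curves.best_level == 1


class TestLevelCurves:
    def test_depth_zero_tree_gives_single_point(self):
        cohort = make_cohort(np.random.default_rng(1).normal(size=(60, 3)),
                             np.random.default_rng(2).integers(0, 2, 60))
        tree = fit_cart(cohort, max_depth=0)
        cfg = SearchConfig(pool=list(cohort.variables), sizes=[1],
                           realizations=50, seed=1, keep_leaderboard=False)
        train, valid = cs.split_cohort(cohort, 40, seed=1)
        tree = fit_cart(train, max_depth=0)
        curves = cp.level_curves(train, valid, tree, cfg)
        assert curves.levels == [0]
        assert len(curves.train_omr) == len(curves.valid_omr) == 1

    def test_noise_overfit_signature(self):
        """Deep partitioning of pure noise: training error keeps falling
        while validation error is non-monotone."""
        cohort = cs.generate_null_cohort(160, 8, seed=200)
        train, valid = cs.split_cohort(cohort, 110, seed=0)
        tree = fit_cart(train, max_depth=4, min_node=10)
        cfg = SearchConfig(pool=list(cohort.variables), sizes=[1, 2, 3],
                          realizations=200, seed=0, keep_leaderboard=False)
        curves = cp.level_curves(train, valid, tree, cfg)
        tm, vm = curves.train_omr, curves.valid_omr
        assert all(tm[i + 1] <= tm[i] + 1e-12 for i in range(len(tm) - 1))
        assert any(vm[i + 1] > vm[i] for i in range(len(vm) - 1))

    def test_routing_identical_between_cohort_copies(self):
        cohort = two_regime_cohort(3)
        tree = fit_cart(cohort, max_depth=2)
        ids1 = tree.route(cohort.X, level=2)
        ids2 = tree.route(cohort.X.copy(), level=2)
        np.testing.assert_array_equal(ids1, ids2)
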