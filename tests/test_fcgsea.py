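import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import cytoscreen as cs
from cytoscreen.cif_forest import VariableImportanceList
from cytoscreen.fcgsea import (
    RankedCorrelationList,
    form_fc_set_explicit,
    random_walk,
    walk_increments,
)

from conftest import make_cohort


def _vil_from_names(names):
    entries = [(n, float(len(names) - i)) for i, n in enumerate(names)]
    return VariableImportanceList(entries=entries,
                                  per_run=np.array([[v for _, v in entries]]),
                                  variables=list(names))


def _ranked(names):
    entries = [(n, 1.0 - i / len(names)) for i, n in enumerate(names)]
    return RankedCorrelationList(entries=entries, method="pearson",
                                 mode="signed")


class TestRankByCorrelation:
    def test_phenotype_copy_ranks_first_with_r_one(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 10)
        X = np.column_stack([rng.standard_normal(20), y.astype(float),
                             rng.standard_normal(20)])
        cohort = make_cohort(X, y, names=["a", "copy", "b"])
        ranked = cs.rank_by_correlation(cohort)
        assert ranked.entries[0][0] == "copy"
        assert ranked.entries[0][1] == pytest.approx(1.0)

    def test_anticopy_ranks_last_signed_first_tier_absolute(self):
        rng = np.random.default_rng(1)
        y = np.array([0, 1] * 10)
        X = np.column_stack([rng.standard_normal(20), 1.0 - y,
                             rng.standard_normal(20)])
        cohort = make_cohort(X, y, names=["a", "anti", "b"])
        signed = cs.rank_by_correlation(cohort, mode="signed")
        assert signed.entries[-1][0] == "anti"
        assert signed.entries[-1][1] == pytest.approx(-1.0)
        absolute = cs.rank_by_correlation(cohort, mode="absolute")
        assert absolute.entries[0][0] == "anti"

    def test_point_biserial_toy_matches_hand_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([0, 0, 1, 1, 1])
        cohort = make_cohort(np.column_stack([x, x[::-1] * 0 + [1, 2, 1, 2, 1]]),
                             y, names=["x", "z"])
        # closed-form point-biserial: (M1 - M0) sqrt(n1 n0) / (n sigma)
        m1, m0 = x[y == 1].mean(), x[y == 0].mean()
        sigma = x.std()  # population sd
        expected = (m1 - m0) * math.sqrt(3 * 2) / (5 * sigma)
        ranked = cs.rank_by_correlation(cohort)
        assert dict(ranked.entries)["x"] == pytest.approx(expected, abs=1e-12)

    def test_spearman_is_rank_pearson(self):
        rng = np.random.default_rng(2)
        cohort = cs.generate_null_cohort(50, 4, seed=3)
        from scipy.stats import spearmanr
        ranked = cs.rank_by_correlation(cohort, method="spearman")
        for name, r in ranked.entries:
            expected = spearmanr(cohort.column(name), cohort.phenotype).statistic
            assert r == pytest.approx(expected, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        cohort = make_cohort([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]], [0, 1, 1],
                             names=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            cs.rank_by_correlation(cohort)
        single = make_cohort([[1.0], [2.0]], [1, 1])
        with pytest.raises(ValueError, match="single class"):
            cs.rank_by_correlation(single)


class TestFormFcSet:
    def test_top_down_window_and_explicit(self):
        names = [f"fc{i:03d}" for i in range(112)]
        vil = _vil_from_names(names)
        assert cs.form_fc_set(vil, 27).members == names[:27]
        window = cs.form_fc_set_window(vil, 20, 30)
        assert window.members == names[19:30] and window.size == 11
        explicit = form_fc_set_explicit(["fc005", "fc009"], universe=names)
        assert explicit.size == 2
        with pytest.raises(ValueError):
            cs.form_fc_set(vil, 112)
        with pytest.raises(ValueError):
            cs.form_fc_set_window(vil, 0, 10)
        with pytest.raises(ValueError):
            form_fc_set_explicit(["nope"], universe=names)


class TestRandomWalk:
    def test_perfect_top_ranking_attains_closed_form_supremum(self):
        names = [f"v{i:03d}" for i in range(112)]
        ranked = _ranked(names)
        fcset = form_fc_set_explicit(names[:27])
        walk = random_walk(ranked, fcset)
        up, down = walk_increments(112, 27)
        assert up == pytest.approx(math.sqrt(85 / 27), abs=1e-12)
        assert down == pytest.approx(-math.sqrt(27 / 85), abs=1e-12)
        assert walk.es == pytest.approx(math.sqrt(2295), rel=1e-12)
        assert walk.es == pytest.approx(47.906, abs=5e-4)
        assert walk.argmax_step == 26

    def test_members_at_bottom_score_zero(self):
        names = [f"v{i:03d}" for i in range(50)]
        ranked = _ranked(names)
        fcset = form_fc_set_explicit(names[-10:])
        walk = random_walk(ranked, fcset)
        assert walk.es == 0.0
        assert walk.running_sum[-1] == pytest.approx(0.0, abs=1e-9)

    @given(n=st.integers(5, 60), g=st.integers(1, 30), seed=st.integers(0, 999))
    def test_walk_closure_and_bounds(self, n, g, seed):
        g = min(g, n - 1)
        names = [f"v{i:03d}" for i in range(n)]
        rng = np.random.default_rng(seed)
        members = [names[i] for i in rng.choice(n, size=g, replace=False)]
        walk = random_walk(_ranked(names), form_fc_set_explicit(members))
        assert abs(walk.running_sum[-1]) < 1e-9
        assert 0.0 <= walk.es <= math.sqrt(g * (n - g)) + 1e-9

    def test_membership_violation_rejected(self):
        names = [f"v{i}" for i in range(10)]
        with pytest.raises(ValueError, match="absent"):
            random_walk(_ranked(names), form_fc_set_explicit(["other"]))

    def test_absolute_mode_invariant_under_sign_flip(self):
        cohort = cs.generate_null_cohort(60, 8, seed=5)
        flipped = make_cohort(cohort.X * np.where(np.arange(8) % 2, -1, 1),
                              cohort.phenotype, names=cohort.variables)
        fcset = form_fc_set_explicit(list(cohort.variables[:3]))
        w1 = random_walk(cs.rank_by_correlation(cohort, mode="absolute"), fcset)
        w2 = random_walk(cs.rank_by_correlation(flipped, mode="absolute"), fcset)
        np.testing.assert_allclose(w1.running_sum, w2.running_sum)

    def test_joint_row_permutation_leaves_ranking_invariant(self):
        cohort = cs.generate_null_cohort(40, 6, seed=6)
        perm = np.random.default_rng(7).permutation(40)
        shuffled = cs.CohortTable(
            patient_ids=[cohort.patient_ids[i] for i in perm],
            variables=list(cohort.variables),
            X=cohort.X[perm], phenotype=cohort.phenotype[perm])
        a = cs.rank_by_correlation(cohort)
        b = cs.rank_by_correlation(shuffled)
        assert a.names == b.names
        np.testing.assert_allclose([r for _, r in a.entries],
                                   [r for _, r in b.entries], atol=1e-12)


class TestScanSetSizes:
    def test_constructed_optimum_found_at_planted_size(self):
        # ten variables with strong coordinated shifts, importance-ranked
        # on top: the ES curve must peak at G = 10
        informative = [(j, 3.0) for j in range(10)]
        spec = cs.SyntheticSpec(n_patients=400, n_vars=30,
                                informative=informative, latent_blocks=[],
                                rho=0.0, prevalence=0.5, seed=8)
        cohort, _ = cs.generate_cohort(spec)
        vil = _vil_from_names(list(cohort.variables))  # planted vars on top
        res = cs.scan_set_sizes(vil, cohort, range(3, 21))
        assert res.best_g == 10

    def test_singleton_range(self):
        cohort = cs.generate_null_cohort(40, 10, seed=9)
        vil = _vil_from_names(list(cohort.variables))
        res = cs.scan_set_sizes(vil, cohort, [4])
        assert res.best_g == 4 and res.es.shape == (1,)

    def test_null_best_es_below_permutation_envelope(self):
        cohort = cs.generate_null_cohort(60, 20, seed=10)
        vil = _vil_from_names(list(cohort.variables))
        res = cs.scan_set_sizes(vil, cohort, range(3, 11), n_perm=200, seed=1)
        # the best set of a null cohort should not be extreme against its
        # own permutation null
        assert res.p_values[list(res.g_values).index(res.best_g)] > 0.01


class TestPermutationPvalue:
    def test_strong_signal_is_significant(self):
        spec = cs.SyntheticSpec(n_patients=200, n_vars=20,
                                informative=[(j, 2.0) for j in range(5)],
                                latent_blocks=[], rho=0.0, prevalence=0.5,
                                seed=11)
        cohort, _ = cs.generate_cohort(spec)
        fcset = form_fc_set_explicit(list(cohort.variables[:5]))
        p = cs.permutation_pvalue(fcset, cohort, n_perm=1000, seed=2)
        assert p < 0.01

    def test_counting_definition_at_single_permutation(self):
        spec = cs.SyntheticSpec(n_patients=200, n_vars=10,
                                informative=[(0, 3.0), (1, 3.0)],
                                latent_blocks=[], rho=0.0, prevalence=0.5,
                                seed=12)
        cohort, _ = cs.generate_cohort(spec)
        fcset = form_fc_set_explicit(list(cohort.variables[:2]))
        p = cs.permutation_pvalue(fcset, cohort, n_perm=1, seed=3)
        assert p == 0.0
        smoothed = cs.permutation_pvalue(fcset, cohort, n_perm=1, seed=3,
                                         smoothed=True)
        assert smoothed == 0.5

    def test_null_pvalues_uniform(self):
        from scipy.stats import kstest
        ps = []
        for rep in range(60):
            cohort = cs.generate_null_cohort(60, 30, seed=7000 + rep)
            fcset = form_fc_set_explicit(list(cohort.variables[:5]))
            ps.append(cs.permutation_pvalue(fcset, cohort, n_perm=200,
                                            seed=rep))
        assert kstest(ps, "uniform").pvalue > 0.01
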