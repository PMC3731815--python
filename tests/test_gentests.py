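"""Test-statistic checks against independent brute-force oracles, plus the
structural invariances (column order, label swap, determinism)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from genewise.gentests import (
    DegenerateGeneError,
    cluster_counts,
    entropy_gene_test,
    entropy_test,
    joint_genotype_table,
    maxT_test,
    pem_cluster,
    perturbation_statistics,
    score_components,
    single_snp_gene_test,
)
from genewise.simgeno import GenotypeMatrix

from conftest import make_sample
from oracles import brute_entropy, brute_perturbed, brute_score


# --- score test ------------------------------------------------------------


class TestScoreComponents:
    def test_worked_instance_matches_brute_force(self, tiny_sample):
        comp = score_components(tiny_sample)
        y = tiny_sample.phenotype.labels.tolist()
        x = tiny_sample.genotypes.dosages[:, 0].tolist()
        assert comp.statistics[0] == pytest.approx(brute_score(y, x), rel=1e-12)

    def test_constant_genotype_untestable(self):
        s = make_sample(np.ones((6, 1)), [1, 1, 1, 0, 0, 0])
        comp = score_components(s)
        assert comp.statistics[0] == 0.0 and not comp.testable[0]
        with pytest.raises(DegenerateGeneError):
            maxT_test(s, B=100, seed=1)

    def test_no_phenotype_variation_errors(self):
        s = make_sample([[0], [1], [2]], [1, 1, 1])
        with pytest.raises(ValueError, match="no variation"):
            score_components(s)

    @given(st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_random_small_instances_match_brute_force(self, data):
        n = data.draw(st.integers(4, 10))
        m = data.draw(st.integers(1, 2))
        x = np.array(data.draw(st.lists(
            st.lists(st.integers(0, 2), min_size=m, max_size=m),
            min_size=n, max_size=n)))
        n_cases = data.draw(st.integers(1, n - 1))
        y = np.array([1] * n_cases + [0] * (n - n_cases))
        comp = score_components(make_sample(x, y))
        for j in range(m):
            assert comp.statistics[j] == pytest.approx(
                brute_score(y.tolist(), x[:, j].tolist()), rel=1e-10, abs=1e-12
            )

    def test_label_swap_leaves_statistics_unchanged(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, size=(60, 5))
        y = np.r_[np.ones(25, int), np.zeros(35, int)]
        a = score_components(make_sample(x, y)).statistics
        b = score_components(make_sample(x, 1 - y)).statistics
        assert np.allclose(a, b)

    def test_genotypic_2df_matches_contingency_scale(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 3, size=(200, 3))
        y = np.r_[np.ones(100, int), np.zeros(100, int)]
        comp = score_components(make_sample(x, y), coding="genotypic_2df")
        assert comp.df == 2
        assert np.all(comp.statistics[comp.testable] >= 0)


class TestMaxT:
    def test_perturbation_matches_brute_force(self, tiny_sample):
        comp = score_components(tiny_sample)
        g = np.random.default_rng(3).standard_normal((5, 8))
        tt = perturbation_statistics(comp, g)
        y = tiny_sample.phenotype.labels.tolist()
        x = tiny_sample.genotypes.dosages[:, 0].tolist()
        for b in range(5):
            assert tt[b, 0] == pytest.approx(
                brute_perturbed(y, x, g[b].tolist()), rel=1e-10
            )

    def test_pvalue_convention_bounds(self):
        rng = np.random.default_rng(4)
        s = make_sample(rng.integers(0, 3, (40, 3)),
                        np.r_[np.ones(20, int), np.zeros(20, int)])
        res = maxT_test(s, B=500, seed=5)
        assert 1 / 501 <= res.p_value <= 1.0

    def test_duplicated_column_equals_single_column(self):
        rng = np.random.default_rng(6)
        x1 = rng.integers(0, 3, size=(50, 1))
        y = np.r_[np.ones(25, int), np.zeros(25, int)]
        p1 = maxT_test(make_sample(x1, y), B=400, seed=7).p_value
        p2 = maxT_test(make_sample(np.hstack([x1, x1]), y), B=400, seed=7).p_value
        assert p1 == p2

    def test_column_order_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 3, size=(60, 4))
        y = np.r_[np.ones(30, int), np.zeros(30, int)]
        a = maxT_test(make_sample(x, y), B=400, seed=9)
        b = maxT_test(make_sample(x[:, ::-1], y), B=400, seed=9)
        assert a.t_max == b.t_max
        # identical G stream and a max over the same set of statistics
        assert a.p_value == b.p_value

    def test_empirical_p_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(10)
        s = make_sample(rng.integers(0, 3, (40, 3)),
                        np.r_[np.ones(20, int), np.zeros(20, int)])
        comp = score_components(s)
        g = np.random.default_rng(11).standard_normal((2000, 40))
        tmax = perturbation_statistics(comp, g).max(axis=1)
        thresholds = np.linspace(0, 10, 30)
        pvals = [(1 + (tmax >= t).sum()) / 2001 for t in thresholds]
        assert np.all(np.diff(pvals) <= 0)


class TestSingleSnp:
    def test_single_snp_threshold_is_alpha(self, tiny_sample):
        res = single_snp_gene_test(tiny_sample, alpha=0.05)
        assert res.detail["n_tested"] == 1
        expected = stats.chi2.sf(score_components(tiny_sample).statistics[0], 1)
        assert res.detail["min_p"] == pytest.approx(expected)
        assert res.significant == (expected < 0.05)

    def test_bonferroni_divides_by_snp_count(self):
        rng = np.random.default_rng(12)
        x = rng.integers(0, 3, size=(80, 8))
        y = np.r_[np.ones(40, int), np.zeros(40, int)]
        res = single_snp_gene_test(make_sample(x, y), alpha=0.005)
        # per-SNP threshold 0.005 / 8 = 0.000625
        assert res.significant == (res.detail["min_p"] < 0.005 / 8)


# --- joint genotypes, PEM, entropy -----------------------------------------


class TestJointGenotypeTable:
    def test_hand_count(self):
        s = make_sample([[0, 1], [0, 1], [2, 2], [0, 1]], [1, 1, 0, 0])
        t = joint_genotype_table(s)
        assert t.s == 2
        assert [list(lbl) for lbl in t.labels] == [[0, 1], [2, 2]]
        assert np.allclose(t.case_freqs, [1.0, 0.0])
        assert np.allclose(t.control_freqs, [0.5, 0.5])

    def test_single_category(self):
        s = make_sample(np.zeros((4, 1)), [1, 1, 0, 0])
        t = joint_genotype_table(s)
        assert t.s == 1 and t.case_freqs[0] == 1.0

    def test_pooled_mixture_identity(self):
        rng = np.random.default_rng(13)
        s = make_sample(rng.integers(0, 3, (100, 3)),
                        np.r_[np.ones(40, int), np.zeros(60, int)])
        t = joint_genotype_table(s)
        pooled = t.pooled_counts / 100
        mix = (40 * t.case_freqs + 60 * t.control_freqs) / 100
        assert np.allclose(pooled, mix)


def table_from_counts(labels, case, ctrl):
    from genewise.gentests import JointGenotypeTable

    return JointGenotypeTable(np.array(labels), np.array(case), np.array(ctrl))


class TestPEM:
    def test_equal_frequencies_never_decrease(self):
        t = table_from_counts([[0, 0], [1, 0], [2, 0], [2, 2]],
                              [25, 25, 25, 25], [0, 0, 0, 0])
        state = pem_cluster(t)
        assert state.cutoff_k == 4
        assert np.all(np.diff(state.pem_values) > 0)

    def test_stopping_rule_increase_then_decrease(self):
        t = table_from_counts([[0, 0, 0], [2, 2, 2], [0, 0, 2]],
                              [20, 15, 1], [20, 15, 1])
        state = pem_cluster(t)
        assert state.cutoff_k == 2
        assert state.pem_values[1] > state.pem_values[0]
        assert state.pem_values[2] < state.pem_values[1]

    def test_rare_assigned_by_dosage_similarity(self):
        t = table_from_counts([[0, 0, 0], [0, 0, 2], [2, 2, 2]],
                              [20, 1, 15], [20, 1, 15])
        state = pem_cluster(t)
        assert state.cutoff_k == 2
        # rare (0,0,2): 2 positions match (0,0,0), 1 matches (2,2,2)
        rare_sorted_pos = 2
        assert state.assignments[rare_sorted_pos] == 0
        case, ctrl = cluster_counts(t, state)
        assert case.sum() == t.n_cases and ctrl.sum() == t.n_controls
        assert case[0] == 21  # 20 + merged rare

    @given(st.data())
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_cluster_counts_conserve_totals(self, data):
        s = data.draw(st.integers(1, 12))
        labels = np.array([[(i >> b) & 1 for b in range(4)] for i in range(s)]) * 2
        case = np.array(data.draw(st.lists(st.integers(0, 50), min_size=s, max_size=s)))
        ctrl = np.array(data.draw(st.lists(st.integers(0, 50), min_size=s, max_size=s)))
        if (case + ctrl == 0).any():
            case = case + 1
        t = table_from_counts(labels, case, ctrl)
        state = pem_cluster(t)
        c, u = cluster_counts(t, state)
        assert c.sum() == case.sum() and u.sum() == ctrl.sum()
        assert 1 <= state.cutoff_k <= s


class TestEntropyTest:
    def test_identical_frequencies_give_zero(self):
        res = entropy_test([40, 35, 25], [40, 35, 25])
        assert res.statistic == pytest.approx(0.0, abs=1e-20)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_brute_force_matrix_assembly(self):
        case, ctrl = [40, 35, 25], [30, 35, 35]
        res = entropy_test(case, ctrl)
        assert res.df == 2
        assert res.statistic == pytest.approx(brute_entropy(case, ctrl), rel=1e-10)

    def test_zero_count_continuity_correction(self):
        res = entropy_test([50, 0, 30], [30, 25, 25])
        assert np.isfinite(res.statistic) and res.statistic > 0
        assert res.statistic == pytest.approx(
            brute_entropy([50, 0, 30], [30, 25, 25]), rel=1e-10
        )

    def test_too_few_clusters_error(self):
        with pytest.raises(DegenerateGeneError):
            entropy_test([10], [12])

    def test_gene_pipeline_label_swap_invariance(self):
        rng = np.random.default_rng(14)
        x = rng.integers(0, 3, size=(200, 3))
        y = np.r_[np.ones(100, int), np.zeros(100, int)]
        a = entropy_gene_test(make_sample(x, y))
        b = entropy_gene_test(make_sample(x, 1 - y))
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_single_cluster_gene_is_nonrejection(self):
        s = make_sample(np.zeros((10, 2)), [1] * 5 + [0] * 5)
        res = entropy_gene_test(s)
        assert res.p_value == 1.0 and res.statistic == 0.0
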