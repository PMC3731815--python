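"""Disease-model checks: penetrances against closed forms, odds models,
and the rejection sampler against an exact conditional-genotype oracle."""

import numpy as np
import pytest

from genewise.simgeno import HaplotypePanel, PanelGenotypeSource
from genewise.simpheno import (
    DegenerateDiseaseModelError,
    OddsModel,
    PenetranceModel,
    choose_causal_snp,
    disease_probability,
    odds,
    penetrances,
    sample_case_control,
)


def hw_weights(p):
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])


@pytest.fixture
def balanced_panel():
    """100 haplotypes, one site with '1'-frequency exactly 0.3."""
    alleles = np.zeros((100, 2), dtype=np.int8)
    alleles[:30, 0] = 1
    alleles[:50, 1] = 1
    return HaplotypePanel(alleles, np.array([10.0, 20.0]), 100)


class TestPenetrances:
    @pytest.mark.parametrize("mode", ["additive", "dominant", "recessive"])
    def test_null_grr_collapses_to_prevalence(self, mode):
        f = penetrances(PenetranceModel(mode, 1.0, 0.3, prevalence=0.08))
        assert np.allclose(f, 0.08)

    def test_additive_closed_form(self):
        f0, f1, f2 = penetrances(PenetranceModel("additive", 1.5, 0.3, 0.1))
        assert f0 == pytest.approx(0.1 / 1.3, rel=1e-12)
        assert f1 == pytest.approx(1.5 * f0)
        assert f2 == pytest.approx(2.0 * f0)

    def test_recessive_closed_form_and_prevalence_identity(self):
        model = PenetranceModel("recessive", 2.0, 0.5, 0.1)
        f = np.array(penetrances(model))
        assert f[0] == pytest.approx(0.1 / (1 + 0.25 * 4 - 0.25), rel=1e-12)
        assert hw_weights(0.5) @ f == pytest.approx(0.1, abs=1e-14)

    def test_invalid_penetrance_rejected(self):
        # large risk with high prevalence pushes f2 above 1
        with pytest.raises(ValueError, match="invalid penetrance"):
            penetrances(PenetranceModel("additive", 10.0, 0.05, 0.5))


class TestOdds:
    @pytest.mark.parametrize("model_id", [1, 2, 3])
    def test_null_effect_gives_baseline(self, model_id):
        m = OddsModel(2, model_id, baseline=1.7, effect=0.0)
        g = np.array([[0, 0], [1, 2], [2, 2]])
        assert np.allclose(odds(m, g), 1.7)

    def test_model1_multiplicative(self):
        m = OddsModel(2, 1, baseline=1.0, effect=0.5)
        assert odds(m, np.array([1, 1])) == pytest.approx(2.25)

    def test_model3_requires_joint_carriers(self):
        m = OddsModel(2, 3, baseline=1.0, effect=0.9)
        assert odds(m, np.array([2, 0])) == pytest.approx(1.0)
        assert odds(m, np.array([2, 1])) == pytest.approx(1.9)

    @pytest.mark.parametrize("model_id", [1, 2])
    def test_exchangeable_in_loci(self, model_id):
        m = OddsModel(3, model_id, baseline=1.3, effect=0.4)
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(50, 3))
        for perm in ([1, 0, 2], [2, 1, 0], [1, 2, 0]):
            assert np.allclose(odds(m, g), odds(m, g[:, perm]))


class TestChooseCausal:
    def test_closest_maf_wins(self):
        freqs = np.array([0.05, 0.28, 0.45, 0.95])
        j, maf = choose_causal_snp(freqs, target_maf=0.3)
        assert j == 1 and maf == pytest.approx(0.28)

    def test_major_allele_frequency_folded(self):
        j, maf = choose_causal_snp(np.array([0.9, 0.5]), target_maf=0.1)
        assert j == 0 and maf == pytest.approx(0.1)


class TestSampling:
    def test_degenerate_model_raises(self, balanced_panel):
        m = OddsModel(2, 1, baseline=1e9, effect=0.0, causal_indices=(0, 1))
        with pytest.raises(DegenerateDiseaseModelError):
            sample_case_control(PanelGenotypeSource(balanced_panel), m, 10, 10, 1)

    def test_counts_and_labels(self, balanced_panel):
        model = PenetranceModel("additive", 1.8, 0.3, 0.1, causal_index=0)
        s = sample_case_control(PanelGenotypeSource(balanced_panel), model,
                                150, 250, seed=2)
        assert s.phenotype.n_cases == 150 and s.phenotype.n_controls == 250
        assert s.genotypes.n_individuals == 400

    def test_null_has_no_allele_frequency_shift(self, balanced_panel):
        model = PenetranceModel("additive", 1.0, 0.3, 0.1, causal_index=0)
        s = sample_case_control(PanelGenotypeSource(balanced_panel), model,
                                2000, 2000, seed=3)
        y = s.phenotype.labels.astype(bool)
        d = s.genotypes.dosages[:, 0]
        diff = d[y].mean() - d[~y].mean()
        se = np.sqrt(2 * 2 * 0.3 * 0.7 / 2000)
        assert abs(diff) < 4 * se

    def test_case_distribution_matches_exact_conditional_oracle(self, balanced_panel):
        """Empirical P(genotype | case) matches P(g)f(g)/Σ P(g)f(g) from
        Hardy-Weinberg weights and the model penetrances."""
        model = PenetranceModel("additive", 1.8, 0.3, 0.1, causal_index=0)
        f = np.array(penetrances(model))
        w = hw_weights(0.3)
        oracle_case = w * f / (w * f).sum()
        oracle_ctrl = w * (1 - f) / (w * (1 - f)).sum()
        s = sample_case_control(PanelGenotypeSource(balanced_panel), model,
                                4000, 4000, seed=4)
        y = s.phenotype.labels.astype(bool)
        d = s.genotypes.dosages[:, 0]
        emp_case = np.bincount(d[y], minlength=3) / 4000
        emp_ctrl = np.bincount(d[~y], minlength=3) / 4000
        for emp, ora in ((emp_case, oracle_case), (emp_ctrl, oracle_ctrl)):
            se = np.sqrt(ora * (1 - ora) / 4000)
            assert np.all(np.abs(emp - ora) < 4 * se)
        # case enrichment monotone in dosage for an additive model
        lr = emp_case / np.maximum(emp_ctrl, 1e-12)
        assert lr[0] < lr[1] < lr[2]

    def test_prevalence_conservation_on_unconditioned_draws(self, balanced_panel):
        model = PenetranceModel("dominant", 1.6, 0.3, 0.1, causal_index=0)
        rng = np.random.default_rng(9)
        g = PanelGenotypeSource(balanced_panel).draw(20_000, rng)
        prob = disease_probability(model, g, risk_flip=np.array([False]))
        status = rng.random(20_000) < prob
        se = np.sqrt(0.1 * 0.9 / 20_000)
        assert abs(status.mean() - 0.1) < 3 * se

    def test_null_spec_deterministic(self, balanced_panel):
        a = sample_case_control(PanelGenotypeSource(balanced_panel), None, 20, 30, 5)
        b = sample_case_control(PanelGenotypeSource(balanced_panel), None, 20, 30, 5)
        assert np.array_equal(a.genotypes.dosages, b.genotypes.dosages)
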