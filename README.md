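# genewise

Gene-based case-control association testing, with the simulation bench to
calibrate and compare the methods.

In a candidate-gene or genome-wide association study, testing every SNP
separately and Bonferroni-correcting is simple but loses power when the
signal is spread over several correlated SNPs in a gene. `genewise`
implements three gene-level procedures that take a gene's SNPs (dosage-coded
0/1/2) and a binary case/control phenotype:

- **single-SNP scan with Bonferroni** — per-SNP score statistics
  T_j = U_j² / V_j with U_j = Σ_i (Y_i − Ȳ)(X_ji − X̄_j) and
  V_j = Σ_i [(Y_i − Ȳ)(X_ji − X̄_j)]², each referred to χ²₁; the gene is
  significant if min_j p_j < α/m;
- **maxT with a Monte-Carlo perturbation null** — the statistic is
  t_max = max_j T_j; its joint null distribution is approximated by drawing
  i.i.d. standard-normal weights G_i, forming Ũ_j = Σ_i U_ji G_i and
  T̃_j = Ũ_j² / V_j, and recording T̃_max over B draws; the empirical
  p-value is (1 + #{T̃_max ≥ t_max}) / (B + 1);
- **entropy test with penalized-entropy (PEM) clustering** — the distinct
  joint genotypes over the gene's SNPs are multinomial categories; rare
  categories are merged into the common set chosen by maximising the
  penalized entropy I(k) = −Σ_{j≤k} p_j log₂ p_j − 2 log₂(k)/m_k; the test
  statistic T = (S^A − S^U) W⁻¹ (S^A − S^U)ᵀ compares the case and control
  entropy vectors S = (−p₁ log p₁, …) through a delta-method covariance W
  and is referred to χ² with (clusters − 1) degrees of freedom.

The simulation bench reproduces the study design these methods are usually
evaluated under: haplotype panels from a neutral coalescent with
recombination (via msprime; 100 sequences, 10 kb, 4N_eµ/bp = 5.6×10⁻⁴,
4N_eγ/bp = 4×10⁻³, windows of 10 adjacent SNPs) or from a first-order
Markov chain with prescribed adjacent-pair LD r²; diploid genotypes by
random haplotype pairing; phenotypes from single-SNP penetrance models
(additive/dominant/recessive, parameterised by genotype relative risk,
disease allele frequency and prevalence) or two/three-locus interaction
odds models Odds(G) = γ(1+θ)^f(G).

## Worked example

```python
import genewise as gw

# a 10-SNP gene under a two-locus interaction: odds = (1 + 0.9)^(Ga+Gb)
panel = gw.simulate_gene_window(gw.CoalescentParams(), n_snps=10, seed=7)
model = gw.OddsSpec(n_loci=2, model_id=1, baseline=1.0, effect=0.9).resolve(
    panel.allele_frequencies())
sample = gw.sample_case_control(gw.PanelGenotypeSource(panel), model,
                                n_cases=800, n_controls=800, seed=8)

comp = gw.score_components(sample)
mt = gw.maxT_test(sample, B=10_000, seed=9, components=comp)
ent = gw.entropy_gene_test(sample)
snp = gw.single_snp_gene_test(sample, alpha=0.05, components=comp)
print(f"maxT   : t_max={mt.t_max:.2f}  p={mt.p_value:.4g}")
print(f"entropy: T={ent.statistic:.2f} df={ent.df}  p={ent.p_value:.4g}")
print(f"snp    : bonferroni p={snp.p_value:.4g}")
```

Output:

```
maxT   : t_max=43.10  p=9.999e-05
entropy: T=62.71 df=15  p=8.591e-08
snp    : bonferroni p=5.19e-10
```

The interaction is strong enough that all three methods reject decisively:
the maxT p-value is at its Monte-Carlo floor 1/(B+1), and the entropy test
finds the case/control joint-genotype distributions incompatible across the
16 PEM clusters formed from the 52 observed joint genotypes.

The same analyses run from the shell: `genewise simulate-data`,
`genewise test-gene`, `genewise simulate-power`, and `genewise scan`
(per-gene analysis of user files: delimited genotype matrix, VCF, or
PLINK-style .ped/.map, with a SNP-to-gene map, MAF ≥ 0.05 filter and a
per-gene nominal level).

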