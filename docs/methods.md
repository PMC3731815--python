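# Methods

This note records the statistical models implemented in `genewise`, the
defaults and why they were chosen, the numerical conventions, and what the
simulation bench does and does not establish.

## Score statistics and the maxT perturbation null

For one gene with m SNPs, binary phenotype Y and dosages X_ji ∈ {0,1,2}, the
per-SNP score ingredients are

    U_ji = (Y_i − Ȳ)(X_ji − X̄_j),   U_j = Σ_i U_ji,
    V_j  = Σ_i U_ji²,                T_j = U_j² / V_j.

The genotype is centred inside both U and V. Because Σ_i (Y_i − Ȳ) = 0,
centring does not change U_j itself, but it makes V_j a proper variance
estimate of U_j under the null; with uncentred X the statistic is
mis-scaled and the null calibration (which the test suite checks by
simulation) fails. An optional genotypic coding replaces each dosage column
by heterozygote/homozygote indicators, giving a 2-dimensional score and a
2-df χ² reference; the additive 1-df coding is the default because the
dosage coding X ∈ {0,1,2} is scalar.

Monomorphic columns have V_j = 0; they are flagged untestable, carry T_j = 0
and are excluded from the Bonferroni count and the maxT maximum. The
single-SNP procedure declares the gene significant when
min_j p_j < α / m_testable.

The maxT statistic is t_max = max_j T_j. Its null distribution is
approximated by the score perturbation scheme: draw G_1..G_n i.i.d. N(0,1),
form Ũ_j = Σ_i U_ji G_i and T̃_j = Ũ_j² / V_j, and record T̃_max; this
reproduces the joint null covariance of the scores without permuting data.
The empirical p-value uses the add-one convention
p = (1 + #{T̃_max ≥ t_max}) / (B + 1), so p ≥ 1/(B+1) and p is never 0.
Draws are generated in chunks of 2048 weight vectors and applied as one
matrix product per chunk, which keeps B = 10,000 draws for an 800+800 sample
around a quarter of a second. The G-stream depends only on the seed and the
sample size, so genes in perfect LD (duplicated columns) reproduce the m=1
p-value exactly.

## Entropy test with penalized-entropy clustering

The s distinct joint genotypes observed in the pooled sample are multinomial
categories with case/control frequencies p^A, p^U. The statistic compares
the entropy-transformed frequency vectors S = (−p_1 log p_1, …):

    T = (S^A − S^U) W⁻¹ (S^A − S^U)ᵀ,
    W = D^A Σ^A D^A / n^A + D^U Σ^U D^U / n^U,

with D = diag(−(1 + log p)) the Jacobian of p ↦ −p log p and
Σ = diag(p) − ppᵀ the multinomial covariance. This delta-method form is the
construction under which T is asymptotically χ²; it is validated by
simulation in the test suite. Σ is singular (components sum to zero), so the
most frequent pooled category is dropped before inversion and the reference
distribution is χ² with (categories − 1) degrees of freedom. Natural logs
are used in S and W (the base cancels from the quadratic form if applied
consistently); base-2 logs are used in the PEM criterion below, as that
formula is conventionally written.

Degrees of freedom are reduced by grouping rare joint genotypes. Categories
are sorted by pooled frequency (descending; lexicographic on the dosage
vector for ties, for determinism) and the penalized entropy

    I(k) = −Σ_{j≤k} p_j log₂ p_j − 2 log₂(k) / m_k

is accumulated, where p_j are pooled sample frequencies (not renormalized
within the growing set) and m_k is the pooled count of the k-th most common
genotype — the reading under which the penalty grows as rarer genotypes
enter. The common set is the largest prefix before I first strictly
decreases. Every rare category joins the common category with the most
matching SNP dosages (Hamming similarity); ties go to the more frequent
common category, then lexicographic order. If any cluster then has zero
count in one group, 0.5 is added to every cluster count in both groups
(continuity correction, configurable) so the logs stay finite. A gene that
collapses to a single cluster carries no contrast and is reported with
statistic 0 and p-value 1 rather than an error.

Two caveats are worth knowing. First, the delta method degenerates for a
category whose frequency is near 1/e ≈ 0.368, where the derivative of
−p log p vanishes; the χ² approximation for a *fixed* two-category split is
poor exactly there (the calibration test uses frequencies away from that
point). In realistic multi-SNP genes the statistic mixes many categories and
the overall null rejection rate measured by the harness is 0.05–0.06 at
α = 0.05, matching published behaviour. Second, the clusters are chosen from
the pooled data before testing; the PEM rule is frequency-based only
(phenotype-blind), which is what keeps the post-clustering χ² reference
honest.

## Genotype generators

**Coalescent panels.** `simulate_coalescent_panel` draws n_seq = 100 haploid
sequences over a 10 kb region from a neutral coalescent with recombination,
using msprime with haploid lineages and population size 2N_e — the scaling
under which 4N_eµ and 4N_eγ are the standard population-scaled rates.
Defaults: N_e = 10⁴, 4N_eµ/bp = 5.6×10⁻⁴ (θ_region = 5.6, so E[S] =
θ Σ_{i<100} 1/i ≈ 29 segregating sites), 4N_eγ/bp = 4×10⁻³. Mutations are
infinite-sites binary; sites monomorphic in the sample are dropped. A gene
is a window of 10 *adjacent* segregating sites with uniformly chosen start;
panels with fewer than 10 sites are resimulated with a derived seed
(probability ≈ 10⁻⁵ at these defaults). The Watterson identity is asserted
by a 200-replicate Monte-Carlo test.

**LD panels.** `simulate_ld_panel` builds haplotypes from a first-order
Markov chain over loci sharing one minor allele frequency (default 0.3, a
mid-range value to which the type-I-error results are insensitive): locus 1
is Bernoulli(maf) and each next allele is drawn from the two-locus haplotype
table with D = r·p(1−p), r = √(target r²). Adjacent pairs then have exactly
the target r² in the population and lag-ℓ pairs have (r²)^ℓ, which the tests
verify empirically at 10⁵ haplotypes.

**Pairing.** Diploid dosages are sums of two haplotypes drawn uniformly
*with replacement* from the panel — the 100-haplotype panel acts as the
population. Windows may therefore contain SNPs monomorphic in a finite
sample; all tests handle zero-variance columns. A fresh panel is generated
for every simulation replicate (configurable via the harness), so
panel-level sampling noise propagates into power estimates.

## Disease models

**Single causal SNP.** Penetrances f_0, f_1, f_2 follow the standard
GRR/prevalence parameterisation with baseline f_0 solved from the
Hardy-Weinberg prevalence identity (1−p)²f_0 + 2p(1−p)f_1 + p²f_2 = k:

| model     | f_1   | f_2      | f_0                      |
|-----------|-------|----------|--------------------------|
| additive  | λf_0  | (2λ−1)f_0| k / (1 − 2p + 2pλ)       |
| dominant  | λf_0  | λf_0     | k / ((1−p)² + λp(2−p))   |
| recessive | f_0   | λ²f_0    | k / (1 + p²λ² − p²)      |

The recessive homozygote penetrance is λ²f_0 — the only form consistent
with the baseline denominator and the prevalence identity, which a
parameter-grid test asserts to 10⁻¹⁴. The causal SNP in a simulated gene is
the one whose minor allele frequency is closest to a target (default 0.3),
the minor allele is the risk allele, and the realized frequency is used as
the model's p. Prevalence defaults to k = 0.1, a common value for complex
disease; the saturated power cells are insensitive to it.

**Interaction models.** Two- or three-locus odds models
Odds(G) = γ(1+θ)^e(G) with e = ΣG (Model 1), Σ G·1{G>0} (Model 2) or
1{all G>0} (Model 3); disease probability odds/(1+odds), the standard
odds→probability mapping. By default the causal loci are the n_loci SNPs
with minor allele frequency closest to 0.3 in the replicate's panel
(`OddsSpec`), mirroring the single-SNP rule: under the coalescent site
frequency spectrum roughly a third of sites are rare (panel MAF ≤ 0.02),
and anchoring causal loci at fixed window positions makes a substantial
fraction of replicates carry essentially no signal, which is incompatible
with the saturated (≈100%) power such studies report for strong-effect
cells. Fixed positions remain available (`OddsModel.causal_indices`,
CLI `--causal`).

**Sampling.** Case/control status is Bernoulli given genotype; fixed totals
(e.g. 400+400) are reached by rejection sampling, accepting each drawn
individual into whichever stratum still has room — the only scheme
consistent with both conditional Bernoulli status and fixed totals. The
risk-allele orientation at the causal columns is fixed once from the panel,
not re-derived per batch. An acceptance probability below 10⁻⁶ for an
unfilled stratum raises a degenerate-model error.

## Harness and problem sizes

`run_cell` runs one design: per replicate, fresh panel → window → phenotype
→ all three tests on the identical dataset (paired comparison; a CRC32
checksum of each dataset folds into the cell record). Per-replicate seeds
derive from (master seed, cell key, replicate index) via NumPy's
SeedSequence, so cells are independent and bit-reproducible. Degenerate
replicates (no testable SNP; single cluster) count as non-rejections.

Default problem sizes mirror a desk-scale study: 500 replicates for
type-I-error cells and 100 for power cells, B = 10,000 perturbation draws,
α = 0.05, samples of 400+400 or 800+800. At these sizes a null cell takes
roughly two to three minutes and a power cell under a minute on one CPU.
The binomial standard error at 100 replicates is about 0.05 at p = 0.5 and
0.01 at p = 0.99, which bounds what a single cell can resolve.

## Gene-scan rules (user data)

The `scan` path applies the conventional candidate-gene filters: SNPs with
pooled minor allele frequency below 0.05 are removed, genes left with fewer
than 2 SNPs are dropped, each gene is tested at a fixed per-gene nominal
level (default 0.005) with the single-SNP method at that level divided by
the gene's SNP count. Missing genotypes are handled at load time — per-SNP
mode imputation by default, or listwise deletion — so all three tests see
the same completed matrix. Input formats: delimited dosage matrix, VCF
(biallelic GT), PLINK-style text .ped/.map (dosages count the minor
allele).

## What the bench does and does not show

The generators emulate the *population-genetic* structure relevant to these
tests — realistic site frequency spectra and LD decay within a short window,
Hardy-Weinberg genotypes, case-control ascertainment under explicit disease
models. They do not model genotyping error, missingness mechanisms,
population stratification, covariates, imputation uncertainty, or rare-
variant architectures; calibration and power results here therefore speak
to the statistics' behaviour under clean ascertainment, not to robustness
against confounding. Power values in unsaturated cells depend on choices a
published table does not pin down (prevalence, causal placement, target
MAF); the harness reports them side by side with reference values rather
than asserting equality, and asserts only calibration, saturated cells and
the qualitative method ordering.

## Known limitations

- The entropy statistic's χ² reference is asymptotic; with few individuals
  per cluster (or cluster frequencies near 1/e, see above) it can drift.
  The continuity correction bounds but does not remove this. With
  coalescent 10-SNP genes the measured null rejection rate is ≈ 0.07 at
  α = 0.05 for both 400+400 and 800+800 samples: larger samples expose
  more joint genotypes, the PEM cutoff retains more clusters (≈14 vs ≈19
  on average), and the extra degrees of freedom offset the per-cell
  asymptotic gain.
- When nearly every individual carries a unique joint genotype — e.g. many
  mutually independent common SNPs, where the 3^m genotype classes swamp
  the sample — the penalized-entropy rule collapses the common set to a
  single cluster and the entropy test cannot reject at all. It is then
  totally conservative, not invalid; the maxT and single-SNP tests are the
  informative procedures in that regime.
- The PEM penalty uses the pooled count of the k-th genotype; other readings
  of the penalty's denominator exist, and the cutoff is sensitive to it for
  small samples.
- The coalescent generator is panmictic and neutral: no growth, structure,
  selection or gene conversion.
- The LD generator's chain construction gives geometrically decaying LD with
  equal MAFs only; it is a calibration device, not a model of real
  haplotype structure.
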