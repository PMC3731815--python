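"""Genotype simulation: coalescent haplotype panels, LD-chain panels, diploid pairing.

Two generators produce :class:`HaplotypePanel` objects — a neutral
coalescent-with-recombination model (via msprime) mimicking Hudson's ``ms``,
and a first-order Markov chain over biallelic loci with a prescribed
adjacent-pair linkage disequilibrium r².  Diploid genotype matrices are
assembled by drawing two haplotypes per individual, uniformly with
replacement, from a finite panel that stands in for the population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np

__all__ = [
    "HaplotypePanel",
    "CoalescentParams",
    "LDParams",
    "GenotypeMatrix",
    "InsufficientPolymorphismError",
    "simulate_coalescent_panel",
    "select_gene_window",
    "pair_haplotypes",
    "simulate_ld_panel",
    "simulate_gene_window",
    "PanelGenotypeSource",
]


class InsufficientPolymorphismError(RuntimeError):
    """Raised when a simulated panel has too few segregating sites; resimulate."""


def _seed_stream(seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent 31-bit seeds from a user seed."""
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n, dtype=np.uint64) % (2**31 - 2) + 1


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes over polymorphic sites.

    Parameters
    ----------
    alleles
        ``(n_seq, n_sites)`` matrix with entries in {0, 1}.
    positions
        Site coordinates in base pairs, strictly increasing, inside
        ``[0, region_length_bp)``.
    region_length_bp
        Length of the simulated region.
    """

    alleles: np.ndarray
    positions: np.ndarray
    region_length_bp: int

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0 or 1")
        if self.positions.shape != (self.alleles.shape[1],):
            raise ValueError("positions must have one entry per site")
        if self.n_sites and (
            np.any(np.diff(self.positions) <= 0)
            or self.positions[0] < 0
            or self.positions[-1] >= self.region_length_bp
        ):
            raise ValueError("positions must be strictly increasing within the region")

    @property
    def n_seq(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Frequency of the '1' allele at each site."""
        return self.alleles.mean(axis=0)

    def is_polymorphic(self) -> np.ndarray:
        counts = self.alleles.sum(axis=0)
        return (counts > 0) & (counts < self.n_seq)


@dataclass(frozen=True)
class CoalescentParams:
    """Parameters of the neutral coalescent-with-recombination generator.

    ``scaled_recomb_per_bp`` and ``scaled_mut_per_bp`` are the population-scaled
    rates 4·N_e·γ per bp and 4·N_e·µ per bp; defaults reproduce a 10 kb region
    with total θ = 5.6 and total ρ = 40 in a sample of 100 sequences.
    """

    effective_pop_size: float = 1e4
    scaled_recomb_per_bp: float = 4e-3
    scaled_mut_per_bp: float = 5.6e-4
    region_length_bp: int = 10_000
    n_seq: int = 100

    def __post_init__(self) -> None:
        if min(
            self.effective_pop_size,
            self.scaled_mut_per_bp,
            self.region_length_bp,
            self.n_seq,
        ) <= 0 or self.scaled_recomb_per_bp < 0:
            raise ValueError("coalescent parameters must be positive")


@dataclass(frozen=True)
class LDParams:
    """Parameters of the Markov-chain LD generator.

    All loci share one minor allele frequency; each adjacent pair of loci has
    haplotype correlation r = sqrt(target_r2) > 0, i.e. population r² equal to
    ``target_r2``.
    """

    n_snps: int = 10
    target_r2: float = 0.0
    maf: float = 0.3

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not 0.0 <= self.target_r2 <= 1.0:
            raise ValueError("target_r2 must lie in [0, 1]")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")
        # With equal allele frequencies at both loci the haplotype table is
        # feasible for any r in [0, 1]: D = r·p(1−p) ≤ p(1−p).  The check is
        # kept explicit so unequal-frequency extensions fail loudly.
        d = np.sqrt(self.target_r2) * self.maf * (1 - self.maf)
        if d > self.maf * (1 - self.maf) + 1e-12:
            raise ValueError(
                "target_r2 infeasible: requires D <= p(1-p) "
                f"(= {self.maf * (1 - self.maf):.4f})"
            )


@dataclass
class GenotypeMatrix:
    """Unphased dosage matrix: individuals × SNPs, entries 0/1/2."""

    dosages: np.ndarray
    snp_ids: list[str] = field(default_factory=list)
    gene_id: str | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2 or self.dosages.shape[1] < 1:
            raise ValueError("dosages must be 2-D with at least one SNP column")
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosages must be 0, 1, or 2")
        if not self.snp_ids:
            self.snp_ids = [f"snp{j + 1}" for j in range(self.dosages.shape[1])]
        if len(self.snp_ids) != self.dosages.shape[1]:
            raise ValueError("one snp_id per column required")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def minor_allele_frequencies(self) -> np.ndarray:
        freq = self.dosages.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)


def simulate_coalescent_panel(
    params: CoalescentParams, seed: int, min_sites: int = 10
) -> HaplotypePanel:
    """Simulate a haplotype panel under the neutral coalescent with recombination.

    Runs an ancestry simulation for ``params.n_seq`` haploid sequences at the
    stated population-scaled recombination rate, then drops infinite-sites
    binary mutations at the stated scaled mutation rate.  Sites monomorphic in
    the sample are removed.

    Raises
    ------
    InsufficientPolymorphismError
        If fewer than ``min_sites`` segregating sites remain; the caller
        should retry with a fresh seed.
    """
    anc_seed, mut_seed = _seed_stream(seed, 2)
    ne = params.effective_pop_size
    # haploid lineages with pair-coalescence time 2·N_e generations, the
    # diploid scaling under which 4·N_e·µ and 4·N_e·γ are the standard
    # population-scaled rates
    ts = msprime.sim_ancestry(
        samples=params.n_seq,
        ploidy=1,
        population_size=2 * ne,
        sequence_length=params.region_length_bp,
        recombination_rate=params.scaled_recomb_per_bp / (4 * ne),
        discrete_genome=False,
        random_seed=int(anc_seed),
    )
    mts = msprime.sim_mutations(
        ts,
        rate=params.scaled_mut_per_bp / (4 * ne),
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=int(mut_seed),
    )
    geno = mts.genotype_matrix().T  # n_seq × n_sites
    positions = mts.sites_position
    counts = geno.sum(axis=0)
    keep = (counts > 0) & (counts < params.n_seq)
    geno, positions = geno[:, keep], positions[keep]
    if geno.shape[1] < min_sites:
        raise InsufficientPolymorphismError(
            f"only {geno.shape[1]} segregating sites; resimulate with a new seed"
        )
    return HaplotypePanel(geno, positions, params.region_length_bp)


def select_gene_window(panel: HaplotypePanel, n_snps: int, seed: int) -> HaplotypePanel:
    """Restrict a panel to ``n_snps`` adjacent segregating sites.

    The window start is uniform over all valid starts.  Raises
    :class:`InsufficientPolymorphismError` if the panel is too short.
    """
    if panel.n_sites < n_snps:
        raise InsufficientPolymorphismError(
            f"panel has {panel.n_sites} sites < requested window of {n_snps}; resimulate"
        )
    rng = np.random.default_rng(seed)
    start = int(rng.integers(0, panel.n_sites - n_snps + 1))
    return HaplotypePanel(
        panel.alleles[:, start : start + n_snps],
        panel.positions[start : start + n_snps],
        panel.region_length_bp,
    )


def pair_haplotypes(
    panel: HaplotypePanel, n_individuals: int, seed: int
) -> GenotypeMatrix:
    """Form diploid genotypes by summing two haplotypes drawn uniformly with
    replacement from the panel (the panel acts as the population)."""
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    if panel.n_seq == 0 or panel.n_sites == 0:
        raise ValueError("panel is empty")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, panel.n_seq, size=(n_individuals, 2))
    dosages = panel.alleles[idx[:, 0]] + panel.alleles[idx[:, 1]]
    return GenotypeMatrix(dosages)


def simulate_ld_panel(params: LDParams, n_seq: int, seed: int) -> HaplotypePanel:
    """Simulate haplotypes from a first-order Markov chain over loci.

    The allele at locus 1 is Bernoulli(maf); each subsequent allele is drawn
    from the two-locus haplotype table with D = r·p(1−p), r = sqrt(target_r2),
    so every adjacent pair has population r² equal to ``target_r2`` and every
    locus has allele frequency ``maf``.  Non-adjacent pairs have r² equal to
    target_r2 raised to the lag, a property of the chain.
    """
    if n_seq <= 0:
        raise ValueError("n_seq must be positive")
    p = params.maf
    r = float(np.sqrt(params.target_r2))
    d = r * p * (1 - p)
    # conditional P(allele=1 | previous allele)
    p1_given_1 = (p * p + d) / p
    p1_given_0 = (p * (1 - p) - d) / (1 - p)
    for seed_k in _seed_stream(seed, 100):
        rng = np.random.default_rng(int(seed_k))
        hap = np.empty((n_seq, params.n_snps), dtype=np.int8)
        hap[:, 0] = rng.random(n_seq) < p
        for j in range(1, params.n_snps):
            cond = np.where(hap[:, j - 1] == 1, p1_given_1, p1_given_0)
            hap[:, j] = rng.random(n_seq) < cond
        counts = hap.sum(axis=0)
        if np.all((counts > 0) & (counts < n_seq)):
            break
    else:  # pragma: no cover - probability ~ (1-p)^(100·n_seq)
        raise InsufficientPolymorphismError(
            "could not obtain a fully polymorphic LD panel"
        )
    positions = 500.0 + 1000.0 * np.arange(params.n_snps)
    return HaplotypePanel(hap, positions, 1000 * params.n_snps)


def simulate_gene_window(
    params: CoalescentParams, n_snps: int, seed: int, max_tries: int = 50
) -> HaplotypePanel:
    """Convenience: coalescent panel restricted to an ``n_snps`` window,
    retrying with derived seeds if a simulation yields too few sites."""
    for sub in _seed_stream(seed, max_tries):
        try:
            panel = simulate_coalescent_panel(params, int(sub))
            if panel.n_sites >= n_snps:
                return select_gene_window(panel, n_snps, int(sub) + 1)
        except InsufficientPolymorphismError:
            continue
    raise InsufficientPolymorphismError(
        f"no panel with >= {n_snps} segregating sites in {max_tries} tries"
    )


class PanelGenotypeSource:
    """Genotype source that pairs haplotypes from a fixed panel on demand.

    Satisfies the ``draw(n, rng) -> dosage array`` protocol used by the
    phenotype simulator.
    """

    def __init__(self, panel: HaplotypePanel):
        self.panel = panel

    @property
    def n_snps(self) -> int:
        return self.panel.n_sites

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        idx = rng.integers(0, self.panel.n_seq, size=(n, 2))
        return (self.panel.alleles[idx[:, 0]] + self.panel.alleles[idx[:, 1]]).astype(
            np.int8
        )
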