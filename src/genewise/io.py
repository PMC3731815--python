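"""File formats and the gene-scan entry point.

Readers and writers for the plain-text formats the toolkit exchanges:

* delimited genotype matrix — one row per individual, one column per SNP,
  header row of SNP ids, entries 0/1/2 (configurable missing sentinel);
* phenotype table — ``id<TAB>status`` with status 0 (control) / 1 (case);
* SNP-to-gene map — ``snp_id<TAB>gene_id``;
* VCF (read: biallelic GT → dosage; write: minimal VCF 4.2);
* PLINK-style text .ped/.map.

:func:`scan_genes` applies the candidate-gene analysis rules: drop SNPs with
minor allele frequency below a floor (computed on the pooled sample), drop
genes left with too few SNPs, then run the three gene tests per gene at a
fixed per-gene nominal level (divided by the SNP count for the single-SNP
method).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gentests import (
    GeneTestResult,
    entropy_gene_test,
    maxT_test,
    score_components,
    single_snp_gene_test,
)
from .simgeno import GenotypeMatrix, HaplotypePanel
from .simpheno import CaseControlSample, PhenotypeVector

__all__ = [
    "GeneMap",
    "ScanConfig",
    "GenotypeParseError",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_phenotype",
    "write_phenotype",
    "read_gene_map",
    "write_gene_map",
    "read_vcf",
    "write_vcf",
    "read_plink",
    "write_plink",
    "read_case_control",
    "scan_genes",
    "results_to_frame",
]

log = logging.getLogger(__name__)


class GenotypeParseError(ValueError):
    """Malformed genotype input; the message carries line and column."""


# ---------------------------------------------------------------------------
# delimited text
# ---------------------------------------------------------------------------


def write_genotype_matrix(
    genotypes: GenotypeMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write a dosage matrix as delimited text with a SNP-id header row."""
    with open(path, "w") as fh:
        fh.write(delimiter.join(genotypes.snp_ids) + "\n")
        np.savetxt(fh, genotypes.dosages, fmt="%d", delimiter=delimiter)


def read_genotype_matrix(
    path: str | Path,
    delimiter: str = "\t",
    missing: str = "NA",
    impute: str = "mode",
) -> GenotypeMatrix:
    """Read a delimited dosage matrix (header row of SNP ids, entries 0/1/2).

    Missing entries (``missing`` sentinel) are imputed to the per-SNP mode by
    default, or the individual is dropped with ``impute='drop'``.  Any other
    entry raises :class:`GenotypeParseError` naming the line and column.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delimiter)
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split(delimiter)
            if len(fields) != len(header):
                raise GenotypeParseError(
                    f"line {lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            row = []
            for col, tok in enumerate(fields, start=1):
                if tok == missing:
                    row.append(-1)
                elif tok in ("0", "1", "2"):
                    row.append(int(tok))
                else:
                    raise GenotypeParseError(
                        f"line {lineno}, column {col}: invalid genotype {tok!r}"
                    )
            rows.append(row)
    dosages = np.array(rows, dtype=np.int8)
    dosages = _handle_missing(dosages, impute)
    return GenotypeMatrix(dosages, snp_ids=header)


def _handle_missing(dosages: np.ndarray, impute: str) -> np.ndarray:
    mask = dosages == -1
    if not mask.any():
        return dosages
    if impute == "drop":
        return dosages[~mask.any(axis=1)]
    if impute == "mode":
        for j in np.flatnonzero(mask.any(axis=0)):
            obs = dosages[~mask[:, j], j]
            fill = np.bincount(obs, minlength=3).argmax() if len(obs) else 0
            dosages[mask[:, j], j] = fill
        return dosages
    raise ValueError(f"unknown missing-genotype policy {impute!r}")


def write_phenotype(phenotype: PhenotypeVector, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tphenotype\n")
        for i, y in enumerate(phenotype.labels, start=1):
            fh.write(f"ind{i}\t{int(y)}\n")


def read_phenotype(path: str | Path) -> PhenotypeVector:
    df = pd.read_csv(path, sep="\t")
    vals = df.iloc[:, -1].to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("phenotype must be binary 0/1")
    return PhenotypeVector(vals.astype(np.int8))


# ---------------------------------------------------------------------------
# gene map
# ---------------------------------------------------------------------------


@dataclass
class GeneMap:
    """SNP → gene assignment preserving per-gene SNP order."""

    snp_to_gene: dict[str, str] = field(default_factory=dict)
    genes: dict[str, list[str]] = field(default_factory=dict)

    def add(self, snp_id: str, gene_id: str) -> None:
        if snp_id in self.snp_to_gene:
            raise ValueError(f"SNP {snp_id} maps to more than one gene")
        self.snp_to_gene[snp_id] = gene_id
        self.genes.setdefault(gene_id, []).append(snp_id)


def read_gene_map(path: str | Path) -> GeneMap:
    gm = GeneMap()
    df = pd.read_csv(path, sep="\t", header=None, names=["snp_id", "gene_id"],
                     comment="#", dtype=str)
    for snp, gene in zip(df.snp_id, df.gene_id):
        gm.add(snp, gene)
    return gm


def write_gene_map(gene_map: GeneMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for snp, gene in gene_map.snp_to_gene.items():
            fh.write(f"{snp}\t{gene}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path, impute: str = "mode") -> GenotypeMatrix:
    """Read biallelic sites of a VCF into a dosage matrix (ALT-allele count).

    Multi-allelic records are skipped with a warning; missing genotypes are
    handled per ``impute`` as in :func:`read_genotype_matrix`.
    """
    import pysam

    ids: list[str] = []
    cols: list[np.ndarray] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                log.warning("skipping non-biallelic record %s:%s", rec.chrom, rec.pos)
                continue
            col = np.empty(len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    col[i] = -1
                else:
                    col[i] = sum(gt)
            ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            cols.append(col)
    if not cols:
        raise ValueError("no biallelic sites in VCF")
    dosages = _handle_missing(np.column_stack(cols), impute)
    return GenotypeMatrix(dosages, snp_ids=ids)


def write_vcf(
    obj: GenotypeMatrix | HaplotypePanel, path: str | Path, chrom: str = "1"
) -> None:
    """Write a panel (phased GT) or genotype matrix (unphased GT) as VCF 4.2."""
    phased = isinstance(obj, HaplotypePanel)
    if phased:
        n_hap = obj.n_seq
        if n_hap % 2:
            raise ValueError("panel must have an even number of haplotypes for VCF")
        n_samples, m = n_hap // 2, obj.n_sites
        positions = [int(p) for p in obj.positions]
        ids = [f"site{j + 1}" for j in range(m)]
    else:
        n_samples, m = obj.n_individuals, obj.n_snps
        positions = list(range(1, m + 1))
        ids = obj.snp_ids
    # enforce strictly increasing integer positions after rounding
    for j in range(1, m):
        if positions[j] <= positions[j - 1]:
            positions[j] = positions[j - 1] + 1
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        names = "\t".join(f"ind{i + 1}" for i in range(n_samples))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{names}\n")
        for j in range(m):
            if phased:
                a = obj.alleles[:, j]
                gts = "\t".join(f"{a[2 * i]}|{a[2 * i + 1]}" for i in range(n_samples))
            else:
                d = obj.dosages[:, j]
                gts = "\t".join(("0/0", "0/1", "1/1")[v] for v in d)
            fh.write(
                f"{chrom}\t{positions[j]}\t{ids[j]}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# PLINK-style text
# ---------------------------------------------------------------------------


def write_plink(sample: CaseControlSample, prefix: str | Path) -> None:
    """Write PLINK-style text .ped/.map (alleles A = reference, G = dosage)."""
    prefix = Path(prefix)
    geno, phen = sample.genotypes, sample.phenotype
    with open(prefix.with_suffix(".map"), "w") as fh:
        for j, snp in enumerate(geno.snp_ids, start=1):
            fh.write(f"1\t{snp}\t0\t{j}\n")
    code = {0: "A A", 1: "A G", 2: "G G"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i in range(geno.n_individuals):
            status = 2 if phen.labels[i] == 1 else 1
            alleles = "\t".join(code[int(v)] for v in geno.dosages[i])
            fh.write(f"fam{i + 1}\tind{i + 1}\t0\t0\t0\t{status}\t{alleles}\n")


def read_plink(prefix: str | Path) -> CaseControlSample:
    """Read PLINK-style text .ped/.map; the minor allele counts as dosage 1."""
    prefix = Path(prefix)
    snp_ids = [
        line.split()[1] for line in open(prefix.with_suffix(".map")) if line.strip()
    ]
    rows, labels = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * len(snp_ids):
                raise GenotypeParseError(
                    f"line {lineno}: expected {6 + 2 * len(snp_ids)} fields"
                )
            labels.append(1 if parts[5] == "2" else 0)
            pairs = parts[6:]
            rows.append([pairs[2 * j : 2 * j + 2] for j in range(len(snp_ids))])
    allele_rows = np.array(rows)  # n × m × 2
    dosages = np.zeros(allele_rows.shape[:2], dtype=np.int8)
    for j in range(allele_rows.shape[1]):
        col = allele_rows[:, j, :]
        alleles = np.unique(col)
        if len(alleles) > 2:
            raise GenotypeParseError(f"SNP {snp_ids[j]} has more than two alleles")
        counted = alleles[-1]  # count the lexicographically later allele
        dosages[:, j] = (col == counted).sum(axis=1)
        if dosages[:, j].mean() > 1:  # make it the minor allele
            dosages[:, j] = 2 - dosages[:, j]
    return CaseControlSample(
        GenotypeMatrix(dosages, snp_ids=snp_ids),
        PhenotypeVector(np.array(labels, dtype=np.int8)),
    )


def read_case_control(
    genotype_path: str | Path,
    phenotype_path: str | Path | None = None,
    **kwargs,
) -> CaseControlSample:
    """Load a case-control sample, dispatching on the genotype file suffix
    (.vcf → VCF, .ped → PLINK text, anything else → delimited matrix)."""
    p = Path(genotype_path)
    if p.suffix == ".ped":
        return read_plink(p.with_suffix(""))
    if p.suffix == ".vcf":
        geno = read_vcf(p, **kwargs)
    else:
        geno = read_genotype_matrix(p, **kwargs)
    if phenotype_path is None:
        raise ValueError("phenotype file required for this genotype format")
    phen = read_phenotype(phenotype_path)
    return CaseControlSample(geno, phen)


# ---------------------------------------------------------------------------
# gene scan
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScanConfig:
    """Analysis rules for a candidate-gene scan.

    ``gene_alpha`` is the per-gene nominal level for the gene-based tests;
    the single-SNP method uses ``gene_alpha`` divided by the gene's SNP count.
    """

    maf_min: float = 0.05
    gene_alpha: float = 0.005
    min_snps_per_gene: int = 2
    mc_draws: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must lie in [0, 0.5)")
        if not 0 < self.gene_alpha < 1:
            raise ValueError("gene_alpha must lie in (0, 1)")


def scan_genes(
    sample: CaseControlSample, gene_map: GeneMap, config: ScanConfig = ScanConfig()
) -> list[GeneTestResult]:
    """Run all three gene tests over every gene of a sample.

    SNPs with pooled minor allele frequency below ``config.maf_min`` are
    removed first; genes left with fewer than ``config.min_snps_per_gene``
    SNPs are skipped (logged).  Returns three results per retained gene.
    """
    geno = sample.genotypes
    maf = geno.minor_allele_frequencies()
    keep = {s for s, ok in zip(geno.snp_ids, maf >= config.maf_min) if ok}
    dropped = geno.n_snps - len(keep)
    if dropped:
        log.info("MAF filter removed %d of %d SNPs", dropped, geno.n_snps)
    col = {s: j for j, s in enumerate(geno.snp_ids)}
    results: list[GeneTestResult] = []
    rng = np.random.default_rng(config.seed)
    for gene_id, snps in gene_map.genes.items():
        use = [s for s in snps if s in keep and s in col]
        if len(use) < config.min_snps_per_gene:
            log.info("gene %s excluded: %d SNPs after filtering", gene_id, len(use))
            continue
        sub = CaseControlSample(
            GenotypeMatrix(geno.dosages[:, [col[s] for s in use]], snp_ids=use),
            sample.phenotype,
        )
        comp = score_components(sub)
        mt = maxT_test(
            sub, B=config.mc_draws, seed=int(rng.integers(2**31 - 1)), components=comp
        )
        results.append(
            GeneTestResult(
                gene_id, "maxT", mt.t_max, comp.df, mt.p_value,
                mt.p_value < config.gene_alpha, {"mc_draws": mt.mc_draws},
            )
        )
        results.append(entropy_gene_test(sub, gene_id=gene_id, alpha=config.gene_alpha))
        results.append(
            single_snp_gene_test(sub, alpha=config.gene_alpha, components=comp,
                                 gene_id=gene_id)
        )
    if not results:
        log.warning("no genes left after filtering")
    return results


def results_to_frame(results: list[GeneTestResult]) -> pd.DataFrame:
    """Tabulate gene test results (one row per gene × method)."""
    return pd.DataFrame(
        {
            "gene_id": r.gene_id,
            "method": r.method,
            "statistic": r.statistic,
            "df": r.df,
            "p_value": r.p_value,
            "significant": r.significant,
        }
        for r in results
    )
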