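"""Disease phenotype simulation on top of simulated genotypes.

Supports single-SNP penetrance models (additive / dominant / recessive,
parameterised by genotype relative risk, disease allele frequency and
prevalence) and two- or three-locus interaction odds models.  Case-control
samples of fixed size are assembled by rejection sampling: individuals are
drawn from a genotype source, disease status is Bernoulli with probability
determined by their genotype, and draws continue until both strata are full.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simgeno import GenotypeMatrix

__all__ = [
    "PenetranceModel",
    "OddsModel",
    "PhenotypeVector",
    "CaseControlSample",
    "DegenerateDiseaseModelError",
    "penetrances",
    "odds",
    "choose_causal_snp",
    "disease_probability",
    "sample_case_control",
]


class DegenerateDiseaseModelError(RuntimeError):
    """Raised when one stratum is (near-)unreachable under the disease model."""


@dataclass(frozen=True)
class PenetranceModel:
    """Single causal SNP penetrance model.

    ``grr`` is the genotype relative risk: λ₁ = f₁/f₀ for additive and
    dominant models, λ₂ = f₂/f₁ for the recessive model.  ``disease_allele_freq``
    is the risk (minor) allele frequency p and ``prevalence`` the population
    disease probability k under Hardy-Weinberg, which pins down the baseline
    penetrance f₀.
    """

    mode: str
    grr: float
    disease_allele_freq: float
    prevalence: float = 0.1
    causal_index: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("additive", "dominant", "recessive"):
            raise ValueError("mode must be additive, dominant or recessive")
        if self.grr < 1:
            raise ValueError("genotype relative risk must be >= 1")
        if not 0 < self.disease_allele_freq < 1:
            raise ValueError("disease allele frequency must lie in (0, 1)")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")


@dataclass(frozen=True)
class OddsModel:
    """Multi-locus interaction odds model.

    ``model_id`` selects the form of the odds of disease given the risk-allele
    counts G at the causal loci (γ = baseline, θ = genotypic effect):

    1. odds = γ(1+θ)^(ΣG)                — multiplicative across risk alleles
    2. odds = γ(1+θ)^(Σ G·1{G>0})        — same but only through carriers
    3. odds = γ(1+θ)^(1{all G > 0})      — pure joint-carrier interaction

    Disease probability is odds/(1+odds).
    """

    n_loci: int
    model_id: int
    baseline: float = 1.0
    effect: float = 0.0
    causal_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.n_loci not in (2, 3):
            raise ValueError("n_loci must be 2 or 3")
        if self.model_id not in (1, 2, 3):
            raise ValueError("model_id must be 1, 2 or 3")
        if self.baseline <= 0:
            raise ValueError("baseline odds must be positive")
        if self.effect <= -1:
            raise ValueError("effect must exceed -1")
        if self.causal_indices and len(self.causal_indices) != self.n_loci:
            raise ValueError("need one causal index per locus")


@dataclass
class PhenotypeVector:
    """Binary case/control labels (1 = case)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")

    @property
    def n_cases(self) -> int:
        return int(self.labels.sum())

    @property
    def n_controls(self) -> int:
        return int(len(self.labels) - self.labels.sum())


@dataclass
class CaseControlSample:
    """A genotype matrix with aligned case/control labels."""

    genotypes: GenotypeMatrix
    phenotype: PhenotypeVector

    def __post_init__(self) -> None:
        if self.genotypes.n_individuals != len(self.phenotype.labels):
            raise ValueError("genotype and phenotype row counts disagree")


def penetrances(model: PenetranceModel) -> tuple[float, float, float]:
    """Genotype penetrances (f₀, f₁, f₂) implied by the model.

    The baseline f₀ is chosen so that the Hardy-Weinberg population prevalence
    (1−p)²f₀ + 2p(1−p)f₁ + p²f₂ equals ``model.prevalence``:

    - additive:  f₁ = λf₀, f₂ = (2λ−1)f₀, f₀ = k/(1 − 2p + 2pλ)
    - dominant:  f₁ = f₂ = λf₀,           f₀ = k/((1−p)² + λp(2−p))
    - recessive: f₁ = f₀, f₂ = λf₀,       f₀ = k/(1 + p²λ² − p²)

    (In the recessive model λ = λ₂ and, with f₁ = f₀, f₂/f₀ enters squared
    through the prevalence constraint written in terms of λ₂².)
    """
    lam, p, k = model.grr, model.disease_allele_freq, model.prevalence
    if model.mode == "additive":
        f0 = k / (1 - 2 * p + 2 * p * lam)
        f = (f0, lam * f0, (2 * lam - 1) * f0)
    elif model.mode == "dominant":
        f0 = k / ((1 - p) ** 2 + lam * p * (2 - p))
        f = (f0, lam * f0, lam * f0)
    else:  # recessive
        f0 = k / (1 + p * p * lam * lam - p * p)
        f = (f0, f0, lam * lam * f0)
    if not all(0 < fi <= 1 for fi in f):
        raise ValueError(f"parameters imply invalid penetrances {f}")
    return f


def odds(model: OddsModel, genotypes_at_causal: np.ndarray) -> np.ndarray:
    """Odds of disease for each row of risk-allele counts at the causal loci.

    Accepts a single genotype vector of length ``n_loci`` or a matrix with one
    row per individual; returns a scalar array or a vector accordingly.
    """
    g = np.atleast_2d(np.asarray(genotypes_at_causal))
    if g.shape[1] != model.n_loci:
        raise ValueError(f"expected {model.n_loci} loci, got {g.shape[1]}")
    if model.model_id == 1:
        expo = g.sum(axis=1)
    elif model.model_id == 2:
        expo = (g * (g > 0)).sum(axis=1)
    else:
        expo = (g > 0).all(axis=1).astype(float)
    out = model.baseline * (1.0 + model.effect) ** expo
    return out[0] if np.asarray(genotypes_at_causal).ndim == 1 else out


def choose_causal_snp(
    dosage_or_freq: np.ndarray, target_maf: float = 0.3
) -> tuple[int, float]:
    """Pick the SNP whose minor allele frequency is closest to ``target_maf``.

    Accepts a dosage matrix (individuals × SNPs) or a vector of '1'-allele
    frequencies.  Returns ``(column index, minor allele frequency)``; the minor
    allele is treated as the risk allele and its realized frequency is the
    model's disease allele frequency p.
    """
    arr = np.asarray(dosage_or_freq, dtype=float)
    freq = arr.mean(axis=0) / 2.0 if arr.ndim == 2 else arr
    maf = np.minimum(freq, 1.0 - freq)
    j = int(np.argmin(np.abs(maf - target_maf)))
    return j, float(maf[j])


def _causal_columns(model: PenetranceModel | OddsModel) -> np.ndarray:
    if isinstance(model, PenetranceModel):
        return np.array([model.causal_index], dtype=int)
    return np.asarray(model.causal_indices, dtype=int)


def disease_probability(
    model: PenetranceModel | OddsModel,
    dosages: np.ndarray,
    risk_flip: np.ndarray | None = None,
) -> np.ndarray:
    """P(case | genotype) for each individual under either model family.

    Risk-allele counts are taken with respect to the minor allele at each
    causal column.  ``risk_flip`` marks causal columns at which the '1' allele
    is the major allele (so risk dosage = 2 − dosage); when omitted it is
    derived from the supplied dosage matrix itself.  Callers generating data
    should fix it once from the source panel so the orientation does not
    wobble across batches.
    """
    cols = _causal_columns(model)
    if risk_flip is None:
        risk_flip = dosages[:, cols].mean(axis=0) / 2.0 > 0.5
    g = dosages[:, cols].astype(np.int8)
    g[:, risk_flip] = 2 - g[:, risk_flip]
    if isinstance(model, PenetranceModel):
        f = np.asarray(penetrances(model))
        return f[g[:, 0]]
    o = np.asarray(odds(model, g), dtype=float)
    return o / (1.0 + o)


def sample_case_control(
    genotype_source,
    disease_model: PenetranceModel | OddsModel | None,
    n_cases: int,
    n_controls: int,
    seed: int,
    batch: int = 4096,
    max_draws: int = 50_000_000,
) -> CaseControlSample:
    """Assemble a fixed-size case-control sample by rejection sampling.

    Individuals are drawn from ``genotype_source.draw(n, rng)``; disease
    status is Bernoulli with probability given by ``disease_model`` (or the
    label is irrelevant under the null, ``disease_model=None``, in which case
    the first ``n_cases`` draws are labelled cases).  Draws are accepted into
    whichever stratum still has room until both are full.
    """
    if n_cases < 1 or n_controls < 1:
        raise ValueError("need at least one case and one control")
    rng = np.random.default_rng(seed)
    if disease_model is None:
        dosages = genotype_source.draw(n_cases + n_controls, rng)
        labels = np.r_[np.ones(n_cases, np.int8), np.zeros(n_controls, np.int8)]
        return CaseControlSample(GenotypeMatrix(dosages), PhenotypeVector(labels))

    cols = _causal_columns(disease_model)
    if hasattr(genotype_source, "panel"):
        risk_flip = genotype_source.panel.allele_frequencies()[cols] > 0.5
    else:  # orient from a one-off calibration draw
        risk_flip = (
            genotype_source.draw(2048, np.random.default_rng(rng.integers(2**31)))[
                :, cols
            ].mean(axis=0)
            / 2.0
            > 0.5
        )

    case_rows: list[np.ndarray] = []
    ctrl_rows: list[np.ndarray] = []
    got_cases = got_ctrls = drawn = 0
    while got_cases < n_cases or got_ctrls < n_controls:
        if drawn > max_draws:
            raise DegenerateDiseaseModelError(
                "acceptance probability too low; disease model is degenerate"
            )
        g = genotype_source.draw(batch, rng)
        drawn += batch
        prob = disease_probability(disease_model, g, risk_flip)
        if drawn >= 2 * batch:
            # early degeneracy check: one stratum essentially unreachable
            mean_p = prob.mean()
            if (got_cases == 0 and mean_p < 1e-6) or (
                got_ctrls == 0 and 1 - mean_p < 1e-6
            ):
                raise DegenerateDiseaseModelError(
                    "acceptance probability below 1e-6; disease model is degenerate"
                )
        is_case = rng.random(batch) < prob
        if got_cases < n_cases:
            take = g[is_case][: n_cases - got_cases]
            case_rows.append(take)
            got_cases += len(take)
        if got_ctrls < n_controls:
            take = g[~is_case][: n_controls - got_ctrls]
            ctrl_rows.append(take)
            got_ctrls += len(take)
    dosages = np.vstack([np.vstack(case_rows), np.vstack(ctrl_rows)])
    labels = np.r_[np.ones(n_cases, np.int8), np.zeros(n_controls, np.int8)]
    return CaseControlSample(GenotypeMatrix(dosages), PhenotypeVector(labels))
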