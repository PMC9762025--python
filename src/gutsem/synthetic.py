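"""Parameter-known synthetic populations for end-to-end testing.

Emulates the study design the analysis assumes: ~400 growing rabbits in
~195 litters and ~189 cages over 5 batch-farm levels and 2 weaning
weight classes; genotypes at biallelic SNPs in Hardy-Weinberg
proportions inducing a dense genomic relationship matrix; one microbial
abundance trait on a CSS-like continuous scale; and the missing-by-
design phenotype pattern (each animal records ADG under exactly one
feeding regime). Traits are built in the model's generative direction:
the microbial trait first, then each ADG trait as fixed effects +
lambda * M + litter + cage + genomic + residual.

The default truth mirrors the study's scale: ADG SDs around 5-6 g/day,
microbial-abundance heritability in the 0.1-0.25 range, structural
coefficients of order 1 g/day per CSS-normalized unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeMatrix, compute_grm
from .sem_core import CovarianceSet, SemDataset, StructuralCoefficients

__all__ = [
    "IdentityGrm",
    "SimulationTruth",
    "default_truth",
    "simulate_population",
    "score_recovery",
]


class IdentityGrm:
    """Identity relationship matrix for populations of unrelated animals.

    Never materializes the n x n matrix unless ``values`` is accessed,
    which keeps very large simulated populations cheap; ``shape`` is
    enough for dataset validation.
    """

    def __init__(self, animal_ids: list[str]):
        self.animal_ids = list(animal_ids)
        self.blend_weight = 0.0

    @property
    def shape(self) -> tuple[int, int]:
        n = len(self.animal_ids)
        return (n, n)

    @property
    def values(self) -> np.ndarray:
        return np.eye(len(self.animal_ids))

    def subset(self, animal_ids: list[str]) -> "IdentityGrm":
        return IdentityGrm(animal_ids)


@dataclass
class SimulationTruth:
    """Everything the generator drew, for recovery scoring."""

    lam: StructuralCoefficients
    covariances: CovarianceSet
    b: np.ndarray  # (p, 3) fixed-effect values (intercept, batches, ww)
    effects_l: np.ndarray
    effects_c: np.ndarray
    effects_u: np.ndarray
    phenotypes: np.ndarray  # (n, 3) complete, pre-masking
    regime: np.ndarray  # "AL"/"R" per animal
    seed: int
    metadata: dict = field(default_factory=dict)


def default_truth(
    lambda_al: float = -1.3,
    lambda_r: float = 1.4,
) -> tuple[StructuralCoefficients, CovarianceSet]:
    """Study-scale truth preset.

    Direct (structural) variance components chosen so the phenotypic SDs
    land near 5.9 (AL) and 5.3 (R) g/day and near 1 CSS unit for M, with
    ADG heritabilities ~0.2 and microbial heritability ~0.15.
    """
    l0 = np.array([[5.0, 1.5, 0.05], [1.5, 4.0, 0.05], [0.05, 0.05, 0.12]])
    c0 = np.array([[3.5, 1.0, 0.03], [1.0, 2.8, 0.03], [0.03, 0.03, 0.10]])
    g0 = np.array([[7.0, 2.5, 0.10], [2.5, 5.5, 0.10], [0.10, 0.10, 0.15]])
    r0 = np.array([19.5, 15.5, 0.63])
    return StructuralCoefficients(lambda_al, lambda_r), CovarianceSet(l0, c0, g0, r0)


def simulate_population(
    n_animals: int = 400,
    n_litters: int = 195,
    n_cages: int = 189,
    n_batches: int = 5,
    n_snps: int = 1000,
    truth: tuple[StructuralCoefficients, CovarianceSet] | None = None,
    fixed_effects: np.ndarray | None = None,
    seed: int = 0,
    grm: str = "genotypes",
) -> tuple[SemDataset, GenotypeMatrix | None, SimulationTruth]:
    """Simulate a complete dataset plus the truth that generated it.

    Genotypes are Binomial(2, p_s) with p_s ~ Uniform(0.05, 0.5) per SNP
    and the GRM is built from them (``grm="identity"`` skips genotypes
    and uses unrelated genetic effects, which keeps very large
    populations cheap). Litter and cage assignment interleaves litters
    across cages so no cage holds more than two litter-mates. Feeding
    regime is assigned 50/50 at random and the unobserved ADG record is
    masked. The same seed reproduces the dataset byte for byte.
    """
    if n_litters > n_animals or n_cages > n_animals:
        raise ValueError("cannot have more litters or cages than animals")
    rng = np.random.default_rng(seed)
    lam, cov = truth if truth is not None else default_truth()
    lam_m = lam.matrix()

    batch = np.arange(n_animals) % n_batches
    ww = rng.integers(0, 2, size=n_animals)
    litter = np.arange(n_animals) % n_litters
    cage = np.arange(n_animals) % n_cages

    # fixed effects: intercept + batch contrasts + ww contrast, per trait
    p = 1 + (n_batches - 1) + 1
    if fixed_effects is None:
        b = np.zeros((p, 3))
        b[0] = [55.0, 39.0, 1.0]  # intercepts near the observed trait means
        b[1 : n_batches, 0] = rng.normal(0.0, 2.0, n_batches - 1)
        b[1 : n_batches, 1] = rng.normal(0.0, 2.0, n_batches - 1)
        b[1 : n_batches, 2] = rng.normal(0.0, 0.2, n_batches - 1)
        b[-1] = [2.0, 2.0, 0.1]  # large-vs-small weaning weight
    else:
        b = np.asarray(fixed_effects, dtype=float)
        if b.shape != (p, 3):
            raise ValueError(f"fixed_effects must have shape ({p}, 3)")

    genotypes = None
    if grm == "identity":
        g_chol = None
        grm_obj = IdentityGrm([f"A{i:05d}" for i in range(n_animals)])
    elif grm == "genotypes":
        freqs = rng.uniform(0.05, 0.5, size=n_snps)
        dosages = rng.binomial(2, freqs, size=(n_animals, n_snps)).astype(float)
        genotypes = GenotypeMatrix(
            animal_ids=[f"A{i:05d}" for i in range(n_animals)],
            snp_ids=[f"snp{j}" for j in range(n_snps)],
            dosages=dosages,
        )
        grm_obj = compute_grm(genotypes, blend_weight=0.01)
        g_chol = np.linalg.cholesky(grm_obj.values)
    else:
        raise ValueError(f"grm must be 'genotypes' or 'identity', got {grm!r}")

    chol_l0 = np.linalg.cholesky(cov.L0)
    chol_c0 = np.linalg.cholesky(cov.C0)
    chol_g0 = np.linalg.cholesky(cov.G0)

    eff_l = rng.standard_normal((n_litters, 3)) @ chol_l0.T
    eff_c = rng.standard_normal((n_cages, 3)) @ chol_c0.T
    z_u = rng.standard_normal((n_animals, 3))
    eff_u = (g_chol @ z_u if g_chol is not None else z_u) @ chol_g0.T
    resid = rng.standard_normal((n_animals, 3)) * np.sqrt(cov.R0_diag)

    x = np.column_stack(
        [np.ones(n_animals)]
        + [(batch == lvl).astype(float) for lvl in range(1, n_batches)]
        + [(ww == 1).astype(float)]
    )
    base = x @ b + eff_l[litter] + eff_c[cage] + eff_u + resid  # structural RHS
    # recursive construction: M first, then the downstream ADG traits
    y = np.empty((n_animals, 3))
    y[:, 2] = base[:, 2]
    y[:, 0] = base[:, 0] + lam_m[0, 2] * y[:, 2]
    y[:, 1] = base[:, 1] + lam_m[1, 2] * y[:, 2]

    regime = np.where(rng.random(n_animals) < 0.5, "AL", "R")
    y_al = np.where(regime == "AL", y[:, 0], np.nan)
    y_r = np.where(regime == "R", y[:, 1], np.nan)

    dataset = SemDataset(
        animal_ids=list(grm_obj.animal_ids),
        y_al=y_al,
        y_r=y_r,
        y_m=y[:, 2],
        batch_farm=batch,
        ww_class=ww,
        litter=litter,
        cage=cage,
        grm=grm_obj,
        otu_id="synthetic",
    )
    truth_out = SimulationTruth(
        lam=lam,
        covariances=cov,
        b=b,
        effects_l=eff_l,
        effects_c=eff_c,
        effects_u=eff_u,
        phenotypes=y,
        regime=regime,
        seed=seed,
        metadata={"n_snps": n_snps if grm == "genotypes" else 0, "grm": grm},
    )
    return dataset, genotypes, truth_out


def score_recovery(truth: SimulationTruth, samples) -> dict[str, dict[str, float]]:
    """Posterior mean, bias and HPD95% coverage for every true parameter."""
    from .decomposition import hpd_interval

    report: dict[str, dict[str, float]] = {}

    def _entry(name: str, draws: np.ndarray, true_value: float) -> None:
        low, high = hpd_interval(draws, 0.95)
        mean = float(draws.mean())
        report[name] = {
            "truth": float(true_value),
            "posterior_mean": mean,
            "bias": mean - float(true_value),
            "hpd_low": low,
            "hpd_high": high,
            "in_hpd": bool(low <= true_value <= high),
        }

    _entry("lambda_AL", samples.lambda_al, truth.lam.lambda_al)
    _entry("lambda_R", samples.lambda_r, truth.lam.lambda_r)
    labels = ("AL", "R", "M")
    for name, draws, true_mat in (
        ("L0", samples.L0, truth.covariances.L0),
        ("C0", samples.C0, truth.covariances.C0),
        ("G0", samples.G0, truth.covariances.G0),
    ):
        for i in range(3):
            for j in range(i, 3):
                _entry(f"{name}_{labels[i]}_{labels[j]}", draws[:, i, j], true_mat[i, j])
    for i, lab in enumerate(labels):
        _entry(f"R0_{lab}", samples.R0[:, i], truth.covariances.R0_diag[i])
    return report
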