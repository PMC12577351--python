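"""Synthetic genotype / microbiome / phenotype generator with known truth.

Emulates the study design the pipeline targets: ~700 beef cattle in 16
management groups nested within 4 diets of 2 diet types (concentrate
vs. forage, proxied by sex), SNP dosages under HWE with MAF >= 0.05,
ORF log10 relative abundances with a weak host-genetic component (per-
ORF heritabilities Beta-distributed with mean 0.07 and median ~0.04)
plus a strong diet-type compositional shift, and phenotypes composed of
fixed effects, genomic, metagenomic, optional interaction and residual
components with configurable variance fractions.

Every random draw flows from ``SimConfig.seed``; the generator returns
a :class:`TruthRecord` holding all latent components so downstream
estimation can be tested against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kernels as kmod
from .design import annihilator, build_design

__all__ = [
    "SimConfig",
    "TruthRecord",
    "SimulatedStudy",
    "simulate_genotypes",
    "simulate_microbiome",
    "simulate_phenotypes",
    "simulate_design",
    "simulate_dataset",
]

#: Beta shape for per-ORF heritability at mean 0.07: b = a (1-mu)/mu with
#: a chosen so the median is 0.04 (right-skewed, most mass near zero).
_ORF_H2_BETA_A = 0.605

#: SD of the latent log10-abundance noise around each ORF's baseline.
_LATENT_SD = 0.5

N_BREEDS = 18


@dataclass
class SimConfig:
    """Generator settings; defaults emulate the study conditions."""

    n_animals: int = 704
    n_snps: int = 2000
    n_orfs: int = 1000
    n_diets: int = 4
    n_diet_types: int = 2
    n_management_groups: int = 16
    maf_range: tuple[float, float] = (0.05, 0.5)
    target_h2: float = 0.30
    target_m2: float = 0.20
    target_i2: float = 0.0
    orf_h2_mean: float = 0.07
    diet_shift_sd: float = 0.5
    diet_shift_frac: float = 0.5
    library_size_mean: float = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in ("n_animals", "n_snps", "n_orfs", "n_diets", "n_diet_types",
                     "n_management_groups"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_diets % self.n_diet_types:
            raise ValueError("n_diets must be divisible by n_diet_types")
        if self.n_management_groups % self.n_diets:
            raise ValueError("n_management_groups must be divisible by n_diets")
        fracs = (self.target_h2, self.target_m2, self.target_i2)
        if any(f < 0 for f in fracs) or sum(fracs) >= 1.0:
            raise ValueError("target fractions must be >= 0 and sum to < 1")
        if not 0.0 <= self.orf_h2_mean < 1.0:
            raise ValueError("orf_h2_mean must lie in [0, 1)")


@dataclass
class TruthRecord:
    """Ground-truth latent quantities for parameter-recovery tests."""

    true_u: np.ndarray
    true_m: np.ndarray
    true_o: np.ndarray
    true_e: np.ndarray
    fixed_part: np.ndarray
    realized_fractions: dict[str, float]
    orf_h2: np.ndarray
    shifted_orfs: np.ndarray
    diet: np.ndarray = field(default=None)
    diet_type: np.ndarray = field(default=None)


@dataclass
class SimulatedStudy:
    """Bundle of simulated inputs plus the truth record."""

    genotypes: pd.DataFrame
    orf_counts: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: TruthRecord
    config: SimConfig


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_genotypes(n: int, s: int, maf_range=(0.05, 0.5), seed: int = 0) -> pd.DataFrame:
    """SNP dosages in {0,1,2}: per-locus Binomial(2, p) under HWE.

    Allele frequencies are drawn uniformly from ``maf_range``.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    if n < 1 or s < 1:
        raise ValueError("n and s must be positive")
    rng = _rng(seed)
    p = rng.uniform(lo, hi, size=s)
    Q = rng.binomial(2, p, size=(n, s))
    ids = [f"A{i:04d}" for i in range(n)]
    snps = [f"snp{j:05d}" for j in range(s)]
    return pd.DataFrame(Q, index=ids, columns=snps)


def simulate_design(config: SimConfig, seed) -> pd.DataFrame:
    """Animal-level design: diet type (sex proxy), diet, management group,
    breed fractions (Dirichlet over 18 breeds) and expected heterozygosity."""
    rng = _rng(seed)
    n = config.n_animals
    ids = [f"A{i:04d}" for i in range(n)]
    # animals dealt evenly across management groups; group structure is
    # nested: diet types > diets > management groups
    mg = np.arange(n) % config.n_management_groups
    groups_per_diet = config.n_management_groups // config.n_diets
    diet = mg // groups_per_diet
    diets_per_type = config.n_diets // config.n_diet_types
    diet_type = diet // diets_per_type
    sex = np.where(diet_type == 0, "steer", "heifer")
    breed = rng.dirichlet(np.full(N_BREEDS, 0.5), size=n)
    het = rng.uniform(0.25, 0.40, size=n)
    out = pd.DataFrame(
        {
            "management_group": [f"MG{g:02d}" for g in mg],
            "diet": [f"D{d}" for d in diet],
            "diet_type": np.where(diet_type == 0, "concentrate", "forage"),
            "sex": sex,
            "heterozygosity": het,
        },
        index=ids,
    )
    for b in range(N_BREEDS):
        out[f"breed{b:02d}"] = breed[:, b]
    return out


def simulate_microbiome(
    genetic_scores: np.ndarray,
    config: SimConfig,
    diet_type: np.ndarray,
    seed,
) -> tuple[pd.DataFrame, dict]:
    """ORF read counts with diet-type and host-genetic structure.

    ``genetic_scores`` is an n x m matrix of standardized per-animal
    genetic values for each ORF (correlated across animals according to
    the realized GRM).  The latent log10 abundance of ORF j is

        baseline_j + diet shift (shifted subset only)
        + sqrt(h2_j) * sd * g_ij + sqrt(1 - h2_j) * sd * eps_ij,

    with h2_j ~ Beta(a, b) matched to ``orf_h2_mean`` (median ~0.04 at
    the default mean 0.07).  Counts are multinomial per animal with
    log-normal library sizes, so row sums equal the drawn library sizes.
    """
    rng = _rng(seed)
    n, m = genetic_scores.shape
    if m != config.n_orfs:
        raise ValueError("genetic_scores ORF dimension mismatch")
    a = _ORF_H2_BETA_A
    mu = config.orf_h2_mean
    if mu == 0:
        h2 = np.zeros(m)
    else:
        b = a * (1.0 - mu) / mu
        h2 = rng.beta(a, b, size=m)
    if ((h2 < 0) | (h2 >= 1)).any():
        raise ValueError("per-ORF h2 outside [0, 1)")

    baseline = rng.normal(0.0, 1.0, size=m)
    n_shift = int(round(config.diet_shift_frac * m))
    shifted = np.zeros(m, dtype=bool)
    shifted[rng.choice(m, size=n_shift, replace=False)] = True
    shift_sign = rng.choice([-1.0, 1.0], size=m)
    type_codes = pd.factorize(np.asarray(diet_type))[0]
    shift = np.where(shifted, shift_sign * config.diet_shift_sd, 0.0)

    eps = rng.normal(0.0, 1.0, size=(n, m))
    latent = (
        baseline
        + np.where(type_codes[:, None] == 1, shift, 0.0)
        + _LATENT_SD * (np.sqrt(h2) * genetic_scores + np.sqrt(1.0 - h2) * eps)
    )
    probs = np.power(10.0, latent)
    probs /= probs.sum(axis=1, keepdims=True)

    lib = rng.lognormal(np.log(config.library_size_mean) - 0.08, 0.4, size=n)
    lib = np.maximum(lib.round().astype(np.int64), 1000)
    counts = np.empty((n, m), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(lib[i], probs[i])
    ids = [f"A{i:04d}" for i in range(n)]
    orfs = [f"orf{j:05d}" for j in range(m)]
    table = pd.DataFrame(counts, index=ids, columns=orfs)
    return table, {"orf_h2": h2, "shifted_orfs": shifted, "library_sizes": lib}


def simulate_phenotypes(
    genotypes: pd.DataFrame,
    log_abundances: pd.DataFrame,
    design: pd.DataFrame,
    config: SimConfig,
    seed,
) -> tuple[pd.Series, TruthRecord]:
    """Phenotypes y = X beta + u + m + o + e with known components.

    u ~ N(0, G s2_u) with G the realized GRM of the simulated
    genotypes; m is a random weighted sum of centered log-abundance
    columns (exactly the method-1 MRM covariance); o ~ N(0, (G o M) s2_o);
    e iid normal.  Component scales are set so the *expected* variance
    fractions equal the targets (using the mean kernel diagonal), with
    total expected phenotypic variance 1.

    The metagenomic and interaction components are projected onto the
    orthogonal complement of the fixed-effect design before scaling:
    the diet-type compositional shift in S is collinear with the
    management-group effects (groups are nested in diets), so without
    the projection part of the targeted microbiability would be
    absorbed by the fixed effects and no estimator could see it.  In
    the error-contrast space used by REML the projected component still
    has exactly the method-1 MRM covariance.
    """
    if not (len(genotypes) == len(log_abundances) == len(design)):
        raise ValueError("inputs cover different numbers of animals")
    rng = _rng(seed)
    n = len(design)

    G = kmod.build_grm(genotypes).values
    S = log_abundances.to_numpy(dtype=float)
    centered = S - S.mean(axis=0)
    col_var = S.var(axis=0, ddof=1)
    sum_var = col_var.sum()
    M = centered @ centered.T / sum_var
    Xproj = annihilator(build_design(design).to_numpy(dtype=float))

    s2_u = config.target_h2 / max(np.mean(np.diag(G)), 1e-12)
    s2_e = 1.0 - config.target_h2 - config.target_m2 - config.target_i2

    u = _draw_mvn(rng, G, s2_u) if config.target_h2 > 0 else np.zeros(n)
    if config.target_m2 > 0:
        # m = (S - N) w with iid normal w has covariance prop. to M1 exactly;
        # project off the fixed-effect span, then scale to the target
        m = Xproj @ (centered @ rng.normal(0.0, 1.0, size=S.shape[1]))
        mean_diag = np.trace(Xproj @ (M @ Xproj)) / n * sum_var
        m *= np.sqrt(config.target_m2 / max(mean_diag, 1e-12))
    else:
        m = np.zeros(n)
    if config.target_i2 > 0:
        J = G * M
        o = Xproj @ _draw_mvn(rng, J, 1.0)
        mean_diag = np.trace(Xproj @ (J @ Xproj)) / n
        o *= np.sqrt(config.target_i2 / max(mean_diag, 1e-12))
    else:
        o = np.zeros(n)
    e = rng.normal(0.0, np.sqrt(s2_e), size=n)

    # fixed part: wide management-group effects, breed and heterozygosity slopes
    mg_codes, mg_levels = pd.factorize(design["management_group"])
    mg_eff = rng.normal(0.0, 1.0, size=len(mg_levels))
    breed_cols = [c for c in design.columns if c.startswith("breed")]
    breed_beta = rng.normal(0.0, 0.3, size=len(breed_cols))
    het_beta = rng.normal(0.0, 0.5)
    fixed = (
        mg_eff[mg_codes]
        + design[breed_cols].to_numpy() @ breed_beta
        + het_beta * design["heterozygosity"].to_numpy()
    )

    y = fixed + u + m + o + e
    genetic_total = u + m + o
    var_y = np.var(y - fixed, ddof=1)
    realized = {
        "h2": float(np.var(u, ddof=1) / var_y),
        "m2": float(np.var(m, ddof=1) / var_y),
        "i2": float(np.var(o, ddof=1) / var_y),
    }
    truth = TruthRecord(
        true_u=u,
        true_m=m,
        true_o=o,
        true_e=e,
        fixed_part=fixed,
        realized_fractions=realized,
        orf_h2=np.array([]),
        shifted_orfs=np.array([]),
        diet=design["diet"].to_numpy(),
        diet_type=design["diet_type"].to_numpy(),
    )
    return pd.Series(y, index=design.index, name="trait"), truth


def _draw_mvn(rng, K, s2) -> np.ndarray:
    n = K.shape[0]
    jitter = 1e-8 * max(np.trace(K) / n, 1.0)
    L = np.linalg.cholesky(K + jitter * np.eye(n))
    return np.sqrt(s2) * (L @ rng.standard_normal(n))


def simulate_dataset(config: SimConfig, trait_names=("ADDMI", "ADG")) -> SimulatedStudy:
    """Run the full generator: design, genotypes, microbiome, phenotypes.

    The master seed fans out deterministically to each stage.  Each
    requested trait is drawn independently from the same genomic and
    metagenomic structure (its own effect vectors).
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.spawn(4 + len(trait_names))
    design = simulate_design(config, seeds[0])
    genotypes = simulate_genotypes(
        config.n_animals, config.n_snps, config.maf_range,
        seed=seeds[1],
    )
    # standardized per-animal genetic scores per ORF, correlated via the GRM
    G = kmod.build_grm(genotypes).values
    n = config.n_animals
    jitter = 1e-8 * max(np.trace(G) / n, 1.0)
    L = np.linalg.cholesky(G + jitter * np.eye(n))
    gscores = L @ _rng(seeds[2]).standard_normal((n, config.n_orfs))

    counts, micro_truth = simulate_microbiome(
        gscores, config, design["diet_type"].to_numpy(), seeds[3]
    )
    S = kmod.log_relative_abundance(counts)

    pheno = design.copy()
    truth = None
    for t, name in enumerate(trait_names):
        yvec, tr = simulate_phenotypes(genotypes, S, design, config, seeds[4 + t])
        pheno[name] = yvec
        if truth is None:
            truth = tr
    truth.orf_h2 = micro_truth["orf_h2"]
    truth.shifted_orfs = micro_truth["shifted_orfs"]
    return SimulatedStudy(
        genotypes=genotypes,
        orf_counts=counts,
        phenotypes=pheno,
        truth=truth,
        config=config,
    )
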