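"""Record and feature filters applied to the three tabular inputs.

Implements the study's quality-control rules: minor-allele-frequency
filtering and mean-dosage imputation of the genotype table, the
prevalence/abundance filter on the ORF count table, and within-group
3-standard-deviation outlier removal on the phenotypes.  A small
manifest records how much each step removed so the filtering is
auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "FilterManifest",
    "filter_maf",
    "impute_missing_genotypes",
    "filter_orfs",
    "filter_phenotype_outliers",
    "align_animals",
]

logger = logging.getLogger(__name__)


@dataclass
class FilterManifest:
    """Counts removed at each filtering step."""

    animals_removed: int = 0
    snps_removed: int = 0
    orfs_removed: int = 0
    removed_animal_ids: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "animals_removed": self.animals_removed,
            "snps_removed": self.snps_removed,
            "orfs_removed": self.orfs_removed,
            "removed_animal_ids": list(self.removed_animal_ids),
        }


@dataclass
class Dataset:
    """Aligned genotype, ORF-count and phenotype tables.

    All three tables are indexed by the same ordered animal list; the
    phenotype table also carries the diet, sex and management-group
    labels used as fixed effects and for fold construction.
    """

    genotypes: pd.DataFrame
    orf_counts: pd.DataFrame
    phenotypes: pd.DataFrame
    manifest: FilterManifest = field(default_factory=FilterManifest)

    def __post_init__(self) -> None:
        ids = list(self.phenotypes.index)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicated animal ids")
        for name, tab in (("genotypes", self.genotypes), ("orf_counts", self.orf_counts)):
            if list(tab.index) != ids:
                raise ValueError(f"{name} animal order differs from phenotypes")

    @property
    def animals(self) -> list:
        return list(self.phenotypes.index)


def align_animals(
    genotypes: pd.DataFrame, orf_counts: pd.DataFrame, phenotypes: pd.DataFrame
) -> Dataset:
    """Restrict all tables to the shared animals, in phenotype order."""
    common = phenotypes.index.intersection(genotypes.index).intersection(
        orf_counts.index
    )
    common = [a for a in phenotypes.index if a in set(common)]
    return Dataset(
        genotypes=genotypes.loc[common],
        orf_counts=orf_counts.loc[common],
        phenotypes=phenotypes.loc[common],
    )


def filter_maf(genotypes: pd.DataFrame, threshold: float = 0.05) -> pd.DataFrame:
    """Keep SNP columns with minor allele frequency strictly above ``threshold``.

    Allele frequency is computed from non-missing calls; column order is
    preserved.
    """
    Q = genotypes.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(Q, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = maf > threshold
    if not keep.any():
        raise ValueError(
            f"MAF filter at {threshold} removed all {Q.shape[1]} SNP columns"
        )
    return genotypes.loc[:, keep]


def impute_missing_genotypes(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Replace missing dosages by the column mean dosage 2*p_i."""
    Q = genotypes.to_numpy(dtype=float)
    missing = np.isnan(Q)
    if not missing.any():
        return genotypes
    fully_missing = missing.all(axis=0)
    if fully_missing.any():
        col = genotypes.columns[int(np.flatnonzero(fully_missing)[0])]
        raise ValueError(f"SNP column {col!r} is fully missing; cannot impute")
    col_mean = np.nanmean(Q, axis=0)
    Q = np.where(missing, col_mean, Q)
    return pd.DataFrame(Q, index=genotypes.index, columns=genotypes.columns)


def filter_orfs(
    counts: pd.DataFrame,
    min_prevalence: float = 0.10,
    min_abundance: float = 0.0001,
    logic: str = "and",
) -> pd.DataFrame:
    """Drop rare *and* lowly abundant ORFs.

    An ORF is removed iff its prevalence (fraction of samples with a
    nonzero count) is below ``min_prevalence`` AND its maximum
    within-sample relative abundance is below ``min_abundance`` — an ORF
    survives if either criterion is met.  ``logic="or"`` switches to the
    stricter reading where failing either criterion removes the ORF.
    """
    R = counts.to_numpy(dtype=float)
    if (R < 0).any():
        raise ValueError("negative read counts")
    totals = R.sum(axis=1)
    if (totals == 0).any():
        sample = counts.index[int(np.flatnonzero(totals == 0)[0])]
        raise ValueError(f"sample {sample!r} has zero total reads")
    prevalence = (R > 0).mean(axis=0)
    rel = R / totals[:, None]
    max_abundance = rel.max(axis=0)
    low_prev = prevalence < min_prevalence
    low_abund = max_abundance < min_abundance
    if logic == "and":
        remove = low_prev & low_abund
    elif logic == "or":
        remove = low_prev | low_abund
    else:
        raise ValueError("logic must be 'and' or 'or'")
    kept = counts.loc[:, ~remove]
    logger.info("filter_orfs removed %d of %d ORFs", int(remove.sum()), R.shape[1])
    return kept


def filter_phenotype_outliers(
    phenotypes: pd.DataFrame,
    traits: list[str],
    group_key: str = "diet",
    z: float = 3.0,
) -> tuple[pd.DataFrame, list]:
    """Remove animals more than ``z`` within-group SDs from the group mean.

    Group means and SDs are computed once on the original table (a
    single pass, no iteration); an animal is removed if it is outlying
    for ANY of the listed traits.  Groups with zero variance keep all
    their animals.
    """
    if group_key not in phenotypes.columns:
        raise KeyError(f"group column {group_key!r} not in phenotype table")
    remove = pd.Series(False, index=phenotypes.index)
    for _, grp in phenotypes.groupby(group_key, observed=True):
        if len(grp) < 2:
            raise ValueError("each group needs at least 2 animals")
        for trait in traits:
            x = grp[trait].astype(float)
            mu, sd = x.mean(), x.std(ddof=1)
            if sd == 0:
                if x.nunique() > 1:  # unreachable, but keep the guard explicit
                    logger.warning("zero SD with distinct values in %s", trait)
                continue
            out = (x - mu).abs() > z * sd
            remove.loc[out.index[out]] = True
    removed_ids = list(phenotypes.index[remove])
    return phenotypes.loc[~remove], removed_ids
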