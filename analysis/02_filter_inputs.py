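#!/usr/bin/env python
"""Apply the study's record/feature filters to the simulated inputs.

MAF > 0.05 on SNP columns, the prevalence/abundance rule on ORFs
(removed only when BOTH prevalence < 10% and max within-sample relative
abundance < 0.01%), and within-diet 3-SD outlier removal on both traits.
Writes the filtered tables and a manifest of what was removed.
"""

from pathlib import Path

from rumenblup import StudyConfig
from rumenblup import io as rio
from rumenblup.filters import align_animals
from rumenblup.workflow import apply_filters

IN = Path("results/data")
OUT = Path("results/filtered")


def main() -> None:
    dataset = align_animals(
        rio.read_genotypes(IN / "genotypes.tsv"),
        rio.read_counts(IN / "orf_counts.tsv"),
        rio.read_phenotypes(IN / "phenotypes.tsv"),
    )
    filtered = apply_filters(dataset, StudyConfig())
    rio.write_genotypes(filtered.genotypes, OUT / "genotypes.tsv")
    rio.write_counts(filtered.orf_counts, OUT / "orf_counts.tsv")
    rio.write_phenotypes(filtered.phenotypes, OUT / "phenotypes.tsv")
    rio.write_manifest(filtered.manifest.as_dict(), OUT / "filter_manifest.json")
    m = filtered.manifest
    print(f"removed {m.animals_removed} animals (3-SD within diet), "
          f"{m.snps_removed} SNPs (MAF), {m.orfs_removed} ORFs "
          f"(prevalence/abundance)")
    print(f"{len(filtered.animals)} animals remain for analysis")


if __name__ == "__main__":
    main()
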