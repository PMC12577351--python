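"""TSV readers/writers for the three study inputs and kernel persistence.

All tables are plain tab-separated text with a header row; the first
column is the animal id.  Kernels are stored as a dense ``.npy`` matrix
with a plain-text animal-id sidecar, with an optional TSV export.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kernels import RelationshipMatrix

__all__ = [
    "read_genotypes", "write_genotypes",
    "read_counts", "write_counts",
    "read_phenotypes", "write_phenotypes",
    "save_kernel", "load_kernel", "export_kernel_tsv",
    "write_manifest",
]

_INDEX = "animal_id"


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def _write_table(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index_label=_INDEX)


def read_genotypes(path) -> pd.DataFrame:
    """Animal x SNP dosage table; empty cells become missing (NaN)."""
    return _read_table(path).astype(float)


def write_genotypes(genotypes: pd.DataFrame, path, seed=None) -> None:
    comment = f"genotype dosages; seed={seed}" if seed is not None else None
    _write_table(genotypes, path, comment)


def read_counts(path) -> pd.DataFrame:
    df = _read_table(path)
    if (df.to_numpy() < 0).any():
        raise ValueError("negative counts in ORF table")
    return df.astype(np.int64)


def write_counts(counts: pd.DataFrame, path, seed=None) -> None:
    comment = f"ORF read counts; seed={seed}" if seed is not None else None
    _write_table(counts, path, comment)


def read_phenotypes(path) -> pd.DataFrame:
    return _read_table(path)


def write_phenotypes(phenotypes: pd.DataFrame, path, seed=None) -> None:
    comment = f"phenotypes and covariates; seed={seed}" if seed is not None else None
    _write_table(phenotypes, path, comment)


def save_kernel(K: RelationshipMatrix, path) -> None:
    """Dense binary matrix plus an ``<stem>.ids.txt`` sidecar and metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path.with_suffix(".npy"), K.values)
    ids = K.ids if K.ids is not None else list(range(K.n))
    path.with_suffix(".ids.txt").write_text("\n".join(map(str, ids)) + "\n")
    meta = {"kind": K.kind, "tuned": K.tuned}
    path.with_suffix(".meta.json").write_text(json.dumps(meta))


def load_kernel(path) -> RelationshipMatrix:
    path = Path(path)
    values = np.load(path.with_suffix(".npy"))
    ids = path.with_suffix(".ids.txt").read_text().splitlines()
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    return RelationshipMatrix(values, kind=meta["kind"], tuned=meta["tuned"], ids=ids)


def export_kernel_tsv(K: RelationshipMatrix, path) -> None:
    _write_table(K.to_frame(), path, f"kernel kind={K.kind} tuned={K.tuned}")


def write_manifest(manifest: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
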