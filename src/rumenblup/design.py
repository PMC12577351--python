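"""Fixed-effect design matrix shared by the generator and the workflow."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["build_design"]


def build_design(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effect design: intercept, management group (reference level
    dropped), all but one breed fraction (dropped to break the sum-to-one
    collinearity) and the expected-heterozygosity covariate."""
    X = pd.DataFrame(index=phenotypes.index)
    X["intercept"] = 1.0
    if "management_group" in phenotypes.columns:
        mg = pd.get_dummies(phenotypes["management_group"], prefix="mg", drop_first=True)
        X = pd.concat([X, mg.astype(float)], axis=1)
    breed_cols = sorted(c for c in phenotypes.columns if c.startswith("breed"))
    for c in breed_cols[1:]:
        X[c] = phenotypes[c].astype(float)
    if "heterozygosity" in phenotypes.columns:
        X["heterozygosity"] = phenotypes["heterozygosity"].astype(float)
    return X


def annihilator(X: np.ndarray) -> np.ndarray:
    """Projection onto the orthogonal complement of the column span of X."""
    Q, _ = np.linalg.qr(np.asarray(X, dtype=float))
    return np.eye(X.shape[0]) - Q @ Q.T
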