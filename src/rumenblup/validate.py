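"""Cross-validation schemes and phenotype-prediction metrics.

Two schemes are implemented: a fourfold cross-validation stratified by
sex (a proxy for concentrate vs. forage diet type) replicated five
times, and leave-one-diet-out (LODO) where three diets train and the
fourth tests.  Per fold, variance components are re-estimated on
training records only, the mixed-model equations deliver BLUP solutions
for the masked test animals through the shared kernels, and prediction
is scored by the Pearson correlation between the summed random-effect
solutions (total animal merit, TAM) and the adjusted phenotype
y_adj = y - X beta_hat, plus RMSE and a calibration (dispersion) slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .reml import FitResult, fit_mixed_model

__all__ = [
    "FoldPlan",
    "PredictionMetrics",
    "make_fourfold_plan",
    "make_lodo_plan",
    "evaluate_fold",
    "summarize",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldPlan:
    """One train/test split."""

    scheme: str
    replicate: int
    fold: int
    train_ids: tuple
    test_ids: tuple

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


@dataclass
class PredictionMetrics:
    """Per-fold prediction scores.

    Accuracies are Pearson correlations between the adjusted phenotype
    and TAM or the individual random-effect solutions (EBV for the
    genomic effect, EMV metagenomic, EIV interaction); dispersion is
    the slope of the regression of y_adj on TAM.
    """

    scheme: str
    replicate: int
    fold: int
    accuracy_TAM: float
    accuracy_EBV: float | None
    accuracy_EMV: float | None
    accuracy_EIV: float | None
    rmse: float
    dispersion: float
    converged: bool
    n_test: int

    def as_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "replicate": self.replicate,
            "fold": self.fold,
            "accuracy_TAM": self.accuracy_TAM,
            "accuracy_EBV": self.accuracy_EBV,
            "accuracy_EMV": self.accuracy_EMV,
            "accuracy_EIV": self.accuracy_EIV,
            "rmse": self.rmse,
            "dispersion": self.dispersion,
            "converged": self.converged,
            "n_test": self.n_test,
        }


def make_fourfold_plan(
    animals,
    sex,
    n_folds: int = 4,
    n_replicates: int = 5,
    seed: int = 0,
) -> list[FoldPlan]:
    """Random folds stratified by sex; replicate r uses seed + r.

    Within a replicate every animal appears in exactly one test fold and
    per-fold counts of each sex differ by at most one.
    """
    animals = list(animals)
    sex = np.asarray(sex)
    if len(sex) != len(animals):
        raise ValueError("sex labels must match animals")
    for level in np.unique(sex):
        if (sex == level).sum() < n_folds:
            raise ValueError(f"sex stratum {level!r} smaller than n_folds={n_folds}")
    plans = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed + rep)
        fold_of = np.empty(len(animals), dtype=int)
        for level in np.unique(sex):
            idx = np.flatnonzero(sex == level)
            rng.shuffle(idx)
            fold_of[idx] = np.arange(len(idx)) % n_folds
        for f in range(n_folds):
            test = tuple(a for a, ff in zip(animals, fold_of) if ff == f)
            train = tuple(a for a, ff in zip(animals, fold_of) if ff != f)
            plans.append(FoldPlan("fourfold", rep, f, train, test))
    return plans


def make_lodo_plan(animals, diet) -> list[FoldPlan]:
    """One plan per diet: that diet tests, the rest train."""
    animals = list(animals)
    diet = np.asarray(diet)
    levels = list(pd.unique(diet))
    if len(levels) < 2:
        raise ValueError("need at least 2 diets")
    plans = []
    for f, level in enumerate(levels):
        test = tuple(a for a, d in zip(animals, diet) if d == level)
        train = tuple(a for a, d in zip(animals, diet) if d != level)
        if not test:
            raise ValueError(f"diet {level!r} has no animals")
        plans.append(FoldPlan("lodo", 0, f, train, test))
    return plans


def _pearson(y_adj, pred) -> float:
    # a constant prediction (e.g. a variance component estimated at the
    # zero boundary) carries no ranking information: accuracy 0
    if np.std(pred) == 0:
        return 0.0
    if np.std(y_adj) == 0:
        return float("nan")
    return float(stats.pearsonr(y_adj, pred)[0])


def evaluate_fold(
    y: pd.Series,
    X: pd.DataFrame,
    kernels: list,
    effect_names: tuple,
    plan: FoldPlan,
    beta_source: str = "full",
    full_fit: FitResult | None = None,
    **fit_options,
) -> tuple[PredictionMetrics, FitResult]:
    """Score masked-phenotype prediction on one fold.

    Components are re-estimated from training records; BLUP solutions
    for the test animals come from the full kernels.  ``beta_source``
    selects whether y_adj uses fixed effects from a full-data fit of the
    same model (default; required for LODO, where test management
    groups are absent from training) or from the training fit.  A
    precomputed ``full_fit`` can be supplied to avoid refitting across
    folds.
    """
    animals = list(y.index)
    pos = {a: i for i, a in enumerate(animals)}
    train_idx = np.array([pos[a] for a in plan.train_ids])
    test_idx = np.array([pos[a] for a in plan.test_ids])
    Xm = X.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)

    X_train = Xm[train_idx]
    # restrict to a full-rank column subset of the training design: the
    # left-out diet's management-group dummies are constant in training,
    # and removing a reference level can leave the rest collinear with
    # the intercept — pivoted QR picks an independent subset
    R, piv = linalg.qr(X_train, mode="r", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > diag.max() * 1e-10).sum())
    keep = np.zeros(Xm.shape[1], dtype=bool)
    keep[piv[:rank]] = True
    fit = fit_mixed_model(
        yv[train_idx], X_train[:, keep],
        kernels, effect_names=effect_names, phenotyped=train_idx, **fit_options
    )

    if beta_source == "full":
        if full_fit is None:
            full_fit = fit_mixed_model(
                yv, Xm, kernels, effect_names=effect_names, **fit_options
            )
        y_adj = yv - Xm @ full_fit.beta
    elif beta_source == "train":
        cols = np.flatnonzero(keep)
        X_test = Xm[np.ix_(test_idx, cols)]
        dropped = np.flatnonzero(~keep)
        if dropped.size and np.any(Xm[np.ix_(test_idx, dropped)] != 0):
            raise ValueError(
                "test animals carry fixed-effect levels absent from training; "
                "use beta_source='full'"
            )
        y_adj = np.full(len(yv), np.nan)
        y_adj[test_idx] = yv[test_idx] - X_test @ fit.beta
    else:
        raise ValueError("beta_source must be 'full' or 'train'")

    tam = np.sum([fit.blup[e] for e in effect_names], axis=0)
    ya, tam_t = y_adj[test_idx], tam[test_idx]
    acc = {e: None for e in ("u", "m", "o")}
    for e in effect_names:
        acc[e] = _pearson(ya, fit.blup[e][test_idx])
    rmse = float(np.sqrt(np.mean((ya - tam_t) ** 2)))
    if np.std(tam_t) > 0:
        slope = float(np.polyfit(tam_t, ya, 1)[0])
    else:
        slope = float("nan")
    metrics = PredictionMetrics(
        scheme=plan.scheme,
        replicate=plan.replicate,
        fold=plan.fold,
        accuracy_TAM=_pearson(ya, tam_t),
        accuracy_EBV=acc["u"],
        accuracy_EMV=acc["m"],
        accuracy_EIV=acc["o"],
        rmse=rmse,
        dispersion=slope,
        converged=fit.converged,
        n_test=len(test_idx),
    )
    return metrics, fit


def summarize(metrics: list[PredictionMetrics] | pd.DataFrame, by=("scheme",)) -> pd.DataFrame:
    """Median and SD of each metric per group, over converged folds only.

    The count of omitted non-converged folds is reported per group.
    """
    if not isinstance(metrics, pd.DataFrame):
        metrics = pd.DataFrame([m.as_dict() for m in metrics])
    by = list(by)
    rows = []
    value_cols = [
        "accuracy_TAM", "accuracy_EBV", "accuracy_EMV", "accuracy_EIV",
        "rmse", "dispersion",
    ]
    for key, grp in metrics.groupby(by, dropna=False):
        ok = grp[grp["converged"]]
        n_omitted = len(grp) - len(ok)
        if ok.empty:
            logger.warning("group %s: no converged folds, omitted", key)
            continue
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        for col in value_cols:
            vals = ok[col].dropna()
            row[f"{col}_median"] = float(vals.median()) if len(vals) else float("nan")
            row[f"{col}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        row["n_folds"] = len(ok)
        row["n_omitted"] = n_omitted
        rows.append(row)
    return pd.DataFrame(rows)
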