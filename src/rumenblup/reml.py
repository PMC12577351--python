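"""Multi-kernel univariate animal models: REML, BLUP and variance ratios.

The models are y = X beta + sum_k Z_k a_k + e with a_k ~ N(0, K_k s2_k)
for one to three tuned kernels K_k (genomic, metagenomic, interaction)
and e ~ N(0, I s2_e).  Variance components are estimated by
average-information (AI) REML with expectation-style fallback steps and
non-negativity constraints; BLUP solutions are returned for every
animal spanned by the kernels, using only phenotyped records.

A fast eigendecomposition-profiled path handles the single-kernel case
(used for the per-ORF heritability sweep, where thousands of traits
share one genomic kernel).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .kernels import RelationshipMatrix

__all__ = [
    "ModelSpec",
    "FitResult",
    "model_grid",
    "restricted_log_likelihood",
    "fit_mixed_model",
    "variance_ratios",
    "estimate_orf_heritabilities",
]

logger = logging.getLogger(__name__)

COMPLEXITIES = ("genomic", "metagenomic", "joint", "interaction")
ADJUSTMENTS = ("naive", "weighted", "data-driven")


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the model grid.

    ``complexity`` is one of genomic / metagenomic / joint /
    interaction; metagenome-bearing models also carry the MRM
    construction method (1 or 2) and adjustment.  Interaction models
    necessarily include both the genomic and metagenomic kernels.
    """

    trait: str
    complexity: str
    mrm_method: int | None = None
    adjustment: str | None = None

    def __post_init__(self) -> None:
        if self.complexity not in COMPLEXITIES:
            raise ValueError(f"unknown complexity {self.complexity!r}")
        has_mrm = self.complexity != "genomic"
        if has_mrm and (self.mrm_method not in (1, 2) or self.adjustment not in ADJUSTMENTS):
            raise ValueError("metagenome-bearing models need mrm_method and adjustment")
        if not has_mrm and (self.mrm_method is not None or self.adjustment is not None):
            raise ValueError("genomic-only models take no MRM settings")

    @property
    def effects(self) -> tuple[str, ...]:
        return {
            "genomic": ("u",),
            "metagenomic": ("m",),
            "joint": ("u", "m"),
            "interaction": ("u", "m", "o"),
        }[self.complexity]

    @property
    def label(self) -> str:
        if self.complexity == "genomic":
            return f"{self.trait}:genomic"
        return f"{self.trait}:{self.complexity}:M{self.mrm_method}:{self.adjustment}"


def model_grid(
    traits,
    complexities=COMPLEXITIES,
    methods=(1, 2),
    adjustments=ADJUSTMENTS,
) -> list[ModelSpec]:
    """Enumerate the model grid in a deterministic order.

    Per trait: one genomic-only model plus (methods x adjustments)
    models at each metagenome-bearing complexity — 1 + 3*6 = 19 with the
    defaults, 38 for two traits.
    """
    specs: list[ModelSpec] = []
    for trait in traits:
        for complexity in complexities:
            if complexity == "genomic":
                specs.append(ModelSpec(trait, "genomic"))
                continue
            for method, adj in itertools.product(methods, adjustments):
                specs.append(ModelSpec(trait, complexity, method, adj))
    return specs


@dataclass
class FitResult:
    """REML fit: components, ratios, fixed effects and BLUP solutions."""

    components: dict[str, float]
    se: dict[str, float]
    beta: np.ndarray
    blup: dict[str, np.ndarray]
    loglik: float
    aic: float
    converged: bool
    n_iter: int
    boundary: list[str] = field(default_factory=list)
    identifiable: bool = True
    ai_inverse: np.ndarray | None = None
    effect_names: tuple[str, ...] = ()

    @property
    def ratios(self) -> dict[str, float]:
        return variance_ratios(self)

    def ratio_se(self) -> dict[str, float]:
        """Delta-method standard errors of the variance ratios."""
        if self.ai_inverse is None:
            return {}
        names = list(self.effect_names) + ["e"]
        theta = np.array([self.components[k] for k in names])
        total = theta.sum()
        cov = self.ai_inverse
        out = {}
        for ratio_name, members in _ratio_members(self.effect_names).items():
            c = np.array([1.0 if k in members else 0.0 for k in names])
            num = float(c @ theta)
            grad = (c * total - num) / total**2
            out[ratio_name] = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
        return out


def _ratio_members(effect_names) -> dict[str, tuple[str, ...]]:
    out = {}
    if "u" in effect_names:
        out["h2"] = ("u",)
    if "m" in effect_names:
        out["m2"] = ("m",)
    if "u" in effect_names and "m" in effect_names:
        out["i_a2"] = ("u", "m")
    if "o" in effect_names:
        out["i_i2"] = ("u", "m", "o")
    return out


def variance_ratios(fit: FitResult) -> dict[str, float]:
    """Variance-component ratios relative to the total of all components.

    h2 = s2_u/Sigma, m2 = s2_m/Sigma, i_a2 = (s2_u+s2_m)/Sigma and
    i_i2 = (s2_u+s2_m+s2_o)/Sigma, where Sigma includes the residual.
    Only ratios whose effects are in the model are reported.
    """
    total = sum(fit.components.values())
    if total <= 0:
        raise ZeroDivisionError("all variance components are zero")
    out = {}
    for name, members in _ratio_members(fit.effect_names).items():
        out[name] = sum(fit.components[k] for k in members) / total
    return out


def _check_design(X: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"fixed-effect design is rank deficient (rank {rank} < {X.shape[1]} columns)"
        )


def _kernel_values(K) -> np.ndarray:
    return K.values if isinstance(K, RelationshipMatrix) else np.asarray(K, float)


def restricted_log_likelihood(y, X, kernels, sigmas) -> float:
    """Restricted log-likelihood at given variance components.

    -0.5 [ log|V| + log|X'V^-1 X| + y'Py ] with
    V = sum_k s2_k K_k + s2_e I (the last entry of ``sigmas`` is the
    residual variance), up to the usual additive constant.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    _check_design(X)
    sigmas = np.asarray(sigmas, float)
    Ks = [_kernel_values(K) for K in kernels]
    if len(sigmas) != len(Ks) + 1:
        raise ValueError("need one variance per kernel plus a residual variance")
    n = len(y)
    V = sigmas[-1] * np.eye(n)
    for s2, K in zip(sigmas[:-1], Ks):
        V += s2 * K
    try:
        cho = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError as err:
        raise linalg.LinAlgError(
            f"V is not positive definite at components {sigmas.tolist()}"
        ) from err
    logdet_v = 2.0 * np.log(np.diag(cho[0])).sum()
    Vinv_X = linalg.cho_solve(cho, X)
    Vinv_y = linalg.cho_solve(cho, y)
    XtVX = X.T @ Vinv_X
    sign, logdet_x = np.linalg.slogdet(XtVX)
    if sign <= 0:
        raise linalg.LinAlgError("X'V^-1X is not positive definite")
    beta = np.linalg.solve(XtVX, X.T @ Vinv_y)
    yPy = float(y @ Vinv_y - (X.T @ Vinv_y) @ beta)
    return -0.5 * (logdet_v + logdet_x + yPy)


def fit_mixed_model(
    y,
    X,
    kernels,
    effect_names=None,
    phenotyped=None,
    max_iter: int = 200,
    tol_logl: float = 1e-8,
    tol_theta: float = 1e-6,
    verbose: bool = False,
) -> FitResult:
    """AI-REML fit of a 1-3 kernel animal model with BLUP back-solving.

    Parameters
    ----------
    y, X
        Phenotypes and full-column-rank fixed-effect design for the
        *phenotyped* animals.
    kernels
        Tuned relationship matrices over all animals (phenotyped or
        not), all with the same animal order.
    effect_names
        Labels for the random effects (default ``u``/``m``/``o`` by
        position, residual always ``e``).
    phenotyped
        Integer indices into the kernel animal order for the rows of
        ``y``; defaults to all animals.

    Notes
    -----
    Average-information updates are taken when they keep all components
    non-negative and increase the likelihood; otherwise an
    expectation-style multiplicative fallback step is used.  Components
    collapsing to zero are pinned at the boundary and reported in
    ``boundary``.  Standard errors come from the inverse AI matrix at
    the optimum; AIC = -2 logL + 2 * (number of variance components).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    _check_design(X)
    K_full = [_kernel_values(K) for K in kernels]
    if not 1 <= len(K_full) <= 3:
        raise ValueError("expected 1-3 kernels")
    N = K_full[0].shape[0]
    if phenotyped is None:
        train = np.arange(N)
    else:
        train = np.asarray(phenotyped, dtype=int)
    n, p = len(train), X.shape[1]
    if len(y) != n or X.shape[0] != n:
        raise ValueError("y/X rows must match the phenotyped index")
    if effect_names is None:
        effect_names = tuple("umo"[: len(K_full)])
    effect_names = tuple(effect_names)

    Kt = [K[np.ix_(train, train)] for K in K_full]
    comps = Kt + [np.eye(n)]
    k = len(comps)
    vy = float(np.var(y)) or 1.0
    theta = np.full(k, vy / k)
    floor = 1e-10 * vy

    identifiable = True
    if len(Kt) == 1 and np.allclose(Kt[0], np.eye(n), atol=1e-10):
        identifiable = False
        logger.warning(
            "single random effect with an identity kernel: only the sum "
            "s2_u + s2_e is identifiable"
        )

    def _state(th):
        V = sum(t * C for t, C in zip(th, comps))
        cho = linalg.cho_factor(V, lower=True)
        logdet_v = 2.0 * np.log(np.diag(cho[0])).sum()
        Vinv = linalg.cho_solve(cho, np.eye(n))
        Vinv_X = Vinv @ X
        XtVX = X.T @ Vinv_X
        XtVX_cho = linalg.cho_factor(XtVX, lower=True)
        logdet_x = 2.0 * np.log(np.diag(XtVX_cho[0])).sum()
        P = Vinv - Vinv_X @ linalg.cho_solve(XtVX_cho, Vinv_X.T)
        Py = P @ y
        ll = -0.5 * (logdet_v + logdet_x + float(y @ Py))
        return ll, P, Py, Vinv, XtVX_cho, Vinv_X

    ll, P, Py, Vinv, XtVX_cho, Vinv_X = _state(theta)
    converged = False
    it = 0
    n_flat = 0  # consecutive iterations with negligible logL gain
    AI = np.eye(k)
    ai_iters = min(max_iter, 30)
    for it in range(1, ai_iters + 1):
        KPy = np.column_stack([C @ Py for C in comps])
        tr_PK = np.array([float((P * C).sum()) for C in comps])
        quad = KPy.T @ Py  # y'P K_j P y
        score = -0.5 * (tr_PK - quad)
        PU = P @ KPy
        AI = 0.5 * (KPy.T @ PU)

        # candidate steps: the AI step clipped at the non-negativity
        # boundary (components may leave the boundary again when their
        # gradient turns positive) and the monotone expectation-style
        # multiplicative step; take whichever improves the likelihood
        # more, step-halving towards the current point on a decrease
        candidates = []
        try:
            delta = np.linalg.solve(AI, score)
            candidates.append(np.clip(theta + delta, 0.0, None))
        except np.linalg.LinAlgError:
            pass
        em = theta.copy()
        for j in range(k):
            if tr_PK[j] > 0 and quad[j] > 0:
                em[j] = theta[j] * quad[j] / tr_PK[j]
        candidates.append(em)

        best_ll, best_state, best_theta = -np.inf, None, None
        for cand in candidates:
            cand[-1] = max(cand[-1], floor)
            for _ in range(30):
                try:
                    state = _state(cand)
                except linalg.LinAlgError:
                    cand = 0.5 * (cand + theta)
                    continue
                if state[0] >= ll - 1e-10:
                    break
                cand = 0.5 * (cand + theta)
            else:
                continue
            if state[0] > best_ll:
                best_ll, best_state, best_theta = state[0], state, cand
        if best_state is None or best_ll < ll - 1e-10:
            converged = True  # no ascent direction left (stalled at optimum)
            break
        new_ll, P, Py, Vinv, XtVX_cho, Vinv_X = best_state
        new_theta = best_theta
        d_ll = new_ll - ll
        d_theta = np.abs(new_theta - theta).max() / vy
        theta, ll = new_theta, new_ll
        if verbose:
            logger.info("iter %d logL=%.6f theta=%s", it, ll, theta.tolist())
        n_flat = n_flat + 1 if abs(d_ll) < tol_logl * (1.0 + abs(ll)) else 0
        if n_flat and d_theta < tol_theta:
            converged = True
            break
        if n_flat >= 3:
            # the restricted likelihood has stopped moving while the
            # components drift along a flat ridge: accept the optimum
            converged = True
            break

    if not converged and max_iter > ai_iters:
        # the AI/EM iteration is crawling along a near-flat ridge (common
        # for interaction models whose kernel is highly collinear with
        # G and M): finish with bounded quasi-Newton on the exact
        # restricted score, which handles the ridge curvature directly
        def _neg_ll_grad(th):
            try:
                ll_, P_, Py_, *_ = _state(th)
            except linalg.LinAlgError:
                return 1e12, np.zeros(k)
            KPy_ = np.column_stack([C @ Py_ for C in comps])
            tr_ = np.array([float((P_ * C).sum()) for C in comps])
            quad_ = KPy_.T @ Py_
            return -ll_, 0.5 * (tr_ - quad_)

        bounds = [(0.0, None)] * (k - 1) + [(floor, None)]
        res = optimize.minimize(
            _neg_ll_grad, theta, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-6},
        )
        it += int(res.nit)
        if -res.fun >= ll:
            theta = np.asarray(res.x)
            ll, P, Py, Vinv, XtVX_cho, Vinv_X = _state(theta)
            converged = bool(res.success)

    # final state quantities; SEs come from the AI matrix restricted to
    # components off the zero boundary
    KPy = np.column_stack([C @ Py for C in comps])
    PU = P @ KPy
    AI = 0.5 * (KPy.T @ PU)
    free = np.flatnonzero((theta > 1e-9 * vy) | (np.arange(k) == k - 1))
    ai_inv = np.zeros((k, k))
    try:
        ai_inv[np.ix_(free, free)] = np.linalg.inv(AI[np.ix_(free, free)])
    except np.linalg.LinAlgError:
        ai_inv[:] = np.nan
    se = np.sqrt(np.clip(np.diag(ai_inv), 0.0, None))

    beta = linalg.cho_solve(XtVX_cho, X.T @ (Vinv @ y))
    names = list(effect_names) + ["e"]
    blup = {}
    for j, name in enumerate(effect_names):
        blup[name] = theta[j] * (K_full[j][:, train] @ Py)
    boundary = [names[j] for j in range(k - 1) if theta[j] <= 1e-9 * vy]
    aic = -2.0 * ll + 2.0 * k

    return FitResult(
        components={nm: float(t) for nm, t in zip(names, theta)},
        se={nm: float(s) for nm, s in zip(names, se)},
        beta=np.asarray(beta, float),
        blup=blup,
        loglik=float(ll),
        aic=float(aic),
        converged=converged,
        n_iter=it,
        boundary=boundary,
        identifiable=identifiable,
        ai_inverse=ai_inv,
        effect_names=effect_names,
    )


# ---------------------------------------------------------------------------
# single-kernel fast path via eigendecomposition (profiled REML)


def _profiled_reml_1k(yt, Xt, eigvals, phi: float) -> float:
    """Profiled restricted logL for V = s2 (phi K + (1-phi) I).

    ``yt``/``Xt`` are already rotated onto the eigenbasis of K (done
    once per phenotype, not per likelihood evaluation).  The overall
    scale s2 is profiled out in closed form; returns the restricted
    logL at the profiled optimum (up to a constant that does not
    depend on phi).
    """
    n, p = Xt.shape
    d = phi * eigvals + (1.0 - phi)
    if (d <= 0).any():
        return -np.inf
    dinv = 1.0 / d
    XtDX = Xt.T @ (Xt * dinv[:, None])
    XtDy = Xt.T @ (yt * dinv)
    sign, logdet_x = np.linalg.slogdet(XtDX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtDX, XtDy)
    ypy = float(yt @ (yt * dinv) - XtDy @ beta)
    if ypy <= 0:
        return -np.inf
    logdet_v = float(np.log(d).sum())
    return -0.5 * (logdet_v + logdet_x + (n - p) * np.log(ypy / (n - p)) + (n - p))


def estimate_orf_heritabilities(S, G_T: RelationshipMatrix, X) -> np.ndarray:
    """Per-ORF heritability of log relative abundance under an animal model.

    Each ORF column is treated as the phenotype of a single-kernel
    animal model with the tuned GRM; h2 = s2_u / (s2_u + s2_e) is
    profiled over the variance ratio on the eigenbasis of G_T, which
    costs O(n p^2) per ORF after one eigendecomposition.  Estimates are
    boundary-constrained to [0, 1); constant columns and failed fits
    fall back to 0 (weight 1 downstream).
    """
    import pandas as pd

    if not G_T.tuned:
        raise ValueError("G_T must be tuned (invertible)")
    Smat = S.to_numpy(dtype=float) if isinstance(S, pd.DataFrame) else np.asarray(S, float)
    X = np.asarray(X, float)
    _check_design(X)
    eigvals, U = np.linalg.eigh(G_T.values)
    Xt = U.T @ X
    St = U.T @ Smat  # rotate all ORF phenotypes at once
    m = Smat.shape[1]
    h2 = np.zeros(m)
    for j in range(m):
        if np.var(Smat[:, j]) == 0:
            logger.warning("ORF column %d is constant: h2 set to 0", j)
            continue
        yt = St[:, j]
        try:
            res = optimize.minimize_scalar(
                lambda phi: -_profiled_reml_1k(yt, Xt, eigvals, phi),
                bounds=(0.0, 1.0 - 1e-6),
                method="bounded",
                options={"xatol": 1e-6},
            )
            est = float(res.x)
            # check the zero boundary explicitly
            if _profiled_reml_1k(yt, Xt, eigvals, 0.0) >= -res.fun:
                est = 0.0
            h2[j] = min(max(est, 0.0), 1.0)
        except Exception:  # propagate as weight 1 downstream, keep sweeping
            logger.warning("ORF column %d: fit failed, h2 set to 0", j)
            h2[j] = 0.0
    return h2
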