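"""Elastic-net / Ridge penalized logistic regression with λ paths and LOOCV.

The fitted objective is

    f(b0, β) = (1/n) Σ_i [log(1 + exp(η_i)) − y_i η_i]
               + λ [ α Σ_j m_j |β_j| + (1−α)/2 Σ_j m_j β_j² ],   η = b0 + Xβ,

where ``α`` is the elastic-net mixing weight (0 = Ridge, 1 = lasso) and
``m_j ∈ {0, 1}`` is a per-column penalty mask: the intercept is never
penalized and individual columns (e.g. design variables forced into a model)
can be exempted.

Two solvers cover the two regimes:

* ``α = 0`` — damped Newton (IRLS) with step halving; converges to machine
  precision on these small well-conditioned problems.
* ``α > 0`` — iteratively reweighted least squares with cyclic coordinate
  descent and soft-thresholding on the working quadratic approximation,
  warm-started along the λ path so the path starts at the exact null model
  at λ_max.

Cross-validation is leave-one-out on the binomial deviance (k-fold is
available for large simulated cohorts); λ_min minimizes the mean held-out
deviance and λ_1se is the largest λ within one standard error of it — the
more regularised choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

try:
    from ._kernels import (HAVE_NUMBA as _HAVE_KERNEL, enet_fit_kernel,
                           enet_path_kernel, ridge_path_kernel)
except ImportError:  # pragma: no cover
    _HAVE_KERNEL = False

__all__ = [
    "PenaltySpec",
    "PenalizedFit",
    "CvPath",
    "SeparationError",
    "fit_penalized",
    "fit_path",
    "make_lambda_grid",
    "loocv_path",
    "binomial_deviance",
]

_EPS_P = 1e-12  # probability clip for deviance evaluation


class SeparationError(RuntimeError):
    """Unpenalized fit diverged: data are (quasi-)separable; use λ > 0."""


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty settings for a path of penalized logistic fits.

    Parameters
    ----------
    alpha
        Elastic-net mixing in [0, 1]; 0 is Ridge, 1 is the lasso.
    n_lambda
        Number of grid points (log-spaced, decreasing).
    lambda_min_ratio
        Smallest grid value as a fraction of λ_max.
    ridge_lambda_max
        For α = 0 the null-model λ_max is infinite; the grid is capped at
        this multiple of the α-free gradient bound max_j |x_jᵀ(y − p̄)| / n.
    lambda_grid
        Explicit decreasing grid; overrides the automatic construction.
    unpenalized
        Column names exempt from the penalty (forced covariates).
    """

    alpha: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    ridge_lambda_max: float = 100.0
    lambda_grid: tuple[float, ...] | None = None
    unpenalized: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.lambda_grid is not None:
            grid = np.asarray(self.lambda_grid, dtype=float)
            if grid.ndim != 1 or len(grid) == 0 or np.any(grid <= 0):
                raise ValueError("lambda_grid must be positive")
            if np.any(np.diff(grid) >= 0):
                raise ValueError("lambda_grid must be strictly decreasing")


@dataclass(frozen=True)
class PenalizedFit:
    """A fitted penalized logistic model on the analysis (standardized) scale."""

    intercept: float
    coef: dict[str, float]
    alpha: float
    lam: float
    converged: bool
    n_iter: int

    def linear_predictor(self, X: np.ndarray, columns: list[str]) -> np.ndarray:
        beta = np.array([self.coef[c] for c in columns])
        return self.intercept + np.asarray(X, dtype=float) @ beta

    def predict_proba(self, X: np.ndarray, columns: list[str]) -> np.ndarray:
        from scipy.special import expit

        return expit(self.linear_predictor(X, columns))


@dataclass(frozen=True)
class CvPath:
    """Cross-validated deviance along a λ grid with the λ_min / λ_1se rules."""

    lambdas: np.ndarray
    mean_deviance: np.ndarray
    se_deviance: np.ndarray
    lambda_min: float
    lambda_1se: float
    n_folds: int
    skipped_folds: tuple[int, ...] = ()
    nonzero: np.ndarray | None = field(default=None, repr=False)


# ----------------------------------------------------------------- internals


def _nll(eta: np.ndarray, y: np.ndarray) -> float:
    # mean negative Bernoulli log-likelihood, numerically stable
    return float(np.mean(np.logaddexp(0.0, eta) - y * eta))


def _objective(b0, beta, X, y, lam, alpha, mask) -> float:
    eta = b0 + X @ beta
    pen = alpha * np.sum(mask * np.abs(beta)) + 0.5 * (1 - alpha) * np.sum(mask * beta**2)
    return _nll(eta, y) + lam * pen


def _expit(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _newton_ridge_aug(Xa, y, dpen, b, max_iter=200, tol_g=5e-14):
    """Damped Newton on the augmented matrix (intercept = column 0), α = 0.

    Converges the gradient to near machine precision; objective-increase
    safeguard with step halving keeps cold starts stable.
    """
    n = len(y)
    eta = Xa @ b
    obj = float(np.mean(np.logaddexp(0.0, eta) - y * eta) + 0.5 * np.dot(dpen, b * b))
    it = 0
    for it in range(1, max_iter + 1):
        prob = _expit(eta)
        g = Xa.T @ (prob - y) / n + dpen * b
        if np.max(np.abs(g)) < tol_g:
            if np.max(np.abs(b[1:])) > 50 and np.max(dpen) < 1e-12:
                raise SeparationError(
                    "unpenalized logistic fit appears separable; refit with λ > 0"
                )
            return b, True, it
        w = prob * (1.0 - prob)
        H = (Xa * w[:, None]).T @ Xa / n
        H[np.diag_indices_from(H)] += dpen
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        t = 1.0
        for _ in range(60):
            nb = b - t * step
            eta = Xa @ nb
            nobj = float(np.mean(np.logaddexp(0.0, eta) - y * eta)
                         + 0.5 * np.dot(dpen, nb * nb))
            if nobj <= obj + 1e-15:
                break
            t *= 0.5
        if abs(obj - nobj) < 1e-16 * (abs(obj) + 1e-12) and np.max(np.abs(t * step)) < 1e-12:
            return nb, True, it
        b, obj = nb, nobj
    if np.max(np.abs(b[1:])) > 50 and np.max(dpen) < 1e-12:
        raise SeparationError(
            "unpenalized logistic fit appears separable; refit with λ > 0"
        )
    return b, False, it


def _newton_ridge(X, y, lam, mask, beta0, b00, tol, max_iter):
    """Ridge (α = 0) fit in the unaugmented parameterisation."""
    Xa = np.hstack([np.ones((len(y), 1)), X])
    dpen = np.concatenate(([0.0], lam * mask))
    b = np.concatenate(([b00], beta0))
    b, conv, it = _newton_ridge_aug(Xa, y, dpen, b, max_iter=max_iter)
    return float(b[0]), b[1:], conv, it


def _soft(z: float, g: float) -> float:
    if z > g:
        return z - g
    if z < -g:
        return z + g
    return 0.0


def _cd_elastic_net(X, y, lam, alpha, mask, beta0, b00, tol, max_iter):
    """IRLS + cyclic coordinate descent for α > 0 (glmnet-style)."""
    n, p = X.shape
    beta = beta0.copy()
    b0 = b00
    obj = _objective(b0, beta, X, y, lam, alpha, mask)
    l1 = lam * alpha * mask
    l2 = lam * (1.0 - alpha) * mask
    total_iter = 0
    for outer in range(1, max_iter + 1):
        eta = b0 + X @ beta
        prob = _expit(eta)
        w = np.clip(prob * (1.0 - prob), 1e-9, None)
        r = y - prob  # working residual w·(z − η) at the current point
        vj = (w @ (X * X)) / n
        sw = w.sum() / n
        # inner CD sweeps on the fixed quadratic approximation
        for _sweep in range(1000):
            delta_max = 0.0
            d0 = r.sum() / n / sw
            if d0 != 0.0:
                b0 += d0
                r -= w * d0
                delta_max = max(delta_max, abs(d0) * sw)
            for j in range(p):
                bj = beta[j]
                u = (X[:, j] @ r) / n + vj[j] * bj
                nbj = _soft(u, l1[j]) / (vj[j] + l2[j])
                if nbj != bj:
                    beta[j] = nbj
                    r -= w * X[:, j] * (nbj - bj)
                    delta_max = max(delta_max, abs(nbj - bj) * max(vj[j], 1e-9))
            total_iter += 1
            if delta_max < 1e-14:
                break
        nobj = _objective(b0, beta, X, y, lam, alpha, mask)
        if abs(obj - nobj) < tol * (abs(obj) + 1.0):
            return b0, beta, True, total_iter
        obj = nobj
    return b0, beta, False, total_iter


def _null_fit(X, y, mask, tol=1e-10, max_iter=200):
    """Fit intercept + unpenalized columns only; returns (b0, beta, prob)."""
    free = np.where(mask == 0)[0]
    n, p = X.shape
    beta = np.zeros(p)
    if len(free) == 0:
        ybar = float(np.mean(y))
        ybar = min(max(ybar, _EPS_P), 1 - _EPS_P)
        b0 = float(np.log(ybar / (1 - ybar)))
    else:
        sub = X[:, free]
        b0, bsub, _, _ = _newton_ridge(
            sub, y, 1e-8, np.ones(len(free)), np.zeros(len(free)), 0.0, tol, max_iter
        )
        beta[free] = bsub
    prob = _expit(b0 + X @ beta)
    return b0, beta, prob


def make_lambda_grid(X: np.ndarray, y: np.ndarray, spec: PenaltySpec,
                     mask: np.ndarray) -> np.ndarray:
    """Decreasing log-spaced λ grid from λ_max down to λ_max·lambda_min_ratio.

    For α > 0, λ_max is the smallest λ at which every penalized coefficient is
    exactly zero given the unpenalized columns: max_j |x_jᵀ(y − p̂)| / (n α).
    For α = 0 that bound is infinite and the grid is capped at
    ``ridge_lambda_max`` times the α-free gradient bound.
    """
    if spec.lambda_grid is not None:
        return np.asarray(spec.lambda_grid, dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    _, _, prob = _null_fit(X, y, mask)
    score = np.abs(X.T @ (y - prob)) / n
    score = np.where(mask > 0, score, 0.0)
    base = float(np.max(score))
    if base <= 0:
        base = 1e-3
    if spec.alpha > 0:
        # tiny safety factor so the path provably starts at the exact null model
        lam_max = base / spec.alpha * (1.0 + 1e-6)
    else:
        lam_max = base * spec.ridge_lambda_max
    return np.geomspace(lam_max, lam_max * spec.lambda_min_ratio, spec.n_lambda)


def _resolve_mask(columns: list[str], spec: PenaltySpec) -> np.ndarray:
    unknown = set(spec.unpenalized) - set(columns)
    if unknown:
        raise ValueError(f"unpenalized columns not in design: {sorted(unknown)}")
    return np.array([0.0 if c in spec.unpenalized else 1.0 for c in columns])


def _check_Xy(X, y, columns, mask):
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != len(y):
        raise ValueError("X and y have different lengths")
    if X.shape[1] != len(columns):
        raise ValueError("column names do not match X width")
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])) or len(classes) < 2:
        raise ValueError("y must be binary with both classes present")
    var = X.var(axis=0)
    dead = [c for c, v, m in zip(columns, var, mask) if m > 0 and v == 0.0]
    if dead:
        raise ValueError(f"zero-variance penalized column(s): {dead}")
    return X, y


def fit_penalized(
    X: np.ndarray,
    y: np.ndarray,
    columns: list[str],
    spec: PenaltySpec,
    lam: float,
    *,
    warm: tuple[float, np.ndarray] | None = None,
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> PenalizedFit:
    """Fit the penalized logistic objective at a single λ.

    ``X`` carries no intercept column; the intercept is fitted unpenalized.
    Deterministic given inputs; non-convergence is flagged on the result, not
    silently dropped.
    """
    mask = _resolve_mask(list(columns), spec)
    X, y = _check_Xy(X, y, columns, mask)
    p = X.shape[1]
    if warm is not None:
        b00, beta0 = warm[0], np.asarray(warm[1], dtype=float).copy()
    else:
        b00, beta0 = 0.0, np.zeros(p)
    if spec.alpha == 0.0:
        b0, beta, conv, it = _newton_ridge(X, y, lam, mask, beta0, b00, tol, min(max_iter, 500))
    elif _HAVE_KERNEL:
        b0, beta, conv, it = enet_fit_kernel(X, y, float(lam), float(spec.alpha),
                                             mask, beta0, float(b00), tol, max_iter)
    else:
        b0, beta, conv, it = _cd_elastic_net(X, y, lam, spec.alpha, mask, beta0, b00, tol, max_iter)
    if not conv:
        warnings.warn(
            f"penalized fit did not converge at λ={lam:.3g} (α={spec.alpha})",
            RuntimeWarning,
            stacklevel=2,
        )
    return PenalizedFit(
        intercept=float(b0),
        coef={c: float(b) for c, b in zip(columns, beta)},
        alpha=spec.alpha,
        lam=float(lam),
        converged=bool(conv),
        n_iter=int(it),
    )


def fit_path(
    X: np.ndarray,
    y: np.ndarray,
    columns: list[str],
    spec: PenaltySpec,
    lambdas: np.ndarray | None = None,
    tol: float = 1e-12,
    validate: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit the whole λ path with warm starts.

    Returns ``(lambdas, intercepts, coefs)`` with ``coefs`` of shape
    ``(len(lambdas), p)``.  ``validate=False`` skips the input checks — used
    by cross-validation, which validates the full data once; a column that
    is constant only within one training fold (e.g. a rare binary) is
    harmless there, as the penalty keeps its coefficient at/near zero.
    """
    mask = _resolve_mask(list(columns), spec)
    if validate:
        X, y = _check_Xy(X, y, columns, mask)
    else:
        X = np.ascontiguousarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
    if lambdas is None:
        lambdas = make_lambda_grid(X, y, spec, mask)
    lambdas = np.asarray(lambdas, dtype=float)
    p = X.shape[1]
    intercepts = np.empty(len(lambdas))
    coefs = np.empty((len(lambdas), p))
    b0, beta, _ = _null_fit(X, y, mask)
    if spec.alpha == 0.0:
        Xa = np.hstack([np.ones((len(y), 1)), X])
        b = np.concatenate(([b0], beta))
        mask_aug = np.concatenate(([0.0], mask))
        if _HAVE_KERNEL:
            B, ok = ridge_path_kernel(Xa, y, lambdas, mask_aug, b)
            if not np.all(ok):
                warnings.warn("ridge path fit did not converge at some λ",
                              RuntimeWarning, stacklevel=2)
            return lambdas, B[:, 0].copy(), B[:, 1:].copy()
        for k, lam in enumerate(lambdas):
            dpen = lam * mask_aug
            b, conv, _ = _newton_ridge_aug(Xa, y, dpen, b)
            if not conv:
                warnings.warn(f"path fit did not converge at λ={lam:.3g}",
                              RuntimeWarning, stacklevel=2)
            intercepts[k] = b[0]
            coefs[k] = b[1:]
        return lambdas, intercepts, coefs
    if _HAVE_KERNEL:
        intercepts, coefs, ok = enet_path_kernel(X, y, lambdas, float(spec.alpha),
                                                 mask, beta, float(b0), tol)
        if not np.all(ok):
            warnings.warn("elastic-net path fit did not converge at some λ",
                          RuntimeWarning, stacklevel=2)
        return lambdas, intercepts, coefs
    for k, lam in enumerate(lambdas):
        b0, beta, conv, _ = _cd_elastic_net(X, y, lam, spec.alpha, mask, beta, b0, tol, 100_000)
        if not conv:
            warnings.warn(f"path fit did not converge at λ={lam:.3g}", RuntimeWarning, stacklevel=2)
        intercepts[k] = b0
        coefs[k] = beta
    return lambdas, intercepts, coefs


def binomial_deviance(prob: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-observation binomial deviance −2·[y log p + (1−y) log(1−p)]."""
    prob = np.clip(np.asarray(prob, dtype=float), _EPS_P, 1.0 - _EPS_P)
    y = np.asarray(y, dtype=float)
    return -2.0 * (y * np.log(prob) + (1.0 - y) * np.log(1.0 - prob))


def _fold_indices(n: int, cv: int | None, seed: int | None) -> list[np.ndarray]:
    if cv is None or cv >= n:
        return [np.array([i]) for i in range(n)]
    if cv < 2:
        raise ValueError("cv must be ≥ 2 folds")
    rng = np.random.default_rng(0 if seed is None else seed)
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, cv)]


def loocv_path(
    X: np.ndarray,
    y: np.ndarray,
    columns: list[str],
    spec: PenaltySpec,
    *,
    cv: int | None = None,
    cv_seed: int | None = None,
    tol: float = 1e-12,
) -> CvPath:
    """Cross-validated binomial deviance along the λ path.

    The default is leave-one-out (the trial-scale procedure); ``cv`` selects
    k-fold for large simulated cohorts.  For each fold, the entire path is
    refitted from scratch on the training rows (warm-started along λ only, so
    every per-fold solution is the exact optimum).  The mean held-out deviance
    and its standard error are computed across the held-out patients; λ_1se is
    the largest grid value whose mean deviance is within one SE of the
    minimum.
    """
    mask = _resolve_mask(list(columns), spec)
    X, y = _check_Xy(X, y, columns, mask)
    n = len(y)
    if n < 10:
        raise ValueError("cross-validation requires n ≥ 10")
    lambdas = make_lambda_grid(X, y, spec, mask)
    folds = _fold_indices(n, cv, cv_seed)
    dev = np.full((n, len(lambdas)), np.nan)
    skipped: list[int] = []
    all_idx = np.arange(n)
    for f, hold in enumerate(folds):
        train = np.setdiff1d(all_idx, hold, assume_unique=True)
        ytr = y[train]
        if ytr.min() == ytr.max():
            skipped.append(f)
            warnings.warn(
                f"fold {f}: single outcome class in training rows; fold skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        _, b0s, betas = fit_path(X[train], ytr, list(columns), spec, lambdas,
                                 tol=tol, validate=False)
        eta = b0s[None, :] + X[hold] @ betas.T  # (n_hold, L)
        prob = _expit(eta)
        dev[hold, :] = binomial_deviance(prob, y[hold][:, None])
    valid = ~np.isnan(dev[:, 0])
    n_eff = int(valid.sum())
    if n_eff == 0:
        raise ValueError("all cross-validation folds were skipped")
    mean_dev = dev[valid].mean(axis=0)
    se_dev = dev[valid].std(axis=0, ddof=1) / np.sqrt(n_eff)
    k_min = int(np.argmin(mean_dev))
    if k_min == 0 or k_min == len(lambdas) - 1:
        warnings.warn(
            "minimum CV deviance at the grid boundary; consider extending the λ grid",
            RuntimeWarning,
            stacklevel=2,
        )
    cutoff = mean_dev[k_min] + se_dev[k_min]
    k_1se = int(np.nonzero(mean_dev <= cutoff)[0][0])  # grid is decreasing in λ
    return CvPath(
        lambdas=lambdas,
        mean_deviance=mean_dev,
        se_deviance=se_dev,
        lambda_min=float(lambdas[k_min]),
        lambda_1se=float(lambdas[k_1se]),
        n_folds=len(folds) - len(skipped),
        skipped_folds=tuple(skipped),
    )
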