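"""Distance-matrix regression: pseudo-F, square-root pseudo-F, resampling.

Multivariate distance matrix regression (MDMR) tests whether subject
labels explain the geometry of a subject-pairwise distance matrix.  With
``G`` the Gower-centered Gram matrix of the distances and ``H`` the hat
matrix of a design containing the group label, the pseudo-F statistic is
the trace ratio ``tr(H G H) / tr((I-H) G (I-H))``.  The square-root
variant applies the same ratio to the PSD matrix square root of ``G``,
which up-weights the leading directions and boosts power when features
are correlated.  Significance comes from resampling: label permutation in
the covariate-free case, or — for a binary outcome with covariates — a
parametric bootstrap of logistic-regression residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import CenteredGram, matrix_sqrt_psd
from .score import fit_null_logistic

__all__ = [
    "PseudoFResult",
    "hat_matrix",
    "pseudo_f",
    "sqrt_pseudo_f",
    "permutation_test",
    "parametric_bootstrap_test",
]


@dataclass
class PseudoFResult:
    statistic: float
    variant: str  # "pseudoF" | "sqrtF"
    p_value: float
    n_resamples: int
    seed: int | None
    resampling: str  # "permutation" | "parametric_bootstrap"
    degenerate: bool = False


def hat_matrix(design: np.ndarray) -> np.ndarray:
    """Orthogonal projector onto the column space of ``design``.

    Uses the pseudo-inverse, so a rank-deficient design still yields a
    valid projector onto its (smaller) column space.
    """
    X = np.atleast_2d(np.asarray(design, dtype=float))
    if X.ndim == 1 or X.shape[1] == 0:
        raise ValueError("design must have at least one column")
    H = X @ np.linalg.pinv(X)
    return (H + H.T) / 2


def _trace_ratio(M: np.ndarray, H: np.ndarray) -> tuple[float, bool]:
    n = M.shape[0]
    I = np.eye(n)
    num = np.trace(H @ M @ H)
    den = np.trace((I - H) @ M @ (I - H))
    if den <= 1e-12:
        return np.inf, True
    return float(num / den), False


def pseudo_f(G: CenteredGram | np.ndarray, hat: np.ndarray) -> float:
    """Pseudo-F trace ratio ``tr(H G H) / tr((I-H) G (I-H))``."""
    M = G.entries if isinstance(G, CenteredGram) else np.asarray(G, dtype=float)
    stat, _ = _trace_ratio(M, hat)
    return stat


def sqrt_pseudo_f(G: CenteredGram | np.ndarray, hat: np.ndarray) -> float:
    """Pseudo-F computed on the PSD matrix square root of ``G``."""
    M = G.entries if isinstance(G, CenteredGram) else np.asarray(G, dtype=float)
    return pseudo_f(matrix_sqrt_psd(M).sqrt_matrix, hat)


def _statistic_matrix(G: CenteredGram | np.ndarray, variant: str) -> np.ndarray:
    M = G.entries if isinstance(G, CenteredGram) else np.asarray(G, dtype=float)
    if variant == "sqrtF":
        return matrix_sqrt_psd(M).sqrt_matrix
    if variant == "pseudoF":
        return M
    raise ValueError("variant must be 'pseudoF' or 'sqrtF'")


def permutation_test(
    G: CenteredGram | np.ndarray,
    y: np.ndarray,
    B: int = 999,
    seed: int | None = None,
    variant: str = "sqrtF",
    add_one: bool = True,
) -> PseudoFResult:
    """Label-permutation MDMR test (covariate-free path).

    The design is ``[y, 1]``; the observed trace-ratio statistic is
    compared against ``B`` random permutations of the labels.  The
    add-one estimator ``p = (1 + #{F_b >= F_obs}) / (1 + B)`` keeps the
    p-value away from zero; ties count as exceedances.
    """
    y = np.asarray(y, dtype=float).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both levels")
    if B < 99:
        raise ValueError("need at least 99 resamples")
    M = _statistic_matrix(G, variant)
    n = y.shape[0]
    ones = np.ones((n, 1))

    def stat_for(labels: np.ndarray) -> float:
        H = hat_matrix(np.column_stack([labels, ones]))
        s, _ = _trace_ratio(M, H)
        return s

    f_obs = stat_for(y)
    degenerate = not np.isfinite(f_obs)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(B):
        f_b = stat_for(rng.permutation(y))
        if f_b >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + B) if add_one else exceed / B
    return PseudoFResult(
        statistic=f_obs,
        variant=variant,
        p_value=float(p),
        n_resamples=B,
        seed=seed,
        resampling="permutation",
        degenerate=degenerate,
    )


def _residual_hat(residuals: np.ndarray) -> np.ndarray | None:
    """Rank-one projector onto the centered residual direction.

    Covariate effects are already removed from the residuals, so the
    design reduces to the single centered residual column; returns None
    when the centered residuals are numerically zero (e.g. a constant
    bootstrap outcome), in which case the statistic is defined as 0.
    """
    r = residuals - residuals.mean()
    nrm = r @ r
    if nrm < 1e-24:
        return None
    return np.outer(r, r) / nrm


def parametric_bootstrap_test(
    G: CenteredGram | np.ndarray,
    y: np.ndarray,
    X: np.ndarray | None = None,
    B: int = 999,
    seed: int | None = None,
    variant: str = "sqrtF",
    add_one: bool = True,
) -> PseudoFResult:
    """Residual parametric bootstrap for a binary outcome with covariates.

    Steps: (1) fit the logistic regression of ``y`` on ``X`` and form the
    residuals ``R = y - expit(X gamma_hat)``; (2) compute the observed
    statistic from the projector onto the centered residual direction;
    (3) for each of ``B`` resamples draw ``y* ~ Bernoulli(expit(X
    gamma_hat))``, refit, recompute residual projector and statistic;
    (4) ``p = (1 + #{F* >= F_obs}) / (1 + B)``.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both levels")
    if X is None:
        X = np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    M = _statistic_matrix(G, variant)

    def stat_for(residuals: np.ndarray) -> tuple[float, bool]:
        H = _residual_hat(residuals)
        if H is None:
            return 0.0, True
        return _trace_ratio(M, H)

    fit = fit_null_logistic(y, X)
    mu = fit.fitted_probs
    f_obs, degenerate = stat_for(y - mu)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(B):
        y_star = (rng.random(n) < mu).astype(float)
        if len(np.unique(y_star)) < 2:
            # constant resample: residuals are constant, statistic is 0
            f_star = 0.0
        else:
            fit_star = fit_null_logistic(y_star, X)
            f_star, _ = stat_for(y_star - fit_star.fitted_probs)
        if f_star >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + B) if add_one else exceed / B
    return PseudoFResult(
        statistic=f_obs,
        variant=variant,
        p_value=float(p),
        n_resamples=B,
        seed=seed,
        resampling="parametric_bootstrap",
        degenerate=degenerate,
    )
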