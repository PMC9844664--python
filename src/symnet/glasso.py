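"""Sparse precision estimation: graphical lasso with an EBIC-selected path.

The estimator maximizes

    log det K - tr(S K) - lambda * sum_{i != j} |k_ij|

over positive-definite K (diagonal unpenalized) by block coordinate
descent: each column in turn is updated by solving a lasso regression
against the current covariance estimate W (Friedman-style), with W's
diagonal fixed at S's.  The lambda path is solved warm-started from the
empty model downwards, and the extended BIC

    EBIC = -2 l(K) + E log n + 4 gamma E log p,   l(K) = (n/2)(log det K - tr(S K))

selects the penalty; gamma = 0.5 is the conservative field default.

The inner loops are numba-compiled: resampling procedures refit the whole
path tens of thousands of times, so the path must cost milliseconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = ["GlassoFit", "graphical_lasso", "glasso_path", "ebic_score"]

#: off-diagonal entries at or below this are treated as absent edges
SUPPORT_TOL = 1e-6


@njit(cache=True)
def _bcd(S, lam, W, Beta, tol, max_iter):  # pragma: no cover - jitted
    p = S.shape[0]
    final_delta = 0.0
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            # lasso for column j by coordinate descent on Beta[:, j]
            for _inner in range(200):
                delta_b = 0.0
                for t in range(p):
                    if t == j:
                        continue
                    acc = 0.0
                    for k2 in range(p):
                        if k2 == j or k2 == t:
                            continue
                        acc += W[t, k2] * Beta[k2, j]
                    r = S[t, j] - acc
                    if r > lam:
                        b_new = (r - lam) / W[t, t]
                    elif r < -lam:
                        b_new = (r + lam) / W[t, t]
                    else:
                        b_new = 0.0
                    d = abs(b_new - Beta[t, j])
                    if d > delta_b:
                        delta_b = d
                    Beta[t, j] = b_new
                if delta_b < 0.1 * tol:
                    break
            # W[., j] <- W_11 beta
            for t in range(p):
                if t == j:
                    continue
                acc = 0.0
                for k2 in range(p):
                    if k2 == j:
                        continue
                    acc += W[t, k2] * Beta[k2, j]
                d = abs(acc - W[t, j])
                if d > max_delta:
                    max_delta = d
                W[t, j] = acc
                W[j, t] = acc
        final_delta = max_delta
        if max_delta < tol:
            return final_delta
    return final_delta


@njit(cache=True)
def _precision_from_wb(W, Beta):  # pragma: no cover - jitted
    p = W.shape[0]
    K = np.zeros((p, p))
    for j in range(p):
        acc = 0.0
        for t in range(p):
            if t != j:
                acc += W[t, j] * Beta[t, j]
        kjj = 1.0 / (W[j, j] - acc)
        K[j, j] = kjj
        for t in range(p):
            if t != j:
                K[t, j] = -Beta[t, j] * kjj
    return K


@dataclass
class GlassoFit:
    """One penalized fit: precision estimate and model-selection bookkeeping."""

    lam: float
    K: np.ndarray
    loglik: float | None = None   # (n/2)(log det K - tr(S K)), set when n known
    ebic: float | None = None
    edge_count: int = 0
    converged: bool = True
    labels: list[str] = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.K.shape[0]

    def partial_correlations(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.K))
        W = -self.K / np.outer(d, d)
        np.fill_diagonal(W, 0.0)
        return W


def _validate_S(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("S must be symmetric")
    w_min = float(np.linalg.eigvalsh(S).min())
    if w_min < -1e-8:
        raise ValueError(
            f"S is not positive semidefinite (min eig {w_min:.3g}); "
            "apply a nearest-PSD repair before the graphical lasso"
        )
    return S


def _finalize(K: np.ndarray, lam: float, converged: bool = True) -> GlassoFit:
    K = (K + K.T) / 2.0
    off = ~np.eye(K.shape[0], dtype=bool)
    K[off & (np.abs(K) <= SUPPORT_TOL)] = 0.0
    edge_count = int(np.count_nonzero(np.triu(K, k=1)))
    return GlassoFit(lam=lam, K=K, edge_count=edge_count, converged=converged)


def graphical_lasso(
    S,
    lam: float,
    *,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> GlassoFit:
    """Single graphical-lasso fit at penalty ``lam``.

    ``lam = 0`` is the unpenalized Gaussian MLE, i.e. ``inv(S)`` (requires
    an invertible S).  Raises if S is not PSD or if block coordinate
    descent fails to converge.
    """
    S = _validate_S(S)
    if not np.isfinite(lam) or lam < 0:
        raise ValueError("lambda must be a nonnegative finite number")
    p = S.shape[0]
    if lam == 0.0:
        w_min = float(np.linalg.eigvalsh(S).min())
        if w_min < 1e-10:
            raise ValueError("lambda = 0 requires an invertible S")
        return _finalize(np.linalg.inv(S), 0.0)
    W = S.copy()
    Beta = np.zeros((p, p))
    gap = _bcd(S, lam, W, Beta, tol, max_iter)
    if gap >= tol:
        raise RuntimeError(
            f"graphical lasso did not converge at lambda={lam:.4g} "
            f"(last parameter change {gap:.3g} >= tol {tol:.3g})"
        )
    return _finalize(_precision_from_wb(W, Beta), lam)


def ebic_score(fit: GlassoFit, S, n: int, gamma: float = 0.5) -> float:
    """Extended BIC of a fit: ``-2 l + E log n + 4 gamma E log p``.

    Also fills in ``fit.loglik`` and ``fit.ebic`` as a side effect.
    """
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    S = np.asarray(S, dtype=float)
    p = fit.p
    if n < p:
        warnings.warn(f"EBIC computed with n={n} < p={p}", stacklevel=2)
    sign, logdet = np.linalg.slogdet(fit.K)
    if sign <= 0:
        raise ValueError("precision estimate is not positive definite")
    loglik = 0.5 * n * (logdet - float(np.sum(S * fit.K)))
    E = fit.edge_count
    ebic = -2.0 * loglik + E * np.log(n) + 4.0 * gamma * E * np.log(p)
    fit.loglik = float(loglik)
    fit.ebic = float(ebic)
    return float(ebic)


def lambda_path(S, n_lambda: int = 100, lambda_min_ratio: float = 0.01) -> np.ndarray:
    """Log-spaced descending penalty grid from lambda_max = max |S_ij|, i != j."""
    S = np.asarray(S, dtype=float)
    lam_max = float(np.max(np.abs(np.triu(S, k=1))))
    if lam_max <= 0:
        return np.array([0.0])
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


def glasso_path(
    S,
    n: int,
    *,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> tuple[list[GlassoFit], GlassoFit]:
    """Fit the whole penalty path (warm-started) and select by minimum EBIC.

    Returns ``(fits, selected)`` with fits ordered from sparsest (largest
    lambda) to densest.  Ties on EBIC go to the sparser model.
    """
    S = _validate_S(S)
    if n_lambda < 2 and float(np.max(np.abs(np.triu(S, k=1)))) > 0:
        raise ValueError("n_lambda must be >= 2")
    if not 0 < lambda_min_ratio < 1:
        raise ValueError("lambda_min_ratio must lie in (0, 1)")
    p = S.shape[0]
    lams = lambda_path(S, n_lambda, lambda_min_ratio)
    fits: list[GlassoFit] = []
    W = S.copy()
    Beta = np.zeros((p, p))
    n_failed = 0
    for lam in lams:
        if lam == 0.0:
            fit = graphical_lasso(S, 0.0)
        else:
            gap = _bcd(S, lam, W, Beta, tol, max_iter)
            if gap >= tol:
                n_failed += 1
                continue
            fit = _finalize(_precision_from_wb(W.copy(), Beta.copy()), float(lam))
        ebic_score(fit, S, n, gamma)
        fits.append(fit)
    if not fits:
        raise RuntimeError("graphical lasso failed to converge at every lambda")
    best = min(fits, key=lambda f: (f.ebic, f.edge_count))
    return fits, best
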