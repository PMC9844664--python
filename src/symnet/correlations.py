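"""Correlation estimation for ordinal symptom data.

Severity items on a 0-10 scale are ordinal: Pearson correlations of the raw
scores understate the association between the latent symptom intensities,
especially for zero-inflated items.  Two estimators are provided:

* Spearman rank correlation (used for the network-density statistic and as a
  fast input to the network estimator), and
* polychoric correlation, the ML correlation of a latent bivariate normal
  assumed to underlie each pair of ordinal items, estimated in two stages
  (thresholds from the margins, then a 1-D likelihood maximization in rho).

Pairwise polychoric matrices need not be positive semidefinite, so a
nearest-PSD repair (eigenvalue clipping, then rescaling to unit diagonal)
is applied before the matrix is handed to the graphical-lasso stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import ndtr, ndtri, owens_t

__all__ = [
    "CorrelationMatrix",
    "spearman_matrix",
    "polychoric_rho",
    "polychoric_matrix",
    "bivariate_normal_cdf",
    "nearest_psd",
]

#: |rho| is restricted to this open interval; degenerate tables clamp here.
RHO_BOUND = 0.999

#: thresholds beyond this many SDs are treated as infinite (Phi saturates).
_THRESH_CLAMP = 12.0


@dataclass
class CorrelationMatrix:
    """A symmetric correlation matrix with provenance flags.

    Attributes
    ----------
    R : (p, p) ndarray
        Symmetric, unit diagonal, entries in [-1, 1].
    labels : list of str
        Variable names, one per row/column.
    method : str
        ``"spearman"``, ``"polychoric"`` or ``"pearson"``.
    n_effective : int
        Number of rows the estimate used (after listwise deletion).
    psd_repaired : bool
        True iff the nearest-PSD repair changed any entry.
    flagged_pairs : list of tuple
        Pairs whose estimate needed special handling (zero variance,
        boundary clamp), as ``(label_i, label_j, reason)``.
    """

    R: np.ndarray
    labels: list[str]
    method: str
    n_effective: int
    psd_repaired: bool = False
    flagged_pairs: list[tuple] = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.R.shape[0]

    def to_csv(self, path) -> None:
        """Labeled CSV plus a JSON sidecar with method and flags."""
        import json

        import pandas as pd

        path = str(path)
        pd.DataFrame(self.R, index=self.labels, columns=self.labels).to_csv(path)
        sidecar = {
            "method": self.method,
            "n_effective": int(self.n_effective),
            "psd_repaired": bool(self.psd_repaired),
            "flagged_pairs": [list(f) for f in self.flagged_pairs],
        }
        with open(path + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        self.R = R


def spearman_matrix(values, labels=None) -> CorrelationMatrix:
    """Pairwise Spearman rank correlation with average ranks for ties.

    Zero-variance columns get correlation 0 with every other column (the
    rank correlation is undefined there; 0 keeps the matrix usable) and are
    flagged.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected an n x p matrix")
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 observations for Spearman correlation")
    if labels is None:
        labels = [f"v{i}" for i in range(p)]

    # Spearman == Pearson on average-ranked columns.
    ranks = np.empty_like(X)
    for j in range(p):
        ranks[:, j] = stats.rankdata(X[:, j], method="average")
    sd = ranks.std(axis=0)
    flagged = [(labels[j], labels[j], "zero variance") for j in np.nonzero(sd == 0)[0]]
    safe = sd > 0
    R = np.eye(p)
    if safe.sum() >= 2:
        sub = np.corrcoef(ranks[:, safe], rowvar=False)
        R[np.ix_(safe, safe)] = sub
    np.fill_diagonal(R, 1.0)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return CorrelationMatrix(R, list(labels), "spearman", n, False, flagged)


def bivariate_normal_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Closed-form identity via Owen's T function; vectorized over h and k.
    Thresholds with |.| > 12 are saturated.  Accuracy ~1e-14 away from
    |rho| = 1; rho is clipped to +-0.9999.
    """
    h = np.clip(np.asarray(h, dtype=float), -_THRESH_CLAMP, _THRESH_CLAMP)
    k = np.clip(np.asarray(k, dtype=float), -_THRESH_CLAMP, _THRESH_CLAMP)
    rho = float(np.clip(rho, -0.9999, 0.9999))
    if abs(rho) < 1e-14:
        return ndtr(h) * ndtr(k)
    # Owen (1956): Phi2 = (Phi(h)+Phi(k))/2 - T(h,a_h) - T(k,a_k) - c,
    # c = 1/2 iff h*k < 0 (or one is 0 and h+k < 0).  Exact zeros are
    # perturbed; Phi2 is continuous so the error is O(1e-13).
    h = np.where(h == 0.0, 1e-13, h)
    k = np.where(k == 0.0, 1e-13, k)
    r = np.sqrt(1.0 - rho * rho)
    a_h = (k - rho * h) / (h * r)
    a_k = (h - rho * k) / (k * r)
    c = np.where(h * k < 0.0, 0.5, 0.0)
    out = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(h, a_h) - owens_t(k, a_k) - c
    return np.clip(out, 0.0, 1.0)


def _cell_probabilities(row_thresh, col_thresh, rho):
    """Rectangle probabilities of a bivariate normal over a threshold grid.

    ``row_thresh``/``col_thresh`` are the interior cutpoints (finite,
    increasing); the implicit outer cutpoints are +-inf.
    """
    a = np.concatenate(([-_THRESH_CLAMP], row_thresh, [_THRESH_CLAMP]))
    b = np.concatenate(([-_THRESH_CLAMP], col_thresh, [_THRESH_CLAMP]))
    F = bivariate_normal_cdf(a[:, None], b[None, :], rho)
    P = F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]
    return np.clip(P, 1e-320, 1.0)


def polychoric_rho(table, *, tol: float = 1e-6, return_flag: bool = False):
    """Two-stage ML polychoric correlation from a two-way contingency table.

    Stage 1 fixes the thresholds at the normal quantiles of the cumulative
    marginal proportions; stage 2 maximizes the multinomial likelihood of
    the bivariate-normal cell probabilities over rho in (-0.999, 0.999) by
    bounded scalar search.

    Empty marginal categories are dropped first (the likelihood is invariant
    to merging them).  A margin with a single observed category leaves rho
    undefined and raises; a degenerate table drives rho to the boundary,
    where it is clamped at +-0.999 and flagged.
    """
    N = np.asarray(table, dtype=float)
    if N.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if np.any(N < 0) or not np.all(np.isfinite(N)):
        raise ValueError("contingency table must hold nonnegative finite counts")
    N = N[N.sum(axis=1) > 0][:, N.sum(axis=0) > 0]
    if N.shape[0] < 2 or N.shape[1] < 2:
        raise ValueError(
            "polychoric correlation undefined: a margin has a single observed category"
        )
    n = N.sum()
    row_cum = np.cumsum(N.sum(axis=1))[:-1] / n
    col_cum = np.cumsum(N.sum(axis=0))[:-1] / n
    row_thresh = ndtri(row_cum)
    col_thresh = ndtri(col_cum)
    obs = N > 0

    def nll(rho: float) -> float:
        P = _cell_probabilities(row_thresh, col_thresh, rho)
        return -float(np.sum(N[obs] * np.log(P[obs])))

    res = minimize_scalar(
        nll, bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
        options={"xatol": tol},
    )
    rho = float(res.x)
    clamped = abs(rho) >= RHO_BOUND - 10 * tol
    if clamped:
        rho = float(np.sign(rho) * RHO_BOUND)
    if return_flag:
        return rho, clamped
    return rho


def _crosstab(x, y):
    """Contingency table of two small nonnegative integer vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    xi, xinv = np.unique(x, return_inverse=True)
    yi, yinv = np.unique(y, return_inverse=True)
    tab = np.zeros((len(xi), len(yi)))
    np.add.at(tab, (xinv, yinv), 1.0)
    return tab


def nearest_psd(R, *, clip: float = 1e-6):
    """Eigenvalue-clipped PSD repair, rescaled back to unit diagonal.

    Returns ``(repaired, changed)`` where ``changed`` is True iff clipping
    altered the matrix beyond numerical noise.
    """
    R = np.asarray(R, dtype=float)
    w, V = np.linalg.eigh((R + R.T) / 2.0)
    if w.min() >= clip:
        return R.copy(), False
    w_clipped = np.maximum(w, clip)
    A = (V * w_clipped) @ V.T
    d = np.sqrt(np.diag(A))
    A = A / np.outer(d, d)
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 1.0)
    return A, True


def polychoric_matrix(values, labels=None, *, tol: float = 1e-6) -> CorrelationMatrix:
    """Pairwise polychoric correlation matrix with PSD repair.

    Any pairwise failure is re-raised naming the offending pair.
    """
    X = np.asarray(values)
    if X.ndim != 2:
        raise ValueError("expected an n x p matrix")
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 observations")
    if labels is None:
        labels = [f"v{i}" for i in range(p)]

    R = np.eye(p)
    flagged: list[tuple] = []
    for i in range(p):
        for j in range(i + 1, p):
            try:
                rho, clamped = polychoric_rho(
                    _crosstab(X[:, i], X[:, j]), tol=tol, return_flag=True
                )
            except ValueError as err:
                raise ValueError(
                    f"polychoric estimation failed for pair "
                    f"({labels[i]}, {labels[j]}): {err}"
                ) from err
            if clamped:
                flagged.append((labels[i], labels[j], "boundary clamp"))
            R[i, j] = R[j, i] = rho
    repaired, changed = nearest_psd(R)
    return CorrelationMatrix(repaired, list(labels), "polychoric", n, changed, flagged)
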