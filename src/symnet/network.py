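"""Contemporaneous symptom-network estimation.

The network is the partial-correlation graph of the EBIC-selected graphical
lasso fit: edge weight ``w_ij = -k_ij / sqrt(k_ii k_jj)`` encodes the
conditional association between symptoms i and j given all other nodes.

Covariate control.  Screened covariates enter the correlation matrix as
extra nodes (polychoric/Spearman among symptoms; Pearson-on-ranks for any
pair involving a covariate), the joint precision matrix is estimated, and
the symptom-by-symptom block of the partial-correlation matrix is returned
- its edges are therefore conditioned on the covariates.  An alternative
``residualize`` mode (rank-transform symptoms, regress out the covariates,
correlate residuals) is kept for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from symnet.correlations import (
    CorrelationMatrix,
    nearest_psd,
    polychoric_matrix,
    spearman_matrix,
)
from symnet.dataset import SymptomDataset
from symnet.glasso import GlassoFit, glasso_path

__all__ = ["EstimationSettings", "PCorNetwork", "estimate_network",
           "mixed_correlation_matrix"]


@dataclass
class EstimationSettings:
    """Tuning knobs of the network estimator.

    correlation_method : "polychoric" (default) or "spearman"
    gamma : EBIC sparsity hyperparameter (0.5 = conservative default)
    n_lambda, lambda_min_ratio : geometry of the penalty path
    covariate_mode : "as_nodes" (default) or "residualize"
    """

    correlation_method: str = "polychoric"
    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    covariate_mode: str = "as_nodes"

    def __post_init__(self) -> None:
        if self.correlation_method not in ("polychoric", "spearman"):
            raise ValueError("correlation_method must be 'polychoric' or 'spearman'")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must lie in (0, 1)")
        if self.covariate_mode not in ("as_nodes", "residualize"):
            raise ValueError("covariate_mode must be 'as_nodes' or 'residualize'")


@dataclass
class PCorNetwork:
    """A symmetric partial-correlation network over the symptom nodes."""

    W: np.ndarray
    labels: list[str]
    lambda_selected: float
    gamma: float
    conditioned_on: list[str] = field(default_factory=list)
    fit: GlassoFit | None = None
    correlation: CorrelationMatrix | None = None
    full_W: np.ndarray | None = None
    full_labels: list[str] | None = None

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if not np.allclose(W, W.T, atol=1e-8):
            raise ValueError("edge-weight matrix must be symmetric")
        if np.any(np.abs(np.diag(W)) > 1e-12):
            raise ValueError("edge-weight matrix must have zero diagonal")
        if np.any(np.abs(W) >= 1.0):
            raise ValueError("partial correlations must have magnitude < 1")
        self.W = (W + W.T) / 2.0
        np.fill_diagonal(self.W, 0.0)

    @property
    def p(self) -> int:
        return self.W.shape[0]

    def edge_weights(self) -> np.ndarray:
        """Upper-triangle edge weights, row-major pair order."""
        return self.W[np.triu_indices(self.p, k=1)]

    def edge_labels(self) -> list[tuple[str, str]]:
        iu = np.triu_indices(self.p, k=1)
        return [(self.labels[i], self.labels[j]) for i, j in zip(*iu)]

    def edge_list(self) -> list[tuple[str, str, float]]:
        """Present edges only (nonzero weights)."""
        iu = np.triu_indices(self.p, k=1)
        return [
            (self.labels[i], self.labels[j], float(self.W[i, j]))
            for i, j in zip(*iu)
            if self.W[i, j] != 0.0
        ]

    def to_graph(self):
        """networkx.Graph with ``weight`` and ``length`` (1/|w|) attributes."""
        import networkx as nx

        G = nx.Graph()
        G.add_nodes_from(self.labels)
        for a, b, w in self.edge_list():
            G.add_edge(a, b, weight=w, length=1.0 / abs(w))
        return G


def _rank_transform(values: np.ndarray) -> np.ndarray:
    out = np.empty(values.shape, dtype=float)
    for j in range(values.shape[1]):
        out[:, j] = stats.rankdata(values[:, j], method="average")
    return out


def mixed_correlation_matrix(
    data: SymptomDataset, covariates: list[str], method: str
) -> CorrelationMatrix:
    """Correlation matrix over symptom nodes plus covariate nodes.

    ``method`` governs the symptom-symptom block; every pair involving a
    covariate uses Pearson on average ranks (= Spearman), which respects
    the ordinal margins without assuming a latent normal for e.g. binary
    therapy indicators.
    """
    X_sym = data.values().astype(float)
    labels = data.item_labels + list(covariates)
    blocks = [X_sym]
    if covariates:
        blocks.append(data.covariates[list(covariates)].to_numpy(dtype=float))
    X_all = np.column_stack(blocks)

    rank_cm = spearman_matrix(X_all, labels=labels)
    if method == "spearman":
        return rank_cm
    p_sym = X_sym.shape[1]
    R = rank_cm.R.copy()
    poly = polychoric_matrix(X_sym, labels=data.item_labels)
    R[:p_sym, :p_sym] = poly.R
    repaired, changed = nearest_psd(R)
    return CorrelationMatrix(
        repaired, labels, "polychoric", data.n,
        changed or poly.psd_repaired, poly.flagged_pairs + rank_cm.flagged_pairs,
    )


def _residualized_correlation(
    data: SymptomDataset, covariates: list[str]
) -> CorrelationMatrix:
    ranks = _rank_transform(data.values().astype(float))
    Z = data.covariates[list(covariates)].to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(ranks)), Z])
    coef, *_ = np.linalg.lstsq(design, ranks, rcond=None)
    resid = ranks - design @ coef
    sd = resid.std(axis=0)
    sd[sd == 0] = 1.0
    R = np.corrcoef(resid / sd, rowvar=False)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    repaired, changed = nearest_psd(R)
    return CorrelationMatrix(
        repaired, data.item_labels, "pearson", data.n, changed
    )


def estimate_network(
    data: SymptomDataset,
    settings: EstimationSettings | None = None,
    covariates: list[str] | None = None,
    *,
    tol: float = 1e-5,
) -> PCorNetwork:
    """Estimate the symptom partial-correlation network.

    ``covariates=None`` conditions on every covariate the dataset carries;
    pass an explicit list (possibly empty) to control the conditioning set.
    """
    settings = settings or EstimationSettings()
    if data.p < 2:
        raise ValueError("need at least 2 symptom columns")
    if covariates is None:
        covariates = data.covariate_labels
    missing = [c for c in covariates if c not in data.covariate_labels]
    if missing:
        raise ValueError(f"covariates not present in dataset: {missing}")

    if covariates and settings.covariate_mode == "residualize":
        cm = _residualized_correlation(data, covariates)
        node_labels = data.item_labels
    else:
        cm = mixed_correlation_matrix(data, list(covariates), settings.correlation_method)
        node_labels = cm.labels

    fits, best = glasso_path(
        cm.R,
        n=data.n,
        gamma=settings.gamma,
        n_lambda=settings.n_lambda,
        lambda_min_ratio=settings.lambda_min_ratio,
        tol=tol,
    )
    W_full = best.partial_correlations()
    p_sym = data.p
    W_sym = W_full[:p_sym, :p_sym].copy()
    np.fill_diagonal(W_sym, 0.0)
    return PCorNetwork(
        W=W_sym,
        labels=data.item_labels,
        lambda_selected=float(best.lam),
        gamma=settings.gamma,
        conditioned_on=list(covariates),
        fit=best,
        correlation=cm,
        full_W=W_full,
        full_labels=list(node_labels),
    )
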