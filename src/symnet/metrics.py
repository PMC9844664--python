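"""Network metrics: centrality, density, and node predictability.

Distances use edge length 1/|w|, so strong conditional associations are
short.  Conventions (documented because the literature varies):

* strength r_s = sum_j |w_ij|; expected influence = sum_j w_ij (signed);
* closeness r_c = 1 / (total shortest-path distance to *reachable* nodes),
  0 for an isolated node — the sum-reciprocal convention of the software
  family standard in psychometric network analysis (a mean-based variant
  differs only by a per-node constant factor);
* betweenness r_b counts node pairs whose shortest path passes through the
  node, with fractional credit when several shortest paths tie;
* density = sum of absolute pairwise coefficients, by default over the
  Spearman correlation matrix (the prognosis-linked definition), with the
  network edge weights available as an alternative basis;
* predictability R^2_i = variance of node i's rank-transformed score
  explained by OLS on its network neighbours' rank-transformed scores
  (0 for an isolated node) — a desk-scale stand-in for a full nodewise
  mixed-model refit that reproduces the quantity's meaning.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from symnet.correlations import CorrelationMatrix
from symnet.dataset import SymptomDataset
from symnet.network import PCorNetwork

__all__ = [
    "CentralityTable",
    "DensityValue",
    "shortest_path_distances",
    "centrality_table",
    "network_density",
    "node_predictability",
]


def shortest_path_distances(net: PCorNetwork) -> np.ndarray:
    """All-pairs shortest-path distances with edge length 1/|w_ij|.

    Unreachable pairs are +inf; the diagonal is 0.
    """
    W = np.abs(net.W)
    lengths = np.zeros_like(W)
    nz = W > 0
    lengths[nz] = 1.0 / W[nz]
    D = dijkstra(csr_matrix(lengths), directed=False)
    np.fill_diagonal(D, 0.0)
    return D


@dataclass
class CentralityTable:
    """Per-node centrality indices."""

    table: pd.DataFrame  # index: node; columns: strength, closeness, betweenness, expected_influence

    def __getitem__(self, col: str) -> np.ndarray:
        return self.table[col].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="node")


def centrality_table(net: PCorNetwork) -> CentralityTable:
    W = net.W
    strength = np.abs(W).sum(axis=1)
    expected_influence = W.sum(axis=1)

    D = shortest_path_distances(net)
    closeness = np.zeros(net.p)
    for i in range(net.p):
        d = D[i]
        reach = np.isfinite(d) & (np.arange(net.p) != i)
        total = d[reach].sum()
        closeness[i] = 1.0 / total if total > 0 else 0.0

    G = net.to_graph()
    bc = nx.betweenness_centrality(G, weight="length", normalized=False)
    betweenness = np.array([bc[lab] for lab in net.labels])

    df = pd.DataFrame(
        {
            "strength": strength,
            "closeness": closeness,
            "betweenness": betweenness,
            "expected_influence": expected_influence,
        },
        index=pd.Index(net.labels, name="node"),
    )
    return CentralityTable(df)


@dataclass
class DensityValue:
    """Sum of absolute pairwise coefficients over all node pairs."""

    value: float
    basis: str  # "spearman" or "edge_weights"


def network_density(obj, basis: str = "spearman") -> DensityValue:
    """Density = sum_{i<j} |coefficient_ij|.

    ``obj`` may be a CorrelationMatrix (typically Spearman, the default
    basis and the definition used for prognosis comparisons), a PCorNetwork
    (basis "edge_weights"), or a bare square symmetric matrix.
    """
    if isinstance(obj, PCorNetwork):
        M = obj.W
        basis = "edge_weights"
    elif isinstance(obj, CorrelationMatrix):
        M = obj.R
    else:
        M = np.asarray(obj, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("density needs a square matrix")
    iu = np.triu_indices(M.shape[0], k=1)
    return DensityValue(float(np.abs(M[iu]).sum()), basis)


@dataclass
class PredictabilityTable:
    table: pd.DataFrame  # index node; columns r_squared, n_neighbors, flagged

    def __getitem__(self, col: str) -> np.ndarray:
        return self.table[col].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="node")


def node_predictability(data: SymptomDataset, net: PCorNetwork) -> PredictabilityTable:
    """R^2 of each node given its network neighbours (rank-transformed OLS)."""
    if list(data.item_labels) != list(net.labels):
        raise ValueError("dataset and network labels disagree")
    X = data.values().astype(float)
    ranks = np.column_stack(
        [stats.rankdata(X[:, j], method="average") for j in range(X.shape[1])]
    )
    n = ranks.shape[0]
    r2 = np.zeros(net.p)
    n_nb = np.zeros(net.p, dtype=int)
    flagged = np.zeros(net.p, dtype=bool)
    for i in range(net.p):
        nb = np.nonzero(net.W[i] != 0)[0]
        n_nb[i] = len(nb)
        if len(nb) == 0:
            continue
        y = ranks[:, i]
        sst = float(np.sum((y - y.mean()) ** 2))
        if sst == 0:
            flagged[i] = True
            continue
        design = np.column_stack([np.ones(n), ranks[:, nb]])
        coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        if rank < design.shape[1]:
            flagged[i] = True  # collinear neighbours; minimum-norm fit used
        resid = y - design @ coef
        r2[i] = max(0.0, min(1.0, 1.0 - float(np.sum(resid**2)) / sst))
    df = pd.DataFrame(
        {"r_squared": r2, "n_neighbors": n_nb, "flagged": flagged},
        index=pd.Index(net.labels, name="node"),
    )
    return PredictabilityTable(df)
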