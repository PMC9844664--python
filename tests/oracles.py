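"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the penalized-likelihood
oracle is a generic box-constrained optimizer over the free entries of K,
and the centrality oracle enumerates every simple path explicitly.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy.optimize import minimize


def direct_glasso(S: np.ndarray, lam: float) -> np.ndarray:
    """Maximize log det K - tr(SK) - lam * sum_{i!=j} |k_ij| directly.

    Off-diagonal entries are split k = a - b with a, b >= 0, which makes
    the objective smooth on the feasible box; -log det acts as the PD
    barrier.  L-BFGS-B with the analytic gradient.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    iu = np.triu_indices(p, k=1)
    m = len(iu[0])

    def unpack(x):
        K = np.zeros((p, p))
        K[np.diag_indices(p)] = x[:p]
        off = x[p:p + m] - x[p + m:]
        K[iu] = off
        K.T[iu] = off
        return K

    def fun(x):
        K = unpack(x)
        sign, logdet = np.linalg.slogdet(K)
        if sign <= 0:
            return 1e10
        return -(logdet - np.sum(S * K)) + 2.0 * lam * np.sum(x[p:])

    def grad(x):
        K = unpack(x)
        sign, _ = np.linalg.slogdet(K)
        if sign <= 0:
            return np.zeros_like(x)
        G = S - np.linalg.inv(K)
        go = 2.0 * G[iu]
        return np.concatenate([np.diag(G), go + 2.0 * lam, -go + 2.0 * lam])

    x0 = np.concatenate([np.ones(p), np.zeros(2 * m)])
    bounds = [(1e-6, None)] * p + [(0.0, None)] * (2 * m)
    res = minimize(fun, x0, jac=grad, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-12})
    return unpack(res.x)


def _all_simple_paths(p: int, i: int, j: int):
    """Every simple path i -> j as a node sequence (exhaustive)."""
    others = [k for k in range(p) if k not in (i, j)]
    for r in range(len(others) + 1):
        for mid in permutations(others, r):
            yield (i, *mid, j)


def brute_force_centrality(W: np.ndarray, tie_tol: float = 1e-9):
    """Strength, closeness and betweenness by exhaustive path enumeration.

    Edge length is 1/|w|; betweenness gives fractional credit to tied
    shortest paths; closeness is the reciprocal of the summed distance to
    reachable nodes (0 when isolated).
    """
    p = W.shape[0]
    lengths = np.full((p, p), np.inf)
    nz = W != 0
    lengths[nz] = 1.0 / np.abs(W[nz])

    dist = np.full((p, p), np.inf)
    np.fill_diagonal(dist, 0.0)
    shortest_paths: dict[tuple[int, int], list[tuple]] = {}
    for i in range(p):
        for j in range(i + 1, p):
            best, paths = np.inf, []
            for path in _all_simple_paths(p, i, j):
                d = sum(lengths[a, b] for a, b in zip(path, path[1:]))
                if d < best - tie_tol:
                    best, paths = d, [path]
                elif d <= best + tie_tol:
                    paths.append(path)
            dist[i, j] = dist[j, i] = best
            if np.isfinite(best):
                shortest_paths[(i, j)] = paths

    strength = np.abs(W).sum(axis=1)
    closeness = np.zeros(p)
    for i in range(p):
        reach = [j for j in range(p) if j != i and np.isfinite(dist[i, j])]
        total = sum(dist[i, j] for j in reach)
        closeness[i] = 1.0 / total if total > 0 else 0.0
    betweenness = np.zeros(p)
    for (i, j), paths in shortest_paths.items():
        for path in paths:
            for mid in path[1:-1]:
                betweenness[mid] += 1.0 / len(paths)
    return strength, closeness, betweenness, dist


def random_weighted_network(p: int, rng: np.random.Generator, density: float = 0.5):
    """Random symmetric weight matrix with |w| in (0.1, 0.9), zero diagonal."""
    W = np.zeros((p, p))
    iu = np.triu_indices(p, k=1)
    present = rng.random(len(iu[0])) < density
    w = rng.uniform(0.1, 0.9, len(iu[0])) * rng.choice([-1, 1], len(iu[0]))
    vals = np.where(present, w, 0.0)
    W[iu] = vals
    W.T[iu] = vals
    return W
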