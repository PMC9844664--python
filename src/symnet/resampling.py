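"""Accuracy, stability and comparison machinery.

* edge-weight accuracy: nonparametric bootstrap (rows resampled with
  replacement, the whole network re-estimated per replicate with its own
  EBIC-selected penalty) and percentile 95% CIs per edge;
* centrality stability: case-dropping subset bootstrap and the
  correlation-stability (CS) coefficient — the largest proportion of cases
  that can be dropped such that >= 95% of replicates correlate >= 0.7 with
  the full-sample statistic (> 0.5 preferred, > 0.25 minimum);
* bootstrapped difference tests between edges (or nodes): significant when
  the percentile interval of the bootstrap difference excludes 0;
* subgroup density contrast: label-permutation test on the absolute
  difference of Spearman-basis densities, with the add-one p-value.

Randomness: every replicate draws from its own counter-derived stream
(``default_rng([seed, ...counters])``), so results are reproducible and
enlarging B extends, rather than reshuffles, the replicate set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from symnet.correlations import spearman_matrix
from symnet.dataset import SymptomDataset
from symnet.metrics import centrality_table, network_density
from symnet.network import EstimationSettings, PCorNetwork, estimate_network

__all__ = [
    "EdgeBootstrap",
    "StabilityResult",
    "DiffMatrix",
    "PermutationResult",
    "bootstrap_edge_ci",
    "case_dropping_stability",
    "bootstrap_difference_test",
    "density_comparison_test",
    "DEFAULT_DROP_GRID",
]

#: case-dropping grid: 10% to 75% of cases dropped, in 5% steps
DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.10, 0.751, 0.05), 2))


@dataclass
class EdgeBootstrap:
    """Bootstrap distribution of the edge weights."""

    replicate_weights: np.ndarray          # (B_effective, E)
    estimates: np.ndarray                  # (E,) full-sample weights
    ci_low: np.ndarray
    ci_high: np.ndarray
    edge_labels: list[tuple[str, str]]
    B: int
    seed: int
    n_failed: int = 0

    def summary_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "edge": [f"{a}--{b}" for a, b in self.edge_labels],
                "estimate": self.estimates,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def _refit_weights(data, rows, settings, covariates, tol):
    net = estimate_network(data.subset(rows), settings, covariates, tol=tol)
    return net


def bootstrap_edge_ci(
    data: SymptomDataset,
    settings: EstimationSettings | None = None,
    B: int = 1000,
    seed: int = 0,
    covariates: list[str] | None = None,
    *,
    tol: float = 1e-5,
    max_failure_rate: float = 0.10,
) -> EdgeBootstrap:
    """Nonparametric bootstrap of the network; percentile 95% CIs per edge.

    Replicates whose estimation fails are dropped and counted; more than
    ``max_failure_rate`` failures aborts.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if B < 100:
        warnings.warn(f"B={B} is small for confidence intervals", stacklevel=2)
    settings = settings or EstimationSettings()
    full = estimate_network(data, settings, covariates, tol=tol)
    estimates = full.edge_weights()
    reps = []
    n_failed = 0
    for b in range(B):
        rng = np.random.default_rng([seed, 1, b])
        rows = rng.integers(0, data.n, size=data.n)
        try:
            net_b = _refit_weights(data, rows, settings, covariates, tol)
            reps.append(net_b.edge_weights())
        except Exception:
            n_failed += 1
    if n_failed > max_failure_rate * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap replicates failed (> {max_failure_rate:.0%})"
        )
    R = np.vstack(reps)
    ci_low = np.percentile(R, 2.5, axis=0)
    ci_high = np.percentile(R, 97.5, axis=0)
    return EdgeBootstrap(
        replicate_weights=R,
        estimates=estimates,
        ci_low=ci_low,
        ci_high=ci_high,
        edge_labels=full.edge_labels(),
        B=B,
        seed=seed,
        n_failed=n_failed,
    )


@dataclass
class StabilityResult:
    """Case-dropping correlation curves and the CS coefficient."""

    statistic: str
    drop_proportions: np.ndarray           # grid actually evaluated
    correlations: np.ndarray               # (n_proportions, B)
    cs_coefficient: float
    skipped_proportions: list[float] = field(default_factory=list)
    n_degenerate: int = 0                  # replicates with undefined correlation

    def retention_curve(self) -> np.ndarray:
        """Share of replicates with correlation >= 0.7, per proportion."""
        return (self.correlations >= 0.7).mean(axis=1)


_STAT_COLUMNS = {"strength": "strength", "expected_influence": "expected_influence",
                 "closeness": "closeness", "betweenness": "betweenness"}


def _node_statistic(net: PCorNetwork, statistic: str) -> np.ndarray:
    return centrality_table(net)[_STAT_COLUMNS[statistic]]


def case_dropping_stability(
    data: SymptomDataset,
    settings: EstimationSettings | None = None,
    statistic: str = "strength",
    proportions=DEFAULT_DROP_GRID,
    B: int = 1000,
    seed: int = 0,
    covariates: list[str] | None = None,
    *,
    tol: float = 1e-5,
    cs_correlation: float = 0.7,
    cs_confidence: float = 0.95,
) -> StabilityResult:
    """Case-dropping subset bootstrap of a centrality statistic.

    For each drop proportion q, B subsamples of ceil((1-q) n) rows are
    drawn without replacement, the network re-estimated, and the node
    statistic correlated with its full-sample value.  A replicate with a
    constant statistic vector has undefined correlation; it is recorded as
    0 and counted in ``n_degenerate``.
    """
    if statistic not in _STAT_COLUMNS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if B < 100:
        warnings.warn(f"B={B} is small for the CS coefficient", stacklevel=2)
    proportions = np.asarray(sorted(proportions), dtype=float)
    if np.any(proportions <= 0) or np.any(proportions >= 0.95):
        raise ValueError("drop proportions must lie in (0, 0.95)")
    settings = settings or EstimationSettings()

    full = estimate_network(data, settings, covariates, tol=tol)
    ref = _node_statistic(full, statistic)
    ref_sd = ref.std()

    kept_q, rows_of_corr, skipped = [], [], []
    n_degenerate = 0
    for qi, q in enumerate(proportions):
        m = int(np.ceil((1.0 - q) * data.n))
        if m < data.p + 1:
            skipped.append(float(q))
            continue
        corr_b = np.empty(B)
        for b in range(B):
            rng = np.random.default_rng([seed, 2, qi, b])
            rows = rng.choice(data.n, size=m, replace=False)
            try:
                net_b = estimate_network(data.subset(rows), settings, covariates, tol=tol)
                stat_b = _node_statistic(net_b, statistic)
            except Exception:
                corr_b[b] = 0.0
                n_degenerate += 1
                continue
            if ref_sd == 0 or stat_b.std() == 0:
                corr_b[b] = 0.0
                n_degenerate += 1
            else:
                corr_b[b] = float(np.corrcoef(ref, stat_b)[0, 1])
        kept_q.append(float(q))
        rows_of_corr.append(corr_b)

    correlations = np.vstack(rows_of_corr) if rows_of_corr else np.empty((0, B))
    cs = 0.0
    for q, corr_b in zip(kept_q, correlations):
        if np.mean(corr_b >= cs_correlation) >= cs_confidence:
            cs = max(cs, q)
    return StabilityResult(
        statistic=statistic,
        drop_proportions=np.asarray(kept_q),
        correlations=correlations,
        cs_coefficient=cs,
        skipped_proportions=skipped,
        n_degenerate=n_degenerate,
    )


@dataclass
class DiffMatrix:
    """Pairwise bootstrapped difference significance."""

    significant: np.ndarray   # (m, m) bool, symmetric, False diagonal
    alpha: float
    labels: list[str]

    def frame(self):
        import pandas as pd

        return pd.DataFrame(self.significant, index=self.labels, columns=self.labels)


def bootstrap_difference_test(boot, alpha: float = 0.05, labels=None) -> DiffMatrix:
    """Percentile difference test between edges (or node statistics).

    ``boot`` is an :class:`EdgeBootstrap` or a (B, m) replicate matrix.
    Pair (e, f) is significant iff the (alpha/2, 1-alpha/2) percentile
    interval of the bootstrap distribution of ``w_e - w_f`` excludes 0.
    No multiplicity correction is applied.
    """
    if isinstance(boot, EdgeBootstrap):
        R = boot.replicate_weights
        if labels is None:
            labels = [f"{a}--{b}" for a, b in boot.edge_labels]
    else:
        R = np.asarray(boot, dtype=float)
    if R.ndim != 2:
        raise ValueError("replicates must form a (B, m) matrix")
    B, m = R.shape
    if B < 100:
        warnings.warn(f"B={B} is small for difference tests", stacklevel=2)
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if labels is None:
        labels = [f"e{i}" for i in range(m)]
    D = R[:, :, None] - R[:, None, :]
    lo = np.percentile(D, 100 * alpha / 2.0, axis=0)
    hi = np.percentile(D, 100 * (1.0 - alpha / 2.0), axis=0)
    sig = (lo > 0) | (hi < 0)
    sig = sig | sig.T
    np.fill_diagonal(sig, False)
    return DiffMatrix(significant=sig, alpha=alpha, labels=list(labels))


@dataclass
class PermutationResult:
    """Observed density difference and its permutation null."""

    observed_diff: float
    null_draws: np.ndarray
    p_value: float
    groups: tuple[str, str]
    densities: dict[str, float] = field(default_factory=dict)


def _group_density(values: np.ndarray) -> float:
    return network_density(spearman_matrix(values)).value


def density_comparison_test(
    data: SymptomDataset,
    groups: tuple[str, str],
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test for a difference in Spearman-basis network density.

    The observed statistic is |density_A - density_B| over the symptom
    columns of the two strata; the null redistributes rows over the two
    group labels (sizes fixed); p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if data.group is None:
        raise ValueError("dataset has no group labels")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small", stacklevel=2)
    g = data.group.to_numpy()
    a, b = groups
    rows_a = np.nonzero(g == a)[0]
    rows_b = np.nonzero(g == b)[0]
    for name, rows in ((a, rows_a), (b, rows_b)):
        if len(rows) < data.p + 1:
            raise ValueError(f"group {name!r} has fewer than p+1 rows")
    X = data.values().astype(float)
    d_a = _group_density(X[rows_a])
    d_b = _group_density(X[rows_b])
    observed = abs(d_a - d_b)

    pooled = np.concatenate([rows_a, rows_b])
    n_a = len(rows_a)
    null = np.empty(n_perm)
    for k in range(n_perm):
        rng = np.random.default_rng([seed, 3, k])
        perm = rng.permutation(pooled)
        null[k] = abs(_group_density(X[perm[:n_a]]) - _group_density(X[perm[n_a:]]))
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return PermutationResult(
        observed_diff=float(observed),
        null_draws=null,
        p_value=float(p),
        groups=(a, b),
        densities={a: float(d_a), b: float(d_b)},
    )
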