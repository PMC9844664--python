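"""Covariate screening and end-to-end orchestration.

The study workflow: (1) regress overall severity (row sum of the 13 items,
0-130) on candidate covariates and keep those with p < alpha; (2) estimate
the full-sample partial-correlation network conditioned on the retained
covariates; (3) centrality, Spearman density and node predictability;
(4) edge-weight bootstrap, case-dropping stability (CS) and bootstrapped
difference tests; (5) survivorship-subgroup networks and permutation tests
of the density contrast.  Every stage's artifacts are written under an
output directory, and a single JSON summary records the results plus the
provenance (seed, settings, library versions) needed to reproduce them.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from symnet.correlations import spearman_matrix
from symnet.dataset import SURVIVORSHIP_GROUPS, SymptomDataset
from symnet.metrics import (
    centrality_table,
    network_density,
    node_predictability,
)
from symnet.network import EstimationSettings, estimate_network
from symnet.resampling import (
    DEFAULT_DROP_GRID,
    bootstrap_difference_test,
    bootstrap_edge_ci,
    case_dropping_stability,
    density_comparison_test,
)
from symnet.simulate import GeneratorSpec, generate_study

__all__ = [
    "RegressionTable",
    "overall_severity_regression",
    "PipelineConfig",
    "ReportBundle",
    "run_full_pipeline",
]

log = logging.getLogger("symnet")


# -- covariate screening -------------------------------------------------


@dataclass
class RegressionTable:
    """Standardized OLS of overall severity on candidate covariates."""

    table: pd.DataFrame            # covariate, beta, p_value
    r2_adj: float
    f_statistic: float
    f_pvalue: float
    selected: list[str]
    excluded: list[str] = field(default_factory=list)


def overall_severity_regression(
    data: SymptomDataset,
    candidate_covariates: list[str] | None = None,
    alpha: float = 0.05,
    min_class_count: int = 100,
) -> RegressionTable:
    """Screen covariates against the total severity score.

    Outcome and predictors are z-scored, so coefficients are standardized
    betas.  Binary candidates whose minority class has fewer than
    ``min_class_count`` observations are excluded up front (insufficient
    power); the selected set is every remaining covariate with p < alpha.
    """
    if data.covariates is None:
        raise ValueError("dataset has no covariates")
    if candidate_covariates is None:
        candidate_covariates = data.covariate_labels
    missing = [c for c in candidate_covariates if c not in data.covariate_labels]
    if missing:
        raise ValueError(f"unknown candidate covariates: {missing}")

    excluded = []
    kept = []
    for c in candidate_covariates:
        x = data.covariates[c].to_numpy(dtype=float)
        uniq = np.unique(x)
        if len(uniq) < 2:
            excluded.append(c)
            continue
        if len(uniq) == 2:  # binary: require a workable minority class
            minority = min((x == uniq[0]).sum(), (x == uniq[1]).sum())
            if minority < min_class_count:
                excluded.append(c)
                continue
        kept.append(c)
    if not kept:
        raise ValueError("no candidate covariate passed the support filter")

    y = data.total_severity().astype(float)
    y = (y - y.mean()) / y.std(ddof=0)
    X = data.covariates[kept].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank:
                aliased.append(kept[j])
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")

    model = sm.OLS(y, sm.add_constant(X)).fit()
    betas = model.params[1:]
    pvals = model.pvalues[1:]
    table = pd.DataFrame({"covariate": kept, "beta": betas, "p_value": pvals})
    selected = [c for c, p in zip(kept, pvals) if p < alpha]
    return RegressionTable(
        table=table,
        r2_adj=float(model.rsquared_adj),
        f_statistic=float(model.fvalue),
        f_pvalue=float(model.f_pvalue),
        selected=selected,
        excluded=excluded,
    )


# -- configuration -------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything needed to run (and re-run) the full analysis."""

    seed: int = 0
    out_dir: str = "results"
    data_csv: str | None = None            # if None, simulate via `generator`
    generator: dict = field(default_factory=dict)
    candidate_covariates: list[str] | None = None
    alpha: float = 0.05
    min_class_count: int = 100
    correlation_method: str = "polychoric"
    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    covariate_mode: str = "as_nodes"
    B_edges: int = 1000
    B_stability: int = 1000
    stability_statistics: tuple = ("strength", "expected_influence")
    drop_proportions: tuple = DEFAULT_DROP_GRID
    n_perm: int = 1000
    diff_alpha: float = 0.05
    subgroups: bool = True

    def settings(self) -> EstimationSettings:
        return EstimationSettings(
            correlation_method=self.correlation_method,
            gamma=self.gamma,
            n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
            covariate_mode=self.covariate_mode,
        )

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        raw = {k: v for k, v in (raw or {}).items()}
        for key in ("stability_statistics", "drop_proportions"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stability_statistics"] = list(self.stability_statistics)
        d["drop_proportions"] = [float(q) for q in self.drop_proportions]
        return d


@dataclass
class ReportBundle:
    """In-memory results of a full run (artifacts also written to disk)."""

    config: PipelineConfig
    data: SymptomDataset
    regression: RegressionTable | None
    selected_covariates: list[str]
    network: object
    centrality: object
    density: float
    predictability: object
    edge_bootstrap: object
    edge_difference: object
    strength_difference: object
    stability: dict
    subgroup_tests: dict
    summary: dict


# -- orchestration -------------------------------------------------------


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as err:
                raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
            log.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def run_full_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the whole analysis and write artifacts under ``out_dir``."""
    if not log.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
        log.addHandler(h)
        log.setLevel(logging.INFO)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    settings = config.settings()
    summary: dict = {"provenance": _provenance(config)}

    # stage: data
    @_stage("data")
    def _load():
        if config.data_csv is not None:
            return SymptomDataset.from_csv(config.data_csv), None
        spec = GeneratorSpec(seed=config.seed, **config.generator)
        ds, truth = generate_study(spec)
        ds.to_csv(out / "data.csv")
        truth.to_json(out / "truth.json")
        return ds, truth

    data, truth = _load()
    summary["n"] = data.n
    summary["p"] = data.p

    # stage: covariate screening
    regression = None
    selected: list[str] = []
    if data.covariates is not None and data.covariates.shape[1] > 0:
        @_stage("regression")
        def _regress():
            return overall_severity_regression(
                data, config.candidate_covariates, config.alpha, config.min_class_count
            )

        regression = _regress()
        selected = regression.selected
        regression.table.to_csv(out / "covariate_regression.csv", index=False)
        summary["covariate_screening"] = {
            "selected": selected,
            "excluded_low_support": regression.excluded,
            "r2_adj": regression.r2_adj,
            "f_statistic": regression.f_statistic,
        }

    # stage: full-sample network + metrics
    @_stage("network")
    def _network():
        net = estimate_network(data, settings, selected)
        _write_network(net, out)
        return net

    network = _network()

    @_stage("metrics")
    def _metrics():
        cent = centrality_table(network)
        cent.to_csv(out / "centrality.csv")
        pred = node_predictability(data, network)
        pred.to_csv(out / "predictability.csv")
        dens = network_density(spearman_matrix(data.values(), data.item_labels)).value
        return cent, pred, dens

    centrality, predictability, density = _metrics()
    summary["density_spearman"] = density
    summary["lambda_selected"] = network.lambda_selected
    summary["edge_count"] = int(np.count_nonzero(np.triu(network.W, k=1)))
    summary["centrality"] = centrality.table.round(6).to_dict(orient="index")
    summary["predictability"] = {
        k: round(float(v), 6)
        for k, v in predictability.table["r_squared"].items()
    }

    # stage: accuracy bootstrap + difference tests
    @_stage("edge_bootstrap")
    def _boot():
        boot = bootstrap_edge_ci(
            data, settings, B=config.B_edges, seed=config.seed, covariates=selected
        )
        boot.summary_frame().to_csv(out / "edge_bootstrap.csv", index=False)
        return boot

    edge_boot = _boot()

    @_stage("difference_tests")
    def _diff():
        edge_diff = bootstrap_difference_test(edge_boot, alpha=config.diff_alpha)
        edge_diff.frame().to_csv(out / "edge_difference.csv")
        # node strength difference test from the same replicate networks
        strength_reps = _strength_replicates(edge_boot, network.labels)
        node_diff = bootstrap_difference_test(
            strength_reps, alpha=config.diff_alpha, labels=network.labels
        )
        node_diff.frame().to_csv(out / "strength_difference.csv")
        return edge_diff, node_diff

    edge_diff, strength_diff = _diff()

    # stage: stability
    @_stage("stability")
    def _stability():
        results = {}
        for stat in config.stability_statistics:
            res = case_dropping_stability(
                data,
                settings,
                statistic=stat,
                proportions=config.drop_proportions,
                B=config.B_stability,
                seed=config.seed,
                covariates=selected,
            )
            results[stat] = res
            pd.DataFrame(
                {
                    "drop_proportion": res.drop_proportions,
                    "share_corr_ge_0.7": res.retention_curve(),
                    "mean_correlation": res.correlations.mean(axis=1),
                }
            ).to_csv(out / f"stability_{stat}.csv", index=False)
        return results

    stability = _stability()
    summary["cs_coefficient"] = {
        stat: res.cs_coefficient for stat, res in stability.items()
    }

    # stage: subgroup densities
    subgroup_tests: dict = {}
    if config.subgroups and data.group is not None:
        @_stage("subgroups")
        def _subgroups():
            tests = {}
            present = [g for g in SURVIVORSHIP_GROUPS if (data.group == g).any()]
            ref = present[0]
            for other in present[1:]:
                res = density_comparison_test(
                    data, (ref, other), n_perm=config.n_perm, seed=config.seed
                )
                tests[f"{ref} vs {other}"] = res
            return tests

        subgroup_tests = _subgroups()
        summary["subgroup_density"] = {
            key: {
                "densities": res.densities,
                "observed_diff": res.observed_diff,
                "p_value": res.p_value,
            }
            for key, res in subgroup_tests.items()
        }
    else:
        summary["subgroup_density"] = "skipped (no group labels)"

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)

    return ReportBundle(
        config=config,
        data=data,
        regression=regression,
        selected_covariates=selected,
        network=network,
        centrality=centrality,
        density=density,
        predictability=predictability,
        edge_bootstrap=edge_boot,
        edge_difference=edge_diff,
        strength_difference=strength_diff,
        stability=stability,
        subgroup_tests=subgroup_tests,
        summary=summary,
    )


def _provenance(config: PipelineConfig) -> dict:
    import networkx
    import scipy
    import statsmodels

    import symnet

    cfg = config.to_dict()
    cfg.pop("out_dir", None)  # a run's location is not part of its identity
    return {
        "seed": config.seed,
        "config": cfg,
        "versions": {
            "symnet": symnet.__version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "networkx": networkx.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }


def _write_network(net, out: Path) -> None:
    import networkx as nx

    pd.DataFrame(net.edge_list(), columns=["node_i", "node_j", "weight"]).to_csv(
        out / "network_edges.csv", index=False
    )
    pd.DataFrame(net.W, index=net.labels, columns=net.labels).to_csv(
        out / "network_adjacency.csv"
    )
    nx.write_graphml(net.to_graph(), out / "network.graphml")
    with open(out / "network_settings.json", "w") as fh:
        json.dump(
            {
                "lambda_selected": net.lambda_selected,
                "gamma": net.gamma,
                "conditioned_on": net.conditioned_on,
            },
            fh,
            indent=1,
        )


def _strength_replicates(edge_boot, labels) -> np.ndarray:
    """Node strength per bootstrap replicate, rebuilt from edge weights."""
    p = len(labels)
    iu = np.triu_indices(p, k=1)
    R = edge_boot.replicate_weights
    out = np.zeros((R.shape[0], p))
    for e, (i, j) in enumerate(zip(*iu)):
        w = np.abs(R[:, e])
        out[:, i] += w
        out[:, j] += w
    return out
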