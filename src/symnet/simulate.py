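"""Synthetic MDASI-like symptom data from a latent Gaussian graphical model.

The generator draws latent symptom intensities from a zero-mean Gaussian
with a known sparse precision matrix (so the true partial-correlation
network is known exactly), then discretizes each coordinate through ordered
cutpoints into 0-10 ordinal scores.  Zero inflation is produced entirely by
the first cutpoint: the marginal prevalence of a symptom (score >= 1) is
1 - Phi(t1).  Cutpoints are calibrated per item so that, at the default
settings, marginal prevalences (27.8-72.7%) and means (1.02-2.71) match the
severity profile of a community cancer-survivor cohort.

A full synthetic study adds three survivorship strata whose off-diagonal
partial correlations are scaled by a per-group density multiplier (the
"<5y" stratum is denser by default), plus covariates (chemotherapy and
cardiovascular-disease indicators, continuous survivorship years) acting as
latent mean shifts, so covariate screening, network conditioning and the
subgroup density contrast all have ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri

from symnet.dataset import MDASI_ITEMS, SURVIVORSHIP_GROUPS, SymptomDataset

__all__ = [
    "SEVERITY_CALIBRATION",
    "GeneratorSpec",
    "StudyTruth",
    "partial_correlations",
    "generate_precision_matrix",
    "calibrated_thresholds",
    "generate_ordinal_dataset",
    "generate_study",
]

#: Per-item calibration targets: (prevalence of score>=1, mean score).
SEVERITY_CALIBRATION: dict[str, tuple[float, float]] = {
    "pain": (0.4977, 1.71),
    "fatigue": (0.7268, 2.71),
    "disturbed_sleep": (0.6394, 2.34),
    "distress": (0.5033, 1.80),
    "shortness_of_breath": (0.4441, 1.49),
    "drowsiness": (0.4798, 1.69),
    "dry_mouth": (0.4498, 1.58),
    "sadness": (0.4291, 1.53),
    "difficulty_remembering": (0.5840, 2.12),
    "numbness": (0.3906, 1.41),
    "lack_of_appetite": (0.5221, 1.71),
    "nausea": (0.3296, 1.17),
    "vomiting": (0.2779, 1.02),
}

_EIG_FLOOR_PRECISION = 0.05   # margin kept when augmenting a raw precision
_EIG_FLOOR_RESCALE = 1e-3     # clip level for density-scaled matrices


def partial_correlations(K: np.ndarray) -> np.ndarray:
    """Partial correlations implied by a precision matrix.

    ``w_ij = -k_ij / sqrt(k_ii * k_jj)``, zero diagonal.
    """
    K = np.asarray(K, dtype=float)
    d = np.sqrt(np.diag(K))
    W = -K / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    return W


def _check_spd(K: np.ndarray, what: str = "precision matrix") -> None:
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError(f"{what} is not symmetric")
    w = np.linalg.eigvalsh(K)
    if w.min() <= 0:
        raise ValueError(f"{what} is not positive definite (min eig {w.min():.3g})")


def _standardize_precision(K_raw: np.ndarray) -> np.ndarray:
    """Rescale so the implied covariance is a correlation matrix.

    ``K = D^(1/2) K_raw D^(1/2)`` with ``D = diag(inv(K_raw))`` leaves the
    partial correlations (and the support) unchanged while fixing every
    latent variance to 1, which is the scale the polychoric model assumes.
    """
    Sigma = np.linalg.inv(K_raw)
    d = np.sqrt(np.diag(Sigma))
    K = K_raw * np.outer(d, d)
    return (K + K.T) / 2.0


def generate_precision_matrix(
    p: int,
    edge_prob: float,
    weight_range: tuple[float, float],
    seed: int,
    labels: list[str] | None = None,
) -> np.ndarray:
    """Random sparse SPD precision matrix with known partial correlations.

    Edges follow an Erdos-Renyi graph with probability ``edge_prob``;
    nonzero partial correlations have magnitudes uniform in ``weight_range``
    and random sign.  Positive definiteness is enforced by diagonal
    augmentation (which shrinks the realized magnitudes when needed) and the
    matrix is rescaled so the implied covariance has unit diagonal.
    """
    if not isinstance(p, (int, np.integer)) or p < 2:
        raise ValueError("p must be an integer >= 2")
    if not np.isfinite(edge_prob) or not 0 <= edge_prob <= 1:
        raise ValueError("edge_prob must lie in [0, 1]")
    lo, hi = float(weight_range[0]), float(weight_range[1])
    if not (np.isfinite(lo) and np.isfinite(hi)) or not 0 <= lo <= hi < 1:
        raise ValueError("weight_range must be a sub-interval of [0, 1)")

    rng = np.random.default_rng(seed)
    K = np.eye(p)
    iu = np.triu_indices(p, k=1)
    present = rng.random(len(iu[0])) < edge_prob
    mags = rng.uniform(lo, hi, size=len(iu[0]))
    signs = rng.choice([-1.0, 1.0], size=len(iu[0]))
    r = np.where(present, signs * mags, 0.0)
    # pcor r on an edge corresponds to off-diagonal entry -r at unit diagonal
    K[iu] = -r
    K.T[iu] = -r

    w_min = np.linalg.eigvalsh(K).min()
    if w_min < _EIG_FLOOR_PRECISION:
        K = K + (_EIG_FLOOR_PRECISION - w_min) * np.eye(p)
    K = _standardize_precision(K)
    _check_spd(K)
    return K


def _mean_given_first_cutpoint(t1: float, delta: float) -> float:
    """Mean of the discretized score for equally spaced cutpoints."""
    ks = np.arange(10)
    return float(np.sum(1.0 - ndtr(t1 + ks * delta)))


def calibrated_thresholds(
    prevalence: float, mean: float | None = None
) -> np.ndarray:
    """Ten ordered cutpoints hitting a target prevalence (and mean).

    The first cutpoint is ``Phi^-1(1 - prevalence)``; the remaining nine are
    equally spaced above it, with the spacing solved (1-D root find) so the
    expected score matches ``mean`` when one is given (feasible for
    prevalence <= mean <= 10*prevalence), else spacing 0.55 SD.
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie in (0, 1)")
    t1 = float(ndtri(1.0 - prevalence))
    if mean is None:
        delta = 0.55
    else:
        if not prevalence < mean < 10 * prevalence:
            raise ValueError("target mean must lie in (prevalence, 10*prevalence)")
        delta = brentq(
            lambda d: _mean_given_first_cutpoint(t1, d) - mean, 1e-4, 20.0,
            xtol=1e-10,
        )
    return t1 + np.arange(10) * delta


def default_thresholds(labels: list[str] | None = None) -> np.ndarray:
    """(p, 10) cutpoint matrix calibrated to the default severity profile."""
    labels = MDASI_ITEMS if labels is None else labels
    rows = []
    for lab in labels:
        prev, mean = SEVERITY_CALIBRATION.get(lab, (0.45, 1.6))
        rows.append(calibrated_thresholds(prev, mean))
    return np.vstack(rows)


def generate_ordinal_dataset(
    n: int,
    K: np.ndarray,
    thresholds: np.ndarray,
    seed: int,
    labels: list[str] | None = None,
    latent_shift: np.ndarray | None = None,
) -> SymptomDataset:
    """Draw n latent Gaussian vectors with precision K and discretize.

    ``thresholds`` is (p, 10), strictly increasing per row (entries may be
    +-inf); score = number of cutpoints below the latent value, so raising a
    latent value can never lower the score.  ``latent_shift`` (n, p) adds
    per-row mean shifts (covariate effects) before discretization.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    K = np.asarray(K, dtype=float)
    _check_spd(K)
    p = K.shape[0]
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.shape != (p, 10):
        raise ValueError(f"thresholds must have shape ({p}, 10)")
    diffs = np.diff(thresholds, axis=1)
    if not np.all(diffs[np.isfinite(diffs)] > 0):
        raise ValueError("thresholds must be strictly increasing per item")
    if labels is None:
        labels = MDASI_ITEMS if p == 13 else [f"item_{j+1:02d}" for j in range(p)]

    rng = np.random.default_rng(seed)
    Sigma = np.linalg.inv(K)
    L = np.linalg.cholesky((Sigma + Sigma.T) / 2.0)
    Z = rng.standard_normal((n, p)) @ L.T
    if latent_shift is not None:
        Z = Z + np.asarray(latent_shift, dtype=float)
    scores = np.empty((n, p), dtype=int)
    for j in range(p):
        scores[:, j] = np.searchsorted(thresholds[j], Z[:, j], side="right")
    return SymptomDataset(pd.DataFrame(scores, columns=list(labels)))


# -- full synthetic study ------------------------------------------------


@dataclass
class GeneratorSpec:
    """Study conditions for the synthetic cohort.

    Defaults emulate the target cohort: ~1065 participants split over three
    survivorship strata, 13 zero-inflated items, a sparse latent network
    (edge probability 0.2, partial correlations 0.15-0.4), a denser network
    in the "<5y" stratum (density_scale 1.5), and covariate effects with
    the screened-covariate sign pattern (chemotherapy +, cardiovascular
    disease +, survivorship duration -, in latent-SD units per unit of the
    centered covariate).
    """

    n_per_group: tuple[int, int, int] = (355, 355, 355)
    p: int = 13
    edge_prob: float = 0.2
    weight_range: tuple[float, float] = (0.15, 0.4)
    thresholds: np.ndarray | None = None
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {
            "chemotherapy": 0.30,
            "cardiovascular": 0.25,
            "survivorship_years": -0.012,
        }
    )
    density_scale: tuple[float, float, float] = (1.5, 1.0, 1.0)
    chemo_prevalence: float = 0.51
    cvd_prevalence: float = 0.14
    seed: int = 0

    def validate(self) -> None:
        if len(self.n_per_group) != 3:
            raise ValueError("n_per_group must have three entries")
        if any(n < self.p + 1 for n in self.n_per_group):
            raise ValueError("each group needs at least p+1 rows for estimability")
        if any(s <= 0 for s in self.density_scale):
            raise ValueError("density_scale entries must be positive")


@dataclass
class StudyTruth:
    """Ground truth recorded alongside a synthetic study."""

    precision_by_group: dict[str, np.ndarray]
    thresholds: np.ndarray
    item_labels: list[str]
    covariate_effects: dict[str, float]
    seed: int

    def pcor_by_group(self) -> dict[str, np.ndarray]:
        return {g: partial_correlations(K) for g, K in self.precision_by_group.items()}

    def density_by_group(self) -> dict[str, float]:
        out = {}
        for g, W in self.pcor_by_group().items():
            out[g] = float(np.abs(W[np.triu_indices_from(W, k=1)]).sum())
        return out

    def to_json(self, path) -> None:
        payload = {
            "precision_by_group": {
                g: K.tolist() for g, K in self.precision_by_group.items()
            },
            "thresholds": self.thresholds.tolist(),
            "item_labels": self.item_labels,
            "covariate_effects": self.covariate_effects,
            "seed": int(self.seed),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _scale_precision_density(K: np.ndarray, scale: float) -> np.ndarray:
    """Multiply all partial correlations by ``scale``; re-project to SPD.

    Scaling can break positive definiteness; eigenvalues are clipped at
    1e-3 and the result rescaled to a unit-diagonal implied correlation
    (which slightly attenuates extreme scalings but is deterministic and
    order-independent).
    """
    W = partial_correlations(K) * scale
    if np.abs(W).max() >= 1.0:
        raise ValueError(
            f"density_scale {scale} pushes a partial correlation to "
            f"{np.abs(W).max():.3f} >= 1; reduce the scale or base weights"
        )
    K_raw = np.eye(K.shape[0]) - W
    w, V = np.linalg.eigh(K_raw)
    if w.min() < _EIG_FLOOR_RESCALE:
        K_raw = (V * np.maximum(w, _EIG_FLOOR_RESCALE)) @ V.T
    K_new = _standardize_precision((K_raw + K_raw.T) / 2.0)
    _check_spd(K_new, "density-scaled precision matrix")
    return K_new


def generate_study(spec: GeneratorSpec) -> tuple[SymptomDataset, StudyTruth]:
    """Generate the full synthetic cohort and its ground truth.

    Returns ``(dataset, truth)``; the dataset carries covariates and group
    labels, the truth carries the per-group precision matrices (after
    density scaling and SPD re-projection) and the cutpoints.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    labels = MDASI_ITEMS if spec.p == 13 else [f"item_{j+1:02d}" for j in range(spec.p)]
    K_base = generate_precision_matrix(
        spec.p, spec.edge_prob, spec.weight_range, seed=int(rng.integers(2**31))
    )
    thresholds = (
        default_thresholds(labels) if spec.thresholds is None
        else np.asarray(spec.thresholds, dtype=float)
    )

    year_ranges = {"<5y": (0.5, 5.0), "5-10y": (5.0, 10.0), ">10y": (10.0, 26.0)}
    items_parts, cov_parts, group_parts = [], [], []
    precision_by_group: dict[str, np.ndarray] = {}
    for g, n_g, scale in zip(SURVIVORSHIP_GROUPS, spec.n_per_group, spec.density_scale):
        K_g = K_base if scale == 1.0 else _scale_precision_density(K_base, scale)
        precision_by_group[g] = K_g
        lo, hi = year_ranges[g]
        cov = pd.DataFrame(
            {
                "chemotherapy": (rng.random(n_g) < spec.chemo_prevalence).astype(int),
                "cardiovascular": (rng.random(n_g) < spec.cvd_prevalence).astype(int),
                "survivorship_years": rng.uniform(lo, hi, size=n_g),
            }
        )
        cov_parts.append(cov)
        group_parts.append(pd.Series([g] * n_g))
    cov_all = pd.concat(cov_parts, ignore_index=True)
    group_all = pd.concat(group_parts, ignore_index=True)

    # Covariate effects shift latent means uniformly across items; centering
    # keeps the marginal calibration at the threshold targets.
    shift_per_row = np.zeros(len(cov_all))
    for name, eff in spec.covariate_effects.items():
        if name not in cov_all.columns:
            raise ValueError(f"covariate_effects names unknown covariate {name!r}")
        x = cov_all[name].to_numpy(dtype=float)
        shift_per_row += eff * (x - x.mean())

    offset = 0
    for g, n_g in zip(SURVIVORSHIP_GROUPS, spec.n_per_group):
        shift = np.tile(shift_per_row[offset:offset + n_g, None], (1, spec.p))
        ds_g = generate_ordinal_dataset(
            n_g,
            precision_by_group[g],
            thresholds,
            seed=int(rng.integers(2**31)),
            labels=labels,
            latent_shift=shift,
        )
        items_parts.append(ds_g.items)
        offset += n_g

    items_all = pd.concat(items_parts, ignore_index=True)
    dataset = SymptomDataset(items_all, cov_all, group_all)
    truth = StudyTruth(
        precision_by_group=precision_by_group,
        thresholds=thresholds,
        item_labels=labels,
        covariate_effects=dict(spec.covariate_effects),
        seed=spec.seed,
    )
    return dataset, truth
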