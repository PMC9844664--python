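# Methods

## The model

Thirteen ordinal symptom severities (0–10, MDASI severity domain) are
treated as discretizations of a latent multivariate normal vector
Z ~ N(0, Σ) with unit variances. The object of interest is the
partial-correlation network

    w_ij = -k_ij / sqrt(k_ii * k_jj),   K = Σ⁻¹,

whose edges are conditional associations given all other nodes. The
estimator is the graphical lasso,

    K̂(λ) = argmax_{K ≻ 0}  log det K − tr(S K) − λ Σ_{i≠j} |k_ij|,

with the diagonal unpenalized, applied to a polychoric correlation matrix
S (Spearman available as an alternative input), over a log-spaced path of
100 penalties from λ_max = max_{i<j}|S_ij| down to 0.01·λ_max. The penalty
is selected by the extended BIC,

    EBIC(λ) = −2 ℓ(K̂) + E log n + 4 γ E log p,
    ℓ(K̂) = (n/2)(log det K̂ − tr(S K̂)),

with E the number of nonzero edges and γ = 0.5, the conservative
field-standard default.

**Polychoric correlations** are estimated pairwise in two stages:
thresholds fixed at normal quantiles of the cumulative marginal
proportions, then a bounded 1-D search (tolerance 1e-6 on ρ, bounds
±0.999 with boundary clamping flagged) maximizing the bivariate-normal
cell-probability likelihood. Cell probabilities use a closed-form
bivariate normal CDF built on Owen's T function (validated against
`scipy.stats.multivariate_normal` to ~1e-14). Empty marginal categories
are merged (the likelihood is invariant to this); a margin with one
observed category is an error. Pairwise matrices need not be PSD, so
eigenvalues are clipped at 1e-6 and the matrix rescaled to unit diagonal;
the repair is flagged when it changes anything.

**Covariate control.** Covariates screened by the severity regression
enter the correlation matrix as extra nodes (rank-based correlations for
any pair involving a covariate, since binary therapy indicators do not fit
the latent-normal model), the joint precision matrix is estimated, and the
symptom-by-symptom block of the partial-correlation matrix is reported —
its edges are thereby conditioned on the covariates. A `residualize` mode
(rank-transform, regress out covariates, correlate residuals) is kept for
sensitivity; with no covariates the two modes coincide.

## Metrics and conventions

- **Strength** r_s,i = Σ_j |w_ij|; **expected influence** Σ_j w_ij.
- **Distances** use edge length 1/|w_ij|. **Closeness** is the reciprocal
  of the summed distance to reachable nodes (0 for isolated nodes) — the
  sum-reciprocal convention of the standard psychometric-network software;
  a mean-based variant differs per node only by a constant factor.
- **Betweenness** counts node pairs whose shortest path passes through the
  node, fractional credit for ties (Brandes, via networkx).
- **Density** Σ_s = Σ_{i<j} |ρ_ij| over the Spearman correlation matrix of
  the symptom items (the prognosis-linked definition); the sum of absolute
  edge weights is available as an alternative basis.
- **Node predictability** is R² of each node's rank-transformed score
  regressed on its network neighbours' rank-transformed scores (isolated
  node → 0; collinear neighbourhoods use the minimum-norm fit and are
  flagged). This reproduces the meaning of the nodewise mixed-graphical-
  model quantity at desk scale but is not a refit of that model; values on
  real data would differ somewhat.

## Inference

- **Edge accuracy**: nonparametric bootstrap (rows with replacement, B
  default 1000), the *entire* estimation pipeline re-run per replicate
  including per-replicate λ selection, percentile 2.5/97.5 CIs per edge.
  Replicate failures are dropped and counted; >10% aborts.
- **Stability**: case-dropping subset bootstrap over drop proportions
  0.10–0.75 (step 0.05). CS coefficient = largest proportion at which
  ≥95% of replicates correlate ≥0.7 with the full-sample statistic
  (>0.5 preferred, >0.25 minimum). Replicates with a constant statistic
  have undefined correlation; they are recorded as 0 and counted.
- **Difference tests**: percentile interval of the bootstrap difference
  between two edges (or nodes) at level α, no multiplicity correction —
  a documented limitation that mirrors standard practice.
- **Subgroup density contrast**: the paper family does not name a test;
  we use a label permutation test on |density_A − density_B| with fixed
  group sizes and the add-one estimator p = (1 + #{null ≥ obs})/(1 + n_perm),
  which cannot return 0 and is super-uniform under exchangeability.
- **Randomness**: every replicate/permutation draws from a counter-derived
  stream `default_rng([seed, stage, counter])`, so runs are reproducible
  and enlarging B extends rather than reshuffles the replicate set.

## Synthetic cohort

The generator emulates a ~1065-person community cancer-survivor cohort:

- latent sparse network: Erdős–Rényi support with edge probability 0.2,
  partial correlations uniform in ±[0.15, 0.4]; positive definiteness by
  diagonal augmentation (kept eigenvalue margin 0.05), then rescaling so
  the implied covariance is a correlation matrix (this preserves support
  and partial correlations and fixes the latent scale, which identifies
  the polychoric recovery experiments);
- ordinal margins: per-item cutpoints with t₁ = Φ⁻¹(1 − prevalence) and
  equal spacing solved so the expected score matches the item mean;
  targets are the published severity-domain marginals (prevalence
  27.8–72.7%, means 1.02–2.71). Zero inflation therefore comes entirely
  from the first cutpoint, keeping the latent-Gaussian assumption that
  polychoric estimation presumes;
- three survivorship strata (<5y, 5–10y, >10y; half-open at 5, closed at
  10), 355 each, with the "<5y" stratum's partial correlations scaled by
  1.5 (eigenvalue clip 1e-3 + rescale when scaling breaks positive
  definiteness), giving a true density contrast;
- covariates: chemotherapy (Bernoulli 0.51) and cardiovascular disease
  (Bernoulli 0.14) indicators and survivorship years (uniform over the
  stratum's range, 0.5–26 overall), acting as uniform latent mean shifts
  of +0.30, +0.25 and −0.012 SD per unit (centered), reproducing the
  published screening pattern of a positive chemotherapy and negative
  duration effect.

What the generator does **not** emulate: item-specific covariate effects,
longitudinal structure, missingness mechanisms, floor effects beyond the
first cutpoint, and any non-Gaussian latent dependence. Tests passing on
this generator show the machinery is correct under its own assumptions,
not that real symptom data satisfy them.

## Numerical choices

- Graphical-lasso block coordinate descent: parameter-change tolerance
  1e-5 (1e-7 in oracle comparisons), inner lasso coordinate descent to
  0.1× that, warm-started along the descending λ path; λ = 0 is returned
  as the explicit inverse. Off-diagonal entries ≤1e-6 are treated as
  absent edges. Implemented with numba; an independent check against
  direct numerical maximization of the penalized likelihood (split-variable
  L-BFGS-B with the log-det barrier) and against
  `sklearn.covariance.graphical_lasso` runs in the test suite. sklearn pins
  the working covariance diagonal at s_ii + λ (penalized-diagonal
  convention) whereas this package keeps s_ii, so that comparison is
  approximate by design.
- EBIC ties go to the sparser model; n is the retained row count after
  listwise deletion.
- Degenerate inputs: zero-variance columns get Spearman correlation 0 and
  a flag; all-mass-in-one-cell tables clamp ρ at ±0.999 and flag;
  subsamples smaller than p+1 are skipped and flagged in stability runs.

## Problem sizes in the test suite

Simulation-based tests run at the smallest sizes that still measure the
property: recovery experiments at p=13, n=1000 (20 seeds); bootstrap
calibration on a 3-node chain at n=300 with B=500 (the regime where the
null-edge estimate fluctuates continuously, so percentile coverage is
informative — in sparser regimes the selection atom at zero makes CIs
cover 0 almost surely); stability at n=2000 vs n=120 with B=200; and
permutation size/power at 200 replications with n_perm=200. Resampling
experiments use Spearman input and a 20-point λ path, which leaves the
resampling distributions essentially unchanged while keeping refits at
milliseconds. The analysis drivers and acceptance script default to
B=150–200 (edge bootstrap), B=50 (stability) and n_perm=500 on the full
1065-row cohort.

## Known limitations

- Predictability is an OLS-on-ranks approximation (above).
- Printed strength/density values from heterogeneous real cohorts are not
  comparable across studies whose node sets (with or without covariate
  nodes) or scaling conventions differ; this package reports raw sums over
  symptom nodes only.
- A pooled cohort whose strata have different precision matrices is a
  Gaussian mixture; the pooled network is then a well-defined descriptive
  estimand but not any stratum's sparse truth (the acceptance script's
  recovery check therefore uses a homogeneous population).
- Percentile difference tests are uncorrected for multiplicity.
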