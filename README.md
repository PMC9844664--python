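# symnet — contemporaneous symptom-network analysis

`symnet` implements the network view of multidimensional symptom burden in
cancer survivors: instead of ranking symptoms by prevalence or severity, it
estimates which symptoms are *conditionally* associated with which, and
which are central to the network. It is aimed at researchers analysing
ordinal patient-reported outcomes (e.g. the 13 severity items of the MD
Anderson Symptom Inventory, scored 0–10) in cross-sectional cohorts.

## What it computes

- **Network**: a sparse partial-correlation network. Polychoric
  correlations (latent-normal ML for ordinal items) feed an L1-penalized
  precision estimate (graphical lasso, diagonal unpenalized); the penalty
  is chosen by the extended BIC with γ = 0.5. Edge weights are
  w_ij = −k_ij/√(k_ii·k_jj). Screened covariates are conditioned out by
  including them as nodes and reporting the symptom subnetwork.
- **Covariate screening**: standardized OLS of the total severity score
  (0–130) on candidate covariates; those with p < 0.05 enter the network.
- **Metrics**: strength Σ|w|, expected influence Σw, closeness and
  betweenness on 1/|w| edge lengths, node predictability (R² from network
  neighbours), and the density statistic Σ_s = Σ_{i<j}|ρ_ij| over Spearman
  correlations.
- **Inference**: nonparametric bootstrap CIs for edge weights, bootstrapped
  difference tests between edges/nodes, the case-dropping correlation-
  stability (CS) coefficient (>0.5 preferred, >0.25 minimum), and a label-
  permutation test for density differences between survivorship strata.
- **Synthetic cohort**: a calibrated generator (latent Gaussian graphical
  model + per-item cutpoints matching published severity marginals, three
  survivorship strata with a denser <5-year network, covariate effects)
  provides ground truth for every stage.

See `docs/methods.md` for models, conventions and limitations.

## Worked example

The numbered scripts under `analysis/` run the whole study on the synthetic
cohort (n = 1065, three survivorship strata):

```sh
python analysis/01_simulate_cohort.py --seed 1     # writes results/data.csv + truth.json
python analysis/02_screen_covariates.py
python analysis/03_estimate_network.py
python analysis/04_accuracy_stability.py
python analysis/05_subgroup_density.py
```

`02` prints the screening regression — all three generator covariates are
recovered with the built-in effect signs (chemotherapy +, cardiovascular
disease +, survivorship duration −):

```
         covariate    beta  p_value
      chemotherapy  0.3931   0.0000
    cardiovascular  0.1978   0.0000
survivorship_years -0.2079   0.0000
adjusted R^2 = 0.228, F = 105.63
```

`03` prints the network summary; strength identifies the hub symptoms and
predictability says how much of a node's variance its neighbours explain:

```
density (sum |Spearman rho|) = 16.03
highest-strength symptoms:
            strength  closeness
distress       1.069      0.005
numbness       1.025      0.005
drowsiness     0.996      0.005
predictability range: 0.5% - 46.1%
```

`04` and `05` quantify stability and the stratum contrast — the CS
coefficient clears the preferred 0.5 bar, and the denser <5-year network is
detected against both longer-survivorship strata:

```
CS(strength) = 0.75 (>0.5 preferred, >0.25 minimum)
CS(expected_influence) = 0.75 (>0.5 preferred, >0.25 minimum)
<5y vs 5-10y: |density diff| = 30.82, p = 0.000999
<5y vs >10y: |density diff| = 30.84, p = 0.000999
```

The same workflow is available as a library (`symnet.estimate_network`,
`symnet.centrality_table`, `symnet.bootstrap_edge_ci`, ...) and as a CLI:

```sh
symnet run --config study.yaml --out results/
symnet simulate --seed 1 --out data.csv --truth truth.json
symnet estimate --data data.csv --covariates chemotherapy,cardiovascular --out net/
```

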