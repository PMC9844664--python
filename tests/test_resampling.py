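"""Bootstrap, stability and permutation machinery: determinism and edge cases."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_dataset
from symnet import (
    EstimationSettings,
    bootstrap_difference_test,
    bootstrap_edge_ci,
    case_dropping_stability,
    density_comparison_test,
    generate_ordinal_dataset,
    generate_precision_matrix,
)
from symnet.dataset import SymptomDataset
from symnet.simulate import default_thresholds


@pytest.fixture(scope="module")
def signal_data():
    K = generate_precision_matrix(5, 0.5, (0.25, 0.4), seed=21)
    return generate_ordinal_dataset(250, K, default_thresholds()[:5], seed=22)


class TestEdgeBootstrap:
    def test_same_seed_reproduces_exactly(self, signal_data, fast_settings):
        a = bootstrap_edge_ci(signal_data, fast_settings, B=20, seed=9)
        b = bootstrap_edge_ci(signal_data, fast_settings, B=20, seed=9)
        assert np.array_equal(a.replicate_weights, b.replicate_weights)
        assert np.array_equal(a.ci_low, b.ci_low)

    def test_growing_B_extends_replicates(self, signal_data, fast_settings):
        a = bootstrap_edge_ci(signal_data, fast_settings, B=10, seed=9)
        b = bootstrap_edge_ci(signal_data, fast_settings, B=20, seed=9)
        assert np.array_equal(
            a.replicate_weights, b.replicate_weights[:10]
        )

    def test_single_replicate_degenerate_ci(self, signal_data, fast_settings):
        boot = bootstrap_edge_ci(signal_data, fast_settings, B=1, seed=3)
        assert np.allclose(boot.ci_low, boot.replicate_weights[0])
        assert np.allclose(boot.ci_high, boot.replicate_weights[0])

    def test_percentile_consistency(self, signal_data, fast_settings):
        boot = bootstrap_edge_ci(signal_data, fast_settings, B=60, seed=4)
        med = np.median(boot.replicate_weights, axis=0)
        assert np.all(boot.ci_low <= med + 1e-12)
        assert np.all(med <= boot.ci_high + 1e-12)

    def test_ci_widens_as_n_shrinks(self, fast_settings):
        K = generate_precision_matrix(5, 0.5, (0.25, 0.4), seed=31)
        widths = {}
        for n in (600, 150):
            med = []
            for seed in range(3):
                data = generate_ordinal_dataset(
                    n, K, default_thresholds()[:5], seed=40 + seed
                )
                boot = bootstrap_edge_ci(data, fast_settings, B=60, seed=seed)
                med.append(np.median(boot.ci_high - boot.ci_low))
            widths[n] = np.median(med)
        assert widths[150] >= widths[600]


class TestStability:
    def test_same_seed_reproduces_exactly(self, signal_data, fast_settings):
        kw = dict(statistic="strength", proportions=(0.2, 0.5), B=15, seed=5)
        a = case_dropping_stability(signal_data, fast_settings, **kw)
        b = case_dropping_stability(signal_data, fast_settings, **kw)
        assert np.array_equal(a.correlations, b.correlations)
        assert a.cs_coefficient == b.cs_coefficient

    def test_constant_statistic_flagged_as_zero(self, fast_settings):
        # pure noise at tiny n: network is empty, strengths all zero
        rng = np.random.default_rng(6)
        data = make_dataset(rng.integers(0, 10, (80, 4)))
        res = case_dropping_stability(
            data, fast_settings, statistic="strength",
            proportions=(0.2,), B=10, seed=1,
        )
        assert res.cs_coefficient == 0.0
        assert res.n_degenerate > 0
        assert np.all(res.correlations == 0.0)

    def test_too_small_subsamples_skipped(self, signal_data, fast_settings):
        res = case_dropping_stability(
            signal_data.subset(np.arange(12)), fast_settings,
            statistic="strength", proportions=(0.3, 0.9), B=5, seed=2,
        )
        assert 0.9 in res.skipped_proportions

    def test_invalid_grid_rejected(self, signal_data, fast_settings):
        with pytest.raises(ValueError):
            case_dropping_stability(
                signal_data, fast_settings, proportions=(0.0, 0.5), B=5
            )


class TestDifferenceTest:
    def test_identical_replicates_never_significant(self):
        rng = np.random.default_rng(7)
        col = rng.normal(0.3, 0.05, 200)
        reps = np.column_stack([col, col])
        diff = bootstrap_difference_test(reps, alpha=0.05)
        assert not diff.significant.any()

    def test_level_monotonicity(self):
        rng = np.random.default_rng(8)
        reps = rng.normal([0.0, 0.15, 0.5], 0.08, size=(300, 3))
        loose = bootstrap_difference_test(reps, alpha=0.5).significant
        strict = bootstrap_difference_test(reps, alpha=0.001).significant
        assert (strict & ~loose).sum() == 0  # strict set within loose set
        # an overlapping pair loses significance as alpha shrinks (a fully
        # separated pair cannot: finite-B percentiles stop at the sample range)
        tiny = bootstrap_difference_test(reps, alpha=1e-9).significant
        assert not tiny[0, 1]

    def test_separated_distributions_detected(self):
        rng = np.random.default_rng(9)
        reps = np.column_stack(
            [rng.normal(0.0, 0.02, 300), rng.normal(0.4, 0.02, 300)]
        )
        diff = bootstrap_difference_test(reps, alpha=0.05)
        assert diff.significant[0, 1] and diff.significant[1, 0]
        assert not diff.significant[0, 0]

    def test_edge_bootstrap_input(self, signal_data, fast_settings):
        boot = bootstrap_edge_ci(signal_data, fast_settings, B=120, seed=10)
        diff = bootstrap_difference_test(boot, alpha=0.05)
        assert diff.significant.shape == (10, 10)
        assert np.array_equal(diff.significant, diff.significant.T)


class TestDensityComparison:
    def test_identical_groups_give_p_one(self):
        rng = np.random.default_rng(11)
        X = rng.integers(0, 10, (40, 4))
        data = make_dataset(
            np.vstack([X, X]), group=["A"] * 40 + ["B"] * 40
        )
        res = density_comparison_test(data, ("A", "B"), n_perm=50, seed=0)
        assert res.observed_diff == pytest.approx(0.0)
        assert res.p_value == 1.0

    def test_same_seed_reproduces(self, small_study):
        data, _ = small_study
        a = density_comparison_test(data, ("<5y", "5-10y"), n_perm=60, seed=3)
        b = density_comparison_test(data, ("<5y", "5-10y"), n_perm=60, seed=3)
        assert np.array_equal(a.null_draws, b.null_draws)
        assert a.p_value == b.p_value

    def test_denser_stratum_detected(self, small_study):
        data, _ = small_study  # density_scale (1.5, 1.0, 1.0)
        res = density_comparison_test(data, ("<5y", ">10y"), n_perm=200, seed=1)
        assert res.densities["<5y"] > res.densities[">10y"]
        assert res.p_value < 0.05

    def test_small_group_rejected(self):
        rng = np.random.default_rng(12)
        data = make_dataset(
            rng.integers(0, 10, (25, 6)), group=["A"] * 20 + ["B"] * 5
        )
        with pytest.raises(ValueError, match="fewer than p\\+1"):
            density_comparison_test(data, ("A", "B"), n_perm=50)

    def test_add_one_p_value_bounds(self, small_study):
        data, _ = small_study
        res = density_comparison_test(data, ("5-10y", ">10y"), n_perm=49, seed=2)
        assert 1.0 / 50 <= res.p_value <= 1.0
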