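"""Generator: SPD structure, calibrated marginals, study-level ground truth."""

import numpy as np
import pytest
from scipy.special import ndtr, ndtri

from symnet import (
    GeneratorSpec,
    generate_ordinal_dataset,
    generate_precision_matrix,
    generate_study,
)
from symnet.simulate import (
    SEVERITY_CALIBRATION,
    calibrated_thresholds,
    default_thresholds,
    partial_correlations,
)


class TestPrecisionMatrix:
    def test_empty_graph_is_identity_structure(self):
        K = generate_precision_matrix(2, 0.0, (0.2, 0.4), seed=1)
        assert partial_correlations(K)[0, 1] == 0.0

    def test_complete_p3_equal_magnitudes(self):
        K = generate_precision_matrix(3, 1.0, (0.3, 0.3), seed=7)
        W = partial_correlations(K)
        iu = np.triu_indices(3, 1)
        # -k_ij / sqrt(k_ii k_jj) should be +-0.3 when no augmentation fires
        assert np.allclose(np.abs(W[iu]), 0.3, atol=1e-10)

    def test_spd_and_expected_edge_count(self):
        counts = []
        for seed in range(100):
            K = generate_precision_matrix(13, 0.25, (0.1, 0.4), seed=seed)
            assert np.linalg.eigvalsh(K).min() > 0
            counts.append(np.count_nonzero(np.triu(partial_correlations(K), 1)))
        assert np.mean(counts) == pytest.approx(0.25 * 78, rel=0.12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            generate_precision_matrix(1, 0.5, (0.2, 0.3), seed=0)
        with pytest.raises(ValueError):
            generate_precision_matrix(5, 1.5, (0.2, 0.3), seed=0)
        with pytest.raises(ValueError):
            generate_precision_matrix(5, 0.5, (0.2, np.inf), seed=0)


class TestThresholds:
    def test_prevalence_and_mean_targets_hit(self):
        for prev, mean in [(0.7268, 2.71), (0.2779, 1.02)]:
            t = calibrated_thresholds(prev, mean)
            assert np.all(np.diff(t) > 0)
            assert 1.0 - ndtr(t[0]) == pytest.approx(prev, abs=1e-10)
            implied_mean = sum(1.0 - ndtr(tk) for tk in t)
            assert implied_mean == pytest.approx(mean, abs=1e-6)

    def test_default_table_covers_all_items(self):
        thr = default_thresholds()
        assert thr.shape == (13, 10)
        assert np.all(np.diff(thr, axis=1) > 0)


class TestOrdinalDataset:
    def test_unreachable_first_cutpoint_gives_all_zeros(self):
        thr = np.tile(50.0 + np.arange(10), (2, 1))
        data = generate_ordinal_dataset(200, np.eye(2), thr, seed=0)
        assert np.all(data.values() == 0)

    def test_fatigue_prevalence_calibration(self):
        prev = SEVERITY_CALIBRATION["fatigue"][0]
        thr = np.tile(ndtri(1 - prev) + np.arange(10) * 0.5, (2, 1))
        data = generate_ordinal_dataset(10000, np.eye(2), thr, seed=4)
        observed = (data.values()[:, 0] >= 1).mean()
        assert observed == pytest.approx(prev, abs=0.015)

    def test_single_edge_dominates_rank_correlation(self):
        K = np.eye(3)
        K[0, 1] = K[1, 0] = -0.5  # pcor(1,2) = 0.5
        from symnet.simulate import _standardize_precision

        K = _standardize_precision(K)
        data = generate_ordinal_dataset(5000, K, default_thresholds()[:3], seed=9)
        from symnet.correlations import spearman_matrix

        R = spearman_matrix(data.values()).R
        assert R[0, 1] > abs(R[0, 2]) and R[0, 1] > abs(R[1, 2])

    def test_discretization_is_monotone(self):
        thr = default_thresholds()[:1]
        lo = generate_ordinal_dataset(
            500, np.eye(1), thr, seed=3, latent_shift=np.zeros((500, 1))
        )
        hi = generate_ordinal_dataset(
            500, np.eye(1), thr, seed=3, latent_shift=np.full((500, 1), 0.7)
        )
        assert np.all(hi.values() >= lo.values())

    def test_category_frequencies_converge_to_normal_mass(self):
        thr = default_thresholds()[:1]
        data = generate_ordinal_dataset(100_000, np.eye(1), thr, seed=11)
        x = data.values()[:, 0]
        edges = np.concatenate(([-np.inf], thr[0], [np.inf]))
        target = np.diff(ndtr(edges))
        observed = np.bincount(x, minlength=11) / len(x)
        assert np.max(np.abs(observed - target)) < 0.01

    def test_same_seed_bitwise_reproducible(self):
        thr = default_thresholds()[:4]
        K = generate_precision_matrix(4, 0.5, (0.2, 0.3), seed=2)
        a = generate_ordinal_dataset(300, K, thr, seed=13)
        b = generate_ordinal_dataset(300, K, thr, seed=13)
        assert np.array_equal(a.values(), b.values())

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            generate_ordinal_dataset(0, np.eye(2), np.zeros((2, 10)), seed=0)
        bad_thr = np.tile(np.arange(10)[::-1].astype(float), (2, 1))
        with pytest.raises(ValueError, match="strictly increasing"):
            generate_ordinal_dataset(10, np.eye(2), bad_thr, seed=0)


class TestStudy:
    def test_denser_first_stratum_in_truth(self, small_study):
        _, truth = small_study
        dens = truth.density_by_group()
        assert dens["<5y"] > dens["5-10y"]
        assert dens["5-10y"] == pytest.approx(dens[">10y"])

    def test_groups_years_consistent(self, small_study):
        data, _ = small_study
        years = data.covariates["survivorship_years"]
        for g, lo, hi in [("<5y", 0.5, 5), ("5-10y", 5, 10), (">10y", 10, 26)]:
            sel = data.group == g
            assert sel.sum() == 120
            assert years[sel].between(lo, hi).all()

    def test_null_density_scale_shares_truth(self):
        spec = GeneratorSpec(
            n_per_group=(30, 30, 30), density_scale=(1.0, 1.0, 1.0), seed=1
        )
        _, truth = generate_study(spec)
        dens = truth.density_by_group()
        assert dens["<5y"] == pytest.approx(dens[">10y"])

    def test_extreme_density_scale_rejected(self):
        spec = GeneratorSpec(
            n_per_group=(30, 30, 30), weight_range=(0.35, 0.4),
            density_scale=(4.0, 1.0, 1.0), seed=1,
        )
        with pytest.raises(ValueError, match="density_scale"):
            generate_study(spec)

    def test_invalid_group_sizes_rejected(self):
        with pytest.raises(ValueError, match="p\\+1"):
            GeneratorSpec(n_per_group=(5, 30, 30)).validate()

    def test_truth_json_roundtrip(self, small_study, tmp_path):
        import json

        _, truth = small_study
        truth.to_json(tmp_path / "truth.json")
        payload = json.loads((tmp_path / "truth.json").read_text())
        assert set(payload["precision_by_group"]) == {"<5y", "5-10y", ">10y"}
        assert np.asarray(payload["thresholds"]).shape == (13, 10)
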