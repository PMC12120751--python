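"""Covariances, generalized eigendecomposition and derived products."""

import numpy as np
import pytest

import freqness as fn
from freqness.datamodel import NarrowbandDataset, VoxelDataset
from freqness.errors import DataError
from freqness.ged import (
    CovariancePair,
    raw_covariance,
    regularize_r,
    solve_ged_whitening_oracle,
)
from tests.conftest import make_narrow


def random_spd(n, rng, scale=1.0):
    a = rng.standard_normal((n, n))
    return scale * (a @ a.T) + n * 1e-3 * np.eye(n)


class TestCovariances:
    def test_hand_example_two_voxels(self):
        # rows already zero-mean, so centering leaves them unchanged
        x = np.array([[1.0, -1.0], [1.0, -1.0]])
        assert np.allclose(raw_covariance(x), [[2.0, 2.0], [2.0, 2.0]])

    def test_narrow_equal_broad_gives_equal_matrices(self, small_dataset):
        narrow = make_narrow(small_dataset)
        fake = NarrowbandDataset(
            data=small_dataset.data, sampling_rate=small_dataset.sampling_rate,
            center_frequency=10.0, fwhm=1.0,
        )
        pair = fn.compute_covariances(small_dataset, fake, gamma_S=0.0, gamma_R_fraction=0.0)
        assert np.allclose(pair.S, pair.R)

    def test_zero_regularization_is_identity(self, small_dataset):
        narrow = make_narrow(small_dataset)
        pair = fn.compute_covariances(small_dataset, narrow, gamma_S=0.0, gamma_R_fraction=0.0)
        assert np.allclose(pair.S, raw_covariance(narrow.data))
        assert np.allclose(pair.R, raw_covariance(small_dataset.data))

    def test_r_regularization_adds_mean_eigenvalue_fraction(self, small_dataset):
        R = raw_covariance(small_dataset.data)
        reg = regularize_r(R, 0.01)
        added = np.diag(reg - R)
        assert np.allclose(added, 0.01 * np.trace(R) / R.shape[0])

    def test_shape_mismatch_rejected(self, small_dataset, rng):
        narrow = NarrowbandDataset(
            data=rng.standard_normal((5, 1000)), sampling_rate=100.0,
            center_frequency=10.0, fwhm=1.0,
        )
        with pytest.raises(DataError, match="shapes differ"):
            fn.compute_covariances(small_dataset, narrow)

    def test_zero_variance_voxel_warns(self, rng):
        data = rng.standard_normal((5, 1000))
        data[2] = 3.14
        broad = VoxelDataset(data=data, sampling_rate=100.0)
        narrow = make_narrow(broad)
        with pytest.warns(UserWarning, match="zero-variance"):
            fn.compute_covariances(broad, narrow)


class TestSolveGed:
    def test_equal_matrices_give_flat_spectrum(self, rng):
        S = random_spd(6, rng)
        pair = CovariancePair(S=S, R=S.copy())
        lam, _ = fn.solve_ged(pair)
        assert np.allclose(lam, 1.0, atol=1e-8)
        assert np.allclose(fn.normalize_eigenvalues(lam), 100.0 / 6, atol=1e-6)

    def test_diagonal_problem_decouples(self):
        pair = CovariancePair(S=np.diag([4.0, 1.0]), R=np.diag([2.0, 1.0]))
        lam, W = fn.solve_ged(pair)
        assert np.allclose(lam, [2.0, 1.0])
        assert np.allclose(np.abs(W), np.eye(2), atol=1e-12)

    def test_matches_whitening_oracle(self, rng):
        for trial in range(20):
            n = int(rng.integers(3, 21))
            pair = CovariancePair(S=random_spd(n, rng), R=random_spd(n, rng))
            lam, W = fn.solve_ged(pair)
            lam_o, W_o = solve_ged_whitening_oracle(pair)
            assert np.max(np.abs(lam - lam_o) / np.abs(lam_o)) < 1e-8
            # filters agree up to sign (sign fixed identically by both)
            for k in range(n):
                assert np.allclose(W[:, k], W_o[:, k], atol=1e-6) or np.allclose(
                    W[:, k], -W_o[:, k], atol=1e-6
                )

    def test_unit_norm_filters(self, rng):
        pair = CovariancePair(S=random_spd(8, rng), R=random_spd(8, rng))
        _, W = fn.solve_ged(pair)
        assert np.allclose(np.linalg.norm(W, axis=0), 1.0)

    def test_voxel_permutation_invariance(self, rng):
        """Consistent relabeling preserves eigenvalues and permutes patterns."""
        n = 30
        S, R = random_spd(n, rng), random_spd(n, rng)
        perm = rng.permutation(n)
        lam, W = fn.solve_ged(CovariancePair(S=S, R=R))
        lam_p, W_p = fn.solve_ged(CovariancePair(S=S[np.ix_(perm, perm)], R=R[np.ix_(perm, perm)]))
        assert np.max(np.abs(lam - lam_p) / np.abs(lam)) < 1e-10
        a = fn.activation_pattern(W[:, 0], S)
        a_p = fn.activation_pattern(W_p[:, 0], S[np.ix_(perm, perm)])
        assert np.allclose(a[perm], a_p, atol=1e-8)

    def test_scale_equivariance_of_normalized_eigenvalues(self, rng):
        S, R = random_spd(7, rng), random_spd(7, rng)
        lam, _ = fn.solve_ged(CovariancePair(S=S, R=R))
        lam_c, _ = fn.solve_ged(CovariancePair(S=25.0 * S, R=25.0 * R))
        assert np.allclose(fn.normalize_eigenvalues(lam), fn.normalize_eigenvalues(lam_c))


class TestNormalizeEigenvalues:
    @pytest.mark.parametrize(
        "lam,expected",
        [([3.0, 1.0], [75.0, 25.0]), ([1.0, 1.0, 1.0, 1.0], [25.0] * 4)],
    )
    def test_examples(self, lam, expected):
        assert np.allclose(fn.normalize_eigenvalues(lam), expected)

    def test_sums_to_hundred(self, rng):
        lam = np.sort(rng.random(50))[::-1]
        assert fn.normalize_eigenvalues(lam).sum() == pytest.approx(100.0, abs=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(DataError):
            fn.normalize_eigenvalues(np.zeros(4))


class TestComponentTimeseries:
    def test_indicator_filter_returns_centered_row(self, small_dataset):
        w = np.zeros(small_dataset.n_voxels)
        w[0] = 1.0
        ts = fn.component_timeseries(w, small_dataset)
        row = small_dataset.data[0] - small_dataset.data[0].mean()
        assert np.allclose(ts.values, row)

    def test_linearity_in_filter(self, small_dataset, rng):
        w = rng.standard_normal(small_dataset.n_voxels)
        y1 = fn.component_timeseries(w, small_dataset).values
        y2 = fn.component_timeseries(3.0 * w, small_dataset).values
        assert np.allclose(y2, 3.0 * y1)

    def test_length_mismatch(self, small_dataset):
        with pytest.raises(DataError):
            fn.component_timeseries(np.ones(3), small_dataset)


class TestActivationPattern:
    def test_identity_covariance_gives_absolute_filter(self, rng):
        w = rng.standard_normal(10)
        a = fn.activation_pattern(w, np.eye(10))
        assert np.allclose(a, np.abs(w) / np.abs(w).max())

    def test_range(self, rng):
        a = fn.activation_pattern(rng.standard_normal(12), random_spd(12, rng))
        assert a.min() >= 0 and a.max() == pytest.approx(1.0)

    def test_zero_projection_rejected(self):
        with pytest.raises(DataError):
            fn.activation_pattern(np.array([1.0, 0.0]), np.zeros((2, 2)))


class TestThresholdPattern:
    def test_constant_pattern_empty_mask(self):
        assert fn.threshold_pattern_for_display(np.full(50, 0.5)).sum() == 0

    def test_single_hot_voxel(self):
        a = np.zeros(100)
        a[0] = 1.0
        mask = fn.threshold_pattern_for_display(a)
        assert mask[0] and mask.sum() == 1

    def test_mask_invariant_to_positive_rescaling(self, rng):
        a = rng.random(64)
        m1 = fn.threshold_pattern_for_display(a)
        m2 = fn.threshold_pattern_for_display(7.3 * a)
        assert np.array_equal(m1, m2)


class TestPcaVariant:
    def test_rank_one_data_dominates(self, rng):
        loading = rng.standard_normal(15)
        source = np.sin(2 * np.pi * 10 * np.arange(2000) / 100.0)
        data = np.outer(loading, source) + 1e-4 * rng.standard_normal((15, 2000))
        narrow = NarrowbandDataset(
            data=data, sampling_rate=100.0, center_frequency=10.0, fwhm=1.0
        )
        decomp = fn.pca_decomposition(narrow, gamma_S=0.0)
        assert decomp.normalized_eigenvalues[0] > 99.0

    def test_equals_ged_with_identity_reference(self, small_dataset):
        narrow = make_narrow(small_dataset)
        pca = fn.pca_decomposition(narrow, gamma_S=1e-6)
        S = raw_covariance(narrow.data) + 1e-6 * np.eye(narrow.n_voxels)
        lam, _ = fn.solve_ged(CovariancePair(S=S, R=np.eye(narrow.n_voxels)))
        assert np.allclose(pca.eigenvalues, lam, rtol=1e-10)

    def test_sorted_descending(self, small_dataset):
        narrow = make_narrow(small_dataset)
        lam = fn.pca_decomposition(narrow).eigenvalues
        assert np.all(np.diff(lam) <= 1e-12)


class TestScanFrequencies:
    def test_single_component_record_count(self, small_dataset, small_grid):
        landscape = fn.scan_frequencies(small_dataset, small_grid, n_keep=1)
        assert len(landscape) == len(small_grid)

    def test_white_noise_spectrum_roughly_flat(self, rng, small_grid):
        ds = VoxelDataset(data=rng.standard_normal((30, 3000)), sampling_rate=100.0)
        landscape = fn.scan_frequencies(ds, small_grid, n_keep=1)
        top = landscape.select(component=1)["eigenvalue_pct"].to_numpy()
        assert top.std() / top.mean() < 0.5

    def test_planted_network_peaks_at_its_bin(self, rng, small_grid):
        from freqness.simulate import SimulationSpec, PlantedNetwork, simulate_dataset

        loading = np.exp(-np.arange(40) / 5.0)
        spec = SimulationSpec(
            n_voxels=40, duration_s=30.0, sampling_rate=100.0,
            networks=[PlantedNetwork(loading=loading, center_frequency=12.0, bandwidth=1.0, amplitude=2.0)],
            seed=11,
        )
        ds, _ = simulate_dataset(spec)
        landscape = fn.scan_frequencies(ds, small_grid, n_keep=1)
        top = landscape.select(component=1)
        best = top.loc[top["eigenvalue_pct"].idxmax(), "frequency_hz"]
        assert best == 12.0

    def test_landscape_ordering_invariant(self, small_dataset, small_grid):
        landscape = fn.scan_frequencies(small_dataset, small_grid, n_keep=5)
        landscape.validate()  # raises on any rank-order violation
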