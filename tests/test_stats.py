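"""Signed-rank tests, FDR and cluster-based permutation."""

import numpy as np
import pytest

import freqness as fn
from freqness.datamodel import Landscape
from freqness.errors import DataError
from freqness.simulate import simulate_group_differences
from freqness.stats import wilcoxon_exact_p


class TestWilcoxon:
    def test_all_positive_extreme_case(self, rng):
        diffs = rng.random(26) + 0.1
        z, p = fn.wilcoxon_signed_rank(diffs, tail="right")
        assert z > 4.0 and p < 1e-5

    def test_symmetric_differences_give_zero_z(self):
        diffs = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0, 4.0, -4.0])
        z, p = fn.wilcoxon_signed_rank(diffs, tail="two")
        assert z == 0.0 and p == 1.0

    def test_matches_exact_enumeration_n8(self, rng):
        """Normal approximation within 0.02 of the exact null over all sign patterns."""
        magnitudes = np.array([0.3, 0.7, 1.1, 1.9, 2.3, 3.1, 4.0, 5.2])
        worst = 0.0
        for bits in range(256):
            signs = np.array([1 if bits >> i & 1 else -1 for i in range(8)], dtype=float)
            diffs = signs * magnitudes
            for tail in ("two", "right"):
                _, p_approx = fn.wilcoxon_signed_rank(diffs, tail=tail)
                p_exact = wilcoxon_exact_p(diffs, tail=tail)
                worst = max(worst, abs(p_approx - p_exact))
        assert worst < 0.02

    def test_zero_differences_dropped(self):
        base = np.array([1.0, 2.0, -0.5, 3.0, -1.5, 2.5])
        z1, p1 = fn.wilcoxon_signed_rank(base)
        z2, p2 = fn.wilcoxon_signed_rank(np.concatenate([base, [0.0, 0.0]]))
        assert z1 == z2 and p1 == p2

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning, match="zero"):
            z, p = fn.wilcoxon_signed_rank(np.zeros(10))
        assert (z, p) == (0.0, 1.0)

    def test_sign_convention(self, rng):
        diffs = rng.random(20) + 0.05  # A > B everywhere
        z, _ = fn.wilcoxon_signed_rank(diffs)
        assert z > 0
        z_neg, _ = fn.wilcoxon_signed_rank(-diffs)
        assert z_neg == pytest.approx(-z)


class TestFdr:
    def test_single_p_unchanged(self):
        adj, mask = fn.fdr_bh(np.array([0.03]))
        assert adj[0] == pytest.approx(0.03) and mask[0]

    def test_step_up_arithmetic(self):
        adj, mask = fn.fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, 0.04)
        assert mask.all()

    def test_all_ones_nothing_significant(self):
        _, mask = fn.fdr_bh(np.ones(10))
        assert not mask.any()

    def test_null_calibration(self):
        """Under the global null the FDR-significant rate stays at or below q."""
        q = 0.05
        n_cells = 200
        rates = []
        for rep in range(100):
            diffs = simulate_group_differences(n_subjects=26, n_bins=n_cells, seed=1000 + rep)
            p = np.array([fn.wilcoxon_signed_rank(diffs[:, b])[1] for b in range(n_cells)])
            _, mask = fn.fdr_bh(p, q)
            rates.append(mask.mean())
        mean_rate = np.mean(rates)
        se = np.std(rates) / 10.0
        assert mean_rate <= q + 2 * se


class TestClusterPermutation:
    def test_no_clusters_under_null(self):
        diffs = simulate_group_differences(n_subjects=20, n_bins=15, seed=3)
        clusters, z = fn.cluster_permutation(diffs, n_perm=1000, seed=0)
        for c in clusters:  # any spurious cluster must be weak
            assert c.p_cluster > 0.05

    def test_planted_contiguous_effect_detected(self):
        detected = 0
        for rep in range(20):
            diffs = simulate_group_differences(
                n_subjects=26, n_bins=40, effect_bins=range(18, 22), effect_size=1.0,
                seed=500 + rep,
            )
            clusters, _ = fn.cluster_permutation(diffs, n_perm=1000, seed=rep)
            hits = [
                c for c in clusters
                if c.p_cluster < 0.01 and c.size >= 4
                and set(range(18, 22)) <= set(c.member_bins.tolist())
            ]
            detected += bool(hits)
        assert detected >= 18  # >= 90% of runs

    def test_p_lower_bound(self):
        diffs = simulate_group_differences(
            n_subjects=26, n_bins=10, effect_bins=range(3, 7), effect_size=3.0, seed=9
        )
        clusters, _ = fn.cluster_permutation(diffs, n_perm=1000, seed=1)
        assert clusters and min(c.p_cluster for c in clusters) >= 1.0 / 1001.0

    def test_global_label_flip_mirrors_z(self):
        diffs = simulate_group_differences(
            n_subjects=20, n_bins=12, effect_bins=range(4, 8), effect_size=1.2, seed=17
        )
        c1, z1 = fn.cluster_permutation(diffs, n_perm=1000, seed=5)
        c2, z2 = fn.cluster_permutation(-diffs, n_perm=1000, seed=5)
        assert np.allclose(z2, -z1)
        assert len(c1) == len(c2)
        for a, b in zip(c1, c2):
            assert np.array_equal(a.member_bins, b.member_bins)
            assert a.p_cluster == pytest.approx(b.p_cluster)

    def test_low_n_perm_warns(self):
        diffs = simulate_group_differences(n_subjects=10, n_bins=5, seed=0)
        with pytest.warns(UserWarning, match="n_perm"):
            fn.cluster_permutation(diffs, n_perm=100, seed=0)


def _landscape_from_matrix(values, condition, freqs, component=1):
    ls = Landscape()
    for s in range(values.shape[0]):
        for j, f in enumerate(freqs):
            ls.add(f"sub{s:02d}", condition, f, component, values[s, j])
    return ls


class TestContrasts:
    def test_identical_landscapes_nothing_significant(self, rng):
        freqs = np.arange(1.0, 9.0)
        vals = rng.random((10, len(freqs))) + 1.0
        a = _landscape_from_matrix(vals, "PL", freqs)
        b = _landscape_from_matrix(vals, "RS", freqs)
        table = fn.landscape_contrast(a, b, components=[1])
        assert not table["significant"].any()
        assert np.allclose(table["z"], 0.0)

    def test_planted_eigenvalue_increase_detected(self):
        rng = np.random.default_rng(42)
        freqs = np.arange(1.0, 21.0)
        base = rng.random((26, len(freqs))) + 2.0
        effect = base.copy()
        effect[:, 5] += 1.0  # planted increase at one bin, component 1
        a = _landscape_from_matrix(effect + 0.1 * rng.standard_normal(base.shape), "PL", freqs)
        b = _landscape_from_matrix(base + 0.1 * rng.standard_normal(base.shape), "RS", freqs)
        table = fn.landscape_contrast(a, b, components=[1])
        hit = table[table["frequency_hz"] == freqs[5]]
        assert bool(hit["significant"].iloc[0]) and float(hit["z"].iloc[0]) > 0

    def test_subject_mismatch_reported(self, rng):
        freqs = np.arange(1.0, 5.0)
        a = _landscape_from_matrix(rng.random((8, len(freqs))), "PL", freqs)
        b = _landscape_from_matrix(rng.random((9, len(freqs))), "RS", freqs)
        with pytest.raises(DataError, match="sub08"):
            fn.landscape_contrast(a, b, components=[1])

    def test_modulation_contrast_directionality(self, rng):
        import pandas as pd

        carriers = [20.0, 30.0, 40.0]
        rows_a, rows_b = [], []
        for s in range(12):
            for c in carriers:
                base = rng.random() + 1.0
                rows_b.append((f"sub{s}", c, base))
                rows_a.append((f"sub{s}", c, base + (1.0 if c == 30.0 else 0.0)))
        cols = ["subject", "carrier_freq_hz", "strength"]
        a = pd.DataFrame(rows_a, columns=cols)
        b = pd.DataFrame(rows_b, columns=cols)
        table = fn.modulation_contrast(a, b)
        assert table.loc[table["carrier_freq_hz"] == 30.0, "significant"].iloc[0]
        # right-tailed: swapping conditions must kill the effect
        swapped = fn.modulation_contrast(b, a)
        assert not swapped["significant"].any()
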