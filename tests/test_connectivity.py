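"""Freedman-Diaconis binning, mutual information, and matrix operations."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.special import xlogy

from eegfc import (ConnectivityMatrix, EpochSet, epoch_mi_matrix,
                   fd_bin_count, matrix_difference, mutual_information,
                   normalize_weights, stage_mi_matrix, top_fraction_edges)


class TestFdBinCount:
    def test_arithmetic_example(self):
        # IQR = 1.0 and range 2 at n = 1000: h = 0.2, so 10 bins
        x = np.linspace(0.0, 2.0, 1000)
        assert np.percentile(x, 75) - np.percentile(x, 25) == pytest.approx(1.0)
        assert fd_bin_count(x) == 10

    def test_degenerate_vectors(self):
        assert fd_bin_count(np.full(100, 3.3)) == 1
        with pytest.raises(ValueError):
            fd_bin_count(np.array([1.0]))

    def test_matches_direct_recomputation(self, rng):
        x = rng.standard_normal(500)
        q75, q25 = np.percentile(x, [75, 25])
        h = 2 * (q75 - q25) * 500 ** (-1 / 3)
        assert fd_bin_count(x) == int(np.ceil((x.max() - x.min()) / h))

    @given(st.integers(0, 2 ** 31 - 1))
    def test_positive_for_any_nondegenerate_sample(self, seed):
        x = np.random.default_rng(seed).standard_normal(64)
        assert fd_bin_count(x) >= 1


class TestMutualInformation:
    def test_identity_equals_binned_entropy(self, rng):
        x = rng.standard_normal(2000)
        nb = fd_bin_count(x)
        counts, _ = np.histogram(x, bins=nb)
        p = counts / counts.sum()
        entropy = -xlogy(p, p).sum()
        assert mutual_information(x, x) == pytest.approx(entropy, rel=1e-10)

    def test_symmetric_and_nonnegative(self, rng):
        x, y = rng.standard_normal((2, 1000))
        assert mutual_information(x, y) == mutual_information(y, x)
        assert mutual_information(x, y) >= 0.0

    def test_independent_uniforms_near_zero(self, rng):
        x, y = rng.random((2, 100_000))
        assert mutual_information(x, y) < 0.05

    def test_gaussian_closed_form(self, rng):
        n, rho = 100_000, 0.9
        x = rng.standard_normal(n)
        y = rho * x + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
        assert mutual_information(x, y) == pytest.approx(
            -0.5 * np.log(1 - rho ** 2), abs=0.1)

    def test_monotone_in_correlation(self):
        mean_mi = []
        for rho in (0.0, 0.3, 0.6, 0.9):
            vals = []
            for seed in range(20):
                r = np.random.default_rng(seed)
                x = r.standard_normal(20_000)
                y = rho * x + np.sqrt(1 - rho ** 2) * r.standard_normal(20_000)
                vals.append(mutual_information(x, y))
            mean_mi.append(np.mean(vals))
        assert np.all(np.diff(mean_mi) > 0)

    def test_noise_does_not_increase_mi(self):
        # data-processing sanity: degrading y cannot add information
        base, noisy = [], []
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = r.standard_normal(5000)
            y = 0.8 * x + 0.6 * r.standard_normal(5000)
            base.append(mutual_information(x, y))
            noisy.append(mutual_information(x, y + r.standard_normal(5000)))
        assert np.mean(noisy) < np.mean(base)

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            mutual_information(rng.standard_normal(10),
                               rng.standard_normal(11))


class TestEpochMatrix:
    def test_matches_pairwise_estimator(self, rng):
        epoch = rng.standard_normal((6, 500))
        m = epoch_mi_matrix(epoch)
        for i in range(6):
            for j in range(i + 1, 6):
                assert m.values[i, j] == pytest.approx(
                    mutual_information(epoch[i], epoch[j]), abs=1e-12)
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0)

    def test_29_channels_give_406_unique_pairs(self, rng):
        m = epoch_mi_matrix(rng.standard_normal((29, 200)))
        assert m.values.shape == (29, 29)
        iu = np.triu_indices(29, k=1)
        assert iu[0].size == 406

    def test_identical_channels(self, rng):
        x = rng.standard_normal(500)
        m = epoch_mi_matrix(np.vstack([x, x]))
        assert m.values[0, 1] == pytest.approx(mutual_information(x, x))

    def test_stage_matrix_averages_epochs(self, rng):
        epochs = rng.standard_normal((5, 4, 300))
        es = EpochSet(epochs=epochs, labels=("a", "b", "c", "d"),
                      sampling_rate=500.0)
        m = stage_mi_matrix(es)
        ref = np.mean([epoch_mi_matrix(e).values for e in epochs], axis=0)
        np.testing.assert_allclose(m.values, ref, atol=1e-12)

    def test_single_epoch_equals_epoch_matrix(self, rng):
        epochs = rng.standard_normal((1, 3, 400))
        es = EpochSet(epochs=epochs, labels=("a", "b", "c"),
                      sampling_rate=500.0)
        np.testing.assert_allclose(stage_mi_matrix(es).values,
                                   epoch_mi_matrix(epochs[0]).values)


def make_matrix(values, normalized=False, **kw):
    values = np.asarray(values, dtype=float)
    labels = tuple(chr(ord("A") + i) for i in range(values.shape[0]))
    return ConnectivityMatrix(labels=labels, values=values,
                              normalized=normalized, **kw)


class TestNormalizeWeights:
    def test_scales_by_max_off_diagonal(self):
        m = make_matrix([[0, 0.5, 0.1], [0.5, 0, 0.25], [0.1, 0.25, 0]])
        out = normalize_weights(m)
        np.testing.assert_allclose(
            out.values, [[0, 1.0, 0.2], [1.0, 0, 0.5], [0.2, 0.5, 0]])
        assert out.normalized

    def test_zero_matrix_unchanged(self):
        out = normalize_weights(make_matrix(np.zeros((3, 3))))
        assert np.all(out.values == 0)

    def test_idempotent(self, rng):
        w = np.abs(rng.standard_normal((5, 5)))
        w = w + w.T
        once = normalize_weights(make_matrix(w))
        twice = normalize_weights(once)
        np.testing.assert_allclose(once.values, twice.values)
        assert once.values.max() == 1.0


class TestMatrixDifference:
    def test_self_difference_is_zero(self, rng):
        w = np.abs(rng.standard_normal((4, 4)))
        a = normalize_weights(make_matrix(w + w.T))
        d = matrix_difference(a, a)
        assert np.all(d.values == 0)

    def test_entries_bounded(self, rng):
        w1, w2 = (np.abs(rng.standard_normal((4, 4))) for _ in range(2))
        a = normalize_weights(make_matrix(w1 + w1.T))
        b = normalize_weights(make_matrix(w2 + w2.T))
        d = matrix_difference(a, b)
        assert np.all(d.values >= -1.0) and np.all(d.values <= 1.0)

    def test_band_mismatch_rejected(self, rng):
        w = np.abs(rng.standard_normal((3, 3)))
        a = normalize_weights(make_matrix(w + w.T, band="beta"))
        b = normalize_weights(make_matrix(w + w.T, band="alpha"))
        with pytest.raises(ValueError):
            matrix_difference(a, b)

    def test_unnormalized_rejected(self, rng):
        w = np.abs(rng.standard_normal((3, 3)))
        m = make_matrix(w + w.T)
        with pytest.raises(ValueError):
            matrix_difference(m, m)


class TestTopFractionEdges:
    def test_hub_submatrix_edge_count(self, rng):
        w = np.abs(rng.standard_normal((9, 9)))
        m = make_matrix(w + w.T)
        # 36 undirected edges, 30% -> round(10.8) = 11
        assert len(top_fraction_edges(m, q=0.3)) == 11

    def test_full_fraction_returns_all_edges(self, rng):
        w = np.abs(rng.standard_normal((29, 29)))
        m = make_matrix(w + w.T)
        assert len(top_fraction_edges(m, q=1.0)) == 406

    def test_sorted_descending_and_strongest(self, rng):
        w = np.abs(rng.standard_normal((8, 8)))
        m = make_matrix(w + w.T)
        edges = top_fraction_edges(m, q=0.5)
        weights = [e[2] for e in edges]
        assert weights == sorted(weights, reverse=True)
        all_w = sorted((m.values[i, j] for i, j in
                        zip(*np.triu_indices(8, 1))), reverse=True)
        assert weights == pytest.approx(all_w[:len(edges)])

    def test_equal_weights_tie_break_lexicographic(self):
        m = make_matrix(np.ones((4, 4)) - np.eye(4))
        edges = top_fraction_edges(m, q=0.3)  # round(1.8) = 2 of 6
        assert [(a, b) for a, b, _ in edges] == [("A", "B"), ("A", "C")]
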