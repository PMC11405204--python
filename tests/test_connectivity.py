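"""Functional-connectivity tests: binning conventions, Fisher-z closed
forms, validity handling, burst-bias control and network thresholding."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from seiznet.connectivity import (
    BinnedSpikeMatrix,
    bin_spike_counts,
    burst_bias_check,
    pair_index,
    pairwise_fc,
    threshold_network,
)
from seiznet.spikes import BurstMask, SpikeTrainSet


def binned_from(counts, width=0.05, mask_flags=None):
    b = BinnedSpikeMatrix(counts=np.asarray(counts), width=width)
    if mask_flags is not None:
        flags = np.asarray(mask_flags, bool)
        b.burst_mask = BurstMask(
            intervals=np.empty((0, 2)), bin_flags=flags, bin_width=width
        )
    return b


class TestBinning:
    def test_half_open_convention(self):
        ts = SpikeTrainSet(trains=[np.array([0.05])], duration=0.1)
        counts = bin_spike_counts(ts, 0.05).counts
        assert counts[0].tolist() == [0, 1]

    def test_trailing_partial_bin_discarded(self):
        ts = SpikeTrainSet(trains=[np.array([0.01, 0.12])], duration=0.13)
        b = bin_spike_counts(ts, 0.05)
        assert b.n_bins == 2 and b.counts.sum() == 1

    def test_empty_train_zero_row(self):
        ts = SpikeTrainSet(trains=[np.array([]), np.array([0.01])], duration=1.0)
        counts = bin_spike_counts(ts).counts
        assert counts[0].sum() == 0 and counts[1].sum() == 1


class TestFisherZ:
    def test_identical_rows_clipped(self):
        counts = np.tile([1, 2, 0, 3, 1, 2, 4, 0], (2, 1))
        fc = pairwise_fc(binned_from(counts))
        expected = 0.5 * np.log((2 - 1e-7) / 1e-7)  # atanh(1 - 1e-7)
        assert fc.z[0, 1] == pytest.approx(expected, rel=1e-9)
        # 0.5 * ln((2 - 1e-7)/1e-7) = 0.5 * ln(2e7 - 1)
        assert expected == pytest.approx(8.4056, abs=5e-4)

    def test_hand_computed_correlation(self):
        # rows (1,2,3) and (1,3,2): rho = 0.5 exactly, z = atanh(0.5) = ln(3)/2
        counts = np.array([[1, 2, 3], [1, 3, 2]])
        fc = pairwise_fc(binned_from(counts))
        assert fc.z[0, 1] == pytest.approx(0.5 * np.log(3.0), rel=1e-12)

    def test_rho_08_closed_form(self):
        # x and y = 0.8*x + orthogonal residual with exact variances
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        r = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0, -1.0, -1.0])
        y = 0.8 * x + 0.6 * r  # unit variance, corr exactly 0.8
        z = np.arctanh(np.corrcoef(np.vstack([x, y]))[0, 1])
        assert z == pytest.approx(0.5 * np.log(9.0), rel=1e-12)
        assert z == pytest.approx(1.0986, abs=1e-4)

    def test_independent_trains_mean_z_near_zero(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(0.5, size=(16, 2000))
        fc = pairwise_fc(binned_from(counts))
        assert abs(fc.mean_z()) < 2 / np.sqrt(2000)

    def test_zero_variance_pair_invalid_not_zero(self):
        counts = np.array([[1, 2, 1, 3], [0, 0, 0, 0], [2, 1, 3, 1]])
        fc = pairwise_fc(binned_from(counts))
        assert not fc.valid[0, 1] and not fc.valid[1, 2]
        assert fc.valid[0, 2]
        zv, va = fc.pair_vector()
        assert va.tolist() == [False, True, False]

    def test_too_few_usable_bins_raises(self):
        counts = np.array([[1, 2, 3], [3, 1, 2]])
        b = binned_from(counts, mask_flags=[True, True, False])
        with pytest.raises(ValueError, match="burst mask"):
            pairwise_fc(b)

    def test_permutation_equivariance(self, rng):
        counts = rng.poisson(1.0, size=(6, 500))
        fc = pairwise_fc(binned_from(counts))
        perm = rng.permutation(6)
        fcp = pairwise_fc(binned_from(counts[perm]))
        assert np.allclose(fcp.z, fc.z[np.ix_(perm, perm)])

    def test_rank_order_preserved_by_transform(self, rng):
        counts = rng.poisson(1.0, size=(8, 400))
        fc = pairwise_fc(binned_from(counts))
        i, j = pair_index(8)
        rho = np.tanh(fc.z[i, j])
        assert np.array_equal(np.argsort(rho), np.argsort(fc.z[i, j]))


class TestBurstBias:
    def test_empty_mask_values_equal(self, rng):
        counts = rng.poisson(0.5, size=(8, 400))
        b = binned_from(counts, mask_flags=np.zeros(400, bool))
        z_with, z_without = burst_bias_check(b)
        assert z_with == z_without

    def test_mask_required(self, rng):
        with pytest.raises(ValueError, match="mask"):
            burst_bias_check(binned_from(rng.poisson(0.5, (4, 100))))

    def test_shared_gain_inflates_included_estimate(self, rng):
        # common multiplicative rate modulation inflates correlation when
        # the modulated bins are included
        lam = np.full(600, 0.3)
        lam[200:260] *= 6
        counts = rng.poisson(lam, size=(12, 600))
        flags = np.zeros(600, bool)
        flags[200:260] = True
        z_with, z_without = burst_bias_check(binned_from(counts, mask_flags=flags))
        assert z_with > z_without


class TestThresholdNetwork:
    def _fc(self, z):
        n = z.shape[0]
        valid = ~np.eye(n, dtype=bool)
        from seiznet.connectivity import FCMatrix

        return FCMatrix(z=z, valid=valid, n_bins_used=100, burst_excluded=True)

    def test_all_below_threshold_empty(self):
        z = np.full((4, 4), 0.5)
        np.fill_diagonal(z, 0)
        net = threshold_network(self._fc(z))
        assert net.n_edges == 0 and np.all(net.degrees == 0)

    def test_single_edge_degrees(self):
        z = np.zeros((4, 4))
        z[1, 3] = z[3, 1] = 0.9
        net = threshold_network(self._fc(z))
        assert net.n_edges == 1
        assert net.edges[0, :2].tolist() == [1, 3]
        assert net.degrees.tolist() == [0, 1, 0, 1]

    def test_invalid_pairs_never_edges(self):
        z = np.zeros((3, 3))
        z[0, 1] = z[1, 0] = 2.0
        from seiznet.connectivity import FCMatrix

        valid = ~np.eye(3, dtype=bool)
        valid[0, 1] = valid[1, 0] = False
        fc = FCMatrix(z=z, valid=valid, n_bins_used=10, burst_excluded=False)
        assert threshold_network(fc).n_edges == 0


@given(st.integers(2, 12))
def test_pair_index_counts(n):
    i, j = pair_index(n)
    assert len(i) == n * (n - 1) // 2
    assert np.all(i < j)
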