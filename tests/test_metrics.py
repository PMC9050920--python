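"""Coherence and frequency measures."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from astrogamma.metrics import (CoherenceConfig, CoherenceResult, SpikeRaster,
                                binarize, gamma_frequency, k_astro,
                                mean_frequency, network_coherence,
                                pairwise_coherence)


class TestMeanFrequency:
    def test_regular_train(self):
        trains = [np.arange(0.0, 500.0, 25.0)]
        assert mean_frequency(trains) == pytest.approx(40.0)

    def test_degenerate_returns_zero(self):
        assert mean_frequency([np.array([10.0]), np.array([])]) == 0.0

    def test_pooled_isi_oracle(self):
        # ISIs {20, 20} and {30, 30}: pooled mean 25 ms -> 40 Hz
        trains = [np.array([0.0, 20.0, 40.0]), np.array([0.0, 30.0, 60.0])]
        assert mean_frequency(trains) == pytest.approx(40.0)

    def test_per_neuron_variant(self):
        trains = [np.array([0.0, 20.0, 40.0]), np.array([0.0, 30.0, 60.0])]
        expected = (50.0 + 1000.0 / 30.0) / 2
        assert mean_frequency(trains, pooled=False) == pytest.approx(expected)


class TestPairwiseCoherence:
    def test_identical_nonempty_is_exactly_one(self):
        x = np.array([1, 0, 1, 1, 0])
        assert pairwise_coherence(x, x) == 1.0

    def test_disjoint_support_is_zero(self):
        assert pairwise_coherence([1, 0, 1, 0], [0, 1, 0, 1]) == 0.0

    def test_hand_worked_example(self):
        k = pairwise_coherence([1, 0, 1, 0], [1, 0, 0, 0])
        assert k == pytest.approx(1 / np.sqrt(2), rel=1e-12)

    def test_empty_train_convention(self):
        assert pairwise_coherence([0, 0, 0], [1, 0, 1]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pairwise_coherence([1, 0], [1, 0, 1])

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=30),
           st.lists(st.integers(0, 1), min_size=1, max_size=30))
    def test_symmetric_and_bounded(self, a, b):
        L = min(len(a), len(b))
        x, y = np.array(a[:L]), np.array(b[:L])
        kxy = pairwise_coherence(x, y)
        assert kxy == pairwise_coherence(y, x)
        assert 0.0 <= kxy <= 1.0 + 1e-12


class TestBinarize:
    def test_bin_assignment_half_open(self):
        trains = [np.array([0.0, 4.999, 5.0, 9.9])]
        out = binarize(trains, 0.0, 20.0, 5.0)
        assert out.shape == (1, 4)
        assert list(out[0]) == [1, 1, 0, 0]

    def test_trailing_partial_bin_dropped(self):
        out = binarize([np.array([11.5])], 0.0, 12.0, 5.0)
        assert out.shape[1] == 2  # floor(12/5); the spike at 11.5 is dropped
        assert out.sum() == 0


class TestNetworkCoherence:
    def _raster(self, trains, t0=0.0, t1=1000.0):
        return SpikeRaster([np.asarray(t, float) for t in trains], t0, t1)

    def test_identical_firing_gives_unit_coherence(self):
        t = np.arange(10.0, 1000.0, 40.0)
        raster = self._raster([t, t, t])
        res = network_coherence(raster)
        assert np.allclose(res.k, 1.0)
        assert np.allclose(res.omega, 25.0)

    def test_single_active_neuron_gives_zero(self):
        raster = self._raster([np.arange(10.0, 1000.0, 40.0), [], []])
        res = network_coherence(raster)
        assert np.all(res.k == 0.0)

    def test_independent_poisson_trains_are_incoherent(self, rng):
        trains = [np.sort(rng.uniform(0, 4000.0, 60)) for _ in range(20)]
        res = network_coherence(self._raster(trains, 0.0, 4000.0))
        assert res.k.mean() < 0.2

    def test_relabeling_invariance(self, rng):
        trains = [np.sort(rng.uniform(0, 1000.0, 25)) for _ in range(8)]
        res1 = network_coherence(self._raster(trains))
        perm = rng.permutation(8)
        res2 = network_coherence(self._raster([trains[i] for i in perm]))
        assert np.allclose(res1.k, res2.k)

    def test_requires_full_epoch(self):
        with pytest.raises(ValueError):
            network_coherence(self._raster([[10.0]], 0.0, 300.0))

    def test_spike_outside_window_rejected(self):
        with pytest.raises(ValueError):
            self._raster([[1500.0]], 0.0, 1000.0)


class TestKAstro:
    def _result(self, k, starts=None):
        k = np.asarray(k, float)
        starts = np.arange(k.size) * 500.0 if starts is None else starts
        return CoherenceResult(epoch_starts=starts, k=k,
                               omega=np.full(k.size, 20.0))

    def test_no_pulse_flags_absent_value(self):
        res = self._result([0.5, 0.5])
        t = np.arange(0, 1000.0, 10.0)
        ca = np.full(t.size, 0.1)
        assert k_astro(res, t, ca) is None

    def test_constant_k_inside_single_pulse(self):
        res = self._result([0.6, 0.6, 0.6, 0.6])
        t = np.arange(0, 2000.0, 10.0)
        ca = np.where((t > 600) & (t < 1400), 0.5, 0.1)
        assert k_astro(res, t, ca, direction="potentiation") == 0.6
        assert k_astro(res, t, ca, direction="depression") == 0.6

    def test_two_pulse_average_of_maxima(self):
        res = self._result([0.2, 0.5, 0.1, 0.7, 0.1, 0.1])
        t = np.arange(0, 3000.0, 10.0)
        ca = np.zeros(t.size)
        ca[(t >= 500) & (t < 1000)] = 0.5  # covers the k=0.5 epoch
        ca[(t >= 1500) & (t < 2000)] = 0.5  # covers the k=0.7 epoch
        assert k_astro(res, t, ca, direction="potentiation") == \
            pytest.approx(0.6)

    def test_depression_takes_minima(self):
        res = self._result([0.2, 0.5, 0.1, 0.7, 0.3, 0.1])
        t = np.arange(0, 3000.0, 10.0)
        ca = np.zeros(t.size)
        ca[(t >= 500) & (t < 1000)] = 0.5
        ca[(t >= 1500) & (t < 2000)] = 0.5
        assert k_astro(res, t, ca, direction="depression") == \
            pytest.approx(0.6)  # (0.5 + 0.7)/2: single epoch per pulse

    def test_bad_direction_rejected(self):
        with pytest.raises(ValueError):
            k_astro(self._result([0.1]), np.array([0.0]), np.array([0.5]),
                    direction="sideways")


class TestGammaFrequency:
    def test_all_subthreshold_gives_zero(self):
        assert gamma_frequency(np.full(4, 0.1), np.full(4, 30.0)) == 0.0

    def test_uniform_coherent_epochs(self):
        assert gamma_frequency(np.full(3, 0.5), np.full(3, 21.0)) == 21.0

    def test_masked_mean(self):
        k = np.array([0.1, 0.5, 0.6])
        om = np.array([30.0, 20.0, 22.0])
        assert gamma_frequency(k, om) == pytest.approx(21.0)

    def test_misaligned_series_rejected(self):
        with pytest.raises(ValueError):
            gamma_frequency(np.zeros(3), np.zeros(4))


def test_refining_bins_does_not_increase_coherence(rng):
    # for fixed spike trains, smaller tau can only separate spikes
    trains = [np.sort(rng.uniform(0, 500.0, 15)) for _ in range(6)]
    ks = []
    for tau in (20.0, 10.0, 5.0, 2.5):
        pats = binarize(trains, 0.0, 500.0, tau)
        vals = [pairwise_coherence(pats[i], pats[j])
                for i in range(6) for j in range(i + 1, 6)]
        ks.append(np.mean(vals))
    assert all(a >= b - 1e-9 for a, b in zip(ks, ks[1:]))
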