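import numpy as np
import pytest

import skimnet as sk
from skimnet.kernels import KernelSpec, compress, truncated_response
from skimnet.network import forward


class TestInitInputWeights:
    def test_shape_range_and_determinism(self):
        w = sk.init_input_weights(5, 100, seed=4)
        assert w.shape == (100, 5)
        assert np.all((w > -0.5) & (w < 0.5))
        np.testing.assert_array_equal(w, sk.init_input_weights(5, 100, seed=4))

    def test_sample_mean_consistent_with_uniform(self):
        w = sk.init_input_weights(1000, 1000, seed=0)
        sigma = np.sqrt(1 / 12)  # Uniform(-.5,.5) sd
        assert abs(w.mean()) < 3 * sigma / 1000

    def test_nonpositive_dimensions_rejected(self):
        with pytest.raises(ValueError):
            sk.init_input_weights(0, 10)


class TestSummedInput:
    def test_no_spikes_gives_zero(self):
        w = sk.init_input_weights(3, 7, seed=0)
        r = sk.SpikeRaster(3, 20)
        assert not sk.summed_input(r, w).any()

    def test_single_spike_copies_weight_column(self):
        w = sk.init_input_weights(5, 9, seed=1)
        r = sk.SpikeRaster(5, 12, events={(4, 2)})
        u = sk.summed_input(r, w)
        np.testing.assert_array_equal(u[:, 4], w[:, 2])
        assert not u[:, :4].any() and not u[:, 5:].any()

    def test_simultaneous_spikes_superpose(self):
        w = sk.init_input_weights(5, 9, seed=2)
        r = sk.SpikeRaster(5, 12, events={(4, 2), (4, 0)})
        np.testing.assert_allclose(
            sk.summed_input(r, w)[:, 4], w[:, 2] + w[:, 0], atol=1e-15)

    def test_channel_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sk.summed_input(sk.SpikeRaster(4, 10), np.zeros((3, 5)))


class TestDendriticActivations:
    def test_zero_input_gives_zero_activations(self):
        u = np.zeros((3, 30))
        A = sk.dendritic_activations(u, [KernelSpec("alpha", ts=5)] * 3)
        assert not A.any()

    def test_single_impulse_closed_form(self):
        # one spike of weight w: activation at t0+ts equals compress(w/e)
        w, ts, t0 = 0.3, 8, 5
        u = np.zeros((1, 40))
        u[0, t0] = w
        A = sk.dendritic_activations(u, [KernelSpec("alpha", ts=ts)])
        assert A[0, t0 + ts] == pytest.approx(compress(w * np.exp(-1), 5), abs=1e-12)

    def test_close_spikes_compress_sublinearly(self):
        # depressive adaptation: second spike on the first's envelope
        u1 = np.zeros((1, 100)); u1[0, 20] = 0.4
        u2 = u1.copy(); u2[0, 24] = 0.4
        spec = [KernelSpec("alpha", ts=10)]
        peak1 = sk.dendritic_activations(u1, spec).max()
        peak2 = sk.dendritic_activations(u2, spec).max()
        assert peak1 < peak2 < 2 * peak1

    def test_matches_literal_per_spike_bookkeeping(self, rng):
        # convolution path vs direct superposition of per-spike responses
        M, K = 4, 200
        u = np.zeros((M, K))
        for _ in range(30):
            u[rng.integers(M), rng.integers(K)] += rng.normal()
        kernels = [KernelSpec("alpha", ts=float(ts)) for ts in (3, 8, 15, 30)]
        A = sk.dendritic_activations(u, kernels)
        V = np.zeros((M, K))
        for j, spec in enumerate(kernels):
            h = truncated_response(spec)
            for t0 in np.nonzero(u[j])[0]:
                seg = min(len(h), K - t0)
                V[j, t0:t0 + seg] += u[j, t0] * h[:seg]
        np.testing.assert_allclose(A, compress(V, 5), atol=1e-10)

    def test_logistic_activations_bounded_even_when_dense(self):
        u = np.full((2, 500), 50.0)  # absurdly dense drive
        A = sk.dendritic_activations(u, [KernelSpec("alpha", ts=20)] * 2)
        assert np.all(np.abs(A) < 0.5)

    def test_causality_truncating_input_preserves_prefix(self, toy_task):
        _, seq, _ = toy_task
        w = sk.init_input_weights(5, 10, seed=3)
        kernels = sk.sample_kernel_bank(10, "alpha", 200, seed=3)
        full = sk.dendritic_activations(sk.summed_input(seq.raster, w), kernels)
        cut = 700
        part = sk.dendritic_activations(
            sk.summed_input(seq.raster.restrict(cut), w), kernels)
        np.testing.assert_allclose(part, full[:, :cut], atol=1e-12)

    def test_kernel_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sk.dendritic_activations(np.zeros((3, 10)), [KernelSpec("alpha", ts=5)])


class TestSoma:
    def test_zero_weights_give_zero_trace(self):
        assert not sk.soma(np.ones((4, 9)), np.zeros((2, 4))).any()

    def test_one_hot_weights_select_a_row(self, rng):
        A = rng.normal(size=(5, 20))
        w = np.zeros((1, 5)); w[0, 3] = 1.0
        np.testing.assert_array_equal(sk.soma(A, w)[0], A[3])

    def test_matches_triple_loop_oracle(self, rng):
        A = rng.normal(size=(6, 11))
        W = rng.normal(size=(3, 6))
        y = sk.soma(A, W)
        oracle = np.zeros((3, 11))
        for n in range(3):
            for j in range(6):
                for t in range(11):
                    oracle[n, t] += W[n, j] * A[j, t]
        np.testing.assert_allclose(y, oracle, atol=1e-12)


class TestThresholdSpikes:
    def test_subthreshold_trace_emits_nothing(self):
        y = np.full((1, 50), 0.2)
        assert sk.threshold_spikes(y, 0.25).n_events == 0

    def test_square_pulse_fires_once_at_onset(self):
        y = np.zeros((1, 50)); y[0, 10:20] = 1.0
        out = sk.threshold_spikes(y, 0.25)
        assert out.events == frozenset({(10, 0)})

    def test_two_separated_pulses_fire_twice(self):
        y = np.zeros((1, 60)); y[0, 5:9] = 1.0; y[0, 30:35] = 1.0
        assert sorted(t for t, _ in sk.threshold_spikes(y, 0.25).events) == [5, 30]

    def test_already_above_at_start_counts_as_onset(self):
        y = np.ones((1, 10))
        assert sk.threshold_spikes(y, 0.5).events == frozenset({(0, 0)})

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            sk.threshold_spikes(np.zeros((1, 5)), 0.0)


class TestForward:
    def test_forward_is_deterministic(self, toy_task, trained):
        _, _, test_seq = toy_task
        model, _, _ = trained
        a = forward(test_seq.raster, model)
        b = forward(test_seq.raster, model)
        assert a == b

    def test_reset_mode_agrees_when_nothing_fires(self, toy_task):
        # with an unreachable threshold, reset never triggers and the
        # stepwise simulation must reproduce the vectorized trace
        _, seq, _ = toy_task
        short = seq.raster.restrict(400)
        model = sk.train(short, [e for e in seq.presentation_end_times if e < 380],
                         M=8, seed=2)
        model.threshold = 1e9
        _, y_fast, _ = forward(short, model, return_trace=True)
        _, y_step, _ = forward(short, model, reset=True, return_trace=True)
        np.testing.assert_allclose(y_step, y_fast, atol=1e-9)

    def test_reset_quenches_dendrites_after_firing(self):
        # one strong spike, identity-ish readout: after the first output
        # spike the pending kernel tail is cleared, so the soma falls back
        raster = sk.SpikeRaster(1, 60, events={(5, 0)})
        model = sk.SKIMModel(
            L=1, M=1, N=1, input_weights=np.array([[0.5]]),
            kernels=[KernelSpec("alpha", ts=10)],
            output_weights=np.array([[10.0]]), threshold=0.5,
        )
        out_plain, y_plain, _ = forward(raster, model, return_trace=True)
        out_reset, y_reset, _ = forward(raster, model, reset=True, return_trace=True)
        t_fire = min(t for t, _ in out_reset.events)
        assert y_reset[0, t_fire + 1] == pytest.approx(0.0, abs=1e-12)
        assert y_plain[0, t_fire + 1] > 0.4

    def test_order_determines_spike_history_adaptation(self):
        # compressing after the filter makes a second spike on the first's
        # envelope count for less (depressive adaptation); compressing each
        # impulse before superposition scales every event independently, so
        # responses add exactly and the adaptation is lost
        spec = [KernelSpec("alpha", ts=10)]
        one = np.zeros((1, 120)); one[0, 20] = 0.4
        two = one.copy(); two[0, 24] = 0.4
        shifted = np.zeros((1, 120)); shifted[0, 24] = 0.4

        for order, additive in [("filter_then_nonlinearity", False),
                                ("nonlinearity_then_filter", True)]:
            a_one = sk.dendritic_activations(one, spec, order=order)
            a_shift = sk.dendritic_activations(shifted, spec, order=order)
            a_two = sk.dendritic_activations(two, spec, order=order)
            if additive:
                np.testing.assert_allclose(a_two, a_one + a_shift, atol=1e-12)
            else:
                assert a_two.max() < (a_one + a_shift).max() - 1e-4

    def test_alternate_order_still_trains_a_working_detector(self, toy_task):
        _, seq, _ = toy_task
        model, A, tgt = sk.train(seq.raster, seq.presentation_end_times,
                                 M=30, seed=1, order="nonlinearity_then_filter",
                                 return_internals=True)
        base = np.linalg.norm(tgt.values)
        assert sk.training_residual(model.output_weights, A, tgt) < base
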