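import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import skimnet as sk
from skimnet.kernels import KernelSpec, truncated_response


class TestImpulseResponse:
    def test_alpha_peaks_at_time_constant_with_value_1_over_e(self):
        r = sk.impulse_response(KernelSpec("alpha", ts=10), 50)
        assert r[10] == pytest.approx(np.exp(-1))
        assert r.argmax() == 10

    def test_alpha_starts_at_zero(self):
        for ts in (3, 10, 42.5):
            assert sk.impulse_response(KernelSpec("alpha", ts=ts), 5)[0] == 0.0

    def test_delayed_families_are_zero_before_delay(self):
        for fam, kw in [("delayed_gaussian", dict(sigma=4.0)),
                        ("delayed_alpha", dict(ts=10.0))]:
            r = sk.impulse_response(KernelSpec(fam, delay=20, **kw), 60)
            assert np.all(r[:20] == 0.0)
            assert r[20:].max() > 0

    def test_delayed_alpha_is_shifted_alpha(self):
        base = sk.impulse_response(KernelSpec("alpha", ts=7), 40)
        shifted = sk.impulse_response(KernelSpec("delayed_alpha", ts=7, delay=15), 55)
        np.testing.assert_allclose(shifted[15:], base, atol=1e-12)

    def test_resonant_is_damped_sine(self):
        r = sk.impulse_response(KernelSpec("resonant", ts=40, omega=0.1), 100)
        t = np.arange(100.0)
        np.testing.assert_allclose(r, np.exp(-t / 40) * np.sin(0.1 * t))

    def test_custom_table_returned_verbatim(self):
        table = (0.0, 0.5, 1.0, 0.25)
        r = sk.impulse_response(KernelSpec("custom", custom_table=table), 6)
        np.testing.assert_allclose(r, [0.0, 0.5, 1.0, 0.25, 0.0, 0.0])

    def test_family_parameter_mismatch_is_configuration_error(self):
        with pytest.raises(ValueError):
            KernelSpec("alpha", ts=0)
        with pytest.raises(ValueError):
            KernelSpec("delayed_gaussian", sigma=0)
        with pytest.raises(ValueError):
            KernelSpec("resonant", ts=10, omega=0)
        with pytest.raises(ValueError):
            KernelSpec("nonesuch")

    def test_truncation_tail_is_negligible(self):
        # dropped tail: magnitude < 1e-6 x peak and < 1e-4 of the L1 mass
        for spec in (KernelSpec("alpha", ts=30), KernelSpec("leaky", ts=50),
                     KernelSpec("delayed_gaussian", delay=40, sigma=10)):
            h = truncated_response(spec)
            tail = spec.response_at(np.arange(spec.truncation, spec.truncation + 2000))
            assert np.abs(tail).max() < 1e-6 * np.abs(h).max()
            assert np.abs(tail).sum() < 1e-4 * np.abs(h).sum()


class TestCompress:
    def test_worked_logistic_values(self):
        assert sk.compress(0.0, 5, "logistic") == 0.0
        assert sk.compress(1.0, 5, "logistic") == pytest.approx(
            1 / (1 + np.exp(-5)) - 0.5, abs=1e-12)
        assert sk.compress(1e6, 5, "logistic") == pytest.approx(0.5, abs=1e-9)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(-50, 50), st.floats(0.1, 20), st.sampled_from(["logistic", "tanh"]))
    def test_bounded_odd_monotone(self, v, k, kind):
        a = sk.compress(v, k, kind)
        assert -0.5 < a < 0.5
        assert sk.compress(-v, k, kind) == pytest.approx(-a, abs=1e-12)
        if abs(k * v) < 18:  # strictly increasing until float saturation
            assert sk.compress(v + 0.5, k, kind) > a
        else:
            assert sk.compress(v + 0.5, k, kind) >= a

    def test_none_is_identity(self, rng):
        v = rng.normal(size=20)
        np.testing.assert_array_equal(sk.compress(v, 5, "none"), v)

    def test_nonpositive_gain_rejected(self):
        with pytest.raises(ValueError):
            sk.compress(1.0, 0.0)


class TestKernelFwhm:
    def test_alpha_matches_published_widths(self):
        # tau=10 -> ~24 ms, tau=20 -> ~49 ms at 1 ms per step
        assert sk.kernel_fwhm(KernelSpec("alpha", ts=10)) == pytest.approx(24.46, abs=0.01)
        assert sk.kernel_fwhm(KernelSpec("alpha", ts=20)) == pytest.approx(48.93, abs=0.01)

    @pytest.mark.parametrize("tau", [2.5, 10, 33, 80])
    def test_alpha_fwhm_scales_linearly_at_244_percent(self, tau):
        assert sk.kernel_fwhm(KernelSpec("alpha", ts=tau)) / tau == pytest.approx(
            2.446, abs=0.01)

    def test_causal_half_gaussian_width(self):
        # zero before the delay leaves only the right half of the bump
        got = sk.kernel_fwhm(KernelSpec("delayed_gaussian", delay=30, sigma=4))
        assert got == pytest.approx(4 * np.sqrt(2 * np.log(2)), abs=0.01)

    def test_multimodal_resonant_rejected(self):
        with pytest.raises(ValueError, match="unimodal"):
            sk.kernel_fwhm(KernelSpec("resonant", ts=40, omega=0.5))


class TestPreferredDelay:
    def test_alpha_peaks_at_its_time_constant(self):
        assert sk.preferred_delay(KernelSpec("alpha", ts=10)) == pytest.approx(10, abs=1e-3)

    def test_delayed_alpha_adds_the_delay(self):
        spec = KernelSpec("delayed_alpha", ts=10, delay=15)
        assert sk.preferred_delay(spec) == pytest.approx(25, abs=1e-3)

    def test_resonant_matches_grid_argmax_oracle(self):
        spec = KernelSpec("resonant", ts=40, omega=0.1)
        grid = np.arange(0, 800, 1e-3)
        oracle = grid[np.argmax(np.exp(-grid / 40) * np.sin(0.1 * grid))]
        assert sk.preferred_delay(spec) == pytest.approx(oracle, abs=1e-2)


class TestSampleKernelBank:
    def test_alpha_time_constants_span_half_tmax(self):
        bank = sk.sample_kernel_bank(100, "alpha", t_max=200, seed=3)
        ts = np.array([k.ts for k in bank])
        assert len(bank) == 100
        assert np.all((ts > 1) & (ts <= 100))

    def test_same_seed_reproduces_bank(self):
        a = sk.sample_kernel_bank(50, "delayed_gaussian", t_max=200, seed=9)
        b = sk.sample_kernel_bank(50, "delayed_gaussian", t_max=200, seed=9)
        assert a == b

    def test_mean_time_constant_near_quarter_tmax(self):
        bank = sk.sample_kernel_bank(10_000, "alpha", t_max=200, seed=5)
        mean = np.mean([k.ts for k in bank])
        # U(1, 100) mean 50.5, law of large numbers
        assert mean == pytest.approx(50.5, rel=0.02)

    def test_heuristic_mode_fixes_ts(self):
        bank = sk.sample_kernel_bank(10, "alpha", t_max=200, seed=0, ts_mode="heuristic")
        assert all(k.ts == 100.0 for k in bank)

    def test_delayed_family_draws_delays_in_range(self):
        bank = sk.sample_kernel_bank(200, "delayed_alpha", t_max=200, seed=1)
        delays = np.array([k.delay for k in bank])
        assert np.all((delays >= 0) & (delays <= 200))

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            sk.sample_kernel_bank(5, "custom", t_max=100, seed=0)


class TestLoadCustomKernel:
    def test_loads_tabulated_response(self, tmp_path):
        from skimnet.kernels import load_custom_kernel

        p = tmp_path / "k.csv"
        p.write_text("timestep,value\n0,0.0\n1,0.6\n2,1.0\n3,0.3\n")
        spec = load_custom_kernel(p)
        np.testing.assert_allclose(sk.impulse_response(spec, 6),
                                   [0.0, 0.6, 1.0, 0.3, 0.0, 0.0])
        assert sk.preferred_delay(spec) == pytest.approx(2, abs=0.51)

    def test_gapped_timesteps_rejected(self, tmp_path):
        from skimnet.kernels import load_custom_kernel

        p = tmp_path / "k.csv"
        p.write_text("timestep,value\n0,0.0\n2,1.0\n")
        with pytest.raises(ValueError, match="consecutive"):
            load_custom_kernel(p)
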