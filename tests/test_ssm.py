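"""Unit tests for the diagonal selective scan and its gated block."""

import numpy as np
import pytest

from cohortssm.autodiff import Tensor
from cohortssm.ssm import (ChannelSequence, SSMConfig, discretize,
                           init_parameters, selective_scan,
                           selective_scan_reference, ssm_block_forward)


def random_scan_inputs(rng, n, channels, state):
    u = rng.standard_normal((n, channels)).astype(np.float32)
    delta = rng.uniform(1e-3, 0.5, (n, channels)).astype(np.float32)
    B = rng.standard_normal((n, state)).astype(np.float32)
    C = rng.standard_normal((n, state)).astype(np.float32)
    A = -rng.uniform(0.05, 3.0, (channels, state)).astype(np.float32)
    skip = rng.standard_normal(channels).astype(np.float32)
    return u, delta, B, C, A, skip


class TestInitParameters:
    def test_log_spaced_A(self):
        params = init_parameters(SSMConfig(model_dim=4, expansion=2, state_dim=16), seed=0)
        expected = np.tile(np.arange(1, 17, dtype=np.float32), (8, 1))
        np.testing.assert_allclose(np.exp(params.A_log.data), expected, rtol=1e-6)

    def test_deterministic(self):
        cfg = SSMConfig(model_dim=4)
        a = init_parameters(cfg, seed=0)
        b = init_parameters(cfg, seed=0)
        for (ka, va), (kb, vb) in zip(sorted(a.parameters().items()),
                                      sorted(b.parameters().items())):
            assert ka == kb
            np.testing.assert_array_equal(va.data, vb.data)

    def test_single_state_log_spacing_is_zero(self):
        params = init_parameters(SSMConfig(model_dim=4, state_dim=1), seed=0)
        np.testing.assert_array_equal(params.A_log.data, 0.0)

    def test_delta_bias_lands_in_init_range(self):
        cfg = SSMConfig(model_dim=8, dt_init_range=(1e-3, 1e-1))
        params = init_parameters(cfg, seed=1)
        dt = np.log1p(np.exp(params.b_dt.data))
        assert dt.min() >= 1e-3 * 0.999 and dt.max() <= 1e-1 * 1.001

    def test_invalid_dims_rejected(self):
        with pytest.raises(ValueError):
            SSMConfig(model_dim=0)
        with pytest.raises(ValueError):
            SSMConfig(model_dim=4, state_dim=-1)


class TestDiscretize:
    def test_closed_form_half(self):
        A_bar, B_bar = discretize(np.log(2.0), -1.0, 1.0)
        assert np.isclose(A_bar, 0.5)
        assert np.isclose(B_bar, np.log(2.0))

    def test_small_delta_freezes_state(self):
        A_bar, B_bar = discretize(1e-12, -3.0, 5.0)
        assert np.isclose(A_bar, 1.0, atol=1e-9)
        assert np.isclose(B_bar, 0.0, atol=1e-9)

    def test_scalar_hand_value(self):
        A_bar, B_bar = discretize(0.1, -2.0, 3.0)
        assert np.isclose(A_bar, np.exp(-0.2))
        assert np.isclose(B_bar, 0.3)

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ValueError):
            discretize(0.0, -1.0, 1.0)


class TestReferenceScan:
    def test_zero_input_gives_zero(self, rng):
        u, delta, B, C, A, skip = random_scan_inputs(rng, 5, 3, 4)
        y = selective_scan_reference(np.zeros_like(u), delta, B, C, A, skip)
        np.testing.assert_array_equal(y, 0.0)

    def test_hand_unrolled_three_steps(self):
        # A_bar=0.5, B_bar=1, C=1, skip=0, u=[1,1,1] -> h=[1,1.5,1.75]
        delta = np.full((3, 1), np.log(2.0))
        A = np.array([[-1.0]])
        B = np.full((3, 1), 1.0 / np.log(2.0))   # B_bar = delta*B = 1
        C = np.ones((3, 1))
        u = np.ones((3, 1))
        y = selective_scan_reference(u, delta, B, C, A, np.zeros(1))
        np.testing.assert_allclose(y[:, 0], [1.0, 1.5, 1.75], rtol=1e-6)

    def test_time_invariant_case_equals_convolution(self, rng):
        # constant Delta/B/C: y_t = sum_k C.(A_bar^(k) * B_bar) u_{t-k} + D u_t
        n, ch, st = 12, 2, 3
        delta = np.tile(rng.uniform(0.05, 0.3, (1, ch)), (n, 1))
        B = np.tile(rng.standard_normal((1, st)), (n, 1))
        C = np.tile(rng.standard_normal((1, st)), (n, 1))
        A = -rng.uniform(0.1, 2.0, (ch, st))
        skip = rng.standard_normal(ch)
        u = rng.standard_normal((n, ch))
        y = selective_scan_reference(u, delta, B, C, A, skip)

        A_bar = np.exp(delta[0][:, None] * A)          # (ch, st)
        B_bar = delta[0][:, None] * B[0][None, :]      # (ch, st)
        kernel = np.empty((n, ch))
        for k in range(n):
            kernel[k] = (A_bar ** k * B_bar) @ C[0]
        expected = np.empty_like(y)
        for t in range(n):
            acc = sum(kernel[k] * u[t - k] for k in range(t + 1))
            expected[t] = acc + skip * u[t]
        np.testing.assert_allclose(y, expected, atol=1e-5)


class TestSelectiveScan:
    def test_matches_reference_on_100_random_instances(self):
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(100):
            n = int(rng.integers(1, 65))
            ch = int(rng.integers(1, 65))
            args = random_scan_inputs(rng, n, ch, 16)
            y_ref = selective_scan_reference(*args)
            y_opt = selective_scan(*args)
            worst = max(worst, float(np.abs(y_ref - y_opt).max()))
        assert worst <= 1e-5

    def test_single_step_unroll(self, rng):
        u, delta, B, C, A, skip = random_scan_inputs(rng, 1, 4, 3)
        y = selective_scan(u, delta, B, C, A, skip)
        B_bar = delta[0][:, None] * B[0][None, :]
        expected = (B_bar * u[0][:, None]) @ C[0] + skip * u[0]
        np.testing.assert_allclose(y[0], expected, atol=1e-5)

    def test_zero_readout_and_skip_annihilates(self, rng):
        u, delta, B, C, A, skip = random_scan_inputs(rng, 6, 3, 4)
        y = selective_scan(u, delta, B, np.zeros_like(C), A, np.zeros_like(skip))
        np.testing.assert_array_equal(y, 0.0)

    def test_nonpositive_delta_rejected(self, rng):
        u, delta, B, C, A, skip = random_scan_inputs(rng, 4, 2, 3)
        delta[1, 0] = 0.0
        with pytest.raises(ValueError):
            selective_scan(u, delta, B, C, A, skip)

    def test_gradients_match_finite_differences(self, rng):
        args = random_scan_inputs(rng, 8, 3, 4)
        tensors = [Tensor(a, requires_grad=True) for a in args]
        w = rng.standard_normal((8, 3)).astype(np.float32)
        out = selective_scan(*tensors)
        (out * Tensor(w)).sum().backward()

        def value(arrays):
            return float((selective_scan_reference(*arrays) * w).sum())

        eps = 1e-4
        for i, t in enumerate(tensors):
            idx = np.unravel_index(np.argmax(np.abs(t.grad)), t.grad.shape)
            arrays = [a.astype(np.float64).copy() for a in args]
            arrays[i][idx] += eps
            up = value(arrays)
            arrays[i][idx] -= 2 * eps
            dn = value(arrays)
            fd = (up - dn) / (2 * eps)
            assert np.isclose(t.grad[idx], fd, rtol=5e-3, atol=1e-4), (i, idx)

    def test_long_sequence_stays_bounded(self, rng):
        # with A < 0, |h_t| <= max|B_bar u| / (1 - max A_bar): no overflow at 1e4 steps
        n, ch, st = 10_000, 2, 3
        u = rng.uniform(-1, 1, (n, ch)).astype(np.float32)
        delta = np.full((n, ch), 0.05, dtype=np.float32)
        B = np.tile(rng.standard_normal((1, st)).astype(np.float32), (n, 1))
        C = np.tile(rng.standard_normal((1, st)).astype(np.float32), (n, 1))
        A = -np.abs(rng.uniform(0.5, 2.0, (ch, st))).astype(np.float32)
        skip = np.zeros(ch, dtype=np.float32)
        y = selective_scan(u, delta, B, C, A, skip)
        assert np.all(np.isfinite(y))
        A_bar_max = float(np.exp(0.05 * A).max())
        B_bar_absmax = float(np.abs(0.05 * B).max())
        bound = st * B_bar_absmax / (1.0 - A_bar_max) * float(np.abs(C).max()) + 1.0
        assert np.abs(y).max() <= bound


class TestBlockForward:
    def test_zero_output_projection_gives_zero(self, small_config, rng):
        from cohortssm.ssm import init_parameters
        params = init_parameters(small_config, seed=0)
        params.W_out.data[:] = 0.0
        params.b_out.data[:] = 0.0
        S = ChannelSequence(rng.standard_normal((6, 8)).astype(np.float32))
        out = ssm_block_forward(S, params)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_deterministic(self, small_config, rng):
        from cohortssm.ssm import init_parameters
        params = init_parameters(small_config, seed=0)
        S = ChannelSequence(rng.standard_normal((6, 8)).astype(np.float32))
        a = ssm_block_forward(S, params)
        b = ssm_block_forward(S, params)
        np.testing.assert_array_equal(a.values, b.values)

    def test_single_position_matches_hand_composition(self, small_config, rng):
        from cohortssm.ssm import init_parameters
        params = init_parameters(small_config, seed=5)
        x_in = rng.standard_normal((1, 8)).astype(np.float32)
        out = ssm_block_forward(ChannelSequence(x_in), params).values[0]

        def silu(v):
            return v / (1.0 + np.exp(-v))

        inner = small_config.inner_dim
        xz = x_in[0] @ params.W_in.data + params.b_in.data
        x, z = silu(xz[:inner]), xz[inner:]
        dt = np.log1p(np.exp(x @ params.W_dt_down.data @ params.W_dt_up.data
                             + params.b_dt.data))
        B = x @ params.W_B.data
        C = x @ params.W_C.data
        B_bar = dt[:, None] * B[None, :]
        y = (B_bar * x[:, None]) @ C + params.skip_D.data * x
        expected = (y * silu(z)) @ params.W_out.data + params.b_out.data
        np.testing.assert_allclose(out, expected, atol=2e-5)

    def test_channel_mismatch_rejected(self, small_config, rng):
        from cohortssm.ssm import init_parameters
        params = init_parameters(small_config, seed=0)
        with pytest.raises(ValueError):
            ssm_block_forward(ChannelSequence(np.ones((3, 5))), params)


class TestOptionalCausalConvolution:
    def test_conv_branch_runs_and_differs_from_default(self, rng):
        from cohortssm.ssm import init_parameters
        cfg_off = SSMConfig(model_dim=8, conv_width=0)
        cfg_on = SSMConfig(model_dim=8, conv_width=3)
        S = ChannelSequence(rng.standard_normal((6, 8)).astype(np.float32))
        out_off = ssm_block_forward(S, init_parameters(cfg_off, seed=0))
        out_on = ssm_block_forward(S, init_parameters(cfg_on, seed=0))
        assert np.all(np.isfinite(out_on.values))
        assert not np.allclose(out_off.values, out_on.values)

    def test_conv_is_causal(self, rng):
        # changing a later position never changes an earlier output of the
        # value-branch convolution (scan itself is causal by construction)
        from cohortssm.ssm import init_parameters
        params = init_parameters(SSMConfig(model_dim=8, conv_width=3), seed=1)
        x = rng.standard_normal((6, 8)).astype(np.float32)
        x2 = x.copy()
        x2[5] += 1.0
        a = ssm_block_forward(ChannelSequence(x), params).values
        b = ssm_block_forward(ChannelSequence(x2), params).values
        np.testing.assert_allclose(a[:5], b[:5], atol=1e-6)
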