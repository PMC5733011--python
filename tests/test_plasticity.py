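"""Unit tests for traces, the two STDP rules and the heterosynaptic decay.

The event-driven trace implementation is validated against a brute-force
oracle that recomputes every trace from the raw spike history at each event.
"""

import numpy as np
import pytest

from seqreservoir import (PlasticityParams, eq1_update, eq2_update, eq3_decay,
                          hebbian_vs_combined_rate, make_traces, update_traces)
from seqreservoir.plasticity import apply_plasticity_step, decay_rate

P = PlasticityParams()


class TestTraces:
    def test_decay_one_time_constant(self):
        tr = make_traces(1, 1)
        tr.x_pre[0] = 1.0
        none = np.zeros(1, dtype=bool)
        for _ in range(60):  # 30 ms at dt = 0.5
            update_traces(tr, none, none, 0.5, P)
        assert tr.x_pre[0] == pytest.approx(np.exp(-1), rel=0.005)

    def test_spike_increments_by_exactly_one(self):
        tr = make_traces(1, 1)
        tr.x_post[0] = 0.25
        spike = np.ones(1, dtype=bool)
        update_traces(tr, np.zeros(1, dtype=bool), spike, 0.5, P)
        assert tr.x_post[0] == pytest.approx(0.25 * np.exp(-0.5 / P.tau_post) + 1.0)

    def test_two_spikes_superpose(self):
        # two spikes 10 ms apart on the fast (tau = 10 ms) trace: 1 + e^-1
        tr = make_traces(1, 1)
        none = np.zeros(1, dtype=bool)
        spike = np.ones(1, dtype=bool)
        update_traces(tr, none, spike, 0.5, P)
        for _ in range(19):
            update_traces(tr, none, none, 0.5, P)
        update_traces(tr, none, spike, 0.5, P)
        assert tr.x_pre_fast[0] == pytest.approx(1 + np.exp(-1), rel=1e-9)

    def test_negative_trace_rejected(self):
        tr = make_traces(1, 1)
        tr.x_pre[0] = -0.1
        with pytest.raises(ValueError):
            update_traces(tr, np.zeros(1, dtype=bool), np.zeros(1, dtype=bool), 0.5, P)


class TestEq1PowerLawSTDP:
    def test_zero_crossing_at_offset(self):
        assert eq1_update(0.3, P.offset, P) == pytest.approx(0.0)

    def test_saturates_at_bound(self):
        assert eq1_update(P.w_max_in, 3.0, P) == pytest.approx(0.0)

    def test_direct_formula_value(self):
        # eta*(x_pre - offset)*(w_max - w)^mu = 0.05 * 0.6 * 1 = 0.03
        p = PlasticityParams(offset=0.4)
        assert eq1_update(0.0, 1.0, p) == pytest.approx(0.03)

    def test_depression_below_offset(self):
        assert eq1_update(0.5, 0.0, P) < 0

    def test_out_of_bounds_weight_rejected(self):
        with pytest.raises(ValueError):
            eq1_update(1.5, 1.0, P)


class TestEq2ExponentialSTDP:
    def test_pre_spike_with_no_post_history_is_neutral(self):
        assert eq2_update(0.3, 0.0, 0.9, "pre", P) == pytest.approx(0.0)

    def test_post_spike_at_bound_is_neutral(self):
        assert eq2_update(P.w_max_ee, 0.7, 0.9, "post", P) == pytest.approx(0.0)

    def test_direct_formula_value(self):
        # 0.01 * 0.5 * 0.8 * 0.3^0.9
        expect = 0.01 * 0.5 * 0.8 * 0.3 ** 0.9
        assert eq2_update(0.2, 0.5, 0.8, "post", P) == pytest.approx(expect, rel=1e-12)

    def test_pre_event_depresses(self):
        assert eq2_update(0.3, 1.0, 0.0, "pre", P) < 0

    def test_unknown_event_rejected(self):
        with pytest.raises(ValueError):
            eq2_update(0.2, 0.5, 0.5, "both", P)


class TestEq3Decay:
    def test_baseline_is_fixed_point(self):
        assert eq3_decay(P.w0, 1.0, 0.0, P, 0.5) == pytest.approx(P.w0)

    def test_silent_neuron_no_decay(self):
        assert eq3_decay(0.45, 0.0, 0.0, P, 0.5) == pytest.approx(0.45)

    def test_matches_linear_ode_closed_form(self):
        # constant gamma = 0.01/ms for 100 ms: w = w0 + (w(0)-w0) e^-1
        p = PlasticityParams(k_decay=0.01)  # with x_post=1, theta=0 -> gamma = 0.01
        w = 0.5
        for _ in range(200):
            w = eq3_decay(w, 1.0, 0.0, p, 0.5, v_thresh=-52.0)
        assert w == pytest.approx(0.2 + 0.3 * np.exp(-1), rel=0.01)

    def test_decay_rate_grows_with_theta(self):
        lo = decay_rate(1.0, 0.0, P, -52.0)
        hi = decay_rate(1.0, 52.0, P, -52.0)
        assert hi == pytest.approx(2 * lo)

    def test_unstable_step_rejected(self):
        p = PlasticityParams(k_decay=1.0)
        with pytest.raises(ValueError):
            eq3_decay(0.4, 10.0, 0.0, p, 50.0)

    def test_contraction_toward_baseline(self, rng):
        # ||w - w0|| is non-increasing under the decay for any activity level
        w = rng.uniform(0, P.w_max_ee, size=200)
        for _ in range(50):
            x_post = rng.uniform(0, 3)
            w_next = eq3_decay(w, x_post, rng.uniform(0, 30), P, 0.5)
            assert np.linalg.norm(w_next - P.w0) <= np.linalg.norm(w - P.w0) + 1e-12
            w = w_next


def brute_force_history(raster_in, raster_post, p, dt, theta=0.0, v_thresh=-52.0,
                        w_in0=None, w_ee0=None, mask_in=None, mask_ee=None):
    """Oracle: replay the raster, recomputing every trace from the full spike
    history at each step (no incremental state)."""
    n_steps, n_in = raster_in.shape
    n_post = raster_post.shape[1]

    def trace_at(raster, col, t, tau):
        ts = np.flatnonzero(raster[:t + 1, col])
        return np.exp(-(t - ts) * dt / tau).sum()

    w_in = w_in0.copy()
    w_ee = w_ee0.copy()
    th = np.full(n_post, theta)
    for t in range(n_steps):
        x_pre = np.array([trace_at(raster_in, i, t, p.tau_pre) for i in range(n_in)])
        x_fast = np.array([trace_at(raster_post, i, t, p.tau_pre_fast)
                           for i in range(n_post)])
        x_post = np.array([trace_at(raster_post, i, t, p.tau_post)
                           for i in range(n_post)])
        posts = np.flatnonzero(raster_post[t])
        for j in posts:
            d = p.eta_in * (x_pre - p.offset) * (p.w_max_in - w_in[:, j]) ** p.mu
            w_in[:, j] = np.clip(w_in[:, j] + d * mask_in[:, j], 0, p.w_max_in)
            d = (p.eta2 * x_post[j] * x_fast
                 * (p.w_max_ee - w_ee[:, j]) ** p.mu)
            w_ee[:, j] = np.clip(w_ee[:, j] + d * mask_ee[:, j], 0, p.w_max_ee)
        for i in posts:
            d = p.eta1 * x_post * w_ee[i] ** p.mu
            w_ee[i] = np.clip(w_ee[i] - d * mask_ee[i], 0, p.w_max_ee)
        gamma = np.where(x_post > 0.02,
                         p.k_decay * x_post ** 2 * (abs(v_thresh) + th) / abs(v_thresh),
                         0.0)
        w_ee -= dt * gamma[None, :] * (w_ee - p.w0) * mask_ee
    return w_in, w_ee


def test_event_driven_updates_match_full_history_oracle(rng):
    """200 random steps, 10 input and 10 excitatory channels: the incremental
    trace implementation must reproduce the from-scratch recomputation."""
    n_steps, n_in, n_post = 200, 10, 10
    p = PlasticityParams()
    raster_in = rng.random((n_steps, n_in)) < 0.05
    raster_post = rng.random((n_steps, n_post)) < 0.04
    mask_in = (rng.random((n_in, n_post)) < 0.6).astype(float)
    mask_ee = (rng.random((n_post, n_post)) < 0.5).astype(float)
    np.fill_diagonal(mask_ee, 0.0)
    w_in0 = rng.uniform(0, 0.3, (n_in, n_post)) * mask_in
    w_ee0 = rng.uniform(0, 0.5, (n_post, n_post)) * mask_ee

    w_in = w_in0.copy()
    w_ee = w_ee0.copy()
    tr = make_traces(n_in, n_post)
    theta = np.zeros(n_post)
    for t in range(n_steps):
        update_traces(tr, raster_in[t], raster_post[t], 0.5, p)
        apply_plasticity_step(w_in, w_ee, p.w_max_in * mask_in,
                              p.w_max_ee * mask_ee, p.w0 * mask_ee, tr,
                              raster_post[t], theta, p, 0.5, -52.0)

    w_in_o, w_ee_o = brute_force_history(raster_in, raster_post, p, 0.5,
                                         w_in0=w_in0, w_ee0=w_ee0,
                                         mask_in=mask_in, mask_ee=mask_ee)
    np.testing.assert_allclose(w_in, w_in_o, rtol=1e-10, atol=1e-12)
    np.testing.assert_allclose(w_ee, w_ee_o, rtol=1e-10, atol=1e-12)


def test_weight_bounds_hold_under_random_spike_fuzz(rng):
    p = PlasticityParams()
    n_in, n_post = 8, 6
    mask_in = np.ones((n_in, n_post))
    mask_ee = 1.0 - np.eye(n_post)
    w_in = rng.uniform(0, 1.0, (n_in, n_post))
    w_ee = rng.uniform(0, 0.5, (n_post, n_post)) * mask_ee
    tr = make_traces(n_in, n_post)
    theta = rng.uniform(0, 50, n_post)
    for t in range(400):
        sp_in = rng.random(n_in) < 0.3   # dense spiking stresses the clipping
        sp_post = rng.random(n_post) < 0.3
        update_traces(tr, sp_in, sp_post, 0.5, p)
        apply_plasticity_step(w_in, w_ee, p.w_max_in * mask_in,
                              p.w_max_ee * mask_ee, p.w0 * mask_ee, tr,
                              sp_post, theta, p, 0.5, -52.0)
        assert w_in.min() >= 0 and w_in.max() <= p.w_max_in + 1e-12
        assert w_ee.min() >= 0 and w_ee.max() <= p.w_max_ee + 1e-12


class TestHebbianVsCombined:
    def test_silent_post_neuron_changes_nothing(self):
        table = hebbian_vs_combined_rate([0.0], duration_ms=2000.0)
        assert np.allclose(table.dw_per_s.abs(), 0.0, atol=1e-6)

    def test_decay_regulates_high_rate_potentiation(self):
        table = hebbian_vs_combined_rate([80.0], w_init=0.4, duration_ms=4000.0)
        eq2 = table.query("mode == 'eq2_only'").dw_per_s.iloc[0]
        comb = table.query("mode == 'combined'").dw_per_s.iloc[0]
        assert comb < eq2

    def test_below_baseline_drifts_up_without_spikes(self):
        p = PlasticityParams()
        w = 0.05
        for _ in range(2000):
            w = eq3_decay(w, 1.2, 0.0, p, 0.5)
        assert 0.05 < w <= p.w0 + 1e-9
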