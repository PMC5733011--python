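"""Unit tests for the LIF dynamics, noise injection and synaptic currents."""

import numpy as np
import pytest

from seqreservoir import (NeuronParams, SynapseParams, SynapticCurrents,
                          accumulate_synaptic_current, default_exc_params,
                          default_inh_params, initial_state, inject_noise,
                          step_neurons)


def make_state(n_exc=4, n_inh=2):
    return initial_state(n_exc, n_inh, default_exc_params(), default_inh_params())


def run_free(v0_offset, n_ms, dt=0.5, tau_m=100.0):
    """Drive a single excitatory neuron with zero current from v_rest + offset."""
    exc, inh = NeuronParams(tau_m=tau_m), default_inh_params()
    state = make_state(1, 1)
    state.v[0] = exc.v_rest + v0_offset
    zero = np.zeros(2)
    for _ in range(round(n_ms / dt)):
        step_neurons(state, zero, exc, inh, dt)
    return state.v[0] - exc.v_rest


def test_rest_is_fixed_point():
    assert run_free(0.0, 50.0) == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("t_ms", [30.0, 100.0, 250.0])
def test_free_decay_matches_exponential(t_ms):
    # closed form: v - v_rest = 10 * exp(-t / tau_m), tau_m = 100 ms
    assert run_free(10.0, t_ms) == pytest.approx(10.0 * np.exp(-t_ms / 100.0), rel=0.01)


def test_suprathreshold_current_spikes_then_resets():
    exc, inh = default_exc_params(), default_inh_params()
    state = make_state(1, 1)
    current = np.array([1.0, 0.0])  # 100 mV steady-state depolarization
    spiked = False
    for _ in range(2000):
        flags = step_neurons(state, current, exc, inh, 0.5)
        if flags[0]:
            spiked = True
            assert state.v[0] == exc.v_reset
            break
    assert spiked


def test_refractory_neuron_never_spikes():
    exc, inh = default_exc_params(), default_inh_params()
    state = make_state(1, 1)
    state.refrac_remaining[0] = exc.t_refrac
    huge = np.array([1e4, 0.0])
    for _ in range(round(exc.t_refrac / 0.5)):
        flags = step_neurons(state, huge, exc, inh, 0.5)
        assert not flags[0]


def test_firing_rate_monotone_in_current():
    exc, inh = default_exc_params(), default_inh_params()
    rates = []
    for amp in [0.2, 0.4, 0.8, 1.6, 3.2]:
        state = make_state(1, 1)
        current = np.array([amp, 0.0])
        n = 0
        for _ in range(4000):  # 2 s
            n += int(step_neurons(state, current, exc, inh, 0.5)[0])
        rates.append(n)
    assert all(b >= a for a, b in zip(rates, rates[1:]))
    assert rates[-1] > rates[0]


def test_theta_increments_on_spike_and_relaxes():
    exc = NeuronParams(theta_plus=0.1, tau_theta=100.0, theta_init=0.0)
    inh = default_inh_params()
    state = make_state(2, 1)
    state.theta[:] = 0.0
    current = np.array([2.0, 0.0, 0.0])
    for _ in range(200):
        step_neurons(state, current, exc, inh, 0.5)
    assert state.theta[0] > 0
    assert state.theta[1] == 0.0
    peak = state.theta[0]
    zero = np.zeros(3)
    for _ in range(round(10 * exc.tau_theta / 0.5)):
        step_neurons(state, zero, exc, inh, 0.5)
    assert state.theta[0] < 1e-3 * peak


def test_relaxation_to_rest_with_zero_input():
    exc, inh = default_exc_params(), default_inh_params()
    state = make_state(3, 2)
    state.v += np.array([5.0, -3.0, 8.0, 4.0, -2.0])
    zero = np.zeros(5)
    gaps = []
    for k in range(round(10 * exc.tau_m / 0.5)):
        step_neurons(state, zero, exc, inh, 0.5)
        gaps.append(np.abs(state.v[:3] - exc.v_rest).max())
    assert all(b <= a + 1e-12 for a, b in zip(gaps, gaps[1:]))
    assert gaps[-1] < 1e-3


def test_step_neurons_rejects_bad_inputs():
    exc, inh = default_exc_params(), default_inh_params()
    state = make_state(2, 1)
    with pytest.raises(ValueError):
        step_neurons(state, np.zeros(5), exc, inh, 0.5)
    with pytest.raises(ValueError):
        step_neurons(state, np.array([np.nan, 0.0, 0.0]), exc, inh, 0.5)


class TestInjectNoise:
    def test_zero_amplitude_is_identity(self, rng):
        x = np.arange(5.0)
        assert inject_noise(x, 0.0, rng) is x

    def test_moments_match_gaussian(self):
        rng = np.random.default_rng(0)
        added = inject_noise(np.zeros(10**5), 0.5, rng)
        se = 0.5 / np.sqrt(10**5)
        assert abs(added.mean()) < 3 * se
        assert added.std() == pytest.approx(0.5, rel=0.02)

    def test_deterministic_under_fixed_seed(self):
        a = inject_noise(np.zeros(100), 1.0, np.random.default_rng(3))
        b = inject_noise(np.zeros(100), 1.0, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_negative_amplitude_rejected(self, rng):
        with pytest.raises(ValueError):
            inject_noise(np.zeros(3), -0.1, rng)


class TestSynapticCurrents:
    def test_no_spikes_gives_zero_current(self, small_topology, small_net):
        cur = SynapticCurrents(50, 1.0, 2.0, 0.5)
        spikes = {pw: np.zeros(m.shape[0], dtype=bool)
                  for pw, m in small_topology.masks.items()}
        total = accumulate_synaptic_current(spikes, small_net.weights,
                                            small_net.syn, cur, small_net.n_exc, 50)
        np.testing.assert_array_equal(total, np.zeros(50))

    def test_single_spike_jump_and_exponential_decay(self):
        cur = SynapticCurrents(1, 1.0, 2.0, 0.5)
        w = 0.3
        gain = 2.0
        cur.decay()
        cur.deliver(slice(0, 1), np.array([gain * w]), inhibitory=False)
        assert cur.total()[0] == pytest.approx(gain * w)
        for k in range(1, 9):
            cur.decay()
            assert cur.total()[0] == pytest.approx(gain * w * np.exp(-0.5 * k / 1.0))

    def test_inhibitory_pathway_contributes_negatively(self, small_topology, small_net):
        # same weight on an E->E and an I->E synapse: with the inhibitory gain
        # at least the excitatory gain, the net drive cannot be positive
        topo = small_topology
        n_e = topo.n_exc
        weights = {pw: np.zeros_like(w) for pw, w in small_net.weights.items()}
        weights["ee"][1, 0] = 0.2
        weights["ie"][1, 0] = 0.2
        spikes = {pw: np.zeros(m.shape[0], dtype=bool) for pw, m in topo.masks.items()}
        spikes["ee"] = np.zeros(n_e, dtype=bool)
        spikes["ee"][1] = True
        spikes["ie"] = np.zeros(topo.n_inh, dtype=bool)
        spikes["ie"][1] = True
        cur = SynapticCurrents(50, 1.0, 2.0, 0.5)
        gains = SynapseParams(g_ee=1.0, g_ie=2.0)
        total = accumulate_synaptic_current(spikes, weights, gains, cur,
                                            n_e, 50)
        assert total[0] <= 0

    def test_negative_weight_rejected(self, small_topology, small_net, rng):
        weights = {pw: w.copy() for pw, w in small_net.weights.items()}
        weights["ee"][0, 1] = -0.5
        spikes = {"ee": np.ones(small_topology.n_exc, dtype=bool)}
        cur = SynapticCurrents(50, 1.0, 2.0, 0.5)
        with pytest.raises(ValueError):
            accumulate_synaptic_current(spikes, weights, small_net.syn, cur,
                                        small_topology.n_exc, 50)
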