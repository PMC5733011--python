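"""Leaky integrate-and-fire dynamics on a fixed time grid.

The membrane equation  tau_m dv/dt = (v_rest - v) + tau_m * I  is advanced
with the exact exponential update for piecewise-constant current, so halving
dt leaves single-neuron trajectories essentially unchanged (no forward-Euler
drift).  A neuron spikes when v >= v_thresh + theta outside its refractory
period, resets to v_reset, and its homeostatic offset theta is incremented;
theta decays exponentially every step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import NeuronParams


@dataclass
class ReservoirState:
    """Mutable per-neuron state of the whole reservoir.

    ``v`` covers all reservoir neurons (excitatory first); ``theta`` covers
    excitatory neurons only, since homeostasis does not apply to inhibitory
    cells.
    """

    v: np.ndarray
    theta: np.ndarray
    refrac_remaining: np.ndarray   # ms left, >= 0
    last_spike_flags: np.ndarray   # bool, all reservoir neurons

    def validate(self) -> None:
        if not np.all(np.isfinite(self.v)):
            raise ValueError("membrane potentials must be finite")
        if np.any(self.theta < 0) or np.any(self.refrac_remaining < 0):
            raise ValueError("theta and refractory counters must be non-negative")


def initial_state(n_exc: int, n_inh: int, exc: NeuronParams, inh: NeuronParams) -> ReservoirState:
    v = np.empty(n_exc + n_inh)
    v[:n_exc] = exc.v_rest
    v[n_exc:] = inh.v_rest
    return ReservoirState(
        v=v,
        theta=np.full(n_exc, exc.theta_init, dtype=float),
        refrac_remaining=np.zeros(n_exc + n_inh),
        last_spike_flags=np.zeros(n_exc + n_inh, dtype=bool),
    )


def _lif_population_step(v, input_current, refrac, thresh_eff, p: NeuronParams, dt: float):
    """Advance one population in place; returns the bool spike vector."""
    alpha = np.exp(-dt / p.tau_m)
    drive = p.v_rest + input_current * p.tau_m
    v[:] = drive + (v - drive) * alpha
    refractory = refrac > 0
    v[refractory] = p.v_reset
    refrac[refractory] = np.maximum(refrac[refractory] - dt, 0.0)
    spikes = (~refractory) & (v >= thresh_eff)
    v[spikes] = p.v_reset
    refrac[spikes] = p.t_refrac
    return spikes


def step_neurons(state: ReservoirState, input_current: np.ndarray,
                 exc_params: NeuronParams, inh_params: NeuronParams,
                 dt: float) -> np.ndarray:
    """Advance all reservoir neurons one step of size ``dt``.

    ``input_current`` is the summed synaptic (plus noise) current in mV/ms,
    one entry per reservoir neuron, held constant across the step.  Mutates
    ``state`` and returns the spike flags (also stored in
    ``state.last_spike_flags``).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if input_current.shape != state.v.shape:
        raise ValueError("current vector length must match neuron count")
    if not np.all(np.isfinite(input_current)):
        raise ValueError("input current must be finite")
    n_e = state.theta.shape[0]

    spikes_e = _lif_population_step(
        state.v[:n_e], input_current[:n_e], state.refrac_remaining[:n_e],
        exc_params.v_thresh + state.theta, exc_params, dt)
    spikes_i = _lif_population_step(
        state.v[n_e:], input_current[n_e:], state.refrac_remaining[n_e:],
        inh_params.v_thresh, inh_params, dt)

    state.theta[spikes_e] += exc_params.theta_plus
    state.theta *= np.exp(-dt / exc_params.tau_theta)
    state.last_spike_flags = np.concatenate([spikes_e, spikes_i])
    return state.last_spike_flags


def inject_noise(currents: np.ndarray, n0: float, rng: np.random.Generator) -> np.ndarray:
    """Add per-neuron Gaussian current noise of amplitude ``n0``.

    Implements I_post = sum_i[W_i * Input_i] + N0 * randn per neuron per
    step; with n0 = 0 the input vector is returned unchanged.
    """
    if n0 < 0:
        raise ValueError("noise amplitude must be non-negative")
    if n0 == 0:
        return currents
    return currents + n0 * rng.standard_normal(currents.shape)


class SynapticCurrents:
    """Exponentially decaying current-based synapses, split by pathway sign.

    Excitatory-origin and inhibitory-origin currents are integrated
    separately (decay constants ``tau_e`` and ``tau_i``); the net current
    delivered to the neurons is their difference, so inhibitory pathways
    always contribute negatively while stored weights stay non-negative.
    """

    def __init__(self, n_total: int, tau_e: float, tau_i: float, dt: float):
        self.exc = np.zeros(n_total)
        self.inh = np.zeros(n_total)
        self._decay_e = np.exp(-dt / tau_e)
        self._decay_i = np.exp(-dt / tau_i)

    def decay(self) -> None:
        self.exc *= self._decay_e
        self.inh *= self._decay_i

    def deliver(self, target: slice, drive: np.ndarray, inhibitory: bool) -> None:
        if inhibitory:
            self.inh[target] += drive
        else:
            self.exc[target] += drive

    def total(self) -> np.ndarray:
        return self.exc - self.inh

    def reset(self) -> None:
        self.exc[:] = 0.0
        self.inh[:] = 0.0


def accumulate_synaptic_current(spikes_pre: dict, weights: dict, gains,
                                currents: SynapticCurrents, n_exc: int,
                                n_reservoir: int | None = None) -> np.ndarray:
    """Decay currents one step and add the contribution of this step's spikes.

    ``spikes_pre`` maps pathway name -> bool vector over that pathway's
    presynaptic population; ``weights`` maps pathway -> non-negative weight
    matrix (pre, post).  Returns the net current vector over all reservoir
    neurons (excitatory entries first).  ``n_reservoir`` applies the
    size-scaling of the recurrent gains.
    """
    currents.decay()
    targets = {"in_e": (slice(0, n_exc), False), "ee": (slice(0, n_exc), False),
               "ei": (slice(n_exc, None), False), "ie": (slice(0, n_exc), True),
               "ii": (slice(n_exc, None), True)}
    for pw, flags in spikes_pre.items():
        w = weights[pw]
        if np.any(w < 0):
            raise ValueError(f"negative stored weight on pathway {pw!r}")
        idx = np.flatnonzero(flags)
        if idx.size == 0:
            continue
        drive = gains.gain(pw, n_reservoir) * w[idx].sum(axis=0)
        target, inhibitory = targets[pw]
        currents.deliver(target, drive, inhibitory)
    return currents.total()
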