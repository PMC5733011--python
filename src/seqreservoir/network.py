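"""The reservoir simulation engine.

Couples the LIF populations, the current-based synapses and the three
plasticity rules on the fixed 0.5 ms grid.  Spikes emitted at step t are
delivered to their targets at step t+1 (one-step synaptic delay).  The
per-step semantics are exactly those of the functional operations in
:mod:`seqreservoir.neurons` and :mod:`seqreservoir.plasticity`; this class
only organizes them into a fast loop and owns the mutable state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import HAVE_NUMBA, plasticity_events
from .neurons import ReservoirState, SynapticCurrents, _lif_population_step, initial_state
from .params import NeuronParams, PlasticityParams, SynapseParams, default_exc_params, default_inh_params
from .plasticity import TraceSet, apply_plasticity_step, make_traces
from .topology import NetworkTopology, init_weights


@dataclass
class SegmentRecord:
    """Spike statistics of one simulated segment."""

    n_steps: int
    dt: float
    spike_counts: np.ndarray              # per reservoir neuron
    binned_exc: np.ndarray | None = None  # (n_bins, n_exc) spike counts
    spike_events: list | None = None      # (time_ms, neuron_id) tuples

    @property
    def exc_rate_hz(self) -> float:
        n_e = self.spike_counts.size if self.binned_exc is None else self.binned_exc.shape[1]
        return float(self.spike_counts[:n_e].sum() / n_e / (self.n_steps * self.dt / 1000.0))


class Reservoir:
    """A wired reservoir: topology + weights + neuron state + traces."""

    def __init__(self, topology: NetworkTopology, weights: dict | None = None,
                 exc_params: NeuronParams | None = None,
                 inh_params: NeuronParams | None = None,
                 syn_params: SynapseParams | None = None,
                 plast_params: PlasticityParams | None = None,
                 dt: float = 0.5):
        self.topology = topology
        self.exc_params = exc_params or default_exc_params()
        self.inh_params = inh_params or default_inh_params()
        self.syn = syn_params or SynapseParams()
        self.plast = plast_params or PlasticityParams()
        self.dt = dt
        self.n_exc = topology.n_exc
        self.n_inh = topology.n_inh
        self.n_total = self.n_exc + self.n_inh
        self.weights = weights if weights is not None else init_weights(topology)
        for pw, w in self.weights.items():
            if np.any(w < 0):
                raise ValueError(f"negative stored weight on pathway {pw!r}")
        # masked bound/baseline arrays used by the plasticity kernels
        self._wmax_in_masked = self.plast.w_max_in * topology.masks["in_e"]
        self._wmax_ee_masked = self.plast.w_max_ee * topology.masks["ee"]
        self._w0_masked = self.plast.w0 * topology.masks["ee"]
        # size-scaled pathway gains (recurrent gains are per reference size)
        self._gain = {pw: self.syn.gain(pw, self.n_total)
                      for pw in ("in_e", "ee", "ei", "ie", "ii")}
        self.state: ReservoirState = initial_state(
            self.n_exc, self.n_inh, self.exc_params, self.inh_params)
        self.currents = SynapticCurrents(self.n_total, self.syn.tau_e, self.syn.tau_i, dt)
        self.traces: TraceSet = make_traces(topology.config.n_inputs, self.n_exc)

    # ------------------------------------------------------------------ state
    def reset_state(self, reset_theta: bool = False) -> None:
        """Return membranes, currents, traces and refractoriness to rest.

        The homeostatic threshold persists across resets unless
        ``reset_theta`` is requested; it is the one variable that survives the
        inter-word rest phases and the transition from training to testing.
        """
        theta = self.state.theta.copy()
        self.state = initial_state(self.n_exc, self.n_inh, self.exc_params, self.inh_params)
        if not reset_theta:
            self.state.theta = theta
        self.currents.reset()
        self.traces = make_traces(self.topology.config.n_inputs, self.n_exc)

    def normalize_input_weights(self) -> None:
        """Divisive normalization of the input pathway (no-op when disabled).

        Rescales every excitatory neuron's incoming input weights to the
        configured mean per connected synapse; called between word
        presentations during training.
        """
        target = self.plast.w_in_target_mean
        if target is None:
            return
        from .topology import normalize_columns
        normalize_columns(self.weights["in_e"], self.topology.masks["in_e"],
                          target, self.plast.w_max_in)

    # ------------------------------------------------------------------- loop
    def run_segment(self, input_raster: np.ndarray | None = None,
                    n_steps: int | None = None, plastic: bool = False,
                    noise_amplitude: float = 0.0,
                    rng: np.random.Generator | None = None,
                    bin_steps: int | None = None,
                    record_spikes: bool = False,
                    _reference: bool = False) -> SegmentRecord:
        """Advance the network through one stimulus segment.

        ``input_raster`` is a bool (n_steps, n_inputs) spike raster, or None
        for a silent segment of ``n_steps``.  With ``plastic`` the three
        learning rules run online; otherwise weights are frozen.  Gaussian
        current noise of amplitude ``noise_amplitude`` (mV/ms) is drawn from
        ``rng`` each step and injected into every reservoir neuron.

        The recurrent heterosynaptic decay is tracked lazily: because
        dw = -gamma (w - w0) dt is linear in the deviation from baseline, each
        postsynaptic column carries a scalar accumulated decay factor that is
        folded into the stored weights whenever an STDP event reads or writes
        the column, and at segment end.  ``_reference`` switches to the plain
        dense per-step implementation (identical semantics, used to validate
        the fast path in the tests).
        """
        if input_raster is not None:
            n_steps = input_raster.shape[0]
            if input_raster.shape[1] != self.topology.config.n_inputs:
                raise ValueError("raster width must equal the number of input channels")
        if n_steps is None:
            raise ValueError("need an input raster or an explicit n_steps")
        if noise_amplitude < 0:
            raise ValueError("noise amplitude must be non-negative")
        if noise_amplitude > 0 and rng is None:
            raise ValueError("noise injection requires an rng")

        dt = self.dt
        n_e, n_i = self.n_exc, self.n_inh
        w = self.weights
        g_in, g_ee, g_ei, g_ie, g_ii = (self._gain[pw] for pw in
                                        ("in_e", "ee", "ei", "ie", "ii"))
        cur = self.currents
        state = self.state
        traces = self.traces
        exc_p, inh_p = self.exc_params, self.inh_params
        theta_decay = np.exp(-dt / exc_p.tau_theta)
        d_pre = np.exp(-dt / self.plast.tau_pre)
        d_fast = np.exp(-dt / self.plast.tau_pre_fast)
        d_post = np.exp(-dt / self.plast.tau_post)

        p = self.plast
        counts = np.zeros(self.n_total, dtype=np.int64)
        binned = None
        if bin_steps:
            binned = np.zeros((int(np.ceil(n_steps / bin_steps)), n_e), dtype=np.int32)
        events = [] if record_spikes else None

        lazy = plastic and p.decay_every_step and not _reference
        if lazy:
            w_ee = w["ee"]
            w0m = self._w0_masked
            wmax_ee_m = self._wmax_ee_masked
            wmax_in_m = self._wmax_in_masked
            dev = w_ee - w0m          # deviation from baseline, column factor F pending
            fac = np.ones(n_e)
            vref = abs(exc_p.v_thresh)

        for t in range(n_steps):
            cur.decay()
            if input_raster is not None:
                in_idx = np.flatnonzero(input_raster[t])
                if in_idx.size:
                    cur.exc[:n_e] += g_in * w["in_e"][in_idx].sum(axis=0)
            sp = state.last_spike_flags
            e_idx = np.flatnonzero(sp[:n_e])
            if e_idx.size:
                if lazy:
                    rows = w0m[e_idx] + dev[e_idx] * fac[None, :]
                    cur.exc[:n_e] += g_ee * rows.sum(axis=0)
                else:
                    cur.exc[:n_e] += g_ee * w["ee"][e_idx].sum(axis=0)
                cur.exc[n_e:] += g_ei * w["ei"][e_idx].sum(axis=0)
            i_idx = np.flatnonzero(sp[n_e:])
            if i_idx.size:
                cur.inh[:n_e] += g_ie * w["ie"][i_idx].sum(axis=0)
                cur.inh[n_e:] += g_ii * w["ii"][i_idx].sum(axis=0)
            current = cur.exc - cur.inh
            if noise_amplitude > 0:
                current = current + noise_amplitude * rng.standard_normal(self.n_total)

            spikes_e = _lif_population_step(
                state.v[:n_e], current[:n_e], state.refrac_remaining[:n_e],
                exc_p.v_thresh + state.theta, exc_p, dt)
            spikes_i = _lif_population_step(
                state.v[n_e:], current[n_e:], state.refrac_remaining[n_e:],
                inh_p.v_thresh, inh_p, dt)
            state.theta[spikes_e] += exc_p.theta_plus
            state.theta *= theta_decay
            state.last_spike_flags[:n_e] = spikes_e
            state.last_spike_flags[n_e:] = spikes_i

            if plastic:
                traces.x_pre *= d_pre
                traces.x_pre_fast *= d_fast
                traces.x_post *= d_post
                if input_raster is not None and in_idx.size:
                    traces.x_pre[in_idx] += 1.0
                se = np.flatnonzero(spikes_e)
                if se.size:
                    traces.x_pre_fast[se] += 1.0
                    traces.x_post[se] += 1.0
                if not lazy:
                    apply_plasticity_step(
                        w["in_e"], w["ee"], self._wmax_in_masked,
                        self._wmax_ee_masked, self._w0_masked, traces,
                        spikes_e, state.theta, p, dt, exc_p.v_thresh)
                else:
                    if se.size:
                        if HAVE_NUMBA:
                            plasticity_events(
                                w["in_e"], dev, fac, w0m, wmax_in_m, wmax_ee_m,
                                traces.x_pre, traces.x_pre_fast, traces.x_post,
                                se, p.eta_in, p.offset, p.mu, p.w_max_in,
                                p.eta1, p.eta2, p.w_max_ee)
                        else:
                            # input pathway, power-law STDP on post spikes
                            cols = w["in_e"][:, se]
                            cols += (p.eta_in * (traces.x_pre - p.offset)[:, None]
                                     * (wmax_in_m[:, se] - cols) ** p.mu)
                            np.clip(cols, 0.0, p.w_max_in, out=cols)
                            w["in_e"][:, se] = cols
                            # fold pending decay into the spiking columns
                            dev[:, se] *= fac[se][None, :]
                            fac[se] = 1.0
                            # recurrent potentiation on post spikes
                            cols = w0m[:, se] + dev[:, se]
                            cols += (p.eta2 * traces.x_post[se][None, :]
                                     * traces.x_pre_fast[:, None]
                                     * (wmax_ee_m[:, se] - cols) ** p.mu)
                            np.clip(cols, 0.0, p.w_max_ee, out=cols)
                            dev[:, se] = cols - w0m[:, se]
                            # recurrent depression on pre spikes
                            rows = w0m[se] + dev[se] * fac[None, :]
                            rows -= p.eta1 * traces.x_post[None, :] * rows ** p.mu
                            np.clip(rows, 0.0, p.w_max_ee, out=rows)
                            dev[se] = (rows - w0m[se]) / fac[None, :]
                    gamma = (p.k_decay * traces.x_post ** 2
                             * (vref + state.theta) / vref)
                    np.multiply(fac, 1.0 - np.where(
                        traces.x_post > 0.02, dt * gamma, 0.0), out=fac)

            counts[:n_e] += spikes_e
            counts[n_e:] += spikes_i
            if binned is not None:
                binned[t // bin_steps] += spikes_e
            if events is not None:
                for nid in np.flatnonzero(state.last_spike_flags):
                    events.append((t * dt, int(nid)))

        if lazy:
            np.add(w0m, dev * fac[None, :], out=w_ee)

        return SegmentRecord(n_steps=n_steps, dt=dt, spike_counts=counts,
                             binned_exc=binned, spike_events=events)


def spikes_to_frame(record: SegmentRecord, n_exc: int):
    """Spike events of a segment as a (time_ms, neuron_id, population) table."""
    import pandas as pd

    if record.spike_events is None:
        raise ValueError("segment was run without record_spikes=True")
    rows = [(t, nid, "excitatory" if nid < n_exc else "inhibitory")
            for t, nid in record.spike_events]
    return pd.DataFrame(rows, columns=["time_ms", "neuron_id", "population"])
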