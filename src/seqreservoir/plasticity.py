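"""Trace-based synaptic plasticity: two Hebbian STDP rules plus
heterosynaptic decay.

Three rules act on the two plastic pathways:

* **Input -> excitatory (power-law STDP).**  When a postsynaptic neuron
  fires, dw = eta_in * (x_pre - offset) * (w_max_in - w)^mu, where x_pre is a
  30 ms presynaptic trace.  A recent presynaptic spike (x_pre > offset)
  potentiates; otherwise the synapse depresses, which realizes the
  anti-causal branch through the offset rather than a separate window.

* **E -> E (exponential weight-dependent STDP).**  On a presynaptic spike,
  dw = -eta1 * x_post * w^mu; on a postsynaptic spike,
  dw = +eta2 * x_post * x_pre_fast * (w_max_ee - w)^mu, with fast traces
  (tau = 10 ms pre, 20 ms post) so only tightly correlated firing produces
  meaningful updates.

* **E -> E heterosynaptic decay (every step).**  dw/dt = -gamma(t) (w - w0)
  with gamma = k_decay * x_post^2 * (|v_thresh| + theta)/|v_thresh|.  The
  rate depends only on postsynaptic activity and the neuron's homeostatic
  threshold, so hyperactive or long-sequence neurons relax their incoming
  recurrent weights toward the baseline w0 from either side.

Traces use decay-then-increment semantics on the simulation grid: every step
each trace is multiplied by exp(-dt/tau), then incremented by exactly 1 for
each spike of its neuron in that step.  Weight updates within a step use the
trace values after that step's increments (one fixed, documented convention;
the brute-force oracle in the tests reproduces it from the raw spike
history).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import PlasticityParams


@dataclass
class TraceSet:
    """Exponentially filtered spike histories used by the learning rules."""

    x_pre: np.ndarray        # per input channel, tau_pre (30 ms)
    x_pre_fast: np.ndarray   # per excitatory neuron, tau_pre_fast (10 ms)
    x_post: np.ndarray       # per excitatory neuron, tau_post (20 ms)

    def validate(self) -> None:
        for arr in (self.x_pre, self.x_pre_fast, self.x_post):
            if np.any(arr < 0):
                raise ValueError("traces must be non-negative")


def make_traces(n_inputs: int, n_exc: int) -> TraceSet:
    return TraceSet(np.zeros(n_inputs), np.zeros(n_exc), np.zeros(n_exc))


def update_traces(traces: TraceSet, input_spikes: np.ndarray,
                  exc_spikes: np.ndarray, dt: float, p: PlasticityParams) -> TraceSet:
    """Decay every trace one step, then add 1 for each spiking neuron."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    traces.validate()
    traces.x_pre *= np.exp(-dt / p.tau_pre)
    traces.x_pre_fast *= np.exp(-dt / p.tau_pre_fast)
    traces.x_post *= np.exp(-dt / p.tau_post)
    traces.x_pre[input_spikes] += 1.0
    traces.x_pre_fast[exc_spikes] += 1.0
    traces.x_post[exc_spikes] += 1.0
    return traces


def eq1_update(w, x_pre, p: PlasticityParams):
    """Power-law STDP delta for the input pathway, applied on a post spike.

    Broadcasts over arrays; the caller clips the updated weight to
    [0, w_max_in].
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0) or np.any(w > p.w_max_in):
        raise ValueError("weight outside [0, w_max_in]")
    return p.eta_in * (np.asarray(x_pre) - p.offset) * (p.w_max_in - w) ** p.mu


def eq2_update(w, x_post, x_pre_fast, event: str, p: PlasticityParams):
    """Exponential weight-dependent STDP delta for the recurrent pathway.

    ``event`` selects the branch: ``"pre"`` (depression, uses only the
    postsynaptic trace) or ``"post"`` (potentiation, uses the product of post
    and fast pre traces).
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0) or np.any(w > p.w_max_ee):
        raise ValueError("weight outside [0, w_max_ee]")
    if event == "pre":
        return -p.eta1 * np.asarray(x_post) * w ** p.mu
    if event == "post":
        return (p.eta2 * np.asarray(x_post) * np.asarray(x_pre_fast)
                * (p.w_max_ee - w) ** p.mu)
    raise ValueError(f"unknown event tag {event!r}")


def decay_rate(x_post, theta, p: PlasticityParams, v_thresh: float):
    """gamma(t): heterosynaptic decay rate per postsynaptic neuron (1/ms)."""
    vref = abs(v_thresh)
    return p.k_decay * np.asarray(x_post) ** 2 * (vref + np.asarray(theta)) / vref


def eq3_decay(w, x_post, theta, p: PlasticityParams, dt: float, v_thresh: float = -52.0):
    """One Euler step of the decay toward w0; fixed point at w = w0.

    ``w`` may be a (pre, post) matrix with ``x_post``/``theta`` per column.
    Rejects steps with gamma*dt >= 1 (unstable explicit update).
    """
    gamma = decay_rate(x_post, theta, p, v_thresh)
    if np.any(gamma * dt >= 1.0):
        raise ValueError("gamma*dt >= 1: decay step unstable, reduce dt or k_decay")
    w = np.asarray(w, dtype=float)
    return w - dt * gamma * (w - p.w0)


def apply_plasticity_step(w_in, w_ee, wmax_in_masked, wmax_ee_masked, w0_masked,
                          traces: TraceSet, exc_spikes: np.ndarray,
                          theta: np.ndarray, p: PlasticityParams, dt: float,
                          v_thresh: float, x_post_cutoff: float = 0.02) -> None:
    """Apply one simulation step of all three rules in place.

    Order within a step (fixed for reproducibility): the caller has already
    integrated the neurons and updated the traces; here Eq-1/Eq-2 event
    updates fire for this step's spikes, then the heterosynaptic decay acts
    on the E->E weights.

    The connectivity masks enter through the precomputed arrays
    ``wmax_in_masked`` = w_max_in * mask, ``wmax_ee_masked`` = w_max_ee * mask
    and ``w0_masked`` = w0 * mask: absent synapses have w = 0 and masked
    bound/baseline 0, so every update vanishes on them identically and no
    explicit mask multiply is needed in the hot loop.

    Columns whose postsynaptic trace is below ``x_post_cutoff`` are skipped in
    the decay; their rate gamma = k * x_post^2 is below k * 4e-4/ms, which
    moves a weight by less than one part in 1e4 over an entire presentation.
    """
    post_idx = np.flatnonzero(exc_spikes)
    if post_idx.size:
        # input pathway: power-law STDP on post spikes
        cols = w_in[:, post_idx]
        cols += (p.eta_in * (traces.x_pre - p.offset)[:, None]
                 * (wmax_in_masked[:, post_idx] - cols) ** p.mu)
        np.clip(cols, 0.0, p.w_max_in, out=cols)
        w_in[:, post_idx] = cols
        # recurrent potentiation on post spikes
        cols = w_ee[:, post_idx]
        cols += (p.eta2 * traces.x_post[post_idx][None, :]
                 * traces.x_pre_fast[:, None]
                 * (wmax_ee_masked[:, post_idx] - cols) ** p.mu)
        np.clip(cols, 0.0, p.w_max_ee, out=cols)
        w_ee[:, post_idx] = cols
        # recurrent depression on pre spikes (same excitatory population);
        # absent synapses stay at 0 since 0^mu = 0
        rows = w_ee[post_idx, :]
        rows -= p.eta1 * traces.x_post[None, :] * rows ** p.mu
        np.clip(rows, 0.0, p.w_max_ee, out=rows)
        w_ee[post_idx, :] = rows
    if p.decay_every_step:
        # the decay moves weights toward w0 from either side, so it cannot
        # leave [0, w_max_ee] while gamma*dt < 1; no clip needed here
        active = np.flatnonzero(traces.x_post > x_post_cutoff)
        if active.size:
            gamma = decay_rate(traces.x_post[active], theta[active], p, v_thresh)
            if np.any(gamma * dt >= 1.0):
                raise ValueError("gamma*dt >= 1: decay step unstable")
            shrink = dt * gamma[None, :]
            cols = w_ee[:, active]
            cols *= 1.0 - shrink
            cols += shrink * w0_masked[:, active]
            w_ee[:, active] = cols


def hebbian_vs_combined_rate(post_rates_hz, pre_rate_hz: float = 20.0,
                             duration_ms: float = 10000.0, dt: float = 0.5,
                             w_init: float = 0.3, seed: int = 0,
                             p: PlasticityParams | None = None,
                             v_thresh: float = -52.0):
    """Diagnostic: net E->E weight drift per second vs. postsynaptic rate.

    Simulates a single synapse between independent Poisson pre/post neurons
    and reports the mean dw/s under the exponential STDP rule alone and with
    the heterosynaptic decay added.  For weights above the baseline w0 the
    combined curve lies below the STDP-only curve at high postsynaptic rates,
    which is the mechanism that regulates over-potentiated synapses.
    """
    import pandas as pd

    p = p or PlasticityParams()
    rows = []
    for mode in ("eq2_only", "combined"):
        for r_post in post_rates_hz:
            rng = np.random.default_rng(seed)  # shared spike trains across modes
            w = w_init
            x_post = x_fast = 0.0
            n_steps = round(duration_ms / dt)
            p_pre = pre_rate_hz * dt / 1000.0
            p_post = r_post * dt / 1000.0
            d_fast, d_post = np.exp(-dt / p.tau_pre_fast), np.exp(-dt / p.tau_post)
            for _ in range(n_steps):
                s_pre = rng.random() < p_pre
                s_post = rng.random() < p_post
                x_fast = x_fast * d_fast + s_pre
                x_post = x_post * d_post + s_post
                if s_post:
                    w += p.eta2 * x_post * x_fast * (p.w_max_ee - w) ** p.mu
                if s_pre:
                    w -= p.eta1 * x_post * w ** p.mu
                if mode == "combined":
                    g = decay_rate(x_post, 0.0, p, v_thresh)
                    w -= dt * g * (w - p.w0)
                w = min(max(w, 0.0), p.w_max_ee)
            rows.append({"post_rate_hz": r_post, "mode": mode,
                         "dw_per_s": (w - w_init) / (duration_ms / 1000.0)})
    return pd.DataFrame(rows)
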