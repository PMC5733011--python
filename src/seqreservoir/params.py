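"""Parameter containers for neurons, synapses, simulation grid and plasticity.

All membrane quantities are in mV, times in ms, rates in Hz.  Synaptic
weights are unitless and bounded; the conversion from a unit weight to
postsynaptic current (mV/ms) is carried by per-pathway gain factors in
:class:`SynapseParams`, so that excitatory and inhibitory pathways can have
different physiological strengths while their stored weight matrices live on
comparable numeric scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class NeuronParams:
    """Leaky integrate-and-fire constants for one population.

    ``theta_plus``/``tau_theta`` parameterize the homeostatic adaptive
    threshold: each spike raises the effective firing threshold
    (v_thresh + theta) by ``theta_plus`` and theta relaxes exponentially with
    ``tau_theta``.  ``theta_init`` starts every neuron above its long-run
    homeostatic level, which keeps the untrained network sparse during the
    first presentations (before competition is shaped by learning) and then
    relaxes toward equilibrium.  Homeostasis applies to excitatory neurons
    only, so inhibitory populations must use ``theta_plus = 0``.
    """

    v_rest: float = -65.0
    v_reset: float = -65.0
    v_thresh: float = -52.0
    tau_m: float = 50.0
    t_refrac: float = 5.0
    theta_plus: float = 0.05
    tau_theta: float = 5e3
    theta_init: float = 10.0
    population_tag: str = "excitatory"

    def __post_init__(self) -> None:
        if not self.v_reset < self.v_thresh:
            raise ValueError("v_reset must lie below v_thresh")
        if self.tau_m <= 0 or self.tau_theta <= 0:
            raise ValueError("time constants must be positive")
        if self.theta_plus < 0 or self.theta_init < 0:
            raise ValueError("theta_plus and theta_init must be non-negative")
        if self.population_tag not in ("excitatory", "inhibitory"):
            raise ValueError(f"unknown population tag {self.population_tag!r}")
        if self.population_tag == "inhibitory" and self.theta_plus != 0:
            raise ValueError("homeostatic threshold applies to excitatory neurons only")


def default_exc_params() -> NeuronParams:
    return NeuronParams()


def default_inh_params() -> NeuronParams:
    return NeuronParams(
        v_rest=-60.0,
        v_reset=-60.0,
        v_thresh=-55.0,
        tau_m=10.0,
        t_refrac=2.0,
        theta_plus=0.0,
        theta_init=0.0,
        population_tag="inhibitory",
    )


@dataclass
class SynapseParams:
    """Current-based exponential synapse model.

    A presynaptic spike through a pathway with weight ``w`` increments the
    target's synaptic current by ``gain * w`` (mV/ms); the current then decays
    exponentially with the pathway-sign time constant (``tau_e`` for
    excitatory-origin, ``tau_i`` for inhibitory-origin current).  Gains were
    set by the spontaneous-activity probe: ~45 Hz Poisson drive on all input
    channels must produce 15-20 Hz excitatory reservoir firing, with balanced
    E/I currents (inhibition per unit weight stronger than excitation).

    Recurrent gains are expressed at the reference reservoir size ``n_ref``
    and scaled by n_ref/N when applied, so the summed recurrent current per
    neuron stays comparable across reservoir sizes (the recurrent in-degree
    grows linearly with N); the input gain is not scaled because the input
    in-degree is set by the image size, not by N.
    """

    tau_e: float = 1.0
    tau_i: float = 2.0
    g_in: float = 0.7
    g_ee: float = 4.0
    g_ei: float = 8.0
    g_ie: float = 1.0
    g_ii: float = 0.5
    n_ref: int = 200

    def __post_init__(self) -> None:
        if self.tau_e <= 0 or self.tau_i <= 0:
            raise ValueError("synaptic time constants must be positive")
        if min(self.g_in, self.g_ee, self.g_ei, self.g_ie, self.g_ii) < 0:
            raise ValueError("gains must be non-negative")
        if self.n_ref <= 0:
            raise ValueError("n_ref must be positive")

    def gain(self, pathway: str, n_reservoir: int | None = None) -> float:
        g = {"in_e": self.g_in, "ee": self.g_ee, "ei": self.g_ei,
             "ie": self.g_ie, "ii": self.g_ii}[pathway]
        if pathway != "in_e" and n_reservoir is not None:
            g *= self.n_ref / n_reservoir
        return g


@dataclass
class SimulationParams:
    """Fixed-grid simulation settings.

    ``presentation_ms`` is the duration a single character (or rate profile)
    is shown; ``rest_ms`` is the silent relaxation phase appended after each
    word during which all state except the adaptive threshold decays toward
    rest.  ``noise_amplitude`` is the N0 of the additive per-step Gaussian
    current noise, in the same mV/ms units as the summed synaptic current.
    """

    dt: float = 0.5
    presentation_ms: float = 350.0
    rest_ms: float = 300.0
    noise_amplitude: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in ("presentation_ms", "rest_ms"):
            val = getattr(self, name)
            n = round(val / self.dt)
            if abs(n * self.dt - val) > 1e-9:
                raise ValueError(f"{name} must be an integer multiple of dt")
        if self.noise_amplitude < 0:
            raise ValueError("noise amplitude must be non-negative")

    @property
    def presentation_steps(self) -> int:
        return round(self.presentation_ms / self.dt)

    @property
    def rest_steps(self) -> int:
        return round(self.rest_ms / self.dt)


@dataclass
class PlasticityParams:
    """Constants of the three learning rules.

    * input->excitatory pathway: power-law weight-dependent STDP driven by a
      30 ms presynaptic trace; depression is carried by the ``offset``
      subtracted from the trace when the postsynaptic neuron fires.  The
      default offset sits at the steady-state trace level of a driven pixel
      (~45 Hz x 30 ms), so only currently-driven pixels potentiate.  Between
      word presentations each neuron's input weights are rescaled to the
      fixed per-synapse mean ``w_in_target_mean`` (divisive normalization):
      competition for a fixed total weight forces each neuron to commit to
      one pattern instead of accumulating the union of everything it ever
      fired for, and equalizes total input drive across neurons.
    * recurrent E->E pathway: exponential weight-dependent STDP with a fast
      10 ms presynaptic trace and a 20 ms postsynaptic trace (``eta1``
      depression on pre spikes, ``eta2`` potentiation on post spikes).
    * recurrent E->E pathway, every step: heterosynaptic decay of the weight
      toward the baseline ``w0`` at rate gamma(t) = k_decay * x_post^2 *
      (|v_thresh| + theta)/|v_thresh|, which depends only on postsynaptic
      state.
    """

    eta_in: float = 0.05
    w_max_in: float = 1.0
    w_in_target_mean: float | None = 0.15
    offset: float = 1.0
    eta1: float = 0.002
    eta2: float = 0.01
    w_max_ee: float = 0.5
    mu: float = 0.9
    w0: float = 0.2
    k_decay: float = 5e-4
    decay_every_step: bool = True
    tau_pre: float = 30.0
    tau_pre_fast: float = 10.0
    tau_post: float = 20.0

    def __post_init__(self) -> None:
        for name in ("eta_in", "eta1", "eta2"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if not 0 <= self.w0 < self.w_max_ee:
            raise ValueError("w0 must lie in [0, w_max_ee)")
        if not 0 < self.mu <= 1:
            raise ValueError("mu must lie in (0, 1]")
        if self.k_decay < 0:
            raise ValueError("k_decay must be non-negative")
        if min(self.tau_pre, self.tau_pre_fast, self.tau_post) <= 0:
            raise ValueError("trace time constants must be positive")


def params_to_dict(*objs) -> dict:
    """Flatten dataclass parameter blocks into one JSON-serializable dict."""
    out = {}
    for obj in objs:
        out[type(obj).__name__] = asdict(obj)
    return out
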