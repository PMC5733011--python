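"""Construction of the two-layer reservoir topology.

The network is an input layer (one channel per image pixel) projecting onto a
recurrent reservoir of N leaky integrate-and-fire neurons, 80% excitatory and
20% inhibitory.  Recurrent pathways E->E, E->I, I->E, I->I are drawn as
independent sparse Bernoulli masks.  Only the pathways that terminate on
excitatory neurons (In->E and E->E) are plastic; the remaining pathways keep
their initial random weights.

E/I balance is enforced two ways: structurally through the probability
inequality p_ee < p_ei * p_ie (checked before construction), and dynamically
by rescaling each neuron's incoming inhibitory weights so that its summed
inhibitory in-weight equals its summed excitatory in-weight.  The exact
per-row balance keeps the spontaneous regime asynchronous and removes the
mean-structure eigenvalue outliers, so the untrained signed weight matrix
shows the uniform circular-law disc expected of a random reservoir.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PATHWAYS = ("in_e", "ee", "ei", "ie", "ii")
#: stored-weight scale of each pathway at initialization (uniform on [0, s])
INIT_SCALES = {"in_e": 0.3, "ee": 0.5, "ei": 0.3, "ie": 0.3, "ii": 0.3}
PLASTIC = {"in_e": True, "ee": True, "ei": False, "ie": False, "ii": False}


@dataclass
class TopologyConfig:
    n_inputs: int = 784
    n_reservoir: int = 500
    exc_fraction: float = 0.8
    p_in: float = 0.3
    p_ee: float = 0.1
    p_ei: float = 0.3
    p_ie: float = 0.4
    p_ii: float = 0.1
    rng_seed: int = 0
    balanced_inhibition: bool = True

    def __post_init__(self) -> None:
        for name in ("p_in", "p_ee", "p_ei", "p_ie", "p_ii", "exc_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_inputs < 1 or self.n_reservoir < 2:
            raise ValueError("need at least one input and two reservoir neurons")

    @property
    def n_exc(self) -> int:
        return round(self.n_reservoir * self.exc_fraction)

    @property
    def n_inh(self) -> int:
        return self.n_reservoir - self.n_exc


@dataclass
class BalanceVerdict:
    ok: bool
    p_ee: float
    p_ei_times_p_ie: float

    def __str__(self) -> str:  # diagnostic used in error messages
        rel = "<" if self.ok else ">="
        return (f"E/I balance {'satisfied' if self.ok else 'VIOLATED'}: "
                f"p_ee = {self.p_ee:.4g} {rel} p_ei*p_ie = {self.p_ei_times_p_ie:.4g}")


def check_balance(config: TopologyConfig) -> BalanceVerdict:
    """Verify the structural balance rule p_ee < p_ei * p_ie."""
    rhs = config.p_ei * config.p_ie
    return BalanceVerdict(ok=config.p_ee < rhs, p_ee=config.p_ee, p_ei_times_p_ie=rhs)


@dataclass
class NetworkTopology:
    """Adjacency masks, plastic flags and population index ranges."""

    config: TopologyConfig
    masks: dict = field(default_factory=dict)   # pathway -> bool ndarray (pre, post)
    plastic: dict = field(default_factory=dict)

    @property
    def n_exc(self) -> int:
        return self.config.n_exc

    @property
    def n_inh(self) -> int:
        return self.config.n_inh

    @property
    def exc_slice(self) -> slice:
        return slice(0, self.n_exc)

    @property
    def inh_slice(self) -> slice:
        return slice(self.n_exc, self.config.n_reservoir)


_SHAPES = {
    "in_e": ("n_inputs", "n_exc"),
    "ee": ("n_exc", "n_exc"),
    "ei": ("n_exc", "n_inh"),
    "ie": ("n_inh", "n_exc"),
    "ii": ("n_inh", "n_inh"),
}
_PROBS = {"in_e": "p_in", "ee": "p_ee", "ei": "p_ei", "ie": "p_ie", "ii": "p_ii"}


def build_topology(config: TopologyConfig, rng: np.random.Generator | None = None) -> NetworkTopology:
    """Draw independent Bernoulli adjacency masks for every pathway.

    Self-connections are excluded on all recurrent pathways.  Raises
    ``ValueError`` with the balance diagnostic if the probability inequality
    is violated.
    """
    verdict = check_balance(config)
    if not verdict.ok:
        raise ValueError(str(verdict))
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)

    def dim(name: str) -> int:
        return {"n_inputs": config.n_inputs, "n_exc": config.n_exc,
                "n_inh": config.n_inh}[name]

    masks = {}
    for pw in PATHWAYS:
        pre, post = (dim(d) for d in _SHAPES[pw])
        p = getattr(config, _PROBS[pw])
        m = rng.random((pre, post)) < p
        if pw in ("ee", "ii"):
            np.fill_diagonal(m, False)
        masks[pw] = m
    return NetworkTopology(config=config, masks=masks, plastic=dict(PLASTIC))


def init_weights(topology: NetworkTopology, rng: np.random.Generator | None = None) -> dict:
    """Draw initial weights, uniform on [0, scale] per pathway, zero off-mask.

    With ``balanced_inhibition`` (default) each reservoir neuron's incoming
    inhibitory weights are rescaled so their sum matches the neuron's summed
    incoming excitatory weight, which zeroes the rows of the signed recurrent
    matrix in expectation and exactly.
    """
    cfg = topology.config
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed + 1)
    weights = {}
    for pw in PATHWAYS:
        m = topology.masks[pw]
        w = rng.uniform(0.0, INIT_SCALES[pw], size=m.shape)
        w[~m] = 0.0
        weights[pw] = w
    # start the plastic input pathway at its normalization target (mean
    # INIT_SCALES/2 per connected synapse), so training-time renormalization
    # is a no-op until learning moves weights
    normalize_columns(weights["in_e"], topology.masks["in_e"],
                      INIT_SCALES["in_e"] / 2)
    if cfg.balanced_inhibition:
        _balance_rows(weights)
    return weights


def normalize_columns(w: np.ndarray, mask: np.ndarray, target_mean: float,
                      w_max: float | None = None) -> None:
    """Rescale each column so its mean weight per connected synapse equals
    ``target_mean`` (divisive weight normalization), in place."""
    in_deg = mask.sum(axis=0)
    sums = w.sum(axis=0)
    ok = (sums > 0) & (in_deg > 0)
    scale = np.ones_like(sums)
    scale[ok] = target_mean * in_deg[ok] / sums[ok]
    w *= scale[None, :]
    if w_max is not None:
        np.clip(w, 0.0, w_max, out=w)


def _balance_rows(weights: dict) -> None:
    """Scale incoming I weights per neuron to match its incoming E weight sum."""
    for exc_pw, inh_pw in (("ee", "ie"), ("ei", "ii")):
        exc_in = weights[exc_pw].sum(axis=0)
        inh_in = weights[inh_pw].sum(axis=0)
        ok = inh_in > 0
        scale = np.ones_like(inh_in)
        scale[ok] = exc_in[ok] / inh_in[ok]
        weights[inh_pw] *= scale[None, :]


def compose_signed_matrix(topology: NetworkTopology, weights: dict) -> np.ndarray:
    """Assemble the N x N signed recurrent weight matrix.

    Entry (j, i) holds the weight of the i -> j connection, positive when the
    presynaptic neuron is excitatory and negative when inhibitory.  All four
    recurrent pathways are included; the input pathway is not part of the
    recurrent operator.
    """
    n_e, n_i = topology.n_exc, topology.n_inh
    n = n_e + n_i
    for pw in ("ee", "ei", "ie", "ii"):
        if pw not in weights:
            raise ValueError(f"missing weights for pathway {pw!r}")
        if weights[pw].shape != topology.masks[pw].shape:
            raise ValueError(f"shape mismatch for pathway {pw!r}")
    m = np.zeros((n, n))
    m[:n_e, :n_e] = weights["ee"].T
    m[n_e:, :n_e] = weights["ei"].T
    m[:n_e, n_e:] = -weights["ie"].T
    m[n_e:, n_e:] = -weights["ii"].T
    return m


def topology_to_edge_frame(topology: NetworkTopology, weights: dict):
    """Flatten the network to a (pre_id, post_id, pathway, weight, plastic) table."""
    import pandas as pd

    rows = []
    for pw in PATHWAYS:
        pre, post = np.nonzero(topology.masks[pw])
        rows.append(pd.DataFrame({
            "pre_id": pre, "post_id": post, "pathway": pw,
            "weight": weights[pw][pre, post], "plastic": topology.plastic[pw],
        }))
    return pd.concat(rows, ignore_index=True)
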