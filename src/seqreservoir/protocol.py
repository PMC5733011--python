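"""Two-phase sequence training and readout-free word generation.

Training presents each word as its characters in order, 350 ms each, with all
three plasticity rules active, followed by a 300 ms silent rest in which every
state variable except the adaptive threshold relaxes toward rest.  After
training, plasticity is frozen and each excitatory neuron is assigned to the
character for which its mean firing rate is maximal.

Generation is readout-free: a test character is presented, per-character
group activities are tallied over the presentation window, and the
second-most-active group names the next character to present.  A large gap
between the top-2 activities signals that the end of a learnt word was
reached and the trial terminates.  Membrane state is carried across the
characters of one trial, never reset mid-word.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import CharacterCorpus, DEFAULT_MAX_RATE, build_schedule, encode_poisson
from .network import Reservoir
from .params import SimulationParams


@dataclass
class AssignmentMap:
    """Excitatory-neuron -> character-label map learnt from a labelling pass."""

    labels: list
    assignment: np.ndarray            # per excitatory neuron; -1 = unassigned
    mean_rates: np.ndarray            # (n_exc, n_labels) Hz, the labelling evidence
    unassignable: list = field(default_factory=list)

    def group(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.assignment == self.labels.index(label))

    @property
    def group_sizes(self) -> dict:
        return {lab: int((self.assignment == k).sum()) for k, lab in enumerate(self.labels)}


@dataclass
class GenerationResult:
    sequence: str
    evidence: list                    # (top1, top2, gap in spikes/window/neuron) per step
    termination: str                  # "gap-threshold" | "length-cap" | "dead-end"
    binned: np.ndarray | None = None  # (n_bins, n_exc) rate trajectory if requested


@dataclass
class EvalReport:
    accuracy: float                   # percent, averaged over starting characters
    per_first_char: dict              # first char -> dict(correct, total, accuracy)
    word_counts: dict                 # dictionary word -> times generated
    garbage: list                     # non-dictionary emissions
    n_trials: int


def train(corpus: CharacterCorpus, net: Reservoir, sim: SimulationParams,
          rng: np.random.Generator, max_rate: float = DEFAULT_MAX_RATE,
          log_every: int = 20) -> pd.DataFrame:
    """Run the full two-phase training pass over the corpus.

    Iterates ``n_train_reps`` repetitions of every word in a uniformly
    shuffled order (a single epoch), rendering fresh glyph variants per
    repetition.  Returns a per-presentation training log (mean rates and mean
    plastic weights).  Aborts if the excitatory population rate diverges
    beyond 500 Hz.
    """
    words = np.repeat(corpus.words, corpus.n_train_reps)
    rng.shuffle(words)
    mask_in = net.topology.masks["in_e"]
    mask_ee = net.topology.masks["ee"]
    rows = []
    for k, word in enumerate(words):
        word_counts = np.zeros(net.n_exc)
        word_steps = 0
        for seg in build_schedule(word, sim):
            if seg.label is None:
                rec = net.run_segment(n_steps=seg.n_steps, plastic=True)
            else:
                img = corpus.render(seg.label, rng)
                raster = encode_poisson(img, max_rate, seg.n_steps * sim.dt, sim.dt, rng)
                rec = net.run_segment(raster, plastic=True)
                word_counts += rec.spike_counts[:net.n_exc]
                word_steps += seg.n_steps
        rate = word_counts.mean() / (word_steps * sim.dt / 1000.0)
        if rate > 500.0:
            raise RuntimeError(
                f"divergent activity: excitatory mean rate {rate:.0f} Hz at word {k}")
        if k % log_every == 0 or k == len(words) - 1:
            rows.append({
                "presentation": k, "word": word, "exc_rate_hz": rate,
                "mean_w_in": float(net.weights["in_e"][mask_in].mean()),
                "mean_w_ee": float(net.weights["ee"][mask_ee].mean()),
                "mean_theta": float(net.state.theta.mean()),
            })
        net.normalize_input_weights()
        net.reset_state()  # rest already relaxed the state; make word starts exact
    return pd.DataFrame(rows)


def response_rates(net: Reservoir, corpus: CharacterCorpus, sim: SimulationParams,
                   rng: np.random.Generator, n_variants: int | None = None,
                   max_rate: float = DEFAULT_MAX_RATE) -> np.ndarray:
    """Mean firing rate (Hz) of each excitatory neuron per character label.

    One labelling pass with plasticity frozen: every test variant of every
    character is presented for one window from a reset state.
    """
    labels = corpus.labels
    n_var = n_variants or corpus.n_test_reps
    rates = np.zeros((net.n_exc, len(labels)))
    window_s = sim.presentation_ms / 1000.0
    for k, lab in enumerate(labels):
        for i in range(n_var):
            net.reset_state()
            raster = encode_poisson(corpus.test_variant(lab, i), max_rate,
                                    sim.presentation_ms, sim.dt, rng)
            rec = net.run_segment(raster, plastic=False)
            rates[:, k] += rec.spike_counts[:net.n_exc]
        rates[:, k] /= n_var * window_s
    return rates


def assign_from_rates(rates: np.ndarray, labels: list,
                      min_selectivity: float | None = None) -> AssignmentMap:
    """Argmax label assignment; silent neurons stay unassigned (-1).

    Ties break toward the lowest label index (labels are sorted).  With
    ``min_selectivity`` set, neurons whose best response is less than that
    factor above their second-best are left unassigned: such neurons encode
    features shared between characters (typically the intersection of two
    glyphs) and only dilute the per-character activity readout.
    """
    rates = np.asarray(rates, dtype=float)
    assignment = np.where(rates.max(axis=1) > 0, rates.argmax(axis=1), -1)
    if min_selectivity is not None and rates.shape[1] > 1:
        top = np.sort(rates, axis=1)
        unselective = top[:, -1] < min_selectivity * top[:, -2]
        assignment[unselective] = -1
    unassignable = [lab for k, lab in enumerate(labels) if not np.any(assignment == k)]
    for lab in unassignable:
        warnings.warn(f"label {lab!r} has no responsive neurons", stacklevel=2)
    return AssignmentMap(labels=list(labels), assignment=assignment,
                         mean_rates=rates, unassignable=unassignable)


def assign_neurons(net: Reservoir, corpus: CharacterCorpus, sim: SimulationParams,
                   rng: np.random.Generator, n_variants: int | None = None,
                   max_rate: float = DEFAULT_MAX_RATE,
                   min_selectivity: float | None = None) -> AssignmentMap:
    rates = response_rates(net, corpus, sim, rng, n_variants, max_rate)
    return assign_from_rates(rates, corpus.labels, min_selectivity)


def group_rates(spike_counts: np.ndarray, assignment: AssignmentMap) -> dict:
    """Mean spike count per assigned neuron for every label, over one window."""
    if not assignment.labels or np.all(assignment.assignment < 0):
        raise ValueError("empty assignment")
    out = {}
    for k, lab in enumerate(assignment.labels):
        idx = np.flatnonzero(assignment.assignment == k)
        out[lab] = float(spike_counts[idx].mean()) if idx.size else 0.0
    return out


def generate_sequence(net: Reservoir, assignment: AssignmentMap,
                      corpus: CharacterCorpus, first_char: str,
                      sim: SimulationParams, rng: np.random.Generator,
                      gap_threshold: float = 10.0, length_cap: int = 10,
                      noise_amplitude: float = 0.0,
                      first_image: np.ndarray | None = None,
                      frozen_rasters: dict | None = None,
                      max_rate: float = DEFAULT_MAX_RATE,
                      bin_steps: int | None = None,
                      forbid_backtrack: bool = True) -> GenerationResult:
    """Generate one word starting from a presentation of ``first_char``.

    After each 350 ms window the per-group mean spike counts are ranked; if
    the top-2 gap exceeds ``gap_threshold`` the word is considered complete,
    otherwise the second-ranked character is appended and presented next
    (falling to the third rank if the runner-up is the character just shown).
    Membrane potentials carry over between presentations within the trial.

    The runner-up choice skips the character just shown and, by default, the
    one shown before it (``forbid_backtrack``): residual activity of the
    predecessor group otherwise wins the runner-up slot and locks the
    generator into a two-character oscillation.  Immediate repetitions are
    impossible for this readout anyway, and no dictionary word returns to a
    character after one step.

    ``frozen_rasters`` (label -> raster) replaces Poisson sampling with fixed
    input realizations, the control used in the noise-robustness analysis.
    """
    if gap_threshold < 0:
        raise ValueError("gap_threshold must be non-negative")
    if first_char in assignment.unassignable:
        raise RuntimeError(f"starting label {first_char!r} is unassignable")
    net.reset_state()
    seq = [first_char]
    evidence = []
    bins = []
    current = first_char
    image = first_image
    termination = "length-cap"
    while True:
        if frozen_rasters is not None:
            raster = frozen_rasters[current]
        else:
            img = image if image is not None else corpus.render(current, rng)
            raster = encode_poisson(img, max_rate, sim.presentation_ms, sim.dt, rng)
        image = None
        rec = net.run_segment(raster, plastic=False,
                              noise_amplitude=noise_amplitude, rng=rng,
                              bin_steps=bin_steps)
        if bin_steps:
            bins.append(rec.binned_exc)
        counts = group_rates(rec.spike_counts[:net.n_exc], assignment)
        ranked = sorted(counts, key=lambda lab: (-counts[lab], lab))
        top1, top2 = ranked[0], ranked[1] if len(ranked) > 1 else ranked[0]
        gap = counts[top1] - counts[top2]
        evidence.append((top1, top2, gap))
        if gap > gap_threshold:
            termination = "gap-threshold"
            break
        previous = seq[-2] if len(seq) >= 2 else None
        blocked = {current}
        if forbid_backtrack and previous is not None:
            blocked.add(previous)
        candidates = [lab for lab in ranked if lab not in blocked]
        if not candidates:
            termination = "dead-end"
            break
        nxt = candidates[0]
        if nxt in assignment.unassignable:
            raise RuntimeError(f"generated label {nxt!r} is unassignable")
        seq.append(nxt)
        current = nxt
        if len(seq) >= length_cap:
            break
    result = GenerationResult(sequence="".join(seq), evidence=evidence,
                              termination=termination)
    if bin_steps:
        result.binned = np.concatenate(bins, axis=0)  # per-trial rate trajectory
    return result


def evaluate(dictionary, trials) -> EvalReport:
    """Score generation trials against the word dictionary.

    A trial is correct iff its emitted string is a dictionary word.  The
    headline accuracy is the mean over starting characters of the per-group
    percent correct.
    """
    if not trials:
        raise ValueError("need at least one trial")
    dictionary = set(dictionary)
    word_counts = {w: 0 for w in sorted(dictionary)}
    garbage = []
    per_first: dict = {}
    for tr in trials:
        first = tr.sequence[0]
        bucket = per_first.setdefault(first, {"correct": 0, "total": 0})
        bucket["total"] += 1
        if tr.sequence in dictionary:
            bucket["correct"] += 1
            word_counts[tr.sequence] += 1
        else:
            garbage.append(tr.sequence)
    for bucket in per_first.values():
        bucket["accuracy"] = 100.0 * bucket["correct"] / bucket["total"]
    accuracy = float(np.mean([b["accuracy"] for b in per_first.values()]))
    return EvalReport(accuracy=accuracy, per_first_char=per_first,
                      word_counts=word_counts, garbage=garbage, n_trials=len(trials))
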