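"""Unit tests for assignment, group rates, generation control flow and
evaluation.

The generation test uses a hand-constructed feedforward network whose input
weights implement a known activity cascade (C fully drives its own group and
partially the A group; A drives A fully and T partially; T drives only
itself), so the expected top-2 sequence and the terminal activity gap are
known by construction.
"""

import numpy as np
import pytest

from seqreservoir import (NeuronParams, Reservoir, SimulationParams,
                          SynapseParams, TopologyConfig, VariabilityParams,
                          assign_from_rates, evaluate, generate_sequence,
                          group_rates, make_charset)
from seqreservoir.protocol import AssignmentMap, GenerationResult
from seqreservoir.topology import NetworkTopology, PLASTIC


class TestAssignment:
    def test_argmax_matches_hand_computation(self):
        # 3 neurons x 2 labels rate table
        rates = np.array([[5.0, 1.0],   # -> label 0 ("A")
                          [0.5, 2.0],   # -> label 1 ("B")
                          [3.0, 3.0]])  # tie -> lowest label index
        amap = assign_from_rates(rates, ["A", "B"])
        np.testing.assert_array_equal(amap.assignment, [0, 1, 0])
        assert amap.unassignable == []

    def test_silent_neurons_stay_unassigned(self):
        rates = np.array([[0.0, 0.0], [1.0, 0.0]])
        with pytest.warns(UserWarning, match="no responsive neurons"):
            amap = assign_from_rates(rates, ["A", "B"])
        assert amap.assignment[0] == -1
        assert amap.unassignable == ["B"]

    def test_empty_response_matrix_all_unassignable(self):
        with pytest.warns(UserWarning):
            amap = assign_from_rates(np.zeros((4, 3)), ["A", "B", "C"])
        assert amap.unassignable == ["A", "B", "C"]


class TestGroupRates:
    def make_map(self):
        return AssignmentMap(labels=["A", "B"],
                             assignment=np.array([0, 0, 1, 1, 1, -1]),
                             mean_rates=np.zeros((6, 2)))

    def test_counts_match_hand_tally(self):
        counts = np.array([4, 6, 1, 2, 3, 50])  # unassigned neuron ignored
        out = group_rates(counts, self.make_map())
        assert out == {"A": 5.0, "B": 2.0}

    def test_no_spikes_all_zero(self):
        out = group_rates(np.zeros(6), self.make_map())
        assert set(out.values()) == {0.0}

    def test_group_size_invariance_of_mean(self):
        amap = self.make_map()
        counts = np.array([3, 3, 7, 7, 7, 0])
        doubled = AssignmentMap(labels=["A", "B"],
                                assignment=np.array([0, 0, 0, 0, 1, 1]),
                                mean_rates=np.zeros((6, 2)))
        assert group_rates(counts, amap)["B"] == group_rates(
            np.array([0, 0, 0, 0, 7, 7]), doubled)["B"]

    def test_empty_assignment_rejected(self):
        amap = AssignmentMap(labels=[], assignment=np.array([]),
                             mean_rates=np.zeros((0, 0)))
        with pytest.raises(ValueError):
            group_rates(np.array([]), amap)


def cascade_fixture():
    """Feedforward network with a known C -> A -> T activity cascade.

    30 excitatory neurons in three groups of 10.  Character images are
    replaced by disjoint pixel bands so cross-talk is exactly zero.  Each
    group's input weights are 1.0 on its own character's pixels; the A group
    additionally carries 0.6 on C's pixels and the T group 0.6 on A's
    pixels.  All recurrent weights are zero, so presenting C ranks the
    groups C > A > T, presenting A ranks A > T, and presenting T leaves
    every other group silent (a large terminal gap).
    """
    corpus = make_charset(["CAT"], n_test_reps=4,
                          variability=VariabilityParams(0, 0.0, 0.0))
    bands = {"C": (0, 9), "A": (10, 19), "T": (20, 28)}
    for lab, (r0, r1) in bands.items():
        img = np.zeros((28, 28), dtype=np.uint8)
        img[r0:r1, :] = 180
        corpus.templates[lab] = img
        corpus.glyphs[lab] = np.stack([img] * corpus.n_test_reps)
    n_e, n_i, n_in = 30, 8, 784
    cfg = TopologyConfig(n_inputs=n_in, n_reservoir=n_e + n_i, exc_fraction=n_e / (n_e + n_i))
    masks = {"in_e": np.zeros((n_in, n_e), dtype=bool),
             "ee": np.zeros((n_e, n_e), dtype=bool),
             "ei": np.zeros((n_e, n_i), dtype=bool),
             "ie": np.zeros((n_i, n_e), dtype=bool),
             "ii": np.zeros((n_i, n_i), dtype=bool)}
    weights = {pw: np.zeros(m.shape) for pw, m in masks.items()}
    pix = {lab: corpus.templates[lab].ravel() > 0 for lab in "CAT"}
    groups = {"C": slice(0, 10), "A": slice(10, 20), "T": slice(20, 30)}
    full, partial = 1.0, 0.6
    for lab, prev in (("C", None), ("A", "C"), ("T", "A")):
        masks["in_e"][np.ix_(pix[lab], range(*groups[lab].indices(n_e)))] = True
        weights["in_e"][np.ix_(pix[lab], range(*groups[lab].indices(n_e)))] = full
        if prev:
            masks["in_e"][np.ix_(pix[prev], range(*groups[lab].indices(n_e)))] = True
            weights["in_e"][np.ix_(pix[prev], range(*groups[lab].indices(n_e)))] = partial
    topo = NetworkTopology(config=cfg, masks=masks, plastic=dict(PLASTIC))
    exc = NeuronParams(theta_plus=0.0, theta_init=0.0)  # no homeostasis in the fixture
    syn = SynapseParams(g_in=0.1, g_ee=0, g_ei=0, g_ie=0, g_ii=0)
    net = Reservoir(topo, weights, exc_params=exc, syn_params=syn)
    labels = ["A", "C", "T"]
    assignment = np.full(n_e, -1)
    for lab, sl in groups.items():
        assignment[sl] = labels.index(lab)
    amap = AssignmentMap(labels=labels, assignment=assignment,
                         mean_rates=np.zeros((n_e, 3)))
    return net, amap, corpus


class TestGenerateSequence:
    def test_cascade_network_emits_cat(self):
        net, amap, corpus = cascade_fixture()
        res = generate_sequence(net, amap, corpus, "C", SimulationParams(),
                                np.random.default_rng(0), gap_threshold=10.0)
        assert res.sequence == "CAT"
        assert res.termination == "gap-threshold"
        # mid-word gaps stay below the terminal gap
        gaps = [g for _, _, g in res.evidence]
        assert gaps[-1] > max(gaps[:-1])

    def test_zero_gap_threshold_emits_single_character(self):
        net, amap, corpus = cascade_fixture()
        res = generate_sequence(net, amap, corpus, "T", SimulationParams(),
                                np.random.default_rng(0), gap_threshold=0.0)
        assert res.sequence == "T"
        assert res.termination == "gap-threshold"

    def test_length_cap_bounds_sequence(self):
        net, amap, corpus = cascade_fixture()
        res = generate_sequence(net, amap, corpus, "C", SimulationParams(),
                                np.random.default_rng(0), gap_threshold=1e9,
                                length_cap=2)
        assert len(res.sequence) == 2
        assert res.termination == "length-cap"

    def test_unassignable_start_rejected(self):
        net, amap, corpus = cascade_fixture()
        amap.unassignable = ["C"]
        with pytest.raises(RuntimeError, match="unassignable"):
            generate_sequence(net, amap, corpus, "C", SimulationParams(),
                              np.random.default_rng(0))


class TestEvaluate:
    @staticmethod
    def trial(seq):
        return GenerationResult(sequence=seq, evidence=[], termination="gap-threshold")

    def test_all_correct_is_100_percent(self):
        rep = evaluate(["CAT", "COT"], [self.trial("CAT"), self.trial("COT")])
        assert rep.accuracy == 100.0
        assert rep.garbage == []

    def test_mixed_trials_arithmetic(self):
        trials = [self.trial("CAT"), self.trial("CAT"), self.trial("CRT")]
        rep = evaluate(["CAT", "COT", "CRAFT"], trials)
        assert rep.accuracy == pytest.approx(200 / 3)
        assert rep.word_counts["CAT"] == 2
        assert rep.garbage == ["CRT"]

    def test_accuracy_averages_over_first_characters(self):
        trials = [self.trial("CAT"), self.trial("CXT"),      # C: 50%
                  self.trial("DOG"), self.trial("DOG")]      # D: 100%
        rep = evaluate(["CAT", "DOG"], trials)
        assert rep.accuracy == pytest.approx(75.0)

    def test_empty_dictionary_all_garbage(self):
        rep = evaluate([], [self.trial("CAT")])
        assert rep.accuracy == 0.0
        assert rep.garbage == ["CAT"]

    def test_no_trials_rejected(self):
        with pytest.raises(ValueError):
            evaluate(["CAT"], [])
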