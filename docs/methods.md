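# Methods

## Model overview

`seqreservoir` simulates a two-layer recurrent spiking network that learns to
recognize visual characters and to generate word sequences without a readout
layer.  An input layer of 28x28 Poisson spike generators (one per pixel)
projects onto a reservoir of N leaky integrate-and-fire (LIF) neurons, 80%
excitatory (E) and 20% inhibitory (I).  Input->E connections are drawn with
probability P_IN = 0.3; recurrent pathways E->E, E->I, I->E, I->I with sparse
probabilities (defaults 0.1, 0.3, 0.4, 0.1) that satisfy the balance rule
P_EE < P_EI * P_IE.  Only the pathways terminating on excitatory neurons
(In->E and E->E) are plastic; all others keep their initial random weights.

Learning combines three rules acting simultaneously during training:

1. **In->E, power-law STDP.**  On each postsynaptic spike,
   `dw = eta_in (x_pre - offset)(w_max - w)^mu`, with a 30 ms presynaptic
   trace `x_pre` incremented by 1 per input spike.  `eta_in = 0.05`,
   `w_max = 1.0`, `mu = 0.9`.
2. **E->E, exponential weight-dependent STDP.**  Depression
   `dw = -eta1 x_post w^mu` on each presynaptic spike, potentiation
   `dw = +eta2 x_post x'_pre (w_max - w)^mu` on each postsynaptic spike, with
   fast traces (tau = 10 ms pre, 20 ms post), `eta1 = 0.002`, `eta2 = 0.01`,
   `w_max = 0.5`.
3. **E->E, heterosynaptic decay (every step).**
   `dw/dt = -gamma(t)(w - w0)` with
   `gamma = k_decay * x_post^2 * (|v_thresh| + theta)/|v_thresh|` and baseline
   `w0 = 0.2`.  The rate depends only on postsynaptic activity and the
   homeostatic threshold, so neurons that become hyperactive through
   recurrent feedback loops relax their incoming recurrent weights toward
   baseline instead of running away.

Excitatory neurons carry a homeostatic adaptive threshold: the effective
threshold is `v_thresh + theta`, `theta` increases by `theta_plus = 0.05 mV`
per spike and decays exponentially.  Words are presented as their characters
in order, 350 ms each at dt = 0.5 ms, followed by a 300 ms silent phase; the
membrane state is never reset inside a word, and `theta` survives the rest
phases and the transition to testing.

After training, plasticity is frozen and each excitatory neuron is assigned
to the character that maximizes its mean firing rate over a labelled pass.
Generation is readout-free: present a character for one window, rank the
per-character mean group spike counts, and use the *second* most active group
as the next character.  The runner-up choice skips the character just shown
and the one before it: residual activity of the predecessor group otherwise
wins the slot and locks the generator into a two-character oscillation (no
dictionary word returns to a character after a single step, and immediate
repetition is inexpressible in this readout anyway).  A top-1/top-2 gap above `gap_threshold = 10` spikes
per neuron per window signals that the end of a learnt word was reached.

## Numerical scheme

The membrane equation is advanced with the exact exponential update for
piecewise-constant current (no forward-Euler drift); synapses are
current-based with exponential kernels (1 ms excitatory, 2 ms inhibitory) and
one-step (0.5 ms) spike delivery delay.  Synaptic traces use
decay-then-increment semantics; weight updates within a step use the trace
values after that step's increments.  The heterosynaptic decay is tracked
lazily as a per-column accumulated factor (exact, because the decay is linear
in `w - w0`) and folded into the weights whenever an STDP event touches the
column; a numba kernel accelerates the event updates, with a bit-identical
numpy fallback.  Update order within a step is fixed: integrate neurons ->
update traces -> STDP events -> heterosynaptic decay -> clip to bounds.

## Constants the source text does not fix, and how they were chosen

The literature this model family draws on does not fix the LIF/synapse
constants or the training/assignment methodology; the package therefore
treats the following as its own design decisions, each exposed in
configuration:

* **LIF constants.**  Excitatory: rest/reset -65 mV, threshold -52 mV,
  tau_m = 50 ms, refractory 5 ms.  The membrane constant also bounds how long
  a character's assembly stays depolarized into the next character's window;
  at 100 ms the carryover lets successor neurons fire during the
  predecessor's window and absorb its pixels into their receptive fields,
  which corrupts mid-word recognition.  Inhibitory: rest/reset -60 mV, threshold
  -55 mV, tau_m = 10 ms, refractory 2 ms.  The low inhibitory threshold makes
  interneurons fast, high-rate followers of excitatory activity, so
  inhibition is delivered in many small current quanta.  This matters: with
  slow, large-quantum inhibition the inhibitory shot noise (several mV per
  spike) blurs the ~15% drive margins that separate a character's true
  responders from partially overlapping ones.
* **Pathway gains.**  Stored weights are unitless; per-pathway gains convert
  them to current (mV/ms).  Recurrent gains are expressed at a reference size
  N = 200 and scaled by 200/N so all reservoir sizes (200/400/500) share one
  operating regime.  Defaults (g_in = 0.7, g_ee = 4, g_ei = 8, g_ie = 1,
  g_ii = 0.5) were calibrated with the spontaneous-activity probe: ~45 Hz
  Poisson drive on all input channels must give >= 15 Hz mean excitatory
  firing in the untrained reservoir, with E/I currents balanced.
* **Homeostasis.**  `tau_theta = 5e3 ms` and `theta_init = 10 mV`.  The decay
  constant keeps `theta` persistent across a word and its rest phase (the
  stated requirement) while giving homeostasis an equilibrium; with a much
  slower decay `theta` becomes a pure spike counter, so group excitability
  depends on training length and character frequency, and the top-2 ranking
  breaks for dictionaries whose characters appear with unequal frequency.
  `theta_init` starts neurons above their long-run threshold so the first
  presentations are sparse rather than a population burst (which would
  saturate every neuron's input weights onto every character at once).
* **Eq. 1 offset = 1.0.**  The steady-state 30 ms trace of a ~45 Hz pixel is
  ~1.35, so an offset at 1.0 means currently driven pixels potentiate while
  pixels that stopped firing more than ~10 ms ago depress.  A small offset
  (e.g. 0.4) potentiates the previous character's pixels during each
  presentation's onset, making successor neurons learn predecessor glyphs.
* **Input-weight normalization.**  Between word presentations each
  excitatory neuron's In->E weights are rescaled to a fixed mean per
  connected synapse (0.15).  This divisive normalization is standard in this
  family of unsupervised spiking classifiers; without it neurons accumulate
  the union of every pattern they ever fired for (the weight-dependent STDP
  cannot depress saturated weights effectively), and receptive fields never
  become character-specific.
* **k_decay = 5e-4 /ms.**  Strong enough to suppress the feedback loop in
  which word-final characters' neurons are recurrently pre-activated during
  every mid-word character (and would otherwise learn every character's
  pixels), weak enough that the E->E block structure encoding character
  transitions survives (at 2e-3 and above the decay flattens all recurrent
  weights to w0 and no associations remain).
* **Training restarts.**  Which character pools survive the competitive
  pool dynamics varies across wiring/training seeds on the synthetic corpus.
  The dictionary pipeline therefore supports unsupervised-training restarts,
  selected by a small internal validation set of generation trials on fresh
  glyph renderings (a seed stream disjoint from any later evaluation); the
  packaged experiments use three restarts.
* **Assignment selectivity filter.**  Assignment is by argmax response, but
  neurons whose best response is within a factor ~1.2-1.5 of their second
  best can optionally be left out of the activity readout: such neurons
  encode glyph intersections and only dilute the per-group means.

## The synthetic glyph generator

Characters are rendered from a built-in 7x7 block font upscaled x4, with
per-instance translation jitter, pixel flips and intensity jitter emulating
intra-class handwriting diversity.  Two properties of the font matter for
the network and were designed deliberately:

* **Bounded pairwise containment.**  For weight-based recognition the
  relevant geometry is |X ∩ Y|/|X|: if one glyph's pixels are (nearly) a
  subset of another's, the subset character is unrecognizable in principle.
  Naive block capitals give containments of 1.0 (C ⊂ O, D, G, B); the font
  was adjusted until all dictionary characters stay below ~0.78.
* **Comparable stroke area.**  All "on" pixels share one intensity, so a
  character's total drive scales with its stroke area; characters much
  smaller than the rest recruit few or no selective neurons.  Stroke areas
  are kept within ~15-20 cells.

What the generator does *not* emulate: stroke-width/slant/style variation,
curvature diversity, or the natural per-writer decorrelation of real
handwriting.  Synthetic variants of two different characters are much more
similar than two handwriting samples; recognition here is therefore harder,
not easier, than on handwritten data in some respects, while intra-class
recognition is easier.  Passing dictionary-generation tests with this
generator shows the mechanism works end to end, not that its accuracy on
real handwritten characters would match.

## Diagnostics

* **Eigenvalue spectra.**  The four recurrent pathways compose into one
  signed N x N matrix (column = presynaptic neuron, positive for E, negative
  for I).  Initial weights are random with comparable scales across pathways
  and each neuron's incoming inhibitory weights are rescaled to match its
  summed incoming excitatory weight (exact per-row balance); this removes
  block-mean outlier modes, so the untrained spectrum follows the circular
  law, which is checked by a KS test of |lambda|^2 against uniformity with a
  robust (median-based) disc radius.  Learning concentrates E->E weights
  and shrinks the spectral radius and the count of modes with Re > 1.
* **PCA trajectories.**  Population rates are binned at 10 ms, smoothed with
  a 50 ms boxcar, and projected on the leading principal components (time
  bins as samples).  Across-trial dispersion is the mean over bins/neurons of
  the across-trial standard deviation of the smoothed rate.
* **Diagonal structure score.**  For the Gaussian-profile experiment, the
  In->E matrix is sorted by each neuron's preferred input index and scored by
  the weight mass within +/-10% of the input dimension around the diagonal
  (1 = perfect topographic map, ~0.2 = unstructured).
* **Noise robustness.**  Gaussian current noise of amplitude N0 is added to
  every neuron each step during testing, with the Poisson input realization
  frozen per character so across-trial variation is attributable to the
  injected noise alone.

## Problem sizes used

The packaged experiments run at desk scale: dictionary training uses up to
200 representations per word (reducible via configuration), assignment uses
a subset of the test variants, and the analysis experiments use a few
hundred presentations.  These sizes reproduce the qualitative phenomena and
the quantitative targets the test-suite checks at seed-level determinism.

## Known limitations

* The generation protocol cannot emit immediate character repetitions
  (top-2 of the same group), so words like "SEEN" collapse to "SEN"; such
  words are flagged by the corpus builder.
* Recognition quality depends on glyph geometry; characters sharing most of
  their stroke mass with others (high containment) accumulate mixed
  receptive fields and dilute the activity readout.
* The homeostatic equilibrium couples test-time firing rates to training
  statistics; very long training slowly lowers absolute rates, which
  rescales the top-2 gap relative to a fixed gap threshold.
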