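"""Stimulus generation: synthetic character glyphs, Poisson rate coding,
Gaussian firing-rate profiles and word presentation schedules.

Characters are rendered from a built-in 7x7 block font upscaled x4 to the
28x28 canvas (one input channel per pixel).  Per-instance variability -
integer translation jitter, salt-and-pepper pixel flips and intensity jitter
- emulates the intra-class diversity of handwritten characters, so no
external dataset is required.  Pixel intensities are encoded as independent
Poisson spike trains with rate proportional to intensity; at the default
``max_rate`` of 63.75 Hz a nominal "on" pixel (intensity 180) fires at
~45 Hz, the drive level the reservoir calibration assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import SimulationParams

CANVAS = 28
_UPSCALE = 4
ON_INTENSITY = 180
DEFAULT_MAX_RATE = 63.75

# 7x7 block font, A-Z.  '#' marks an "on" cell.
_FONT = {
 "A": ["...#...", "..#.#..", ".#...#.", ".#####.", ".#...#.", ".#...#.", ".#...#."],
 "B": ["###....", "#..#...", "###....", "#..#...", "#..#...", "#..#...", "###...."],
 "C": ["..##...", ".##....", "##.....", "##.....", "##.....", ".##....", "..##..."],
 "D": ["####...", "#...#..", "#....#.", "#....#.", "#....#.", "#...#..", "####..."],
 "E": ["#####..", "#......", "#......", "###....", "#......", "#......", "######."],
 "F": [".#.....", ".####..", ".#.....", ".###...", ".#.....", ".#.....", ".#....."],
 "G": ["...####", "..#....", ".#.....", ".#.####", ".#....#", "..#...#", "...####"],
 "H": ["#.....#", "#.....#", "#.....#", "#######", "#.....#", "#.....#", "#.....#"],
 "I": ["...###.", "....#..", "....#..", "....#..", "....#..", "....#..", "...###."],
 "J": ["....###", ".....#.", ".....#.", ".....#.", ".....#.", "#....#.", ".####.."],
 "K": ["#....#.", "#...#..", "#..#...", "###....", "#..#...", "#...#..", "#....#."],
 "L": ["#......", "#......", "#......", "#......", "#......", "#......", "#######"],
 "M": ["#.....#", "##...##", "#.#.#.#", "#..#..#", "#.....#", "#.....#", "#.....#"],
 "N": [".#...#.", ".##..#.", ".#.#.#.", ".#..##.", ".#...#.", ".#...#.", ".#...#."],
 "O": ["...###.", "..#...#", "..#...#", "..#...#", "..#...#", "..#...#", "...###."],
 "P": ["..####.", "..#...#", "..#...#", "..####.", "..#....", "..#....", "..#...."],
 "Q": ["..###..", ".#...#.", ".#...#.", ".#...#.", ".#.#.#.", ".#..#..", "..##.#."],
 "R": ["###....", "#..#...", "#..#...", "###....", "#.#....", "#..#...", "#...#.."],
 "S": [".######", "#......", "#......", ".#####.", "......#", "......#", "######."],
 "T": ["#######", "...#...", "...#...", "...#...", "...#...", "...#...", "...#..."],
 "U": ["#.....#", "#.....#", "#.....#", "#.....#", "#.....#", "#.....#", ".#####."],
 "V": ["#.....#", "#.....#", "#.....#", ".#...#.", ".#...#.", "..#.#..", "...#..."],
 "W": ["#.....#", "#.....#", ".#...#.", ".#...#.", ".#.#.#.", ".##.##.", "..#.#.."],
 "X": ["#.....#", ".#...#.", "..#.#..", "...#...", "..#.#..", ".#...#.", "#.....#"],
 "Y": ["#.....#", ".#...#.", "..#.#..", "...#...", "...#...", "...#...", "...#..."],
 "Z": ["#######", ".....#.", "....#..", "...#...", "..#....", ".#.....", "#######"],
}


@dataclass
class VariabilityParams:
    """Knobs of the intra-class variability model (all zero => identical copies)."""

    max_shift: int = 1        # uniform integer translation in +/- pixels
    p_flip: float = 0.03      # per-pixel flip probability (<= 0.05 keeps classes separable)
    jitter_std: float = 20.0  # additive Gaussian intensity noise on "on" pixels

    def __post_init__(self) -> None:
        if self.max_shift < 0 or self.jitter_std < 0 or not 0 <= self.p_flip <= 0.05:
            raise ValueError("invalid variability parameters (p_flip must be <= 0.05)")


def glyph_template(char: str) -> np.ndarray:
    """28x28 uint8 base rendering of one character.

    All "on" pixels share one intensity (one Poisson rate): the per-pixel
    statistics the plasticity offset is calibrated against are then the same
    for every character, and the homeostatic threshold absorbs the remaining
    per-character differences in total stroke area.
    """
    if char not in _FONT:
        raise ValueError(f"unsupported character {char!r} (A-Z only)")
    cells = np.array([[c == "#" for c in row] for row in _FONT[char]], dtype=np.uint8)
    img = np.kron(cells, np.ones((_UPSCALE, _UPSCALE), dtype=np.uint8)) * ON_INTENSITY
    return img


def render_variant(template: np.ndarray, variability: VariabilityParams,
                   rng: np.random.Generator) -> np.ndarray:
    """One seeded random rendering of a character instance."""
    img = template.astype(float)
    if variability.max_shift > 0:
        dy, dx = rng.integers(-variability.max_shift, variability.max_shift + 1, size=2)
        img = np.roll(np.roll(img, dy, axis=0), dx, axis=1)
    if variability.jitter_std > 0:
        on = img > 0
        img[on] += rng.normal(0.0, variability.jitter_std, size=int(on.sum()))
    if variability.p_flip > 0:
        flips = rng.random(img.shape) < variability.p_flip
        img[flips] = np.where(img[flips] > 0, 0.0, float(ON_INTENSITY))
    return np.clip(img, 0, 255).astype(np.uint8)


def nearest_template_label(image: np.ndarray, templates: dict,
                           max_shift: int = 2) -> str:
    """Classify an image by minimum Euclidean distance to the base glyphs.

    Distance is minimized over integer translations up to ``max_shift``, the
    same family the variability model draws from, so the metric is tolerant
    to the renderer's positional jitter.
    """
    img = image.astype(float)
    labels = sorted(templates)
    dists = []
    for k in labels:
        tpl = templates[k].astype(float)
        best = np.inf
        for dy in range(-max_shift, max_shift + 1):
            for dx in range(-max_shift, max_shift + 1):
                shifted = np.roll(np.roll(tpl, dy, axis=0), dx, axis=1)
                best = min(best, float(((img - shifted) ** 2).sum()))
        dists.append(best)
    return labels[int(np.argmin(dists))]


@dataclass
class CharacterCorpus:
    """Synthetic glyph corpus plus the word dictionary it serves.

    ``glyphs`` holds the pre-rendered test variants per character
    (n_test_reps each); training presentations draw fresh variants through
    :meth:`render`, so every word repetition uses independent renderings.
    """

    words: list
    templates: dict
    glyphs: dict                       # label -> (n_test_reps, 28, 28) uint8
    n_train_reps: int
    n_test_reps: int
    variability: VariabilityParams
    rng_seed: int
    repeated_char_words: list = field(default_factory=list)

    @property
    def labels(self) -> list:
        return sorted(self.templates)

    def render(self, label: str, rng: np.random.Generator) -> np.ndarray:
        return render_variant(self.templates[label], self.variability, rng)

    def test_variant(self, label: str, index: int) -> np.ndarray:
        return self.glyphs[label][index % self.n_test_reps]


def make_charset(words, n_train_reps: int = 200, n_test_reps: int = 100,
                 variability: VariabilityParams | None = None,
                 rng_seed: int = 0) -> CharacterCorpus:
    """Build the corpus for a word dictionary.

    Words must be uppercase A-Z.  Words with repeated characters are allowed
    but flagged in ``repeated_char_words``: the top-2 generation scheme
    cannot reproduce immediate repetitions, so such words collapse during
    evaluation.
    """
    variability = variability if variability is not None else VariabilityParams()
    words = list(words)
    for w in words:
        if not w or not all("A" <= c <= "Z" for c in w):
            raise ValueError(f"word {w!r} must be non-empty uppercase A-Z")
    chars = sorted({c for w in words for c in w})
    rng = np.random.default_rng(rng_seed)
    templates = {c: glyph_template(c) for c in chars}
    glyphs = {c: np.stack([render_variant(templates[c], variability, rng)
                           for _ in range(n_test_reps)]) for c in chars}
    repeated = [w for w in words if any(a == b for a, b in zip(w, w[1:]))]
    return CharacterCorpus(words=words, templates=templates, glyphs=glyphs,
                           n_train_reps=n_train_reps, n_test_reps=n_test_reps,
                           variability=variability, rng_seed=rng_seed,
                           repeated_char_words=repeated)


def encode_poisson(image: np.ndarray, max_rate: float, duration_ms: float,
                   dt: float, rng: np.random.Generator) -> np.ndarray:
    """Encode an intensity image as a Bernoulli-thinned Poisson spike raster.

    Pixel i fires independently each step with probability
    intensity_i/255 * max_rate * dt; returns a bool array of shape
    (n_steps, n_pixels).  Rejects rate aliasing (max_rate * dt >= 1 spike per
    step).
    """
    img = np.asarray(image, dtype=float).ravel()
    if img.min() < 0 or img.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    if max_rate <= 0:
        raise ValueError("max_rate must be positive")
    if max_rate * dt / 1000.0 >= 1.0:
        raise ValueError("dt * max_rate >= 1: spike probability per step exceeds 1")
    p = img / 255.0 * max_rate * dt / 1000.0
    n_steps = round(duration_ms / dt)
    return rng.random((n_steps, img.size)) < p[None, :]


def rates_to_raster(rates_hz: np.ndarray, duration_ms: float, dt: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Constant-rate Poisson raster for an arbitrary per-channel rate vector."""
    rates_hz = np.asarray(rates_hz, dtype=float)
    if np.any(rates_hz < 0):
        raise ValueError("rates must be non-negative")
    p = rates_hz * dt / 1000.0
    if np.any(p >= 1.0):
        raise ValueError("dt * rate >= 1: spike probability per step exceeds 1")
    n_steps = round(duration_ms / dt)
    return rng.random((n_steps, rates_hz.size)) < p[None, :]


@dataclass
class RateProfile:
    rates: np.ndarray
    shape_tag: str  # "image" | "gaussian"


def gaussian_profile(n_inputs: int, center: float, width: float,
                     mean_rate: float = 5.0) -> RateProfile:
    """Bell-shaped firing-rate profile over the input index.

    Scaled so the population-average rate equals ``mean_rate``; as
    width -> inf the profile approaches the uniform rate ``mean_rate``.
    """
    if width <= 0 or mean_rate <= 0:
        raise ValueError("width and mean_rate must be positive")
    idx = np.arange(n_inputs, dtype=float)
    log_g = -0.5 * ((idx - center) / width) ** 2
    g = np.exp(log_g - log_g.max())  # shift exponents so the peak is 1 (the
    rates = g * (mean_rate * n_inputs / g.sum())  # rescaling cancels the shift)
    return RateProfile(rates=rates, shape_tag="gaussian")


@dataclass
class StimulusSegment:
    label: str | None   # None => silent rest segment
    n_steps: int


def build_schedule(word: str, sim: SimulationParams) -> list:
    """Presentation schedule of one word: each character for
    ``presentation_ms``, then a single silent rest segment.

    Membrane state is never reset between the characters of a word; the rest
    segment lets all state except the adaptive threshold relax toward rest.
    """
    if not word:
        raise ValueError("word must be non-empty")
    segments = [StimulusSegment(c, sim.presentation_steps) for c in word]
    segments.append(StimulusSegment(None, sim.rest_steps))
    return segments
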