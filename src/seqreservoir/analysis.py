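"""Quantitative diagnostics of reservoir structure and dynamics.

Covers the eigenvalue spectrum of the signed recurrent weight matrix (with a
circular-law uniformity check for the untrained reservoir), PCA of population
rate trajectories, the diagonal-structure score of the input weight matrix
after learning a sweeping Gaussian rate profile, weight-concentration (Gini)
statistics, and the noise-robustness sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .encoding import CharacterCorpus, DEFAULT_MAX_RATE, encode_poisson
from .network import Reservoir
from .params import SimulationParams
from .protocol import AssignmentMap, evaluate, generate_sequence


@dataclass
class SpectrumReport:
    eigenvalues: np.ndarray
    spectral_radius: float
    n_unstable: int          # eigenvalues with real part > 1
    stage: str               # "before" | "after"


def eigen_spectrum(matrix: np.ndarray, stage: str = "before") -> SpectrumReport:
    """Full eigendecomposition of the signed recurrent weight matrix."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("need a square matrix")
    if not np.all(np.isfinite(matrix)):
        raise ValueError("matrix entries must be finite")
    ev = np.linalg.eigvals(matrix)
    return SpectrumReport(eigenvalues=ev,
                          spectral_radius=float(np.abs(ev).max()) if ev.size else 0.0,
                          n_unstable=int((ev.real > 1.0).sum()),
                          stage=stage)


def circle_law_pvalue(matrix: np.ndarray, standardize: bool = True) -> float:
    """KS p-value of the circular-law uniformity-in-disc check.

    Girko's law describes the i.i.d. fluctuation part of a random matrix;
    the signed reservoir matrix additionally carries deterministic structure
    (positive/negative block means from Dale's law, pathway-dependent column
    variances from the sparse densities).  With ``standardize`` each column
    is therefore centered and scaled to variance 1/N before the
    eigendecomposition, which is the matrix the law applies to.  For
    eigenvalues uniform on a disc of radius R, |lambda|^2 is uniform on
    [0, R^2]; the radius is estimated robustly from the median of |lambda|^2
    (median = R^2/2 under uniformity) and eigenvalues outside the estimated
    disc are excluded from the test sample.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("need a square matrix")
    n = m.shape[0]
    if n < 10:
        raise ValueError("too few eigenvalues for a uniformity check")
    if standardize:
        m = m - m.mean(axis=0, keepdims=True)
        sd = m.std(axis=0, keepdims=True)
        sd[sd == 0] = 1.0
        m = m / (sd * np.sqrt(n))
    r2 = np.abs(np.linalg.eigvals(m)) ** 2
    scale = 2.0 * np.median(r2)
    u = r2 / scale
    u = u[u <= 1.0]
    return float(stats.kstest(u, "uniform").pvalue)


@dataclass
class TrajectoryBundle:
    projections: np.ndarray            # (n_timebins, n_components)
    explained_variance: np.ndarray     # fractions, non-increasing
    components: np.ndarray             # (n_components, n_neurons)


def pca_trajectories(rate_matrix: np.ndarray, n_components: int = 3) -> TrajectoryBundle:
    """Project population activity (neurons x timebins) onto its leading PCs.

    Time bins are the samples and neurons the features; activity is
    mean-centered over time before the decomposition.
    """
    from sklearn.decomposition import PCA

    rates = np.asarray(rate_matrix, dtype=float)
    if rates.ndim != 2 or rates.shape[1] < 2:
        raise ValueError("need a (neurons x timebins) matrix with >= 2 bins")
    x = rates.T  # samples = timebins
    if np.allclose(x.var(axis=0), 0):
        raise ValueError("constant activity has no principal components")
    n_components = min(n_components, min(x.shape))
    pca = PCA(n_components=n_components)
    proj = pca.fit_transform(x)
    return TrajectoryBundle(projections=proj,
                            explained_variance=pca.explained_variance_ratio_,
                            components=pca.components_)


def boxcar_rates(binned_counts: np.ndarray, bin_ms: float, smooth_ms: float = 50.0) -> np.ndarray:
    """Binned spike counts (bins x neurons) -> smoothed rates in Hz."""
    rates = np.asarray(binned_counts, dtype=float) / (bin_ms / 1000.0)
    width = max(1, round(smooth_ms / bin_ms))
    kernel = np.ones(width) / width
    return np.apply_along_axis(lambda col: np.convolve(col, kernel, mode="same"),
                               0, rates)


def diagonal_structure_score(in_weights: np.ndarray, band_fraction: float = 0.1) -> float:
    """Fraction of input-weight mass on the diagonal band after sorting
    neurons by their preferred input index.

    Each neuron's preference is the weight centroid over the input index;
    neurons are sorted by centroid and the score is the share of total mass
    within +/- ``band_fraction`` of the input dimension around the diagonal of
    the sorted (inputs x neurons) matrix.  1 for a perfectly diagonal map,
    about 2*band_fraction for unstructured weights.
    """
    w = np.asarray(in_weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total == 0:
        raise ValueError("all-zero weight matrix has no structure to score")
    n_in, n_neur = w.shape
    idx = np.arange(n_in, dtype=float)
    mass = w.sum(axis=0)
    centroid = np.where(mass > 0, (idx @ w) / np.where(mass > 0, mass, 1.0), n_in / 2.0)
    order = np.argsort(centroid, kind="stable")
    w_sorted = w[:, order]
    diag_pos = (np.arange(n_neur) + 0.5) * n_in / n_neur
    band = np.abs(idx[:, None] - diag_pos[None, :]) <= band_fraction * n_in
    return float(w_sorted[band].sum() / total)


def gini(values: np.ndarray) -> float:
    """Gini coefficient of a non-negative sample (0 = equal, 1 = concentrated)."""
    x = np.sort(np.asarray(values, dtype=float).ravel())
    if x.size == 0 or np.any(x < 0):
        raise ValueError("need non-negative values")
    if x.sum() == 0:
        return 0.0
    n = x.size
    return float((2 * np.arange(1, n + 1) - n - 1) @ x / (n * x.sum()))


def trajectory_dispersion(binned_trials: list, bin_ms: float = 10.0,
                          smooth_ms: float = 50.0) -> float:
    """Across-trial variability of the population rate trajectory.

    Mean over time bins and neurons of the across-trial standard deviation of
    the boxcar-smoothed binned rate; 0 when all trials are identical.
    """
    n_bins = min(b.shape[0] for b in binned_trials)
    stack = np.stack([boxcar_rates(b[:n_bins], bin_ms, smooth_ms) for b in binned_trials])
    return float(stack.std(axis=0, ddof=0).mean())


def noise_sweep(net: Reservoir, corpus: CharacterCorpus, assignment: AssignmentMap,
                sim: SimulationParams, rng: np.random.Generator,
                n0_grid=(0.0, 0.3, 0.5, 0.7, 1.0), trials_per_level: int = 20,
                start_chars=None, gap_threshold: float = 10.0,
                length_cap: int = 10, max_rate: float = DEFAULT_MAX_RATE,
                bin_ms: float = 10.0):
    """Generation accuracy and trajectory dispersion versus noise amplitude.

    The Poisson input realization is frozen per character (one raster reused
    across all trials and noise levels), and the homeostatic thresholds are
    restored before every trial, so that across-trial variation is
    attributable to the injected current noise alone.  Dispersion is measured
    on the first presentation window, which is shared by construction.
    """
    import pandas as pd

    n0_grid = list(n0_grid)
    if not n0_grid:
        raise ValueError("empty noise grid")
    if start_chars is None:
        start_chars = sorted({w[0] for w in corpus.words})
    frozen = {lab: encode_poisson(corpus.test_variant(lab, 0), max_rate,
                                  sim.presentation_ms, sim.dt, rng)
              for lab in corpus.labels}
    bin_steps = max(1, round(bin_ms / sim.dt))
    theta0 = net.state.theta.copy()
    rows = []
    for n0 in n0_grid:
        trials = []
        first_windows = []
        for first in start_chars:
            for _ in range(trials_per_level):
                net.state.theta[:] = theta0
                res = generate_sequence(net, assignment, corpus, first, sim, rng,
                                        gap_threshold=gap_threshold,
                                        length_cap=length_cap,
                                        noise_amplitude=n0,
                                        frozen_rasters=frozen,
                                        bin_steps=bin_steps)
                trials.append(res)
                first_windows.append(res.binned[:sim.presentation_steps // bin_steps])
        report = evaluate(corpus.words, trials)
        rows.append({"n0": n0, "accuracy": report.accuracy,
                     "dispersion": trajectory_dispersion(first_windows, bin_ms),
                     "n_trials": len(trials)})
    return pd.DataFrame(rows)
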