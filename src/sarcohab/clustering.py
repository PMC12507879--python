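"""Cohort-level 1-D two-class intensity clustering and thresholding.

Three unsupervised routes to a single scalar muscle/fat decision threshold,
fitted on intensities pooled over the training cohort:

* **Otsu** — exhaustive search over histogram bin boundaries for the
  threshold maximising the between-class variance
  ``w0 * w1 * (mu0 - mu1)**2``.
* **K-means** — two clusters, k-means++ initialisation, Lloyd iterations
  with restarts; the decision boundary is where the nearest-centroid
  assignment flips (the centroid midpoint in 1-D).
* **GMM** — two-component Gaussian mixture fitted by EM, initialised from
  the k-means solution; the boundary is the intensity between the component
  means where the posterior responsibilities are equal.

Whatever the route, the initial boundary is then *refined*: the two highest
local maxima of the smoothed pooled histogram are taken as the muscle and
fat peaks, and Otsu is re-run on the intensities inside the closed interval
between the peaks flanking the initial boundary.  On cleanly bimodal data
this reproduces the unrestricted Otsu threshold; on skewed data it anchors
the threshold to the valley between the two tissue modes.

All routines are written for 1-D data; no spatial regularisation is
applied.  Label maps use the integer codes 0 = outside ROI, 1 = muscle,
2 = fat.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .errors import DegenerateInputError, InputError
from .volumes import IntensityVolume, PooledIntensities, RoiMask

LABEL_OUTSIDE, LABEL_MUSCLE, LABEL_FAT = 0, 1, 2

DEFAULT_N_BINS = 256
KMEANS_RESTARTS = 10
KMEANS_MAX_ITER = 300
GMM_TOL = 1e-6
GMM_MAX_ITER = 500
GMM_VAR_FLOOR_FRAC = 1e-6
PEAK_SMOOTH_WINDOW = 5


@dataclass
class ClusterModel:
    """A fitted two-class intensity model and its scalar threshold.

    ``fat_is_lower`` records the modality polarity: fat lies below the
    threshold on CT and above it on (non-fat-suppressed T2) MRI.
    """

    method: str
    threshold: float
    fat_is_lower: bool
    modality: str
    n_bins: int = DEFAULT_N_BINS
    seed: int | None = None
    initial_boundary: float | None = None
    kmeans_centroids: tuple[float, float] | None = None
    gmm_weights: tuple[float, float] | None = None
    gmm_means: tuple[float, float] | None = None
    gmm_variances: tuple[float, float] | None = None
    loglik_trace: list[float] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterModel":
        raw = json.loads(Path(path).read_text())
        for key in ("kmeans_centroids", "gmm_weights", "gmm_means",
                    "gmm_variances"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _as_values(values: Sequence[float]) -> np.ndarray:
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 2:
        raise DegenerateInputError("need at least two intensity values")
    if not np.all(np.isfinite(values)):
        raise InputError("non-finite intensity values")
    if values.min() == values.max():
        raise DegenerateInputError("all intensity values are identical")
    return values


# ---------------------------------------------------------------------------
# Otsu

def otsu_threshold(values: Sequence[float], n_bins: int = DEFAULT_N_BINS) -> float:
    """Between-class-variance-maximising threshold of a 1-D sample.

    The sample is binned into ``n_bins`` equal-width bins over its range and
    every interior bin boundary is scored by ``w0 * w1 * (mu0 - mu1)**2``;
    the boundary with the largest score wins, ties going to the smallest
    threshold.
    """
    values = _as_values(values)
    counts, edges = np.histogram(values, bins=n_bins)
    return _otsu_from_histogram(counts, edges)


def _otsu_from_histogram(counts: np.ndarray, edges: np.ndarray) -> float:
    p = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(p)[:-1]
    w1 = 1.0 - w0
    cum_mass = np.cumsum(p * centers)[:-1]
    total_mass = np.sum(p * centers)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = np.where(w0 > 0, cum_mass / w0, 0.0)
        mu1 = np.where(w1 > 0, (total_mass - cum_mass) / w1, 0.0)
    score = w0 * w1 * (mu0 - mu1) ** 2
    # smallest boundary within a relative ulp of the maximum: empty-bin
    # plateaus are exact ties and must resolve to the lowest threshold
    k = int(np.flatnonzero(score >= score.max() * (1 - 1e-12))[0])
    return float(edges[k + 1])


# ---------------------------------------------------------------------------
# K-means (k = 2, 1-D)

def _kmeans_pp_init(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    first = values[rng.integers(values.size)]
    d2 = (values - first) ** 2
    total = d2.sum()
    if total == 0:
        second = values[rng.integers(values.size)]
    else:
        second = values[rng.choice(values.size, p=d2 / total)]
    return np.array([first, second], dtype=np.float64)


def _lloyd(values: np.ndarray, centres: np.ndarray,
           max_iter: int) -> tuple[np.ndarray, np.ndarray, float]:
    lo, hi = np.sort(centres)
    assign = values > (lo + hi) / 2.0  # False -> low cluster
    for _ in range(max_iter):
        new = np.empty(2)
        for c, sel in enumerate((~assign, assign)):
            if sel.any():
                new[c] = values[sel].mean()
            else:  # empty cluster: reseed at the point farthest from the other
                other = values[~sel].mean() if (~sel).any() else values.mean()
                new[c] = values[np.argmax(np.abs(values - other))]
        lo, hi = np.sort(new)
        new_assign = values > (lo + hi) / 2.0
        if np.array_equal(new_assign, assign) and lo != hi:
            break
        assign = new_assign
    centres = np.array([lo, hi])
    inertia = float(np.sum((values - centres[assign.astype(int)]) ** 2))
    return centres, assign.astype(int), inertia


def kmeans_1d(values: Sequence[float], seed: int = 0,
              n_restarts: int = KMEANS_RESTARTS,
              max_iter: int = KMEANS_MAX_ITER
              ) -> tuple[np.ndarray, np.ndarray]:
    """Two-cluster 1-D k-means with k-means++ restarts.

    Returns ``(centroids, assignments)`` with centroids sorted ascending and
    assignments in {0, 1} indexing the sorted centroids; the best
    within-cluster sum of squares over ``n_restarts`` restarts is kept.
    """
    values = _as_values(values)
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(n_restarts):
        centres = _kmeans_pp_init(values, rng)
        centres, assign, inertia = _lloyd(values, centres, max_iter)
        if best is None or inertia < best[0]:
            best = (inertia, centres, assign)
    _, centres, assign = best  # type: ignore[misc]
    return centres, assign


def kmeans_objective(values: Sequence[float], centroids: Sequence[float]) -> float:
    """Within-cluster sum of squares of a 1-D sample under two centroids."""
    values = np.asarray(values, dtype=np.float64)
    centroids = np.asarray(centroids, dtype=np.float64)
    d2 = (values[:, None] - centroids[None, :]) ** 2
    return float(d2.min(axis=1).sum())


# ---------------------------------------------------------------------------
# Gaussian mixture EM

@dataclass
class GmmFit:
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    loglik_trace: list[float]
    converged: bool


def gmm_em(values: Sequence[float], init_means: Sequence[float],
           tol: float = GMM_TOL, max_iter: int = GMM_MAX_ITER,
           var_floor_frac: float = GMM_VAR_FLOOR_FRAC) -> GmmFit:
    """Fit a two-component 1-D Gaussian mixture by EM.

    Initialised from the k-means partition implied by ``init_means``
    (weights = cluster proportions, means = cluster means, variances =
    within-cluster variances).  Variances are clamped to a floor of
    ``var_floor_frac * var(values)`` so a component can never collapse onto
    a single point.  Iteration stops when the relative log-likelihood gain
    drops below ``tol``.
    """
    values = _as_values(values)
    n = values.size
    init_means = np.sort(np.asarray(init_means, dtype=np.float64))
    if init_means.size != 2:
        raise InputError("init_means must contain exactly two values")

    var_floor = max(var_floor_frac * float(np.var(values)), 1e-12)
    mid = init_means.mean()
    assign = values > mid
    weights = np.array([max((~assign).mean(), 1e-3),
                        max(assign.mean(), 1e-3)])
    weights /= weights.sum()
    means = init_means.copy()
    variances = np.empty(2)
    for c, sel in enumerate((~assign, assign)):
        variances[c] = np.var(values[sel]) if sel.sum() > 1 else np.var(values)
    variances = np.maximum(variances, var_floor)

    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        # E-step: log responsibilities
        log_comp = (np.log(weights)[None, :]
                    - 0.5 * np.log(2.0 * np.pi * variances)[None, :]
                    - 0.5 * (values[:, None] - means[None, :]) ** 2
                    / variances[None, :])
        log_norm = logsumexp(log_comp, axis=1)
        loglik = float(log_norm.sum())
        if not np.isfinite(loglik):
            raise InputError("non-finite mixture likelihood")
        resp = np.exp(log_comp - log_norm[:, None])
        if trace and abs(loglik - trace[-1]) <= tol * abs(trace[-1]):
            trace.append(loglik)
            converged = True
            break
        trace.append(loglik)
        # M-step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-10)
        weights = nk / n
        means = (resp * values[:, None]).sum(axis=0) / nk
        variances = ((resp * (values[:, None] - means[None, :]) ** 2)
                     .sum(axis=0) / nk)
        variances = np.maximum(variances, var_floor)

    order = np.argsort(means)
    return GmmFit(weights=weights[order], means=means[order],
                  variances=variances[order], loglik_trace=trace,
                  converged=converged)


def gmm_equal_posterior_boundary(weights: Sequence[float],
                                 means: Sequence[float],
                                 variances: Sequence[float]) -> float:
    """Intensity between the two component means where the posterior
    responsibilities of a two-component 1-D Gaussian mixture are equal.

    Solved numerically on the open interval between the means; falls back
    to the midpoint if the weighted densities do not bracket a crossing
    there (possible under extreme weight imbalance).
    """
    w = np.asarray(weights, float)
    m = np.asarray(means, float)
    v = np.asarray(variances, float)
    order = np.argsort(m)
    w, m, v = w[order], m[order], v[order]
    if np.isclose(m[0], m[1]):
        return float(m.mean())

    def log_ratio(x: float) -> float:
        lo = np.log(w[0]) - 0.5 * np.log(2 * np.pi * v[0]) \
            - 0.5 * (x - m[0]) ** 2 / v[0]
        hi = np.log(w[1]) - 0.5 * np.log(2 * np.pi * v[1]) \
            - 0.5 * (x - m[1]) ** 2 / v[1]
        return lo - hi

    eps = 1e-9 * (m[1] - m[0])
    a, b = m[0] + eps, m[1] - eps
    if log_ratio(a) > 0 and log_ratio(b) < 0:
        return float(brentq(log_ratio, a, b, xtol=1e-12 * max(1.0, m[1] - m[0])))
    return float(m.mean())


# ---------------------------------------------------------------------------
# Histogram peaks and threshold refinement

def smoothed_histogram(values: np.ndarray, n_bins: int,
                       window: int = PEAK_SMOOTH_WINDOW
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram counts smoothed with a centred moving average
    (reflect-padded), plus the bin edges."""
    counts, edges = np.histogram(values, bins=n_bins)
    half = window // 2
    padded = np.pad(counts.astype(np.float64), half, mode="reflect")
    kernel = np.ones(window) / window
    smooth = np.convolve(padded, kernel, mode="valid")
    return smooth, edges


def _local_maxima(smooth: np.ndarray, min_separation: int) -> np.ndarray:
    """Indices of prominent local maxima at least ``min_separation`` bins
    apart, boundary bins eligible.  Residual histogram noise produces
    shallow bumps on a single tissue mode; a genuine mode is required to
    rise at least twice as high as the valley separating it from its
    neighbours (prominence >= half its own height)."""
    from scipy.signal import find_peaks
    padded = np.r_[-np.inf, smooth, -np.inf]
    idx, props = find_peaks(padded, distance=max(1, min_separation),
                            prominence=0.0)
    keep = (props["prominences"] >= 0.5 * padded[idx]) \
        & (padded[idx] >= 0.05 * float(smooth.max()))
    return idx[keep] - 1


def histogram_peaks(values: np.ndarray, n_bins: int = DEFAULT_N_BINS,
                    window: int = PEAK_SMOOTH_WINDOW) -> np.ndarray:
    """Intensity positions (bin centres) of the two highest well-separated
    local maxima of the smoothed histogram, sorted ascending.  May return
    fewer than two on unimodal data."""
    smooth, edges = smoothed_histogram(values, n_bins, window)
    centers = 0.5 * (edges[:-1] + edges[1:])
    maxima = _local_maxima(smooth, min_separation=max(2, n_bins // 16))
    if maxima.size == 0:
        return np.array([])
    top = maxima[np.argsort(smooth[maxima])][::-1][:2]
    return np.sort(centers[top])


def refine_threshold(values: np.ndarray, initial: float,
                     n_bins: int = DEFAULT_N_BINS) -> float:
    """Refine a muscle/fat boundary with peak-restricted Otsu.

    The two dominant histogram peaks are located; if they flank the initial
    boundary, Otsu is recomputed on the sample restricted to the closed
    interval between them.  Without two flanking peaks the initial boundary
    is kept and a warning emitted.
    """
    peaks = histogram_peaks(values, n_bins)
    if peaks.size < 2 or not (peaks[0] <= initial <= peaks[1]):
        warnings.warn(
            "could not locate two histogram peaks flanking the boundary; "
            "keeping the unrefined threshold", stacklevel=2)
        return float(initial)
    window_values = values[(values >= peaks[0]) & (values <= peaks[1])]
    if window_values.size < 2 or window_values.min() == window_values.max():
        warnings.warn("degenerate peak window; keeping the unrefined "
                      "threshold", stacklevel=2)
        return float(initial)
    return otsu_threshold(window_values, n_bins)


# ---------------------------------------------------------------------------
# Fitting front-end

def fit_cluster_model(pooled: PooledIntensities, method: str,
                      n_bins: int = DEFAULT_N_BINS, seed: int = 0,
                      refine: bool = True) -> ClusterModel:
    """Fit one clustering method on pooled training intensities and derive
    the final muscle/fat threshold (initial boundary + peak-restricted Otsu
    refinement)."""
    values = _as_values(pooled.values)
    fat_is_lower = pooled.modality == "CT"
    model = ClusterModel(method=method, threshold=np.nan,
                         fat_is_lower=fat_is_lower, modality=pooled.modality,
                         n_bins=n_bins, seed=seed)
    if method == "otsu":
        initial = otsu_threshold(values, n_bins)
    elif method == "kmeans":
        centres, _ = kmeans_1d(values, seed=seed)
        model.kmeans_centroids = (float(centres[0]), float(centres[1]))
        initial = float(centres.mean())  # assignment flip point in 1-D
    elif method == "gmm":
        centres, _ = kmeans_1d(values, seed=seed)
        model.kmeans_centroids = (float(centres[0]), float(centres[1]))
        fit = gmm_em(values, centres)
        model.gmm_weights = tuple(fit.weights)
        model.gmm_means = tuple(fit.means)
        model.gmm_variances = tuple(fit.variances)
        model.loglik_trace = [float(x) for x in fit.loglik_trace]
        initial = gmm_equal_posterior_boundary(fit.weights, fit.means,
                                               fit.variances)
    else:
        raise InputError(f"unknown method {method!r}")
    model.initial_boundary = float(initial)
    model.threshold = refine_threshold(values, initial, n_bins) if refine \
        else float(initial)
    return model


# ---------------------------------------------------------------------------
# Voxel classification

def classify_voxels(volume: IntensityVolume, mask: RoiMask, threshold: float,
                    modality: str | None = None) -> np.ndarray:
    """Label ROI voxels muscle/fat by thresholding with modality polarity.

    CT: intensity <= threshold -> fat (fat is hypodense).
    MRI: intensity >= threshold -> fat (fat is T2-hyperintense).
    Returns an int8 grid with codes 0 = outside, 1 = muscle, 2 = fat.
    """
    if modality is None:
        modality = volume.modality
    if modality not in ("CT", "MRI"):
        raise InputError(f"unknown modality {modality!r}")
    if not np.isfinite(threshold):
        raise InputError("threshold must be finite")
    if volume.shape != mask.shape:
        raise InputError("volume/mask shape mismatch")
    if modality == "CT":
        is_fat = volume.voxels <= threshold
    else:
        is_fat = volume.voxels >= threshold
    labels = np.zeros(volume.shape, dtype=np.int8)
    labels[mask.voxels] = np.where(is_fat[mask.voxels], LABEL_FAT, LABEL_MUSCLE)
    return labels
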