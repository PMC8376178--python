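"""Spot-detector parameter extraction and tuning against annotations.

Given a sample image and a handful of annotated spot centers (expert or
crowd consensus), this module measures spot sizes by Gaussian fitting,
derives the sigma range and intensity threshold for the multi-scale LoG
detector (threshold chosen to maximise precision x recall against the
annotations), sweeps the integer "stringency" knob of a local-max peak
finder, and characterises how many ground-truth points are needed via
training curves over random annotation subsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InsufficientAnnotationsError
from ._gaussfit import GaussianFit, fit_gaussian
from .evalmetrics import DEFAULT_CORRECTNESS_THRESHOLD, match_points
from .imageprep import detect_from_stack, log_response_stack, sigma_grid
from .records import SpotRecord, spot_coords

logger = logging.getLogger(__name__)


@dataclass
class DetectionParams:
    """LoG detector settings extracted from an annotated sample image."""

    sigma_min: float
    sigma_max: float
    intensity_threshold: float
    n_scales: int = 7

    def __post_init__(self) -> None:
        if not 0 < self.sigma_min <= self.sigma_max:
            raise ValueError("need 0 < sigma_min <= sigma_max")


@dataclass
class TuningResult:
    """Precision/recall curves over a stringency (or threshold) grid."""

    grid: list
    precision_curve: list[float]
    recall_curve: list[float]
    best_stringency: object = None
    best_precision: float = 0.0
    best_recall: float = 0.0
    extras: dict = field(default_factory=dict)


def fit_gaussian_sigma(
    image: np.ndarray, x: float, y: float, window_halfwidth: int = 6
) -> GaussianFit:
    """Isotropic Gaussian fit around an annotated spot center.

    Returns sigma, amplitude and background offset (plus the refined
    center and a ``flagged`` bit for fits that fell back to second
    moments).  The fit model is ``offset + A exp(-r^2 / 2 sigma^2)``, so
    adding a constant to the image only shifts the offset.
    """
    if window_halfwidth < 3:
        raise ValueError("window_halfwidth must be >= 3")
    return fit_gaussian(image, x, y, window_halfwidth=window_halfwidth)


def extract_spot_params(
    image: np.ndarray,
    expert_points,
    sigma_scales: int = 7,
    threshold_grid: np.ndarray | None = None,
    correctness_threshold: float = DEFAULT_CORRECTNESS_THRESHOLD,
    sigma_guard: float = 0.10,
) -> DetectionParams:
    """Derive LoG detector parameters from annotated spot centers.

    Per annotated point an isotropic Gaussian is fitted; the detector's
    sigma range is the fitted range widened by ``sigma_guard`` (the
    annotations mark centers, not extents) and floored at 0.5 px.  The
    intensity threshold is the grid value maximising precision x recall
    of the detector against the annotations, ties broken toward the
    larger threshold (favoring precision).  The default grid is 50
    geometric points over the detector's response range.
    """
    pts = spot_coords(expert_points)
    if len(pts) < 3:
        raise InsufficientAnnotationsError(
            f"parameter extraction needs >= 3 annotated spots, got {len(pts)}"
        )
    fits = [fit_gaussian_sigma(image, x, y) for x, y in pts]
    sigmas = np.array([f.sigma for f in fits if not f.flagged])
    if len(sigmas) == 0:
        sigmas = np.array([f.sigma for f in fits])
    sigma_min = max(0.5, float(sigmas.min()) * (1.0 - sigma_guard))
    sigma_max = float(sigmas.max()) * (1.0 + sigma_guard)
    sigma_max = max(sigma_max, sigma_min)

    scales = sigma_grid(sigma_min, sigma_max, sigma_scales)
    responses = log_response_stack(image, scales)
    if threshold_grid is None:
        top = float(responses.max())
        if top <= 0:
            return DetectionParams(sigma_min, sigma_max, 0.0, sigma_scales)
        threshold_grid = np.geomspace(top / 1000.0, top, 50)
    grid_sorted = np.sort(np.asarray(threshold_grid, dtype=float))
    # one detection pass at the lowest threshold; higher thresholds are
    # exact amplitude-filtered subsets (see detect_from_stack)
    base = detect_from_stack(responses, scales, float(grid_sorted[0]))
    base_xy = spot_coords(base)
    base_amp = np.array([d.amplitude for d in base])
    best_score, best_t = -1.0, float(grid_sorted[0])
    for t in grid_sorted:
        sel = base_xy[base_amp > t] if len(base) else base_xy
        res = match_points(sel, pts, correctness_threshold)
        score = res.precision * res.recall
        # ascending grid + non-strict comparison = ties go to the larger
        # threshold (favor precision)
        if score >= best_score - 1e-12:
            best_score, best_t = max(score, best_score), float(t)
    return DetectionParams(sigma_min, sigma_max, best_t, sigma_scales)


def detect_with_params(image: np.ndarray, params: DetectionParams) -> list[SpotRecord]:
    """Run the LoG detector with extracted parameters."""
    scales = sigma_grid(params.sigma_min, params.sigma_max, params.n_scales)
    responses = log_response_stack(image, scales)
    return detect_from_stack(responses, scales, params.intensity_threshold)


def _local_maxima(image: np.ndarray, min_distance: int) -> tuple[np.ndarray, np.ndarray]:
    """(coords (n,2) as x,y; intensities) of strict regional maxima."""
    size = 2 * min_distance + 1
    footprint = np.ones((size, size), dtype=bool)
    mx = ndimage.maximum_filter(image, footprint=footprint, mode="nearest")
    # ignore flat background plateaus: require the max to exceed the image minimum
    mask = (image >= mx) & (image > image.min())
    ys, xs = np.nonzero(mask)
    return np.column_stack([xs, ys]).astype(float), image[ys, xs]


def _stringency_cutoff(intensities: np.ndarray, stringency: int, n_grid: int = 100):
    """Plateau-based cutoff selection for the local-max peak finder.

    The candidate cutoffs are a dense grid over the local-maximum
    intensity range; the peak-count-vs-cutoff staircase has a "stable
    plateau" (the longest run of constant count), whose start is the
    base cutoff.  Stringency s moves s distinct count-levels further
    down the staircase (fewer peaks).  Returns (cutoff, clamped).
    """
    lo, hi = float(intensities.min()), float(intensities.max())
    if hi <= lo:
        return lo, False
    grid = np.linspace(lo, hi, n_grid)
    counts = np.array([(intensities >= g).sum() for g in grid])
    # longest run of constant count = the stable plateau
    best_len, best_start = 0, 0
    run_start = 0
    for i in range(1, len(counts) + 1):
        if i == len(counts) or counts[i] != counts[run_start]:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = i
    base_count = counts[best_start]
    # distinct count levels below the plateau, in decreasing order
    levels = sorted({c for c in counts if c < base_count}, reverse=True)
    if stringency == 0 or not levels:
        return float(grid[best_start]), stringency > len(levels)
    clamped = stringency > len(levels)
    target = levels[min(stringency, len(levels)) - 1]
    idx = int(np.argmax(counts <= target))
    return float(grid[idx]), clamped


def local_max_peakfind(
    image: np.ndarray, stringency: int = 0, min_distance: int = 2
) -> list[SpotRecord]:
    """Local-maximum peak finder with an integer stringency knob.

    Stringency indirectly controls the intensity cutoff for accepting a
    peak: higher stringency selects a higher cutoff along the
    peak-count staircase, so the detection count is non-increasing in
    stringency.  Out-of-range stringency clamps to the highest cutoff
    with a logged warning.
    """
    if stringency < 0:
        raise ValueError("stringency must be a non-negative integer")
    if min_distance < 1:
        raise ValueError("min_distance must be >= 1")
    image = np.asarray(image, dtype=float)
    coords, intensities = _local_maxima(image, min_distance)
    if len(coords) == 0:
        return []
    cutoff, clamped = _stringency_cutoff(intensities, stringency)
    if clamped:
        logger.warning("stringency %d beyond available cutoffs; clamped", stringency)
    keep = intensities >= cutoff
    order = np.argsort(-intensities[keep], kind="stable")
    sel_coords = coords[keep][order]
    sel_int = intensities[keep][order]
    # enforce the minimum separation among accepted peaks
    out: list[SpotRecord] = []
    for (x, y), v in zip(sel_coords, sel_int):
        if all((x - s.x) ** 2 + (y - s.y) ** 2 >= min_distance**2 for s in out):
            out.append(SpotRecord(x=float(x), y=float(y), sigma=1.0, amplitude=float(v)))
    return out


def tune_stringency(
    image: np.ndarray,
    truth_points,
    grid=range(0, 11),
    correctness_threshold: float = DEFAULT_CORRECTNESS_THRESHOLD,
    min_distance: int = 2,
) -> TuningResult:
    """Sweep the stringency grid and pick the precision x recall maximiser.

    Ties are broken toward higher stringency (prefer missing spots over
    detecting spurious ones).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("stringency grid is empty")
    truth = spot_coords(truth_points)
    if len(truth) == 0:
        raise ValueError("truth point set is empty")
    precisions, recalls = [], []
    best_score, best_idx = -1.0, 0
    for i, s in enumerate(sorted(grid)):
        det = local_max_peakfind(image, int(s), min_distance)
        res = match_points(spot_coords(det), truth, correctness_threshold)
        precisions.append(res.precision)
        recalls.append(res.recall)
        score = res.precision * res.recall
        # ascending sweep + non-strict comparison = ties go to the higher
        # stringency (prefer missing spots over spurious detections)
        if score >= best_score - 1e-12:
            best_score, best_idx = max(score, best_score), i
    grid = sorted(grid)
    return TuningResult(
        grid=grid,
        precision_curve=precisions,
        recall_curve=recalls,
        best_stringency=grid[best_idx],
        best_precision=precisions[best_idx],
        best_recall=recalls[best_idx],
    )


def training_curve(
    image: np.ndarray,
    truth_points,
    subset_sizes,
    n_reps: int = 20,
    seed: int = 0,
    correctness_threshold: float = DEFAULT_CORRECTNESS_THRESHOLD,
):
    """How detector performance grows with ground-truth sample size.

    For each subset size, ``n_reps`` random subsets (without
    replacement) are used to extract detector parameters; the tuned
    detector is evaluated against the *full* truth set.  Returns a list
    of dicts (size, mean/std precision and recall).  A subset equal to
    the full truth is evaluated once (it is deterministic).
    """
    import pandas as pd

    truth = spot_coords(truth_points)
    rng = np.random.default_rng(seed)
    rows = []
    for size in subset_sizes:
        if size > len(truth):
            raise ValueError(f"subset size {size} exceeds truth size {len(truth)}")
        reps = 1 if size == len(truth) else n_reps
        ps, rs = [], []
        for _ in range(reps):
            sel = rng.choice(len(truth), size=size, replace=False)
            try:
                params = extract_spot_params(
                    image, truth[sel], correctness_threshold=correctness_threshold
                )
            except InsufficientAnnotationsError:
                continue
            det = detect_with_params(image, params)
            res = match_points(spot_coords(det), truth, correctness_threshold)
            ps.append(res.precision)
            rs.append(res.recall)
        rows.append(
            {
                "size": int(size),
                "mean_precision": float(np.mean(ps)),
                "std_precision": float(np.std(ps)),
                "mean_recall": float(np.mean(rs)),
                "std_recall": float(np.std(rs)),
                "n_reps": len(ps),
            }
        )
    return pd.DataFrame(rows)
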