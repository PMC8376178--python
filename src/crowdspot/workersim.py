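"""Simulated crowd annotators.

A stand-in for a crowdsourcing service: each synthetic worker detects
spots with an SNR-dependent (logistic) probability, clicks with Gaussian
jitter, occasionally merges close spot pairs into a single click (or
multi-clicks inside the pair region), adds Poisson false positives, and
never places more clicks than a per-image budget.  The behavioral knobs
are invented but configurable; defaults are chosen to be plausible for
paid micro-task annotators.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import ANNOTATION_COLUMNS, AnnotationSet, SpotRecord, spot_coords


@dataclass
class WorkerModel:
    """Behavioral parameters of one simulated annotator population.

    ``p_detect_midpoint`` is the SNR at which detection probability is
    0.5 and ``p_detect_slope`` the logistic steepness; spots with sigma
    below 1 px have their effective SNR halved (small spots are harder).
    ``merge_radius_frac`` is the fraction of the displayed image width
    below which a spot pair may be merged into one click, mimicking the
    finite radius of the click marker at the annotation interface.
    """

    p_detect_midpoint: float = 5.0
    p_detect_slope: float = 1.0
    click_jitter_sigma: float = 1.0
    fp_rate: float = 2.0
    click_budget: int = 120
    merge_radius_frac: float = 0.04
    p_merge: float = 0.6
    p_multiclick: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_merge", "p_multiclick"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.click_budget <= 0:
            raise ValueError("click_budget must be positive")
        if self.fp_rate < 0 or self.click_jitter_sigma < 0:
            raise ValueError("fp_rate and click_jitter_sigma must be non-negative")

    def detection_probability(self, snr: float, sigma: float = 1.5) -> float:
        eff = snr * (0.5 if sigma < 1.0 else 1.0)
        z = self.p_detect_slope * (eff - self.p_detect_midpoint)
        # clip to keep exp() finite for extreme slopes
        return 1.0 / (1.0 + math.exp(-min(max(z, -700.0), 700.0)))


def _worker_rng(model_seed: int, worker_id: str) -> np.random.Generator:
    # stable across processes: crc32, not Python's salted hash
    stream = (int(model_seed) ^ zlib.crc32(worker_id.encode())) & 0x7FFFFFFF
    return np.random.default_rng(stream)


def simulate_worker(
    truth: list[SpotRecord],
    image_width: int,
    image_height: int,
    model: WorkerModel,
    worker_id: str,
    image_id: str = "img0",
) -> pd.DataFrame:
    """One worker's clicks on an image with known spots.

    Returns a DataFrame in the canonical annotation schema.  Deterministic
    given ``(model.seed, worker_id)``; workers are independent streams, so
    adding workers never perturbs existing ones.
    """
    rng = _worker_rng(model.seed, worker_id)
    coords = spot_coords(truth)
    n = len(truth)
    snrs = np.array([s.snr if math.isfinite(s.snr) else 50.0 for s in truth])
    sigmas = np.array([s.sigma for s in truth])

    p = np.array([model.detection_probability(s, g) for s, g in zip(snrs, sigmas)])
    detected = np.flatnonzero(rng.random(n) < p)

    clicks: list[tuple[float, float]] = []
    merge_radius = model.merge_radius_frac * image_width
    consumed = np.zeros(n, dtype=bool)
    if merge_radius > 0 and len(detected) > 1:
        det_pts = coords[detected]
        # candidate merge pairs among this worker's detections, closest first
        from scipy.spatial import cKDTree

        pairs = sorted(
            cKDTree(det_pts).query_pairs(merge_radius),
            key=lambda ij: float(np.hypot(*(det_pts[ij[0]] - det_pts[ij[1]]))),
        )
        for i_loc, j_loc in pairs:
            i, j = detected[i_loc], detected[j_loc]
            if consumed[i] or consumed[j]:
                continue
            if rng.random() < model.p_merge:
                consumed[i] = consumed[j] = True
                mid = (coords[i] + coords[j]) / 2.0
                clicks.append(tuple(mid + rng.normal(0.0, model.click_jitter_sigma, 2)))
                if rng.random() < model.p_multiclick:
                    # a second click somewhere along the pair axis
                    t = rng.uniform(0.2, 0.8)
                    pt = coords[i] * (1 - t) + coords[j] * t
                    clicks.append(tuple(pt + rng.normal(0.0, model.click_jitter_sigma, 2)))

    for i in detected:
        if not consumed[i]:
            clicks.append(tuple(coords[i] + rng.normal(0.0, model.click_jitter_sigma, 2)))

    n_fp = rng.poisson(model.fp_rate)
    fps = [
        (rng.uniform(0, image_width - 1), rng.uniform(0, image_height - 1))
        for _ in range(n_fp)
    ]

    # budget: keep spot-derived clicks preferentially, then false positives
    if len(clicks) > model.click_budget:
        keep = rng.choice(len(clicks), size=model.click_budget, replace=False)
        clicks = [clicks[k] for k in sorted(keep)]
        fps = []
    else:
        room = model.click_budget - len(clicks)
        fps = fps[:room]
    all_clicks = clicks + fps
    order = rng.permutation(len(all_clicks))
    all_clicks = [all_clicks[k] for k in order]

    xs = np.clip([c[0] for c in all_clicks], 0.0, image_width - 1e-6)
    ys = np.clip([c[1] for c in all_clicks], 0.0, image_height - 1e-6)
    return pd.DataFrame(
        {
            "worker_id": worker_id,
            "image_id": image_id,
            "x": xs,
            "y": ys,
        },
        columns=ANNOTATION_COLUMNS,
    )


def simulate_crowd(
    truth: list[SpotRecord],
    image_width: int,
    image_height: int,
    model: WorkerModel,
    n_workers: int = 25,
    image_id: str = "img0",
) -> AnnotationSet:
    """Concatenate independent workers ``w000 .. w{n-1}`` into one set."""
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    frames = [
        simulate_worker(truth, image_width, image_height, model, f"w{k:03d}", image_id)
        for k in range(n_workers)
    ]
    df = pd.concat(frames, ignore_index=True)
    return AnnotationSet(image_id=image_id, df=df)
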