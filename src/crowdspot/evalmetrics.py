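"""Point-set evaluation: matching, precision/recall/Jaccard, spacing
statistics and worker-performance summaries.

A predicted point counts as correct when it can be matched one-to-one to
a ground-truth point no farther than the correctness threshold (pixels).
Matching is greedy over pairs sorted by distance; an optimal
maximum-cardinality bipartite matcher is also provided and serves as the
cross-check oracle in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching
from scipy.spatial import cKDTree

from .records import AnnotationSet, spot_coords

DEFAULT_CORRECTNESS_THRESHOLD = 4.0


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def precision(self) -> float:
        if self.tp + self.fp == 0:
            return 1.0 if self.fn == 0 else 0.0
        return self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        if self.tp + self.fn == 0:
            return 1.0
        return self.tp / (self.tp + self.fn)

    @property
    def jaccard(self) -> float:
        denom = self.tp + self.fp + self.fn
        return 1.0 if denom == 0 else self.tp / denom

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "jaccard": self.jaccard,
        }


def _threshold_pairs(pred: np.ndarray, truth: np.ndarray, threshold: float):
    """All (i, j, distance) with distance <= threshold, via KD-tree."""
    if len(pred) == 0 or len(truth) == 0:
        return []
    tree = cKDTree(truth)
    out = []
    for i, neighbors in enumerate(tree.query_ball_point(pred, threshold)):
        for j in neighbors:
            out.append((i, j, float(np.hypot(*(pred[i] - truth[j])))))
    return out


def match_points(pred, truth, correctness_threshold: float = DEFAULT_CORRECTNESS_THRESHOLD) -> MatchResult:
    """Greedy one-to-one matching of predictions to ground truth.

    Pairs are visited by ascending distance (ties broken by index for
    order stability) and accepted when both endpoints are unclaimed.
    """
    if correctness_threshold <= 0:
        raise ValueError("correctness_threshold must be positive")
    p = spot_coords(pred)
    t = spot_coords(truth)
    pairs = sorted(_threshold_pairs(p, t, correctness_threshold), key=lambda e: (e[2], e[0], e[1]))
    used_p = np.zeros(len(p), dtype=bool)
    used_t = np.zeros(len(t), dtype=bool)
    matched = []
    for i, j, d in pairs:
        if not used_p[i] and not used_t[j]:
            used_p[i] = used_t[j] = True
            matched.append((i, j, d))
    tp = len(matched)
    return MatchResult(tp=tp, fp=len(p) - tp, fn=len(t) - tp, pairs=matched)


def optimal_match_count(pred, truth, correctness_threshold: float = DEFAULT_CORRECTNESS_THRESHOLD) -> int:
    """Maximum-cardinality matching size on the threshold graph."""
    p = spot_coords(pred)
    t = spot_coords(truth)
    pairs = _threshold_pairs(p, t, correctness_threshold)
    if not pairs:
        return 0
    rows = [e[0] for e in pairs]
    cols = [e[1] for e in pairs]
    graph = csr_matrix((np.ones(len(pairs)), (rows, cols)), shape=(len(p), len(t)))
    match = maximum_bipartite_matching(graph, perm_type="column")
    return int((match >= 0).sum())


def jaccard_between(set_a, set_b, threshold: float = DEFAULT_CORRECTNESS_THRESHOLD) -> float:
    """Intersection-over-union agreement between two point sets."""
    return match_points(set_a, set_b, threshold).jaccard


def nnd_stats(points) -> tuple[float, float, float]:
    """(mean, median, min) nearest-neighbor distance of a point set."""
    pts = spot_coords(points)
    if len(pts) < 2:
        raise ValueError("nearest-neighbor statistics need at least 2 points")
    d, _ = cKDTree(pts).query(pts, k=2)
    nnd = d[:, 1]
    return float(nnd.mean()), float(np.median(nnd)), float(nnd.min())


def annotation_capacity(click_ceiling: float, spots_per_cell: float) -> float:
    """Cells per image one annotator can cover given a click ceiling.

    With a per-image click budget and a typical number of spots per cell,
    the reliable annotation capacity is simply their ratio.
    """
    if spots_per_cell <= 0:
        raise ValueError("spots_per_cell must be positive")
    return click_ceiling / spots_per_cell


def worker_performance(
    annos: AnnotationSet,
    truth,
    threshold: float = DEFAULT_CORRECTNESS_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Per-worker and per-spot performance tables plus aggregates.

    Per worker: click count, spots covered (>=1 click within threshold),
    greedy one-to-one recall.  Per spot: fraction of workers covering it.
    The identity sum(worker spots_covered) == sum(spot worker counts)
    holds by construction.
    """
    if annos.n_workers < 1:
        raise ValueError("need at least one worker")
    t = spot_coords(truth)
    n_truth = len(t)
    tree = cKDTree(t) if n_truth else None
    worker_rows = []
    cover_counts = np.zeros(n_truth, dtype=int)
    for wid, grp in annos.df.groupby("worker_id", sort=True):
        clicks = grp[["x", "y"]].to_numpy(dtype=float)
        covered = np.zeros(n_truth, dtype=bool)
        if tree is not None and len(clicks):
            for neighbors in tree.query_ball_point(clicks, threshold):
                covered[neighbors] = True
        cover_counts += covered
        res = match_points(clicks, t, threshold) if n_truth else MatchResult(0, len(clicks), 0)
        worker_rows.append(
            {
                "worker_id": wid,
                "n_clicks": len(clicks),
                "n_spots_covered": int(covered.sum()),
                "recall": res.recall,
            }
        )
    worker_df = pd.DataFrame(worker_rows)
    n_workers = len(worker_df)
    spot_df = pd.DataFrame(
        {
            "spot_index": np.arange(n_truth),
            "x": t[:, 0] if n_truth else [],
            "y": t[:, 1] if n_truth else [],
            "n_workers": cover_counts,
            "worker_fraction": cover_counts / n_workers if n_truth else [],
        }
    )
    aggregate = {
        "mean_clicks_per_worker": float(worker_df["n_clicks"].mean()),
        "mean_fraction_spots_clicked": float(
            (worker_df["n_spots_covered"] / n_truth).mean()
        )
        if n_truth
        else math.nan,
        "fraction_spots_covered_by_half": float((spot_df["worker_fraction"] >= 0.5).mean())
        if n_truth
        else math.nan,
    }
    return worker_df, spot_df, aggregate
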