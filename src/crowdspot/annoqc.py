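"""Consensus building from redundant point annotations.

Redundant clicks from many annotators are clustered (affinity
propagation), then quality-controlled with two rules:

* **size thresholding** — clusters backed by few annotations are usually
  spurious; a 1-D 2-means split of cluster sizes separates the low-support
  mode and removes it;
* **clump handling** — when adjacent spots are merged into one cluster, an
  elevated fraction of annotators contribute *more than one* click to it;
  clusters past the steepest-increase point of the multi-click-fraction
  histogram are routed to 2-D k-means declumping.

The output is a list of consensus spot locations with support counts and
provenance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import AffinityPropagation

from .imageprep import _single_linkage_groups
from .records import AnnotationSet, spot_coords

logger = logging.getLogger(__name__)


@dataclass
class Cluster:
    """A group of annotations presumed to target one spot."""

    cluster_id: str
    members: "np.ndarray"  # (n, 2) click coordinates
    worker_ids: list[str]

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.members.mean(axis=0)
        return float(c[0]), float(c[1])

    @property
    def n_annotations(self) -> int:
        return len(self.members)

    @property
    def n_unique_workers(self) -> int:
        return len(set(self.worker_ids))

    @property
    def multi_frac(self) -> float:
        """Fraction of contributing workers who contribute more than once."""
        uniq, counts = np.unique(np.asarray(self.worker_ids), return_counts=True)
        return float((counts >= 2).sum() / len(uniq))


@dataclass
class ConsensusPoint:
    x: float
    y: float
    n_support: int
    origin: str = "retained"  # or "declumped"


@dataclass
class QCOptions:
    """Knobs of :func:`run_qc`; defaults follow the toolkit conventions."""

    n_bins: int = 10
    declump_k: int = 2
    partition_radius: float | None = 6.0
    damping: float = 0.9
    max_iter: int = 400
    fallback_radius: float = 3.0


def _component_preference(pts: np.ndarray) -> float:
    """Exemplar preference for one spatial component of clicks.

    Affinity propagation trades the summed within-cluster squared
    distances against one 'preference' cost per exemplar.  With the
    conventional median-similarity preference a component holding one
    spot's clicks (n clicks with jitter spread sigma_j) is worth
    splitting, because the preference (~ -4 sigma_j^2) is cheaper than
    the ~n sigma_j^2 distance saving.  Scaling the preference by the
    click count, ``-(n * median pairwise d^2)``, makes splitting a
    single coherent blob unprofitable at any jitter scale while leaving
    genuinely multi-spot clumps (whose split saving grows with the spot
    separation squared) to the declumping stage.
    """
    d2 = cdist(pts, pts, "sqeuclidean")
    med = float(np.median(d2[np.triu_indices_from(d2, k=1)]))
    return -max(len(pts), 2) * max(med, 1.0)


def cluster_annotations(
    annos: AnnotationSet,
    damping: float = 0.9,
    max_iter: int = 400,
    convergence_iter: int = 25,
    partition_radius: float | None = 6.0,
    fallback_radius: float = 3.0,
    preference: float | str | None = None,
) -> list[Cluster]:
    """Cluster clicks by affinity propagation (no preset cluster count).

    Similarity is negative squared Euclidean distance.  For scalability
    and determinism the clicks are first partitioned into spatial
    connected components at ``partition_radius`` (single linkage) and
    affinity propagation runs per component;
    ``partition_radius=None`` clusters all clicks in one pass.  The
    default exemplar preference is the click-count-scaled rule of
    :func:`_component_preference`; pass ``preference='median'`` for the
    conventional median-similarity default or a float for a fixed
    value.  A non-converged component falls back to single-linkage
    clustering at ``fallback_radius`` with a logged warning.
    """
    if len(annos) == 0:
        raise ValueError("annotation set is empty")
    coords = annos.coords()
    workers = annos.df["worker_id"].to_numpy()
    n = len(coords)
    if n == 1:
        return [Cluster("c0000", coords.copy(), [str(workers[0])])]

    if partition_radius is None:
        components = np.zeros(n, dtype=int)
    else:
        components = _single_linkage_groups(coords, partition_radius)

    clusters: list[Cluster] = []
    for comp in np.unique(components):
        idx = np.flatnonzero(components == comp)
        pts = coords[idx]
        if len(pts) == 1:
            labels = np.zeros(1, dtype=int)
        else:
            if preference is None:
                pref = _component_preference(pts)
            elif preference == "median":
                pref = None  # sklearn computes the median similarity itself
            else:
                pref = float(preference)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ap = AffinityPropagation(
                    damping=damping,
                    max_iter=max_iter,
                    convergence_iter=convergence_iter,
                    preference=pref,
                    affinity="euclidean",  # sklearn uses -||a-b||^2
                    random_state=0,
                ).fit(pts)
            labels = ap.labels_
            if len(ap.cluster_centers_indices_) == 0 or np.any(labels < 0):
                logger.warning(
                    "affinity propagation did not converge on a %d-click component; "
                    "falling back to single linkage at %.1f px",
                    len(pts),
                    fallback_radius,
                )
                labels = _single_linkage_groups(pts, fallback_radius)
        for lab in np.unique(labels):
            m = idx[labels == lab]
            clusters.append(
                Cluster(
                    cluster_id=f"c{len(clusters):04d}",
                    members=coords[m].copy(),
                    worker_ids=[str(w) for w in workers[m]],
                )
            )
    return clusters


def _kmeans_1d_two(values: np.ndarray) -> tuple[float, float]:
    """Exact 1-D 2-means: best split point by exhaustive scan.

    In one dimension the 2-means optimum is a split of the sorted
    values, so it can be found exactly (and deterministically) by
    scanning every split and minimising the summed within-group
    variance.  Lloyd iterations from heuristic seeds can stick in a
    poor local optimum when the size distribution has high outliers
    (e.g. a few clumped clusters above the main mode), which would
    misplace the threshold.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    csum = np.cumsum(v)
    csq = np.cumsum(v**2)
    best = (np.inf, v[0], v[-1])
    for k in range(1, n):  # low group = v[:k], high group = v[k:]
        lo_mean = csum[k - 1] / k
        hi_mean = (csum[-1] - csum[k - 1]) / (n - k)
        ss = (
            csq[k - 1]
            - k * lo_mean**2
            + (csq[-1] - csq[k - 1])
            - (n - k) * hi_mean**2
        )
        if ss < best[0] - 1e-12:
            best = (ss, lo_mean, hi_mean)
    return float(best[1]), float(best[2])


def size_threshold(
    clusters: list[Cluster], bimodality_ratio: float = 0.5
) -> tuple[list[Cluster], list[Cluster], float]:
    """Remove low-support clusters via a 1-D 2-means split of sizes.

    Cluster sizes are typically bimodal: well-supported true spots and a
    low-count mode of stray clicks.  The threshold is the midpoint of
    the two converged centers; clusters at or above it are kept.  With
    fewer than two distinct sizes everything is kept, and the removal
    only fires when the low center falls below ``bimodality_ratio``
    times the high center — a genuinely unimodal size distribution
    (e.g. all clusters well supported, a few clumps above) must not
    lose its main mode to a spurious split.
    """
    sizes = np.array([c.n_annotations for c in clusters], dtype=float)
    if len(clusters) < 2 or len(np.unique(sizes)) < 2:
        return list(clusters), [], float(sizes.min()) if len(sizes) else 0.0
    lo, hi = _kmeans_1d_two(sizes)
    if lo >= bimodality_ratio * hi:
        return list(clusters), [], float(sizes.min())
    threshold = (lo + hi) / 2.0
    kept = [c for c in clusters if c.n_annotations >= threshold]
    removed = [c for c in clusters if c.n_annotations < threshold]
    return kept, removed, threshold


def detect_clumpy(
    clusters: list[Cluster], n_bins: int = 10
) -> tuple[list[Cluster], float]:
    """Flag clusters whose multi-click fraction sits past the histogram's
    steepest increase beyond the main mode.

    The multi-click fractions are histogrammed over [0, 1]; scanning
    right of the modal bin, the bin with the largest positive count
    increase marks the clump tail; its left edge is the threshold and
    clusters with ``multi_frac >=`` it are flagged.  No increase beyond
    the mode means no clumps.
    """
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    if not clusters:
        return [], 1.0
    fracs = np.array([c.multi_frac for c in clusters])
    counts, edges = np.histogram(fracs, bins=n_bins, range=(0.0, 1.0))
    mode = int(np.argmax(counts))
    best_rise, best_bin = 0, None
    for b in range(mode + 1, n_bins):
        rise = counts[b] - counts[b - 1]
        if rise > best_rise:
            best_rise, best_bin = rise, b
    if best_bin is None:
        return [], 1.0
    threshold = float(edges[best_bin])
    flagged = [c for c in clusters if c.multi_frac >= threshold]
    return flagged, threshold


def _kmeans_2d(points: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Deterministic 2-D k-means with farthest-point seeding; returns labels."""
    centers = [points[np.argmax(((points - points.mean(axis=0)) ** 2).sum(axis=1))]]
    while len(centers) < k:
        d = np.min(cdist(points, np.array(centers), "sqeuclidean"), axis=1)
        centers.append(points[int(np.argmax(d))])
    centers = np.array(centers, dtype=float)
    labels = np.zeros(len(points), dtype=int)
    for _ in range(max_iter):
        labels_new = np.argmin(cdist(points, centers, "sqeuclidean"), axis=1)
        if np.array_equal(labels_new, labels) and _ > 0:
            break
        labels = labels_new
        for j in range(k):
            if np.any(labels == j):
                centers[j] = points[labels == j].mean(axis=0)
    return labels


def declump(cluster: Cluster, k: int = 2) -> list[Cluster]:
    """Split a clumpy cluster into ``k`` children by 2-D k-means.

    Children inherit the parent's members partitioned by the k-means
    labels; a cluster with fewer members than ``k`` is returned
    unchanged with a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if cluster.n_annotations < k:
        logger.warning(
            "cluster %s has %d members < k=%d; not declumped",
            cluster.cluster_id,
            cluster.n_annotations,
            k,
        )
        return [cluster]
    labels = _kmeans_2d(cluster.members, k)
    children = []
    for j in np.unique(labels):
        m = labels == j
        children.append(
            Cluster(
                cluster_id=f"{cluster.cluster_id}.{j}",
                members=cluster.members[m],
                worker_ids=[w for w, keep in zip(cluster.worker_ids, m) if keep],
            )
        )
    return children


@dataclass
class QCReport:
    """Per-stage thresholds and counts from one QC run."""

    n_annotations: int = 0
    n_clusters: int = 0
    size_threshold: float = 0.0
    n_removed: int = 0
    clump_threshold_frac: float = 1.0
    n_flagged_clumpy: int = 0
    n_declumped_children: int = 0
    n_consensus: int = 0
    stages: dict = field(default_factory=dict)


def run_qc(
    annos: AnnotationSet, options: QCOptions | None = None
) -> tuple[list[ConsensusPoint], QCReport]:
    """Full QC pipeline: cluster -> size-threshold -> clump-detect -> declump.

    False-positive removal runs before declumping (declumping afterwards
    preserves recall on the kept clusters).  Consensus points are the
    centroids of unflagged kept clusters plus the centroids of declumped
    children.
    """
    opts = options or QCOptions()
    clusters = cluster_annotations(
        annos,
        damping=opts.damping,
        max_iter=opts.max_iter,
        partition_radius=opts.partition_radius,
        fallback_radius=opts.fallback_radius,
    )
    kept, removed, size_thr = size_threshold(clusters)
    flagged, clump_thr = detect_clumpy(kept, n_bins=opts.n_bins)
    flagged_ids = {c.cluster_id for c in flagged}
    consensus: list[ConsensusPoint] = []
    n_children = 0
    for c in kept:
        if c.cluster_id in flagged_ids:
            for child in declump(c, opts.declump_k):
                x, y = child.centroid
                consensus.append(ConsensusPoint(x, y, child.n_annotations, "declumped"))
                n_children += 1
        else:
            x, y = c.centroid
            consensus.append(ConsensusPoint(x, y, c.n_annotations, "retained"))
    report = QCReport(
        n_annotations=len(annos),
        n_clusters=len(clusters),
        size_threshold=size_thr,
        n_removed=len(removed),
        clump_threshold_frac=clump_thr,
        n_flagged_clumpy=len(flagged),
        n_declumped_children=n_children,
        n_consensus=len(consensus),
        stages={
            "clusters": len(clusters),
            "kept_after_size": len(kept),
            "removed_by_size": len(removed),
            "flagged_clumpy": len(flagged),
            "declumped_children": n_children,
            "consensus": len(consensus),
        },
    )
    return consensus, report


def qc_stages(
    annos: AnnotationSet, options: QCOptions | None = None
) -> dict[str, np.ndarray]:
    """Consensus point sets after each QC stage, for before/after studies.

    Returns (n, 2) arrays keyed ``raw`` (all cluster centroids),
    ``size_thresholded`` (kept centroids) and ``final`` (after clump
    routing and declumping).
    """
    opts = options or QCOptions()
    clusters = cluster_annotations(
        annos,
        damping=opts.damping,
        max_iter=opts.max_iter,
        partition_radius=opts.partition_radius,
        fallback_radius=opts.fallback_radius,
    )
    kept, _removed, _ = size_threshold(clusters)
    flagged, _ = detect_clumpy(kept, n_bins=opts.n_bins)
    flagged_ids = {c.cluster_id for c in flagged}
    final = []
    for c in kept:
        if c.cluster_id in flagged_ids:
            final.extend(child.centroid for child in declump(c, opts.declump_k))
        else:
            final.append(c.centroid)
    return {
        "raw": np.array([c.centroid for c in clusters]).reshape(-1, 2),
        "size_thresholded": np.array([c.centroid for c in kept]).reshape(-1, 2),
        "final": np.array(final).reshape(-1, 2),
    }


def qc_confusion(
    clusters: list[Cluster],
    removed: list[Cluster],
    truth,
    radius: float = 4.0,
) -> tuple[float, float]:
    """Sensitivity/specificity of a QC removal decision against truth.

    A cluster is *correct* when its centroid claims an unclaimed true
    spot within ``radius`` (greedy nearest assignment).  Sensitivity is
    the fraction of incorrect clusters that were removed; specificity
    the fraction of correct clusters that were kept.  With no incorrect
    (or no correct) clusters the corresponding rate is reported as 1.0
    by convention.
    """
    truth_pts = spot_coords(truth)
    removed_ids = {c.cluster_id for c in removed}
    centroids = np.array([c.centroid for c in clusters])
    pairs = []
    for i, c in enumerate(centroids):
        d = np.hypot(*(truth_pts - c).T) if len(truth_pts) else np.array([])
        for j in np.flatnonzero(d <= radius):
            pairs.append((float(d[j]), i, j))
    pairs.sort()
    claimed_t: set[int] = set()
    correct: set[int] = set()
    for _, i, j in pairs:
        if i in correct or j in claimed_t:
            continue
        correct.add(i)
        claimed_t.add(j)
    n_correct = len(correct)
    n_incorrect = len(clusters) - n_correct
    removed_incorrect = sum(
        1 for i, c in enumerate(clusters) if i not in correct and c.cluster_id in removed_ids
    )
    kept_correct = sum(
        1 for i, c in enumerate(clusters) if i in correct and c.cluster_id not in removed_ids
    )
    sensitivity = removed_incorrect / n_incorrect if n_incorrect else 1.0
    specificity = kept_correct / n_correct if n_correct else 1.0
    return sensitivity, specificity
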