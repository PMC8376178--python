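"""Image preparation for annotation: filtering, first-pass detection,
crowded-region handling and recursive subdivision into annotatable crops.

Raw fluorescence images are rarely suitable for point annotation as-is:
spots sit on uneven background and can be too dense for a human to click
individually.  The pipeline here (1) enhances spots with a Gaussian
high-pass, a Laplacian and a maximum z-projection, (2) finds spots with a
multi-scale Laplacian-of-Gaussian detector, (3) locates crowded regions,
and (4) recursively crops/upscales until every sub-image satisfies
density guidelines, with exact coordinate mapping back to the parent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import BoundaryError
from .records import SpotRecord, spot_coords


@dataclass
class Guidelines:
    """Annotatability targets for a displayed sub-image.

    Spots should have SNR >= ``min_snr`` and mean spacing in the
    ``[target_nnd_lo, target_nnd_hi]`` pixel range; no displayed spot
    pair should be closer than ``min_display_nnd_frac`` of the displayed
    width (the click marker radius obscures closer neighbors); at most
    ``max_spots_per_crop`` spots per displayed image.
    """

    min_snr: float = 10.0
    target_nnd_lo: float = 12.0
    target_nnd_hi: float = 15.0
    min_display_nnd_frac: float = 0.04
    max_spots_per_crop: int = 100
    max_depth: int = 4

    def __post_init__(self) -> None:
        if self.target_nnd_lo > self.target_nnd_hi:
            raise ValueError("target_nnd_lo must be <= target_nnd_hi")
        if not 0.0 < self.min_display_nnd_frac < 1.0:
            raise ValueError("min_display_nnd_frac must be in (0, 1)")


@dataclass
class CropSpec:
    """A rectangular sub-image with provenance for exact round trips.

    ``(x0, y0)`` is the crop's top-left corner in the parent frame;
    ``scale`` is displayed pixels per parent pixel at the annotation
    interface.  ``flag`` is '' for compliant leaves, 'saturated' when the
    guidelines cannot be met even at max depth.
    """

    crop_id: str
    parent_id: str
    x0: int
    y0: int
    width: int
    height: int
    scale: float = 1.0
    depth: int = 0
    flag: str = ""

    def contains_parent_point(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x0 + self.width and self.y0 <= y < self.y0 + self.height


def preprocess_stack(stack, highpass_sigma: float = 4.5) -> np.ndarray:
    """High-pass, Laplacian-enhance and max-project a z-stack.

    Per plane: subtract a Gaussian blur (high-pass), apply a negated
    Laplacian (bright blobs give positive peaks), rectify negatives to
    zero; then take the pixel-wise maximum across planes.  A 2-D array is
    treated as a single-plane stack.
    """
    if highpass_sigma <= 0:
        raise ValueError("highpass_sigma must be positive")
    arr = np.asarray(stack, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise ValueError("stack must contain at least one 2-D plane")
    out = None
    for plane in arr:
        hp = plane - ndimage.gaussian_filter(plane, highpass_sigma)
        lap = -ndimage.laplace(hp)
        lap = np.clip(lap, 0.0, None)
        out = lap if out is None else np.maximum(out, lap)
    return out


def log_response_stack(image: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """Scale-normalised LoG responses, one plane per sigma.

    Response is ``-sigma^2 * gaussian_laplace`` so bright blobs of width
    ~sigma give positive peaks of comparable height across scales.
    """
    image = np.asarray(image, dtype=float)
    return np.stack([-s**2 * ndimage.gaussian_laplace(image, s) for s in sigmas])


def sigma_grid(sigma_min: float, sigma_max: float, n_scales: int) -> np.ndarray:
    if not 0 < sigma_min <= sigma_max:
        raise ValueError("need 0 < sigma_min <= sigma_max")
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")
    return np.geomspace(sigma_min, sigma_max, n_scales)


def detect_from_stack(
    responses: np.ndarray,
    sigmas: np.ndarray,
    threshold: float,
    max_candidates: int = 10_000,
) -> list[SpotRecord]:
    """Local maxima of a precomputed LoG scale-space above ``threshold``.

    A voxel is a detection when it attains the maximum of its 3x3x3
    scale-space neighborhood and exceeds the threshold.  Overlapping
    detections (center distance < sqrt(2) x sigma of the larger) are
    pruned keeping the stronger response.  Because suppression flows
    only from stronger to weaker candidates, detections at a higher
    threshold are exactly the amplitude-filtered subset of detections
    at a lower one.  ``max_candidates`` bounds the pruning work at very
    low thresholds by keeping only the strongest candidates.
    """
    if responses.size == 0:
        return []
    footprint = np.ones((3, 3, 3), dtype=bool)
    local_max = ndimage.maximum_filter(responses, footprint=footprint, mode="nearest")
    mask = (responses >= local_max) & (responses > threshold)
    ks, ys, xs = np.nonzero(mask)
    if len(ks) == 0:
        return []
    vals = responses[ks, ys, xs]
    order = np.argsort(-vals, kind="stable")
    if len(order) > max_candidates:
        order = order[:max_candidates]
    pts = np.column_stack([xs, ys]).astype(float)[order]
    sig = np.asarray(sigmas, dtype=float)[ks][order]
    val = vals[order]
    # greedy strongest-first suppression of overlapping weaker detections
    tree = cKDTree(pts)
    sqrt2 = math.sqrt(2.0)
    max_sigma = float(sig.max())
    suppressed = np.zeros(len(pts), dtype=bool)
    kept_idx = []
    for i in range(len(pts)):
        if suppressed[i]:
            continue
        kept_idx.append(i)
        for j in tree.query_ball_point(pts[i], sqrt2 * max(sig[i], max_sigma)):
            if j > i and not suppressed[j]:
                if np.hypot(*(pts[i] - pts[j])) < sqrt2 * max(sig[i], sig[j]):
                    suppressed[j] = True
    kept = sorted(
        ((pts[i][0], pts[i][1], sig[i], val[i]) for i in kept_idx),
        key=lambda t: (t[1], t[0]),
    )
    return [
        SpotRecord(x=float(x), y=float(y), sigma=float(s), amplitude=float(v))
        for x, y, s, v in kept
    ]


def log_detect(
    image: np.ndarray,
    sigma_min: float = 1.0,
    sigma_max: float = 4.0,
    n_scales: int = 7,
    threshold: float = 0.0,
) -> list[SpotRecord]:
    """Multi-scale Laplacian-of-Gaussian blob detection.

    Each returned SpotRecord carries the detecting sigma and the LoG
    response as its amplitude.  Raising the threshold can only remove
    detections (monotone).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    sigmas = sigma_grid(sigma_min, sigma_max, n_scales)
    responses = log_response_stack(image, sigmas)
    return detect_from_stack(responses, sigmas, threshold)


def _single_linkage_groups(points: np.ndarray, radius: float) -> np.ndarray:
    """Component label per point under the 'within radius' relation."""
    n = len(points)
    if n == 0:
        return np.empty(0, dtype=int)
    pairs = list(cKDTree(points).query_pairs(radius))
    if not pairs:
        return np.arange(n)
    rows = [p[0] for p in pairs] + [p[1] for p in pairs]
    cols = [p[1] for p in pairs] + [p[0] for p in pairs]
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    return labels


def find_crowded_regions(
    spots, guidelines: Guidelines, image_width: int, image_height: int
) -> list[tuple[int, int, int, int]]:
    """Bounding boxes (x0, y0, x1, y1) around groups of crowded spots.

    A spot is crowded when its nearest neighbor is closer than
    ``target_nnd_hi``; crowded spots are grouped by single linkage at
    that radius and each group's axis-aligned box is padded by
    ``2 x target_nnd_hi`` and clipped to the image.
    """
    pts = spot_coords(spots)
    if len(pts) < 2:
        return []
    d, _ = cKDTree(pts).query(pts, k=2)
    crowded = pts[d[:, 1] < guidelines.target_nnd_hi]
    if len(crowded) == 0:
        return []
    labels = _single_linkage_groups(crowded, guidelines.target_nnd_hi)
    pad = 2.0 * guidelines.target_nnd_hi
    boxes = []
    for lab in np.unique(labels):
        grp = crowded[labels == lab]
        x0 = max(0, int(math.floor(grp[:, 0].min() - pad)))
        y0 = max(0, int(math.floor(grp[:, 1].min() - pad)))
        x1 = min(image_width, int(math.ceil(grp[:, 0].max() + pad)) + 1)
        y1 = min(image_height, int(math.ceil(grp[:, 1].max() + pad)) + 1)
        boxes.append((x0, y0, x1, y1))
    boxes.sort()
    return boxes


def _region_compliant(pts: np.ndarray, width: int, guidelines: Guidelines) -> bool:
    """Does a region meet the count and displayed-spacing guidelines?

    After upscaling a crop of width w to the display width D, a parent
    spacing of d pixels appears as d*(D/w) displayed pixels; requiring
    that to exceed ``min_display_nnd_frac * D`` reduces to
    ``d >= min_display_nnd_frac * w`` independent of D.
    """
    if len(pts) > guidelines.max_spots_per_crop:
        return False
    if len(pts) >= 2:
        dmin, _ = cKDTree(pts).query(pts, k=2)
        if dmin[:, 1].min() < guidelines.min_display_nnd_frac * width:
            return False
    return True


def recursive_subdivide(
    image: np.ndarray,
    spots,
    guidelines: Guidelines | None = None,
    display_width: int = 512,
    parent_id: str = "img0",
) -> list[tuple[CropSpec, np.ndarray]]:
    """Crop the image until every leaf is annotatable, or flag it saturated.

    A region is split into 2x2 quadrants of its spots' padded bounding
    box (10% overlap margin between quadrants) whenever it exceeds the
    per-crop spot budget or its minimum displayed nearest-neighbor
    spacing falls below the marker-radius guideline.  Recursion stops at
    ``guidelines.max_depth``; non-compliant leaves at the depth cap are
    flagged ``saturated``.  Returns the leaf crops (the parent itself
    when it is already compliant), each with its pixel data.
    """
    if display_width <= 0:
        raise ValueError("display_width must be positive")
    g = guidelines or Guidelines()
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    pts = spot_coords(spots)

    leaves: list[CropSpec] = []

    def region_spots(x0, y0, x1, y1):
        if len(pts) == 0:
            return pts
        m = (pts[:, 0] >= x0) & (pts[:, 0] < x1) & (pts[:, 1] >= y0) & (pts[:, 1] < y1)
        return pts[m]

    def recurse(x0: int, y0: int, x1: int, y1: int, depth: int) -> None:
        rw, rh = x1 - x0, y1 - y0
        rpts = region_spots(x0, y0, x1, y1)
        compliant = _region_compliant(rpts, rw, g)
        can_split = (
            not compliant
            and depth < g.max_depth
            and min(rw, rh) >= 16
            and len(rpts) >= 2
            # identical coordinates can never be separated by zooming
            and cKDTree(rpts).query(rpts, k=2)[0][:, 1].min() > 0
        )
        if not can_split:
            leaves.append(
                CropSpec(
                    crop_id=f"{parent_id}_d{depth}_{x0}_{y0}",
                    parent_id=parent_id,
                    x0=x0,
                    y0=y0,
                    width=rw,
                    height=rh,
                    scale=max(1.0, display_width / rw),
                    depth=depth,
                    flag="" if compliant else "saturated",
                )
            )
            return
        # split the padded bounding box of this region's spots
        pad = 2.0 * g.target_nnd_hi
        bx0 = max(x0, int(math.floor(rpts[:, 0].min() - pad)))
        by0 = max(y0, int(math.floor(rpts[:, 1].min() - pad)))
        bx1 = min(x1, int(math.ceil(rpts[:, 0].max() + pad)) + 1)
        by1 = min(y1, int(math.ceil(rpts[:, 1].max() + pad)) + 1)
        mx = (bx0 + bx1) // 2
        my = (by0 + by1) // 2
        ox = max(1, int(round(0.05 * (bx1 - bx0))))  # 10% total overlap
        oy = max(1, int(round(0.05 * (by1 - by0))))
        quads = [
            (bx0, by0, min(bx1, mx + ox), min(by1, my + oy)),
            (max(bx0, mx - ox), by0, bx1, min(by1, my + oy)),
            (bx0, max(by0, my - oy), min(bx1, mx + ox), by1),
            (max(bx0, mx - ox), max(by0, my - oy), bx1, by1),
        ]
        for qx0, qy0, qx1, qy1 in quads:
            if qx1 - qx0 >= 1 and qy1 - qy0 >= 1:
                recurse(qx0, qy0, qx1, qy1, depth + 1)

    recurse(0, 0, w, h, 0)
    return [(spec, image[spec.y0 : spec.y0 + spec.height, spec.x0 : spec.x0 + spec.width]) for spec in leaves]


def to_display_coords(crop: CropSpec, points_parent) -> np.ndarray:
    """Map parent-frame points into the crop's displayed coordinates."""
    pts = spot_coords(points_parent)
    return (pts - np.array([crop.x0, crop.y0])) * crop.scale


def map_to_parent(crop: CropSpec, points_displayed) -> np.ndarray:
    """Map displayed-crop click coordinates back to the parent frame.

    Exact inverse of :func:`to_display_coords`:
    ``parent = displayed / scale + (x0, y0)``.
    """
    pts = spot_coords(points_displayed)
    limit_x = crop.width * crop.scale
    limit_y = crop.height * crop.scale
    for x, y in pts:
        if not (-1e-9 <= x <= limit_x and -1e-9 <= y <= limit_y):
            raise BoundaryError(
                f"displayed point ({x}, {y}) outside crop {crop.crop_id} "
                f"({limit_x:.1f}x{limit_y:.1f} displayed px)"
            )
    return pts / crop.scale + np.array([crop.x0, crop.y0])


def reassemble(
    points_by_crop: dict[str, "np.ndarray | list"],
    crops: list[CropSpec],
    dedup_radius: float = 4.0,
) -> np.ndarray:
    """Merge per-crop consensus points back into the parent frame.

    Points are mapped to the parent and single-linkage groups at
    ``dedup_radius`` are collapsed to their mean, repeatedly, until no
    two representatives are closer than the radius (duplicates arise
    from the crops' overlap margins).
    """
    by_id = {c.crop_id: c for c in crops}
    parents = {c.parent_id for c in crops}
    if len(parents) > 1:
        raise ValueError(f"crops span multiple parents: {sorted(parents)}")
    mapped = []
    for crop_id, pts in points_by_crop.items():
        if crop_id not in by_id:
            raise KeyError(f"unknown crop_id {crop_id!r}")
        if len(pts):
            mapped.append(map_to_parent(by_id[crop_id], pts))
    if not mapped:
        return np.empty((0, 2))
    merged = np.vstack(mapped)
    if dedup_radius <= 0:
        return merged
    while len(merged) > 1:
        labels = _single_linkage_groups(merged, dedup_radius)
        if len(np.unique(labels)) == len(merged):
            break
        merged = np.vstack([merged[labels == lab].mean(axis=0) for lab in np.unique(labels)])
    return merged
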