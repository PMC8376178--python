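import math

import numpy as np
import pytest

from crowdspot import (
    CropSpec,
    Guidelines,
    SynthConfig,
    find_crowded_regions,
    log_detect,
    map_to_parent,
    preprocess_stack,
    reassemble,
    recursive_subdivide,
    simulate_image,
)
from crowdspot.errors import BoundaryError
from crowdspot.imageprep import (
    detect_from_stack,
    log_response_stack,
    sigma_grid,
    to_display_coords,
)
from crowdspot.records import spot_coords


def gaussian_blob(shape, x, y, sigma, amplitude=100.0):
    yy, xx = np.indices(shape)
    return amplitude * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))


class TestPreprocessStack:
    def test_constant_plane_gives_zeros(self):
        out = preprocess_stack(np.full((64, 64), 55.0), highpass_sigma=3.0)
        assert np.allclose(out, 0.0)
        assert out.min() >= 0.0

    def test_peak_survives_in_projection(self):
        spot = gaussian_blob((64, 64), 20, 40, 1.5)
        stack = np.stack([spot + 10.0, np.full((64, 64), 10.0)])
        out = preprocess_stack(stack, highpass_sigma=4.0)
        py, px = np.unravel_index(np.argmax(out), out.shape)
        assert abs(px - 20) <= 1 and abs(py - 40) <= 1

    def test_identical_planes_match_single_plane(self):
        plane = gaussian_blob((64, 64), 30, 30, 2.0) + 5.0
        single = preprocess_stack(plane, 4.0)
        triple = preprocess_stack(np.stack([plane] * 3), 4.0)
        assert np.array_equal(single, triple)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            preprocess_stack(np.empty((0, 32, 32)), 3.0)


class TestLogDetect:
    def test_blank_image_empty(self):
        assert log_detect(np.zeros((64, 64)), 1.0, 4.0, 7, 0.1) == []

    def test_single_blob_recovered_with_scale(self):
        img = gaussian_blob((64, 64), 25.0, 33.0, 2.0)
        det = log_detect(img, 1.0, 4.0, 9, threshold=5.0)
        assert len(det) == 1
        assert math.hypot(det[0].x - 25, det[0].y - 33) <= 1.0
        grid = sigma_grid(1.0, 4.0, 9)
        step = grid[1] / grid[0]
        assert 2.0 / step <= det[0].sigma <= 2.0 * step

    def test_higher_threshold_detects_subset(self):
        img, _ = simulate_image(SynthConfig(n_spots=40, seed=3), 256, 256)
        low = {(d.x, d.y) for d in log_detect(img, 1.0, 3.0, 5, threshold=10.0)}
        high = {(d.x, d.y) for d in log_detect(img, 1.0, 3.0, 5, threshold=40.0)}
        assert high <= low

    def test_matches_dense_scan_oracle(self):
        """Scale-space maxima must agree with an independent brute-force
        scan over every pixel and scale on small instances."""
        rng = np.random.default_rng(0)
        for trial in range(5):
            img = rng.normal(10.0, 1.0, (64, 64))
            for _ in range(4):
                x, y = rng.uniform(8, 56, 2)
                img += gaussian_blob((64, 64), x, y, rng.uniform(1.0, 3.0), 50.0)
            sigmas = sigma_grid(1.0, 3.5, 6)
            responses = log_response_stack(img, sigmas)
            threshold = 5.0
            # oracle: explicit neighborhood check at every voxel
            n_s, h, w = responses.shape
            cands = []
            for k in range(n_s):
                for yy in range(h):
                    for xx in range(w):
                        v = responses[k, yy, xx]
                        if v <= threshold:
                            continue
                        neigh = responses[
                            max(0, k - 1) : k + 2,
                            max(0, yy - 1) : yy + 2,
                            max(0, xx - 1) : xx + 2,
                        ]
                        if v >= neigh.max():
                            cands.append((v, xx, yy, sigmas[k]))
            cands.sort(key=lambda t: -t[0])
            kept = []
            for v, xx, yy, s in cands:
                if all(
                    math.hypot(xx - ox, yy - oy) >= math.sqrt(2) * max(s, osig)
                    for _, ox, oy, osig in kept
                ):
                    kept.append((v, xx, yy, s))
            expected = {(x, y, round(s, 9)) for _, x, y, s in kept}
            got = {
                (d.x, d.y, round(d.sigma, 9))
                for d in detect_from_stack(responses, sigmas, threshold)
            }
            assert got == expected


class TestFindCrowdedRegions:
    def test_sparse_spots_no_regions(self):
        pts = [(20.0, 20.0), (100.0, 100.0), (200.0, 50.0)]
        assert find_crowded_regions(pts, Guidelines(), 256, 256) == []

    def test_close_pair_bound_with_padding(self):
        g = Guidelines(target_nnd_hi=15.0)
        boxes = find_crowded_regions([(100.0, 100.0), (105.0, 100.0)], g, 256, 256)
        assert len(boxes) == 1
        x0, y0, x1, y1 = boxes[0]
        assert x0 <= 100 - 30 + 1 and x1 >= 105 + 30
        assert y0 <= 100 - 30 + 1 and y1 >= 100 + 30

    def test_distant_pairs_give_disjoint_boxes(self):
        pts = [(30.0, 30.0), (35.0, 30.0), (530.0, 530.0), (535.0, 530.0)]
        boxes = find_crowded_regions(pts, Guidelines(), 600, 600)
        assert len(boxes) == 2


class TestRecursiveSubdivide:
    def test_sparse_image_single_crop(self, snr15_image):
        image, truth = snr15_image
        crops = recursive_subdivide(image, truth, Guidelines(), 512)
        assert len(crops) == 1
        spec, pixels = crops[0]
        assert (spec.depth, spec.x0, spec.y0) == (0, 0, 0)
        assert pixels.shape == image.shape
        assert spec.flag == ""

    def test_crowded_corner_subdivided_and_leaves_compliant(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(10, 110, (300, 2))
        img = np.zeros((512, 512))
        g = Guidelines()
        crops = recursive_subdivide(img, pts, g, 512)
        assert any(spec.depth >= 1 for spec, _ in crops)
        for spec, _ in crops:
            if spec.flag == "saturated":
                continue
            inside = pts[
                (pts[:, 0] >= spec.x0)
                & (pts[:, 0] < spec.x0 + spec.width)
                & (pts[:, 1] >= spec.y0)
                & (pts[:, 1] < spec.y0 + spec.height)
            ]
            assert len(inside) <= g.max_spots_per_crop
            if len(inside) >= 2:
                d = np.hypot(
                    inside[:, None, 0] - inside[None, :, 0],
                    inside[:, None, 1] - inside[None, :, 1],
                )
                np.fill_diagonal(d, np.inf)
                assert d.min() >= g.min_display_nnd_frac * spec.width

    def test_depth_cap_returns_parent_only(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(10, 50, (200, 2))
        crops = recursive_subdivide(np.zeros((256, 256)), pts, Guidelines(max_depth=0), 512)
        assert len(crops) == 1
        assert crops[0][0].flag == "saturated"

    def test_depth_and_leaf_count_bounds(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 256, (400, 2))
        g = Guidelines(max_depth=3)
        crops = recursive_subdivide(np.zeros((256, 256)), pts, g, 512)
        assert all(spec.depth <= 3 for spec, _ in crops)
        assert len(crops) <= 4**3 + 1


class TestCoordinateMapping:
    def test_known_arithmetic(self):
        crop = CropSpec("c", "p", 100, 200, 50, 50, scale=4.0)
        out = map_to_parent(crop, [(40.0, 80.0)])
        assert out.tolist() == [[110.0, 220.0]]

    def test_round_trip_is_identity(self):
        crop = CropSpec("c", "p", 37, 91, 64, 64, scale=3.5)
        pts = np.array([[40.0, 95.0], [95.5, 140.25], [68.25, 154.0]])
        disp = to_display_coords(crop, pts)
        back = map_to_parent(crop, disp)
        assert np.allclose(back, pts, atol=1e-12)

    def test_unit_crop_identity(self):
        crop = CropSpec("c", "p", 0, 0, 64, 64, scale=1.0)
        pts = [(10.0, 20.0)]
        assert map_to_parent(crop, pts).tolist() == [[10.0, 20.0]]

    def test_out_of_bounds_named_in_error(self):
        crop = CropSpec("c", "p", 0, 0, 10, 10, scale=1.0)
        with pytest.raises(BoundaryError, match="99"):
            map_to_parent(crop, [(99.0, 5.0)])


class TestReassemble:
    def test_single_crop_points_unchanged(self):
        crop = CropSpec("c0", "p", 0, 0, 100, 100, scale=1.0)
        pts = np.array([[10.0, 10.0], [50.0, 60.0]])
        out = reassemble({"c0": pts}, [crop], dedup_radius=4.0)
        assert sorted(out.tolist()) == sorted(pts.tolist())

    def test_duplicate_from_overlap_merged_to_midpoint(self):
        a = CropSpec("a", "p", 0, 0, 60, 60, scale=1.0)
        b = CropSpec("b", "p", 40, 0, 60, 60, scale=1.0)
        out = reassemble({"a": [(50.0, 30.0)], "b": [(10.5, 30.0)]}, [a, b], 4.0)
        assert out.shape == (1, 2)
        assert out[0] == pytest.approx([50.25, 30.0])

    def test_distinct_spots_retained(self):
        crop = CropSpec("c0", "p", 0, 0, 100, 100, scale=1.0)
        out = reassemble({"c0": [(10.0, 10.0), (60.0, 10.0)]}, [crop], 4.0)
        assert len(out) == 2

    def test_unknown_crop_id_raises(self):
        crop = CropSpec("c0", "p", 0, 0, 100, 100, scale=1.0)
        with pytest.raises(KeyError):
            reassemble({"nope": [(1.0, 1.0)]}, [crop], 4.0)


def test_crop_reassemble_round_trip_recovers_truth():
    """Subdividing, mapping truth into every covering crop, and
    reassembling recovers each original point once."""
    for seed in range(5):
        cfg = SynthConfig(n_spots=150, min_nnd=6.0, sigma=1.5, seed=seed)
        image, truth = simulate_image(cfg, 384, 384)
        crops = recursive_subdivide(image, truth, Guidelines(), 512)
        pts = spot_coords(truth)
        per = {}
        for spec, _ in crops:
            inside = pts[
                (pts[:, 0] >= spec.x0)
                & (pts[:, 0] < spec.x0 + spec.width)
                & (pts[:, 1] >= spec.y0)
                & (pts[:, 1] < spec.y0 + spec.height)
            ]
            if len(inside):
                per[spec.crop_id] = to_display_coords(spec, inside)
        rec = reassemble(per, [c for c, _ in crops], dedup_radius=2.0)
        assert len(rec) == len(pts)
        d = np.hypot(rec[:, None, 0] - pts[None, :, 0], rec[:, None, 1] - pts[None, :, 1])
        assert d.min(axis=1).max() <= 2.0
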