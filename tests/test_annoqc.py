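import numpy as np
import pandas as pd
import pytest

from crowdspot import (
    AnnotationSet,
    cluster_annotations,
    declump,
    detect_clumpy,
    qc_confusion,
    run_qc,
    size_threshold,
)
from crowdspot.annoqc import Cluster, _kmeans_1d_two, qc_stages
from crowdspot.records import ANNOTATION_COLUMNS, spot_coords


def annoset(points, workers=None, image_id="img0"):
    points = np.asarray(points, dtype=float)
    if workers is None:
        workers = [f"w{i}" for i in range(len(points))]
    df = pd.DataFrame(
        {
            "worker_id": workers,
            "image_id": image_id,
            "x": points[:, 0],
            "y": points[:, 1],
        },
        columns=ANNOTATION_COLUMNS,
    )
    return AnnotationSet(image_id=image_id, df=df)


def make_cluster(cid, points, workers):
    return Cluster(cid, np.asarray(points, dtype=float), list(workers))


class TestClusterAnnotations:
    def test_single_annotation_single_cluster(self):
        cl = cluster_annotations(annoset([(10.0, 20.0)]))
        assert len(cl) == 1
        assert cl[0].centroid == (10.0, 20.0)

    def test_three_separated_groups(self):
        rng = np.random.default_rng(0)
        centers = np.array([[30.0, 30.0], [120.0, 40.0], [60.0, 150.0]])
        pts = np.vstack([c + rng.normal(0, 0.5, (10, 2)) for c in centers])
        workers = [f"w{i % 10}" for i in range(30)]
        cl = cluster_annotations(annoset(pts, workers))
        assert len(cl) == 3
        got = np.array(sorted(c.centroid for c in cl))
        want = np.array(sorted(map(tuple, centers)))
        assert np.all(np.hypot(*(got - want).T) <= 1.0)

    def test_partition_conservation(self, small_crowd):
        annos, _ = small_crowd
        cl = cluster_annotations(annos)
        assert sum(c.n_annotations for c in cl) == len(annos)

    def test_empty_set_rejected(self):
        df = pd.DataFrame(columns=ANNOTATION_COLUMNS)
        with pytest.raises(ValueError):
            cluster_annotations(AnnotationSet("img0", df))

    def test_deterministic(self, small_crowd):
        annos, _ = small_crowd
        a = cluster_annotations(annos)
        b = cluster_annotations(annos)
        assert [c.centroid for c in a] == [c.centroid for c in b]


class TestSizeThreshold:
    def test_bimodal_sizes_split_as_expected(self):
        clusters = [
            make_cluster(f"c{i}", np.zeros((n, 2)), [f"w{j}" for j in range(n)])
            for i, n in enumerate([25, 24, 23, 2, 1])
        ]
        kept, removed, thr = size_threshold(clusters)
        assert sorted(c.n_annotations for c in removed) == [1, 2]
        assert sorted(c.n_annotations for c in kept) == [23, 24, 25]
        assert 2 < thr <= 23

    def test_all_equal_sizes_all_kept(self):
        clusters = [
            make_cluster(f"c{i}", np.zeros((5, 2)), [f"w{j}" for j in range(5)])
            for i in range(4)
        ]
        kept, removed, _ = size_threshold(clusters)
        assert len(kept) == 4 and removed == []

    def test_single_cluster_kept(self):
        c = make_cluster("c0", np.zeros((3, 2)), ["a", "b", "c"])
        kept, removed, _ = size_threshold([c])
        assert kept == [c] and removed == []

    def test_removal_is_monotone(self, small_crowd):
        annos, _ = small_crowd
        kept, removed, _ = size_threshold(cluster_annotations(annos))
        if kept and removed:
            assert min(c.n_annotations for c in kept) >= max(
                c.n_annotations for c in removed
            )

    def test_split_is_globally_optimal(self):
        """The 1-D 2-means split must match an independent multi-start
        Lloyd solver on awkward size distributions."""
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(1)
        for _ in range(20):
            sizes = np.concatenate(
                [
                    rng.integers(1, 4, rng.integers(2, 10)),
                    rng.integers(20, 30, rng.integers(2, 30)),
                    rng.integers(45, 60, rng.integers(0, 4)),
                ]
            ).astype(float)
            lo, hi = _kmeans_1d_two(sizes)
            km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(sizes.reshape(-1, 1))
            ref = sorted(km.cluster_centers_.ravel())
            assert lo == pytest.approx(ref[0])
            assert hi == pytest.approx(ref[1])


class TestDetectClumpy:
    def test_no_multi_clickers_nothing_flagged(self):
        clusters = [
            make_cluster(f"c{i}", np.zeros((4, 2)), [f"w{j}" for j in range(4)])
            for i in range(10)
        ]
        flagged, _ = detect_clumpy(clusters)
        assert flagged == []

    def test_hand_evaluated_histogram_scan(self):
        """Fractions {0.0 x18, 0.05, 0.5, 0.55, 0.6}: the steepest rise
        beyond the mode is into the [0.5, 0.6) bin, so the three
        clusters with fraction >= 0.5 are flagged."""

        def with_frac(cid, frac, n_workers=20):
            workers = [f"w{j}" for j in range(n_workers)]
            extra = [f"w{j}" for j in range(int(round(frac * n_workers)))]
            pts = np.zeros((n_workers + len(extra), 2))
            return make_cluster(cid, pts, workers + extra)

        clusters = [with_frac(f"a{i}", 0.0) for i in range(18)]
        clusters.append(with_frac("b", 0.05))
        clusters += [with_frac("c", 0.5), with_frac("d", 0.55), with_frac("e", 0.6)]
        flagged, thr = detect_clumpy(clusters, n_bins=10)
        assert thr == pytest.approx(0.5)
        assert sorted(c.cluster_id for c in flagged) == ["c", "d", "e"]

    def test_monotone_declining_histogram_unflagged(self):
        fracs = [0.0] * 10 + [0.1] * 6 + [0.2] * 3 + [0.3]
        clusters = []
        for i, f in enumerate(fracs):
            n = 20
            workers = [f"w{j}" for j in range(n)] + [
                f"w{j}" for j in range(int(round(f * n)))
            ]
            clusters.append(make_cluster(f"c{i}", np.zeros((len(workers), 2)), workers))
        flagged, _ = detect_clumpy(clusters, n_bins=10)
        assert flagged == []


class TestDeclump:
    def test_two_tight_groups_split(self):
        rng = np.random.default_rng(2)
        pts = np.vstack(
            [
                rng.normal(0, 0.3, (10, 2)) + [0.0, 0.0],
                rng.normal(0, 0.3, (10, 2)) + [6.0, 0.0],
            ]
        )
        workers = [f"w{i}" for i in range(10)] * 2
        children = declump(make_cluster("c", pts, workers), k=2)
        assert len(children) == 2
        cents = sorted(c.centroid for c in children)
        assert np.hypot(*(np.array(cents[0]) - [0.0, 0.0])) <= 1.0
        assert np.hypot(*(np.array(cents[1]) - [6.0, 0.0])) <= 1.0

    def test_two_points_become_singletons(self):
        children = declump(make_cluster("c", [(0.0, 0.0), (5.0, 0.0)], ["a", "b"]), 2)
        assert sorted(c.centroid for c in children) == [(0.0, 0.0), (5.0, 0.0)]

    def test_membership_conserved(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 10, (17, 2))
        parent = make_cluster("c", pts, [f"w{i}" for i in range(17)])
        children = declump(parent, k=3)
        assert sum(c.n_annotations for c in children) == 17

    def test_too_few_members_returned_unchanged(self):
        parent = make_cluster("c", [(1.0, 1.0)], ["a"])
        assert declump(parent, k=2) == [parent]


class TestRunQc:
    def test_clean_crowd_fixed_point(self):
        """A noiseless 25-worker crowd on 10 separated spots collapses
        to exactly those 10 locations."""
        centers = np.array([[20.0 + 20 * i, 40.0] for i in range(10)])
        pts = np.tile(centers, (25, 1))
        workers = np.repeat([f"w{k}" for k in range(25)], 10)
        consensus, report = run_qc(annoset(pts, list(workers)))
        assert len(consensus) == 10
        got = np.array(sorted((p.x, p.y) for p in consensus))
        assert np.allclose(got, centers[np.argsort(centers[:, 0])])
        assert report.n_removed == 0

    def test_small_false_clusters_removed(self, small_crowd):
        annos, truth = small_crowd
        consensus, report = run_qc(annos)
        pts = np.array([[p.x, p.y] for p in consensus])
        from crowdspot import match_points

        res = match_points(pts, spot_coords(truth), 4.0)
        assert res.precision == 1.0
        assert report.n_removed > 0

    def test_clump_declumped_into_two_spots(self):
        """Two spots 5 px apart annotated by 20 workers who mostly merge
        them but sometimes click both: QC yields two consensus points."""
        rng = np.random.default_rng(4)
        a, b = np.array([50.0, 50.0]), np.array([55.0, 50.0])
        rows, workers = [], []
        for k in range(20):
            if k < 8:  # these workers resolve the pair: two clicks
                rows += [a + rng.normal(0, 0.4, 2), b + rng.normal(0, 0.4, 2)]
                workers += [f"w{k}"] * 2
            else:  # the rest merge it into one midpoint click
                rows.append((a + b) / 2 + rng.normal(0, 0.4, 2))
                workers.append(f"w{k}")
        # plus 12 well-supported ordinary spots so thresholds are sane
        for j in range(12):
            c = np.array([20.0 + 18 * j, 150.0])
            for k in range(20):
                rows.append(c + rng.normal(0, 0.4, 2))
                workers.append(f"w{k}")
        consensus, report = run_qc(annoset(np.array(rows), workers))
        assert report.n_flagged_clumpy >= 1
        declumped = [p for p in consensus if p.origin == "declumped"]
        assert len(declumped) >= 2
        d_a = min(np.hypot(p.x - a[0], p.y - a[1]) for p in declumped)
        d_b = min(np.hypot(p.x - b[0], p.y - b[1]) for p in declumped)
        assert d_a <= 2.0 and d_b <= 2.0

    def test_annotation_conservation(self, small_crowd):
        annos, _ = small_crowd
        consensus, report = run_qc(annos)
        clusters = cluster_annotations(annos)
        kept, removed, _ = size_threshold(clusters)
        assert sum(p.n_support for p in consensus) + sum(
            c.n_annotations for c in removed
        ) == len(annos)

    def test_stage_metrics_shapes(self, small_crowd):
        annos, _ = small_crowd
        stages = qc_stages(annos)
        assert set(stages) == {"raw", "size_thresholded", "final"}
        assert len(stages["raw"]) >= len(stages["size_thresholded"])


class TestQcConfusion:
    def test_all_correct_kept_conventions(self):
        clusters = [make_cluster(f"c{i}", [(float(i * 10), 0.0)], ["w"]) for i in range(3)]
        sens, spec = qc_confusion(clusters, [], [(0.0, 0.0), (10.0, 0.0), (20.0, 0.0)], 4.0)
        assert sens == 1.0 and spec == 1.0

    def test_perfect_separation(self):
        correct = [make_cluster(f"c{i}", [(float(i * 10), 0.0)], ["w"]) for i in range(3)]
        wrong = [make_cluster(f"x{i}", [(200.0 + i, 200.0)], ["w"]) for i in range(2)]
        truth = [(0.0, 0.0), (10.0, 0.0), (20.0, 0.0)]
        sens, spec = qc_confusion(correct + wrong, wrong, truth, 4.0)
        assert sens == 1.0 and spec == 1.0

    def test_one_correct_removed(self):
        correct = [make_cluster(f"c{i}", [(float(i * 10), 0.0)], ["w"]) for i in range(4)]
        truth = [(float(i * 10), 0.0) for i in range(4)]
        sens, spec = qc_confusion(correct, [correct[0]], truth, 4.0)
        assert spec == 0.75
        assert sens == 1.0
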