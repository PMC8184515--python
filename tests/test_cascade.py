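"""Binarization, per-frame clustering, spatiotemporal linking, summaries."""

import numpy as np
import pytest

import cascadefish as cf
from cascadefish.cascade import frame_clusters, link_cascades
from cascadefish.io import RunLog
from cascadefish.preprocess import TraceMatrix

from reference import flood_fill_clusters, link_cascades_reference


def _pixel_traces(values, coords=None, fps=20.0):
    values = np.asarray(values, dtype=float)
    if coords is None:
        coords = [(0, i) for i in range(values.shape[0])]
    return TraceMatrix(
        values=values, unit_kind="pixel", unit_coords=np.asarray(coords, float), fps=fps
    )


def _cluster_sets(clusters):
    return sorted(tuple(sorted(map(tuple, cl))) for cl in clusters)


class TestBinarize:
    def test_silent_traces_never_activate(self):
        roi = np.ones((1, 4), dtype=bool)
        dff = _pixel_traces(np.zeros((4, 100)))
        raster = cf.binarize(dff, roi, log=RunLog())
        assert not raster.active.any()

    def test_spike_crosses_five_sd_threshold(self, rng):
        # explicit-loop oracle: recompute the sample SD and compare per frame
        roi = np.ones((1, 3), dtype=bool)
        traces = rng.normal(0, 0.01, size=(3, 400))
        traces[1, 200] = 0.1  # 10 sigma excursion
        raster = cf.binarize(_pixel_traces(traces), roi, k=5.0)
        for unit in range(3):
            sd = np.sqrt(
                np.sum((traces[unit] - traces[unit].mean()) ** 2) / (400 - 1)
            )
            expected = traces[unit] > 5.0 * sd
            assert np.array_equal(raster.active[:, 0, unit], expected)
        assert raster.active[200, 0, 1]

    def test_nonpositive_k_rejected(self):
        roi = np.ones((1, 2), dtype=bool)
        with pytest.raises(ValueError):
            cf.binarize(_pixel_traces(np.zeros((2, 50))), roi, k=0.0)

    def test_zero_variance_pixel_logged_inactive(self):
        log = RunLog()
        roi = np.ones((1, 2), dtype=bool)
        traces = np.stack([np.full(100, 0.5), np.random.default_rng(0).normal(size=100)])
        raster = cf.binarize(_pixel_traces(traces), roi, log=log)
        assert not raster.active[:, 0, 0].any()
        assert len(log.exclusions) == 1

    def test_raising_k_never_adds_active_pixels(self, rng):
        roi = np.ones((1, 8), dtype=bool)
        traces = rng.normal(0, 0.02, size=(8, 300)) + rng.random((8, 1))
        counts = [
            cf.binarize(_pixel_traces(traces), roi, k=k).active.sum()
            for k in (1.0, 2.0, 3.0, 5.0)
        ]
        assert np.all(np.diff(counts) <= 0)


class TestFrameClusters:
    def test_pairs_below_minimum_discarded(self):
        frame = np.zeros((6, 6), dtype=bool)
        frame[1, 1] = frame[4, 4] = True
        assert frame_clusters(frame, min_pixels=3) == []

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_l_shaped_triple_is_one_cluster(self, connectivity):
        frame = np.zeros((5, 5), dtype=bool)
        frame[1, 1] = frame[2, 1] = frame[2, 2] = True
        clusters = frame_clusters(frame, min_pixels=3, connectivity=connectivity)
        assert _cluster_sets(clusters) == [((1, 1), (2, 1), (2, 2))]

    def test_diagonal_triples_split_by_connectivity(self):
        frame = np.zeros((8, 8), dtype=bool)
        frame[1, 1] = frame[1, 2] = frame[1, 3] = True
        frame[2, 4] = frame[2, 5] = frame[2, 6] = True  # touches only diagonally
        assert len(frame_clusters(frame, connectivity=8)) == 1
        assert len(frame_clusters(frame, connectivity=4)) == 2
        for conn in (4, 8):
            assert _cluster_sets(frame_clusters(frame, connectivity=conn)) == (
                _cluster_sets(flood_fill_clusters(frame, 3, conn))
            )

    def test_lowering_min_pixels_never_drops_clusters(self, rng):
        frame = rng.random((15, 15)) < 0.3
        counts = [len(frame_clusters(frame, min_pixels=m)) for m in (5, 4, 3, 2, 1)]
        assert np.all(np.diff(counts) >= 0)


def _stack_from(frames_pixels, shape=(10, 10)):
    stack = np.zeros((len(frames_pixels),) + shape, dtype=bool)
    for t, pixels in enumerate(frames_pixels):
        for r, c in pixels:
            stack[t, r, c] = True
    return stack


def _link(stack, connectivity=4, min_pixels=3, fps=20.0):
    clusters = [
        frame_clusters(stack[t], min_pixels, connectivity)
        for t in range(stack.shape[0])
    ]
    return link_cascades(
        clusters, fps=fps, connectivity=connectivity, shape=stack.shape[1:]
    )


class TestLinkCascades:
    def test_static_cluster_accumulates_pixel_frame_activations(self):
        pix = [(3, 3), (3, 4), (3, 5), (4, 4), (4, 5)]
        stack = _stack_from([[], [], [], pix, pix, pix, pix, pix, []])
        (cascade,) = _link(stack)
        assert cascade.start_frame == 3 and cascade.end_frame == 7
        assert cascade.duration_frames == 5
        assert cascade.duration_s == pytest.approx(0.25)
        assert cascade.size == 25
        assert cascade.peak_extent == 5

    def test_distant_clusters_stay_separate(self):
        a = [(1, 1), (1, 2), (1, 3)]
        b = [(7, 7), (7, 8), (8, 8)]
        stack = _stack_from([a + b, a + b])
        assert len(_link(stack)) == 2

    def test_temporal_gap_ends_cascade(self):
        pix = [(2, 2), (2, 3), (3, 2)]
        stack = _stack_from([pix, [], pix])
        cascades = _link(stack)
        assert len(cascades) == 2
        assert [c.duration_frames for c in cascades] == [1, 1]

    def test_contact_merges_ongoing_cascades(self):
        left = [(4, 1), (4, 2), (4, 3)]
        right = [(4, 7), (4, 8), (4, 9)]
        bridge = [(4, c) for c in range(1, 10)]
        stack = _stack_from([left + right, bridge])
        (merged,) = _link(stack)
        assert merged.size == 6 + 9
        assert merged.start_frame == 0 and merged.end_frame == 1

    def test_adjacency_without_overlap_continues(self):
        a = [(2, 2), (2, 3), (2, 4)]
        shifted = [(3, 2), (3, 3), (3, 4)]  # edge-adjacent, zero overlap
        (cascade,) = _link(_stack_from([a, shifted]))
        assert cascade.duration_frames == 2

    def test_matches_nested_loop_reference(self, rng):
        for _ in range(20):
            T = int(rng.integers(3, 16))
            stack = rng.random((T, 12, 12)) < rng.uniform(0.05, 0.3)
            conn = int(rng.choice([4, 8]))
            mine = sorted(
                (c.start_frame, c.end_frame, c.size, tuple(sorted(c.footprint)))
                for c in _link(stack, connectivity=conn)
            )
            theirs = sorted(
                (d["start"], d["end"], d["size"], tuple(sorted(d["footprint"])))
                for d in link_cascades_reference(stack, 3, conn)
            )
            assert mine == theirs

    def test_sizes_partition_retained_activations(self, rng):
        stack = rng.random((20, 15, 15)) < 0.2
        retained = sum(
            len(cl)
            for t in range(20)
            for cl in frame_clusters(stack[t], 3, 4)
        )
        assert sum(c.size for c in _link(stack)) == retained


class TestSummaries:
    def test_empty_input_summary(self):
        s = cf.summarize([])
        assert (s.n_cascades, s.max_size, s.max_duration_s) == (0, 0, 0.0)

    def test_maxima_reported(self):
        pix3 = [(1, 1), (1, 2), (1, 3)]
        stack = _stack_from([pix3] * 5 + [[]] * 2 + [pix3] * 3)
        s = cf.summarize(_link(stack))
        assert s.n_cascades == 2
        assert s.max_size == 15
        assert s.max_duration_s == pytest.approx(0.25)
        assert sorted(s.size_list) == [9, 15]

    def test_probability_distribution_counts(self):
        pix3 = [(1, 1), (1, 2), (1, 3)]
        pix4 = pix3 + [(2, 2)]
        stack = _stack_from([pix3, [], pix3, [], pix4])
        dists = cf.size_duration_distributions(_link(stack), bins=[2.5, 3.5, 4.5])
        assert dists["size_prob"].tolist() == pytest.approx([2 / 3, 1 / 3])
        assert dists["size_ecdf_y"][-1] == 1.0
        assert np.all(np.diff(dists["size_ecdf_y"]) >= 0)

    def test_distributions_require_cascades(self):
        with pytest.raises(ValueError):
            cf.size_duration_distributions([])


class TestStackSummation:
    def test_counts_active_frames_per_pixel(self):
        stack = np.zeros((9, 5, 5), dtype=bool)
        stack[:7, 2, 2] = True
        raster = cf.BinaryRaster(
            active=stack,
            threshold_k=5.0,
            per_pixel_sd=np.ones((5, 5)),
            roi=np.ones((5, 5), bool),
            fps=20.0,
        )
        ssum = cf.stack_summation(raster)
        assert ssum[2, 2] == 7
        assert ssum.sum() == 7

    def test_total_equals_cascade_sizes_plus_subthreshold(self, rng):
        stack = rng.random((25, 12, 12)) < 0.15
        raster = cf.BinaryRaster(
            active=stack,
            threshold_k=5.0,
            per_pixel_sd=np.ones((12, 12)),
            roi=np.ones((12, 12), bool),
            fps=20.0,
        )
        total = cf.stack_summation(raster).sum()
        cascade_total = sum(c.size for c in _link(stack))
        discarded = sum(
            len(cl)
            for t in range(25)
            for cl in flood_fill_clusters(stack[t], 1, 4)
            if len(cl) < 3
        )
        assert total == cascade_total + discarded
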