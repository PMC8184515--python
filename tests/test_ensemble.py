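"""Event detection, coactivity, surrogate null and ensemble calling."""

import numpy as np
import pytest

import cascadefish as cf
from cascadefish.ensemble import EventRaster, SurrogateNull, _window_counts
from cascadefish.io import RunLog
from cascadefish.preprocess import TraceMatrix

from reference import coactivity_reference


def _raster(events, fps=20.0):
    events = np.asarray(events, dtype=bool)
    coords = np.column_stack(
        [np.arange(events.shape[0], dtype=float), np.zeros(events.shape[0])]
    )
    return EventRaster(events=events, fps=fps, neuron_coords=coords)


class TestDetectEvents:
    def setup_method(self):
        self.templates = cf.make_template_library(fps=20.0)

    def test_flat_trace_has_no_events(self):
        assert cf.detect_events(np.zeros(500), self.templates).size == 0

    def test_template_shaped_transient_detected_at_onset(self):
        trace = np.zeros(600)
        template = self.templates[4]
        trace[100 : 100 + template.size] = 0.2 * template
        onsets = cf.detect_events(trace, self.templates)
        assert onsets.tolist() == [100]

    def test_amplitude_gate_blocks_small_transients(self):
        trace = np.zeros(600)
        template = self.templates[4]
        trace[100 : 100 + template.size] = 0.04 * template  # corr ≈ 1, amp < 0.05
        assert cf.detect_events(trace, self.templates).size == 0

    @pytest.mark.parametrize("scale", [1.0, 2.0, 17.5])
    def test_scale_invariance_above_amplitude_gate(self, scale):
        rng = np.random.default_rng(3)
        trace = rng.normal(0, 0.004, 800)
        template = self.templates[0]
        for onset in (100, 400, 650):
            trace[onset : onset + template.size] += 0.1 * template
        base = cf.detect_events(trace, self.templates)
        scaled = cf.detect_events(trace * scale, self.templates)
        assert base.size > 0
        assert np.array_equal(base, scaled)

    def test_empty_template_library_rejected(self):
        with pytest.raises(ValueError):
            cf.detect_events(np.zeros(100), [])


class TestCoactivity:
    def test_synchronous_events_counted_through_window(self):
        events = np.zeros((10, 100), dtype=bool)
        events[:, 50] = True
        counts = cf.coactivity(_raster(events), window_frames=10).counts
        assert np.all(counts[50:60] == 10)
        assert counts[49] == 0 and counts[60] == 0

    def test_empty_raster_all_zero(self):
        counts = cf.coactivity(_raster(np.zeros((5, 50), bool))).counts
        assert not counts.any()

    def test_counts_distinct_neurons_not_events(self):
        events = np.zeros((3, 50), dtype=bool)
        events[0, 5] = events[0, 8] = True
        counts = cf.coactivity(_raster(events), window_frames=10).counts
        assert counts[8] == 1

    def test_matches_naive_reference(self, rng):
        for _ in range(5):
            events = rng.random((12, 120)) < 0.05
            w = int(rng.integers(1, 15))
            counts = cf.coactivity(_raster(events), window_frames=w).counts
            assert np.array_equal(counts, coactivity_reference(events, w))


class TestBuildNull:
    def test_zero_event_raster_degenerate(self):
        log = RunLog()
        null = cf.build_null(_raster(np.zeros((5, 100), bool)), n_shuffles=10, log=log)
        assert null.critical_value == 0
        assert null.null_counts[0] == null.n_pooled
        assert any(r["kind"] == "warning" for r in log.records)

    @pytest.mark.parametrize("scheme", ["permute", "circular"])
    def test_shuffles_preserve_per_neuron_event_counts(self, rng, scheme):
        events = rng.random((8, 200)) < 0.05
        raster = _raster(events)
        null = cf.build_null(raster, n_shuffles=50, scheme=scheme, seed=4)
        # pooled null mass equals shuffles × frames, and the total coactivity
        # mass matches the (rate-preserving) event content of the raster
        assert null.n_pooled == 50 * 200
        expected_mass = 0
        for row in events:
            frames = np.nonzero(row)[0]
            covered = set()
            for f in frames:
                covered.update(range(f, min(f + 10, 200)))
            expected_mass += len(covered)
        # circular shifts preserve within-neuron gaps, permutations only the
        # count; both preserve the per-neuron event count, so mean coverage
        # stays within a narrow band of the unshuffled mass
        mean_mass = (null.null_counts * np.arange(null.null_counts.size)).sum() / 50
        assert mean_mass == pytest.approx(expected_mass, rel=0.25)

    def test_deterministic_given_seed(self, rng):
        events = rng.random((10, 300)) < 0.02
        a = cf.build_null(_raster(events), n_shuffles=30, seed=11)
        b = cf.build_null(_raster(events), n_shuffles=30, seed=11)
        assert np.array_equal(a.null_counts, b.null_counts)
        assert a.critical_value == b.critical_value

    def test_critical_value_is_999_quantile(self):
        # hand-built pooled histogram: 99.9% of values at 0, rest at 5
        null = cf.build_null(_raster(np.zeros((5, 100), bool)), n_shuffles=1)
        hist = np.zeros(6, dtype=np.int64)
        hist[0] = 9990
        hist[5] = 10
        cdf = np.cumsum(hist)
        crit = int(np.nonzero(cdf >= 0.999 * cdf[-1])[0][0])
        assert crit == 0  # counts > 0 would be called significant
        hist[0] = 9989
        hist[5] = 11
        cdf = np.cumsum(hist)
        assert int(np.nonzero(cdf >= 0.999 * cdf[-1])[0][0]) == 5


class TestCallEnsembles:
    def test_hand_constructed_peak_called_once(self):
        events = np.zeros((12, 100), dtype=bool)
        events[:10, 50] = True  # coactivity 10 on frames 50..59
        events[10, 20] = True
        raster = _raster(events)
        counts = cf.coactivity(raster, window_frames=10)
        null = SurrogateNull(
            n_shuffles=1,
            null_counts=np.array([100]),
            n_pooled=100,
            critical_value=3,
            alpha=0.001,
            seed=0,
            window_frames=10,
        )
        ensembles = cf.call_ensembles(counts, null, raster)
        assert len(ensembles) == 1
        assert ensembles[0].frame_span == (50, 59)
        assert ensembles[0].member_neuron_ids == set(range(10))
        assert ensembles[0].size == 10

    def test_subcritical_counts_yield_nothing(self):
        events = np.zeros((5, 60), dtype=bool)
        events[0, 10] = True
        raster = _raster(events)
        counts = cf.coactivity(raster)
        null = SurrogateNull(1, np.array([10]), 10, 3, 0.001, 0, 10)
        assert cf.call_ensembles(counts, null, raster) == []

    def test_member_distances_scale_with_pixel_pitch(self):
        events = np.zeros((4, 40), dtype=bool)
        events[:, 20] = True
        coords = np.array([[0.0, 0.0], [0.0, 2.0], [2.0, 0.0], [2.0, 2.0]])
        raster = EventRaster(events=events, fps=20.0, neuron_coords=coords)
        counts = cf.coactivity(raster)
        null = SurrogateNull(1, np.array([10]), 10, 1, 0.001, 0, 10)
        (ens,) = cf.call_ensembles(counts, null, raster, pixel_pitch_um=0.5)
        assert ens.centroid == (1.0, 1.0)
        assert np.allclose(ens.member_distances_um, np.sqrt(2) * 0.5)

    def test_injected_ensemble_recovered_end_to_end(self):
        members = list(range(40, 50))
        spec = cf.InjectedEnsembleSpec(member_neuron_ids=members, event_frames=[500])
        raster, traces, _ = cf.generate_microscale_raster(
            100, 2000, [spec], seed=21, background_rate=0.002
        )
        detected = cf.detect_events_matrix(traces)
        counts = cf.coactivity(detected)
        null = cf.build_null(detected, n_shuffles=300, seed=22)
        ensembles = cf.call_ensembles(counts, null, detected)
        assert any(set(members) <= e.member_neuron_ids for e in ensembles)


class TestEnsembleSummary:
    def test_count_and_mean_size(self):
        def ens(size):
            return cf.EnsembleEvent(
                frame_span=(0, 1),
                member_neuron_ids=set(range(size)),
                centroid=(0.0, 0.0),
                member_distances_um=np.zeros(size),
            )

        s = cf.ensemble_summary([ens(4), ens(6)], recording_length_s=300.0)
        assert s.n_ensembles == 2
        assert s.avg_size == 5.0
        assert s.rate_per_min == pytest.approx(0.4)
        assert not s.empty

    def test_empty_is_flagged(self):
        s = cf.ensemble_summary([], recording_length_s=300.0)
        assert (s.n_ensembles, s.avg_size) == (0, 0.0)
        assert s.empty


def test_window_counts_start_truncation():
    # events at the very first frames must not index before frame 0
    rows = np.array([0, 1])
    frames = np.array([0, 2])
    counts = _window_counts(rows, frames, n_frames=20, window=10)
    assert counts[0] == 1 and counts[2] == 2 and counts[11] == 1 and counts[12] == 0
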