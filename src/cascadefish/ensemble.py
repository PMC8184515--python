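"""Microscale ensemble detection: events, coactivity, surrogate null.

Single-neuron calcium events are detected by template matching: a frame is
an event onset when the Pearson correlation between a GCaMP-like transient
template and the ΔF/F segment starting there exceeds ``min_corr`` (default
0.85) and the segment's peak ΔF/F exceeds ``min_amp`` (default 0.05).
Coactivity is the number of distinct neurons with at least one event inside
a trailing 0.5-s (10-frame) window.  Significance comes from a within-neuron
shuffle null: event times are permuted independently within each neuron
(preserving per-neuron rates, destroying coordination) 2000 times, the
coactivity values of all surrogate frames are pooled, and a frame is called
significant when its observed coactivity exceeds 99.9% of all pooled
surrogate values (p < 0.001).  Runs of significant frames become ensemble
events with member neurons, spatial centroid and member-to-centroid
distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .synth import gcamp_kernel

__all__ = [
    "EventRaster",
    "CoactivitySeries",
    "SurrogateNull",
    "EnsembleEvent",
    "EnsembleSummary",
    "make_template_library",
    "detect_events",
    "detect_events_matrix",
    "coactivity",
    "build_null",
    "call_ensembles",
    "ensemble_summary",
]


@dataclass
class EventRaster:
    """Binary neurons × frames matrix of event onsets."""

    events: np.ndarray
    fps: float
    neuron_coords: np.ndarray  # (n_neurons, 2) in pixels

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=bool)
        self.neuron_coords = np.asarray(self.neuron_coords, dtype=np.float64)
        if self.events.ndim != 2:
            raise ValueError("events must be (neurons, frames)")
        if self.neuron_coords.shape != (self.events.shape[0], 2):
            raise ValueError("neuron_coords must be (n_neurons, 2)")

    @property
    def n_neurons(self) -> int:
        return self.events.shape[0]

    @property
    def n_frames(self) -> int:
        return self.events.shape[1]


@dataclass
class CoactivitySeries:
    counts: np.ndarray  # per-frame distinct-neuron count
    window_frames: int


@dataclass
class SurrogateNull:
    """Pooled surrogate coactivity distribution and its critical value.

    ``null_counts`` is a histogram: ``null_counts[v]`` is how many of the
    ``n_pooled`` surrogate frame values equal coactivity v.  A frame is
    significant when its observed count is STRICTLY greater than
    ``critical_value``, the empirical (1 - alpha) quantile of the pool.
    """

    n_shuffles: int
    null_counts: np.ndarray
    n_pooled: int
    critical_value: int
    alpha: float
    seed: int
    window_frames: int


@dataclass
class EnsembleEvent:
    frame_span: tuple[int, int]  # first, last significant frame (inclusive)
    member_neuron_ids: set[int]
    centroid: tuple[float, float]
    member_distances_um: np.ndarray = field(repr=False)

    @property
    def size(self) -> int:
        return len(self.member_neuron_ids)


@dataclass
class EnsembleSummary:
    n_ensembles: int
    avg_size: float
    rate_per_min: float
    empty: bool = False


def make_template_library(
    fps: float,
    rise_times_s: tuple[float, ...] = (0.02, 0.05, 0.1),
    decay_times_s: tuple[float, ...] = (0.2, 0.5, 1.0),
) -> list[np.ndarray]:
    """Double-exponential transient templates over a small (rise, decay) grid.

    Each template spans rise + 4 decay time constants, enough to cover the
    transient to <2% of peak.
    """
    lib = []
    for tr in rise_times_s:
        for td in decay_times_s:
            length = max(4, int(round((tr + 4 * td) * fps)))
            lib.append(gcamp_kernel(tr, td, fps, length))
    return lib


def _template_hits(
    trace: np.ndarray, template: np.ndarray, min_amp: float, min_corr: float
) -> tuple[np.ndarray, np.ndarray]:
    """Start frames where the template matches, with their correlations."""
    L = template.size
    if trace.size < L:
        return np.empty(0, dtype=np.int64), np.empty(0)
    X = sliding_window_view(trace, L)
    mx = X.mean(axis=1)
    sx = X.std(axis=1)
    mw = template.mean()
    sw = template.std()
    num = X @ template / L - mx * mw
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = num / (sx * sw)
    corr[~np.isfinite(corr)] = 0.0  # constant segments carry no event
    peak = X.max(axis=1)
    hits = np.nonzero((corr > min_corr) & (peak > min_amp))[0]
    return hits, corr[hits]


def detect_events(
    trace: np.ndarray,
    templates: list[np.ndarray],
    min_amp: float = 0.05,
    min_corr: float = 0.85,
) -> np.ndarray:
    """Event-onset frames for one ΔF/F trace.

    Correlation is scale-free, so the amplitude gate is the only
    scale-dependent element: multiplying the trace by any c > 0 that keeps
    the peak above ``min_amp`` leaves the output unchanged.  A run of
    overlapping detections (each within one template length of the next)
    collapses to its best-correlated frame, so a noise-free copy of a
    template yields exactly one event at its true onset; ties break to the
    earliest frame.
    """
    if not templates:
        raise ValueError("template library is empty")
    trace = np.asarray(trace, dtype=np.float64)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite values")
    best: dict[int, tuple[float, int]] = {}  # onset -> (corr, template length)
    for w in templates:
        w = np.asarray(w, dtype=np.float64)
        if w.size < 2:
            raise ValueError("templates must have at least 2 frames")
        hits, corrs = _template_hits(trace, w, min_amp, min_corr)
        for t, c in zip(hits, corrs):
            t = int(t)
            if t not in best or c > best[t][0]:
                best[t] = (float(c), w.size)

    def _pick(group: list[int]) -> int:
        return max(group, key=lambda u: (best[u][0], -u))

    # a single transient produces matches at a contiguous run of start
    # frames; collapse each run to its best-correlated frame first, then
    # suppress residual tail re-matches within one template length
    candidates: list[int] = []
    group: list[int] = []
    for t in sorted(best):
        if group and t > group[-1] + 1:
            candidates.append(_pick(group))
            group = []
        group.append(t)
    if group:
        candidates.append(_pick(group))

    onsets: list[int] = []
    blocked_until = -1
    for t in candidates:
        if t > blocked_until:
            onsets.append(t)
            blocked_until = t + best[t][1] - 1
    return np.array(onsets, dtype=np.int64)


def detect_events_matrix(
    traces: "TraceMatrix",
    templates: list[np.ndarray] | None = None,
    min_amp: float = 0.05,
    min_corr: float = 0.85,
) -> EventRaster:
    """Template-matching event detection for every valid neuron trace."""
    from .preprocess import TraceMatrix  # noqa: F401 (typing aid)

    if templates is None:
        templates = make_template_library(traces.fps)
    events = np.zeros(traces.values.shape, dtype=bool)
    for i in range(traces.n_units):
        if not traces.valid[i]:
            continue
        on = detect_events(traces.values[i], templates, min_amp, min_corr)
        events[i, on] = True
    return EventRaster(events=events, fps=traces.fps, neuron_coords=traces.unit_coords)


def _window_counts(
    rows: np.ndarray, frames: np.ndarray, n_frames: int, window: int
) -> np.ndarray:
    """counts(t) = # distinct neurons with an event in [t-window+1, t].

    Each event at frame f covers frames [f, f+window-1]; coverage intervals
    of consecutive events of the same neuron are clipped so no neuron is
    counted twice.
    """
    counts_diff = np.zeros(n_frames + 1, dtype=np.int64)
    if rows.size:
        order = np.lexsort((frames, rows))
        r = rows[order]
        f = frames[order]
        end = np.minimum(f + window, n_frames)
        same = r[1:] == r[:-1]
        end[:-1][same] = np.minimum(end[:-1][same], f[1:][same])
        np.add.at(counts_diff, f, 1)
        np.add.at(counts_diff, end, -1)
    return np.cumsum(counts_diff[:n_frames])


def coactivity(events: EventRaster, window_frames: int = 10) -> CoactivitySeries:
    """Trailing-window coactivity series (distinct neurons per window)."""
    if window_frames < 1:
        raise ValueError("window_frames must be >= 1")
    rows, frames = np.nonzero(events.events)
    counts = _window_counts(rows, frames, events.n_frames, window_frames)
    return CoactivitySeries(counts=counts, window_frames=window_frames)


def build_null(
    events: EventRaster,
    n_shuffles: int = 2000,
    window_frames: int = 10,
    seed: int = 0,
    alpha: float = 0.001,
    scheme: str = "permute",
    log=None,
) -> SurrogateNull:
    """Within-neuron shuffle null for the coactivity series.

    ``scheme="permute"`` redraws each neuron's event frames uniformly without
    replacement (a uniform permutation of its event train); ``"circular"``
    applies an independent circular shift per neuron, preserving within-neuron
    inter-event structure.  Coactivity values of all surrogate frames are
    pooled into one distribution.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if scheme not in ("permute", "circular"):
        raise ValueError("scheme must be 'permute' or 'circular'")
    rng = np.random.default_rng(seed)
    n, T = events.events.shape
    per_neuron_frames = [np.nonzero(events.events[u])[0] for u in range(n)]
    k = np.array([f.size for f in per_neuron_frames])
    active_units = np.nonzero(k > 0)[0]
    hist = np.zeros(n + 1, dtype=np.int64)

    if k.sum() == 0:
        if log is not None:
            log.warn("build_null", "raster has zero events; degenerate null")
        hist[0] = n_shuffles * T
        return SurrogateNull(
            n_shuffles=n_shuffles,
            null_counts=hist,
            n_pooled=int(hist.sum()),
            critical_value=0,
            alpha=alpha,
            seed=seed,
            window_frames=window_frames,
        )

    for _ in range(n_shuffles):
        rows_parts = []
        frame_parts = []
        for u in active_units:
            if scheme == "permute":
                pos = rng.choice(T, size=int(k[u]), replace=False)
            else:
                pos = (per_neuron_frames[u] + rng.integers(T)) % T
            rows_parts.append(np.full(pos.size, u, dtype=np.int64))
            frame_parts.append(pos)
        counts = _window_counts(
            np.concatenate(rows_parts),
            np.concatenate(frame_parts).astype(np.int64),
            T,
            window_frames,
        )
        hist += np.bincount(counts, minlength=n + 1)

    n_pooled = int(hist.sum())
    cdf = np.cumsum(hist)
    # empirical (1 - alpha) quantile: smallest v with #(null <= v) >= (1-alpha)·N
    critical = int(np.nonzero(cdf >= (1.0 - alpha) * n_pooled)[0][0])
    return SurrogateNull(
        n_shuffles=n_shuffles,
        null_counts=hist,
        n_pooled=n_pooled,
        critical_value=critical,
        alpha=alpha,
        seed=seed,
        window_frames=window_frames,
    )


def call_ensembles(
    counts: CoactivitySeries,
    null: SurrogateNull,
    events: EventRaster,
    pixel_pitch_um: float = 1.0,
) -> list[EnsembleEvent]:
    """Ensemble events from significant coactivity frames.

    A frame is significant when its coactivity exceeds 99.9% of the pooled
    surrogate values, i.e. counts(t) > critical_value.  Consecutive
    significant frames merge into one event; members are the neurons with an
    event inside the run's trailing-window support
    [first - window + 1, last].
    """
    sig = counts.counts > null.critical_value
    if not np.any(sig):
        return []
    w = counts.window_frames
    padded = np.diff(np.concatenate(([0], sig.astype(np.int8), [0])))
    starts = np.nonzero(padded == 1)[0]
    ends = np.nonzero(padded == -1)[0] - 1
    out = []
    for a, b in zip(starts, ends):
        lo = max(0, a - w + 1)
        members = set(np.nonzero(events.events[:, lo : b + 1].any(axis=1))[0].tolist())
        coords = events.neuron_coords[sorted(members)]
        centroid = coords.mean(axis=0)
        dists = np.linalg.norm(coords - centroid, axis=1) * pixel_pitch_um
        out.append(
            EnsembleEvent(
                frame_span=(int(a), int(b)),
                member_neuron_ids=members,
                centroid=(float(centroid[0]), float(centroid[1])),
                member_distances_um=dists,
            )
        )
    return out


def ensemble_summary(
    ensembles: list[EnsembleEvent], recording_length_s: float
) -> EnsembleSummary:
    """Occurrence count/rate and the average number of coactive members."""
    n = len(ensembles)
    if n == 0:
        return EnsembleSummary(0, 0.0, 0.0, empty=True)
    avg = float(np.mean([e.size for e in ensembles]))
    return EnsembleSummary(n, avg, n / (recording_length_s / 60.0))
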