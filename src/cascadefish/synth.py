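"""Synthetic calcium-imaging data with known ground truth.

Two generators emulate the two acquisition scales of the study system
(larval-zebrafish optic tectum, GCaMP6f, 20 fps, 5-min epochs):

* mesoscale movies — pixel fluorescence = slowly drifting baseline +
  amplitude-scaled transient responses at injected cascade activations +
  i.i.d. Gaussian noise.  Cascades are spatiotemporally contiguous
  per-frame pixel sets with controlled footprint and duration.
* microscale rasters — per-neuron Bernoulli background events plus forced
  coactivation events for injected ensembles; ΔF/F traces are the raster
  convolved with a GCaMP6f-like kernel plus noise, generated per ROI
  directly (no pixel rendering), with neuron centroids on a jittered grid.

Everything is deterministic given the seed, and the injected ground truth is
returned (and JSON-serializable) so every downstream stage can be tested
without real recordings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.signal import fftconvolve

from .preprocess import Movie, TraceMatrix

__all__ = [
    "SynthMovieParams",
    "InjectedCascade",
    "InjectedEnsembleSpec",
    "GroundTruth",
    "gcamp_kernel",
    "generate_mesoscale_movie",
    "generate_microscale_raster",
    "random_cascade",
    "random_cascades",
]


def gcamp_kernel(
    tau_rise: float, tau_decay: float, fps: float, length: int
) -> np.ndarray:
    """Unit-peak double-exponential calcium transient waveform.

    w(t) = exp(-t/tau_decay) - exp(-t/tau_rise), sampled at 1/fps and
    normalized so its maximum sample is exactly 1.  w[0] = 0; the waveform
    rises to its peak and decays monotonically after it.  GCaMP6f-like
    defaults elsewhere in the package use tau_rise ≈ 0.05 s,
    tau_decay ≈ 0.4 s.
    """
    if tau_rise <= 0 or tau_decay <= 0:
        raise ValueError("time constants must be positive")
    if tau_rise >= tau_decay:
        raise ValueError("tau_rise must be smaller than tau_decay")
    if length < 2:
        raise ValueError("length must be >= 2 frames")
    t = np.arange(length) / fps
    w = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    return w / w.max()


@dataclass
class SynthMovieParams:
    """Mesoscale movie generation parameters.

    Defaults emulate one 5-min epoch at 20 fps over a 60×60-pixel tectal
    ROI: baseline 1000 a.u., ±5% sinusoidal drift with a 120-s period,
    Gaussian noise of 2% of baseline per pixel per frame, GCaMP6f-like
    transient time constants.  ``transient_shape`` selects how an injected
    (pixel, frame) activation is rendered: "gcamp" convolves activations
    with the double-exponential kernel; "impulse" raises fluorescence for
    exactly the activation frame, which makes the injected activation set
    identical to the super-threshold set and hence exactly recoverable.
    """

    height: int = 60
    width: int = 60
    n_frames: int = 6000
    fps: float = 20.0
    baseline_level: float = 1000.0
    drift_amplitude: float = 0.05
    drift_period_s: float = 120.0
    noise_sd: float = 0.02
    tau_rise: float = 0.05
    tau_decay: float = 0.4
    transient_shape: str = "gcamp"
    pixel_pitch_um: float = 2.67
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValueError("height and width must be >= 8")
        if self.n_frames < 200:
            raise ValueError("n_frames must be >= 200")
        if self.fps <= 0 or self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError("rates and time constants must be positive")
        if self.drift_period_s < 60.0:
            raise ValueError("drift_period_s must be >= 60 s (slow drift)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.transient_shape not in ("gcamp", "impulse"):
            raise ValueError("transient_shape must be 'gcamp' or 'impulse'")


@dataclass
class InjectedCascade:
    """Ground-truth cascade: one ordered pixel set per event frame.

    ``per_frame_pixel_sets[i]`` lists (row, col) pixels active at frame
    ``start_frame + i``; each set has >= 3 internally connected pixels and
    consecutive sets are spatially contiguous, so the injected object is
    itself a valid cascade under the detection rule.
    """

    start_frame: int
    per_frame_pixel_sets: list[list[tuple[int, int]]]
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        self.per_frame_pixel_sets = [
            sorted((int(r), int(c)) for r, c in s) for s in self.per_frame_pixel_sets
        ]

    @property
    def n_event_frames(self) -> int:
        return len(self.per_frame_pixel_sets)

    @property
    def size(self) -> int:
        return sum(len(s) for s in self.per_frame_pixel_sets)

    def activations(self):
        """Yield every (frame, row, col) activation."""
        for i, pix in enumerate(self.per_frame_pixel_sets):
            for r, c in pix:
                yield self.start_frame + i, r, c


@dataclass
class InjectedEnsembleSpec:
    """Ground-truth ensemble: members forced to fire at the event frames."""

    member_neuron_ids: list[int]
    event_frames: list[int]
    background_rate: float = 0.002

    def __post_init__(self) -> None:
        self.member_neuron_ids = sorted(int(i) for i in self.member_neuron_ids)
        self.event_frames = sorted(int(f) for f in self.event_frames)
        if len(self.member_neuron_ids) < 2:
            raise ValueError("an ensemble needs >= 2 members")
        if not 0 <= self.background_rate < 1:
            raise ValueError("background_rate must be in [0, 1)")


@dataclass
class GroundTruth:
    """Injected structure of one synthetic dataset; JSON round-trippable."""

    cascades: list[InjectedCascade] = field(default_factory=list)
    ensembles: list[InjectedEnsembleSpec] = field(default_factory=list)
    neuron_centroids: list[tuple[float, float]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            cascades=[
                InjectedCascade(
                    start_frame=c["start_frame"],
                    per_frame_pixel_sets=[
                        [tuple(p) for p in s] for s in c["per_frame_pixel_sets"]
                    ],
                    amplitude=c["amplitude"],
                )
                for c in d["cascades"]
            ],
            ensembles=[InjectedEnsembleSpec(**e) for e in d["ensembles"]],
            neuron_centroids=[tuple(p) for p in d["neuron_centroids"]],
        )


_OFFS4 = ((-1, 0), (1, 0), (0, -1), (0, 1))


def _connected(pixels: set[tuple[int, int]]) -> bool:
    if not pixels:
        return False
    seen = set()
    stack = [next(iter(pixels))]
    while stack:
        r, c = stack.pop()
        if (r, c) in seen:
            continue
        seen.add((r, c))
        for dr, dc in _OFFS4:
            if (r + dr, c + dc) in pixels:
                stack.append((r + dr, c + dc))
    return len(seen) == len(pixels)


def _grow_region(
    rng: np.random.Generator,
    roi_set: set[tuple[int, int]],
    seed_pixel: tuple[int, int],
    size: int,
) -> set[tuple[int, int]]:
    """Random 4-connected region of ~``size`` pixels grown inside the ROI."""
    region = {seed_pixel}
    frontier = [seed_pixel]
    while len(region) < size and frontier:
        idx = int(rng.integers(len(frontier)))
        r, c = frontier[idx]
        nbrs = [
            (r + dr, c + dc)
            for dr, dc in _OFFS4
            if (r + dr, c + dc) in roi_set and (r + dr, c + dc) not in region
        ]
        if not nbrs:
            frontier.pop(idx)
            continue
        pick = nbrs[int(rng.integers(len(nbrs)))]
        region.add(pick)
        frontier.append(pick)
    return region


def random_cascade(
    rng: np.random.Generator,
    roi: np.ndarray,
    start_frame: int,
    n_event_frames: int,
    pixels_per_frame: int,
    amplitude: float = 1.0,
) -> InjectedCascade:
    """A random propagating cascade footprint inside the ROI.

    The first frame's region grows from a random ROI pixel; each subsequent
    frame regrows from a random pixel of the previous frame's set, which
    guarantees frame-to-frame contiguity and internal 4-connectivity.
    """
    if pixels_per_frame < 3:
        raise ValueError("each per-frame set needs >= 3 pixels")
    roi_set = {(int(r), int(c)) for r, c in np.argwhere(np.asarray(roi).astype(bool))}
    if len(roi_set) < pixels_per_frame:
        raise ValueError("ROI too small for the requested footprint")
    sets: list[list[tuple[int, int]]] = []
    prev: set[tuple[int, int]] | None = None
    for _ in range(n_event_frames):
        while True:
            if prev is None:
                seed_pixel = list(roi_set)[int(rng.integers(len(roi_set)))]
            else:
                prev_list = sorted(prev)
                seed_pixel = prev_list[int(rng.integers(len(prev_list)))]
            region = _grow_region(rng, roi_set, seed_pixel, pixels_per_frame)
            if len(region) >= 3 and _connected(region):
                break
        sets.append(sorted(region))
        prev = region
    return InjectedCascade(
        start_frame=start_frame, per_frame_pixel_sets=sets, amplitude=amplitude
    )


def random_cascades(
    rng: np.random.Generator,
    roi: np.ndarray,
    n_cascades: int,
    n_frames: int,
    duration_frames: tuple[int, int] = (2, 6),
    pixels_per_frame: tuple[int, int] = (4, 12),
    amplitude: float = 1.0,
    first_frame: int = 150,
    guard_frames: int = 30,
) -> list[InjectedCascade]:
    """Temporally well-separated random cascades (no accidental merging).

    Start frames are spaced so consecutive cascades are separated by at
    least ``guard_frames`` silent frames, which keeps each injected object
    a distinct detected cascade.
    """
    cascades = []
    t = first_frame
    for _ in range(n_cascades):
        dur = int(rng.integers(duration_frames[0], duration_frames[1] + 1))
        npx = int(rng.integers(pixels_per_frame[0], pixels_per_frame[1] + 1))
        if t + dur + guard_frames >= n_frames:
            raise ValueError("recording too short for the requested cascades")
        cascades.append(random_cascade(rng, roi, t, dur, npx, amplitude))
        t += dur + guard_frames
    return cascades


def generate_mesoscale_movie(
    params: SynthMovieParams,
    cascades: list[InjectedCascade],
    roi: np.ndarray,
) -> tuple[Movie, GroundTruth]:
    """Mesoscale movie = drifting baseline + injected cascades + noise.

    F(t, p) = B·(1 + a·sin(2πt/period)) + B·amplitude·shape(t - t_act) + ε,
    with ε ~ N(0, (noise_sd·B)²) i.i.d. per pixel per frame.  Transient
    amplitudes are therefore calibrated in ΔF/F units.  Deterministic given
    ``params.seed``.
    """
    roi = np.asarray(roi).astype(bool)
    if roi.shape != (params.height, params.width):
        raise ValueError("ROI shape must match (height, width)")
    roi_set = {(int(r), int(c)) for r, c in np.argwhere(roi)}
    for casc in cascades:
        last = casc.start_frame + casc.n_event_frames - 1
        if casc.start_frame < 0 or last >= params.n_frames:
            raise ValueError(
                f"cascade frames [{casc.start_frame}, {last}] outside recording"
            )
        for _, r, c in casc.activations():
            if (r, c) not in roi_set:
                raise ValueError(f"cascade pixel ({r}, {c}) outside ROI")

    rng = np.random.default_rng(params.seed)
    T, H, W = params.n_frames, params.height, params.width
    t = np.arange(T) / params.fps
    drift = 1.0 + params.drift_amplitude * np.sin(
        2 * np.pi * t / params.drift_period_s
    )
    frames = np.empty((T, H, W))
    frames[:] = (params.baseline_level * drift)[:, None, None]

    if params.transient_shape == "gcamp":
        kern_len = max(2, int(round((params.tau_rise + 5 * params.tau_decay) * params.fps)))
        kern = gcamp_kernel(params.tau_rise, params.tau_decay, params.fps, kern_len)
    else:
        kern = np.array([1.0])
    for casc in cascades:
        bump = params.baseline_level * casc.amplitude * kern
        for f, r, c in casc.activations():
            seg = min(bump.size, T - f)
            frames[f : f + seg, r, c] += bump[:seg]

    if params.noise_sd > 0:
        frames += rng.normal(
            0.0, params.noise_sd * params.baseline_level, size=frames.shape
        )
        np.clip(frames, 0.0, None, out=frames)

    movie = Movie(frames=frames, fps=params.fps, pixel_pitch_um=params.pixel_pitch_um)
    return movie, GroundTruth(cascades=list(cascades))


def generate_microscale_raster(
    n_neurons: int,
    n_frames: int,
    specs: list[InjectedEnsembleSpec],
    seed: int,
    fps: float = 20.0,
    background_rate: float = 0.002,
    event_amplitude: float = 0.2,
    noise_sd: float = 0.01,
    tau_rise: float = 0.05,
    tau_decay: float = 0.4,
    field_px: float = 400.0,
) -> tuple["EventRaster", TraceMatrix, GroundTruth]:
    """Microscale ground-truth raster, ΔF/F traces and neuron positions.

    Events are i.i.d. Bernoulli(``background_rate``) per neuron per frame,
    plus forced events for each ensemble's members at its event frames.
    Traces are the raster convolved with the GCaMP kernel, scaled to
    ``event_amplitude`` ΔF/F per event, plus Gaussian noise.  Neuron
    centroids sit on a jittered square grid across ``field_px`` pixels.
    """
    from .ensemble import EventRaster  # local import avoids a cycle

    if not 0 <= background_rate < 1:
        raise ValueError("background_rate must be in [0, 1)")
    for spec in specs:
        if max(spec.member_neuron_ids) >= n_neurons:
            raise ValueError("spec references a neuron id >= n_neurons")
        if spec.event_frames and (
            min(spec.event_frames) < 0 or max(spec.event_frames) >= n_frames
        ):
            raise ValueError("spec event frame outside recording")

    rng = np.random.default_rng(seed)
    events = rng.random((n_neurons, n_frames)) < background_rate
    for spec in specs:
        for f in spec.event_frames:
            events[spec.member_neuron_ids, f] = True

    kern_len = max(2, int(round((tau_rise + 5 * tau_decay) * fps)))
    kern = gcamp_kernel(tau_rise, tau_decay, fps, kern_len) * event_amplitude
    traces = fftconvolve(events.astype(np.float64), kern[None, :], axes=1)[
        :, :n_frames
    ]
    if noise_sd > 0:
        traces += rng.normal(0.0, noise_sd, size=traces.shape)

    side = int(np.ceil(np.sqrt(n_neurons)))
    pitch = field_px / side
    gr, gc = np.divmod(np.arange(n_neurons), side)
    coords = np.stack(
        [
            (gr + 0.5) * pitch + rng.uniform(-0.25, 0.25, n_neurons) * pitch,
            (gc + 0.5) * pitch + rng.uniform(-0.25, 0.25, n_neurons) * pitch,
        ],
        axis=1,
    )

    raster = EventRaster(events=events, fps=fps, neuron_coords=coords)
    trace_matrix = TraceMatrix(
        values=traces, unit_kind="neuron", unit_coords=coords, fps=fps
    )
    truth = GroundTruth(
        ensembles=list(specs),
        neuron_centroids=[(float(r), float(c)) for r, c in coords],
    )
    return raster, trace_matrix, truth
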