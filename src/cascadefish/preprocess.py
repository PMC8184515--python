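"""Raw-fluorescence preprocessing: onset discard, ROI trace extraction, ΔF/F.

The ΔF/F convention used throughout is a strictly causal sliding baseline:
for frame ``t`` the baseline ``B(t)`` is the mean of the lower 50% of the
fluorescence values in the preceding ``window_s`` seconds (the window ends at
``t - 1``, so a transient never depresses its own baseline), and

    dff(t) = (F(t) - B(t)) / B(t)

Taking only the lower half of the window makes the baseline insensitive to
transients riding on it, while still tracking slow drift of the resting
fluorescence (photobleaching, focus drift, illumination fluctuation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._baseline import sliding_lower_half_mean

__all__ = [
    "Movie",
    "TraceMatrix",
    "discard_onset",
    "extract_traces",
    "compute_dff",
]

DEFAULT_PIXEL_PITCH_UM = 2.67  # mesoscale (5x objective) pixel edge, µm


@dataclass
class Movie:
    """A frame-major fluorescence stack with acquisition metadata.

    frames : (n_frames, height, width) array, arbitrary fluorescence units,
        nonnegative.
    fps : acquisition rate, Hz.
    pixel_pitch_um : physical pixel edge length in µm.
    """

    frames: np.ndarray
    fps: float = 20.0
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"movie must be (frames, rows, cols), got shape {self.frames.shape}"
            )
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if np.issubdtype(self.frames.dtype, np.floating) and not np.all(
            np.isfinite(self.frames)
        ):
            raise ValueError("movie contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class TraceMatrix:
    """Per-unit time series (units × frames); units are pixels or neurons.

    ``unit_coords`` holds (row, col) positions: the pixel itself at mesoscale,
    the pixel-mean centroid of the ROI for neurons.  ``valid`` flags units that
    survived preprocessing; invalid units (non-positive or non-finite ΔF/F
    baseline) are kept in place so unit indexing is stable, but must be ignored
    downstream.
    """

    values: np.ndarray
    unit_kind: str  # "pixel" | "neuron"
    unit_coords: np.ndarray
    fps: float
    unit_labels: np.ndarray | None = None
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be (units, frames)")
        self.unit_coords = np.asarray(self.unit_coords, dtype=np.float64)
        if self.unit_coords.shape != (self.values.shape[0], 2):
            raise ValueError("unit_coords must be (n_units, 2)")
        if self.unit_kind not in ("pixel", "neuron"):
            raise ValueError("unit_kind must be 'pixel' or 'neuron'")
        if self.valid is None:
            self.valid = np.ones(self.values.shape[0], dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def discard_onset(movie: Movie, n_discard: int = 100) -> Movie:
    """Drop the first ``n_discard`` frames (laser-onset indicator response).

    At 20 fps the default removes the first 5 s of each epoch, where the
    sudden excitation-light exposure evokes a brief global GCaMP response.
    """
    if n_discard < 0:
        raise ValueError("n_discard must be >= 0")
    if movie.n_frames <= n_discard:
        raise ValueError(
            f"movie has {movie.n_frames} frames, cannot discard {n_discard}"
        )
    if n_discard == 0:
        return replace(movie)
    return replace(movie, frames=movie.frames[n_discard:])


def _mask_kind(roi: np.ndarray) -> str:
    if roi.dtype == bool:
        return "binary"
    vals = np.unique(roi)
    if set(vals.tolist()) <= {0, 1} or set(vals.tolist()) <= {0, 255}:
        return "binary"
    return "label"


def extract_traces(movie: Movie, roi: np.ndarray, kind: str | None = None) -> TraceMatrix:
    """Extract raw fluorescence traces from a binary or label ROI mask.

    A binary mask yields one trace per in-mask pixel (row-major order);
    a label mask yields one trace per label (ascending label order), each
    the mean over the label's pixels.
    """
    roi = np.asarray(roi)
    if roi.shape != movie.frame_shape:
        raise ValueError(
            f"mask shape {roi.shape} does not match frame shape {movie.frame_shape}"
        )
    if kind is None:
        kind = _mask_kind(roi)

    frames = movie.frames.astype(np.float64, copy=False)
    if kind == "binary":
        mask = roi.astype(bool)
        coords = np.argwhere(mask)  # row-major order
        if coords.shape[0] == 0:
            raise ValueError("ROI mask is empty")
        values = frames[:, coords[:, 0], coords[:, 1]].T
        labels = coords[:, 0] * roi.shape[1] + coords[:, 1]
        return TraceMatrix(
            values=values,
            unit_kind="pixel",
            unit_coords=coords.astype(np.float64),
            fps=movie.fps,
            unit_labels=labels,
        )
    if kind == "label":
        labels = np.unique(roi)
        labels = labels[labels > 0]
        if labels.size == 0:
            raise ValueError("label mask contains no ROIs")
        values = np.empty((labels.size, movie.n_frames))
        coords = np.empty((labels.size, 2))
        for i, lab in enumerate(labels):
            pix = np.argwhere(roi == lab)
            values[i] = frames[:, pix[:, 0], pix[:, 1]].mean(axis=1)
            coords[i] = pix.mean(axis=0)
        return TraceMatrix(
            values=values,
            unit_kind="neuron",
            unit_coords=coords,
            fps=movie.fps,
            unit_labels=labels,
        )
    raise ValueError(f"unknown mask kind {kind!r}")


def sliding_baseline(raw: np.ndarray, fps: float, window_s: float = 10.0) -> np.ndarray:
    """Causal lower-50% sliding baseline, one value per (unit, frame).

    The window for frame ``t`` is frames ``[t - W, t - 1]`` with
    ``W = round(window_s * fps)``; early frames use all available preceding
    frames; frame 0 uses itself (so ΔF/F there is 0 by construction).  The
    lower 50% of a k-frame window is its ⌊k/2⌋ smallest values, minimum 1.
    """
    raw = np.ascontiguousarray(np.asarray(raw, dtype=np.float64))
    window = int(round(window_s * fps))
    if window < 2:
        raise ValueError("window_s * fps must be at least 2 frames")
    return sliding_lower_half_mean(raw, window)


def compute_dff(
    raw: TraceMatrix, window_s: float = 10.0, log: "RunLog | None" = None
) -> TraceMatrix:
    """ΔF/F with the causal sliding lower-50% baseline.

    Units whose baseline is ever non-positive or non-finite are flagged
    invalid (``valid=False``) rather than propagating NaN; downstream stages
    treat them as silent.  Scale invariance holds exactly: dff(c·F) = dff(F)
    for any c > 0.
    """
    baseline = sliding_baseline(raw.values, raw.fps, window_s)
    good = np.all(np.isfinite(baseline) & (baseline > 0), axis=1) & np.all(
        np.isfinite(raw.values), axis=1
    )
    dff = np.zeros_like(raw.values, dtype=np.float64)
    if np.any(good):
        dff[good] = (raw.values[good] - baseline[good]) / baseline[good]
    n_bad = int(np.count_nonzero(~good))
    if n_bad and log is not None:
        log.exclude(
            "compute_dff",
            f"{n_bad} unit(s) flagged invalid (non-positive or non-finite baseline)",
            units=np.nonzero(~good)[0].tolist(),
        )
    return TraceMatrix(
        values=dff,
        unit_kind=raw.unit_kind,
        unit_coords=raw.unit_coords,
        fps=raw.fps,
        unit_labels=raw.unit_labels,
        valid=raw.valid & good,
    )
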