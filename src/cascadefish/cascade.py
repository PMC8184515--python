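"""Mesoscale cascade (avalanche) detection from pixel ΔF/F.

A pixel is active when its ΔF/F exceeds k× its own standard deviation
(default k = 5).  Within each frame, connected components of at least
``min_pixels`` active pixels (default 3) are retained as clusters; smaller
components are treated as inactive.  Clusters are then linked across
consecutive frames: a cascade starts with a cluster whose pixels touch no
retained activity in the preceding frame, continues while some cluster in the
next frame is spatially contiguous (overlapping or adjacent under the chosen
connectivity) with its current-frame pixels, and ends the first frame this
fails — no temporal gap is tolerated.  A cluster contiguous with several
ongoing cascades merges them, so one cascade is always one connected
spatiotemporal object.  Cascade size is the cumulative number of
(pixel, frame) activations; a pixel active in 5 frames contributes 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as _cc_label

from .preprocess import TraceMatrix

__all__ = [
    "BinaryRaster",
    "Cascade",
    "CascadeSummary",
    "binarize",
    "frame_clusters",
    "link_cascades",
    "detect_cascades",
    "summarize",
    "size_duration_distributions",
    "stack_summation",
]


@dataclass
class BinaryRaster:
    """Thresholded pixel activity: (frame, row, col) boolean stack."""

    active: np.ndarray
    threshold_k: float
    per_pixel_sd: np.ndarray  # (rows, cols); NaN outside the ROI
    roi: np.ndarray  # (rows, cols) bool
    fps: float

    @property
    def n_frames(self) -> int:
        return self.active.shape[0]


@dataclass
class Cascade:
    """One spatiotemporally contiguous activation event."""

    id: int
    start_frame: int
    end_frame: int  # inclusive
    size: int  # cumulative (pixel, frame) activations
    peak_extent: int  # max active pixels in any single frame
    footprint: set[tuple[int, int, int]] = field(repr=False)  # (frame, row, col)
    fps: float = 20.0

    @property
    def duration_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    @property
    def duration_s(self) -> float:
        return self.duration_frames / self.fps

    @property
    def centroid(self) -> tuple[float, float]:
        arr = np.array(sorted(self.footprint))
        return float(arr[:, 1].mean()), float(arr[:, 2].mean())


@dataclass
class CascadeSummary:
    n_cascades: int
    max_size: int
    max_duration_s: float
    size_list: list[int]
    duration_list: list[float]


def binarize(
    dff: TraceMatrix,
    roi: np.ndarray,
    k: float = 5.0,
    global_sd: bool = False,
    log=None,
) -> BinaryRaster:
    """Binarize pixel ΔF/F at k× the signal standard deviation (+k SD).

    SD is computed per pixel over that pixel's entire (post-discard) ΔF/F
    trace; ``global_sd=True`` instead pools one SD across all ROI pixels.
    Zero-variance or invalid pixels never activate and are logged.
    """
    if dff.unit_kind != "pixel":
        raise ValueError("binarize expects pixel traces")
    if k <= 0:
        raise ValueError("threshold multiplier k must be > 0")
    roi = np.asarray(roi).astype(bool)
    n_units, n_frames = dff.values.shape
    coords = dff.unit_coords.astype(int)

    sd = dff.values.std(axis=1, ddof=1)
    usable = dff.valid & np.isfinite(sd) & (sd > 0)
    if global_sd:
        pooled = float(np.sqrt(np.mean(sd[usable] ** 2))) if np.any(usable) else 0.0
        sd = np.full(n_units, pooled)
    n_dead = int(np.count_nonzero(~usable))
    if n_dead and log is not None:
        log.exclude(
            "binarize",
            f"{n_dead} pixel(s) with zero/undefined variance held inactive",
            units=np.nonzero(~usable)[0].tolist(),
        )

    active = np.zeros((n_frames,) + roi.shape, dtype=bool)
    hits = dff.values > k * sd[:, None]
    hits[~usable] = False
    active[:, coords[:, 0], coords[:, 1]] = hits.T
    active &= roi[None, :, :]

    sd_map = np.full(roi.shape, np.nan)
    sd_map[coords[usable, 0], coords[usable, 1]] = sd[usable]
    return BinaryRaster(
        active=active, threshold_k=k, per_pixel_sd=sd_map, roi=roi, fps=dff.fps
    )


def frame_clusters(
    frame: np.ndarray, min_pixels: int = 3, connectivity: int = 4
) -> list[np.ndarray]:
    """Connected components of ≥ min_pixels active pixels in one frame.

    Returns a list of (n, 2) integer coordinate arrays.  Components smaller
    than ``min_pixels`` are discarded entirely (their pixels count as
    inactive for cascade linking).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    lab = _cc_label(frame.astype(bool), connectivity=1 if connectivity == 4 else 2)
    out = []
    counts = np.bincount(lab.ravel())
    for cid in range(1, counts.size):
        if counts[cid] >= min_pixels:
            out.append(np.argwhere(lab == cid))
    return out


_OFFS4 = ((0, 0), (-1, 0), (1, 0), (0, -1), (0, 1))
_OFFS8 = _OFFS4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


class _UnionFind:
    def __init__(self) -> None:
        self.parent: list[int] = []

    def make(self) -> int:
        self.parent.append(len(self.parent))
        return len(self.parent) - 1

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> int:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri
        return ri


def link_cascades(
    clusters_per_frame: list[list[np.ndarray]],
    fps: float,
    connectivity: int = 4,
    shape: tuple[int, int] | None = None,
) -> list[Cascade]:
    """Link per-frame clusters into cascades (initiation/continuation/merge).

    ``clusters_per_frame[t]`` holds the retained clusters of frame ``t``;
    frames are consecutive by construction.  A frame-(t+1) cluster continues
    every cascade whose frame-t pixels it overlaps or neighbours under the
    configured connectivity; if that is several cascades they merge into one.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    offs = _OFFS4 if connectivity == 4 else _OFFS8
    if shape is None:
        mx = [0, 0]
        for clusters in clusters_per_frame:
            for cl in clusters:
                if len(cl):
                    mx[0] = max(mx[0], int(cl[:, 0].max()) + 1)
                    mx[1] = max(mx[1], int(cl[:, 1].max()) + 1)
        shape = (mx[0] + 1, mx[1] + 1)

    uf = _UnionFind()
    # per original id: list of (frame, cluster array); merged under find()
    records: dict[int, list[tuple[int, np.ndarray]]] = {}
    prev_map = np.full(shape, -1, dtype=np.int64)

    for t, clusters in enumerate(clusters_per_frame):
        cur_map = np.full(shape, -1, dtype=np.int64)
        for cl in clusters:
            cl = np.asarray(cl, dtype=np.int64)
            # collect cascade ids active at/adjacent to these pixels at t-1
            touched: set[int] = set()
            for dr, dc in offs:
                rr = cl[:, 0] + dr
                cc = cl[:, 1] + dc
                ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
                ids = prev_map[rr[ok], cc[ok]]
                for i in ids[ids >= 0]:
                    touched.add(uf.find(int(i)))
            if not touched:
                cid = uf.make()
                records[cid] = []
            else:
                it = iter(touched)
                cid = next(it)
                for other in it:
                    root = uf.union(cid, other)
                    if root != cid:
                        records[root].extend(records.pop(cid))
                        cid = root
                    else:
                        records[cid].extend(records.pop(other))
            records[cid].append((t, cl))
            cur_map[cl[:, 0], cl[:, 1]] = cid
        prev_map = cur_map

    cascades: list[Cascade] = []
    for cid in sorted(records, key=lambda c: min(f for f, _ in records[c])):
        recs = records[cid]
        frames = [f for f, _ in recs]
        per_frame: dict[int, int] = {}
        footprint: set[tuple[int, int, int]] = set()
        for f, cl in recs:
            per_frame[f] = per_frame.get(f, 0) + len(cl)
            for r, c in cl:
                footprint.add((f, int(r), int(c)))
        cascades.append(
            Cascade(
                id=len(cascades),
                start_frame=min(frames),
                end_frame=max(frames),
                size=len(footprint),
                peak_extent=max(per_frame.values()),
                footprint=footprint,
                fps=fps,
            )
        )
    return cascades


def detect_cascades(
    binary: BinaryRaster, min_pixels: int = 3, connectivity: int = 4
) -> list[Cascade]:
    """Full chain: per-frame clustering followed by temporal linking."""
    clusters = [
        frame_clusters(binary.active[t], min_pixels, connectivity)
        for t in range(binary.n_frames)
    ]
    return link_cascades(
        clusters, fps=binary.fps, connectivity=connectivity, shape=binary.roi.shape
    )


def summarize(cascades: list[Cascade]) -> CascadeSummary:
    """Per-recording cascade metrics: count and the maxima of size/duration."""
    sizes = [c.size for c in cascades]
    durations = [c.duration_s for c in cascades]
    return CascadeSummary(
        n_cascades=len(cascades),
        max_size=max(sizes) if sizes else 0,
        max_duration_s=max(durations) if durations else 0.0,
        size_list=sizes,
        duration_list=durations,
    )


def size_duration_distributions(
    cascades: list[Cascade], bins: int | np.ndarray = 20
) -> dict[str, np.ndarray]:
    """Probability and cumulative distributions of cascade size and duration.

    Probability histograms are normalized to sum to 1; ECDFs are evaluated at
    the sorted sample values and end at 1.
    """
    if not cascades:
        raise ValueError("need at least one cascade")
    out: dict[str, np.ndarray] = {}
    for name, vals in (
        ("size", np.array([c.size for c in cascades], dtype=float)),
        ("duration_s", np.array([c.duration_s for c in cascades])),
    ):
        hist, edges = np.histogram(vals, bins=bins)
        out[f"{name}_prob"] = hist / hist.sum()
        out[f"{name}_bin_edges"] = edges
        xs = np.sort(vals)
        out[f"{name}_ecdf_x"] = xs
        out[f"{name}_ecdf_y"] = np.arange(1, xs.size + 1) / xs.size
    return out


def stack_summation(binary: BinaryRaster) -> np.ndarray:
    """Per-pixel count of active frames (cumulative activation map)."""
    return binary.active.sum(axis=0).astype(np.int64)
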