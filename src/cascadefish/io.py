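"""File I/O, run configuration and run logging.

Conventions: coordinates are 0-based (row, col); stacks are frame-major.
Movies, masks and maps travel as TIFF; traces as compressed ``.npz`` with a
JSON sidecar; tables as CSV; summaries, ground truth and configs as JSON or
YAML.  JSON output is written with sorted keys and a fixed float format so
identical runs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .preprocess import Movie, TraceMatrix, DEFAULT_PIXEL_PITCH_UM

__all__ = [
    "RunConfig",
    "RunLog",
    "read_movie",
    "write_movie",
    "read_mask",
    "write_mask",
    "write_map",
    "save_traces",
    "load_traces",
    "write_json",
]


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the study's printed values."""

    fps: float = 20.0
    discard_frames: int = 100
    dff_window_s: float = 10.0
    threshold_k: float = 5.0
    min_cluster_pixels: int = 3
    connectivity: int = 4
    ensemble_window_frames: int = 10
    n_shuffles: int = 2000
    alpha: float = 0.001
    min_event_amp: float = 0.05
    min_event_corr: float = 0.85
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.dff_window_s <= 0 or self.threshold_k <= 0:
            raise ValueError("fps, dff_window_s and threshold_k must be positive")
        if self.discard_frames < 0 or self.min_cluster_pixels < 1:
            raise ValueError("discard_frames >= 0 and min_cluster_pixels >= 1 required")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.ensemble_window_frames < 1 or self.n_shuffles < 1:
            raise ValueError("ensemble_window_frames and n_shuffles must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


class RunLog:
    """Timestamped record of parameters, seeds, warnings and exclusions.

    Every exclusion decision made anywhere in the pipeline lands here so a
    run can be audited afterwards.
    """

    def __init__(self) -> None:
        self.records: list[dict] = []

    def _add(self, kind: str, stage: str, message: str, **extra) -> None:
        self.records.append(
            {
                "time": datetime.datetime.now().isoformat(timespec="seconds"),
                "kind": kind,
                "stage": stage,
                "message": message,
                **extra,
            }
        )

    def param(self, stage: str, message: str, **extra) -> None:
        self._add("param", stage, message, **extra)

    def warn(self, stage: str, message: str, **extra) -> None:
        self._add("warning", stage, message, **extra)

    def exclude(self, stage: str, message: str, **extra) -> None:
        self._add("exclusion", stage, message, **extra)

    @property
    def exclusions(self) -> list[dict]:
        return [r for r in self.records if r["kind"] == "exclusion"]

    def write(self, path: str | Path) -> None:
        lines = [
            f"[{r['time']}] {r['kind'].upper()} {r['stage']}: {r['message']}"
            for r in self.records
        ]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def _atomic_write(path: Path, writer) -> None:
    """Write via a temp file + rename so readers never see partial output."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=path.suffix)
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_movie(
    path: str | Path,
    fps: float = 20.0,
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM,
) -> Movie:
    """Read a multi-frame TIFF stack; metadata from a JSON sidecar if present.

    A sidecar ``<path>.json`` with keys ``fps`` / ``pixel_pitch_um``
    overrides the defaults.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"movie file not found: {path}")
    try:
        frames = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"could not read TIFF movie {path}: {exc}") from exc
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fps = meta.get("fps", fps)
        pixel_pitch_um = meta.get("pixel_pitch_um", pixel_pitch_um)
    if np.issubdtype(frames.dtype, np.signedinteger) and frames.min() < 0:
        raise ValueError(f"movie {path} contains negative fluorescence values")
    return Movie(frames=frames, fps=fps, pixel_pitch_um=pixel_pitch_um)


def write_movie(
    movie: Movie, path: str | Path, dtype: str = "uint16", sidecar: bool = True
) -> None:
    """Write a frame-major TIFF stack (rounded uint16 by default)."""
    path = Path(path)
    frames = movie.frames
    if dtype == "uint16":
        data = np.clip(np.rint(frames), 0, 65535).astype(np.uint16)
    elif dtype == "float32":
        data = frames.astype(np.float32)
    else:
        raise ValueError("dtype must be 'uint16' or 'float32'")
    _atomic_write(path, lambda tmp: tifffile.imwrite(tmp, data))
    if sidecar:
        write_json(
            {"fps": movie.fps, "pixel_pitch_um": movie.pixel_pitch_um},
            path.with_suffix(path.suffix + ".json"),
        )


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-frame mask TIFF (0/255 binary or integer labels)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    mask = tifffile.imread(path)
    if mask.ndim != 2:
        raise ValueError(f"mask {path} must be a single frame, got shape {mask.shape}")
    return mask


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    mask = np.asarray(mask)
    if mask.dtype == bool:
        mask = mask.astype(np.uint8) * 255
    _atomic_write(
        Path(path), lambda tmp: tifffile.imwrite(tmp, mask.astype(np.uint16))
    )


def write_map(map2d: np.ndarray, path: str | Path) -> None:
    """Write a 2-D summary map (e.g. stack summation) as 32-bit float TIFF."""
    _atomic_write(
        Path(path), lambda tmp: tifffile.imwrite(tmp, map2d.astype(np.float32))
    )


def save_traces(traces: TraceMatrix, path: str | Path) -> None:
    """Save a TraceMatrix as compressed .npz with a JSON metadata sidecar."""
    path = Path(path)
    _atomic_write(
        path,
        lambda tmp: np.savez_compressed(
            _ensure_npz(tmp),
            values=traces.values,
            unit_coords=traces.unit_coords,
            valid=traces.valid,
            unit_labels=(
                traces.unit_labels
                if traces.unit_labels is not None
                else np.array([])
            ),
        ),
    )
    write_json(
        {"fps": traces.fps, "unit_kind": traces.unit_kind, "n_units": traces.n_units},
        path.with_suffix(path.suffix + ".json"),
    )


def _ensure_npz(tmp: str) -> str:
    # np.savez_compressed appends .npz unless already present; pin the name.
    return tmp if tmp.endswith(".npz") else tmp


def load_traces(path: str | Path) -> TraceMatrix:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    with np.load(path) as z:
        labels = z["unit_labels"]
        return TraceMatrix(
            values=z["values"],
            unit_kind=meta["unit_kind"],
            unit_coords=z["unit_coords"],
            fps=meta["fps"],
            unit_labels=labels if labels.size else None,
            valid=z["valid"],
        )


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, newline-terminated."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    text = json.dumps(obj, indent=1, sort_keys=True, default=default) + "\n"
    _atomic_write(Path(path), lambda tmp: Path(tmp).write_text(text))
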