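"""End-to-end pipelines chaining preprocessing, detection and summaries."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import cascade as casc_mod
from . import ensemble as ens_mod
from .io import (
    RunConfig,
    RunLog,
    read_mask,
    read_movie,
    write_json,
    write_map,
)
from .preprocess import Movie, compute_dff, discard_onset, extract_traces

__all__ = ["run_mesoscale", "run_microscale", "run_pipeline"]


def _prep(movie: Movie, roi: np.ndarray, config: RunConfig, log: RunLog):
    movie = discard_onset(movie, config.discard_frames)
    raw = extract_traces(movie, roi)
    return compute_dff(raw, config.dff_window_s, log=log)


def run_mesoscale(
    movie: Movie, roi: np.ndarray, config: RunConfig, out_dir: str | Path | None = None
) -> dict:
    """Movie + binary tectum mask → cascades, summary, stack-summation map."""
    log = RunLog()
    log.param("config", "run_mesoscale", **dataclasses.asdict(config))
    dff = _prep(movie, roi.astype(bool), config, log)
    binary = casc_mod.binarize(dff, roi.astype(bool), k=config.threshold_k, log=log)
    cascades = casc_mod.detect_cascades(
        binary,
        min_pixels=config.min_cluster_pixels,
        connectivity=config.connectivity,
    )
    summary = casc_mod.summarize(cascades)
    result = {
        "cascades": cascades,
        "summary": summary,
        "stack_summation": casc_mod.stack_summation(binary),
        "binary": binary,
        "dff": dff,
        "log": log,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = [
            {
                "id": c.id,
                "start_frame": c.start_frame,
                "end_frame": c.end_frame,
                "duration_frames": c.duration_frames,
                "duration_s": c.duration_s,
                "size": c.size,
                "peak_extent": c.peak_extent,
                "centroid_row": c.centroid[0],
                "centroid_col": c.centroid[1],
            }
            for c in cascades
        ]
        pd.DataFrame(
            rows,
            columns=[
                "id",
                "start_frame",
                "end_frame",
                "duration_frames",
                "duration_s",
                "size",
                "peak_extent",
                "centroid_row",
                "centroid_col",
            ],
        ).to_csv(out / "cascades.csv", index=False)
        write_json(
            {
                "n_cascades": summary.n_cascades,
                "max_size": summary.max_size,
                "max_duration_s": summary.max_duration_s,
                "size_list": summary.size_list,
                "duration_list": summary.duration_list,
            },
            out / "cascade_summary.json",
        )
        write_map(result["stack_summation"], out / "stack_summation.tif")
        log.write(out / "run.log")
    return result


def run_microscale(
    movie_or_traces,
    roi: np.ndarray | None,
    config: RunConfig,
    out_dir: str | Path | None = None,
) -> dict:
    """Movie + neuron-label mask (or a precomputed ΔF/F TraceMatrix) →
    events, coactivity, surrogate null, ensembles."""
    log = RunLog()
    log.param("config", "run_microscale", **dataclasses.asdict(config))
    if isinstance(movie_or_traces, Movie):
        if roi is None:
            raise ValueError("a neuron-label ROI mask is required with a movie")
        dff = _prep(movie_or_traces, roi, config, log)
    else:
        dff = movie_or_traces
    raster = ens_mod.detect_events_matrix(
        dff, min_amp=config.min_event_amp, min_corr=config.min_event_corr
    )
    counts = ens_mod.coactivity(raster, config.ensemble_window_frames)
    null = ens_mod.build_null(
        raster,
        n_shuffles=config.n_shuffles,
        window_frames=config.ensemble_window_frames,
        seed=config.seed,
        alpha=config.alpha,
        log=log,
    )
    ensembles = ens_mod.call_ensembles(
        counts, null, raster, pixel_pitch_um=config.pixel_pitch_um
    )
    summary = ens_mod.ensemble_summary(ensembles, dff.n_frames / dff.fps)
    result = {
        "events": raster,
        "coactivity": counts,
        "null": null,
        "ensembles": ensembles,
        "summary": summary,
        "dff": dff,
        "log": log,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = [
            {
                "first_frame": e.frame_span[0],
                "last_frame": e.frame_span[1],
                "size": e.size,
                "centroid_row": e.centroid[0],
                "centroid_col": e.centroid[1],
                "members": ";".join(str(m) for m in sorted(e.member_neuron_ids)),
            }
            for e in ensembles
        ]
        pd.DataFrame(
            rows,
            columns=[
                "first_frame",
                "last_frame",
                "size",
                "centroid_row",
                "centroid_col",
                "members",
            ],
        ).to_csv(out / "ensembles.csv", index=False)
        write_json(
            {
                "n_ensembles": summary.n_ensembles,
                "avg_size": summary.avg_size,
                "rate_per_min": summary.rate_per_min,
                "critical_value": null.critical_value,
                "n_shuffles": null.n_shuffles,
                "alpha": null.alpha,
                "seed": null.seed,
            },
            out / "ensemble_summary.json",
        )
        log.write(out / "run.log")
    return result


def run_pipeline(config: RunConfig, mode: str, out_dir: str | Path) -> dict:
    """File-driven pipeline: reads paths from ``config.paths``.

    Required paths: ``movie`` (multi-frame TIFF) and ``roi`` (binary mask at
    mesoscale, neuron labels at microscale).
    """
    if mode not in ("mesoscale", "microscale"):
        raise ValueError("mode must be 'mesoscale' or 'microscale'")
    movie_path = config.paths.get("movie")
    roi_path = config.paths.get("roi")
    if movie_path is None or roi_path is None:
        raise ValueError("config.paths must provide 'movie' and 'roi'")
    movie = read_movie(movie_path, fps=config.fps, pixel_pitch_um=config.pixel_pitch_um)
    roi = read_mask(roi_path)
    if mode == "mesoscale":
        return run_mesoscale(movie, roi.astype(bool), config, out_dir)
    return run_microscale(movie, roi, config, out_dir)
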