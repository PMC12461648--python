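"""End-to-end orchestration: segment -> track -> FRAP -> subcompartments.

``run_pipeline`` consumes a movie (path or in-memory), derives or reads
the bleach/control/background ROIs, runs every analysis stage, and
returns a result bundle of tidy tables; with an output directory it also
writes the CSV/JSON artifacts and a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import __version__
from .config import PipelineConfig
from .frap_kinetics import (
    extract_trace,
    fit_one_phase,
    immobile_fraction,
    normalize_frap,
    partition_periods,
    percent_recovered_at,
)
from .io import read_movie, roi_mask_from_spec
from .phantom import Movie
from .segmentation import (
    focus_displacement,
    segment_foci,
    segment_nucleus,
    sum_project_z,
    track_foci,
)
from .subcompartments import (
    classify_compartments,
    classify_contour,
    decompose_subregions,
    per_region_kinetics,
    recovery_map,
)

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _default_rois(movie: Movie, nucleus_mask: np.ndarray) -> dict[str, np.ndarray]:
    """Bleach mask from movie metadata; control = nucleus minus the
    (dilated) bleach ROI; background = outside the (dilated) nucleus."""
    if movie.bleach is None:
        raise ValueError("movie has no bleach metadata and no ROI file was given")
    rr, cc = np.mgrid[0 : movie.shape[0], 0 : movie.shape[1]]
    x = cc * movie.pixel_size
    y = rr * movie.pixel_size
    bx, by = movie.bleach.center
    bleach = (x - bx) ** 2 + (y - by) ** 2 <= movie.bleach.radius**2
    pad = max(3, int(round(500.0 / movie.pixel_size)))
    control = nucleus_mask & ~ndimage.binary_dilation(bleach, iterations=pad)
    background = ~ndimage.binary_dilation(nucleus_mask, iterations=pad)
    return {"bleach": bleach, "control": control, "background": background}


def run_pipeline(
    movie,
    config: PipelineConfig | None = None,
    rois: dict | None = None,
    out_dir=None,
) -> dict:
    """Run the full analysis; see module docstring.

    ``rois`` may map names to boolean masks or to ROI specs in µm
    (disk/polygon dicts).  Deterministic for fixed inputs and config.
    """
    config = config or PipelineConfig()
    t_wall = time.time()

    # --- load -------------------------------------------------------------
    try:
        if not isinstance(movie, Movie):
            movie = read_movie(movie)
    except Exception as exc:
        raise PipelineError("load", exc) from exc

    frames2d = np.stack([sum_project_z(s) for s in movie.frames])
    pre = movie.times < 0
    px_um = movie.pixel_size / 1000.0

    # --- segmentation -----------------------------------------------------
    try:
        pre_mean = frames2d[pre].mean(axis=0) if pre.any() else frames2d[0]
        nucleus_mask, nucleus_px = segment_nucleus(
            pre_mean, smooth_sigma=config.segmentation.nucleus_smooth_sigma_px
        )
        seg = config.segmentation
        per_frame_foci = [
            segment_foci(
                frames2d[i],
                nucleus_mask,
                pixel_size_um=px_um,
                intensity_threshold=seg.intensity_threshold,
                min_area_px=seg.min_area_px,
                mean_intensity_min=seg.mean_intensity_min,
                frame_index=i,
            )
            for i in range(len(frames2d))
        ]
        tracks = track_foci(per_frame_foci, max_jump_um=seg.max_jump_um)
    except Exception as exc:
        raise PipelineError("segmentation", exc) from exc

    # --- ROIs -------------------------------------------------------------
    try:
        if rois is None:
            masks = _default_rois(movie, nucleus_mask)
        else:
            masks = {}
            for name in ("bleach", "control", "background"):
                spec = rois[name]
                masks[name] = (
                    np.asarray(spec, dtype=bool)
                    if isinstance(spec, np.ndarray)
                    else roi_mask_from_spec(spec, movie.shape, movie.pixel_size)
                )
    except Exception as exc:
        raise PipelineError("rois", exc) from exc

    # --- per-focus FRAP + subcompartments ----------------------------------
    foci_rows, fit_rows, call_rows, traces = [], [], [], {}
    call_objects = []
    subregion_labels: dict[int, np.ndarray] = {}
    pre_idx = np.nonzero(pre)[0]
    for tr in tracks:
        pre_foci = [f for f in tr.foci if f.frame_index in set(pre_idx)]
        if not pre_foci:
            continue
        ref = pre_foci[-1]
        roi_mask = ref.mask & masks["bleach"]
        if roi_mask.sum() < 4:
            continue
        control = masks["control"] & ~ref.mask
        try:
            trace = extract_trace(movie, roi_mask, control, masks["background"])
            ntrace = normalize_frap(trace, denom_tol=config.frap.denom_tol)
            fit = fit_one_phase(ntrace, t_start=config.frap.t_start_s)
            recovery_seg, plateau_seg = partition_periods(ntrace)
        except Exception as exc:
            raise PipelineError("frap", exc) from exc
        traces[tr.track_id] = ntrace
        row = {
            "focus_id": tr.track_id,
            "k_per_s": fit.k,
            "t_half_s": fit.t_half,
            "f_post": fit.f_post,
            "plateau": fit.plateau,
            "rss": fit.rss,
            "converged": fit.converged,
        }
        if fit.converged:
            row["immobile_fraction"] = immobile_fraction(fit)
            row["percent_recovered_60s"] = percent_recovered_at(fit, 60.0)
        fit_rows.append(row)

        try:
            # the focus is invisible (below threshold) right after a deep
            # bleach; fall back to the pre-bleach reference mask for frames
            # where the track has no segmented focus
            per_frame_masks = []
            for i in range(len(movie.times)):
                f = tr.at_frame(i)
                if f is not None and (f.mask & ref.mask).sum() >= 0.1 * ref.mask.sum():
                    per_frame_masks.append(f.mask)
                else:
                    per_frame_masks.append(ref.mask)
            rmap = recovery_map(
                movie, per_frame_masks, control, masks["background"], focus_id=tr.track_id
            )
            sub = config.subcompartments
            labels = decompose_subregions(
                rmap,
                mode=sub.mode,
                min_region_px=sub.min_region_px,
                lag_contrast_s=sub.lag_contrast_s,
                smooth_sigma_px=sub.smooth_sigma_px,
            )
            n_regions = int(labels.max())
            fits = per_region_kinetics(rmap, labels, min_region_px=1)
            call = classify_compartments(
                n_regions, fits, cv_threshold=sub.cv_threshold, focus_id=tr.track_id
            )
            contour = (
                classify_contour(tr, s_thr=sub.s_thr, iou_thr=sub.iou_thr, times=movie.times)
                if len(tr.foci) >= 3
                else "unclassified"
            )
            call.contour_call = contour
        except Exception as exc:
            raise PipelineError("subcompartments", exc) from exc
        call_objects.append(call)
        subregion_labels[tr.track_id] = labels
        call_rows.append(
            {
                "focus_id": tr.track_id,
                "n_subregions": call.n_subregions,
                "heterogeneity_index": call.heterogeneity_index,
                "call": call.call,
                "contour_call": contour,
            }
        )
        try:
            disp = focus_displacement(tr, movie.times)
        except ValueError:
            disp = np.nan
        for f in tr.foci:
            foci_rows.append(
                {
                    "focus_id": tr.track_id,
                    "frame": f.frame_index,
                    "time_s": movie.times[f.frame_index],
                    "area_um2": f.area_um2,
                    "centroid_x_um": f.centroid_um[0],
                    "centroid_y_um": f.centroid_um[1],
                    "perimeter_um": f.perimeter_um,
                    "hull_perimeter_um": f.hull_perimeter_um,
                    "sphericity": f.sphericity,
                    "mean_intensity": f.mean_intensity,
                    "displacement_pre_post_um": disp,
                }
            )

    n_pre_foci = len(per_frame_foci[pre_idx[-1]]) if len(pre_idx) else 0
    bundle = {
        "nucleus_area_um2": nucleus_px * px_um**2,
        "focus_count_prebleach": n_pre_foci,
        "foci": pd.DataFrame(foci_rows),
        "fits": pd.DataFrame(fit_rows),
        "calls": pd.DataFrame(call_rows),
        "call_objects": call_objects,
        "subregion_labels": subregion_labels,
        "traces": traces,
        "tracks": tracks,
        "nucleus_mask": nucleus_mask,
        "roi_masks": masks,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        bundle["foci"].to_csv(out_dir / "foci.csv", index=False)
        bundle["fits"].to_csv(out_dir / "frap_fits.csv", index=False)
        bundle["calls"].to_csv(out_dir / "compartment_calls.csv", index=False)
        rows = []
        for fid, ntrace in traces.items():
            for t, v in zip(ntrace.times, ntrace.value):
                rows.append({"focus_id": fid, "time_s": t, "normalized": v})
        pd.DataFrame(rows).to_csv(out_dir / "normalized_traces.csv", index=False)
        if subregion_labels:
            import tifffile

            for fid, labels in subregion_labels.items():
                tifffile.imwrite(
                    out_dir / f"subregions_focus{fid}.tif", labels.astype(np.uint16)
                )
        manifest = {
            "software": f"frapsr {__version__}",
            "config_hash": config.digest(),
            "config": config.to_dict(),
            "seed": config.seed,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "wall_time_s": round(time.time() - t_wall, 3),
            "n_frames": int(movie.n_frames),
            "input_checksum": _movie_checksum(movie),
        }
        with open(out_dir / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        bundle["manifest"] = manifest
    return bundle


def _movie_checksum(movie: Movie) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(movie.frames).tobytes())
    h.update(np.ascontiguousarray(movie.times).tobytes())
    return h.hexdigest()[:16]
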