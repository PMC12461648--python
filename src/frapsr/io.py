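"""Movie and table I/O: multi-page TIFF with a YAML sidecar.

A movie is stored as a 16-bit multi-page TIFF (frames in acquisition
order, z-planes as consecutive pages) plus a YAML sidecar carrying pixel
size, frame times, z-plane count, and the bleach event.  Ground truth
from the simulator is written as a label TIFF plus a kinetics CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .phantom import BleachEvent, GroundTruth, Movie

__all__ = ["write_movie", "read_movie", "write_ground_truth", "roi_mask_from_spec"]

_SIDECAR_REQUIRED = ("pixel_size_nm", "frame_times_s", "n_z")


def write_movie(movie: Movie, tiff_path, sidecar_path=None) -> Path:
    """Write frames (scaled/clipped to uint16) and the metadata sidecar."""
    tiff_path = Path(tiff_path)
    if sidecar_path is None:
        sidecar_path = tiff_path.with_suffix(".yaml")
    t, z, h, w = movie.frames.shape
    data = np.clip(np.round(movie.frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(tiff_path, data.reshape(t * z, h, w))
    meta = {
        "pixel_size_nm": float(movie.pixel_size),
        "frame_times_s": [float(x) for x in movie.times],
        "n_z": int(z),
    }
    if movie.bleach is not None:
        meta["bleach"] = {
            "center_nm": [float(c) for c in movie.bleach.center],
            "radius_nm": float(movie.bleach.radius),
            "depth": float(movie.bleach.depth),
            "time_s": float(movie.bleach.time),
        }
    scene = movie.provenance.get("scene")
    if scene is not None and getattr(scene, "preset_name", None):
        meta["preset"] = scene.preset_name
    with open(sidecar_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return tiff_path


def read_movie(tiff_path, sidecar_path=None) -> Movie:
    """Read a TIFF + sidecar pair back into a Movie.

    Missing sidecar keys and TIFF/sidecar frame-count mismatches are
    reported explicitly.
    """
    tiff_path = Path(tiff_path)
    if sidecar_path is None:
        sidecar_path = tiff_path.with_suffix(".yaml")
    try:
        pages = tifffile.imread(tiff_path)
    except Exception as exc:
        raise ValueError(f"cannot read TIFF {tiff_path}: {exc}") from exc
    with open(sidecar_path) as fh:
        meta = yaml.safe_load(fh)
    missing = [k for k in _SIDECAR_REQUIRED if k not in meta]
    if missing:
        raise ValueError(f"sidecar {sidecar_path} missing keys: {missing}")
    times = np.asarray(meta["frame_times_s"], dtype=float)
    n_z = int(meta["n_z"])
    pages = np.atleast_3d(pages)
    if pages.ndim == 2:
        pages = pages[None]
    if len(pages) != len(times) * n_z:
        raise ValueError(
            f"frame-count mismatch: TIFF has {len(pages)} pages, sidecar "
            f"implies {len(times)} frames x {n_z} z-planes"
        )
    frames = pages.reshape(len(times), n_z, *pages.shape[-2:]).astype(float)
    bleach = None
    if "bleach" in meta:
        b = meta["bleach"]
        bleach = BleachEvent(
            center=tuple(b["center_nm"]),
            radius=float(b["radius_nm"]),
            depth=float(b.get("depth", 1.0)),
            time=float(b.get("time_s", 0.0)),
        )
    return Movie(
        frames=frames,
        times=times,
        pixel_size=float(meta["pixel_size_nm"]),
        bleach=bleach,
        provenance={"source": str(tiff_path), "preset": meta.get("preset")},
    )


def write_ground_truth(truth: GroundTruth, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out_dir / "truth_focus_labels.tif", truth.focus_labels.astype(np.uint16))
    tifffile.imwrite(out_dir / "truth_subcomp_labels.tif", truth.subcomp_labels.astype(np.uint16))
    truth.kinetics.to_csv(out_dir / "truth_kinetics.csv", index=False)
    truth.centroids.to_csv(out_dir / "truth_centroids.csv", index=False)


def roi_mask_from_spec(spec: dict, shape, pixel_size_nm: float) -> np.ndarray:
    """Boolean mask for a ROI spec: disk or polygon, coordinates in µm."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    x_um = cc * pixel_size_nm / 1000.0
    y_um = rr * pixel_size_nm / 1000.0
    kind = spec.get("type", "disk")
    if kind == "disk":
        cx, cy = spec["center_um"]
        r = spec["radius_um"]
        return (x_um - cx) ** 2 + (y_um - cy) ** 2 <= r**2
    if kind == "polygon":
        from skimage.draw import polygon2mask

        verts = np.asarray(spec["vertices_um"], dtype=float)
        poly_rc = np.column_stack([verts[:, 1], verts[:, 0]]) * 1000.0 / pixel_size_nm
        return polygon2mask(shape, poly_rc)
    raise ValueError(f"unknown ROI type {kind!r}")


def read_rois(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
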