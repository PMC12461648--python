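"""Calibrate contour-classifier thresholds on the phantom presets.

Runs the compact and amorphous presets over a set of seeds, collects the
per-track mean pre-bleach sphericity and frame-to-frame mask IoU, and
prints class summaries plus the midpoint thresholds between the class
extremes.  The defaults stored in ``frapsr.config.SubcompartmentConfig``
are the outputs of this script.

Usage: python scripts/calibrate_thresholds.py [--seeds N]
"""

import argparse

import numpy as np

from frapsr.phantom import imaging_preset, preset_bleach, preset_scene, simulate_frap_movie
from frapsr.pipeline import run_pipeline


def collect(preset: str, seeds: int):
    sph, iou = [], []
    for seed in range(seeds):
        scene = preset_scene(preset)
        imaging = imaging_preset("disim", seed=seed, n_z=1)
        movie, _ = simulate_frap_movie(scene, imaging, preset_bleach(scene))
        bundle = run_pipeline(movie)
        pre = movie.times < 0
        for tr in bundle["tracks"]:
            foci = [f for f in tr.foci if pre[f.frame_index]]
            if len(foci) < 3:
                continue
            sph.append(np.mean([f.sphericity for f in foci]))
            pair_iou = [
                (a.mask & b.mask).sum() / (a.mask | b.mask).sum()
                for a, b in zip(foci[:-1], foci[1:])
            ]
            iou.append(np.mean(pair_iou))
    return np.array(sph), np.array(iou)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seeds", type=int, default=12)
    args = ap.parse_args()

    stats = {}
    for preset in ("untreated_compact", "untreated_amorphous"):
        sph, iou = collect(preset, args.seeds)
        stats[preset] = (sph, iou)
        print(
            f"{preset:22s} sphericity {sph.mean():.3f} "
            f"[{sph.min():.3f}, {sph.max():.3f}]  "
            f"IoU {iou.mean():.3f} [{iou.min():.3f}, {iou.max():.3f}]"
        )
    s_thr = 0.5 * (stats["untreated_compact"][0].min() + stats["untreated_amorphous"][0].max())
    iou_thr = 0.5 * (stats["untreated_compact"][1].min() + stats["untreated_amorphous"][1].max())
    print(f"suggested s_thr   = {s_thr:.3f} (amorphous if mean sphericity below)")
    print(f"suggested iou_thr = {iou_thr:.3f} (amorphous if mean frame-to-frame IoU below)")


if __name__ == "__main__":
    main()
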