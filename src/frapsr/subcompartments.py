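"""Spatially resolved recovery: per-pixel maps, subregion decomposition,
per-region kinetics, and the single- vs multi-compartment call.

An amorphous focus containing subcompartments with distinct exchange
rates recovers unevenly after photobleaching.  The per-pixel normalized
recovery map makes this measurable: the mask is decomposed into candidate
subregions (by the time-to-half-recovery lag map, by a PCA split, or by
tiling), each region's mean curve is fit with the one-phase association
model, and the spread of the per-region half-times (population CV)
decides between a single- and a multi-compartment focus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import h_maxima, h_minima

from .frap_kinetics import FitResult, NormalizedTrace, fit_one_phase
from .segmentation import sum_project_z

__all__ = [
    "RecoveryMap",
    "CompartmentCall",
    "recovery_map",
    "region_curve",
    "whole_focus_curve",
    "area_weighted_mean_curve",
    "decompose_subregions",
    "per_region_kinetics",
    "heterogeneity_index",
    "classify_compartments",
    "classify_contour",
]


@dataclass
class RecoveryMap:
    """Per-pixel normalized recovery values over the focus mask.

    ``values`` has shape (T_post, H, W) with NaN outside the mask (and at
    pixels that leave the mask through shape change); ``pre_mean`` is the
    per-pixel pre-bleach mean image used as the pixelwise baseline.
    """

    focus_id: int
    times: np.ndarray  # post-bleach times, s
    values: np.ndarray  # (T_post, H, W)
    mask: np.ndarray  # (H, W) reference mask (pre-bleach)
    pre_mean: np.ndarray  # (H, W)
    Fb: np.ndarray  # per-frame background, post-bleach
    truncated: bool = False


@dataclass
class CompartmentCall:
    focus_id: int
    n_subregions: int
    fits: list[FitResult]
    heterogeneity_index: float
    call: str  # "single" | "multi"
    contour_call: str | None = None  # "compact" | "amorphous" | None


def recovery_map(
    movie,
    focus_masks,
    control_mask,
    background_mask,
    focus_id: int = 0,
) -> RecoveryMap:
    """Per-pixel double normalization over a (possibly changing) focus mask.

    ``focus_masks`` is either a single 2D mask or a per-frame sequence of
    masks (len == n_frames, None for frames where the focus was lost).
    The control and background series are shared across pixels; a pixel's
    own pre-bleach mean is its baseline.  Frames where the focus was lost
    truncate the map (flagged).
    """
    frames2d = np.stack([sum_project_z(s) for s in movie.frames])
    times = movie.times
    pre = times < 0
    post = ~pre
    if pre.sum() < 2:
        raise ValueError("need >= 2 pre-bleach frames")

    if isinstance(focus_masks, np.ndarray) and focus_masks.ndim == 2:
        masks = [focus_masks] * len(times)
    else:
        masks = list(focus_masks)
        if len(masks) != len(times):
            raise ValueError("need one focus mask per frame (None where lost)")

    Fb = np.array([frames2d[i][background_mask].mean() for i in range(len(times))])
    Fc = np.array([frames2d[i][control_mask].mean() for i in range(len(times))])
    Fc0 = Fc[pre].mean()
    r = (Fc - Fb) / (Fc0 - Fb)

    ref_mask = np.zeros(movie.shape, dtype=bool)
    for i in np.nonzero(pre)[0]:
        if masks[i] is not None:
            ref_mask |= masks[i]
    if not ref_mask.any():
        raise ValueError("no pre-bleach focus mask available")
    pre_mean = frames2d[pre].mean(axis=0)

    truncated = False
    post_idx = np.nonzero(post)[0]
    values = np.full((len(post_idx),) + movie.shape, np.nan)
    denom = pre_mean - Fb[pre].mean()
    for j, i in enumerate(post_idx):
        if masks[i] is None:
            truncated = True
            values = values[:j]
            post_idx = post_idx[:j]
            break
        m = ref_mask & masks[i]
        vals = (frames2d[i][m] - Fb[i]) / denom[m]
        values[j][m] = vals / r[i]
    return RecoveryMap(
        focus_id=focus_id,
        times=times[post_idx],
        values=values,
        mask=ref_mask,
        pre_mean=pre_mean,
        Fb=Fb[post_idx],
        truncated=truncated,
    )


def region_curve(rmap: RecoveryMap, region_mask) -> NormalizedTrace:
    """Mean normalized recovery over a subregion, ignoring missing pixels."""
    region_mask = np.asarray(region_mask, dtype=bool) & rmap.mask
    if not region_mask.any():
        raise ValueError("region has no pixels inside the focus mask")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vals = np.nanmean(rmap.values[:, region_mask], axis=1)
    return NormalizedTrace(rmap.times, vals)


def whole_focus_curve(rmap: RecoveryMap) -> NormalizedTrace:
    """ROI-mean normalized curve: mean intensity first, then normalization
    by the ROI-mean baseline (matches the whole-focus FRAP trace)."""
    out = np.empty(len(rmap.times))
    denom0 = None
    for j in range(len(rmap.times)):
        m = np.isfinite(rmap.values[j]) & rmap.mask
        w = rmap.pre_mean[m] - rmap.Fb[j]
        out[j] = np.sum(rmap.values[j][m] * w) / np.sum(w)
    return NormalizedTrace(rmap.times, out)


def area_weighted_mean_curve(rmap: RecoveryMap, labels) -> NormalizedTrace:
    """Partition identity: the whole-focus curve reassembled from subregion
    curves with weights proportional to area x baseline intensity."""
    labels = np.asarray(labels)
    out = np.zeros(len(rmap.times))
    for j in range(len(rmap.times)):
        num = den = 0.0
        for lab in np.unique(labels[labels > 0]):
            m = (labels == lab) & np.isfinite(rmap.values[j])
            if not m.any():
                continue
            w = float(np.sum(rmap.pre_mean[m] - rmap.Fb[j]))
            num += np.mean(rmap.values[j][m] * (rmap.pre_mean[m] - rmap.Fb[j])) * m.sum()
            den += w
        out[j] = num / den
    return NormalizedTrace(rmap.times, out)


def _lag_map(rmap: RecoveryMap, smooth_sigma_px: float) -> np.ndarray:
    """Per-pixel time to half its own plateau (first crossing), after a
    light spatial smoothing of the map; NaN where undefined."""
    vals = rmap.values.copy()
    if smooth_sigma_px > 0:
        for j in range(len(vals)):
            filled = np.where(np.isfinite(vals[j]), vals[j], 0.0)
            support = ndimage.gaussian_filter(np.isfinite(vals[j]).astype(float), smooth_sigma_px)
            smoothed = ndimage.gaussian_filter(filled, smooth_sigma_px)
            with np.errstate(invalid="ignore", divide="ignore"):
                vals[j] = np.where(support > 1e-6, smoothed / support, np.nan)
            vals[j][~rmap.mask] = np.nan
    n_tail = max(2, len(vals) // 4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        plateau = np.nanmean(vals[-n_tail:], axis=0)
    lag = np.full(rmap.mask.shape, np.nan)
    t = rmap.times
    for (rr, cc) in zip(*np.nonzero(rmap.mask)):
        series = vals[:, rr, cc]
        fin = np.isfinite(series)
        if not fin.any() or not np.isfinite(plateau[rr, cc]):
            continue
        floor = series[np.argmax(fin)]  # first finite frame is the floor
        half_val = floor + 0.5 * (plateau[rr, cc] - floor)
        above = np.where(fin, series >= half_val, False)
        idx = np.argmax(above)
        if not above[idx]:
            lag[rr, cc] = t[-1]
        elif idx == 0:
            lag[rr, cc] = t[0]
        else:
            y0, y1 = series[idx - 1], series[idx]
            if not (np.isfinite(y0) and np.isfinite(y1)) or y1 == y0:
                lag[rr, cc] = t[idx]
            else:
                frac = (half_val - y0) / (y1 - y0)
                lag[rr, cc] = t[idx - 1] + frac * (t[idx] - t[idx - 1])
    return lag


def decompose_subregions(
    rmap: RecoveryMap,
    mode: str = "watershed_lag",
    min_region_px: int = 20,
    lag_contrast_s: float = 5.0,
    smooth_sigma_px: float = 2.0,
    grid_shape: tuple[int, int] = (3, 3),
) -> np.ndarray:
    """Deterministic partition of the focus mask into candidate subregions.

    - ``watershed_lag``: watershed of the per-pixel time-to-half-recovery
      map, seeded at its h-extrema (h = ``lag_contrast_s``); a lag map
      flat to within h yields a single region.
    - ``halves_pca``: split along the first principal axis of the mask.
    - ``grid``: tile the mask bounding box.

    Returns an integer label image (0 outside the mask).
    """
    mask = rmap.mask
    labels = np.zeros(mask.shape, dtype=np.int32)
    if mask.sum() < min_region_px:
        labels[mask] = 1
        return labels

    if mode == "grid":
        ys, xs = np.nonzero(mask)
        ry = np.clip(((ys - ys.min()) * grid_shape[0]) // (ys.max() - ys.min() + 1), 0, grid_shape[0] - 1)
        rx = np.clip(((xs - xs.min()) * grid_shape[1]) // (xs.max() - xs.min() + 1), 0, grid_shape[1] - 1)
        tile = ry * grid_shape[1] + rx
        for i, t in enumerate(np.unique(tile)):
            labels[ys[tile == t], xs[tile == t]] = i + 1
        return _relabel_connected(labels, mask, min_region_px=1)

    if mode == "halves_pca":
        ys, xs = np.nonzero(mask)
        pts = np.column_stack([xs, ys]).astype(float)
        pts -= pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts, full_matrices=False)
        proj = pts @ vt[0]
        labels[ys[proj <= np.median(proj)], xs[proj <= np.median(proj)]] = 1
        labels[ys[proj > np.median(proj)], xs[proj > np.median(proj)]] = 2
        return _relabel_connected(labels, mask, min_region_px)

    if mode != "watershed_lag":
        raise ValueError(f"unknown decomposition mode {mode!r}")

    lag = _lag_map(rmap, smooth_sigma_px)
    finite = np.isfinite(lag) & mask
    if finite.sum() < min_region_px:
        labels[mask] = 1
        return labels
    filled = np.where(finite, lag, np.nanmedian(lag[finite]))
    h = lag_contrast_s
    lo = h_minima(filled, h).astype(bool) & mask
    hi = h_maxima(filled, h).astype(bool) & mask
    # a flat map (extrema shallower than h, or overlapping) -> one region
    if not lo.any() or not hi.any() or np.any(lo & hi):
        labels[mask] = 1
        return labels
    levels = sorted(
        {float(np.mean(filled[m])) for ext in (lo, hi) for m in _components(ext)}
    )
    # collapse levels closer than the contrast scale h
    merged_levels: list[float] = []
    for lv in levels:
        if merged_levels and lv - merged_levels[-1] < h:
            merged_levels[-1] = 0.5 * (merged_levels[-1] + lv)
        else:
            merged_levels.append(lv)
    if len(merged_levels) < 2:
        labels[mask] = 1
        return labels
    # quantize the lag map to the nearest extremal level; connected
    # components of each level band are the candidate subregions
    lv = np.asarray(merged_levels)
    assign = np.argmin(np.abs(filled[..., None] - lv[None, None, :]), axis=-1)
    labels = np.where(mask, assign + 1, 0).astype(np.int32)
    labels = _merge_similar_lag(labels, lag, h)
    return _relabel_connected(labels, mask, min_region_px)


def _components(binary):
    lab, n = ndimage.label(binary)
    return [lab == i for i in range(1, n + 1)]


def _merge_similar_lag(labels, lag, h):
    """Merge adjacent regions whose mean lags differ by less than h."""
    labs = [l for l in np.unique(labels) if l > 0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = {l: np.nanmean(lag[labels == l]) for l in labs}
    changed = True
    while changed and len(labs) > 1:
        changed = False
        for a in list(labs):
            for b in list(labs):
                if a >= b:
                    continue
                grown = ndimage.binary_dilation(labels == a)
                if not np.any(grown & (labels == b)):
                    continue
                da, db = means[a], means[b]
                if np.isnan(da) or np.isnan(db) or abs(da - db) < h:
                    labels[labels == b] = a
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        means[a] = np.nanmean(lag[labels == a])
                    labs.remove(b)
                    changed = True
                    break
            if changed:
                break
    return labels


def _relabel_connected(labels, mask, min_region_px):
    """Split labels into connected components and absorb tiny fragments
    into the largest neighbouring region."""
    out = np.zeros_like(labels)
    nxt = 1
    for l in np.unique(labels[labels > 0]):
        comp, n = ndimage.label(labels == l)
        for i in range(1, n + 1):
            out[comp == i] = nxt
            nxt += 1
    # absorb fragments
    sizes = {l: int((out == l).sum()) for l in np.unique(out[out > 0])}
    for l, sz in sorted(sizes.items(), key=lambda kv: kv[1]):
        if sz >= min_region_px or len(sizes) == 1:
            continue
        grown = ndimage.binary_dilation(out == l) & mask & (out != l) & (out > 0)
        if grown.any():
            target = np.bincount(out[grown]).argmax()
            out[out == l] = target
        else:
            bigger = max(sizes, key=lambda k: sizes[k] if k != l else -1)
            out[out == l] = bigger
        del sizes[l]
    # compact label values
    final = np.zeros_like(out)
    for i, l in enumerate(np.unique(out[out > 0])):
        final[out == l] = i + 1
    return final


def per_region_kinetics(rmap: RecoveryMap, labels, min_region_px: int = 5) -> list[FitResult]:
    """One-phase-association fit of each subregion's mean curve."""
    fits = []
    for lab in np.unique(np.asarray(labels)[np.asarray(labels) > 0]):
        m = labels == lab
        if m.sum() < min_region_px:
            raise ValueError(f"region {lab} smaller than {min_region_px} px")
        curve = region_curve(rmap, m)
        finite = np.isfinite(curve.value)  # frames where the region left the mask
        fits.append(fit_one_phase(NormalizedTrace(curve.times[finite], curve.value[finite])))
    return fits


def heterogeneity_index(fits: list[FitResult]) -> float:
    """Population coefficient of variation of the per-region half-times."""
    conv = [f.t_half for f in fits if f.converged]
    if len(conv) < 2:
        return 0.0
    arr = np.asarray(conv)
    return float(arr.std() / arr.mean())


def classify_compartments(
    n_subregions: int,
    fits: list[FitResult],
    cv_threshold: float = 0.3,
    focus_id: int = 0,
) -> CompartmentCall:
    """Multi-compartment iff >= 2 subregions with half-time CV above the
    threshold.  The CV rule is this pipeline's operationalization of the
    visually identified subcompartments."""
    hi = heterogeneity_index(fits)
    call = "multi" if (n_subregions >= 2 and hi > cv_threshold) else "single"
    return CompartmentCall(
        focus_id=focus_id,
        n_subregions=n_subregions,
        fits=fits,
        heterogeneity_index=hi,
        call=call,
    )


def classify_contour(
    track,
    s_thr: float = 0.97,
    iou_thr: float = 0.96,
    times=None,
) -> str:
    """Compact vs amorphous contour from a focus track.

    Amorphous iff the mean sphericity over tracked frames falls below
    ``s_thr`` or the mean frame-to-frame mask IoU falls below ``iou_thr``
    (irregular or dynamically shape-changing contour).  When frame times
    are given, only pre-bleach frames are used (if at least three exist):
    post-bleach masks of a deeply bleached focus reflect the recovery
    front, not the contour.
    """
    foci = track.foci
    if times is not None:
        times = np.asarray(times, dtype=float)
        pre = [f for f in foci if times[f.frame_index] < 0]
        if len(pre) >= 3:
            foci = pre
    if len(foci) < 3:
        raise ValueError("track too short to classify (need >= 3 frames)")
    sphericities = [f.sphericity for f in foci if np.isfinite(f.sphericity)]
    ious = []
    for a, b in zip(foci[:-1], foci[1:]):
        inter = np.logical_and(a.mask, b.mask).sum()
        union = np.logical_or(a.mask, b.mask).sum()
        if union:
            ious.append(inter / union)
    amorphous = (np.mean(sphericities) < s_thr) or (len(ious) > 0 and np.mean(ious) < iou_thr)
    return "amorphous" if amorphous else "compact"
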