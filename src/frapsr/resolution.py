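"""Twin-bead resolvability assay.

Nanoruler phantoms (or real bead images) carry pairs of emitters at a
designed separation.  A pair is *resolved* ("twin") when the intensity
profile along the pair axis shows two significant local maxima; for two
equal Gaussians of width sigma this happens exactly when the separation
exceeds 2*sigma (the dip criterion), so a 60-nm pair is resolvable at a
60-nm-FWHM PSF (sigma ~ 25.5 nm) but not at 120 nm FWHM (sigma ~ 51 nm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.signal import find_peaks

__all__ = [
    "BeadPairMeasurement",
    "measure_pair",
    "measure_pairs_from_truth",
    "summarize_beads",
    "two_gaussian_profile",
    "two_gaussian_peak_count",
]


@dataclass
class BeadPairMeasurement:
    pair_id: int
    status: str  # "single" | "twin"
    peak_distance_nm: float | None  # defined only for twin
    profile: np.ndarray  # sampled intensities along the pair axis
    profile_positions_nm: np.ndarray  # positions along the axis, midpoint at 0


def two_gaussian_profile(x, separation, sigma, amplitude=1.0):
    """Analytic 1D profile of two equal Gaussians ``separation`` apart."""
    x = np.asarray(x, dtype=float)
    return amplitude * (
        np.exp(-((x - separation / 2) ** 2) / (2 * sigma**2))
        + np.exp(-((x + separation / 2) ** 2) / (2 * sigma**2))
    )


def two_gaussian_peak_count(separation, sigma):
    """Number of local maxima of the two-Gaussian sum: 2 iff d > 2*sigma."""
    return 2 if separation > 2.0 * sigma else 1


def _parabolic_refine(xs, ys, i):
    """3-point parabolic sub-sample refinement of a local maximum."""
    if i == 0 or i == len(ys) - 1:
        return xs[i]
    y0, y1, y2 = ys[i - 1], ys[i], ys[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return xs[i]
    delta = 0.5 * (y0 - y2) / denom
    step = xs[i + 1] - xs[i]
    return xs[i] + delta * step


def measure_pair(
    image,
    pair_location_nm,
    pair_axis_rad,
    pixel_size_nm,
    profile_halflength_nm: float | None = None,
    prominence_fraction: float = 0.05,
    pair_id: int = 0,
) -> BeadPairMeasurement:
    """Classify one bead pair as single or twin and measure the peak gap.

    A profile is sampled along the pair axis through the stated midpoint
    at pixel_size/4 spacing with cubic-spline interpolation; maxima need a
    prominence of at least ``prominence_fraction`` of the profile range
    (the default 5% sits below the ~7% dip of a pair at the d = 2.355 sigma
    Rayleigh-like limit, so a just-resolvable noiseless pair counts as twin).
    Exactly two significant maxima give status "twin" with the distance
    between the parabolic-refined peak positions; note this distance is
    biased below the true separation near the 2 sigma limit (peak pulling).
    """
    image = np.asarray(image, dtype=float)
    mx, my = pair_location_nm
    if profile_halflength_nm is None:
        # long enough to cover the pair plus PSF tails, short enough not to
        # graze neighbouring pairs placed >= 5 FWHM away
        profile_halflength_nm = 10 * pixel_size_nm
    step = pixel_size_nm / 4.0
    s = np.arange(-profile_halflength_nm, profile_halflength_nm + step / 2, step)
    ux, uy = np.cos(pair_axis_rad), np.sin(pair_axis_rad)
    cols = (mx + s * ux) / pixel_size_nm
    rows = (my + s * uy) / pixel_size_nm
    profile = map_coordinates(image, np.vstack([rows, cols]), order=3, mode="nearest")

    rng_val = profile.max() - profile.min()
    if rng_val <= 0:
        raise ValueError("empty or flat intensity profile")
    peaks, _ = find_peaks(profile, prominence=prominence_fraction * rng_val)
    if len(peaks) == 2:
        p0 = _parabolic_refine(s, profile, peaks[0])
        p1 = _parabolic_refine(s, profile, peaks[1])
        return BeadPairMeasurement(pair_id, "twin", float(abs(p1 - p0)), profile, s)
    return BeadPairMeasurement(pair_id, "single", None, profile, s)


def measure_pairs_from_truth(image, truth: pd.DataFrame, pixel_size_nm, **kwargs):
    """Measure every pair listed in a phantom truth table."""
    out = []
    for _, row in truth.iterrows():
        out.append(
            measure_pair(
                image,
                (row["mid_x_nm"], row["mid_y_nm"]),
                row["angle_rad"],
                pixel_size_nm,
                pair_id=int(row["pair_id"]),
                **kwargs,
            )
        )
    return out


def summarize_beads(measurements) -> dict:
    """Fraction of pairs resolved as twins and the median peak distance."""
    if len(measurements) == 0:
        raise ValueError("no measurements to summarize")
    n_twin = sum(1 for m in measurements if m.status == "twin")
    fraction_twin = n_twin / len(measurements)
    distances = [m.peak_distance_nm for m in measurements if m.status == "twin"]
    median = float(np.median(distances)) if distances else None
    return {
        "n_pairs": len(measurements),
        "fraction_twin": fraction_twin,
        "median_peak_distance_nm": median,
    }
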