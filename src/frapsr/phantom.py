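"""Synthetic FRAP movies and bead phantoms with known ground truth.

The generator emulates photobleaching-recovery experiments on nuclear
condensates (53BP1-EGFP foci in an RPE1-like nucleus) rendered at
wide-field, SIM, or diSIM resolution.  The kinetic model is compartmental:
each subcompartment of a focus has one exchange rate constant and one
mobile fraction, and the bleached fluorescent fraction recovers as a
one-phase association

    f(t) = f_post + mobile_fraction * (1 - f_post) * (1 - exp(-k t)),

with ``f_post = 1 - depth`` inside the bleach ROI at t = 0.  Image
formation is: rasterize emitter densities -> convolve with a Gaussian PSF
of the stated FWHM -> scale to expected photons -> Poisson shot noise ->
Gaussian read noise -> camera offset.  Structured-illumination
reconstruction itself is not modelled; SIM and diSIM are emulated purely
as narrower PSFs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon2mask

__all__ = [
    "SubcompartmentSpec",
    "FocusSpec",
    "SceneSpec",
    "ImagingSpec",
    "BleachEvent",
    "Movie",
    "GroundTruth",
    "PSF_PRESETS",
    "PRESET_NAMES",
    "imaging_preset",
    "preset_scene",
    "preset_bleach",
    "recovery_fraction",
    "simulate_frap_movie",
    "make_bead_phantom",
]

#: Gaussian PSF FWHM (nm) emulating each rendering mode.
PSF_PRESETS = {"widefield": 250.0, "sim": 120.0, "disim": 60.0}

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # sigma = FWHM * this


@dataclass(frozen=True)
class SubcompartmentSpec:
    """One kinetic compartment inside a focus.

    ``region`` is a polygon (N x 2 array of (x, y) in nm, scene frame)
    that claims the focus pixels falling inside it; focus pixels claimed
    by no region are assigned to the nearest region centroid.
    """

    region: np.ndarray
    k_exchange: float  # 1/s
    mobile_fraction: float
    brightness: float  # emitter density (arbitrary units, scaled by photon_scale)

    def __post_init__(self):
        object.__setattr__(self, "region", np.asarray(self.region, dtype=float))
        if self.region.ndim != 2 or self.region.shape[1] != 2 or len(self.region) < 3:
            raise ValueError("region must be an (N>=3, 2) polygon in nm")
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ValueError("mobile_fraction must lie in [0, 1]")
        if self.k_exchange <= 0:
            raise ValueError("k_exchange must be positive")
        if self.brightness < 0:
            raise ValueError("brightness must be non-negative")


@dataclass(frozen=True)
class FocusSpec:
    """A single focus: a compact disk or an amorphous lobed blob.

    ``lobes`` is a list of (dx, dy, radius) in nm relative to the centroid;
    compact foci use ``radius`` instead and must have exactly one
    subcompartment and no shape jitter.
    """

    centroid: tuple[float, float]  # (x, y) nm
    contour_class: str  # "compact" | "amorphous"
    subcompartments: tuple[SubcompartmentSpec, ...]
    radius: float | None = None  # compact only
    lobes: tuple[tuple[float, float, float], ...] = ()  # amorphous only
    drift_velocity: tuple[float, float] = (0.0, 0.0)  # nm/s
    shape_jitter_amplitude: float = 0.0  # nm per frame (random-walk step)

    def __post_init__(self):
        if self.contour_class not in ("compact", "amorphous"):
            raise ValueError("contour_class must be 'compact' or 'amorphous'")
        if self.contour_class == "compact":
            if len(self.subcompartments) != 1:
                raise ValueError("compact foci have exactly one subcompartment")
            if self.shape_jitter_amplitude != 0.0:
                raise ValueError("compact foci have no shape jitter")
            if self.radius is None or self.radius <= 0:
                raise ValueError("compact foci need a positive disk radius")
        else:
            if len(self.subcompartments) < 2:
                raise ValueError("amorphous foci need >= 2 subcompartments")
            if len(self.lobes) < 2:
                raise ValueError("amorphous foci are lobed blobs (>= 2 lobes)")


@dataclass(frozen=True)
class SceneSpec:
    """Nucleus geometry plus foci; lengths in nm, scene origin at the
    top-left pixel center, x along columns, y along rows."""

    nucleus_center: tuple[float, float]
    nucleus_semi_axes: tuple[float, float]  # (ax, ay) nm
    foci: tuple[FocusSpec, ...]
    nucleoplasm_brightness: float = 1.0
    nucleoplasm_k: float = 0.3  # free-pool recovery rate, 1/s
    preset_name: str | None = None
    margin: float = 600.0  # nm of dark border kept around the nucleus

    def __post_init__(self):
        if self.nucleoplasm_brightness < 0:
            raise ValueError("densities must be non-negative")
        cx, cy = self.nucleus_center
        ax, ay = self.nucleus_semi_axes
        for f in self.foci:
            fx, fy = f.centroid
            extent = f.radius if f.radius else max(
                math.hypot(dx, dy) + r for dx, dy, r in f.lobes
            )
            if ((fx - cx) / ax) ** 2 + ((fy - cy) / ay) ** 2 > (1 - extent / min(ax, ay)) ** 2:
                raise ValueError("focus extends outside the nucleus")

    @property
    def field_size_nm(self) -> tuple[float, float]:
        """(width_x, height_y) of the rendered field."""
        cx, cy = self.nucleus_center
        ax, ay = self.nucleus_semi_axes
        return (cx + ax + self.margin, cy + ay + self.margin)


@dataclass(frozen=True)
class ImagingSpec:
    pixel_size: float  # nm
    psf_fwhm: float  # nm
    frame_interval: float = 5.0  # s
    n_pre_frames: int = 3
    n_post_frames: int = 24
    n_z: int = 3
    photon_scale: float = 80.0  # expected photons per unit density per pixel
    read_noise_sd: float = 2.0  # photons rms
    camera_offset: float = 100.0  # counts
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size > self.psf_fwhm / 2.0:
            raise ValueError(
                f"Nyquist violation: pixel_size {self.pixel_size} nm exceeds "
                f"psf_fwhm/2 = {self.psf_fwhm / 2.0} nm"
            )
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_fwhm * FWHM_TO_SIGMA / self.pixel_size

    @property
    def noiseless(self) -> bool:
        return not self.shot_noise and self.read_noise_sd == 0.0


def imaging_preset(psf: str = "disim", **overrides) -> ImagingSpec:
    """ImagingSpec for a named rendering mode (widefield, sim, disim).

    Pixel size defaults to FWHM / 2.5, comfortably inside Nyquist.
    """
    fwhm = PSF_PRESETS[psf]
    kw = dict(pixel_size=fwhm / 2.5, psf_fwhm=fwhm)
    kw.update(overrides)
    return ImagingSpec(**kw)


@dataclass(frozen=True)
class BleachEvent:
    """Instantaneous bleach ending at t = 0: a disk ROI within which the
    fluorescent fraction drops to 1 - depth."""

    center: tuple[float, float]  # nm
    radius: float  # nm
    depth: float = 1.0
    time: float = 0.0  # s; t = 0 is defined as bleach end

    def __post_init__(self):
        if not 0.0 < self.depth <= 1.0:
            raise ValueError("depth must lie in (0, 1]")
        if self.radius <= 0:
            raise ValueError("bleach radius must be positive")


@dataclass
class Movie:
    """Time-lapse stack: ``frames`` has shape (T, Z, H, W); times are in
    seconds relative to bleach end (pre-bleach negative)."""

    frames: np.ndarray
    times: np.ndarray
    pixel_size: float  # nm
    bleach: BleachEvent | None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim == 3:  # (T, H, W) -> single z-plane
            self.frames = self.frames[:, None]
        if self.frames.ndim != 4:
            raise ValueError("frames must have shape (T, Z, H, W)")
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[-2:]


@dataclass
class GroundTruth:
    """Per-frame truth labels and the kinetic parameters behind them."""

    nucleus_mask: np.ndarray  # (H, W) bool
    focus_labels: np.ndarray  # (T, H, W) int, 0 = none, focus i -> i + 1
    subcomp_labels: np.ndarray  # (T, H, W) int, global subcompartment ids from 1
    kinetics: pd.DataFrame  # focus_id, subcompartment_id, k_exchange, mobile_fraction
    centroids: pd.DataFrame  # frame, time_s, focus_id, x_nm, y_nm


def recovery_fraction(t, k, mobile_fraction=1.0, depth=1.0):
    """Fluorescent fraction of a bleached compartment at time t >= 0."""
    t = np.asarray(t, dtype=float)
    f_post = 1.0 - depth
    return f_post + mobile_fraction * (1.0 - f_post) * (1.0 - np.exp(-k * t))


# ---------------------------------------------------------------------------
# rasterization helpers

def _grids(shape, pixel_size):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return cc * pixel_size, rr * pixel_size  # x, y in nm at pixel centers


def _ellipse_mask(shape, pixel_size, center, semi_axes):
    x, y = _grids(shape, pixel_size)
    cx, cy = center
    ax, ay = semi_axes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0


def _disk_mask(shape, pixel_size, center, radius):
    x, y = _grids(shape, pixel_size)
    return (x - center[0]) ** 2 + (y - center[1]) ** 2 <= radius**2


def _polygon_mask(shape, pixel_size, polygon_nm):
    poly_rc = np.column_stack([polygon_nm[:, 1], polygon_nm[:, 0]]) / pixel_size
    return polygon2mask(shape, poly_rc)


def _focus_mask(focus, shape, pixel_size, offset, lobe_offsets):
    """Binary mask of a focus at one frame; ``offset`` is the drift (nm),
    ``lobe_offsets`` the per-lobe jitter displacements (amorphous only)."""
    cx = focus.centroid[0] + offset[0]
    cy = focus.centroid[1] + offset[1]
    if focus.contour_class == "compact":
        return _disk_mask(shape, pixel_size, (cx, cy), focus.radius)
    mask = np.zeros(shape, dtype=bool)
    for (dx, dy, r), (jx, jy) in zip(focus.lobes, lobe_offsets):
        mask |= _disk_mask(shape, pixel_size, (cx + dx + jx, cy + dy + jy), r)
    return mask


def _partition_subcompartments(focus, mask, shape, pixel_size, offset):
    """Assign each focus pixel to a subcompartment.

    Pixels inside a region polygon (translated by drift) belong to it;
    the rest go to the subcompartment with the nearest region centroid.
    """
    n = len(focus.subcompartments)
    labels = np.zeros(shape, dtype=np.int32)
    if n == 1:
        labels[mask] = 1
        return labels
    x, y = _grids(shape, pixel_size)
    claimed = np.zeros(shape, dtype=bool)
    for i, sc in enumerate(focus.subcompartments):
        poly = sc.region + np.asarray(offset)
        inside = _polygon_mask(shape, pixel_size, poly) & mask & ~claimed
        labels[inside] = i + 1
        claimed |= inside
    left = mask & ~claimed
    if np.any(left):
        cents = np.array(
            [sc.region.mean(axis=0) + np.asarray(offset) for sc in focus.subcompartments]
        )
        d2 = np.stack(
            [(x[left] - cx) ** 2 + (y[left] - cy) ** 2 for cx, cy in cents]
        )
        labels[left] = np.argmin(d2, axis=0) + 1
    return labels


# ---------------------------------------------------------------------------
# movie simulation

def simulate_frap_movie(
    scene: SceneSpec, imaging: ImagingSpec, bleach: BleachEvent
) -> tuple[Movie, GroundTruth]:
    """Render a FRAP movie and its ground truth.

    Pre-bleach frames are stationary (compact scenes exactly so; amorphous
    foci jitter by construction).  Bleach is instantaneous at t = 0 with
    uniform ``depth`` inside the ROI; each bleached compartment then
    recovers by one-phase association with its own rate and mobile
    fraction.  Kinetics are applied before any z projection: the ``n_z``
    planes are replicate renders with independent noise.
    """
    px = imaging.pixel_size
    fw, fh = scene.field_size_nm
    shape = (int(math.ceil(fh / px)), int(math.ceil(fw / px)))
    rng = np.random.default_rng(imaging.seed)

    nucleus = _ellipse_mask(shape, px, scene.nucleus_center, scene.nucleus_semi_axes)
    roi = _disk_mask(shape, px, bleach.center, bleach.radius)
    if not np.any(roi & nucleus):
        raise ValueError("bleach ROI lies outside the nucleus")

    dt = imaging.frame_interval
    times = np.concatenate(
        [
            -dt * np.arange(imaging.n_pre_frames, 0, -1),
            dt * np.arange(imaging.n_post_frames),
        ]
    )
    n_frames = len(times)

    # seeded per-lobe jitter, drawn up-front for determinism: a stationary
    # AR(1) (mean-reverting) walk with sd = shape_jitter_amplitude, so the
    # shape changes every frame without drifting apart over the movie
    jitter = []
    rho = 0.8
    for focus in scene.foci:
        if focus.contour_class == "amorphous" and focus.shape_jitter_amplitude > 0:
            amp = focus.shape_jitter_amplitude
            eps = rng.normal(0.0, amp, size=(n_frames, len(focus.lobes), 2))
            walk = np.empty_like(eps)
            walk[0] = eps[0]
            for i in range(1, n_frames):
                walk[i] = rho * walk[i - 1] + math.sqrt(1 - rho**2) * eps[i]
            jitter.append(walk)
        else:
            jitter.append(np.zeros((n_frames, max(len(focus.lobes), 1), 2)))

    # global subcompartment ids
    sc_ids, rows = {}, []
    next_id = 1
    for fi, focus in enumerate(scene.foci):
        for si, sc in enumerate(focus.subcompartments):
            sc_ids[(fi, si)] = next_id
            rows.append(
                {
                    "focus_id": fi,
                    "subcompartment_id": next_id,
                    "k_exchange": sc.k_exchange,
                    "mobile_fraction": sc.mobile_fraction,
                    "brightness": sc.brightness,
                }
            )
            next_id += 1
    kinetics = pd.DataFrame(rows)

    frames = np.empty((n_frames, imaging.n_z) + shape)
    focus_labels = np.zeros((n_frames,) + shape, dtype=np.int32)
    subcomp_labels = np.zeros((n_frames,) + shape, dtype=np.int32)
    cent_rows = []
    x, y = _grids(shape, px)
    f_post = 1.0 - bleach.depth
    any_focus_overlap = False

    for ti, t in enumerate(times):
        density = np.zeros(shape)
        occupied = np.zeros(shape, dtype=bool)
        for fi, focus in enumerate(scene.foci):
            offset = (focus.drift_velocity[0] * t, focus.drift_velocity[1] * t)
            mask = _focus_mask(focus, shape, px, offset, jitter[fi][ti]) & nucleus
            labels = _partition_subcompartments(focus, mask, shape, px, offset)
            for si, sc in enumerate(focus.subcompartments):
                m = labels == si + 1
                fluor = np.ones(shape)
                if t >= 0:
                    bleached = m & roi
                    if np.any(bleached):
                        any_focus_overlap = True
                    fluor[bleached] = recovery_fraction(
                        t, sc.k_exchange, sc.mobile_fraction, bleach.depth
                    )
                density[m] = sc.brightness * fluor[m]
                subcomp_labels[ti][m] = sc_ids[(fi, si)]
            focus_labels[ti][mask] = fi + 1
            occupied |= mask
            if np.any(mask):
                cent_rows.append(
                    {
                        "frame": ti,
                        "time_s": t,
                        "focus_id": fi,
                        "x_nm": float(x[mask].mean()),
                        "y_nm": float(y[mask].mean()),
                    }
                )
        nucleoplasm = nucleus & ~occupied
        np_fluor = np.ones(shape)
        if t >= 0:
            np_fluor[roi] = recovery_fraction(t, scene.nucleoplasm_k, 1.0, bleach.depth)
        density[nucleoplasm] = scene.nucleoplasm_brightness * np_fluor[nucleoplasm]

        expected = ndimage.gaussian_filter(density, imaging.psf_sigma_px, mode="constant")
        expected *= imaging.photon_scale
        for zi in range(imaging.n_z):
            img = expected
            if imaging.shot_noise:
                img = rng.poisson(img).astype(float)
            if imaging.read_noise_sd > 0:
                img = img + rng.normal(0.0, imaging.read_noise_sd, size=shape)
            frames[ti, zi] = img + imaging.camera_offset

    if not any_focus_overlap and imaging.n_post_frames > 0:
        raise ValueError("bleach ROI overlaps no focus")

    movie = Movie(
        frames=frames,
        times=times,
        pixel_size=px,
        bleach=bleach,
        provenance={"scene": scene, "imaging": imaging},
    )
    truth = GroundTruth(
        nucleus_mask=nucleus,
        focus_labels=focus_labels,
        subcomp_labels=subcomp_labels,
        kinetics=kinetics,
        centroids=pd.DataFrame(cent_rows),
    )
    return movie, truth


# ---------------------------------------------------------------------------
# bead phantoms

def make_bead_phantom(
    n_pairs: int,
    separation: float,
    psf_fwhm: float,
    imaging: ImagingSpec,
    field_size_nm: float | None = None,
    amplitude: float = 1000.0,
    max_tries: int = 10_000,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Field of twin-emitter pairs emulating 60-nm DNA-origami nanorulers.

    Each pair is two equal point emitters ``separation`` nm apart at a
    random orientation, rendered as analytic Gaussian spots of the stated
    FWHM.  Pair midpoints are kept >= 5 * psf_fwhm apart.  Returns the
    image and a truth table (pair_id, mid_x_nm, mid_y_nm, angle_rad,
    separation_nm).
    """
    if separation < 0:
        raise ValueError("separation must be non-negative")
    px = imaging.pixel_size
    min_dist = 5.0 * psf_fwhm
    if field_size_nm is None:
        field_size_nm = max(2.0, math.sqrt(n_pairs)) * 2.2 * min_dist
    shape = (int(math.ceil(field_size_nm / px)),) * 2
    rng = np.random.default_rng(imaging.seed)
    margin = 2.0 * psf_fwhm + separation

    mids: list[tuple[float, float]] = []
    tries = 0
    while len(mids) < n_pairs:
        if tries >= max_tries:
            raise ValueError(
                f"overcrowded field: placed {len(mids)}/{n_pairs} pairs "
                f"at min distance {min_dist:.0f} nm"
            )
        tries += 1
        mx, my = rng.uniform(margin, field_size_nm - margin, size=2)
        if all((mx - ox) ** 2 + (my - oy) ** 2 >= min_dist**2 for ox, oy in mids):
            mids.append((mx, my))
    angles = rng.uniform(0, np.pi, size=n_pairs)

    sigma = psf_fwhm * FWHM_TO_SIGMA
    x, y = _grids(shape, px)
    image = np.zeros(shape)
    rows = []
    for pid, ((mx, my), ang) in enumerate(zip(mids, angles)):
        ux, uy = math.cos(ang), math.sin(ang)
        for s in (-0.5, 0.5):
            ex, ey = mx + s * separation * ux, my + s * separation * uy
            image += amplitude * np.exp(-((x - ex) ** 2 + (y - ey) ** 2) / (2 * sigma**2))
        rows.append(
            {
                "pair_id": pid,
                "mid_x_nm": mx,
                "mid_y_nm": my,
                "angle_rad": ang,
                "separation_nm": separation,
            }
        )
    if imaging.shot_noise:
        image = rng.poisson(image).astype(float)
    if imaging.read_noise_sd > 0:
        image = image + rng.normal(0.0, imaging.read_noise_sd, size=shape)
    image = image + imaging.camera_offset
    return image, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scene presets

LN2 = math.log(2.0)

#: Mean half-times (s) of 53BP1-EGFP recovery per experimental condition,
#: turned into exchange-rate constants k = ln 2 / t_half.
CONDITION_T_HALF = {
    "untreated_compact": 19.67,
    "untreated_amorphous": 15.58,
    "aphidicolin_arrest": 28.6,
    "aphidicolin_release_compact": 28.6,
    "aphidicolin_release_amorphous": 10.25,
}

PRESET_NAMES = (
    "untreated_compact",
    "untreated_amorphous",
    "aphidicolin_arrest",
    "aphidicolin_release",
)

_NUCLEUS_CENTER = (4200.0, 3400.0)
_NUCLEUS_AXES = (3600.0, 2800.0)
_FOCUS_BRIGHTNESS = 5.0

# Lobe layout (dx, dy, radius in nm): an overlapping chain of disks with
# concave necks, giving a connected but clearly non-convex contour;
# subcompartments split it left/right.
_AMORPHOUS_LOBES = (
    (-420.0, -80.0, 285.0),
    (-160.0, 240.0, 255.0),
    (-40.0, -160.0, 285.0),
    (300.0, 120.0, 265.0),
    (480.0, -220.0, 235.0),
)
_JITTER_NM = 45.0


def _compact_focus(center, t_half, mobile_fraction=0.85, radius=600.0):
    disk = _regular_polygon(center, radius * 1.5, 16)
    sc = SubcompartmentSpec(
        region=disk,
        k_exchange=LN2 / t_half,
        mobile_fraction=mobile_fraction,
        brightness=_FOCUS_BRIGHTNESS,
    )
    return FocusSpec(
        centroid=center,
        contour_class="compact",
        subcompartments=(sc,),
        radius=radius,
    )


def _regular_polygon(center, radius, n):
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)]
    )


def _amorphous_focus(center, mean_t_half, k_contrast=4.0, mobile_fraction=0.9):
    """Two-subcompartment lobed focus; the fast and slow exchange rates are
    the geometric mean k = ln2 / mean_t_half split by ``k_contrast``."""
    k_mean = LN2 / mean_t_half
    k_fast = k_mean * math.sqrt(k_contrast)
    k_slow = k_mean / math.sqrt(k_contrast)
    cx, cy = center
    big = 3000.0
    left = np.array(
        [[cx - big, cy - big], [cx, cy - big], [cx, cy + big], [cx - big, cy + big]]
    )
    right = np.array(
        [[cx, cy - big], [cx + big, cy - big], [cx + big, cy + big], [cx, cy + big]]
    )
    scs = (
        SubcompartmentSpec(left, k_fast, mobile_fraction, _FOCUS_BRIGHTNESS),
        SubcompartmentSpec(right, k_slow, mobile_fraction, _FOCUS_BRIGHTNESS),
    )
    return FocusSpec(
        centroid=center,
        contour_class="amorphous",
        subcompartments=scs,
        lobes=_AMORPHOUS_LOBES,
        shape_jitter_amplitude=_JITTER_NM,
    )


def preset_scene(name: str) -> SceneSpec:
    """Deterministic scene for a named experimental condition.

    - ``untreated_compact``: one compact focus, t_half 19.67 s.
    - ``untreated_amorphous``: one amorphous two-subcompartment focus,
      mean t_half 15.58 s, 4x rate contrast between subcompartments.
    - ``aphidicolin_arrest``: one compact focus with slower exchange
      (t_half 28.6 s) and a reduced mobile fraction.
    - ``aphidicolin_release``: one compact (t_half 28.6 s) and one
      amorphous focus (mean t_half 10.25 s) in the same nucleus.
    """
    c = _NUCLEUS_CENTER
    if name == "untreated_compact":
        foci = (_compact_focus(c, CONDITION_T_HALF[name]),)
    elif name == "untreated_amorphous":
        foci = (_amorphous_focus(c, CONDITION_T_HALF[name]),)
    elif name == "aphidicolin_arrest":
        foci = (_compact_focus(c, CONDITION_T_HALF[name], mobile_fraction=0.7),)
    elif name == "aphidicolin_release":
        foci = (
            _compact_focus(
                (c[0] - 1800.0, c[1] + 700.0),
                CONDITION_T_HALF["aphidicolin_release_compact"],
                mobile_fraction=0.7,
                radius=500.0,
            ),
            _amorphous_focus(
                (c[0] + 1300.0, c[1] - 500.0),
                CONDITION_T_HALF["aphidicolin_release_amorphous"],
            ),
        )
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return SceneSpec(
        nucleus_center=c,
        nucleus_semi_axes=_NUCLEUS_AXES,
        foci=foci,
        preset_name=name,
    )


def preset_bleach(scene: SceneSpec, focus_index: int = 0, depth: float = 0.95) -> BleachEvent:
    """Bleach disk covering one focus plus a PSF-scale margin."""
    focus = scene.foci[focus_index]
    if focus.contour_class == "compact":
        extent = focus.radius
        center = focus.centroid
    else:
        pts = np.array([(focus.centroid[0] + dx, focus.centroid[1] + dy) for dx, dy, _ in focus.lobes])
        rads = np.array([r for _, _, r in focus.lobes])
        center = tuple(pts.mean(axis=0))
        extent = float(np.max(np.hypot(*(pts - center).T) + rads))
    return BleachEvent(center=center, radius=extent + 300.0, depth=depth)
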