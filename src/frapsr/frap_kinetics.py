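"""Double-normalized FRAP curves and one-phase-association kinetics.

The normalization is the three-step double normalization used for
photobleaching-corrected recovery curves:

    r   = (Fc - Fb) / (Fc0 - Fb)        photobleaching rate (control)
    R   = (Fi - Fb) / (Fi0 - Fb)        recovery rate of the ROI
    N   = R / r                         normalized recovery

with Fi the bleach-ROI mean, Fc an unbleached control-region mean, Fb the
background mean (applied per frame), and Fi0, Fc0 the pre-bleach means.

Recovery is fit with the one-phase association model

    y(t) = f_post + (plateau - f_post) * (1 - exp(-k t)),   t >= 0,

whose half-time is t_half = ln 2 / k.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FrapTrace",
    "NormalizedTrace",
    "FitResult",
    "one_phase",
    "extract_trace",
    "normalize_frap",
    "fit_one_phase",
    "immobile_fraction",
    "partition_periods",
    "percent_recovered_at",
]

LN2 = math.log(2.0)


def one_phase(t, k, f_post=0.0, plateau=1.0):
    """One-phase association: f_post + (plateau - f_post)(1 - exp(-k t))."""
    t = np.asarray(t, dtype=float)
    return f_post + (plateau - f_post) * (1.0 - np.exp(-k * t))


@dataclass
class FrapTrace:
    """Raw ROI/control/background mean-intensity series.

    Times are seconds relative to bleach end; pre-bleach frames have
    negative times.  ``Fi0`` and ``Fc0`` are means over pre-bleach frames.
    """

    times: np.ndarray
    Fi: np.ndarray
    Fc: np.ndarray
    Fb: np.ndarray
    Fi0: float = None  # type: ignore[assignment]
    Fc0: float = None  # type: ignore[assignment]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.Fi = np.asarray(self.Fi, dtype=float)
        self.Fc = np.asarray(self.Fc, dtype=float)
        self.Fb = np.asarray(self.Fb, dtype=float)
        if not (len(self.times) == len(self.Fi) == len(self.Fc) == len(self.Fb)):
            raise ValueError("times, Fi, Fc, Fb must have equal length")
        pre = self.times < 0
        if self.Fi0 is None:
            if pre.sum() < 2:
                raise ValueError("need >= 2 pre-bleach frames to set Fi0/Fc0")
            self.Fi0 = float(self.Fi[pre].mean())
        if self.Fc0 is None:
            self.Fc0 = float(self.Fc[pre].mean())


@dataclass
class NormalizedTrace:
    """Dimensionless normalized recovery series (pre-bleach mean ~ 1)."""

    times: np.ndarray
    value: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if len(self.times) != len(self.value):
            raise ValueError("times and value must have equal length")


@dataclass
class FitResult:
    k: float  # 1/s
    t_half: float  # s, always ln2/k
    f_post: float
    plateau: float
    rss: float
    converged: bool
    n_points: int = 0
    message: str = ""

    @property
    def immobile_fraction(self) -> float:
        return immobile_fraction(self)


def extract_trace(movie, roi_mask, control_mask, background_mask) -> FrapTrace:
    """Per-frame ROI/control/background means on sum-projected frames.

    Masks are 2D boolean arrays on the frame grid; z-stacks are summed
    over z before averaging (the projection convention for kinetics).
    """
    from .segmentation import sum_project_z

    for name, m in (
        ("roi", roi_mask),
        ("control", control_mask),
        ("background", background_mask),
    ):
        m = np.asarray(m)
        if m.shape != movie.shape:
            raise ValueError(f"{name} mask shape {m.shape} != frame shape {movie.shape}")
        if not m.any():
            raise ValueError(f"{name} mask is empty")
    if (movie.times < 0).sum() < 2:
        raise ValueError("need >= 2 pre-bleach frames")
    Fi, Fc, Fb = [], [], []
    for stack in movie.frames:
        frame = sum_project_z(stack)
        Fi.append(frame[roi_mask].mean())
        Fc.append(frame[control_mask].mean())
        Fb.append(frame[background_mask].mean())
    return FrapTrace(times=movie.times, Fi=Fi, Fc=Fc, Fb=Fb)


def normalize_frap(trace: FrapTrace, denom_tol: float = 1e-9) -> NormalizedTrace:
    """Double normalization N = R / r with per-frame background subtraction.

    Raises if any denominator (Fc - Fb per frame, or the pre-bleach
    baselines) comes within ``denom_tol`` of zero, naming the frame.
    """
    Fb = trace.Fb
    denom_c = trace.Fc - Fb
    bad = np.nonzero(np.abs(denom_c) <= denom_tol)[0]
    if bad.size:
        raise ValueError(f"near-zero control denominator (Fc - Fb) at frame {bad[0]}")
    denom_c0 = trace.Fc0 - Fb
    bad = np.nonzero(np.abs(denom_c0) <= denom_tol)[0]
    if bad.size:
        raise ValueError(f"near-zero baseline denominator (Fc0 - Fb) at frame {bad[0]}")
    denom_i0 = trace.Fi0 - Fb
    bad = np.nonzero(np.abs(denom_i0) <= denom_tol)[0]
    if bad.size:
        raise ValueError(f"near-zero baseline denominator (Fi0 - Fb) at frame {bad[0]}")
    r = denom_c / denom_c0
    R = (trace.Fi - Fb) / denom_i0
    return NormalizedTrace(times=trace.times, value=R / r)


_K_BOUNDS = (1e-4, 10.0)
_K_STARTS = (0.01, 0.05, 0.2)  # multi-start seeds, 1/s


def fit_one_phase(trace: NormalizedTrace, t_start: float = 0.0) -> FitResult:
    """Least-squares one-phase-association fit on t >= t_start.

    Deterministic multi-start (three k seeds) guards against local minima;
    a degenerate (flat) series is reported with ``converged=False`` rather
    than dropped.
    """
    sel = trace.times >= t_start
    t = trace.times[sel]
    y = trace.value[sel]
    if len(t) < 5:
        raise ValueError("need >= 5 post-bleach points to fit")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in trace")

    span = float(y.max() - y.min())
    if span < 1e-12:
        return FitResult(
            k=np.nan, t_half=np.nan, f_post=float(y[0]), plateau=float(y[-1]),
            rss=0.0, converged=False, n_points=len(t), message="constant series",
        )

    t0 = t.min()

    def resid(p):
        f_post, plateau, k = p
        return one_phase(t - t0, k, f_post, plateau) - y

    f0 = float(y[0])
    p_hi = float(np.median(y[-max(3, len(y) // 4):]))
    lo = [min(-0.5, f0 - 1.0), min(f0, p_hi) - 1e-6, _K_BOUNDS[0]]
    hi = [max(1.0, f0 + 1.0), max(1.5, p_hi + 0.5), _K_BOUNDS[1]]

    best = None
    for k0 in _K_STARTS:
        x0 = [np.clip(f0, lo[0] + 1e-9, hi[0] - 1e-9),
              np.clip(p_hi, lo[1] + 1e-9, hi[1] - 1e-9),
              k0]
        try:
            res = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-15, ftol=1e-15,
                                gtol=1e-15, max_nfev=5000)
        except Exception:  # pragma: no cover - scipy failure path
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return FitResult(np.nan, np.nan, f0, p_hi, np.nan, False, len(t), "optimizer failure")

    f_post, plateau, k = best.x
    rss = float(2.0 * best.cost)
    converged = bool(best.success) and k > _K_BOUNDS[0] * 1.01 and plateau - f_post > 1e-6
    return FitResult(
        k=float(k), t_half=LN2 / float(k), f_post=float(f_post),
        plateau=float(plateau), rss=rss, converged=converged,
        n_points=len(t), message=best.message,
    )


def immobile_fraction(fit: FitResult) -> float:
    """1 - (plateau - f_post)/(1 - f_post), clipped to [0, 1].

    The fraction of the bleached signal that never recovers, relative to
    the full bleach depth.
    """
    if not fit.converged:
        raise ValueError("immobile fraction requires a converged fit")
    if fit.f_post >= 1.0:
        raise ValueError("undefined for f_post >= 1 (no bleach depth)")
    frac = 1.0 - (fit.plateau - fit.f_post) / (1.0 - fit.f_post)
    return float(np.clip(frac, 0.0, 1.0))


def partition_periods(
    trace: NormalizedTrace, boundary_s: float = 25.0
) -> tuple[NormalizedTrace, NormalizedTrace]:
    """Split post-bleach frames into the signal-recovery and plateau periods.

    At the nominal 5-s frame interval the recovery period is the first
    five post-bleach frames (< 25 s after photobleaching) and the plateau
    period the frames beyond; with irregular timing the 25-s boundary is
    applied directly.
    """
    post = trace.times >= 0
    t = trace.times[post]
    v = trace.value[post]
    dt = np.diff(t)
    if len(dt) and np.allclose(dt, dt[0]):
        n_rec = min(5, len(t))
        rec_sel = np.zeros(len(t), dtype=bool)
        rec_sel[:n_rec] = True
    else:
        rec_sel = t < boundary_s
    recovery = NormalizedTrace(t[rec_sel], v[rec_sel])
    plateau = NormalizedTrace(t[~rec_sel], v[~rec_sel])
    if len(plateau.times) == 0:
        warnings.warn("fewer than 6 post-bleach frames: plateau period is empty")
    return recovery, plateau


def percent_recovered_at(source, t: float = 60.0) -> float:
    """Normalized recovery at time t, from a fit or by interpolation.

    With a FitResult the model is evaluated; with a NormalizedTrace the
    measured curve is linearly interpolated (t must lie within the
    acquisition window).
    """
    if isinstance(source, FitResult):
        if not source.converged:
            raise ValueError("fit did not converge")
        return float(one_phase(t, source.k, source.f_post, source.plateau))
    trace = source
    post = trace.times >= 0
    tt, vv = trace.times[post], trace.value[post]
    if not (tt.min() <= t <= tt.max()):
        raise ValueError(f"t={t} s outside acquisition window and no fit supplied")
    return float(np.interp(t, tt, vv))
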