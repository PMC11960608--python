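"""Standard and relative Patlak estimation, SUV/SUVr, and the global scale.

The standard Patlak plot linearizes irreversible tracer kinetics after an
equilibrium time t*:

    C_T(t)/Cp(t) = Ki * [int_0^t Cp] / Cp(t) + b,      t > t*

The relative Patlak (RP) plot replaces the full input integral with the
late-time integral only, so no early-scan input function is needed:

    C_T(t)/Cp(t) = Ki' * [int_{t*}^t Cp] / Cp(t) + b',  t > t*

Within a subject Ki' = alpha * Ki with a global scaling factor alpha set by
the input-function shape, and the RP intercept b' equals the SUV ratio
relative to plasma at t*: b' = C_T(t*)/Cp(t*).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .kinetics import FrameSchedule, InputFunction, TissueCurve
from .phantom import DynamicImage

__all__ = [
    "PatlakFit",
    "ParametricImage",
    "patlak_xy",
    "fit_patlak",
    "fit_parametric",
    "suv_image",
    "suvr_image",
    "estimate_alpha",
    "default_mask",
    "PatlakImager",
]

log = logging.getLogger(__name__)

#: voxels below this fraction of the max late-frame activity are masked out
MASK_FRACTION = 0.01


@dataclass(frozen=True)
class PatlakFit:
    """Result of a single Patlak regression."""

    slope: float
    intercept: float
    method: str  # "standard" | "relative"
    t_star: float
    n_points: int
    r2: float


@dataclass(frozen=True)
class ParametricImage:
    """Voxelwise slope/intercept volumes from a Patlak fit."""

    slope_vol: np.ndarray
    intercept_vol: np.ndarray
    method: str
    t_star: float
    mask: np.ndarray

    def __post_init__(self):
        if not (self.slope_vol.shape == self.intercept_vol.shape
                == self.mask.shape):
            raise ValueError("slope/intercept/mask shapes must match")

    def masked_slopes(self) -> np.ndarray:
        return self.slope_vol[self.mask]


# ---------------------------------------------------------------------- #

def _retained_frames(sched: FrameSchedule, t_star: float) -> np.ndarray:
    """A frame enters the fit iff its start time >= t* (integral over
    acquired data only)."""
    return np.flatnonzero(sched.starts >= t_star - 1e-9)


def _design_x(f: InputFunction, sched: FrameSchedule, t_star: float,
              method: str, keep: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Patlak abscissa at retained frame mid-times, and Cp at those times."""
    if method not in ("standard", "relative"):
        raise ValueError(f"unknown Patlak method {method!r}")
    mids = sched.mid[keep]
    cp = np.asarray(f(mids), dtype=float)
    if np.any(cp <= 0):
        raise ValueError("Cp must be positive at retained frame mid-times")
    lower = t_star if method == "relative" else 0.0
    integrals = np.array([f.integral(lower, t) for t in mids])
    return integrals / cp, cp


def patlak_xy(curve: TissueCurve, f: InputFunction, t_star: float,
              method: str = "relative") -> tuple[np.ndarray, np.ndarray]:
    """Patlak coordinates: y = C_T/Cp, x = (input integral)/Cp.

    The standard method integrates the input from 0, the relative method
    from t*; frames starting before t* are dropped.
    """
    keep = _retained_frames(curve.schedule, t_star)
    if keep.size < 2:
        raise ValueError("need at least 2 frames starting at or after t*")
    x, cp = _design_x(f, curve.schedule, t_star, method, keep)
    y = curve.values[keep] / cp
    return x, y


def _line_fit(x: np.ndarray, y: np.ndarray, w: np.ndarray | None):
    """(Weighted) OLS line; returns slope, intercept, r2."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.ones_like(x) if w is None else np.asarray(w, float)
    sw = w.sum()
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    if sxx <= 1e-12 * max(1.0, xm ** 2):
        raise ValueError("degenerate Patlak abscissa (zero variance)")
    sxy = (w * (x - xm) * (y - ym)).sum()
    slope = sxy / sxx
    intercept = ym - slope * xm
    syy = (w * (y - ym) ** 2).sum()
    r2 = 1.0 if syy == 0 else min(max(1.0 - (w * (y - intercept - slope * x) ** 2).sum() / syy, 0.0), 1.0)
    return slope, intercept, r2


def fit_patlak(curve: TissueCurve, f: InputFunction, t_star: float,
               method: str = "relative",
               weights: str = "none") -> PatlakFit:
    """Least-squares Patlak line through (x, y); optionally duration-weighted."""
    keep = _retained_frames(curve.schedule, t_star)
    if keep.size < 2:
        raise ValueError("need at least 2 frames starting at or after t*")
    x, y = patlak_xy(curve, f, t_star, method)
    if weights == "duration":
        w = curve.schedule.durations[keep]
    elif weights == "none":
        w = None
    else:
        raise ValueError(f"unknown weighting {weights!r}")
    slope, intercept, r2 = _line_fit(x, y, w)
    return PatlakFit(slope=slope, intercept=intercept, method=method,
                     t_star=t_star, n_points=int(keep.size), r2=r2)


def default_mask(img: DynamicImage) -> np.ndarray:
    """Voxels whose last-frame activity exceeds 1% of its maximum; excludes
    air where Cp-normalized ratios blow up."""
    last = img.data[..., -1]
    return last > MASK_FRACTION * last.max()


def fit_parametric(img: DynamicImage, f: InputFunction, t_star: float,
                   method: str = "relative", mask: np.ndarray | None = None,
                   weights: str = "none") -> ParametricImage:
    """Voxelwise Patlak fit over a mask.

    The abscissa is computed once (the input is global), so the per-volume
    cost is a single closed-form weighted regression over all voxels.
    Voxels producing non-finite estimates are masked out (count logged).
    """
    if mask is None:
        mask = default_mask(img)
    mask = np.asarray(mask, bool)
    if mask.shape != img.shape:
        raise ValueError("mask shape must match image grid")
    keep = _retained_frames(img.schedule, t_star)
    if keep.size < 2:
        raise ValueError("need at least 2 frames starting at or after t*")
    x, cp = _design_x(f, img.schedule, t_star, method, keep)
    if weights == "duration":
        w = img.schedule.durations[keep]
    elif weights == "none":
        w = np.ones_like(x)
    else:
        raise ValueError(f"unknown weighting {weights!r}")

    yv = img.data[mask][:, keep] / cp  # (n_vox, n_frames)
    sw = w.sum()
    xm = (w * x).sum() / sw
    ym = (yv * w).sum(axis=1) / sw
    sxx = (w * (x - xm) ** 2).sum()
    if sxx <= 1e-12 * max(1.0, xm ** 2):
        raise ValueError("degenerate Patlak abscissa (zero variance)")
    sxy = ((yv - ym[:, None]) * (w * (x - xm))).sum(axis=1)
    slopes = sxy / sxx
    intercepts = ym - slopes * xm

    bad = ~(np.isfinite(slopes) & np.isfinite(intercepts))
    if bad.any():
        log.warning("masked out %d voxels with non-finite Patlak estimates",
                    int(bad.sum()))
        slopes[bad] = 0.0
        intercepts[bad] = 0.0
    final_mask = mask.copy()
    final_mask[mask] = ~bad
    slope_vol = np.zeros(img.shape)
    intercept_vol = np.zeros(img.shape)
    slope_vol[mask] = slopes
    intercept_vol[mask] = intercepts
    slope_vol[~final_mask] = 0.0
    intercept_vol[~final_mask] = 0.0
    return ParametricImage(slope_vol=slope_vol, intercept_vol=intercept_vol,
                           method=method, t_star=t_star, mask=final_mask)


# ---------------------------------------------------------------------- #
# SUV-type images

def suv_image(img: DynamicImage, window: tuple[float, float] | None = None,
              scale: float = 1.0) -> np.ndarray:
    """Duration-weighted mean activity over frames inside a time window.

    Default window is the last 5 minutes of the schedule.  The result is an
    activity-concentration surrogate for SUV; body-weight/dose normalization
    enters only as the optional scalar `scale`.
    """
    if window is None:
        window = (img.schedule.ends[-1] - 5.0, img.schedule.ends[-1])
    w0, w1 = window
    inside = (img.schedule.starts >= w0 - 1e-9) & (img.schedule.ends <= w1 + 1e-9)
    if not inside.any():
        raise ValueError("no frames inside the SUV window")
    dur = img.schedule.durations[inside]
    return scale * (img.data[..., inside] * dur).sum(axis=-1) / dur.sum()


def suvr_image(img: DynamicImage, f: InputFunction, t_star: float,
               frame_select: str = "interp") -> np.ndarray:
    """SUV ratio relative to plasma at t*: C_T(t*)/Cp(t*) per voxel.

    `frame_select` controls how the tissue value at t* is read from the
    frame sequence: 'interp' (default) interpolates voxel TACs linearly in
    time between frame mid-times (extrapolating from the first two frames
    when t* precedes the first mid-time), which keeps the b' = SUVr algebra
    intact; 'nearest' samples the frame whose mid-time is closest to t*.
    """
    sched = img.schedule
    if not (sched.starts[0] - 1e-9 <= t_star <= sched.ends[-1] + 1e-9):
        raise ValueError("t* must lie inside the acquired schedule")
    mids = sched.mid
    if frame_select == "nearest":
        i = int(np.argmin(np.abs(mids - t_star)))
        t_eval = float(mids[i])
        ct = img.data[..., i]
    elif frame_select == "interp":
        t_eval = float(t_star)
        i = int(np.clip(np.searchsorted(mids, t_star) - 1, 0, len(sched) - 2))
        t0, t1 = mids[i], mids[i + 1]
        a = (t_star - t0) / (t1 - t0)
        ct = (1.0 - a) * img.data[..., i] + a * img.data[..., i + 1]
    else:
        raise ValueError(f"unknown frame_select {frame_select!r}")
    cp = float(f(t_eval))
    if cp <= 0:
        raise ValueError("Cp must be positive at the SUVr reference time")
    return ct / cp


# ---------------------------------------------------------------------- #

def estimate_alpha(ki: ParametricImage, kip: ParametricImage,
                   mask: np.ndarray | None = None):
    """Global scaling factor: OLS of the RP slope Ki' on the standard Ki.

    Returns (alpha, intercept, r).
    """
    if ki.slope_vol.shape != kip.slope_vol.shape:
        raise ValueError("parametric images must share geometry")
    if mask is None:
        mask = ki.mask & kip.mask
    mask = np.asarray(mask, bool)
    x = ki.slope_vol[mask]
    y = kip.slope_vol[mask]
    if x.size < 10:
        raise ValueError("need at least 10 voxels to estimate alpha")
    slope, intercept, _ = _line_fit(x, y, None)
    sx = x.std()
    sy = y.std()
    r = float(np.corrcoef(x, y)[0, 1]) if sx > 0 and sy > 0 else 0.0
    return float(slope), float(intercept), r


# ---------------------------------------------------------------------- #

class PatlakImager(BaseEstimator):
    """Voxelwise Patlak imaging as a scikit-learn style estimator.

    Parameters
    ----------
    method : 'standard' | 'relative'
        Which Patlak abscissa to use; 'relative' needs only the late-time
        input function.
    t_star : float
        Equilibrium time in minutes (frames starting earlier are dropped).
    weights : 'none' | 'duration'
        Frame weighting for the regression.

    After ``fit(img, input_function=f)`` the result is available as
    ``image_`` (ParametricImage) plus ``slope_vol_`` / ``intercept_vol_``.
    """

    def __init__(self, method: str = "relative", t_star: float = 40.0,
                 weights: str = "none"):
        self.method = method
        self.t_star = t_star
        self.weights = weights

    def fit(self, X: DynamicImage, y=None, *,
            input_function: InputFunction | None = None,
            mask: np.ndarray | None = None):
        if input_function is None:
            raise ValueError("fit requires input_function=")
        self.image_ = fit_parametric(X, input_function, self.t_star,
                                     method=self.method, mask=mask,
                                     weights=self.weights)
        self.slope_vol_ = self.image_.slope_vol
        self.intercept_vol_ = self.image_.intercept_vol
        self.mask_ = self.image_.mask
        return self
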