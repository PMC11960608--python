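"""ROI quantification and agreement statistics.

Covers the evaluation toolbox for parametric images: ROI means,
lesion-to-liver contrast ratios and their percentage differences, liver
noise level (SD/mean), coefficient of variation, linear agreement regression
with 95% CI and prediction interval, Bland--Altman limits of agreement,
healthy-cohort calibration of the RP slope, and a population-based input
function (PIF) built from healthy-subject inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .kinetics import InputFunction
from .patlak import ParametricImage

__all__ = [
    "ROISet",
    "AgreementReport",
    "BlandAltman",
    "roi_mean",
    "contrast_ratio",
    "cr_percent_diff",
    "roi_percent_diff",
    "noise_level",
    "coefficient_of_variation",
    "agreement_regression",
    "bland_altman",
    "paired_tests",
    "calibrate_ki",
    "build_pif",
    "scale_pif",
]


@dataclass(frozen=True)
class ROISet:
    """Integer label volume plus label -> name mapping."""

    labels: np.ndarray
    names: dict[int, str]

    def mask(self, name: str) -> np.ndarray:
        for lab, n in self.names.items():
            if n == name:
                m = self.labels == lab
                if not m.any():
                    raise ValueError(f"ROI {name!r} is empty")
                return m
        raise KeyError(f"no ROI named {name!r}")

    @classmethod
    def from_phantom(cls, spec) -> "ROISet":
        return cls(labels=spec.labels, names=dict(spec.organ_names))


@dataclass(frozen=True)
class AgreementReport:
    """OLS agreement fit with inference."""

    slope: float
    intercept: float
    r: float
    p: float
    ci95: tuple[float, float]     # 95% CI of the slope
    pi95: np.ndarray              # (n, 2) per-point 95% prediction band
    n: int


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    loa: tuple[float, float]      # mean_diff +/- 1.96 SD(diffs)
    diffs: np.ndarray


# ---------------------------------------------------------------------- #

def roi_mean(vol: np.ndarray, rois: ROISet, name: str) -> float:
    """Arithmetic mean of a volume over one named ROI."""
    return float(vol[rois.mask(name)].mean())


def contrast_ratio(vol: np.ndarray, rois: ROISet, lesion_name: str,
                   background_name: str = "liver") -> float:
    """Lesion-to-background contrast ratio ROI_lesion / ROI_background."""
    bg = roi_mean(vol, rois, background_name)
    if bg == 0:
        raise ValueError("background ROI mean is zero")
    return roi_mean(vol, rois, lesion_name) / bg


def cr_percent_diff(cr_a: float, cr_b: float) -> float:
    """100 * (CR_a - CR_b) / CR_b."""
    if cr_b == 0:
        raise ValueError("reference contrast ratio is zero")
    return 100.0 * (cr_a - cr_b) / cr_b


def roi_percent_diff(v_denoised: float, v_ref: float) -> float:
    """Percentage quantification difference against a reference ROI value."""
    if v_ref == 0:
        raise ValueError("reference ROI value is zero")
    return 100.0 * (v_denoised - v_ref) / v_ref


def noise_level(vol: np.ndarray, rois: ROISet, name: str = "liver") -> float:
    """Noise level in an ROI: sample SD divided by the mean."""
    vals = vol[rois.mask(name)]
    if vals.size < 2:
        raise ValueError("noise level needs at least 2 voxels")
    mean = vals.mean()
    if mean == 0:
        raise ValueError("ROI mean is zero")
    return float(vals.std(ddof=1) / mean)


def coefficient_of_variation(values) -> float:
    """SD / mean of a sample."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = values.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(values.std(ddof=1) / mean)


# ---------------------------------------------------------------------- #

def agreement_regression(x, y) -> AgreementReport:
    """OLS agreement fit with 95% CI on the slope and a per-point 95%
    prediction interval; r and two-sided p come from the correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need matched vectors with n >= 3")
    if x.std() == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    dof = n - 2
    tcrit = stats.t.ppf(0.975, dof)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    resid = y - (res.intercept + res.slope * x)
    s = np.sqrt((resid ** 2).sum() / dof) if dof > 0 else 0.0
    xm = x.mean()
    sxx = ((x - xm) ** 2).sum()
    half = tcrit * s * np.sqrt(1.0 + 1.0 / n + (x - xm) ** 2 / sxx)
    yhat = res.intercept + res.slope * x
    pi = np.column_stack([yhat - half, yhat + half])
    return AgreementReport(slope=float(res.slope),
                           intercept=float(res.intercept),
                           r=float(res.rvalue), p=float(res.pvalue),
                           ci95=(float(ci[0]), float(ci[1])), pi95=pi, n=n)


def bland_altman(a, b) -> BlandAltman:
    """Bland--Altman agreement: mean difference and 1.96-SD limits."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 2:
        raise ValueError("need n >= 2 pairs")
    diffs = a - b
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltman(mean_diff=mean, loa=(mean - 1.96 * sd, mean + 1.96 * sd),
                       diffs=diffs)


def paired_tests(a, b) -> dict:
    """Two-sided paired t test and Wilcoxon signed-rank test (exact for
    n <= 25, normal approximation beyond); significance at 0.05."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t_res = stats.ttest_rel(a, b)
    method = "exact" if a.size <= 25 else "approx"
    try:
        w_res = stats.wilcoxon(a, b, method=method)
        p_w = float(w_res.pvalue)
    except ValueError:  # all differences zero
        p_w = 1.0
    return {"p_t": float(t_res.pvalue), "p_wilcoxon": p_w}


# ---------------------------------------------------------------------- #

def calibrate_ki(kip: ParametricImage, alpha_cohort: float) -> ParametricImage:
    """Divide the RP slope by a cohort-level alpha to put it on the standard
    Patlak Ki scale."""
    if alpha_cohort <= 0:
        raise ValueError("alpha must be positive")
    return ParametricImage(slope_vol=kip.slope_vol / alpha_cohort,
                           intercept_vol=kip.intercept_vol.copy(),
                           method="standard-calibrated",
                           t_star=kip.t_star, mask=kip.mask)


# ---------------------------------------------------------------------- #
# population-based input function

def build_pif(healthy_inputs: list[InputFunction],
              anchor_window: tuple[float, float],
              grid_step: float = 0.1) -> InputFunction:
    """Population-based input function.

    Each input is normalized by its mean over the anchor window (default use:
    [t*, scan end], the blood data a short scan actually has), then the
    normalized curves are averaged pointwise on a common grid.  The result
    has unit mean over the anchor window; `scale_pif` rescales it to a
    subject's measured late-window blood mean.
    """
    if len(healthy_inputs) < 2:
        raise ValueError("PIF needs at least 2 input functions")
    w0, w1 = anchor_window
    if not 0 <= w0 < w1:
        raise ValueError("invalid anchor window")
    t = np.arange(0.0, w1 + grid_step / 2, grid_step)
    acc = np.zeros_like(t)
    for f in healthy_inputs:
        anchor = f.integral(w0, w1) / (w1 - w0)
        if anchor <= 0:
            raise ValueError("input has nonpositive anchor-window mean")
        acc += f(t) / anchor
    return InputFunction.from_samples(t, acc / len(healthy_inputs))


def scale_pif(pif: InputFunction, blood_mean: float) -> InputFunction:
    """Rescale a unit-anchor PIF by a subject's late-window blood mean."""
    if blood_mean <= 0:
        raise ValueError("blood mean must be positive")
    return InputFunction.from_samples(pif.times, pif.values * blood_mean)
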