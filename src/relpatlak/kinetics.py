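"""Continuous-time kinetic models for dynamic FDG PET simulation.

This module provides the arterial plasma input function :math:`C_p(t)` (a
Feng-type sum of exponentials or an arbitrary sampled series) and the
irreversible two-tissue-compartment model that generates ground-truth tissue
time--activity curves.  All times are minutes and all activity concentrations
are kBq/mL; simulated activities are decay-corrected by construction, so no
isotope half-life enters the math.

The two-tissue irreversible model is

.. math::

    \\dot C_1 = K_1 C_p - (k_2 + k_3) C_1, \\qquad \\dot C_2 = k_3 C_1,

with total tissue activity :math:`C_T = C_1 + C_2` and measured voxel
activity :math:`C_{PET} = (1 - v_b) C_T + v_b C_p`.  At late times the model
obeys Patlak linearity with net influx rate
:math:`K_i = K_1 k_3 / (k_2 + k_3)`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid, simpson
from scipy.signal import lfilter

__all__ = [
    "FrameSchedule",
    "InputFunction",
    "KineticParams",
    "TissueCurve",
    "eval_input",
    "integrate_input",
    "tissue_curve",
    "FENG_DEFAULT_PARAMS",
]

#: Classic Feng model coefficients for an FDG bolus: amplitudes in kBq/mL
#: (A1 in kBq/mL/min), eigenvalues in 1/min.  Peak near 0.55 min, terminal
#: clearance dominated by the slow |lambda3| = 0.0105/min component.
FENG_DEFAULT_PARAMS = {
    "A1": 851.1225,
    "A2": 21.8798,
    "A3": 20.8113,
    "lambda1": -4.133859,
    "lambda2": -0.1191,
    "lambda3": -0.0104728,
}

#: Quadrature step (min) for input-function integrals; well below the ~1 min
#: width of the bolus peak.
QUADRATURE_STEP = 0.05

#: Fine-grid step (min) for tissue-curve generation.  One second, so that
#: frame boundaries on whole-second schedules fall exactly on grid nodes.
CURVE_STEP = 1.0 / 60.0


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered, non-overlapping acquisition frames (start/end in minutes)."""

    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self):
        starts = np.asarray(self.starts, dtype=float)
        ends = np.asarray(self.ends, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        if starts.ndim != 1 or starts.shape != ends.shape or starts.size == 0:
            raise ValueError("starts/ends must be matching nonempty 1-D arrays")
        if not np.all(ends > starts):
            raise ValueError("every frame must have end > start")
        if np.any(np.diff(starts) <= 0) or np.any(starts[1:] < ends[:-1] - 1e-9):
            raise ValueError("frames must be increasing and non-overlapping")

    def __len__(self) -> int:
        return int(self.starts.size)

    @property
    def n_frames(self) -> int:
        return len(self)

    @property
    def durations(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def mid(self) -> np.ndarray:
        return 0.5 * (self.starts + self.ends)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.starts[0]), float(self.ends[-1])


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the irreversible two-tissue FDG model.

    K1 is in mL/min/cm^3, k2 and k3 in 1/min, vb is the unitless fractional
    blood volume.
    """

    K1: float
    k2: float
    k3: float
    vb: float = 0.0

    def __post_init__(self):
        if self.K1 < 0:
            raise ValueError("K1 must be >= 0")
        if self.k2 <= 0:
            raise ValueError("k2 must be > 0")
        if self.k3 < 0:
            raise ValueError("k3 must be >= 0")
        if not 0 <= self.vb < 1:
            raise ValueError("vb must be in [0, 1)")

    @property
    def ki_true(self) -> float:
        """Net influx rate K1*k3/(k2+k3) (mL/min/cm^3)."""
        return self.K1 * self.k3 / (self.k2 + self.k3)


@dataclass(frozen=True)
class TissueCurve:
    """Frame-averaged tissue activity sampled at frame mid-times."""

    times: np.ndarray
    values: np.ndarray
    schedule: FrameSchedule

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if len(values) != len(self.schedule):
            raise ValueError("curve length must equal number of frames")
        if not np.all(np.isfinite(values)):
            raise ValueError("curve values must be finite")


class InputFunction:
    """Plasma input function Cp(t), parametric (Feng) or sampled.

    The Feng form is

    .. math::

        C_p(t) = (A_1 t - A_2 - A_3) e^{\\lambda_1 t}
                 + A_2 e^{\\lambda_2 t} + A_3 e^{\\lambda_3 t},

    which satisfies Cp(0) = 0.  A sampled input interpolates linearly
    between samples and extrapolates beyond the last sample with a
    terminal mono-exponential fitted to the final samples.
    """

    def __init__(self, kind: str, params: dict | None = None,
                 times: np.ndarray | None = None,
                 values: np.ndarray | None = None):
        if kind not in ("feng", "sampled"):
            raise ValueError(f"unknown input-function kind {kind!r}")
        self.kind = kind
        if kind == "feng":
            self.params = dict(FENG_DEFAULT_PARAMS)
            if params:
                unknown = set(params) - set(FENG_DEFAULT_PARAMS)
                if unknown:
                    raise ValueError(f"unknown Feng parameters: {sorted(unknown)}")
                self.params.update(params)
            self.times = None
            self.values = None
        else:
            times = np.asarray(times, dtype=float)
            values = np.asarray(values, dtype=float)
            if times.ndim != 1 or times.shape != values.shape or times.size < 2:
                raise ValueError("sampled input needs >= 2 (time, value) pairs")
            if np.any(np.diff(times) <= 0):
                raise ValueError("sample times must be strictly increasing")
            if np.any(times < 0):
                raise ValueError("sample times must be >= 0")
            if np.any(values < -1e-12):
                raise ValueError("input-function values must be >= 0")
            self.params = dict(params) if params else {}
            self.times = times
            self.values = np.clip(values, 0.0, None)
            self._tail_amp, self._tail_rate = self._fit_tail()

    # ------------------------------------------------------------------ #
    @classmethod
    def feng(cls, **overrides) -> "InputFunction":
        return cls("feng", params=overrides)

    @classmethod
    def from_samples(cls, times, values) -> "InputFunction":
        return cls("sampled", times=times, values=values)

    # ------------------------------------------------------------------ #
    def _fit_tail(self) -> tuple[float, float]:
        """Terminal exponential A*exp(-rate*(t-t_last)) anchored at the tail."""
        n_tail = min(5, self.times.size)
        t = self.times[-n_tail:]
        v = self.values[-n_tail:]
        pos = v > 0
        if pos.sum() < 2:
            return float(v[-1]), 0.0
        coef = np.polyfit(t[pos], np.log(v[pos]), 1)
        rate = max(-coef[0], 0.0)  # never extrapolate with growth
        return float(v[-1]), float(rate)

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        if np.any(t < 0):
            raise ValueError("input function is only defined for t >= 0")
        if self.kind == "feng":
            p = self.params
            out = ((p["A1"] * t - p["A2"] - p["A3"]) * np.exp(p["lambda1"] * t)
                   + p["A2"] * np.exp(p["lambda2"] * t)
                   + p["A3"] * np.exp(p["lambda3"] * t))
            out = np.clip(out, 0.0, None)
        else:
            out = np.interp(t, self.times, self.values)
            late = t > self.times[-1]
            if np.any(late):
                dt = t[late] - self.times[-1]
                out[late] = self._tail_amp * np.exp(-self._tail_rate * dt)
        return float(out[0]) if scalar else out

    # ------------------------------------------------------------------ #
    def antiderivative(self, t: float) -> float:
        """F(t) = integral of Cp from 0 to t; integrals use F(b) - F(a) so
        that interval additivity holds exactly."""
        t = float(t)
        if t < 0:
            raise ValueError("t must be >= 0")
        if t == 0:
            return 0.0
        if self.kind == "sampled":
            return self._antiderivative_sampled(t)
        # composite Simpson on a grid with step <= QUADRATURE_STEP
        n = max(2, int(np.ceil(t / QUADRATURE_STEP)))
        if n % 2:
            n += 1
        grid = np.linspace(0.0, t, n + 1)
        return float(simpson(self(grid), x=grid))

    def _antiderivative_sampled(self, t: float) -> float:
        # exact integral of the piecewise-linear interpolant + analytic tail
        knots = self.times[self.times < t]
        grid = np.unique(np.concatenate([[0.0], knots, [t]]))
        t_last = self.times[-1]
        if t <= t_last:
            vals = np.interp(grid, self.times, self.values)
            return float(np.trapezoid(vals, grid))
        head = grid[grid <= t_last]
        if head.size == 0 or head[-1] < t_last:
            head = np.append(head, t_last)
        base = float(np.trapezoid(np.interp(head, self.times, self.values), head))
        dt = t - t_last
        if self._tail_rate > 0:
            tail = self._tail_amp / self._tail_rate * (1.0 - np.exp(-self._tail_rate * dt))
        else:
            tail = self._tail_amp * dt
        return base + float(tail)

    def integral(self, t0: float, t1: float) -> float:
        """Integral of Cp over [t0, t1] (kBq/mL * min)."""
        if t0 < 0 or t1 < t0:
            raise ValueError("require 0 <= t0 <= t1")
        return self.antiderivative(t1) - self.antiderivative(t0)


# ---------------------------------------------------------------------- #
# module-level operation wrappers

def eval_input(f: InputFunction, t) -> np.ndarray:
    """Evaluate Cp(t) at the given times (minutes)."""
    return f(t)


def integrate_input(f: InputFunction, t0: float, t1: float) -> float:
    """Integral of the plasma input over [t0, t1]."""
    return f.integral(t0, t1)


def _fine_grid(t_end: float, dt: float = CURVE_STEP) -> np.ndarray:
    n = int(np.ceil(t_end / dt + 1e-9))
    return np.linspace(0.0, n * dt, n + 1)


def continuous_tissue_curve(f: InputFunction, p: KineticParams,
                            t_end: float, dt: float = CURVE_STEP):
    """Solve the two-tissue model on a fine grid; returns (t, C_PET).

    C1 is advanced with an exact exponential integrator for piecewise-linear
    Cp (an IIR recursion, evaluated with scipy.signal.lfilter); the trapped
    compartment C2 = k3 * cumulative integral of C1.
    """
    t = _fine_grid(t_end, dt)
    cp = f(t)
    beta = p.k2 + p.k3
    step = t[1] - t[0]
    e = np.exp(-beta * step)
    i0 = (1.0 - e) / beta
    i1 = (step - i0) / beta
    c_new = p.K1 * i1 / step               # weight of Cp at the new node
    c_old = p.K1 * (i0 - i1 / step)        # weight of Cp at the previous node
    c1 = lfilter([c_new, c_old], [1.0, -e], cp)
    # lfilter starts from y[0] = c_new*cp[0]; the model requires C1(0) = 0
    c1 -= c_new * cp[0] * e ** np.arange(t.size)
    c2 = p.k3 * cumulative_trapezoid(c1, t, initial=0.0)
    ct = c1 + c2
    return t, (1.0 - p.vb) * ct + p.vb * cp


def frame_average(t: np.ndarray, values: np.ndarray,
                  sched: FrameSchedule) -> np.ndarray:
    """Time-average a continuous curve over each frame interval."""
    cum = cumulative_trapezoid(values, t, initial=0.0)
    lo = np.interp(sched.starts, t, cum)
    hi = np.interp(sched.ends, t, cum)
    return (hi - lo) / sched.durations


def tissue_curve(f: InputFunction, p: KineticParams,
                 sched: FrameSchedule) -> TissueCurve:
    """Frame-averaged voxel activity C_PET = (1-vb)*C_T + vb*Cp.

    Each frame value is the time-average of the continuous solution over
    [start, end]; the frame mid-time is the curve's abscissa.
    """
    t, cpet = continuous_tissue_curve(f, p, sched.span[1])
    return TissueCurve(times=sched.mid, values=frame_average(t, cpet, sched),
                       schedule=sched)
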