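"""Synthetic total-body dynamic FDG-PET phantom.

Builds a deterministic multi-organ label volume (ellipsoid-composed, scaled
to any grid), assigns per-organ two-tissue kinetics that obey Patlak
linearity at late times, and simulates a 4-D dynamic acquisition with
count-dependent Gaussian noise (per-frame SD proportional to
sqrt(mean activity / frame duration), the dependence reconstruction noise
shows on frame duration and count level).

The default frame schedules mirror a 1-h total-body protocol: 29 frames
(6x10 s, 2x30 s, 6x60 s, 5x120 s, 4x180 s, 6x300 s) for the full scan and
4 contiguous 5-min frames for the late 20-min short-scan setting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .kinetics import FrameSchedule, InputFunction, KineticParams, tissue_curve

__all__ = [
    "PhantomConfig",
    "PhantomSpec",
    "DynamicImage",
    "default_schedule_1h",
    "late_schedule",
    "build_phantom",
    "simulate_dynamic",
    "DEFAULT_ORGAN_PARAMS",
    "DEFAULT_NOISE_SCALE",
]

log = logging.getLogger(__name__)

#: Noise level used by the packaged short-scan denoising study: chosen so a
#: non-denoised late-window Ki' map has liver SD/mean well above 0.3,
#: i.e. visibly noisy voxelwise Patlak maps.
DEFAULT_NOISE_SCALE = 1.0

#: Typical FDG rate constants (K1 mL/min/cm^3; k2, k3 1/min; vb fraction).
#: Lesions are hypermetabolic (high k3) so Ki clearly exceeds liver Ki.
DEFAULT_ORGAN_PARAMS: dict[str, KineticParams] = {
    "muscle": KineticParams(K1=0.047, k2=0.325, k3=0.022, vb=0.04),
    "liver": KineticParams(K1=0.864, k2=0.981, k3=0.005, vb=0.15),
    "lung": KineticParams(K1=0.108, k2=0.735, k3=0.016, vb=0.15),
    "spleen": KineticParams(K1=1.207, k2=1.909, k3=0.008, vb=0.20),
    "gray_matter": KineticParams(K1=0.107, k2=0.165, k3=0.069, vb=0.05),
    "bone_marrow": KineticParams(K1=0.425, k2=1.055, k3=0.023, vb=0.05),
    "myocardium": KineticParams(K1=0.600, k2=1.200, k3=0.100, vb=0.30),
    "lesion_1": KineticParams(K1=0.350, k2=0.750, k3=0.100, vb=0.05),
    "lesion_2": KineticParams(K1=0.300, k2=0.600, k3=0.150, vb=0.05),
    "lesion_3": KineticParams(K1=0.250, k2=0.550, k3=0.120, vb=0.05),
}

# organ geometry as (center, semi-axes) in fractional grid coordinates;
# painted in order, later entries overwrite earlier ones
_ORGAN_GEOMETRY: list[tuple[str, tuple, tuple]] = [
    ("muscle", (0.50, 0.50, 0.56), (0.40, 0.34, 0.36)),       # torso
    ("gray_matter", (0.50, 0.50, 0.09), (0.30, 0.30, 0.075)),  # head
    ("lung", (0.33, 0.46, 0.32), (0.13, 0.15, 0.09)),
    ("lung", (0.67, 0.46, 0.32), (0.13, 0.15, 0.09)),
    ("liver", (0.63, 0.52, 0.50), (0.20, 0.22, 0.075)),
    ("spleen", (0.30, 0.56, 0.47), (0.09, 0.10, 0.05)),
    ("bone_marrow", (0.50, 0.70, 0.56), (0.055, 0.055, 0.33)),  # spine
    ("myocardium", (0.50, 0.50, 0.335), (0.085, 0.085, 0.05)),
    ("blood_pool", (0.50, 0.58, 0.42), (0.055, 0.055, 0.16)),   # aorta
]

# lesion centers (fractional) and radii in voxels: lung, liver, pelvis
_LESION_SITES = [
    ((0.67, 0.40, 0.31), 2.0),
    ((0.58, 0.46, 0.50), 2.0),
    ((0.45, 0.52, 0.80), 3.0),
]

REQUIRED_ORGANS = ("blood_pool", "liver", "lung", "spleen", "muscle",
                   "gray_matter", "bone_marrow", "myocardium")


@dataclass(frozen=True)
class PhantomConfig:
    """Grid and content of the synthetic phantom."""

    shape: tuple[int, int, int] = (48, 48, 96)
    voxel_mm: float = 4.0
    n_lesions: int = 3
    organ_params: dict[str, KineticParams] = field(
        default_factory=lambda: dict(DEFAULT_ORGAN_PARAMS))


@dataclass(frozen=True)
class PhantomSpec:
    """Label volume plus per-organ kinetics."""

    shape: tuple[int, int, int]
    voxel_mm: float
    labels: np.ndarray
    organ_params: dict[int, KineticParams]
    organ_names: dict[int, str]

    def label_of(self, name: str) -> int:
        for lab, n in self.organ_names.items():
            if n == name:
                return lab
        raise KeyError(f"no organ named {name!r}")

    @property
    def name_to_label(self) -> dict[str, int]:
        return {n: lab for lab, n in self.organ_names.items()}

    def lesion_names(self) -> list[str]:
        return sorted(n for n in self.organ_names.values()
                      if n.startswith("lesion"))


@dataclass(frozen=True)
class DynamicImage:
    """4-D activity array (x, y, z, frame) with its schedule and voxel size."""

    data: np.ndarray
    schedule: FrameSchedule
    voxel_mm: float = 4.0

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 4:
            raise ValueError("dynamic image must be 4-D (x, y, z, frame)")
        if data.shape[3] != len(self.schedule):
            raise ValueError("frame axis must match schedule length")
        if not np.all(np.isfinite(data)):
            raise ValueError("dynamic image must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]


# ---------------------------------------------------------------------- #
# frame schedules

def default_schedule_1h() -> FrameSchedule:
    """29-frame 1-h dynamic protocol: 6x10s, 2x30s, 6x60s, 5x120s, 4x180s,
    6x300s (durations in seconds; schedule stored in minutes)."""
    dur_s = [10] * 6 + [30] * 2 + [60] * 6 + [120] * 5 + [180] * 4 + [300] * 6
    ends = np.cumsum(dur_s) / 60.0
    starts = ends - np.asarray(dur_s) / 60.0
    return FrameSchedule(starts=starts, ends=ends)


def late_schedule(t_start: float = 40.0, n: int = 4,
                  dur: float = 5.0) -> FrameSchedule:
    """n contiguous frames of length dur (min) starting at t_start."""
    if n < 1 or dur <= 0:
        raise ValueError("require n >= 1 and dur > 0")
    starts = t_start + dur * np.arange(n)
    return FrameSchedule(starts=starts, ends=starts + dur)


# ---------------------------------------------------------------------- #
# phantom construction

def _paint_ellipsoid(labels: np.ndarray, center_frac, semi_frac, value: int):
    shape = np.asarray(labels.shape, dtype=float)
    c = np.asarray(center_frac) * (shape - 1)
    r = np.maximum(np.asarray(semi_frac) * shape, 1.0)
    x, y, z = np.ogrid[:labels.shape[0], :labels.shape[1], :labels.shape[2]]
    d = (((x - c[0]) / r[0]) ** 2 + ((y - c[1]) / r[1]) ** 2
         + ((z - c[2]) / r[2]) ** 2)
    inside = d <= 1.0
    n_over = int(np.count_nonzero(labels[inside] != 0))
    if n_over:
        log.debug("label %d overwrites %d voxels", value, n_over)
    labels[inside] = value


def _paint_sphere_vox(labels: np.ndarray, center_frac, radius_vox: float,
                      value: int):
    shape = np.asarray(labels.shape, dtype=float)
    c = np.asarray(center_frac) * (shape - 1)
    x, y, z = np.ogrid[:labels.shape[0], :labels.shape[1], :labels.shape[2]]
    d = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2
    labels[d <= radius_vox ** 2] = value


def build_phantom(config: PhantomConfig | None = None) -> PhantomSpec:
    """Deterministic multi-organ label volume with kinetic parameters.

    Organs are painted in a fixed order; where shapes overlap the later
    label wins (logged at debug level).  Lesions are small spheres embedded
    in lung, liver and pelvis.
    """
    config = config or PhantomConfig()
    if config.n_lesions < 1:
        raise ValueError("phantom must contain at least one lesion")
    if config.n_lesions > len(_LESION_SITES):
        raise ValueError(f"at most {len(_LESION_SITES)} lesions supported")

    labels = np.zeros(config.shape, dtype=np.int16)
    names: dict[int, str] = {}
    name_to_label: dict[str, int] = {}
    next_label = 1
    for name, center, semi in _ORGAN_GEOMETRY:
        if name not in name_to_label:
            name_to_label[name] = next_label
            names[next_label] = name
            next_label += 1
        _paint_ellipsoid(labels, center, semi, name_to_label[name])
    for i in range(config.n_lesions):
        center, radius = _LESION_SITES[i]
        name = f"lesion_{i + 1}"
        name_to_label[name] = next_label
        names[next_label] = name
        _paint_sphere_vox(labels, center, radius, next_label)
        next_label += 1

    params: dict[int, KineticParams] = {}
    for lab, name in names.items():
        if name == "blood_pool":
            continue  # carries Cp itself
        if name not in config.organ_params:
            raise ValueError(f"no kinetic parameters for organ {name!r}")
        params[lab] = config.organ_params[name]

    spec = PhantomSpec(shape=config.shape, voxel_mm=config.voxel_mm,
                       labels=labels, organ_params=params, organ_names=names)
    _validate_phantom(spec)
    return spec


def _validate_phantom(spec: PhantomSpec):
    present = set(spec.organ_names.values())
    missing = [n for n in REQUIRED_ORGANS if n not in present]
    if missing:
        raise ValueError(f"phantom is missing required organs: {missing}")
    lesions = spec.lesion_names()
    if not lesions:
        raise ValueError("phantom must contain at least one lesion")
    liver_ki = spec.organ_params[spec.label_of("liver")].ki_true
    if not any(spec.organ_params[spec.label_of(n)].ki_true > liver_ki
               for n in lesions):
        raise ValueError("at least one lesion must have Ki above liver Ki")
    for lab in spec.organ_names:
        if np.count_nonzero(spec.labels == lab) == 0:
            raise ValueError(
                f"organ {spec.organ_names[lab]!r} has no voxels on this grid")


# ---------------------------------------------------------------------- #
# dynamic simulation

def organ_curves(spec: PhantomSpec, f: InputFunction,
                 sched: FrameSchedule) -> dict[int, np.ndarray]:
    """Noise-free frame-averaged activity per organ label.

    Blood-pool voxels carry the frame-averaged plasma input itself.
    """
    from .kinetics import _fine_grid, frame_average

    curves: dict[int, np.ndarray] = {}
    t = _fine_grid(sched.span[1])
    cp_avg = frame_average(t, f(t), sched)
    for lab, name in spec.organ_names.items():
        if name == "blood_pool":
            curves[lab] = cp_avg
        else:
            curves[lab] = tissue_curve(f, spec.organ_params[lab], sched).values
    return curves


def noise_free_dynamic(spec: PhantomSpec, f: InputFunction,
                       sched: FrameSchedule) -> DynamicImage:
    """Assemble the noise-free 4-D image from per-organ curves."""
    curves = organ_curves(spec, f, sched)
    data = np.zeros(spec.shape + (len(sched),), dtype=float)
    for lab, curve in curves.items():
        data[spec.labels == lab] = curve
    return DynamicImage(data=data, schedule=sched, voxel_mm=spec.voxel_mm)


def nominal_noise_sd(img: DynamicImage, noise_scale: float) -> np.ndarray:
    """Per-frame noise SD: noise_scale * sqrt(mean frame activity / duration)."""
    mean_act = np.clip(img.data.reshape(-1, img.n_frames).mean(axis=0), 0, None)
    return noise_scale * np.sqrt(mean_act / img.schedule.durations)


def simulate_dynamic(spec: PhantomSpec, f: InputFunction, sched: FrameSchedule,
                     noise_scale: float = 0.0, seed: int = 0) -> DynamicImage:
    """Simulate a dynamic acquisition.

    Additive Gaussian noise per frame with SD proportional to
    sqrt(mean activity / duration); negative noisy values are retained so
    downstream fits stay unbiased.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    img = noise_free_dynamic(spec, f, sched)
    if noise_scale == 0:
        return img
    rng = np.random.default_rng(seed)
    sd = nominal_noise_sd(img, noise_scale)
    noisy = img.data + rng.normal(0.0, 1.0, img.data.shape) * sd
    return DynamicImage(data=noisy, schedule=sched, voxel_mm=spec.voxel_mm)
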