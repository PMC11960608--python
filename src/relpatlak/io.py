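"""Standard-format I/O: NIfTI volumes with JSON sidecars, input-function
tables, label maps and study configuration.

Conventions: all volumes are written as .nii.gz with a diagonal affine from
the voxel size (the math operates in voxel-index space; an existing affine
is preserved verbatim on round trip); times are minutes and activities
kBq/mL everywhere, converted only at this boundary.  Every sidecar carries
the package version and a hash of the configuration it was produced with.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from . import __version__
from .analysis import ROISet
from .kinetics import FrameSchedule, InputFunction
from .patlak import ParametricImage
from .phantom import DynamicImage, PhantomSpec

__all__ = [
    "StudyConfig",
    "read_dynamic",
    "write_dynamic",
    "read_input_table",
    "write_input_table",
    "extract_input_from_image",
    "read_labels",
    "write_labels",
    "write_parametric",
    "read_parametric",
    "load_config",
]


@dataclass
class StudyConfig:
    """Configuration of a simulation/fit run (YAML-serializable)."""

    grid: tuple[int, int, int] = (48, 48, 96)
    voxel_mm: float = 4.0
    t_star: float = 40.0
    schedule: dict = field(default_factory=lambda: {
        "kind": "late", "t_start": 40.0, "n": 4, "dur": 5.0})
    noise_scale: float = 1.0
    seed: int = 0
    denoise: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.t_star < 0:
            raise ValueError("t_star must be >= 0")


def load_config(path) -> StudyConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "grid" in raw:
        raw["grid"] = tuple(raw["grid"])
    return StudyConfig(**raw)


def _config_hash(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _sidecar_base(extra: dict) -> dict:
    side = dict(extra)
    side["version"] = __version__
    side["config_hash"] = _config_hash(extra)
    return side


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


# ---------------------------------------------------------------------- #
# dynamic images

def write_dynamic(img: DynamicImage, path, *, seed: int | None = None,
                  noise_scale: float | None = None,
                  affine: np.ndarray | None = None) -> Path:
    path = Path(path)
    if affine is None:
        affine = np.diag([img.voxel_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(img.data.astype(np.float32), affine), str(path))
    side = _sidecar_base({
        "starts_min": img.schedule.starts.tolist(),
        "ends_min": img.schedule.ends.tolist(),
        "voxel_mm": img.voxel_mm,
        "seed": seed,
        "noise_scale": noise_scale,
    })
    _sidecar_path(path).write_text(json.dumps(side, indent=2))
    return path


def _schedule_from_legacy_csv(path: Path, n_frames: int) -> FrameSchedule:
    arr = np.loadtxt(path, delimiter=",", ndmin=2)
    if arr.shape[1] != 3:
        raise ValueError(f"legacy schedule CSV {path} must have 3 columns")
    warnings.warn(f"reading legacy 3-column schedule CSV {path}", UserWarning)
    sched = FrameSchedule(starts=arr[:, 1], ends=arr[:, 2])
    if len(sched) != n_frames:
        raise ValueError(
            f"{path}: schedule has {len(sched)} frames, image has {n_frames}")
    return sched


def read_dynamic(path) -> DynamicImage:
    """Read a 4-D NIfTI with its JSON sidecar (or legacy schedule CSV)."""
    path = Path(path)
    nii = nib.load(str(path))
    data = np.asanyarray(nii.dataobj).astype(np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D dynamic image")
    side_path = _sidecar_path(path)
    if side_path.exists():
        side = json.loads(side_path.read_text())
        sched = FrameSchedule(starts=np.asarray(side["starts_min"]),
                              ends=np.asarray(side["ends_min"]))
        voxel_mm = float(side.get("voxel_mm",
                                  float(nii.header.get_zooms()[0])))
        if len(sched) != data.shape[3]:
            raise ValueError(
                f"{side_path}: sidecar lists {len(sched)} frames but "
                f"{path} has {data.shape[3]}")
    else:
        csv_path = side_path.with_suffix(".csv")
        if not csv_path.exists():
            raise FileNotFoundError(
                f"no sidecar {side_path} (or legacy {csv_path}) for {path}")
        sched = _schedule_from_legacy_csv(csv_path, data.shape[3])
        voxel_mm = float(nii.header.get_zooms()[0])
    return DynamicImage(data=data, schedule=sched, voxel_mm=voxel_mm)


# ---------------------------------------------------------------------- #
# input functions

def read_input_table(path) -> InputFunction:
    """2-column delimited text (time_min, kBq_per_mL); header optional."""
    path = Path(path)
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.replace(",", " ").replace("\t", " ").split()
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except (ValueError, IndexError):
            if rows:
                raise ValueError(f"{path}: malformed row {line!r}")
            continue  # header line
    if len(rows) < 2:
        raise ValueError(f"{path}: need at least 2 data rows")
    arr = np.asarray(rows)
    if np.any(np.diff(arr[:, 0]) <= 0):
        raise ValueError(f"{path}: times must be strictly increasing")
    return InputFunction.from_samples(arr[:, 0], arr[:, 1])


def write_input_table(f: InputFunction, path, header: bool = True) -> Path:
    path = Path(path)
    if f.kind != "sampled":
        raise ValueError("only sampled input functions are serialized; "
                         "sample a parametric one first")
    lines = ["time_min\tkBq_per_mL"] if header else []
    lines += [f"{t:.6g}\t{v:.8g}" for t, v in zip(f.times, f.values)]
    path.write_text("\n".join(lines) + "\n")
    return path


def extract_input_from_image(img: DynamicImage, rois: ROISet,
                             name: str = "blood_pool") -> InputFunction:
    """Image-derived input function: per-frame ROI mean at frame mid-times."""
    mask = rois.mask(name)
    tac = img.data[mask].mean(axis=0)
    return InputFunction.from_samples(img.schedule.mid, np.clip(tac, 0, None))


# ---------------------------------------------------------------------- #
# label maps and parametric images

def write_labels(spec_or_rois, path) -> Path:
    path = Path(path)
    if isinstance(spec_or_rois, PhantomSpec):
        labels, names = spec_or_rois.labels, spec_or_rois.organ_names
        voxel_mm = spec_or_rois.voxel_mm
    else:
        labels, names = spec_or_rois.labels, spec_or_rois.names
        voxel_mm = 4.0
    affine = np.diag([voxel_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(labels.astype(np.int16), affine), str(path))
    side = _sidecar_base({"names": {str(k): v for k, v in names.items()}})
    _sidecar_path(path).write_text(json.dumps(side, indent=2))
    return path


def read_labels(path) -> ROISet:
    path = Path(path)
    nii = nib.load(str(path))
    labels = np.asanyarray(nii.dataobj).astype(np.int32)
    side_path = _sidecar_path(path)
    if side_path.exists():
        names = {int(k): v for k, v in
                 json.loads(side_path.read_text())["names"].items()}
    else:
        names = {int(lab): f"label_{lab}" for lab in np.unique(labels)
                 if lab != 0}
    return ROISet(labels=labels, names=names)


def write_parametric(pimg: ParametricImage, prefix, *,
                     mask_rule: str = "last_frame_gt_1pct_max",
                     n_dropped_voxels: int = 0,
                     voxel_mm: float = 4.0) -> dict:
    """Write slope/intercept volumes plus a JSON sidecar."""
    prefix = Path(prefix)
    affine = np.diag([voxel_mm] * 3 + [1.0])
    paths = {}
    for tag, vol in (("slope", pimg.slope_vol),
                     ("intercept", pimg.intercept_vol)):
        p = prefix.parent / f"{prefix.name}_{tag}.nii.gz"
        nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), str(p))
        paths[tag] = p
    side = _sidecar_base({
        "method": pimg.method,
        "t_star_min": pimg.t_star,
        "mask_rule": mask_rule,
        "n_dropped_voxels": int(n_dropped_voxels),
    })
    side_path = prefix.parent / f"{prefix.name}.json"
    side_path.write_text(json.dumps(side, indent=2))
    paths["sidecar"] = side_path
    return paths


def read_parametric(prefix) -> ParametricImage:
    prefix = Path(prefix)
    side = json.loads((prefix.parent / f"{prefix.name}.json").read_text())
    vols = {}
    for tag in ("slope", "intercept"):
        nii = nib.load(str(prefix.parent / f"{prefix.name}_{tag}.nii.gz"))
        vols[tag] = np.asanyarray(nii.dataobj).astype(np.float64)
    mask = vols["slope"] != 0
    return ParametricImage(slope_vol=vols["slope"],
                           intercept_vol=vols["intercept"],
                           method=side["method"],
                           t_star=float(side["t_star_min"]), mask=mask)
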