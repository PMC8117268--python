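"""Core data containers and file I/O.

Velocity volumes and label masks travel as NIfTI plus a JSON sidecar holding
acquisition metadata (venc, frame interval, voxel size); traces and cohort
tables travel as CSV.  Velocities are stored in cm/s, grid spacing in mm,
frame interval in ms; time axes of traces are in seconds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VelocityField",
    "LumenMask",
    "FlowTrace",
    "RelativePressureTrace",
    "BACKGROUND",
    "TL",
    "FL",
    "read_velocity_field",
    "write_velocity_field",
    "read_mask",
    "write_mask",
    "read_trace",
    "write_trace",
    "refine_static_tissue",
    "write_provenance",
    "FlumenError",
    "GridMismatchError",
    "MetadataError",
]

BACKGROUND, TL, FL = 0, 1, 2
LABEL_NAMES = {TL: "TL", FL: "FL"}

MMHG_PER_PA = 1.0 / 133.322


class FlumenError(Exception):
    """Base class for structured pipeline errors."""


class GridMismatchError(FlumenError):
    """Inputs do not share a congruent voxel grid."""


class MetadataError(FlumenError):
    """Required acquisition metadata is missing or inconsistent."""


def _default_affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    """Grid-to-physical transform placing voxel centers at (i + 1/2) * h mm."""
    aff = np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])
    aff[:3, 3] = 0.5 * np.asarray(voxel_size)
    return aff


@dataclass
class VelocityField:
    """Time-resolved 3-component voxel velocity data.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz, nt, 3)
        Velocity in cm/s.
    voxel_size : tuple of float
        Grid spacing in mm per axis.
    frame_interval : float
        Time between frames in ms.
    venc : float
        Velocity-encoding limit in cm/s.
    affine : ndarray (4, 4), optional
        Grid-to-physical transform (mm).  Defaults to a scaled identity with
        voxel centers at ``(index + 1/2) * voxel_size``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    frame_interval: float
    venc: float
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 5 or self.data.shape[-1] != 3:
            raise MetadataError(
                f"velocity data must have shape (nx, ny, nz, nt, 3), got {self.data.shape}"
            )
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise MetadataError("voxel_size must be positive")
        if self.frame_interval <= 0:
            raise MetadataError("frame_interval must be positive")
        if self.venc is None or self.venc <= 0:
            raise MetadataError("venc metadata is required and must be positive")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.aliased:
            warnings.warn(
                "velocity magnitudes exceed venc; possible aliasing", stacklevel=2
            )

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def period(self) -> float:
        """Cycle duration in seconds (n_frames * frame_interval)."""
        return self.n_frames * self.frame_interval * 1e-3

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds."""
        return np.arange(self.n_frames) * self.frame_interval * 1e-3

    @property
    def aliased(self) -> bool:
        """True if any velocity component exceeds venc (potential aliasing)."""
        return bool(np.any(np.abs(self.data) > self.venc))

    def congruent_with(self, other: "VelocityField | LumenMask") -> bool:
        return (
            self.grid_shape == other.grid_shape
            and np.allclose(self.voxel_size, other.voxel_size)
        )


@dataclass
class LumenMask:
    """Voxel labels {0: background, 1: TL, 2: FL} on a velocity-field grid."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise MetadataError("mask labels must be a 3-D array")
        extra = set(np.unique(self.labels)) - {BACKGROUND, TL, FL}
        if extra:
            raise MetadataError(f"unknown labels in mask: {sorted(extra)}")
        self.labels = self.labels.astype(np.uint8)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def lumen(self, label: int | str) -> np.ndarray:
        """Boolean voxel set of one lumen ('TL'/'FL' or label integer)."""
        label = resolve_label(label)
        return self.labels == label

    def count(self, label: int | str) -> int:
        return int(self.lumen(label).sum())


def resolve_label(label: int | str) -> int:
    if isinstance(label, str):
        try:
            return {"TL": TL, "FL": FL, "BACKGROUND": BACKGROUND}[label.upper()]
        except KeyError:
            raise MetadataError(f"unknown lumen name {label!r}") from None
    if label not in (BACKGROUND, TL, FL):
        raise MetadataError(f"unknown lumen label {label!r}")
    return int(label)


@dataclass
class FlowTrace:
    """Flow rate through one analysis plane, per cardiac frame."""

    time: np.ndarray  # s
    flow_rate: np.ndarray  # ml/s
    plane_id: str = "plane"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.flow_rate = np.asarray(self.flow_rate, dtype=float)
        if self.time.shape != self.flow_rate.shape:
            raise MetadataError("time and flow_rate must have equal length")
        if self.time.size > 1 and np.any(np.diff(self.time) <= 0):
            raise MetadataError("trace time must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.time.size


@dataclass
class RelativePressureTrace:
    """Inlet-to-outlet relative pressure per frame.

    ``delta_p`` is in mmHg, or mmHg/m when ``normalized`` is set (in which
    case ``length_used`` carries the normalizing centerline length in m).
    """

    time: np.ndarray
    delta_p: np.ndarray
    lumen: str = "FL"
    normalized: bool = False
    length_used: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.delta_p = np.asarray(self.delta_p, dtype=float)
        if self.time.shape != self.delta_p.shape:
            raise MetadataError("time and delta_p must have equal length")
        if self.normalized and not (self.length_used and self.length_used > 0):
            raise MetadataError("normalized traces require length_used > 0")

    @property
    def dp_max(self) -> float:
        return float(self.delta_p.max())

    @property
    def dp_min(self) -> float:
        return float(self.delta_p.min())


# ---------------------------------------------------------------------------
# NIfTI / sidecar I/O


def write_velocity_field(field: VelocityField, path: str | Path) -> tuple[Path, Path]:
    """Write a velocity field as a 5-D NIfTI plus JSON sidecar.

    ``path`` is the NIfTI filename; the sidecar is written next to it with a
    ``.json`` suffix.  Returns (nifti_path, sidecar_path).
    """
    path = Path(path)
    img = nib.Nifti1Image(field.data.astype(np.float64), field.affine)
    nib.save(img, path)
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii or .nii.gz
    sidecar = sidecar.parent / (sidecar.name + ".json")
    meta = {
        "venc_cm_s": field.venc,
        "frame_interval_ms": field.frame_interval,
        "voxel_size_mm": list(field.voxel_size),
    }
    sidecar.write_text(json.dumps(meta, indent=2))
    return path, sidecar


def read_velocity_field(
    path: str | Path, sidecar: str | Path | None = None
) -> VelocityField:
    """Read a 5-D NIfTI velocity volume and its JSON sidecar."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sidecar is None:
        stem = path.with_suffix("").with_suffix("")
        sidecar = stem.parent / (stem.name + ".json")
    sidecar = Path(sidecar)
    if not sidecar.exists():
        raise MetadataError(f"sidecar {sidecar} not found")
    meta = json.loads(sidecar.read_text())
    for key in ("venc_cm_s", "frame_interval_ms", "voxel_size_mm"):
        if key not in meta:
            raise MetadataError(f"sidecar missing required key {key!r}")
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[-1] == 3:  # single-frame convenience
        data = data[:, :, :, None, :]
    if data.ndim != 5 or data.shape[-1] != 3:
        raise MetadataError(f"expected 5-D (x,y,z,t,3) volume, got shape {data.shape}")
    return VelocityField(
        data=data,
        voxel_size=tuple(meta["voxel_size_mm"]),
        frame_interval=float(meta["frame_interval_ms"]),
        venc=float(meta["venc_cm_s"]),
        affine=img.affine,
    )


def write_mask(mask: LumenMask, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.labels.astype(np.uint8), mask.affine)
    nib.save(img, path)
    return path


def read_mask(path: str | Path, reference: VelocityField | None = None) -> LumenMask:
    """Read an integer-label NIfTI mask, optionally validating grid congruence."""
    img = nib.load(Path(path))
    labels = np.asarray(img.dataobj)
    if reference is not None:
        if labels.shape != reference.grid_shape:
            raise GridMismatchError(
                f"mask grid {labels.shape} != field grid {reference.grid_shape}"
            )
        voxel_size = reference.voxel_size
        affine = reference.affine
    else:
        voxel_size = tuple(float(v) for v in img.header.get_zooms()[:3])
        affine = img.affine
    return LumenMask(labels=labels, voxel_size=voxel_size, affine=affine)


def write_trace(trace: FlowTrace | RelativePressureTrace, path: str | Path) -> Path:
    path = Path(path)
    if isinstance(trace, FlowTrace):
        df = pd.DataFrame({"time_s": trace.time, "flow_rate_ml_s": trace.flow_rate})
    else:
        unit = "mmhg_per_m" if trace.normalized else "mmhg"
        df = pd.DataFrame({"time_s": trace.time, f"delta_p_{unit}": trace.delta_p})
    df.to_csv(path, index=False)
    return path


def read_trace(path: str | Path) -> FlowTrace:
    df = pd.read_csv(path)
    return FlowTrace(
        time=df["time_s"].to_numpy(),
        flow_rate=df[df.columns[1]].to_numpy(),
        plane_id=Path(path).stem,
    )


# ---------------------------------------------------------------------------
# Mask refinement


def refine_static_tissue(
    mask: LumenMask,
    fld: VelocityField,
    threshold_fraction: float = 0.1,
    max_removal_fraction: float = 0.2,
) -> LumenMask:
    """Drop lumen voxels that look like static tissue.

    A voxel is removed when its temporal-peak speed falls below
    ``threshold_fraction`` times the median temporal-peak speed of its lumen.
    If the rule would remove more than ``max_removal_fraction`` of a lumen the
    input is returned unchanged with a warning.
    """
    if not fld.congruent_with(mask):
        raise GridMismatchError("mask and field grids are not congruent")
    speed = np.linalg.norm(fld.data, axis=-1)  # (nx,ny,nz,nt)
    peak = speed.max(axis=-1)
    labels = mask.labels.copy()
    for label in (TL, FL):
        lum = mask.labels == label
        n = int(lum.sum())
        if n == 0:
            if label == TL:
                raise FlumenError("mask has an empty TL lumen")
            continue
        median_peak = np.median(peak[lum])
        drop = lum & (peak < threshold_fraction * median_peak)
        if drop.sum() > max_removal_fraction * n:
            warnings.warn(
                f"static-tissue refinement would remove {int(drop.sum())}/{n} "
                f"{LABEL_NAMES[label]} voxels; returning input unchanged",
                stacklevel=2,
            )
            return mask
        labels[drop] = BACKGROUND
    return LumenMask(labels=labels, voxel_size=mask.voxel_size, affine=mask.affine)


# ---------------------------------------------------------------------------
# Provenance


def write_provenance(
    out_dir: str | Path,
    command: str,
    inputs: dict,
    config: dict | None = None,
    seed: int | None = None,
) -> Path:
    """Write a JSON provenance record for a CLI run."""
    from flumen import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_text = json.dumps(config or {}, sort_keys=True, default=str)
    record = {
        "command": command,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": seed,
        "version": __version__,
    }
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(record, indent=2))
    return path


def as_dict(obj) -> dict:
    """JSON-friendly dict view of a dataclass result object."""
    def convert(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        return v

    return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
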