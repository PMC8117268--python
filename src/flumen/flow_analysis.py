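"""Geometric and temporal primitives shared by the pressurization metrics.

Plane flow quantification, cardiac-phase detection, lumen subsections,
mean-speed/acceleration traces, centerline lengths, noise estimation, and
the mask/plane perturbation machinery used for reproducibility analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import (
    BACKGROUND,
    FL,
    TL,
    FlowTrace,
    FlumenError,
    GridMismatchError,
    LumenMask,
    VelocityField,
    resolve_label,
)

__all__ = [
    "AnalysisPlane",
    "CardiacPhases",
    "AccelerationTrace",
    "compute_flow_trace",
    "detect_cardiac_phases",
    "antegrade_retrograde_volumes",
    "extract_fl_subsection",
    "mean_speed_trace",
    "differentiate_trace",
    "centerline_length",
    "estimate_vnr",
    "perturb_mask",
    "perturb_plane",
]


@dataclass
class AnalysisPlane:
    """Oriented cross-section with a disk region of interest.

    ``origin`` is a physical point in mm, ``normal`` a unit vector;
    integration is limited to in-plane points within ``roi_radius`` mm of the
    origin.  Positive flow is along ``antegrade_sign * normal``.
    """

    origin: tuple[float, float, float]
    normal: tuple[float, float, float]
    roi_radius: float
    antegrade_sign: int = 1
    plane_id: str = "plane"

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise FlumenError("plane normal must be non-zero")
        self.normal = n / norm
        if self.roi_radius <= 0:
            raise FlumenError("roi_radius must be positive")
        if self.antegrade_sign not in (1, -1):
            raise FlumenError("antegrade_sign must be +1 or -1")

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Two in-plane orthonormal vectors."""
        n = self.normal
        a = np.zeros(3)
        a[np.argmin(np.abs(n))] = 1.0
        u = np.cross(n, a)
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        return u, v

    def to_dict(self) -> dict:
        return {
            "origin_mm": list(map(float, self.origin)),
            "normal": list(map(float, self.normal)),
            "roi_radius_mm": float(self.roi_radius),
            "antegrade_sign": int(self.antegrade_sign),
            "plane_id": self.plane_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisPlane":
        return cls(
            origin=tuple(d["origin_mm"]),
            normal=tuple(d["normal"]),
            roi_radius=float(d["roi_radius_mm"]),
            antegrade_sign=int(d.get("antegrade_sign", 1)),
            plane_id=d.get("plane_id", "plane"),
        )


@dataclass
class CardiacPhases:
    """Frame-index partition of the cycle into systole and diastole."""

    systole: tuple[int, int]  # inclusive [first, last]
    n_frames: int

    def __post_init__(self) -> None:
        first, last = self.systole
        if not (0 <= first < self.n_frames and 0 <= last < self.n_frames):
            raise FlumenError("systole interval outside the cycle")
        self.systole = (int(first), int(last))

    @property
    def systole_frames(self) -> np.ndarray:
        first, last = self.systole
        if first <= last:
            return np.arange(first, last + 1)
        return np.concatenate([np.arange(first, self.n_frames), np.arange(0, last + 1)])

    @property
    def diastole_frames(self) -> np.ndarray:
        """Cyclic complement of the systolic interval."""
        sys = set(self.systole_frames.tolist())
        first, _ = self.systole
        order = np.concatenate([np.arange(first, self.n_frames), np.arange(0, first)])
        return np.array([f for f in order if f not in sys], dtype=int)


@dataclass
class AccelerationTrace:
    """Subsection mean-speed trace and (after differentiation) acceleration.

    Speeds in cm/s, acceleration in cm/s^2, time in s.
    """

    time: np.ndarray
    mean_speed: np.ndarray
    acceleration: np.ndarray | None = None
    subsection_id: str = "subsection"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.mean_speed = np.asarray(self.mean_speed, dtype=float)
        if self.time.shape != self.mean_speed.shape:
            raise FlumenError("time and mean_speed must have equal length")
        if self.acceleration is not None:
            self.acceleration = np.asarray(self.acceleration, dtype=float)
            if self.acceleration.shape != self.time.shape:
                raise FlumenError("acceleration length mismatch")

    @property
    def n_frames(self) -> int:
        return self.time.size


# ---------------------------------------------------------------------------
# Plane flow


def compute_flow_trace(
    fld: VelocityField,
    plane: AnalysisPlane,
    sample_spacing: float | None = None,
) -> FlowTrace:
    """Integrate velocity through a plane ROI: Q(t) = sum_roi v.n dA (ml/s).

    Velocities are sampled onto the plane by trilinear interpolation (values
    outside the grid count as zero).
    """
    if sample_spacing is None:
        sample_spacing = 0.5 * min(fld.voxel_size)
    u, v = plane.basis()
    r = plane.roi_radius
    m = int(np.ceil(r / sample_spacing))
    s = (np.arange(-m, m + 1)) * sample_spacing
    S, T = np.meshgrid(s, s, indexing="ij")
    keep = S**2 + T**2 <= r**2
    if not np.any(keep):
        raise FlumenError("empty plane ROI")
    pts = (
        plane.origin[None, :]
        + S[keep][:, None] * u[None, :]
        + T[keep][:, None] * v[None, :]
    )  # (npts, 3) physical mm
    inv = np.linalg.inv(fld.affine)
    idx = (pts @ inv[:3, :3].T) + inv[:3, 3]  # voxel coordinates
    coords = idx.T  # (3, npts)

    da_cm2 = sample_spacing**2 * 1e-2  # mm^2 -> cm^2
    n = plane.normal
    q = np.zeros(fld.n_frames)
    any_inside = False
    shape = np.asarray(fld.grid_shape)
    inside = np.all((coords.T > -0.5) & (coords.T < shape - 0.5), axis=1)
    if inside.any():
        any_inside = True
    for f in range(fld.n_frames):
        vn = np.zeros(coords.shape[1])
        for c in range(3):
            if n[c] == 0.0:
                continue
            vals = ndimage.map_coordinates(
                fld.data[:, :, :, f, c], coords, order=1, mode="constant", cval=0.0
            )
            vn += vals * n[c]
        q[f] = vn.sum() * da_cm2 * plane.antegrade_sign
    if not any_inside:
        raise FlumenError("plane ROI does not intersect the image grid")
    return FlowTrace(time=fld.times, flow_rate=q, plane_id=plane.plane_id)


def detect_cardiac_phases(trace: FlowTrace, threshold_fraction: float = 0.1) -> CardiacPhases:
    """Locate systole on a flow trace with a dominant positive lobe.

    Onset is the last frame before flow first exceeds ``threshold_fraction``
    of the peak; the end is the first non-positive frame after the peak (or
    the global-minimum frame when the trace never crosses zero).
    """
    q = trace.flow_rate
    n = q.size
    if np.allclose(q, 0.0):
        raise FlumenError("cannot detect phases on an all-zero trace")
    peak = int(np.argmax(q))
    if q[peak] <= 0:
        raise FlumenError("trace has no dominant positive lobe")
    thresh = threshold_fraction * q[peak]
    above = np.nonzero(q > thresh)[0]
    onset = max(int(above[0]) - 1, 0)
    end = None
    zero_tol = 1e-9 * q[peak]
    for k in range(peak + 1, n):
        if q[k] <= zero_tol:
            end = k
            break
    if end is None:
        end = int(np.argmin(q))
        if end <= peak:
            end = n - 1
    return CardiacPhases(systole=(onset, end), n_frames=n)


def _cyclic_trapezoid(time: np.ndarray, values: np.ndarray, period: float) -> float:
    """Integral of a cyclic trace over one full period (closes the wrap)."""
    t = np.append(time, time[0] + period)
    v = np.append(values, values[0])
    return float(np.trapezoid(v, t))


def antegrade_retrograde_volumes(
    trace: FlowTrace,
    phases: CardiacPhases,
    denominator_window: str = "cycle",
) -> tuple[float, float]:
    """(antegrade volume over the cycle, retrograde volume during diastole), ml.

    ``denominator_window`` selects whether the antegrade integral runs over
    the full cycle (default) or the systolic window only.
    """
    if phases.n_frames != trace.n_frames:
        raise FlumenError("phases inconsistent with trace length")
    q = trace.flow_rate
    t = trace.time
    n = trace.n_frames
    dt = np.median(np.diff(t)) if n > 1 else 0.0
    period = t[-1] - t[0] + dt

    if denominator_window == "cycle":
        antegrade = _cyclic_trapezoid(t, np.clip(q, 0.0, None), period)
    elif denominator_window == "systole":
        frames = phases.systole_frames
        antegrade = float(np.trapezoid(np.clip(q[frames], 0.0, None), dx=dt))
    else:
        raise FlumenError(f"unknown denominator_window {denominator_window!r}")

    dia = phases.diastole_frames
    if dia.size < 2:
        retro = 0.0
    else:
        # diastole frames are cyclic-contiguous; unwrap the time axis
        td = t[dia].copy()
        wrap = np.nonzero(np.diff(dia) != 1)[0]
        if wrap.size:
            td[wrap[0] + 1 :] += period
        retro = float(np.trapezoid(np.clip(-q[dia], 0.0, None), td))
    return antegrade, retro


# ---------------------------------------------------------------------------
# Subsections and traces


def extract_fl_subsection(
    mask: LumenMask,
    tear_axial_position: float,
    landmark_axial_position: float | None = None,
    half_window: float = 25.0,
    axis: int = 2,
) -> LumenMask:
    """FL voxels between two axial stations (mm along the vessel axis).

    With a landmark the window spans [landmark, tear]; without one it spans
    +/- ``half_window`` mm around the tear (5 cm total by default).
    """
    fl = mask.lumen(FL)
    if not fl.any():
        raise FlumenError("mask has an empty FL lumen")
    if landmark_axial_position is not None:
        lo, hi = sorted((landmark_axial_position, tear_axial_position))
    else:
        lo = tear_axial_position - half_window
        hi = tear_axial_position + half_window
    extent = mask.grid_shape[axis] * mask.voxel_size[axis]
    if lo < 0 or hi > extent:
        warnings.warn(
            f"subsection window [{lo:.1f}, {hi:.1f}] mm truncated to the axial "
            f"extent [0, {extent:.1f}] mm",
            stacklevel=2,
        )
        lo, hi = max(lo, 0.0), min(hi, extent)
    coord = (np.arange(mask.grid_shape[axis]) + 0.5) * mask.voxel_size[axis]
    in_window = (coord >= lo) & (coord <= hi)
    shape = [1, 1, 1]
    shape[axis] = -1
    keep = fl & in_window.reshape(shape)
    if not keep.any():
        raise FlumenError("empty FL subsection")
    labels = np.zeros_like(mask.labels)
    labels[keep] = FL
    return LumenMask(labels=labels, voxel_size=mask.voxel_size, affine=mask.affine)


def mean_speed_trace(fld: VelocityField, subsection: LumenMask | np.ndarray) -> AccelerationTrace:
    """Mean velocity magnitude over a voxel subsection, per frame."""
    sel = subsection.labels > 0 if isinstance(subsection, LumenMask) else np.asarray(subsection, bool)
    if sel.shape != fld.grid_shape:
        raise GridMismatchError("subsection grid does not match the field")
    if not sel.any():
        raise FlumenError("empty subsection")
    speed = np.linalg.norm(fld.data[sel], axis=-1)  # (nvox, nt)
    return AccelerationTrace(time=fld.times, mean_speed=speed.mean(axis=0))


def differentiate_trace(trace: AccelerationTrace) -> AccelerationTrace:
    """Acceleration by cyclic central differences of the mean-speed trace."""
    n = trace.n_frames
    if n < 3:
        raise FlumenError("need >= 3 frames to differentiate")
    dt = float(np.median(np.diff(trace.time)))
    s = trace.mean_speed
    acc = (np.roll(s, -1) - np.roll(s, 1)) / (2.0 * dt)
    return AccelerationTrace(
        time=trace.time,
        mean_speed=s,
        acceleration=acc,
        subsection_id=trace.subsection_id,
    )


# ---------------------------------------------------------------------------
# Centerline


_NEIGHBOR_OFFSETS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]


def centerline_path(
    lum: np.ndarray,
    spacing: np.ndarray,
    axis: int,
    s0: float,
    s1: float,
) -> tuple[np.ndarray, float]:
    """Medial path through a lumen between two axial stations.

    A 26-connected shortest path over lumen voxels, with routing costs
    penalized by inverse wall distance so the path follows the medial axis;
    the returned length (mm) is the unpenalized physical polyline length.
    Returns (path voxel indices (n, 3), length_mm).
    """
    import scipy.sparse as sp
    from scipy.sparse.csgraph import dijkstra

    spacing = np.asarray(spacing, dtype=float)
    edt = ndimage.distance_transform_edt(lum, sampling=spacing)
    vox_index = -np.ones(lum.shape, dtype=np.int64)
    pts = np.argwhere(lum)
    n = pts.shape[0]
    vox_index[lum] = np.arange(n)
    phys_axis = (pts[:, axis] + 0.5) * spacing[axis]

    def endpoint(stn: float) -> int:
        d = np.abs(phys_axis - stn)
        slab = d <= d.min() + 0.5 * spacing[axis]
        cand = np.nonzero(slab)[0]
        return int(cand[np.argmax(edt[tuple(pts[cand].T)])])

    i0, i1 = endpoint(s0), endpoint(s1)
    if i0 == i1:
        return pts[[i0]], 0.0

    rows, cols, route_w = [], [], []
    for off in _NEIGHBOR_OFFSETS:
        sl_a = tuple(
            slice(max(-o, 0), lum.shape[k] - max(o, 0)) for k, o in enumerate(off)
        )
        sl_b = tuple(
            slice(max(o, 0), lum.shape[k] + min(o, 0)) for k, o in enumerate(off)
        )
        ia = vox_index[sl_a]
        ib = vox_index[sl_b]
        both = (ia >= 0) & (ib >= 0)
        a, b = ia[both], ib[both]
        length = float(np.linalg.norm(np.asarray(off) * spacing))
        ea = edt[sl_a][both]
        eb = edt[sl_b][both]
        rows.append(a)
        cols.append(b)
        route_w.append(length / (0.5 * (ea + eb) + 1e-6))
    g_route = sp.coo_matrix(
        (np.concatenate(route_w), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    dist, pred = dijkstra(
        g_route, directed=False, indices=i0, return_predecessors=True
    )
    if not np.isfinite(dist[i1]):
        raise FlumenError("lumen is disconnected between the stations")
    path = [i1]
    while path[-1] != i0:
        path.append(int(pred[path[-1]]))
    path = np.asarray(path[::-1])
    steps = (pts[path[1:]] - pts[path[:-1]]) * spacing
    length_mm = float(np.linalg.norm(steps, axis=1).sum())
    return pts[path], length_mm


def centerline_length(
    mask: LumenMask,
    lumen: int | str,
    start: "AnalysisPlane | float",
    end: "AnalysisPlane | float",
    axis: int = 2,
) -> float:
    """Geodesic centerline length between two axial stations, in metres.

    ``start``/``end`` may be analysis planes (their origins are used) or bare
    axial positions in mm.
    """
    label = resolve_label(lumen)
    lum = mask.labels == label
    if not lum.any():
        raise FlumenError("empty lumen")
    n_comp = ndimage.label(lum)[1]
    if n_comp != 1:
        raise FlumenError(f"lumen is disconnected ({n_comp} components)")

    spacing = np.asarray(mask.voxel_size, dtype=float)

    def station(p) -> float:
        if isinstance(p, AnalysisPlane):
            return float(p.origin[axis])
        return float(p)

    s0, s1 = station(start), station(end)
    if np.isclose(s0, s1):
        return 0.0
    _, length_mm = centerline_path(lum, spacing, axis, s0, s1)
    return length_mm * 1e-3


# ---------------------------------------------------------------------------
# Noise


def estimate_vnr(fld: VelocityField, static_roi: np.ndarray) -> float:
    """venc divided by the velocity-noise SD over a static-tissue ROI."""
    roi = np.asarray(static_roi, bool)
    if roi.shape != fld.grid_shape:
        raise GridMismatchError("static ROI grid does not match the field")
    if not roi.any():
        raise FlumenError("empty static ROI")
    sd = float(fld.data[roi].std())
    if sd == 0.0:
        return float("inf")
    return fld.venc / sd


# ---------------------------------------------------------------------------
# Perturbations (reproducibility machinery)


def _check_lumen(labels: np.ndarray, label: int, original: np.ndarray) -> None:
    lum = labels == label
    if not lum.any():
        raise FlumenError("perturbation emptied a lumen")
    if ndimage.label(lum)[1] > ndimage.label(original == label)[1]:
        raise FlumenError("perturbation disconnected a lumen")


def perturb_mask(
    mask: LumenMask,
    mode: str,
    magnitude: int = 1,
    seed: int = 0,
    slab_thickness: int = 5,
    axis: int = 2,
) -> LumenMask:
    """Systematic segmentation perturbation.

    ``smaller`` erodes each lumen, ``larger`` dilates each lumen into
    background only (the lumens stay disjoint), and ``mixed`` chooses
    erode/dilate per axial slab with a seeded RNG (emulating manual
    segmentation variability along the vessel).
    """
    if magnitude < 1:
        raise FlumenError("magnitude must be >= 1")
    if mode not in ("smaller", "larger", "mixed"):
        raise FlumenError(f"unknown perturbation mode {mode!r}")
    struct = ndimage.generate_binary_structure(3, 1)
    labels = mask.labels

    def eroded(label: int) -> np.ndarray:
        return ndimage.binary_erosion(labels == label, struct, iterations=magnitude)

    def dilated(label: int, forbidden: np.ndarray) -> np.ndarray:
        grown = ndimage.binary_dilation(labels == label, struct, iterations=magnitude)
        return (labels == label) | (grown & ~forbidden)

    if mode == "smaller":
        new_tl = eroded(TL)
        new_fl = eroded(FL)
    elif mode == "larger":
        new_tl = dilated(TL, forbidden=(labels == FL))
        new_fl = dilated(FL, forbidden=(labels == TL) | new_tl)
    else:
        rng = np.random.default_rng(seed)
        nz = mask.grid_shape[axis]
        n_slabs = int(np.ceil(nz / slab_thickness))
        grow = np.repeat(rng.integers(0, 2, size=n_slabs).astype(bool), slab_thickness)[:nz]
        shape = [1, 1, 1]
        shape[axis] = -1
        grow3d = grow.reshape(shape)
        small_tl, small_fl = eroded(TL), eroded(FL)
        big_tl = dilated(TL, forbidden=(labels == FL))
        big_fl = dilated(FL, forbidden=(labels == TL) | big_tl)
        new_tl = np.where(grow3d, big_tl, small_tl)
        new_fl = np.where(grow3d, big_fl, small_fl) & ~new_tl

    out = np.zeros_like(labels)
    out[new_tl] = TL
    out[new_fl & ~new_tl] = FL
    for label in (TL, FL):
        if (labels == label).any():
            _check_lumen(out, label, labels)
    return LumenMask(labels=out, voxel_size=mask.voxel_size, affine=mask.affine)


def perturb_plane(
    plane: AnalysisPlane,
    max_tilt_deg: float,
    max_shift_mm: float,
    seed: int = 0,
) -> AnalysisPlane:
    """Seeded random tilt and shift of an analysis plane (second-rater proxy)."""
    if max_tilt_deg < 0 or max_shift_mm < 0:
        raise FlumenError("perturbation bounds must be >= 0")
    rng = np.random.default_rng(seed)

    def random_unit() -> np.ndarray:
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    normal = np.asarray(plane.normal, dtype=float)
    if max_tilt_deg > 0:
        angle = np.deg2rad(rng.uniform(0, max_tilt_deg))
        # rotation axis orthogonal to the normal
        a = random_unit()
        axis_vec = np.cross(normal, a)
        while np.linalg.norm(axis_vec) < 1e-12:
            axis_vec = np.cross(normal, random_unit())
        axis_vec /= np.linalg.norm(axis_vec)
        k = axis_vec
        normal = (
            normal * np.cos(angle)
            + np.cross(k, normal) * np.sin(angle)
            + k * np.dot(k, normal) * (1 - np.cos(angle))
        )
    origin = np.asarray(plane.origin, dtype=float)
    if max_shift_mm > 0:
        origin = origin + rng.uniform(0, max_shift_mm) * random_unit()
    return AnalysisPlane(
        origin=tuple(origin),
        normal=tuple(normal),
        roi_radius=plane.roi_radius,
        antegrade_sign=plane.antegrade_sign,
        plane_id=plane.plane_id + "_perturbed",
    )
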