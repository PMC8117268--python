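"""Synthetic dissected-vessel phantoms with machine-readable ground truth.

Every generator returns both the artifact (mask, velocity field, cohort
table) and the analytic quantities it was built from (prescribed flow
volumes, reference pressure drops, generating coefficients), so downstream
stages can be tested without any external data.

Geometry convention: the vessel runs along the z grid axis; the true lumen
(TL) and false lumen (FL) are parallel cylinders separated by a septum slab,
connected through a cylindrical entry-tear channel drilled along x.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import FL, TL, FlumenError, LumenMask, MetadataError, VelocityField

__all__ = [
    "PhantomGeometry",
    "WaveformSpec",
    "FluidProperties",
    "CohortSpec",
    "GroupParams",
    "PulsatileGroundTruth",
    "make_dissection_mask",
    "make_tube_mask",
    "make_poiseuille_field",
    "make_pulsatile_field",
    "add_velocity_noise",
    "simulate_cohort",
    "sinusoidal_speed_trace",
]

MMHG_PER_PA = 1.0 / 133.322

#: default acquisition regime: ~1.5 x 1.5 x 2.5 mm voxels, 47 ms frames,
#: venc 200 cm/s
DEFAULT_VOXEL_SIZE = (1.5, 1.5, 2.5)
DEFAULT_FRAME_INTERVAL_MS = 47.0
DEFAULT_VENC = 200.0


class GeometryError(FlumenError):
    """Phantom geometry cannot be realized on the requested grid."""


@dataclass
class PhantomGeometry:
    """Two-lumen dissected-vessel geometry on a voxel grid (lengths in mm)."""

    grid_shape: tuple[int, int, int] = (48, 24, 80)
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    lumen_radius_tl: float = 8.0
    lumen_radius_fl: float = 10.0
    septum_thickness: float = 3.0
    tear_center_axial: float = 100.0
    tear_diameter: float = 12.0

    def __post_init__(self) -> None:
        if self.tear_diameter <= 0:
            raise GeometryError("tear_diameter must be positive")
        if self.lumen_radius_tl <= 0 or self.lumen_radius_fl <= 0:
            raise GeometryError("lumen radii must be positive")
        if self.septum_thickness <= 0:
            raise GeometryError("septum_thickness must be positive")
        if not (0 < self.tear_center_axial < self.axial_extent):
            raise GeometryError(
                f"tear_center_axial {self.tear_center_axial} outside axial extent "
                f"(0, {self.axial_extent})"
            )

    @property
    def axial_extent(self) -> float:
        return self.grid_shape[2] * self.voxel_size[2]

    # lumen center x positions: TL | septum | FL stacked along x, centered in
    # y.  Centers are snapped to voxel-lattice corners so the circular
    # cross-sections voxelize symmetrically (keeps the effective radius
    # consistent across grid refinements).
    @property
    def tl_center(self) -> tuple[float, float]:
        hx, hy = self.voxel_size[0], self.voxel_size[1]
        x = np.ceil((2 * hx + self.lumen_radius_tl) / hx) * hx
        return (float(x), self.grid_shape[1] * hy / 2)

    @property
    def fl_center(self) -> tuple[float, float]:
        hx = self.voxel_size[0]
        tlx, cy = self.tl_center
        x = tlx + self.lumen_radius_tl + self.septum_thickness + self.lumen_radius_fl
        return (float(np.ceil(x / hx) * hx), cy)

    @property
    def tear_plane_x(self) -> float:
        """x position of the mid-septum plane (mm)."""
        tlx, _ = self.tl_center
        return tlx + self.lumen_radius_tl + self.septum_thickness / 2


def _voxel_centers(geometry: PhantomGeometry):
    nx, ny, nz = geometry.grid_shape
    hx, hy, hz = geometry.voxel_size
    x = (np.arange(nx) + 0.5) * hx
    y = (np.arange(ny) + 0.5) * hy
    z = (np.arange(nz) + 0.5) * hz
    return x, y, z


def make_dissection_mask(geometry: PhantomGeometry) -> LumenMask:
    """Voxelize the two-lumen geometry into a {background, TL, FL} label mask.

    The entry-tear channel voxels are labeled FL so that the tear connects
    the lumens across the septum.
    """
    nx, ny, nz = geometry.grid_shape
    hx, hy, hz = geometry.voxel_size
    x, y, z = _voxel_centers(geometry)

    tlx, cy = geometry.tl_center
    flx, _ = geometry.fl_center
    need_x = flx + geometry.lumen_radius_fl + 2 * hx
    need_y = cy + max(geometry.lumen_radius_tl, geometry.lumen_radius_fl) + 2 * hy
    if need_x > nx * hx or need_y > ny * hy:
        raise GeometryError(
            f"grid {geometry.grid_shape} at voxel size {geometry.voxel_size} cannot "
            "contain both lumens plus a background margin"
        )

    r2_tl = (x[:, None] - tlx) ** 2 + (y[None, :] - cy) ** 2
    r2_fl = (x[:, None] - flx) ** 2 + (y[None, :] - cy) ** 2
    tl2d = r2_tl <= geometry.lumen_radius_tl**2
    fl2d = r2_fl <= geometry.lumen_radius_fl**2

    labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    labels[tl2d] = TL
    labels[fl2d] = FL

    # entry tear: cylinder along x through the septum gap
    tear_r = geometry.tear_diameter / 2
    in_tear_yz = (y[:, None] - cy) ** 2 + (z[None, :] - geometry.tear_center_axial) ** 2 <= tear_r**2
    in_gap_x = (x >= tlx) & (x <= flx)
    tear = in_gap_x[:, None, None] & in_tear_yz[None, :, :]
    labels[tear & (labels == 0)] = FL
    return LumenMask(labels=labels, voxel_size=geometry.voxel_size)


def make_tube_mask(geometry: PhantomGeometry) -> LumenMask:
    """Single straight TL cylinder (no FL, no tear): the Poiseuille domain."""
    nx, ny, nz = geometry.grid_shape
    x, y, _ = _voxel_centers(geometry)
    tlx, cy = geometry.tl_center
    r2 = (x[:, None] - tlx) ** 2 + (y[None, :] - cy) ** 2
    tl2d = r2 <= geometry.lumen_radius_tl**2
    labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    labels[tl2d] = TL
    return LumenMask(labels=labels, voxel_size=geometry.voxel_size)


@dataclass
class FluidProperties:
    """Blood-analog fluid constants (SI)."""

    density: float = 1060.0  # kg/m^3
    dynamic_viscosity: float = 4.0e-3  # Pa s

    def __post_init__(self) -> None:
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise MetadataError("fluid properties must be strictly positive")


def make_poiseuille_field(
    geometry: PhantomGeometry,
    flow: float,
    fluid: FluidProperties | None = None,
    n_frames: int = 1,
    frame_interval: float = DEFAULT_FRAME_INTERVAL_MS,
    venc: float = DEFAULT_VENC,
) -> tuple[VelocityField, float]:
    """Steady axial parabolic flow in the TL cylinder.

    ``flow`` is the volume rate in ml/s.  Returns the velocity field (cm/s)
    and the Hagen-Poiseuille reference pressure drop 8*mu*L*Q/(pi*R^4) over
    the full axial extent, in mmHg.
    """
    fluid = fluid or FluidProperties()
    nx, ny, nz = geometry.grid_shape
    x, y, _ = _voxel_centers(geometry)
    tlx, cy = geometry.tl_center
    R = geometry.lumen_radius_tl
    r2 = (x[:, None] - tlx) ** 2 + (y[None, :] - cy) ** 2
    inside = r2 <= R**2
    # v(r) = 2 Q / (pi R^2) * (1 - r^2/R^2); Q in cm^3/s, lengths in cm
    R_cm = R / 10.0
    vz = np.zeros((nx, ny))
    vz[inside] = 2.0 * flow / (np.pi * R_cm**2) * (1.0 - r2[inside] / R**2)  # cm/s
    data = np.zeros((nx, ny, nz, n_frames, 3))
    data[:, :, :, :, 2] = vz[:, :, None, None]
    fld = VelocityField(
        data=data,
        voxel_size=geometry.voxel_size,
        frame_interval=frame_interval,
        venc=venc,
    )
    Q_si = flow * 1e-6  # m^3/s
    L_si = geometry.axial_extent * 1e-3
    R_si = R * 1e-3
    dp_pa = 8.0 * fluid.dynamic_viscosity * L_si * Q_si / (np.pi * R_si**4)
    return fld, dp_pa * MMHG_PER_PA


@dataclass
class WaveformSpec:
    """Pulsatile cycle prescription (times in s, volumes in ml)."""

    period: float = 1.0
    n_frames: int = 30
    peak_flow: float = 300.0  # ml/s through the TL during systole
    systolic_fraction: float = 0.35
    antegrade_tear_volume: float = 10.0
    diastolic_retrograde_volume: float = 4.9

    def __post_init__(self) -> None:
        if self.n_frames < 10:
            raise MetadataError("n_frames must be >= 10")
        if self.period <= 0:
            raise MetadataError("period must be positive")
        if not (0 < self.systolic_fraction < 1):
            raise MetadataError("systolic_fraction must lie in (0, 1)")
        if self.antegrade_tear_volume < 0 or self.diastolic_retrograde_volume < 0:
            raise MetadataError("tear volumes must be non-negative")

    @property
    def frame_interval_ms(self) -> float:
        return self.period / self.n_frames * 1e3

    @property
    def systole_duration(self) -> float:
        return self.systolic_fraction * self.period

    def tear_flow(self, t: np.ndarray) -> np.ndarray:
        """Prescribed through-tear flow rate (ml/s), positive = TL -> FL.

        Antegrade half-sine during systole; retrograde half-sine centered in
        diastole with a margin so the lobe vanishes well inside the window.
        """
        t = np.asarray(t, dtype=float) % self.period
        q = np.zeros_like(t)
        t_sys = self.systole_duration
        sys = (t > 0) & (t < t_sys)
        if self.antegrade_tear_volume > 0:
            amp = self.antegrade_tear_volume * np.pi / (2.0 * t_sys)
            q[sys] = amp * np.sin(np.pi * t[sys] / t_sys)
        if self.diastolic_retrograde_volume > 0:
            margin = 0.1 * (self.period - t_sys)
            t0 = t_sys + margin
            t_lobe = self.period - t_sys - 2 * margin
            dia = (t > t0) & (t < t0 + t_lobe)
            amp = self.diastolic_retrograde_volume * np.pi / (2.0 * t_lobe)
            q[dia] -= amp * np.sin(np.pi * (t[dia] - t0) / t_lobe)
        return q

    def tl_inflow(self, t: np.ndarray) -> np.ndarray:
        """Prescribed TL inlet flow rate (ml/s): half-sine systolic pulse."""
        t = np.asarray(t, dtype=float) % self.period
        q = np.zeros_like(t)
        t_sys = self.systole_duration
        sys = (t > 0) & (t < t_sys)
        q[sys] = self.peak_flow * np.sin(np.pi * t[sys] / t_sys)
        return q


@dataclass
class PulsatileGroundTruth:
    """Analytic quantities the pulsatile phantom was generated from."""

    antegrade_tear_volume: float
    diastolic_retrograde_volume: float
    flef_percent: float
    tear_plane_origin_mm: tuple[float, float, float]
    tear_plane_normal: tuple[float, float, float]
    tear_roi_radius_mm: float
    systole_frames: tuple[int, int]
    tear_area_mm2: float


def make_pulsatile_field(
    geometry: PhantomGeometry,
    waveform: WaveformSpec,
    venc: float = DEFAULT_VENC,
    mask: LumenMask | None = None,
) -> tuple[VelocityField, PulsatileGroundTruth]:
    """Time-resolved two-lumen field with prescribed tear flow volumes.

    Construction is mass-consistent away from the tear junction: the TL
    carries ``tl_inflow`` upstream of the tear and ``tl_inflow - tear_flow``
    downstream; the FL carries ``tear_flow`` downstream of the tear and is
    quiescent upstream.  The tear channel carries a uniform x-velocity scaled
    by the voxelized channel cross-section, so plane integration of the
    resulting field reproduces the prescribed volumes to quadrature accuracy.
    """
    if mask is None:
        mask = make_dissection_mask(geometry)
    nx, ny, nz = geometry.grid_shape
    hx, hy, hz = geometry.voxel_size
    x, y, z = _voxel_centers(geometry)
    t = np.arange(waveform.n_frames) * waveform.period / waveform.n_frames

    q_tl = waveform.tl_inflow(t)  # ml/s
    q_tear = waveform.tear_flow(t)

    tlx, cy = geometry.tl_center
    flx, _ = geometry.fl_center
    tl3d = mask.labels == TL
    # FL proper: the cylinder, excluding tear-channel voxels in the septum gap
    r2_fl = (x[:, None] - flx) ** 2 + (y[None, :] - cy) ** 2
    fl_cyl = (r2_fl <= geometry.lumen_radius_fl**2)[:, :, None] & (mask.labels == FL)
    tear3d = (mask.labels == FL) & ~fl_cyl

    a_tl_cm2 = tl3d[:, :, 0].sum() * hx * hy * 1e-2  # cm^2 per slice
    a_fl_cm2 = fl_cyl[:, :, 0].sum() * hx * hy * 1e-2
    # voxelized tear-channel cross-section in the mid-septum plane
    ix_mid = int(geometry.tear_plane_x / hx)
    tear_plane_voxels = tear3d[ix_mid, :, :]
    a_tear_cm2 = tear_plane_voxels.sum() * hy * hz * 1e-2
    if a_tear_cm2 == 0:
        raise GeometryError("tear channel does not intersect the mid-septum plane")

    downstream = z > geometry.tear_center_axial  # (nz,)

    data = np.zeros((nx, ny, nz, waveform.n_frames, 3))
    # axial plug flow, cm/s = (ml/s) / cm^2
    vz_tl_up = q_tl / a_tl_cm2
    vz_tl_dn = (q_tl - q_tear) / a_tl_cm2
    vz_fl_dn = q_tear / a_fl_cm2
    up = ~downstream
    data[:, :, :, :, 2] += tl3d[:, :, :, None] * (
        up[None, None, :, None] * vz_tl_up[None, None, None, :]
        + downstream[None, None, :, None] * vz_tl_dn[None, None, None, :]
    )
    data[:, :, :, :, 2] += (
        fl_cyl[:, :, :, None]
        * downstream[None, None, :, None]
        * vz_fl_dn[None, None, None, :]
    )
    # tear channel: uniform x velocity (TL -> FL is +x)
    ux_tear = q_tear / a_tear_cm2
    data[:, :, :, :, 0] += tear3d[:, :, :, None] * ux_tear[None, None, None, :]

    fld = VelocityField(
        data=data,
        voxel_size=geometry.voxel_size,
        frame_interval=waveform.frame_interval_ms,
        venc=venc,
    )
    dt = waveform.period / waveform.n_frames
    sys_last = int(np.floor(waveform.systole_duration / dt))
    flef = (
        100.0 * waveform.diastolic_retrograde_volume / waveform.antegrade_tear_volume
        if waveform.antegrade_tear_volume > 0
        else np.nan
    )
    truth = PulsatileGroundTruth(
        antegrade_tear_volume=waveform.antegrade_tear_volume,
        diastolic_retrograde_volume=waveform.diastolic_retrograde_volume,
        flef_percent=flef,
        tear_plane_origin_mm=(geometry.tear_plane_x, cy, geometry.tear_center_axial),
        tear_plane_normal=(1.0, 0.0, 0.0),
        tear_roi_radius_mm=geometry.tear_diameter / 2 + 2 * max(hy, hz),
        systole_frames=(0, min(sys_last, waveform.n_frames - 1)),
        tear_area_mm2=a_tear_cm2 * 100.0,
    )
    return fld, truth


def add_velocity_noise(field: VelocityField, vnr: float, seed: int) -> VelocityField:
    """Add zero-mean Gaussian noise with sigma = venc / vnr per component."""
    if not np.isfinite(vnr) or vnr <= 0:
        raise MetadataError("vnr must be positive and finite")
    if field.venc is None or field.venc <= 0:
        raise MetadataError("field is missing venc metadata")
    rng = np.random.default_rng(seed)
    sigma = field.venc / vnr
    noisy = field.data + rng.normal(0.0, sigma, size=field.data.shape)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # noise may nominally exceed venc
        return VelocityField(
            data=noisy,
            voxel_size=field.voxel_size,
            frame_interval=field.frame_interval,
            venc=field.venc,
            affine=field.affine,
        )


# ---------------------------------------------------------------------------
# Synthetic cohorts


@dataclass
class GroupParams:
    """Per-group (mean, SD) for each simulated metric."""

    flef: tuple[float, float]
    msdr: tuple[float, float]
    fl_dp_max: tuple[float, float]
    baseline_diameter: tuple[float, float]


@dataclass
class CohortSpec:
    """Generative prescription for a synthetic two-group cohort.

    Default distribution parameters follow the published group summaries
    (stable vs enlarging) and the published growth-rate regression
    coefficients; residual SD chosen to match the reported adjusted R^2.
    """

    n_stable: int = 4
    n_enlarging: int = 8
    stable: GroupParams = field(
        default_factory=lambda: GroupParams(
            flef=(10.0, 11.9),
            msdr=(1146.0, 782.0),
            fl_dp_max=(57.2, 12.5),
            baseline_diameter=(38.0, 6.1),
        )
    )
    enlarging: GroupParams = field(
        default_factory=lambda: GroupParams(
            flef=(49.0, 17.9),
            msdr=(1529.0, 1058.0),
            fl_dp_max=(32.3, 10.8),
            baseline_diameter=(42.9, 9.2),
        )
    )
    growth_intercept: float = -20.8
    growth_betas: dict = field(
        default_factory=lambda: {"flef": 0.23, "baseline_diameter": 0.45}
    )
    growth_residual_sd: float = 2.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stable < 1 or self.n_enlarging < 1:
            raise MetadataError("group sizes must be >= 1")
        for grp in (self.stable, self.enlarging):
            for name in ("flef", "msdr", "fl_dp_max", "baseline_diameter"):
                if getattr(grp, name)[1] < 0:
                    raise MetadataError(f"{name} SD must be >= 0")
        if self.growth_residual_sd < 0:
            raise MetadataError("growth_residual_sd must be >= 0")


GROWTH_THRESHOLD_MM_PER_YEAR = 3.0


def simulate_cohort(spec: CohortSpec):
    """Draw a synthetic cohort table (pandas DataFrame).

    Metric values come from group-specific normals truncated at physical
    bounds (FLEF >= 0, MSDR >= 0, diameter > 0); growth rate is the linear
    predictor plus Gaussian residual.  ``group`` is re-derived from the
    realized growth rate via the >= 3 mm/year rule; the group used for the
    draw is kept in ``drawn_group``.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)

    def draw(params: GroupParams, n: int) -> dict:
        def trunc(mean, sd, lo):
            v = rng.normal(mean, sd, size=n)
            return np.maximum(v, lo)

        return {
            "flef": trunc(*params.flef, 0.0),
            "msdr": trunc(*params.msdr, 0.0),
            "fl_dp_max": rng.normal(*params.fl_dp_max, size=n),
            "baseline_diameter": trunc(*params.baseline_diameter, 1.0),
        }

    rows = {}
    stable = draw(spec.stable, spec.n_stable)
    enlarging = draw(spec.enlarging, spec.n_enlarging)
    for key in stable:
        rows[key] = np.concatenate([stable[key], enlarging[key]])
    n = spec.n_stable + spec.n_enlarging
    rows["drawn_group"] = np.array(
        ["stable"] * spec.n_stable + ["enlarging"] * spec.n_enlarging
    )

    growth = np.full(n, spec.growth_intercept)
    for name, beta in spec.growth_betas.items():
        growth = growth + beta * rows[name]
    if spec.growth_residual_sd > 0:
        growth = growth + rng.normal(0.0, spec.growth_residual_sd, size=n)
    rows["growth_rate"] = growth
    rows["group"] = np.where(
        growth >= GROWTH_THRESHOLD_MM_PER_YEAR, "enlarging", "stable"
    )
    df = pd.DataFrame(rows)
    df.insert(0, "id", [f"S{i:03d}" for i in range(n)])
    return df


# ---------------------------------------------------------------------------
# Trace-level phantom for the deceleration-rate closed form


def sinusoidal_speed_trace(
    v_amp: float,
    period: float,
    n_frames: int,
    baseline: float | None = None,
):
    """Smooth sinusoidal mean-speed trace with a closed-form deceleration rate.

    ``speed(t) = baseline + v_amp * sin(2 pi t / period)``; with systole taken
    as the first half-period (duration ``T_sys = period / 2``), acceleration
    extrema are ``+/- 2 pi v_amp / period`` at t = 0 and t = period/2, so the
    max systolic deceleration rate is ``2 pi v_amp / T_sys**2``.

    Returns (AccelerationTrace speed part, CardiacPhases, expected msdr).
    """
    from .flow_analysis import AccelerationTrace, CardiacPhases

    if baseline is None:
        baseline = 1.5 * v_amp  # keep the speed positive
    t = np.arange(n_frames) * period / n_frames
    speed = baseline + v_amp * np.sin(2 * np.pi * t / period)
    trace = AccelerationTrace(time=t, mean_speed=speed, subsection_id="sinusoid")
    half = n_frames // 2
    phases = CardiacPhases(systole=(0, half), n_frames=n_frames)
    t_sys = period / 2.0
    expected = 2.0 * np.pi * v_amp / t_sys**2
    return trace, phases, expected
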