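"""Relative pressure from velocity fields via a virtual work-energy balance.

A divergence-free, no-slip "virtual" field ``w`` with unit net through-flow
is computed over the lumen segmentation by solving a Stokes problem on a
staggered (MAC) voxel grid: velocity unknowns on cell faces, the pressure
multiplier on cell centers, a plug Dirichlet inlet profile scaled to unit
flux, and natural outflow at the outlet.  The energy balance of the
Navier-Stokes equations then yields the inlet-to-outlet relative pressure

    dP(t) = (dKe/dt + A(t) + V(t)) / Q_v,          dP = p_inlet - p_outlet

with Ke = rho * int v.w dV, A = rho * int (v.grad v).w dV and
V = mu * int grad v : grad w dV.  SI units internally; mmHg on output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import ndimage

from .flow_analysis import AnalysisPlane
from .io import (
    MMHG_PER_PA,
    FlumenError,
    GridMismatchError,
    LumenMask,
    RelativePressureTrace,
    VelocityField,
    resolve_label,
)
from .phantom import FluidProperties

__all__ = [
    "VirtualField",
    "EnergyTerms",
    "RadiusCheckResult",
    "DisconnectedDomainError",
    "SolverError",
    "compute_virtual_field",
    "compute_energy_terms",
    "compute_relative_pressure",
    "normalize_and_extract",
    "transseptal_pressure",
    "lumen_radius_check",
    "vwerp_pressure_trace",
]

AXES = (0, 1, 2)


class DisconnectedDomainError(FlumenError):
    """The lumen is not connected between the inlet and outlet stations."""


class SolverError(FlumenError):
    """The Stokes solve did not meet the requested tolerance."""


def _face_shape(shape: tuple[int, int, int], d: int) -> tuple[int, int, int]:
    s = list(shape)
    s[d] += 1
    return tuple(s)


class _StaggeredDomain:
    """MAC face bookkeeping for one fluid mask with through-flow along `axis`.

    Face values live on arrays of shape ``mask.shape + e_d`` per direction d.
    Walls are zero-Dirichlet; the inlet boundary (index 0 along `axis`) takes
    a prescribed plug profile; outlet faces are free (natural outflow).
    """

    def __init__(self, mask: np.ndarray, spacing_mm: np.ndarray, axis: int):
        self.mask = mask
        self.h = np.asarray(spacing_mm, dtype=float)  # mm
        self.axis = axis
        self.vol = float(self.h.prod())
        self.area = [self.vol / self.h[d] for d in AXES]
        shape = mask.shape

        self.face_active: list[np.ndarray] = []
        self.face_unknown: list[np.ndarray] = []
        for d in AXES:
            fs = _face_shape(shape, d)
            lo = np.zeros(fs, bool)  # fluid cell on the minus side
            hi = np.zeros(fs, bool)  # fluid cell on the plus side
            sl = [slice(None)] * 3
            sl[d] = slice(1, None)
            lo[tuple(sl)] = mask
            sl[d] = slice(0, fs[d] - 1)
            hi[tuple(sl)] = mask
            active = lo | hi
            unknown = lo & hi
            if d == axis:
                outlet = np.zeros(fs, bool)
                sl[d] = fs[d] - 1
                outlet[tuple(sl)] = np.take(mask, -1, axis=d)
                unknown |= outlet
            self.face_active.append(active)
            self.face_unknown.append(unknown)

        fs = _face_shape(shape, axis)
        inlet = np.zeros(fs, bool)
        sl = [slice(None)] * 3
        sl[axis] = 0
        inlet[tuple(sl)] = np.take(mask, 0, axis=axis)
        self.inlet_faces = inlet
        if not inlet.any():
            raise DisconnectedDomainError("no fluid cells at the inlet station")
        if not np.take(mask, -1, axis=axis).any():
            raise DisconnectedDomainError("no fluid cells at the outlet station")

    # -- assembly ----------------------------------------------------------

    def solve_unit_flow(self, mu_v: float = 1.0) -> list[np.ndarray]:
        """Solve the Stokes saddle-point system; returns face arrays (mm/s)
        carrying total flux 1 mm^3/s from inlet to outlet."""
        mask, h, vol = self.mask, self.h, self.vol
        shape = mask.shape

        face_value = [np.zeros(_face_shape(shape, d)) for d in AXES]
        n_in = int(self.inlet_faces.sum())
        face_value[self.axis][self.inlet_faces] = 1.0 / (n_in * self.area[self.axis])

        idx, n_unk = [], 0
        for d in AXES:
            m = -np.ones(self.face_unknown[d].shape, dtype=np.int64)
            k = int(self.face_unknown[d].sum())
            m[self.face_unknown[d]] = np.arange(n_unk, n_unk + k)
            idx.append(m)
            n_unk += k
        cell_idx = -np.ones(shape, dtype=np.int64)
        n_cell = int(mask.sum())
        cell_idx[mask] = np.arange(n_cell)

        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        vals: list[np.ndarray] = []
        b = np.zeros(n_unk + n_cell)

        def add(r, c, v):
            rows.append(np.asarray(r, dtype=np.int64))
            cols.append(np.asarray(c, dtype=np.int64))
            vals.append(np.asarray(v, dtype=float))

        # viscous stiffness from the Dirichlet energy form: edges between
        # same-direction faces offset along dp, weight vol/h_dp^2; a missing
        # tangential neighbor is a wall ghost contributing 2*vol/h^2 to the
        # diagonal (no-slip wall at half spacing).
        for d in AXES:
            unk, act, val, fidx = (
                self.face_unknown[d],
                self.face_active[d],
                face_value[d],
                idx[d],
            )
            fs = unk.shape
            for dp in AXES:
                w_e = mu_v * vol / h[dp] ** 2
                sl_a = [slice(None)] * 3
                sl_b = [slice(None)] * 3
                sl_a[dp] = slice(0, fs[dp] - 1)
                sl_b[dp] = slice(1, None)
                A, B = tuple(sl_a), tuple(sl_b)
                pair = act[A] & act[B]
                both = pair & unk[A] & unk[B]
                ia, ib = fidx[A][both], fidx[B][both]
                add(ia, ib, np.full(ia.size, -w_e))
                add(ib, ia, np.full(ia.size, -w_e))
                add(ia, ia, np.full(ia.size, w_e))
                add(ib, ib, np.full(ib.size, w_e))
                ud = pair & unk[A] & ~unk[B]
                ia = fidx[A][ud]
                add(ia, ia, np.full(ia.size, w_e))
                np.add.at(b, ia, w_e * val[B][ud])
                du = pair & ~unk[A] & unk[B]
                ib = fidx[B][du]
                add(ib, ib, np.full(ib.size, w_e))
                np.add.at(b, ib, w_e * val[A][du])
                if dp != d:
                    ghost_a = np.zeros(fs, bool)
                    ghost_a[A] = unk[A] & ~act[B]
                    ghost_b = np.zeros(fs, bool)
                    ghost_b[B] = unk[B] & ~act[A]
                    for g in (ghost_a, ghost_b):
                        ig = fidx[g]
                        add(ig, ig, np.full(ig.size, 2.0 * w_e))

        # pressure gradient / continuity blocks (symmetric, +/- face area);
        # a missing adjacent cell means multiplier 0 there (pins the level
        # at the outlet, which has no exterior cell).
        for d in AXES:
            unk, fidx = self.face_unknown[d], idx[d]
            a_f = self.area[d]
            pos = np.nonzero(unk)
            fi = fidx[pos]
            ip = pos[d]
            for side, sgn in ((0, +1.0), (1, -1.0)):
                cells = [p.copy() for p in pos]
                cells[d] = ip - side
                valid = (cells[d] >= 0) & (cells[d] < shape[d])
                cid = cell_idx[tuple(c[valid] for c in cells)]
                ok = cid >= 0
                f_ok = fi[valid][ok]
                cid = cid[ok]
                add(f_ok, n_unk + cid, np.full(f_ok.size, sgn * a_f))
                add(n_unk + cid, f_ok, np.full(f_ok.size, sgn * a_f))
            # Dirichlet faces feed the continuity rhs
            dirich = self.face_active[d] & ~unk
            dval = face_value[d]
            nz = dirich & (dval != 0.0)
            if nz.any():
                pos_d = np.nonzero(nz)
                ipd = pos_d[d]
                for side, sgn in ((0, +1.0), (1, -1.0)):
                    cells = [p.copy() for p in pos_d]
                    cells[d] = ipd - side
                    valid = (cells[d] >= 0) & (cells[d] < shape[d])
                    cid = cell_idx[tuple(c[valid] for c in cells)]
                    ok = cid >= 0
                    np.add.at(
                        b,
                        n_unk + cid[ok],
                        -sgn * a_f * dval[tuple(p[valid] for p in pos_d)][ok],
                    )

        n_total = n_unk + n_cell
        K = sp.csc_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_total, n_total),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", sp.SparseEfficiencyWarning)
            sol = spla.spsolve(K, b)
        if not np.all(np.isfinite(sol)):
            raise SolverError("Stokes solve produced non-finite values")

        faces = []
        for d in AXES:
            arr = face_value[d]
            arr[self.face_unknown[d]] = sol[: n_unk][idx[d][self.face_unknown[d]]]
            arr[~self.face_active[d]] = 0.0
            faces.append(arr)
        return faces

    # -- diagnostics -------------------------------------------------------

    def divergence(self, faces: list[np.ndarray]) -> np.ndarray:
        """Net face flux out of each cell (same units as flux)."""
        div = np.zeros(self.mask.shape)
        for d in AXES:
            n = self.mask.shape[d]
            fp = np.take(faces[d], np.arange(1, n + 1), axis=d)
            fm = np.take(faces[d], np.arange(0, n), axis=d)
            div += (fp - fm) * self.area[d]
        return div

    def station_flux(self, faces: list[np.ndarray], k: int) -> float:
        f = np.take(faces[self.axis], k, axis=self.axis)
        return float(f.sum() * self.area[self.axis])

    def cell_average(self, faces: list[np.ndarray]) -> np.ndarray:
        """Face field averaged to cell centers, (nx, ny, nz, 3)."""
        out = np.zeros(self.mask.shape + (3,))
        for d in AXES:
            n = self.mask.shape[d]
            fp = np.take(faces[d], np.arange(1, n + 1), axis=d)
            fm = np.take(faces[d], np.arange(0, n), axis=d)
            out[..., d] = 0.5 * (fp + fm)
        out[~self.mask] = 0.0
        return out

    def cells_to_faces(self, v_cell: np.ndarray) -> list[np.ndarray]:
        """Cell-centered vector field sampled onto faces.

        Interior faces average the two adjacent cells, wall faces are zero
        (no-slip) and inlet/outlet boundary faces copy the adjacent cell
        (through-flow).
        """
        mask = self.mask
        faces = []
        for d in AXES:
            fs = _face_shape(mask.shape, d)
            vc = v_cell[..., d] * mask
            vf = np.zeros(fs)
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[d] = slice(0, fs[d] - 1)
            sl_hi[d] = slice(1, None)
            vf[tuple(sl_lo)] += vc
            vf[tuple(sl_hi)] += vc
            lo = np.zeros(fs, bool)
            hi = np.zeros(fs, bool)
            lo[tuple(sl_hi)] = mask
            hi[tuple(sl_lo)] = mask
            both = lo & hi
            vf[both] /= 2.0
            vf[(lo | hi) & ~both] = 0.0
            if d == self.axis:
                sl = [slice(None)] * 3
                sl[d] = 0
                vf[tuple(sl)] = np.take(vc, 0, axis=d)
                sl[d] = fs[d] - 1
                vf[tuple(sl)] = np.take(vc, -1, axis=d)
            faces.append(vf)
        return faces

    def gradient_inner_product(
        self, f_faces: list[np.ndarray], g_faces: list[np.ndarray], scale: float = 1.0
    ) -> float:
        """int grad f : grad g dV via the same Dirichlet energy form as the
        Stokes stiffness.  ``scale`` converts the mm-based measure to other
        units (e.g. 1e-3 for face values in m/s with mm spacings -> SI)."""
        h = self.h
        vol = self.vol
        total = 0.0
        for d in AXES:
            act = self.face_active[d]
            ff, gf = f_faces[d], g_faces[d]
            fs = act.shape
            for dp in AXES:
                w_e = vol / h[dp] ** 2
                sl_a = [slice(None)] * 3
                sl_b = [slice(None)] * 3
                sl_a[dp] = slice(0, fs[dp] - 1)
                sl_b[dp] = slice(1, None)
                A, B = tuple(sl_a), tuple(sl_b)
                pair = act[A] & act[B]
                df = (ff[B] - ff[A])[pair]
                dg = (gf[B] - gf[A])[pair]
                total += w_e * float(np.dot(df, dg))
                if dp != d:
                    ghost_a = act[A] & ~act[B]
                    ghost_b = act[B] & ~act[A]
                    total += 2.0 * w_e * float(np.dot(ff[A][ghost_a], gf[A][ghost_a]))
                    total += 2.0 * w_e * float(np.dot(ff[B][ghost_b], gf[B][ghost_b]))
        return total * scale


@dataclass
class VirtualField:
    """Divergence-free unit-net-flow virtual field over one lumen segment.

    ``faces`` hold the staggered representation in m/s with a net flux of
    ``q_v`` = 1e-9 m^3/s (i.e. 1 mm^3/s) from inlet to outlet; ``w_cell`` is
    the cell-centered average.  ``crop`` indexes the analyzed sub-grid of the
    original mask/field arrays.
    """

    faces: list[np.ndarray]
    domain: _StaggeredDomain
    crop: tuple[slice, slice, slice]
    q_v: float
    lumen: str
    axis: int
    reversed_flow: bool
    divergence_residual: float
    station_fluxes: list[float]
    spacing_mm: tuple[float, float, float]

    @property
    def w_cell(self) -> np.ndarray:
        return self.domain.cell_average(self.faces)

    @property
    def fluid(self) -> np.ndarray:
        return self.domain.mask


@dataclass
class EnergyTerms:
    """Per-frame work-energy contributions (SI: watts for A and V; joules-
    rate after differentiating Ke)."""

    time: np.ndarray
    kinetic: np.ndarray  # Ke(t) = rho int v.w dV  [J s/m ... differentiated later]
    advective: np.ndarray  # A(t) = rho int (v.grad v).w dV
    viscous: np.ndarray  # V(t) = mu int grad v : grad w dV
    fluid: FluidProperties


def _axis_from_plane(plane: AnalysisPlane) -> int:
    axis = int(np.argmax(np.abs(plane.normal)))
    if abs(plane.normal[axis]) < 0.99:
        warnings.warn(
            "inlet/outlet plane normal is not grid-axis aligned; using the "
            "dominant axis",
            stacklevel=3,
        )
    return axis


def compute_virtual_field(
    mask: LumenMask,
    lumen: int | str,
    inlet_plane: AnalysisPlane,
    outlet_plane: AnalysisPlane,
    tolerance: float = 1e-8,
    mu_v: float = 1.0,
) -> VirtualField:
    """Stokes virtual field over `lumen` between two axial stations.

    The stations are taken from the plane origins along the dominant normal
    axis.  Swapping inlet and outlet exactly negates the field (Stokes
    linearity).  Raises :class:`SolverError` if the interior divergence
    residual (relative to the unit net flux) exceeds ``tolerance``.
    """
    axis = _axis_from_plane(inlet_plane)
    if axis != _axis_from_plane(outlet_plane):
        raise FlumenError("inlet and outlet planes must share a dominant axis")
    h = np.asarray(mask.voxel_size, dtype=float)
    n_ax = mask.grid_shape[axis]
    k_in = int(np.clip(round(inlet_plane.origin[axis] / h[axis]), 0, n_ax))
    k_out = int(np.clip(round(outlet_plane.origin[axis] / h[axis]), 0, n_ax))
    if k_in == k_out:
        raise FlumenError("inlet and outlet stations coincide")
    reversed_flow = k_in > k_out
    k_lo, k_hi = sorted((k_in, k_out))

    if isinstance(lumen, str) and lumen.lower() == "both":
        fluid_full = mask.labels > 0
        lumen_name = "both"
    else:
        label = resolve_label(lumen)
        fluid_full = mask.labels == label
        lumen_name = {1: "TL", 2: "FL"}[label]

    crop = [slice(None)] * 3
    crop[axis] = slice(k_lo, k_hi)
    fluid = fluid_full[tuple(crop)]
    # tighten the transverse bounding box (1-voxel margin) for solver size
    other = [d for d in AXES if d != axis]
    nz = np.nonzero(fluid)
    if nz[0].size == 0:
        raise DisconnectedDomainError("lumen has no voxels between the stations")
    for d in other:
        lo = max(int(nz[d].min()) - 1, 0)
        hi = min(int(nz[d].max()) + 2, fluid.shape[d])
        crop[d] = slice(lo, hi)
    fluid = fluid_full[tuple(crop)]

    # keep only the component reaching the inlet face; require it to also
    # reach the outlet face
    lab, n_comp = ndimage.label(fluid)
    inlet_ids = set(np.unique(np.take(lab, 0, axis=axis))) - {0}
    outlet_ids = set(np.unique(np.take(lab, -1, axis=axis))) - {0}
    through = sorted(inlet_ids & outlet_ids)
    if not through:
        raise DisconnectedDomainError(
            "lumen is not connected from the inlet to the outlet station"
        )
    fluid = np.isin(lab, through)

    dom = _StaggeredDomain(fluid, h, axis)
    faces_mm = dom.solve_unit_flow(mu_v=mu_v)

    div = dom.divergence(faces_mm)
    residual = float(np.abs(div[fluid]).max())  # relative to unit flux
    if residual > tolerance:
        raise SolverError(
            f"divergence residual {residual:.3e} exceeds tolerance {tolerance:.1e}"
        )
    n_ax_crop = fluid.shape[axis]
    stations = np.unique(
        np.clip(np.linspace(0, n_ax_crop, 5).round().astype(int), 0, n_ax_crop)
    )
    fluxes = [dom.station_flux(faces_mm, int(k)) for k in stations]

    sign = -1.0 if reversed_flow else 1.0
    faces_si = [sign * f * 1e-3 for f in faces_mm]  # mm/s -> m/s
    return VirtualField(
        faces=faces_si,
        domain=dom,
        crop=tuple(crop),
        q_v=1e-9,  # flux in the inlet->outlet direction: 1 mm^3/s, in m^3/s
        lumen=lumen_name,
        axis=axis,
        reversed_flow=reversed_flow,
        divergence_residual=residual,
        station_fluxes=fluxes,
        spacing_mm=tuple(h),
    )


def lumen_radius_check(mask: LumenMask, lumen: int | str, axis: int = 2):
    """Mean inscribed radius along the lumen centerline, in voxels.

    Fails when the average radius is below 2 voxels (too narrow for reliable
    velocity sampling and pressure estimation).
    """
    from .flow_analysis import centerline_path

    label = resolve_label(lumen)
    lum = mask.labels == label
    if not lum.any():
        raise FlumenError("empty lumen")
    dist = ndimage.distance_transform_edt(lum)  # voxel units
    h = np.asarray(mask.voxel_size, dtype=float)
    stations = np.nonzero(lum.any(axis=tuple(d for d in AXES if d != axis)))[0]
    s0 = (stations.min() + 0.5) * h[axis]
    s1 = (stations.max() + 0.5) * h[axis]
    path, _ = centerline_path(lum, h, axis, s0, s1)
    mean_radius = float(dist[tuple(path.T)].mean())
    return RadiusCheckResult(passed=mean_radius >= 2.0, mean_radius_voxels=mean_radius)


@dataclass
class RadiusCheckResult:
    passed: bool
    mean_radius_voxels: float


def compute_energy_terms(
    fld: VelocityField,
    virtual: VirtualField,
    fluid: FluidProperties | None = None,
) -> EnergyTerms:
    """Per-frame kinetic, advective and viscous work-energy terms (SI)."""
    fluid = fluid or FluidProperties()
    if fld.grid_shape[virtual.axis] < virtual.crop[virtual.axis].stop:
        raise GridMismatchError("velocity field grid does not cover the virtual domain")
    crop = virtual.crop
    v = fld.data[crop[0], crop[1], crop[2]] * 1e-2  # cm/s -> m/s, (..., nt, 3)
    mask = virtual.fluid
    v = v * mask[..., None, None]

    h_si = np.asarray(virtual.spacing_mm) * 1e-3
    cell_vol = float(h_si.prod())
    rho, mu = fluid.density, fluid.dynamic_viscosity
    w_cell = virtual.w_cell
    dom = virtual.domain

    nt = fld.n_frames
    ke = np.zeros(nt)
    adv = np.zeros(nt)
    visc = np.zeros(nt)
    for f in range(nt):
        vf = v[:, :, :, f, :]
        ke[f] = rho * float(np.einsum("xyzc,xyzc->", vf, w_cell)) * cell_vol
        # (v . grad) v with central differences (one-sided at array edges)
        conv = np.zeros_like(vf)
        grads = [np.gradient(vf[..., c], *h_si, edge_order=1) for c in range(3)]
        for c in range(3):
            conv[..., c] = (
                vf[..., 0] * grads[c][0]
                + vf[..., 1] * grads[c][1]
                + vf[..., 2] * grads[c][2]
            )
        conv *= mask[..., None]
        adv[f] = rho * float(np.einsum("xyzc,xyzc->", conv, w_cell)) * cell_vol
        v_faces = dom.cells_to_faces(vf)
        # face values in m/s, spacings in mm: the energy form carries
        # vol/h^2 = mm; convert the measure mm -> m
        visc[f] = mu * dom.gradient_inner_product(v_faces, virtual.faces, scale=1e-3)
    return EnergyTerms(time=fld.times, kinetic=ke, advective=adv, viscous=visc, fluid=fluid)


def compute_relative_pressure(
    terms: EnergyTerms,
    virtual: VirtualField,
    tolerance: float = 1e-30,
) -> RelativePressureTrace:
    """Inlet-to-outlet relative pressure trace, mmHg.

    dP(t) = (dKe/dt + A(t) + V(t)) / Q_v with dKe/dt by cyclic central
    differences (zero in single-frame steady mode).
    """
    if abs(virtual.q_v) <= tolerance:
        raise SolverError("virtual flux Q_v is numerically zero")
    n = terms.time.size
    if n == 1:
        dke = np.zeros(1)
    elif n < 3:
        raise FlumenError("need >= 3 frames for the temporal derivative (or 1 for steady)")
    else:
        dt = float(np.median(np.diff(terms.time)))
        dke = (np.roll(terms.kinetic, -1) - np.roll(terms.kinetic, 1)) / (2.0 * dt)
    dp_pa = (dke + terms.advective + terms.viscous) / virtual.q_v
    return RelativePressureTrace(
        time=terms.time,
        delta_p=dp_pa * MMHG_PER_PA,
        lumen=virtual.lumen,
        normalized=False,
    )


def normalize_and_extract(
    trace: RelativePressureTrace, length: float
) -> tuple[float, float, RelativePressureTrace]:
    """Length-normalize a pressure trace; returns (dP_max, dP_min, trace).

    ``length`` is the centerline length in metres; outputs are in mmHg/m.
    """
    if length <= 0:
        raise FlumenError("normalization length must be positive")
    normalized = RelativePressureTrace(
        time=trace.time,
        delta_p=trace.delta_p / length,
        lumen=trace.lumen,
        normalized=True,
        length_used=length,
    )
    return normalized.dp_max, normalized.dp_min, normalized


def transseptal_pressure(
    tl: RelativePressureTrace, fl: RelativePressureTrace
) -> RelativePressureTrace:
    """Transseptal pressure trace: TL minus FL, frame-wise."""
    if tl.time.shape != fl.time.shape or not np.allclose(tl.time, fl.time):
        raise FlumenError("TL and FL traces have mismatched time bases")
    if tl.normalized != fl.normalized:
        raise FlumenError("TL and FL traces have mismatched normalization state")
    return RelativePressureTrace(
        time=tl.time,
        delta_p=tl.delta_p - fl.delta_p,
        lumen="transseptal",
        normalized=tl.normalized,
        length_used=tl.length_used,
    )


def vwerp_pressure_trace(
    fld: VelocityField,
    mask: LumenMask,
    lumen: int | str,
    inlet_plane: AnalysisPlane,
    outlet_plane: AnalysisPlane,
    fluid: FluidProperties | None = None,
    tolerance: float = 1e-8,
) -> tuple[RelativePressureTrace, VirtualField]:
    """Convenience pipeline: virtual field -> energy terms -> dP(t)."""
    virtual = compute_virtual_field(
        mask, lumen, inlet_plane, outlet_plane, tolerance=tolerance
    )
    terms = compute_energy_terms(fld, virtual, fluid)
    return compute_relative_pressure(terms, virtual), virtual
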