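"""Indirect false-lumen pressurization metrics: FLEF and MSDR."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .flow_analysis import (
    AccelerationTrace,
    AnalysisPlane,
    CardiacPhases,
    antegrade_retrograde_volumes,
    compute_flow_trace,
    detect_cardiac_phases,
    differentiate_trace,
)
from .io import FlumenError, VelocityField

__all__ = [
    "FlefResult",
    "MsdrResult",
    "UndefinedMetricError",
    "compute_flef",
    "compute_msdr",
]


class UndefinedMetricError(FlumenError):
    """The metric is undefined for this input (e.g. zero antegrade volume)."""


@dataclass
class FlefResult:
    """False lumen ejection fraction.

    FLEF (%) = 100 * retrograde diastolic tear volume / antegrade volume.
    """

    flef: float
    antegrade_volume: float
    retrograde_diastolic_volume: float
    plane_id: str
    systole: tuple[int, int]


@dataclass
class MsdrResult:
    """Maximum systolic deceleration rate: |a_max - a_min| / |t_amin - t_amax|.

    ``degenerate`` is set when acceleration is constant over systole (the
    extrema coincide and the rate is reported as 0).
    """

    msdr: float  # cm/s^3
    a_max: float  # cm/s^2
    a_min: float
    t_amax: float  # s
    t_amin: float
    subsection_id: str
    degenerate: bool = False


def compute_flef(
    fld: VelocityField,
    tear_plane: AnalysisPlane,
    phases: CardiacPhases | None = None,
    denominator_window: str = "cycle",
) -> FlefResult:
    """FLEF at the entry-tear plane.

    When ``phases`` is omitted, systole/diastole are detected from the tear
    trace itself.  Raises :class:`UndefinedMetricError` when the antegrade
    volume vanishes (measurement failure, distinct from FLEF = 0).
    """
    trace = compute_flow_trace(fld, tear_plane)
    if phases is None:
        phases = detect_cardiac_phases(trace)
    antegrade, retro = antegrade_retrograde_volumes(
        trace, phases, denominator_window=denominator_window
    )
    if antegrade <= 0:
        raise UndefinedMetricError(
            "antegrade tear volume is zero; FLEF is undefined"
        )
    return FlefResult(
        flef=100.0 * retro / antegrade,
        antegrade_volume=antegrade,
        retrograde_diastolic_volume=retro,
        plane_id=tear_plane.plane_id,
        systole=phases.systole,
    )


def compute_msdr(trace: AccelerationTrace, phases: CardiacPhases) -> MsdrResult:
    """MSDR from a subsection acceleration trace over the systolic window."""
    if trace.acceleration is None:
        trace = differentiate_trace(trace)
    frames = phases.systole_frames
    if frames.size < 3:
        raise FlumenError("systole must contain >= 3 frames")
    acc = trace.acceleration[frames]
    t = trace.time[frames]
    i_max = int(np.argmax(acc))
    i_min = int(np.argmin(acc))
    a_max, a_min = float(acc[i_max]), float(acc[i_min])
    t_amax, t_amin = float(t[i_max]), float(t[i_min])
    if i_max == i_min:
        return MsdrResult(
            msdr=0.0,
            a_max=a_max,
            a_min=a_min,
            t_amax=t_amax,
            t_amin=t_amin,
            subsection_id=trace.subsection_id,
            degenerate=True,
        )
    if t_amin < t_amax:
        warnings.warn(
            "peak deceleration precedes peak acceleration in systole",
            stacklevel=2,
        )
    msdr = abs(a_max - a_min) / abs(t_amin - t_amax)
    return MsdrResult(
        msdr=msdr,
        a_max=a_max,
        a_min=a_min,
        t_amax=t_amax,
        t_amin=t_amin,
        subsection_id=trace.subsection_id,
    )
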