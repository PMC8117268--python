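"""Shared phantom fixtures (session-scoped: several suites reuse them)."""

import numpy as np
import pytest

from flumen.flow_analysis import AnalysisPlane
from flumen.phantom import (
    PhantomGeometry,
    WaveformSpec,
    make_dissection_mask,
    make_poiseuille_field,
    make_pulsatile_field,
    make_tube_mask,
)


@pytest.fixture(scope="session")
def geometry():
    return PhantomGeometry()  # 48x24x80 @ 1.5x1.5x2.5 mm, tear at 100 mm


@pytest.fixture(scope="session")
def dissection_mask(geometry):
    return make_dissection_mask(geometry)


@pytest.fixture(scope="session")
def waveform():
    return WaveformSpec()  # antegrade 10 ml, diastolic retrograde 4.9 ml


@pytest.fixture(scope="session")
def pulsatile(geometry, waveform, dissection_mask):
    """(field, ground_truth) for the default pulsatile dissection phantom."""
    return make_pulsatile_field(geometry, waveform, mask=dissection_mask)


@pytest.fixture(scope="session")
def tear_plane(pulsatile):
    _, truth = pulsatile
    return AnalysisPlane(
        origin=truth.tear_plane_origin_mm,
        normal=truth.tear_plane_normal,
        roi_radius=truth.tear_roi_radius_mm,
        plane_id="entry_tear",
    )


@pytest.fixture(scope="session")
def tube_geometry():
    """Short straight tube, cheap enough for repeated Stokes solves."""
    return PhantomGeometry(
        grid_shape=(18, 18, 24),
        voxel_size=(1.5, 1.5, 2.5),
        lumen_radius_tl=8.0,
        tear_center_axial=30.0,
    )


@pytest.fixture(scope="session")
def tube_mask(tube_geometry):
    return make_tube_mask(tube_geometry)


@pytest.fixture(scope="session")
def tube_planes(tube_geometry):
    cx, cy = tube_geometry.tl_center
    inlet = AnalysisPlane(origin=(cx, cy, 0.0), normal=(0, 0, 1), roi_radius=12.0,
                          plane_id="inlet")
    outlet = AnalysisPlane(
        origin=(cx, cy, tube_geometry.axial_extent), normal=(0, 0, 1), roi_radius=12.0,
        plane_id="outlet",
    )
    return inlet, outlet


@pytest.fixture(scope="session")
def poiseuille(tube_geometry):
    """(field, reference dp in mmHg) at Q = 83.3 ml/s."""
    return make_poiseuille_field(tube_geometry, flow=83.3)


@pytest.fixture(scope="session")
def tube_virtual(tube_mask, tube_planes):
    from flumen.vwerp import compute_virtual_field

    inlet, outlet = tube_planes
    return compute_virtual_field(tube_mask, "TL", inlet, outlet)
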