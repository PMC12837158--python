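import numpy as np
import pytest
import trimesh

from eritwin import (
    AnalysisRegion,
    SurfaceMesh,
    SyntheticCaseSpec,
    generate_case,
    radial_sampling,
    resample_centerline,
)
from eritwin.synthetic import GapDefect


@pytest.fixture(scope="session")
def cylinder_mesh() -> SurfaceMesh:
    """Analytic right circular cylinder, radius 10 mm, z in [-20, 20]."""
    return SurfaceMesh.from_trimesh(
        trimesh.creation.cylinder(radius=10.0, height=40.0, sections=256)
    )


@pytest.fixture(scope="session")
def straight_case():
    """Uniform neck, circular graft, no defects: perfect apposition."""
    spec = SyntheticCaseSpec(seed=11)
    aorta, graft, path = generate_case(spec)
    return spec, aorta, graft, path


@pytest.fixture(scope="session")
def straight_field(straight_case):
    _, aorta, graft, path = straight_case
    return radial_sampling(aorta, graft, path)


@pytest.fixture(scope="session")
def defect_case():
    """Tapered neck with one declared 2-mm-deep, 6-mm-long gap defect."""
    spec = SyntheticCaseSpec(
        neck_radius_proximal=12.0,
        neck_radius_distal=10.0,
        neck_length=30.0,
        gap_defects=[GapDefect(start_s=4.0, length=6.0, angular_center_deg=90.0,
                               angular_span_deg=90.0, depth=2.0)],
        seed=7,
    )
    aorta, graft, path = generate_case(spec)
    return spec, aorta, graft, path


@pytest.fixture(scope="session")
def defect_field(defect_case):
    _, aorta, graft, path = defect_case
    return radial_sampling(aorta, graft, path)


@pytest.fixture()
def straight_path():
    return resample_centerline([[0.0, 0.0, 0.0], [0.0, 0.0, 40.0]], 0.5)


def concentric_cylinder_pair(r_outer=12.0, r_inner=10.0, length=40.0, sections=256):
    """Two coaxial analytic cylinders spanning z in [0, length]."""
    shift = trimesh.transformations.translation_matrix([0, 0, length / 2])
    outer = trimesh.creation.cylinder(radius=r_outer, height=length,
                                      sections=sections, transform=shift)
    inner = trimesh.creation.cylinder(radius=r_inner, height=length,
                                      sections=sections, transform=shift)
    return SurfaceMesh.from_trimesh(outer), SurfaceMesh.from_trimesh(inner)
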