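import numpy as np
import pytest

from phantomkit import _meshops, photon_transport
from phantomkit.phantom_io import (PolygonPhantom, Region,
                                   default_material_library)


@pytest.fixture(scope="session")
def material_library():
    return default_material_library()


@pytest.fixture(scope="session")
def xs_table(material_library):
    return photon_transport.build_cross_sections(material_library)


@pytest.fixture
def unit_cube_region():
    v, f = _meshops.box_mesh((0, 0, 0), (1, 1, 1))
    return Region(1, "cube", v, f)


@pytest.fixture
def sphere_region():
    v, f = _meshops.icosphere(4, 1.0)
    return Region(2, "sphere", v, f)


def make_water_column(depth_cm, pitch_mm=1.0, lateral_cm=100.0):
    """1-voxel-wide water column along y for slab physics tests."""
    from phantomkit.phantom_io import VoxelPhantom

    ny = int(round(depth_cm * 10.0 / pitch_mm))
    ids = np.ones((1, ny, 1), dtype=np.int32)
    return VoxelPhantom(ids, pitch=(lateral_cm * 10.0, pitch_mm,
                                    lateral_cm * 10.0))


@pytest.fixture
def obj_cube_text():
    lines = ["g skin_100"]
    v, f = _meshops.box_mesh((0, 0, 0), (1, 1, 1))
    for x, y, z in v:
        lines.append(f"v {x:.17g} {y:.17g} {z:.17g}")
    for a, b, c in f:
        lines.append(f"f {a + 1} {b + 1} {c + 1}")
    return "\n".join(lines) + "\n"


def two_region_phantom():
    ov, of = _meshops.icosphere(2, 3.0)
    iv, if_ = _meshops.icosphere(2, 1.5)
    return PolygonPhantom([
        Region(1, "body", ov, of),
        Region(2, "content", iv, if_),
    ])
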