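"""Deterministic stylized phantoms and packaged table fixtures.

The stylized body is an ellipsoid with a full-thickness skin shell, a
50-100 um sensitive sublayer, a soft-tissue interior, an optional
breast-analog sphere directly beneath the anterior skin and an optional
homogenized bone slab.  The stylized eye is a spherical eyeball holding an
oblate lens split by a coronal plane into an anterior sensitive and a
posterior insensitive part; both eyeball and lens are mass-targeted by
uniform scaling.

Anterior means the minimum-y side throughout (the AP beam travels +y).
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from importlib.resources import files

import numpy as np
import pandas as pd

from . import _meshops, geometry_qa
from .phantom_io import PolygonPhantom, Region, VoxelPhantom

# canonical region ids for the stylized anatomy
RID_SOFT = 1
RID_SKIN = 2
RID_SKIN_SENSITIVE = 3
RID_BREAST = 4
RID_BONE = 5
RID_EYEBALL = 10
RID_LENS_SENSITIVE = 11
RID_LENS_INSENSITIVE = 12

#: region id -> material id in the packaged library
SYNTH_MATERIALS = {
    0: "air",
    RID_SOFT: "soft_tissue",
    RID_SKIN: "skin",
    RID_SKIN_SENSITIVE: "skin",
    RID_BREAST: "breast",
    RID_BONE: "hard_bone",
    RID_EYEBALL: "eyeball",
    RID_LENS_SENSITIVE: "lens",
    RID_LENS_INSENSITIVE: "lens",
}


@dataclass
class StylizedBodySpec:
    sex: str = "male"
    semi_axes: tuple = (15.0, 10.0, 30.0)     # cm, (x, y, z); y is AP depth
    skin_thickness_mm: float | None = None    # default 1.28 male / 1.13 female
    sensitive_lo_um: float = 50.0
    sensitive_hi_um: float = 100.0
    include_breast: bool = True
    breast_radius_cm: float = 3.0       # lateral semi-axis
    breast_depth_cm: float = 0.6        # AP semi-axis
    include_bone: bool = False
    bone_slab_cm: tuple = (4.0, 2.0, 10.0)
    subdivisions: int = 3
    voxel_pitch_mm: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if self.skin_thickness_mm is None:
            self.skin_thickness_mm = 1.28 if self.sex == "male" else 1.13
        if self.skin_thickness_mm * 0.1 >= min(self.semi_axes) / 20.0:
            raise ValueError("skin thickness must stay below the smallest "
                             "semi-axis / 20")
        if self.voxel_pitch_mm <= 0:
            raise ValueError("voxel pitch must be positive")
        if not (0 <= self.sensitive_lo_um < self.sensitive_hi_um):
            raise ValueError("sensitive sublayer window is invalid")


@dataclass
class StylizedEyeSpec:
    sex: str = "male"
    eyeball_mass_kg: float | None = None      # default 0.015 male / 0.012 female
    lens_mass_kg: float | None = None         # default 0.0004 / 0.0003
    eyeball_density: float = 1.05             # g/cm^3
    lens_density: float = 1.07
    lens_aspect: float = 0.45                 # AP semi-axis / lateral semi-axis
    lens_offset_fraction: float = 0.55        # lens centre along -y, in radii
    subdivisions: int = 3

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if self.eyeball_mass_kg is None:
            self.eyeball_mass_kg = 0.015 if self.sex == "male" else 0.012
        if self.lens_mass_kg is None:
            self.lens_mass_kg = 0.0004 if self.sex == "male" else 0.0003
        for v in (self.eyeball_mass_kg, self.lens_mass_kg,
                  self.eyeball_density, self.lens_density):
            if v <= 0:
                raise ValueError("masses and densities must be positive")


def make_layered_body(spec: StylizedBodySpec) -> PolygonPhantom:
    """Closed nested stylized body; deterministic for a fixed spec."""
    outer_v, outer_f = _meshops.ellipsoid_mesh(spec.semi_axes,
                                               subdivisions=spec.subdivisions)
    body = Region(RID_SKIN, "skin", outer_v, outer_f)
    t_um = spec.skin_thickness_mm * 1000.0
    if spec.sensitive_hi_um >= t_um:
        raise ValueError("sensitive sublayer deeper than the skin itself")
    skin = geometry_qa.extract_shell_layer(
        body, geometry_qa.LayerSpec(0.0, t_um, "skin", RID_SKIN),
        check_intersections=False)
    sensitive = geometry_qa.extract_shell_layer(
        body, geometry_qa.LayerSpec(spec.sensitive_lo_um, spec.sensitive_hi_um,
                                    "skin_sensitive", RID_SKIN_SENSITIVE),
        check_intersections=False)
    interior_surface = geometry_qa.offset_surface(body, t_um)
    interior = Region(RID_SOFT, "soft_tissue",
                      interior_surface.vertices, interior_surface.faces)
    regions = [interior, skin, sensitive]
    if spec.include_breast:
        # broad, thin oblate region tangent to the inner skin surface, so it
        # sits directly beneath the anterior skin like a surface organ
        a, c = spec.breast_radius_cm, spec.breast_depth_cm
        centre = (0.0, -(spec.semi_axes[1] - spec.skin_thickness_mm / 10.0
                         - c), 0.0)
        bv, bf = _meshops.ellipsoid_mesh((a, c, a), centre,
                                         max(2, spec.subdivisions - 1))
        regions.append(Region(RID_BREAST, "breast_analog", bv, bf))
    if spec.include_bone:
        half = np.asarray(spec.bone_slab_cm) / 2.0
        centre = np.array([0.0, spec.semi_axes[1] * 0.3, 0.0])
        bv, bf = _meshops.box_mesh(centre - half, centre + half)
        regions.append(Region(RID_BONE, "bone_slab", bv, bf))
    ph = PolygonPhantom(regions, metadata={"sex": spec.sex,
                                          "source": "stylized-body"})
    ph.validate()
    return ph


def make_stylized_eye(spec: StylizedEyeSpec) -> PolygonPhantom:
    """Mass-targeted eyeball + split lens; masses recover within 0.5%."""
    ev, ef = _meshops.icosphere(spec.subdivisions, 1.0)
    eyeball, _ = geometry_qa.scale_to_target_mass(
        Region(RID_EYEBALL, "eyeball", ev, ef),
        spec.eyeball_density, spec.eyeball_mass_kg)
    r_eye = float(np.linalg.norm(eyeball.vertices, axis=1).mean())
    # oblate lens (flattened along y), scaled to its own mass target
    lens_axes = (1.0, spec.lens_aspect, 1.0)
    lv, lf = _meshops.ellipsoid_mesh(lens_axes, subdivisions=spec.subdivisions)
    lens_whole, _ = geometry_qa.scale_to_target_mass(
        Region(0, "lens", lv, lf), spec.lens_density, spec.lens_mass_kg)
    centre = np.array([0.0, -spec.lens_offset_fraction * r_eye, 0.0])
    lens_v = lens_whole.vertices + centre
    lens_extent = np.abs(lens_v).max()
    if lens_extent >= r_eye:
        raise ValueError("lens does not fit inside the eyeball")
    # split by the coronal plane through the lens centre: anterior (-y) is
    # the sensitive part
    av, af = _meshops.clip_halfspace(lens_v, lens_whole.faces, centre,
                                     (0.0, 1.0, 0.0))
    pv, pf = _meshops.clip_halfspace(lens_v, lens_whole.faces, centre,
                                     (0.0, -1.0, 0.0))
    regions = [
        eyeball,
        Region(RID_LENS_SENSITIVE, "lens_sensitive", av, af),
        Region(RID_LENS_INSENSITIVE, "lens_insensitive", pv, pf),
    ]
    ph = PolygonPhantom(regions, metadata={"sex": spec.sex,
                                          "source": "stylized-eye"})
    ph.validate()
    return ph


def make_perforated_voxel_skin(body: VoxelPhantom, hole_fraction: float,
                               seed: int, skin_id=RID_SKIN,
                               replace_id=None, air_id=0) -> VoxelPhantom:
    """Reassign a random fraction of skin voxels to the underlying tissue.

    Mimics the resolution-limited voxel skin that cannot fully enclose its
    contents: where the membrane fails, the tissue beneath it occupies the
    voxel and is directly exposed to the exterior.  The underlying tissue of
    each hole is the nearest voxel that is neither skin nor air (so holes
    over the breast analog become breast); pass ``replace_id`` to force one
    id instead.  Deterministic per seed.
    """
    if not (0 <= hole_fraction < 1):
        raise ValueError("hole_fraction must be in [0, 1)")
    ids = body.organ_ids.copy()
    skin_voxels = np.flatnonzero(ids == skin_id)
    if len(skin_voxels) == 0:
        raise ValueError(f"phantom has no skin region (id {skin_id})")
    n_holes = int(round(hole_fraction * len(skin_voxels)))
    if n_holes == 0:
        return VoxelPhantom(ids, body.pitch, body.origin)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(skin_voxels, size=n_holes, replace=False)
    flat = ids.ravel()
    if replace_id is not None:
        flat[chosen] = replace_id
    else:
        from scipy.ndimage import distance_transform_edt
        tissue = (ids != skin_id) & (ids != air_id)
        _, nearest = distance_transform_edt(~tissue, return_indices=True)
        under = ids[nearest[0], nearest[1], nearest[2]].ravel()
        flat[chosen] = under[chosen]
    return VoxelPhantom(flat.reshape(body.organ_ids.shape), body.pitch,
                        body.origin)


_FIXTURES = ("jpm_masses", "jpf_masses", "jpm_bone", "jpf_bone",
             "reference_masses", "wt_icrp103")


def load_fixture(name: str) -> pd.DataFrame:
    """Packaged data tables, values exactly as shipped."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {_FIXTURES}")
    text = files("phantomkit.data").joinpath(f"{name}.tsv").read_text()
    df = pd.read_csv(StringIO(text), sep="\t", comment="#")
    return df.set_index(df.columns[0])
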