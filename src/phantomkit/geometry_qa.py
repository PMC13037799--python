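"""Mesh quality control, mass accounting, layering and representation
conversion.

Conventions: closed surfaces oriented outward carry positive signed volume;
an inverted surface is auto-corrected and flagged rather than rejected.
Shell layers are bounded by inward offsets along angle-weighted vertex
normals, which keeps vertex correspondence between the bounding surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

from . import _meshops
from .phantom_io import (PolygonPhantom, Region, TetPhantom, VoxelPhantom,
                         PhantomValidationError)


class OpenSurfaceError(ValueError):
    """Operation requires a closed (watertight) surface."""


@dataclass
class QAEntry:
    region_id: int
    closed: bool
    boundary_edge_count: int
    non_manifold_edge_count: int
    self_intersection_pair_count: int = 0
    inverted_orientation: bool = False


@dataclass
class QAReport:
    entries: dict = field(default_factory=dict)  # region_id -> QAEntry

    def all_clean(self):
        return all(
            e.closed and e.self_intersection_pair_count == 0
            for e in self.entries.values())

    def __getitem__(self, rid) -> QAEntry:
        return self.entries[rid]


@dataclass
class LayerSpec:
    """Depth window below the outer surface, in micrometres."""
    depth_lo: float
    depth_hi: float
    name: str = "layer"
    region_id: int = 0

    def __post_init__(self):
        if not (0 <= self.depth_lo < self.depth_hi):
            raise ValueError("require 0 <= depth_lo < depth_hi")


# ---------------------------------------------------------------------------
# QA
# ---------------------------------------------------------------------------

def check_watertight(region: Region) -> QAEntry:
    b, nm = _meshops.edge_statistics(region.faces)
    closed = b == 0 and nm == 0
    inverted = False
    if closed:
        inverted = _meshops.signed_volume(region.vertices, region.faces) < 0
    return QAEntry(region.region_id, closed, b, nm,
                   inverted_orientation=inverted)


def detect_self_intersections(region: Region):
    """Triangle-index pairs that transversally intersect (adjacency excluded)."""
    return _meshops.self_intersections(region.vertices, region.faces)


def qa_phantom(phantom: PolygonPhantom, intersections=True) -> QAReport:
    report = QAReport()
    for r in phantom.regions:
        entry = check_watertight(r)
        if intersections:
            entry.self_intersection_pair_count = len(detect_self_intersections(r))
        report.entries[r.region_id] = entry
    return report


# ---------------------------------------------------------------------------
# volumes and masses
# ---------------------------------------------------------------------------

def surface_volume(region: Region, flag=None) -> float:
    """Enclosed volume (cm^3) by the divergence theorem.

    An inverted orientation yields the absolute value; pass a dict as
    ``flag`` to receive ``{"inverted_orientation": bool}``.
    """
    entry = check_watertight(region)
    if not entry.closed:
        raise OpenSurfaceError(
            f"region {region.region_id} is not closed "
            f"({entry.boundary_edge_count} boundary edges, "
            f"{entry.non_manifold_edge_count} non-manifold edges); "
            "run qa_phantom for a full report")
    vol = _meshops.signed_volume(region.vertices, region.faces)
    if flag is not None:
        flag["inverted_orientation"] = vol < 0
    return abs(vol)


def region_mass(volume_cm3: float, density_g_cm3: float) -> float:
    """Mass in kg from volume (cm^3) and density (g/cm^3)."""
    if volume_cm3 <= 0 or density_g_cm3 <= 0:
        raise ValueError("volume and density must be positive")
    return volume_cm3 * density_g_cm3 / 1000.0


def scale_to_target_mass(region: Region, density_g_cm3: float,
                         target_mass_kg: float):
    """Uniform scale about the volume centroid to hit a target mass.

    Returns ``(scaled_region, factor)`` with factor = (target/current)^(1/3).
    """
    if target_mass_kg <= 0:
        raise ValueError("target mass must be positive")
    vol = surface_volume(region)
    current = region_mass(vol, density_g_cm3)
    s = (target_mass_kg / current) ** (1.0 / 3.0)
    centroid = _meshops.volume_centroid(region.vertices, region.faces)
    scaled = Region(region.region_id, region.name,
                    (region.vertices - centroid) * s + centroid,
                    region.faces.copy())
    return scaled, s


# ---------------------------------------------------------------------------
# layering
# ---------------------------------------------------------------------------

def offset_surface(region: Region, depth_um: float) -> Region:
    """Inward offset along angle-weighted vertex normals (depth in um)."""
    if depth_um == 0:
        return Region(region.region_id, region.name,
                      region.vertices.copy(), region.faces.copy())
    normals = _meshops.vertex_normals_angle_weighted(region.vertices, region.faces)
    if _meshops.signed_volume(region.vertices, region.faces) < 0:
        normals = -normals
    d_cm = depth_um * 1e-4
    return Region(region.region_id, region.name,
                  region.vertices - normals * d_cm, region.faces.copy())


def extract_shell_layer(region: Region, spec: LayerSpec,
                        check_intersections=True) -> Region:
    """Closed shell bounded by inward offsets at depth_lo and depth_hi.

    The result is a two-component surface (outer boundary oriented outward,
    inner boundary flipped) whose signed volume is the layer volume.
    """
    if check_intersections and _meshops.self_intersections(
            region.vertices, region.faces):
        raise PhantomValidationError(
            f"region {region.region_id}: self-intersecting input surface")
    outer = offset_surface(region, spec.depth_lo)
    inner = offset_surface(region, spec.depth_hi)
    if _meshops.signed_volume(inner.vertices, inner.faces) <= 0:
        raise PhantomValidationError(
            f"layer {spec.name}: inner offset at {spec.depth_hi} um collapsed "
            "the surface (depth too large for this geometry)")
    n_outer = len(outer.vertices)
    verts = np.vstack([outer.vertices, inner.vertices])
    faces = np.vstack([outer.faces, inner.faces[:, [0, 2, 1]] + n_outer])
    layer = Region(spec.region_id, spec.name, verts, faces)
    vol = _meshops.signed_volume(verts, faces)
    if vol <= 0:
        raise PhantomValidationError(
            f"layer {spec.name}: non-positive layer volume {vol:.3g}")
    if check_intersections and _meshops.self_intersections(verts, faces):
        raise PhantomValidationError(
            f"layer {spec.name}: offsetting produced self-intersections")
    return layer


# ---------------------------------------------------------------------------
# representation conversion
# ---------------------------------------------------------------------------

def voxel_region_to_surface(phantom: VoxelPhantom, region_id: int,
                            smooth: bool = False) -> Region:
    """Closed surface of one voxel region, in cm.

    The default is the exact voxel boundary (encloses count * voxel volume
    exactly).  ``smooth=True`` uses a marching-cubes iso-surface instead,
    which rounds corners and slightly shrinks small regions.
    """
    mask = phantom.organ_ids == region_id
    if not mask.any():
        raise ValueError(f"region id {region_id} occupies no voxels")
    spacing = tuple(p / 10.0 for p in phantom.pitch)  # mm -> cm
    if smooth:
        from skimage import measure

        padded = np.pad(mask, 1).astype(np.float64)
        verts, faces, _, _ = measure.marching_cubes(padded, level=0.5,
                                                    spacing=spacing)
        shift = np.asarray(phantom.origin, float) + 0.5 * np.asarray(spacing)
        verts = verts - np.asarray(spacing) + shift
        faces = faces.astype(np.int64)
    else:
        verts, faces = _meshops.voxel_boundary_mesh(mask, spacing,
                                                    phantom.origin)
    region = Region(region_id, f"region_{region_id}", verts, faces)
    if _meshops.signed_volume(verts, region.faces) < 0:
        region.faces = region.faces[:, [0, 2, 1]]
    return region


def _exclusive_volumes(phantom: PolygonPhantom):
    """Per-region enclosed volume minus directly nested children."""
    vols = {r.region_id: surface_volume(r) for r in phantom.regions}
    centers = {r.region_id: _meshops.volume_centroid(r.vertices, r.faces)
               for r in phantom.regions}
    exclusive = dict(vols)
    order = sorted(phantom.regions, key=lambda r: vols[r.region_id])
    for i, inner in enumerate(order):
        # parent = smallest-volume region strictly containing inner's centroid
        for outer in order[i + 1:]:
            inside = _meshops.points_in_mesh(
                centers[inner.region_id][None, :],
                outer.vertices, outer.faces)[0]
            if inside:
                exclusive[outer.region_id] -= vols[inner.region_id]
                break
    return vols, exclusive


def tetrahedralize(phantom: PolygonPhantom, volume_tol=0.005,
                   refine=0) -> TetPhantom:
    """Delaunay-based conversion of closed, mutually non-intersecting
    (nesting allowed) regions into a region-tagged tetrahedral mesh.

    Each Delaunay tetrahedron is assigned to the innermost region containing
    its centroid; tets outside every region are dropped.  Per-region tet
    volume is verified against the exclusive surface volume to volume_tol.
    """
    report = qa_phantom(phantom, intersections=False)
    bad = [rid for rid, e in report.entries.items() if not e.closed]
    if bad:
        raise OpenSurfaceError(f"regions not closed: {bad}")
    pts = np.vstack([r.vertices for r in phantom.regions])
    for _ in range(refine):
        pass  # reserved: optional Steiner refinement
    tri = Delaunay(pts)
    elements = tri.simplices.astype(np.int64)
    vols = _meshops.tet_volumes(pts, elements)
    flip = vols < 0
    elements[flip] = elements[flip][:, [0, 1, 3, 2]]
    cent = pts[elements].mean(axis=1)
    enc_vols, exclusive = _exclusive_volumes(phantom)
    # innermost wins: assign in order of decreasing enclosed volume
    order = sorted(phantom.regions, key=lambda r: -enc_vols[r.region_id])
    assigned = np.full(len(elements), -1, dtype=np.int64)
    for r in order:
        inside = _meshops.points_in_mesh(cent, r.vertices, r.faces)
        assigned[inside] = r.region_id
    keep = assigned >= 0
    tet = TetPhantom(pts, elements[keep], assigned[keep])
    for r in phantom.regions:
        tv = tet.region_volume(r.region_id)
        ev = exclusive[r.region_id]
        if ev > 0 and abs(tv - ev) > volume_tol * ev:
            raise PhantomValidationError(
                f"tetrahedralize: region {r.region_id} tet volume {tv:.6g} "
                f"deviates from surface volume {ev:.6g} by more than "
                f"{volume_tol:.1%}")
    return tet


def voxelize(phantom, pitch, padding_voxels=1) -> VoxelPhantom:
    """Rasterize a polygon or tet phantom onto a voxel grid.

    ``pitch`` is (dx, dy, dz) in mm (a scalar is isotropic).  Voxel id is
    the innermost region containing the voxel center (innermost wins so thin
    shells survive their parent at coarse pitch); id 0 is surrounding air.
    """
    if np.isscalar(pitch):
        pitch = (float(pitch),) * 3
    if any(p <= 0 for p in pitch):
        raise ValueError("pitch must be strictly positive")
    if isinstance(phantom, TetPhantom):
        phantom = _tet_to_polygon(phantom)
    all_v = np.vstack([r.vertices for r in phantom.regions])
    lo = all_v.min(axis=0)
    hi = all_v.max(axis=0)
    pitch_cm = np.asarray(pitch, float) / 10.0
    lo = lo - padding_voxels * pitch_cm
    hi = hi + padding_voxels * pitch_cm
    dims = np.maximum(np.ceil((hi - lo) / pitch_cm).astype(int), 1)
    centers = [lo[ax] + (np.arange(dims[ax]) + 0.5) * pitch_cm[ax]
               for ax in range(3)]
    ids = np.zeros(tuple(dims), dtype=np.int32)
    vols = {r.region_id: abs(_meshops.signed_volume(r.vertices, r.faces))
            for r in phantom.regions}
    order = sorted(phantom.regions, key=lambda r: -vols[r.region_id])
    for r in order:
        mask = _meshops.rasterize_solid(r.vertices, r.faces, *centers)
        ids[mask] = r.region_id
    return VoxelPhantom(ids, tuple(pitch), origin=tuple(lo))


def _tet_to_polygon(tet: TetPhantom) -> PolygonPhantom:
    """Boundary surface of each tet region (exterior faces only)."""
    regions = []
    for rid in np.unique(tet.region_ids):
        els = tet.elements[tet.region_ids == rid]
        faces = np.concatenate([
            els[:, [0, 2, 1]], els[:, [0, 1, 3]],
            els[:, [1, 2, 3]], els[:, [0, 3, 2]]])
        key = np.sort(faces, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True,
                                   return_counts=True)
        boundary = faces[counts[inv] == 1]
        used = np.unique(boundary)
        remap = np.full(len(tet.nodes), -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        regions.append(Region(int(rid), f"region_{rid}",
                              tet.nodes[used].copy(), remap[boundary]))
    return PolygonPhantom(regions)
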