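"""Phantom description formats and the material/region catalogs.

Three on-disk phantom descriptions are supported, all plain text:

* Wavefront OBJ polygon surfaces, one region per ``g`` group.  The region
  id rides in the group-name suffix ``_<id>`` and is mirrored in a
  ``usemtl m<id>`` statement.
* TetGen-dialect ELE/NODE tetrahedral meshes (1-based on disk, region id
  as the single element attribute).
* Whitespace-separated ASCII voxel rasters, x fastest, then y, then z.

Coordinates are cm internally; voxel pitch is mm.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _meshops


class PhantomFormatError(ValueError):
    """Malformed phantom file."""


class PhantomValidationError(ValueError):
    """Structurally valid file describing an invalid phantom."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Region:
    region_id: int
    name: str
    vertices: np.ndarray  # (n, 3) cm
    faces: np.ndarray     # (m, 3) vertex-index triples

    def validate(self):
        if len(self.faces) < 4:
            raise PhantomValidationError(
                f"region {self.region_id} ({self.name}): fewer than 4 faces")
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise PhantomValidationError(
                f"region {self.region_id}: face references missing vertex")
        if not np.isfinite(self.vertices).all():
            raise PhantomValidationError(
                f"region {self.region_id}: non-finite coordinates")


@dataclass
class PolygonPhantom:
    regions: list[Region]
    metadata: dict = field(default_factory=dict)

    def validate(self):
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise PhantomValidationError("duplicate region ids")
        for r in self.regions:
            r.validate()

    def region(self, region_id: int) -> Region:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(f"no region with id {region_id}")

    @property
    def region_ids(self):
        return [r.region_id for r in self.regions]


@dataclass
class TetPhantom:
    nodes: np.ndarray        # (n, 3) cm
    elements: np.ndarray     # (m, 4) 0-based node indices
    region_ids: np.ndarray   # (m,)

    def validate(self):
        if len(self.elements) and self.elements.max() >= len(self.nodes):
            raise PhantomValidationError("element references missing node")
        if len(self.elements) != len(self.region_ids):
            raise PhantomValidationError("elements/region_ids length mismatch")

    def volumes(self):
        return _meshops.tet_volumes(self.nodes, self.elements)

    def degenerate_elements(self, tol=1e-9):
        """Indices of elements whose volume is below tol (cm^3)."""
        return np.flatnonzero(np.abs(self.volumes()) < tol)

    def region_volume(self, region_id, degenerate_tol=1e-9):
        vols = np.abs(self.volumes())
        sel = (self.region_ids == region_id) & (vols >= degenerate_tol)
        return float(vols[sel].sum())


@dataclass
class VoxelPhantom:
    organ_ids: np.ndarray            # (nx, ny, nz) integer raster
    pitch: tuple = (0.98, 0.98, 1.0)  # mm
    origin: tuple = (0.0, 0.0, 0.0)   # cm, corner of voxel (0,0,0)

    def __post_init__(self):
        self.organ_ids = np.asarray(self.organ_ids)
        if self.organ_ids.ndim != 3:
            raise PhantomValidationError("organ_ids must be a 3-D raster")
        if any(p <= 0 for p in self.pitch):
            raise PhantomValidationError("pitch must be strictly positive")

    @property
    def dims(self):
        return self.organ_ids.shape

    @property
    def voxel_volume_cm3(self):
        dx, dy, dz = self.pitch
        return dx * dy * dz / 1000.0

    def region_volume(self, organ_id):
        return float((self.organ_ids == organ_id).sum()) * self.voxel_volume_cm3

    def extents_cm(self):
        """((x0, x1), (y0, y1), (z0, z1)) of the raster in cm."""
        out = []
        for ax in range(3):
            lo = self.origin[ax]
            out.append((lo, lo + self.dims[ax] * self.pitch[ax] / 10.0))
        return tuple(out)


@dataclass
class Material:
    name: str
    fractions: dict       # element symbol -> mass fraction
    density: float        # g/cm^3


ELEMENTS = ("H", "C", "N", "O", "Na", "Mg", "P", "S", "Cl", "K", "Ca", "Fe", "I")


@dataclass
class MaterialLibrary:
    materials: dict  # material_id -> Material

    def __getitem__(self, key) -> Material:
        return self.materials[key]

    def __contains__(self, key):
        return key in self.materials

    def ids(self):
        return list(self.materials)


@dataclass
class CatalogEntry:
    name: str
    material_id: str
    target_mass: float | None = None        # kg
    component_role: str = "organ"           # organ|content|sensitive-layer|bone-region


@dataclass
class RegionCatalog:
    entries: dict  # region_id -> CatalogEntry

    def validate(self, materials: MaterialLibrary):
        for rid, e in self.entries.items():
            if e.material_id not in materials:
                raise PhantomValidationError(
                    f"region {rid}: unknown material {e.material_id!r}")
            if e.target_mass is not None and e.target_mass <= 0:
                raise PhantomValidationError(
                    f"region {rid}: target mass must be positive")

    def __getitem__(self, rid) -> CatalogEntry:
        return self.entries[rid]

    def material_for(self, rid) -> str:
        return self.entries[rid].material_id


# ---------------------------------------------------------------------------
# OBJ
# ---------------------------------------------------------------------------

def _ensure_text(stream):
    if isinstance(stream, str):
        return io.StringIO(stream)
    return stream


def _resolve_region_id(group_name, mapping):
    if mapping and group_name in mapping:
        return int(mapping[group_name])
    if "_" in group_name:
        tail = group_name.rsplit("_", 1)[1]
        if tail.lstrip("-").isdigit():
            return int(tail)
    raise PhantomFormatError(
        f"cannot resolve region id for OBJ group {group_name!r}")


def read_obj_phantom(stream, group_to_region=None, metadata=None) -> PolygonPhantom:
    """Parse region-tagged OBJ text into a PolygonPhantom.

    Vertices are shared OBJ-globally; each region gets a compacted copy.
    N-gon faces are fan-triangulated from the first vertex.
    """
    fh = _ensure_text(stream)
    all_verts: list[list[float]] = []
    groups: dict[str, list[list[int]]] = {}
    order: list[str] = []
    current = None
    for lineno, raw in enumerate(fh, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        tag = parts[0]
        if tag == "v":
            all_verts.append([float(x) for x in parts[1:4]])
        elif tag in ("g", "o"):
            current = " ".join(parts[1:]) if len(parts) > 1 else "default"
            if current not in groups:
                groups[current] = []
                order.append(current)
        elif tag == "f":
            if current is None:
                current = "default"
                groups[current] = []
                order.append(current)
            idx = []
            for tok in parts[1:]:
                i = int(tok.split("/")[0])
                if i < 0:
                    i = len(all_verts) + 1 + i
                if not (1 <= i <= len(all_verts)):
                    raise PhantomFormatError(
                        f"line {lineno}: face references missing vertex {i}")
                idx.append(i - 1)
            if len(idx) < 3:
                raise PhantomFormatError(f"line {lineno}: face with <3 vertices")
            for k in range(1, len(idx) - 1):
                groups[current].append([idx[0], idx[k], idx[k + 1]])
    verts = np.asarray(all_verts, dtype=np.float64)
    regions = []
    for name in order:
        faces = np.asarray(groups[name], dtype=np.int64)
        if len(faces) == 0:
            continue
        rid = _resolve_region_id(name, group_to_region)
        used = np.unique(faces)
        remap = np.full(len(verts), -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        clean_name = name.rsplit("_", 1)[0] if name.rsplit("_", 1)[-1].lstrip("-").isdigit() else name
        regions.append(Region(rid, clean_name, verts[used].copy(), remap[faces]))
    ph = PolygonPhantom(regions, metadata=dict(metadata or {}))
    ph.validate()
    return ph


def write_obj_phantom(phantom: PolygonPhantom, stream) -> None:
    """Emit one ``g``/``usemtl`` pair per region; %.17g float round-trip."""
    for r in phantom.regions:
        if len(r.faces) == 0:
            raise PhantomValidationError(
                f"region {r.region_id}: cannot write region with zero faces")
    if not phantom.regions:
        raise PhantomValidationError("cannot write empty phantom")
    fh = _ensure_text(stream)
    offset = 1
    for r in phantom.regions:
        fh.write(f"g {r.name}_{r.region_id}\n")
        fh.write(f"usemtl m{r.region_id}\n")
        for x, y, z in r.vertices:
            fh.write(f"v {x:.17g} {y:.17g} {z:.17g}\n")
        for a, b, c in r.faces:
            fh.write(f"f {a + offset} {b + offset} {c + offset}\n")
        offset += len(r.vertices)


# ---------------------------------------------------------------------------
# TetGen ELE/NODE
# ---------------------------------------------------------------------------

def _data_lines(fh):
    for lineno, raw in enumerate(fh, start=1):
        line = raw.split("#")[0].strip()
        if line:
            yield lineno, line.split()


def read_tet_phantom(ele_stream, node_stream) -> TetPhantom:
    """Read a TetGen-dialect ELE/NODE pair (1-based indices on disk)."""
    nfh = _ensure_text(node_stream)
    lines = _data_lines(nfh)
    try:
        _, head = next(lines)
    except StopIteration:
        raise PhantomFormatError("empty NODE file") from None
    n_nodes = int(head[0])
    labels = np.empty(n_nodes, dtype=np.int64)
    coords = np.empty((n_nodes, 3), dtype=np.float64)
    count = 0
    for lineno, parts in lines:
        if count >= n_nodes:
            raise PhantomFormatError(
                f"NODE line {lineno}: more records than header count {n_nodes}")
        labels[count] = int(parts[0])
        coords[count] = [float(x) for x in parts[1:4]]
        count += 1
    if count != n_nodes:
        raise PhantomFormatError(
            f"NODE: header says {n_nodes} records, found {count}")
    label_to_row = {int(l): i for i, l in enumerate(labels)}

    efh = _ensure_text(ele_stream)
    lines = _data_lines(efh)
    try:
        _, head = next(lines)
    except StopIteration:
        raise PhantomFormatError("empty ELE file") from None
    n_ele = int(head[0])
    elements = np.empty((n_ele, 4), dtype=np.int64)
    region_ids = np.zeros(n_ele, dtype=np.int64)
    count = 0
    for lineno, parts in lines:
        if count >= n_ele:
            raise PhantomFormatError(
                f"ELE line {lineno}: more records than header count {n_ele}")
        for k in range(4):
            node_label = int(parts[1 + k])
            if node_label not in label_to_row:
                raise PhantomFormatError(
                    f"ELE line {lineno}: node index {node_label} out of range")
            elements[count, k] = label_to_row[node_label]
        if len(parts) > 5:
            region_ids[count] = int(float(parts[5]))
        count += 1
    if count != n_ele:
        raise PhantomFormatError(
            f"ELE: header says {n_ele} records, found {count}")
    ph = TetPhantom(coords, elements, region_ids)
    ph.validate()
    # orientation normalization: positive volumes
    vols = ph.volumes()
    flip = vols < 0
    if flip.any():
        ph.elements[flip] = ph.elements[flip][:, [0, 1, 3, 2]]
    degen = ph.degenerate_elements()
    if len(degen):
        warnings.warn(
            f"{len(degen)} degenerate tetrahedra flagged (indices "
            f"{degen[:10].tolist()}{'...' if len(degen) > 10 else ''})",
            stacklevel=2)
    return ph


def write_tet_phantom(phantom: TetPhantom, ele_stream, node_stream) -> None:
    nfh = _ensure_text(node_stream)
    nfh.write(f"{len(phantom.nodes)} 3 0 0\n")
    for i, (x, y, z) in enumerate(phantom.nodes, start=1):
        nfh.write(f"{i} {x:.17g} {y:.17g} {z:.17g}\n")
    efh = _ensure_text(ele_stream)
    efh.write(f"{len(phantom.elements)} 4 1\n")
    for i, (el, rid) in enumerate(zip(phantom.elements, phantom.region_ids),
                                  start=1):
        a, b, c, d = (int(x) + 1 for x in el)
        efh.write(f"{i} {a} {b} {c} {d} {int(rid)}\n")


# ---------------------------------------------------------------------------
# voxel ASCII
# ---------------------------------------------------------------------------

def read_voxel_phantom(stream, dims, pitch=(0.98, 0.98, 1.0),
                       known_ids=None) -> VoxelPhantom:
    """Read a whitespace-separated integer raster (x fastest, then y, then z)."""
    fh = _ensure_text(stream)
    tokens = fh.read().split()
    nx, ny, nz = dims
    expected = nx * ny * nz
    if len(tokens) != expected:
        raise PhantomFormatError(
            f"voxel raster: expected {expected} values for dims {tuple(dims)}, "
            f"got {len(tokens)}")
    arr = np.array(tokens, dtype=np.int64)
    if known_ids is not None:
        unknown = sorted(set(np.unique(arr)) - set(known_ids) - {0})
        if unknown:
            warnings.warn(f"voxel raster contains ids outside catalog: {unknown}",
                          stacklevel=2)
    organ_ids = arr.reshape(nz, ny, nx).transpose(2, 1, 0)
    return VoxelPhantom(organ_ids, tuple(pitch))


def write_voxel_phantom(phantom: VoxelPhantom, stream, per_line=16) -> None:
    fh = _ensure_text(stream)
    flat = phantom.organ_ids.transpose(2, 1, 0).ravel()
    for i in range(0, len(flat), per_line):
        fh.write(" ".join(str(int(x)) for x in flat[i:i + per_line]))
        fh.write("\n")


# ---------------------------------------------------------------------------
# material library / region catalog configs
# ---------------------------------------------------------------------------

def read_material_library(config) -> MaterialLibrary:
    """Parse a TSV material table (columns: material, density, element symbols).

    Fraction sums within 1e-4 of 1 are renormalized; worse sums are rejected.
    """
    fh = _ensure_text(config)
    header = None
    mats = {}
    for raw in fh:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            header = parts
            continue
        row = dict(zip(header, parts))
        name = row[header[0]]
        density = float(row["density"])
        if density <= 0:
            raise PhantomValidationError(f"material {name!r}: density must be > 0")
        fractions = {}
        for el in ELEMENTS:
            val = float(row.get(el, 0) or 0)
            if val < 0:
                raise PhantomValidationError(
                    f"material {name!r}: negative fraction for {el}")
            if val > 0:
                fractions[el] = val
        total = sum(fractions.values())
        if abs(total - 1.0) > 1e-4:
            raise PhantomValidationError(
                f"material {name!r}: fractions sum to {total:.6f}, not 1")
        fractions = {el: w / total for el, w in fractions.items()}
        mats[name] = Material(name, fractions, density)
    return MaterialLibrary(mats)


def read_region_catalog(config, materials: MaterialLibrary | None = None) -> RegionCatalog:
    """Parse a TSV region catalog (region_id, name, material, target_mass, role)."""
    fh = _ensure_text(config)
    header = None
    entries = {}
    for raw in fh:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            header = parts
            continue
        row = dict(zip(header, parts))
        rid = int(row["region_id"])
        tm = row.get("target_mass", "")
        entries[rid] = CatalogEntry(
            name=row["name"],
            material_id=row["material"],
            target_mass=float(tm) if tm not in ("", "-", None) else None,
            component_role=row.get("role", "organ"),
        )
    cat = RegionCatalog(entries)
    if materials is not None:
        cat.validate(materials)
    return cat


def default_material_library() -> MaterialLibrary:
    """The packaged material library."""
    from importlib.resources import files
    text = files("phantomkit.data").joinpath("materials.tsv").read_text()
    return read_material_library(text)
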