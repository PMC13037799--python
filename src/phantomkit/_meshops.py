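"""Low-level triangle-mesh and tetrahedron primitives.

All coordinates are in cm, areas in cm^2, volumes in cm^3.  Meshes are
(vertices, faces) pairs: float64 (n, 3) vertex arrays and int (m, 3) face
index arrays.  A closed mesh oriented outward has positive signed volume.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def _vf(vertices, faces):
    v = np.asarray(vertices, dtype=np.float64)
    f = np.asarray(faces, dtype=np.int64)
    if v.ndim != 2 or v.shape[1] != 3:
        raise ValueError("vertices must be (n, 3)")
    if f.ndim != 2 or f.shape[1] != 3:
        raise ValueError("faces must be (m, 3)")
    return v, f


def face_corners(vertices, faces):
    v, f = _vf(vertices, faces)
    return v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]


def face_normals(vertices, faces, normalize=True):
    a, b, c = face_corners(vertices, faces)
    n = np.cross(b - a, c - a)
    if normalize:
        lens = np.linalg.norm(n, axis=1)
        lens[lens == 0.0] = 1.0
        n = n / lens[:, None]
    return n


def face_areas(vertices, faces):
    a, b, c = face_corners(vertices, faces)
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def signed_volume(vertices, faces):
    """Divergence-theorem signed volume (positive for outward orientation)."""
    a, b, c = face_corners(vertices, faces)
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def volume_centroid(vertices, faces):
    """Centroid of the enclosed solid (signed-tet decomposition to origin)."""
    a, b, c = face_corners(vertices, faces)
    w = np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0
    cent = (a + b + c) / 4.0  # tet corner at origin
    vol = w.sum()
    if vol == 0.0:
        raise ValueError("degenerate surface: zero enclosed volume")
    return (w[:, None] * cent).sum(axis=0) / vol


def edge_statistics(faces):
    """Return (boundary_edge_count, non_manifold_edge_count).

    Boundary edges appear on exactly one face; non-manifold edges on more
    than two.
    """
    f = np.asarray(faces, dtype=np.int64)
    e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    e.sort(axis=1)
    _, counts = np.unique(e, axis=0, return_counts=True)
    return int((counts == 1).sum()), int((counts > 2).sum())


def is_closed(faces):
    b, nm = edge_statistics(faces)
    return b == 0 and nm == 0


def vertex_normals_angle_weighted(vertices, faces):
    """Per-vertex normals, each incident face weighted by its corner angle."""
    v, f = _vf(vertices, faces)
    fn = face_normals(v, f)
    normals = np.zeros_like(v)
    corners = v[f]  # (m, 3, 3)
    for k in range(3):
        p = corners[:, k]
        q = corners[:, (k + 1) % 3]
        r = corners[:, (k + 2) % 3]
        u, w = q - p, r - p
        cosang = np.einsum("ij,ij->i", u, w) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(w, axis=1) + 1e-300
        )
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        np.add.at(normals, f[:, k], fn * ang[:, None])
    lens = np.linalg.norm(normals, axis=1)
    lens[lens == 0.0] = 1.0
    return normals / lens[:, None]


# ---------------------------------------------------------------------------
# primitive meshes
# ---------------------------------------------------------------------------

def box_mesh(lo, hi):
    """Axis-aligned box as 12 outward-oriented triangles."""
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    x0, y0, z0 = lo
    x1, y1, z1 = hi
    v = np.array([
        [x0, y0, z0], [x1, y0, z0], [x1, y1, z0], [x0, y1, z0],
        [x0, y0, z1], [x1, y0, z1], [x1, y1, z1], [x0, y1, z1],
    ])
    f = np.array([
        [0, 2, 1], [0, 3, 2],          # z = z0 (normal -z)
        [4, 5, 6], [4, 6, 7],          # z = z1 (+z)
        [0, 1, 5], [0, 5, 4],          # y = y0 (-y)
        [2, 3, 7], [2, 7, 6],          # y = y1 (+y)
        [0, 4, 7], [0, 7, 3],          # x = x0 (-x)
        [1, 2, 6], [1, 6, 5],          # x = x1 (+x)
    ])
    return v, f


def icosphere(subdivisions=3, radius=1.0, center=(0.0, 0.0, 0.0)):
    """Deterministic geodesic sphere from a subdivided icosahedron."""
    t = (1.0 + np.sqrt(5.0)) / 2.0
    v = np.array([
        [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
        [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
        [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
    ], dtype=np.float64)
    v /= np.linalg.norm(v, axis=1)[:, None]
    f = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ], dtype=np.int64)
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}
        verts = list(v)

        def midpoint(i, j):
            key = (i, j) if i < j else (j, i)
            if key not in cache:
                m = verts[i] + verts[j]
                m /= np.linalg.norm(m)
                cache[key] = len(verts)
                verts.append(m)
            return cache[key]

        new_f = []
        for a, b, c in f:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_f += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        v = np.array(verts)
        f = np.array(new_f, dtype=np.int64)
    return v * radius + np.asarray(center, float), f


def ellipsoid_mesh(semi_axes, center=(0.0, 0.0, 0.0), subdivisions=3):
    v, f = icosphere(subdivisions)
    return v * np.asarray(semi_axes, float) + np.asarray(center, float), f


def regular_tetrahedron(edge=1.0):
    """Regular tetrahedron nodes with the given edge length."""
    v = np.array([
        [1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1],
    ], dtype=np.float64)
    return v * (edge / (2.0 * np.sqrt(2.0)))


# ---------------------------------------------------------------------------
# intersection tests
# ---------------------------------------------------------------------------

def _segment_triangle_hits(p0, p1, a, b, c, eps=1e-12):
    """Vectorized segment/triangle intersection (Moller-Trumbore, t in [0,1])."""
    d = p1 - p0
    e1 = b - a
    e2 = c - a
    h = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(det) > eps
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    s = p0 - a
    u = np.einsum("ij,ij->i", s, h) * inv
    q = np.cross(s, e1)
    vpar = np.einsum("ij,ij->i", d, q) * inv
    t = np.einsum("ij,ij->i", e2, q) * inv
    return (
        ok
        & (u >= -eps)
        & (vpar >= -eps)
        & (u + vpar <= 1.0 + eps)
        & (t >= -eps)
        & (t <= 1.0 + eps)
    )


def triangle_pairs_intersect(t1, t2):
    """Transversal intersection test for triangle arrays (k,3,3) vs (k,3,3)."""
    hit = np.zeros(len(t1), dtype=bool)
    for src, dst in ((t1, t2), (t2, t1)):
        a, b, c = dst[:, 0], dst[:, 1], dst[:, 2]
        for i, j in ((0, 1), (1, 2), (2, 0)):
            hit |= _segment_triangle_hits(src[:, i], src[:, j], a, b, c)
    return hit


def self_intersections(vertices, faces):
    """Exact-ish self-intersection pairs; vertex-sharing neighbours excluded.

    Coplanar-overlap-only contacts are not reported (transversal test).
    """
    v, f = _vf(vertices, faces)
    if len(f) < 2:
        return []
    tri = v[f]
    cent = tri.mean(axis=1)
    rad = np.linalg.norm(tri - cent[:, None, :], axis=2).max(axis=1)
    tree = cKDTree(cent)
    pairs = tree.query_pairs(2.0 * rad.max(), output_type="ndarray")
    if len(pairs) == 0:
        return []
    # prune by per-pair bounding spheres
    d = np.linalg.norm(cent[pairs[:, 0]] - cent[pairs[:, 1]], axis=1)
    pairs = pairs[d <= rad[pairs[:, 0]] + rad[pairs[:, 1]]]
    if len(pairs) == 0:
        return []
    # exclude pairs sharing any vertex index
    fa, fb = f[pairs[:, 0]], f[pairs[:, 1]]
    share = (fa[:, :, None] == fb[:, None, :]).any(axis=(1, 2))
    pairs = pairs[~share]
    if len(pairs) == 0:
        return []
    hit = triangle_pairs_intersect(tri[pairs[:, 0]], tri[pairs[:, 1]])
    return [tuple(int(x) for x in p) for p in pairs[hit]]


# ---------------------------------------------------------------------------
# containment / rasterization
# ---------------------------------------------------------------------------

def points_in_mesh(points, vertices, faces, chunk=4_000_000):
    """Parity ray casting along +z for each query point.

    The ray origin is nudged deterministically off exact-vertex alignment.
    """
    v, f = _vf(vertices, faces)
    p = np.asarray(points, dtype=np.float64).reshape(-1, 3).copy()
    scale = max(1.0, float(np.abs(v).max()))
    p[:, 0] += 1.3e-9 * scale
    p[:, 1] += 2.7e-9 * scale
    a, b, c = face_corners(v, f)
    # 2D edge functions in the xy projection
    crossings = np.zeros(len(p), dtype=np.int64)
    n_tri = len(f)
    step = max(1, int(chunk // max(1, len(p))))
    for lo in range(0, n_tri, step):
        aa, bb, cc = a[lo:lo + step], b[lo:lo + step], c[lo:lo + step]
        d = (bb[:, 1] - cc[:, 1]) * (aa[:, 0] - cc[:, 0]) + (
            cc[:, 0] - bb[:, 0]) * (aa[:, 1] - cc[:, 1])
        good = np.abs(d) > 1e-300
        px = p[:, 0][:, None]
        py = p[:, 1][:, None]
        l1 = ((bb[:, 1] - cc[:, 1]) * (px - cc[:, 0])
              + (cc[:, 0] - bb[:, 0]) * (py - cc[:, 1])) / np.where(good, d, 1.0)
        l2 = ((cc[:, 1] - aa[:, 1]) * (px - cc[:, 0])
              + (aa[:, 0] - cc[:, 0]) * (py - cc[:, 1])) / np.where(good, d, 1.0)
        l3 = 1.0 - l1 - l2
        inside2d = good & (l1 >= 0) & (l2 >= 0) & (l3 >= 0)
        zhit = l1 * aa[:, 2] + l2 * bb[:, 2] + l3 * cc[:, 2]
        above = inside2d & (zhit > p[:, 2][:, None])
        crossings += above.sum(axis=1)
    return crossings % 2 == 1


def rasterize_solid(vertices, faces, xs, ys, zs):
    """Boolean occupancy mask (nx, ny, nz) of the solid bounded by the mesh.

    Column-parity fill: for every (x, y) grid column, z-crossings with the
    surface are paired up and voxel centers between entry and exit are
    marked inside.  Handles multi-component (shell/annulus) surfaces.
    """
    v, f = _vf(vertices, faces)
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    zs = np.asarray(zs, float)
    nx, ny, nz = len(xs), len(ys), len(zs)
    a, b, c = face_corners(v, f)
    col_hits: list[np.ndarray] = []
    z_hits: list[np.ndarray] = []
    dx = xs[1] - xs[0] if nx > 1 else 1.0
    dy = ys[1] - ys[0] if ny > 1 else 1.0
    for k in range(len(f)):
        ta, tb, tc = a[k], b[k], c[k]
        d = (tb[1] - tc[1]) * (ta[0] - tc[0]) + (tc[0] - tb[0]) * (ta[1] - tc[1])
        if abs(d) < 1e-300:
            continue  # vertical in projection: measure-zero for column rays
        xlo = max(0, int(np.ceil((min(ta[0], tb[0], tc[0]) - xs[0]) / dx - 1e-12)))
        xhi = min(nx - 1, int(np.floor((max(ta[0], tb[0], tc[0]) - xs[0]) / dx + 1e-12)))
        ylo = max(0, int(np.ceil((min(ta[1], tb[1], tc[1]) - ys[0]) / dy - 1e-12)))
        yhi = min(ny - 1, int(np.floor((max(ta[1], tb[1], tc[1]) - ys[0]) / dy + 1e-12)))
        if xhi < xlo or yhi < ylo:
            continue
        gx, gy = np.meshgrid(xs[xlo:xhi + 1], ys[ylo:yhi + 1], indexing="ij")
        l1 = ((tb[1] - tc[1]) * (gx - tc[0]) + (tc[0] - tb[0]) * (gy - tc[1])) / d
        l2 = ((tc[1] - ta[1]) * (gx - tc[0]) + (ta[0] - tc[0]) * (gy - tc[1])) / d
        l3 = 1.0 - l1 - l2
        ins = (l1 >= 0) & (l2 >= 0) & (l3 >= 0)
        if not ins.any():
            continue
        ix, iy = np.nonzero(ins)
        zhit = l1[ins] * ta[2] + l2[ins] * tb[2] + l3[ins] * tc[2]
        col_hits.append((ix + xlo) * ny + (iy + ylo))
        z_hits.append(zhit)
    mask = np.zeros((nx, ny, nz), dtype=bool)
    if not col_hits:
        return mask
    cols = np.concatenate(col_hits)
    zvals = np.concatenate(z_hits)
    order = np.lexsort((zvals, cols))
    cols, zvals = cols[order], zvals[order]
    # rank of each crossing within its column
    first = np.ones(len(cols), dtype=bool)
    first[1:] = cols[1:] != cols[:-1]
    start = np.flatnonzero(first)
    rank = np.arange(len(cols)) - np.repeat(start, np.diff(np.append(start, len(cols))))
    entries = rank % 2 == 0
    # z-interval fill via difference array
    zlo = zs[0]
    dz = zs[1] - zs[0] if nz > 1 else 1.0
    idx = np.ceil((zvals - zlo) / dz - 1e-12).astype(np.int64)
    idx = np.clip(idx, 0, nz)
    diff = np.zeros((nx * ny, nz + 1), dtype=np.int32)
    np.add.at(diff, (cols[entries], idx[entries]), 1)
    np.add.at(diff, (cols[~entries], idx[~entries]), -1)
    inside = np.cumsum(diff[:, :nz], axis=1) > 0
    return inside.reshape(nx, ny, nz)


def voxel_boundary_mesh(mask, pitch_cm, origin_cm=(0.0, 0.0, 0.0)):
    """Exact boundary surface of an occupancy mask (outward-oriented quads
    split into triangles).  Encloses exactly count * voxel volume."""
    mask = np.asarray(mask, bool)
    nx, ny, nz = mask.shape
    pitch = np.asarray(pitch_cm, float)
    origin = np.asarray(origin_cm, float)

    def corner_id(ix, iy, iz):
        return (ix * (ny + 1) + iy) * (nz + 1) + iz

    padded = np.pad(mask, 1, constant_values=False)
    tris = []
    # faces perpendicular to each axis; normal points occupied -> empty
    for ax in range(3):
        lower = np.moveaxis(padded, ax, 0)
        plus = lower[1:] & ~lower[:-1]    # empty below, occupied above: -ax face
        minus = lower[:-1] & ~lower[1:]   # occupied below, empty above: +ax face
        for sign, bound in ((-1, plus), (+1, minus)):
            idx = np.argwhere(bound)
            # strip the padding offset; face plane index along ax
            idx = idx - 1
            idx[:, 0] += 1  # boundary plane sits above the lower cell
            for rec in idx:
                plane = rec[0]
                a, b = rec[1], rec[2]
                # unrotate axis ordering
                coord = np.empty(3, dtype=int)
                order = [ax, (ax + 1) % 3, (ax + 2) % 3]
                coord[order[0]], coord[order[1]], coord[order[2]] = plane, a, b
                u, w = order[1], order[2]
                c00 = coord.copy()
                c10 = coord.copy(); c10[u] += 1
                c01 = coord.copy(); c01[w] += 1
                c11 = coord.copy(); c11[u] += 1; c11[w] += 1
                i00 = corner_id(*c00); i10 = corner_id(*c10)
                i01 = corner_id(*c01); i11 = corner_id(*c11)
                if sign > 0:
                    tris += [[i00, i10, i11], [i00, i11, i01]]
                else:
                    tris += [[i00, i11, i10], [i00, i01, i11]]
    tris = np.asarray(tris, dtype=np.int64)
    used = np.unique(tris)
    remap = {}
    verts = np.empty((len(used), 3))
    for row, cid in enumerate(used):
        iz = cid % (nz + 1)
        iy = (cid // (nz + 1)) % (ny + 1)
        ix = cid // ((nz + 1) * (ny + 1))
        verts[row] = origin + np.array([ix, iy, iz]) * pitch
        remap[cid] = row
    faces = np.vectorize(remap.get)(tris)
    return verts, faces.astype(np.int64)


# ---------------------------------------------------------------------------
# half-space clipping (convex caps)
# ---------------------------------------------------------------------------

def clip_halfspace(vertices, faces, plane_point, plane_normal):
    """Clip a closed mesh, keeping the side with (x - p) . n <= 0.

    On-plane vertices are kept by both half-spaces, so clipping with (p, n)
    and (p, -n) partitions the solid exactly.  The cut cross-section is
    re-closed by fanning each boundary loop of the kept surface about its
    centroid (loops must be star-shaped about their centroid, which holds
    for convex cuts).
    """
    v, f = _vf(vertices, faces)
    p0 = np.asarray(plane_point, float)
    n = np.asarray(plane_normal, float)
    n = n / np.linalg.norm(n)
    scale = max(1.0, float(np.abs(v).max()))
    tol = 1e-9 * scale
    d = (v - p0) @ n
    d[np.abs(d) <= tol] = 0.0
    out_verts: list[np.ndarray] = []
    out_faces: list[list[int]] = []
    cache: dict = {}

    def add_vert(pt):
        key = tuple(np.round(np.asarray(pt, float) / tol).astype(np.int64))
        if key not in cache:
            cache[key] = len(out_verts)
            out_verts.append(np.asarray(pt, float))
        return cache[key]

    for tri in f:
        dd = d[tri]
        if (dd <= 0.0).all():
            poly = [v[i] for i in tri]
        elif (dd > 0.0).all():
            continue
        else:
            # Sutherland-Hodgman against the plane
            poly = []
            for k in range(3):
                i, j = tri[k], tri[(k + 1) % 3]
                di, dj = d[i], d[j]
                if di <= 0.0:
                    poly.append(v[i])
                if (di < 0.0 and dj > 0.0) or (di > 0.0 and dj <= 0.0):
                    t = di / (di - dj)
                    if 0.0 < t < 1.0:
                        poly.append(v[i] + t * (v[j] - v[i]))
        idx = [add_vert(p) for p in poly]
        idx = [i for k, i in enumerate(idx) if i != idx[k - 1]]
        if len(idx) < 3 or len(set(idx)) < 3:
            continue
        for k in range(1, len(idx) - 1):
            if idx[0] != idx[k] and idx[k] != idx[k + 1] and idx[0] != idx[k + 1]:
                out_faces.append([idx[0], idx[k], idx[k + 1]])
    if not out_faces:
        raise ValueError("clip removed the entire mesh")
    # close the cut: fan every boundary loop of the kept surface
    farr = np.array(out_faces, dtype=np.int64)
    directed = np.concatenate([farr[:, [0, 1]], farr[:, [1, 2]], farr[:, [2, 0]]])
    und = np.sort(directed, axis=1)
    _, inv, counts = np.unique(und, axis=0, return_inverse=True,
                               return_counts=True)
    boundary = directed[counts[inv] == 1]
    if len(boundary):
        succ = {int(a): int(b) for a, b in boundary}
        seen: set[int] = set()
        varr = np.array(out_verts)
        for start in list(succ):
            if start in seen:
                continue
            loop = [start]
            seen.add(start)
            cur = succ[start]
            while cur != start:
                loop.append(cur)
                seen.add(cur)
                cur = succ[cur]
            if len(loop) < 3:
                continue
            centre = varr[loop].mean(axis=0)
            ci = add_vert(centre)
            m = len(loop)
            # kept faces traverse a->b on the boundary; cap runs b->a
            for i in range(m):
                a_i, b_i = loop[i], loop[(i + 1) % m]
                out_faces.append([ci, b_i, a_i])
    nv = np.array(out_verts)
    nf = np.array(out_faces, dtype=np.int64)
    return nv, nf


# ---------------------------------------------------------------------------
# tetrahedra
# ---------------------------------------------------------------------------

def tet_volumes(nodes, elements):
    n = np.asarray(nodes, float)
    e = np.asarray(elements, dtype=np.int64)
    a, b, c, d = n[e[:, 0]], n[e[:, 1]], n[e[:, 2]], n[e[:, 3]]
    return np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0
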