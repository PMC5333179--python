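"""Synthetic neural-tissue fixtures: morphologies, meshes, solid voxelization.

The generator produces neuron-like morphologies (a soma sphere plus a tree of
tapered segments), tessellates them into watertight triangle meshes, clips
them to an axis-aligned tissue block and converts them to voxel occupancy by
solid voxelization.

Meshes are emitted as unions of closed components (soma/joint spheres and
closed truncated cones).  Solid voxelization casts an axis-aligned ray through
every voxel centre and counts *signed* surface crossings (the generalized
winding number along the ray); a centre is inside the solid union iff the
count is >= 1.  For a single closed component this reduces to ray-crossing
parity.  Ties (a ray grazing an edge or vertex) are resolved by re-casting the
offending rays from an origin jittered by a fixed sub-voxel epsilon.

Units are micrometres throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "Segment",
    "Morphology",
    "Block",
    "MorphologyParams",
    "generate_morphology",
    "place_population",
    "transform_morphology",
    "morphology_to_mesh",
    "check_watertight",
    "clip_to_block",
    "voxelize_solid",
    "rasterize_morphology",
    "read_swc",
    "write_swc",
]


@dataclass(frozen=True)
class Segment:
    """Tapered capsule from p0 (radius r0) to p1 (radius r1), um."""

    p0: tuple
    r0: float
    p1: tuple
    r1: float
    parent: int = -1          # index of parent segment, -1 = soma

    def __post_init__(self):
        if self.r0 <= 0 or self.r1 <= 0:
            raise ValueError("segment radii must be positive")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.subtract(self.p1, self.p0)))


@dataclass
class Morphology:
    """Soma sphere plus a tree of tapered segments rooted at the soma."""

    soma_center: np.ndarray
    soma_radius: float
    segments: list = field(default_factory=list)

    def __post_init__(self):
        self.soma_center = np.asarray(self.soma_center, dtype=float)
        if self.soma_radius <= 0:
            raise ValueError("soma radius must be positive")
        self.validate_tree()

    def validate_tree(self, tol: float = 1e-6):
        """Check connectivity: each segment starts at the soma surface or at
        its parent's endpoint."""
        for i, s in enumerate(self.segments):
            if s.parent < 0:
                d = np.linalg.norm(np.asarray(s.p0) - self.soma_center)
                if abs(d - self.soma_radius) > tol * max(1.0, self.soma_radius):
                    raise ValueError(
                        f"stem {i} does not start on the soma surface")
            else:
                p = self.segments[s.parent]
                if np.linalg.norm(np.subtract(s.p0, p.p1)) > tol:
                    raise ValueError(
                        f"segment {i} detached from parent {s.parent}")


@dataclass(frozen=True)
class Block:
    """Axis-aligned bounding box, um."""

    lo: tuple
    hi: tuple

    def __post_init__(self):
        lo, hi = np.asarray(self.lo, float), np.asarray(self.hi, float)
        if not np.all(lo < hi):
            raise ValueError("block min corner must be < max corner per axis")

    @property
    def size(self) -> np.ndarray:
        return np.asarray(self.hi, float) - np.asarray(self.lo, float)


@dataclass(frozen=True)
class MorphologyParams:
    """Growth parameters of the procedural morphology generator."""

    n_stems: int = 3
    branch_prob: float = 0.3
    mean_segment_len: float = 8.0      # um
    taper: float = 0.85                # child/parent radius ratio
    max_depth: int = 4
    extent: float = 40.0               # max tip distance from soma, um
    soma_radius: float = 5.0           # um
    stem_radius: float = 1.5           # um
    min_radius: float = 0.3            # um
    direction_jitter: float = 0.4      # rad-scale angular wobble per step

    def __post_init__(self):
        for name in ("n_stems", "mean_segment_len", "taper", "extent",
                     "soma_radius", "stem_radius", "min_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must lie in [0, 1]")
        if self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")


def _unit(v):
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([0.0, 0.0, 1.0])


def generate_morphology(seed: int,
                        params: MorphologyParams = MorphologyParams()
                        ) -> Morphology:
    """Grow a random neuron-like tree, deterministically per seed.

    ``n_stems`` trunks leave the soma in random directions; each grows in
    steps of ~``mean_segment_len`` with angular wobble, tapers by ``taper``
    per depth level, branches into two with probability ``branch_prob``, and
    stops at ``max_depth``, at ``min_radius`` or at the ``extent`` sphere.
    """
    rng = np.random.default_rng(seed)
    c = np.zeros(3)
    morph = Morphology(soma_center=c, soma_radius=params.soma_radius,
                       segments=[])
    if params.max_depth == 0:
        return morph

    segments: list[Segment] = []
    # (start point, direction, radius, depth, parent index)
    stack = []
    for _ in range(params.n_stems):
        d = _unit(rng.normal(size=3))
        p0 = c + params.soma_radius * d
        stack.append((p0, d, params.stem_radius, 1, -1))

    while stack:
        p0, d, r0, depth, parent = stack.pop()
        length = params.mean_segment_len * rng.uniform(0.7, 1.3)
        d_new = _unit(d + params.direction_jitter * rng.normal(size=3))
        p1 = p0 + length * d_new
        r1 = max(params.min_radius, r0 * params.taper)
        seg = Segment(p0=tuple(p0), r0=r0, p1=tuple(p1), r1=r1, parent=parent)
        segments.append(seg)
        idx = len(segments) - 1
        if depth >= params.max_depth:
            continue
        if np.linalg.norm(p1 - c) >= params.extent:
            continue
        if r1 <= params.min_radius:
            continue
        n_children = 2 if rng.random() < params.branch_prob else 1
        for _ in range(n_children):
            stack.append((p1, d_new, r1, depth + 1, idx))

    morph.segments = segments
    morph.validate_tree()
    return morph


def transform_morphology(morph: Morphology, matrix: np.ndarray) -> Morphology:
    """Apply a rigid 4x4 transform to a morphology."""
    R = np.asarray(matrix)[:3, :3]
    t = np.asarray(matrix)[:3, 3]

    def tp(p):
        return tuple(R @ np.asarray(p) + t)

    segs = [replace(s, p0=tp(s.p0), p1=tp(s.p1)) for s in morph.segments]
    return Morphology(soma_center=R @ morph.soma_center + t,
                      soma_radius=morph.soma_radius, segments=segs)


def place_population(n: int, block: Block, seed: int,
                     params: MorphologyParams = MorphologyParams()
                     ) -> list[tuple[Morphology, np.ndarray]]:
    """Statistically position and orient ``n`` morphologies in a block.

    Soma centres are uniform in the block, orientations uniform over
    rotations; each cell gets its own morphology seed derived from ``seed``.
    Returns (morphology, 4x4 rigid transform) pairs; the morphology is in its
    local frame, the transform places it in the block.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    rng = np.random.default_rng(seed)
    lo = np.asarray(block.lo, float)
    hi = np.asarray(block.hi, float)
    out = []
    for i in range(n):
        morph = generate_morphology(int(rng.integers(0, 2**31 - 1)), params)
        pos = rng.uniform(lo, hi)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        T = np.eye(4)
        T[:3, :3] = R
        T[:3, 3] = pos
        out.append((morph, T))
    return out


# -- meshing ----------------------------------------------------------------

def _frame(axis: np.ndarray):
    """Orthonormal (u, v) perpendicular to a unit axis."""
    a = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else \
        np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(axis, a))
    v = np.cross(axis, u)
    return u, v


def _closed_cone(p0, r0, p1, r1, n: int):
    """Closed truncated cone (two rings + centre-fan end caps), outward
    winding.  Ring radii are scaled so the n-gon has the area of the circle."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    axis = _unit(p1 - p0)
    u, v = _frame(axis)
    scale = math.sqrt(2.0 * math.pi / (n * math.sin(2.0 * math.pi / n)))
    ang = 2.0 * np.pi * np.arange(n) / n
    circ = np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * v
    ring0 = p0 + r0 * scale * circ
    ring1 = p1 + r1 * scale * circ
    verts = np.vstack([ring0, ring1, p0[None, :], p1[None, :]])
    c0, c1 = 2 * n, 2 * n + 1
    faces = []
    for i in range(n):
        j = (i + 1) % n
        # side quad (outward)
        faces.append([i, j, n + j])
        faces.append([i, n + j, n + i])
        # bottom cap, normal along -axis
        faces.append([c0, j, i])
        # top cap, normal along +axis
        faces.append([c1, n + i, n + j])
    return verts, np.asarray(faces, dtype=np.int64)


def morphology_to_mesh(morph: Morphology, segments_per_circle: int = 16,
                       sphere_subdivisions: int = 3) -> trimesh.Trimesh:
    """Tessellate a morphology as a union of closed components.

    One icosphere for the soma, and per segment a closed truncated cone plus
    an icosphere at the distal joint (rounding branch points and tips).  The
    components overlap; the solid they describe is their union, which is what
    :func:`voxelize_solid` computes.  Zero-length segments are skipped with a
    warning.
    """
    parts = [trimesh.creation.icosphere(subdivisions=sphere_subdivisions,
                                        radius=morph.soma_radius)]
    parts[0].apply_translation(morph.soma_center)
    for i, s in enumerate(morph.segments):
        if s.length <= 1e-12:
            warnings.warn(f"segment {i} has zero length; skipped")
            continue
        v, f = _closed_cone(s.p0, s.r0, s.p1, s.r1, segments_per_circle)
        parts.append(trimesh.Trimesh(vertices=v, faces=f, process=False))
        ball = trimesh.creation.icosphere(subdivisions=sphere_subdivisions,
                                          radius=s.r1)
        ball.apply_translation(np.asarray(s.p1))
        parts.append(ball)
    mesh = trimesh.util.concatenate(parts)
    return trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                           process=False)


def check_watertight(mesh: trimesh.Trimesh):
    """Every edge must have exactly two incident faces, oppositely directed.

    Returns ``(ok, report)`` where ``report`` lists offending (sorted) edges.
    """
    faces = np.asarray(mesh.faces, dtype=np.int64)
    if len(faces) == 0:
        return True, []
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    # directed-edge multiset: closed 2-manifold with consistent orientation
    # iff every directed edge appears exactly once and its reverse once
    fwd = {}
    bad = set()
    for a, b in map(tuple, e):
        key = (a, b)
        fwd[key] = fwd.get(key, 0) + 1
    for (a, b), cnt in fwd.items():
        if cnt != 1 or fwd.get((b, a), 0) != 1:
            bad.add((min(a, b), max(a, b)))
    return len(bad) == 0, sorted(bad)


# -- clipping ---------------------------------------------------------------

def _clip_halfspace(vertices, faces, normal, offset, eps_scale):
    """Keep the part of a closed triangle soup with normal.x <= offset,
    re-closing the cut with cap faces.  Returns (vertices, faces) arrays."""
    normal = np.asarray(normal, float)
    s = vertices @ normal - offset
    eps = 1e-9 * eps_scale
    new_tris = []           # lists of 3 points
    boundary = []           # (pA, pB) directed so caps wind outward (+normal)

    def lerp(pa, pb, sa, sb):
        t = sa / (sa - sb)
        return pa + t * (pb - pa)

    for tri in faces:
        pts = vertices[tri]
        sv = s[tri]
        inside = sv <= eps
        if inside.all():
            new_tris.append(pts)
            continue
        if (~inside).all():
            continue
        # Sutherland-Hodgman against the plane
        poly = []
        q_exit = q_enter = None
        for i in range(3):
            j = (i + 1) % 3
            pa, pb, sa, sb = pts[i], pts[j], sv[i], sv[j]
            if sa <= eps:
                poly.append(pa)
            if (sa <= eps) != (sb <= eps):
                q = lerp(pa, pb, sa, sb)
                poly.append(q)
                if sa <= eps:       # in -> out crossing
                    q_exit = q
                else:               # out -> in crossing
                    q_enter = q
        if (q_exit is not None and q_enter is not None
                and np.linalg.norm(q_exit - q_enter) > 1e-7 * eps_scale):
            # the side triangles carry the directed cut edge exit -> enter;
            # the cap must carry its reverse to close the seam (zero-length
            # segments arise when a vertex lies exactly on the plane)
            boundary.append((q_enter, q_exit))
        for k in range(1, len(poly) - 1):
            new_tris.append([poly[0], poly[k], poly[k + 1]])

    cap_tris = _cap_loops(boundary, normal, eps_scale)
    all_tris = new_tris + cap_tris
    if not all_tris:
        return np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64)
    pts = np.asarray(all_tris, float).reshape(-1, 3)
    # merge coincident vertices so the seam is topologically closed
    key = np.round(pts / (1e-7 * eps_scale)).astype(np.int64)
    _, idx, inv = np.unique(key, axis=0, return_index=True,
                            return_inverse=True)
    verts = pts[idx]
    faces_out = inv.reshape(-1, 3)
    keep = ((faces_out[:, 0] != faces_out[:, 1]) &
            (faces_out[:, 1] != faces_out[:, 2]) &
            (faces_out[:, 2] != faces_out[:, 0]))
    return verts, faces_out[keep]


def _cap_loops(boundary, normal, eps_scale):
    """Chain directed boundary segments into loops and ear-clip them into
    cap triangles lying in the clip plane."""
    if not boundary:
        return []
    q = 1e-7 * eps_scale

    def key(p):
        return tuple(np.round(np.asarray(p) / q).astype(np.int64))

    nxt = {}
    for a, b in boundary:
        nxt[key(a)] = (np.asarray(a), np.asarray(b))
    tris = []
    used = set()
    u, v = _frame(_unit(np.asarray(normal, float)))
    for start in list(nxt):
        if start in used:
            continue
        loop = []
        k = start
        while k in nxt and k not in used:
            used.add(k)
            a, b = nxt[k]
            loop.append(a)
            k = key(b)
        if len(loop) < 3 or k != start:
            continue
        tris.extend(_ear_clip(loop, u, v))
    return tris


def _ear_clip(loop, u, v):
    """Triangulate a simple planar polygon given as 3-D points."""
    pts3 = [np.asarray(p) for p in loop]
    pts2 = np.array([[p @ u, p @ v] for p in pts3])
    n = len(pts2)
    idx = list(range(n))
    # signed area decides winding
    x, y = pts2[:, 0], pts2[:, 1]
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    ccw = area2 > 0
    tris = []
    guard = 0
    while len(idx) > 3 and guard < 10 * n * n:
        guard += 1
        m = len(idx)
        for ii in range(m):
            i0, i1, i2 = idx[ii - 1], idx[ii], idx[(ii + 1) % m]
            a, b, c = pts2[i0], pts2[i1], pts2[i2]
            cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            if (cross > 0) != ccw or abs(cross) < 1e-30:
                continue
            # no other loop vertex inside the candidate ear
            ok = True
            for jj in idx:
                if jj in (i0, i1, i2):
                    continue
                if _in_tri(pts2[jj], a, b, c):
                    ok = False
                    break
            if ok:
                tris.append([pts3[i0], pts3[i1], pts3[i2]])
                del idx[ii]
                break
        else:
            break
    if len(idx) == 3:
        tris.append([pts3[idx[0]], pts3[idx[1]], pts3[idx[2]]])
    # triangles inherit the loop's winding, which for a consistently
    # outward-wound input is already the outward (+clip-normal) winding
    return tris


def _in_tri(p, a, b, c):
    d1 = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
    d2 = (c[0] - b[0]) * (p[1] - b[1]) - (c[1] - b[1]) * (p[0] - b[0])
    d3 = (a[0] - c[0]) * (p[1] - c[1]) - (a[1] - c[1]) * (p[0] - c[0])
    neg = (d1 < 0) or (d2 < 0) or (d3 < 0)
    pos = (d1 > 0) or (d2 > 0) or (d3 > 0)
    return not (neg and pos)


def clip_to_block(mesh: trimesh.Trimesh, block: Block) -> trimesh.Trimesh:
    """Intersect a closed mesh with an axis-aligned box, re-closing the cut
    faces so the result is again closed.  An empty intersection yields an
    empty mesh."""
    lo = np.asarray(block.lo, float)
    hi = np.asarray(block.hi, float)
    verts = np.asarray(mesh.vertices, float)
    faces = np.asarray(mesh.faces, np.int64)
    if len(faces) == 0:
        return trimesh.Trimesh(vertices=np.zeros((0, 3)),
                               faces=np.zeros((0, 3), np.int64),
                               process=False)
    # fast path: fully inside
    if np.all(verts >= lo - 1e-12) and np.all(verts <= hi + 1e-12):
        return mesh.copy()
    scale = float(np.max(hi - lo) + np.max(np.abs(verts)) if len(verts) else 1.0)
    planes = []
    for ax in range(3):
        n = np.zeros(3)
        n[ax] = 1.0
        planes.append((n.copy(), hi[ax]))
        n[ax] = -1.0
        planes.append((n.copy(), -lo[ax]))
    for nrm, off in planes:
        verts, faces = _clip_halfspace(verts, faces, nrm, off, scale)
        if len(faces) == 0:
            break
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


# -- solid voxelization -----------------------------------------------------

def _grid_shape(block: Block, spacing: float):
    size = block.size
    dims = np.maximum(1, np.round(size / spacing).astype(int))
    return dims


def voxelize_solid(mesh: trimesh.Trimesh, spacing: float, block: Block,
                   axis: int = 2, conservative: bool = False) -> np.ndarray:
    """Binary occupancy over the block: voxel centre inside the solid.

    A ray is cast along ``axis`` through each centre and signed crossings of
    the oriented surface are summed; winding >= 1 marks the centre inside the
    union of the mesh's closed components.  Requires a watertight mesh.  With
    ``conservative=True``, voxels whose box overlaps a triangle's bounding box
    are additionally marked (a superset of boundary-intersecting voxels).
    Returns a boolean array of shape ``round(block.size / spacing)``.
    """
    ok, bad = check_watertight(mesh)
    if not ok:
        raise ValueError(f"mesh is not watertight; offending edges: {bad[:10]}"
                         f"{'...' if len(bad) > 10 else ''}")
    dims = _grid_shape(block, spacing)
    lo = np.asarray(block.lo, float)
    occ = np.zeros(tuple(dims), dtype=bool)
    faces = np.asarray(mesh.faces, np.int64)
    if len(faces) == 0:
        return occ

    # permute so the cast axis is local z; occ.transpose(perm) views the
    # occupancy in local (x, y, z) order
    perm = {0: (1, 2, 0), 1: (2, 0, 1), 2: (0, 1, 2)}[axis]
    view = occ.transpose(perm)
    tv = np.asarray(mesh.vertices, float)[faces][:, :, perm]   # (T, 3, 3)
    nx, ny, nz = dims[perm[0]], dims[perm[1]], dims[perm[2]]
    ox, oy, oz = lo[perm[0]], lo[perm[1]], lo[perm[2]]
    zc = oz + (np.arange(nz) + 0.5) * spacing

    def crossings(dx, dy):
        """All (column_id, z, sign) crossings with ray origins offset by
        (dx, dy) from centres; also the set of ambiguous columns."""
        cols, zs, sgn = [], [], []
        ambig = set()
        for v0, v1, v2 in tv:
            nzv = ((v1[0] - v0[0]) * (v2[1] - v0[1])
                   - (v1[1] - v0[1]) * (v2[0] - v0[0]))   # 2*area, signed
            if nzv == 0.0:
                continue
            xmin, xmax = min(v0[0], v1[0], v2[0]), max(v0[0], v1[0], v2[0])
            ymin, ymax = min(v0[1], v1[1], v2[1]), max(v0[1], v1[1], v2[1])
            i0 = max(0, int(math.floor((xmin - ox - dx) / spacing - 0.5 + 1)))
            i1 = min(nx - 1, int(math.floor((xmax - ox - dx) / spacing - 0.5)))
            j0 = max(0, int(math.floor((ymin - oy - dy) / spacing - 0.5 + 1)))
            j1 = min(ny - 1, int(math.floor((ymax - oy - dy) / spacing - 0.5)))
            if i0 > i1 or j0 > j1:
                continue
            xs = ox + dx + (np.arange(i0, i1 + 1) + 0.5) * spacing
            ys = oy + dy + (np.arange(j0, j1 + 1) + 0.5) * spacing
            X, Y = np.meshgrid(xs, ys, indexing="ij")
            w0 = ((v2[0] - v1[0]) * (Y - v1[1]) - (v2[1] - v1[1]) * (X - v1[0]))
            w1 = ((v0[0] - v2[0]) * (Y - v2[1]) - (v0[1] - v2[1]) * (X - v2[0]))
            w2 = ((v1[0] - v0[0]) * (Y - v0[1]) - (v1[1] - v0[1]) * (X - v0[0]))
            if nzv > 0:
                inside = (w0 > 0) & (w1 > 0) & (w2 > 0)
                grazing = ((w0 >= 0) & (w1 >= 0) & (w2 >= 0)) & ~inside
            else:
                inside = (w0 < 0) & (w1 < 0) & (w2 < 0)
                grazing = ((w0 <= 0) & (w1 <= 0) & (w2 <= 0)) & ~inside
            if grazing.any():
                gi, gj = np.nonzero(grazing)
                for a, b in zip(gi + i0, gj + j0):
                    ambig.add(int(a) * ny + int(b))
            if not inside.any():
                continue
            ii, jj = np.nonzero(inside)
            a = w0[inside] / nzv
            b = w1[inside] / nzv
            cvals = 1.0 - a - b
            z = a * v0[2] + b * v1[2] + cvals * v2[2]
            cols.append((ii + i0) * ny + (jj + j0))
            zs.append(z)
            sgn.append(np.full(z.shape, 1 if nzv > 0 else -1, dtype=np.int8))
        if cols:
            return (np.concatenate(cols), np.concatenate(zs),
                    np.concatenate(sgn), ambig)
        return (np.zeros(0, np.int64), np.zeros(0), np.zeros(0, np.int8),
                ambig)

    def fill(col_subset, dx, dy):
        cols, zs, sgn, ambig = crossings(dx, dy)
        if col_subset is not None:
            m = np.isin(cols, col_subset)
            cols, zs, sgn = cols[m], zs[m], sgn[m]
        order = np.lexsort((zs, cols))
        cols, zs, sgn = cols[order], zs[order], sgn[order]
        starts = np.searchsorted(cols, np.arange(nx * ny), side="left")
        ends = np.searchsorted(cols, np.arange(nx * ny), side="right")
        targets = (range(nx * ny) if col_subset is None
                   else np.asarray(col_subset, np.int64))
        for cid in targets:
            a, b = starts[cid], ends[cid]
            if a == b:
                occ_col = np.zeros(nz, dtype=bool)
            else:
                z_sorted = zs[a:b]
                s_sorted = sgn[a:b].astype(np.int64)
                suffix = np.concatenate(
                    [np.cumsum(s_sorted[::-1])[::-1], [0]])
                pos = np.searchsorted(z_sorted, zc, side="right")
                occ_col = suffix[pos] >= 1
            i, j = divmod(int(cid), ny)
            view[i, j, :] = occ_col
        return ambig

    ambig = fill(None, 0.0, 0.0)
    if ambig:
        # fixed sub-voxel jitter of the ray origin for grazing rays
        fill(sorted(ambig), 1.0e-4 * spacing, 2.3e-4 * spacing)
    if conservative:
        for v0, v1, v2 in tv:
            bmin = np.minimum(np.minimum(v0, v1), v2)
            bmax = np.maximum(np.maximum(v0, v1), v2)
            sel = []
            for d, o, nn, (b0, b1) in zip(range(3), (ox, oy, oz),
                                          (nx, ny, nz),
                                          zip(bmin, bmax)):
                lo_i = max(0, int(math.floor((b0 - o) / spacing)))
                hi_i = min(nn - 1, int(math.floor((b1 - o) / spacing)))
                if lo_i > hi_i:
                    sel = None
                    break
                sel.append(slice(lo_i, hi_i + 1))
            if sel is not None:
                view[tuple(sel)] = True
    return occ


def rasterize_morphology(morph: Morphology, spacing: float, block: Block
                         ) -> np.ndarray:
    """Distance-based occupancy: centre within the soma sphere or within a
    tapered capsule (linearly interpolated radius) of any segment.  Needs no
    mesh; cross-checks :func:`voxelize_solid`."""
    dims = _grid_shape(block, spacing)
    lo = np.asarray(block.lo, float)
    ax = [lo[d] + (np.arange(dims[d]) + 0.5) * spacing for d in range(3)]
    occ = np.zeros(tuple(dims), dtype=bool)
    # process in z-slabs to bound the point-array memory
    chunk = max(1, int(4_000_000 // (dims[0] * dims[1])))
    for k0 in range(0, dims[2], chunk):
        k1 = min(k0 + chunk, dims[2])
        X, Y, Z = np.meshgrid(ax[0], ax[1], ax[2][k0:k1], indexing="ij")
        pts = np.stack([X, Y, Z], axis=-1)
        part = (np.linalg.norm(pts - morph.soma_center, axis=-1)
                <= morph.soma_radius)
        for s in morph.segments:
            p0 = np.asarray(s.p0)
            p1 = np.asarray(s.p1)
            d = p1 - p0
            L2 = float(d @ d)
            if L2 <= 0:
                continue
            t = np.clip(((pts - p0) @ d) / L2, 0.0, 1.0)
            closest = p0 + t[..., None] * d
            r = s.r0 + t * (s.r1 - s.r0)
            part |= np.linalg.norm(pts - closest, axis=-1) <= r
        occ[:, :, k0:k1] = part
    return occ


# -- SWC interchange --------------------------------------------------------

def write_swc(morph: Morphology, path: str | Path) -> None:
    """Write the morphology as SWC (id type x y z radius parent)."""
    def g(x):
        return format(float(x), ".17g")

    lines = ["# id type x y z radius parent"]
    c = morph.soma_center
    lines.append(f"1 1 {g(c[0])} {g(c[1])} {g(c[2])} {g(morph.soma_radius)} -1")
    node_of_seg = {}
    next_id = 2
    for i, s in enumerate(morph.segments):
        if s.parent < 0:
            p0 = s.p0
            lines.append(f"{next_id} 3 {g(p0[0])} {g(p0[1])} {g(p0[2])} "
                         f"{g(s.r0)} 1")
            parent_node = next_id
            next_id += 1
        else:
            parent_node = node_of_seg[s.parent]
        p1 = s.p1
        lines.append(f"{next_id} 3 {g(p1[0])} {g(p1[1])} {g(p1[2])} {g(s.r1)} "
                     f"{parent_node}")
        node_of_seg[i] = next_id
        next_id += 1
    Path(path).write_text("\n".join(lines) + "\n")


def read_swc(path: str | Path) -> Morphology:
    """Read an SWC file written by :func:`write_swc`."""
    nodes = {}
    order = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split()
        nid = int(f[0])
        nodes[nid] = dict(type=int(f[1]),
                          p=np.array([float(f[2]), float(f[3]), float(f[4])]),
                          r=float(f[5]), parent=int(f[6]))
        order.append(nid)
    soma_id = next(i for i in order if nodes[i]["type"] == 1)
    soma = nodes[soma_id]
    segs = []
    seg_of_node = {}
    for nid in order:
        nd = nodes[nid]
        if nd["type"] == 1 or nd["parent"] < 0:
            continue
        par = nodes[nd["parent"]]
        if par["type"] == 1:
            # first point of a stem: no geometry yet, remembered as the
            # attachment sample
            seg_of_node[nid] = None
            continue
        segs.append(Segment(p0=tuple(par["p"]), r0=par["r"],
                            p1=tuple(nd["p"]), r1=nd["r"],
                            parent=(seg_of_node[nd["parent"]]
                                    if seg_of_node.get(nd["parent"]) is not None
                                    else -1)))
        seg_of_node[nid] = len(segs) - 1
    return Morphology(soma_center=soma["p"], soma_radius=soma["r"],
                      segments=segs)
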