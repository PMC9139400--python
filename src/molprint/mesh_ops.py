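"""Printability: manifold diagnosis, repair, hollowing, Booleans, thin checks.

A 3D printer needs a *manifold* file — every edge shared by exactly two
triangles, normals pointing outward, an unambiguous enclosed volume. These
operations diagnose violations (open edges, inverted normals, non-manifold
fans), repair the common ones, and implement the volumetric edits a physical
model needs: hollow interiors to save material, Boolean subtraction to carve
magnet sockets, and a thickness/orientation screen for the rod-like features
that fail in anisotropic FDM prints.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.ndimage import distance_transform_edt
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import (
    EmptyResultError,
    PrintabilityError,
    RepairError,
    UnitError,
    WallThicknessWarning,
)
from .mesh import TriMesh, concatenate
from . import voxel


@dataclass
class ManifoldReport:
    """Printability diagnosis of a triangle mesh."""

    watertight: bool
    boundary_edge_count: int
    nonmanifold_edge_count: int
    euler_characteristic: int
    component_count: int
    self_intersecting: bool
    signed_volume: float


@dataclass
class PrintWarning:
    """A local feature thinner than the printer profile allows."""

    kind: str  # thin_wall | thin_rod_perpendicular | unsupported_overhang_flag
    location: np.ndarray
    measured: float
    limit: float


# ---------------------------------------------------------------------------
# validation


def _edge_counts(faces: np.ndarray):
    edges = np.sort(
        np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1
    )
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    return uniq, counts


def _vertex_components(faces: np.ndarray) -> int:
    refs = np.unique(faces)
    remap = np.zeros(refs.max() + 1, dtype=np.int64)
    remap[refs] = np.arange(len(refs))
    f = remap[faces]
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
    cols = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
    g = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(refs), len(refs))
    )
    n, _ = connected_components(g, directed=False)
    return int(n)


def validate_mesh(m: TriMesh, check_self_intersections: bool = True) -> ManifoldReport:
    """Diagnose manifoldness of a mesh.

    Boundary edges are used by exactly one face, non-manifold edges by three
    or more; the Euler characteristic is V - E + F over referenced vertices;
    the signed volume (divergence theorem) is negative when the winding
    points the normals inward. Self-intersection (triangle-triangle overlap,
    excluding triangles that share a vertex) can be skipped for large meshes.
    """
    if m.n_faces == 0:
        raise ValueError("cannot validate an empty mesh")
    _, counts = _edge_counts(m.faces)
    boundary = int((counts == 1).sum())
    nonmanifold = int((counts >= 3).sum())
    V = len(np.unique(m.faces))
    E = len(counts)
    F = m.n_faces
    return ManifoldReport(
        watertight=(boundary == 0 and nonmanifold == 0),
        boundary_edge_count=boundary,
        nonmanifold_edge_count=nonmanifold,
        euler_characteristic=V - E + F,
        component_count=_vertex_components(m.faces),
        self_intersecting=self_intersects(m) if check_self_intersections else False,
        signed_volume=m.signed_volume(),
    )


# ---------------------------------------------------------------------------
# triangle-triangle overlap (report-only diagnosis)


def _tri_intervals(proj: np.ndarray, dist: np.ndarray):
    """Interval of the intersection line covered by each triangle.

    ``proj``: (n, 3) vertex projections on the line, ``dist``: (n, 3) signed
    distances to the other triangle's plane (mixed signs guaranteed).
    """
    sign = np.where(dist > 0, 1, -1)
    odd = np.argmax(sign != np.sign(sign.sum(axis=1))[:, None], axis=1)
    idx = np.arange(len(proj))
    others = np.array([[1, 2], [0, 2], [0, 1]])[odd]
    po = proj[idx, odd]
    do = dist[idx, odd]
    t = []
    for k in (0, 1):
        oa = others[:, k]
        pa, da = proj[idx, oa], dist[idx, oa]
        t.append(po + (pa - po) * do / (do - da))
    t = np.stack(t, axis=1)
    return t.min(axis=1), t.max(axis=1)


def _tri_tri_overlap(t1: np.ndarray, t2: np.ndarray, eps: float) -> np.ndarray:
    """Moller-style transversal intersection test for triangle pairs.

    Coplanar pairs and pairs that merely touch (contact within ``eps``) are
    reported as non-intersecting.
    """
    n2 = np.cross(t2[:, 1] - t2[:, 0], t2[:, 2] - t2[:, 0])
    d1 = np.einsum("nij,nj->ni", t1 - t2[:, 0:1], n2)
    n1 = np.cross(t1[:, 1] - t1[:, 0], t1[:, 2] - t1[:, 0])
    d2 = np.einsum("nij,nj->ni", t2 - t1[:, 0:1], n1)
    scale = np.maximum(np.abs(t1).max(), np.abs(t2).max()) + 1.0
    snap = eps * scale
    d1 = np.where(np.abs(d1) < snap, snap, d1)
    d2 = np.where(np.abs(d2) < snap, snap, d2)
    mixed = (
        ((d1 > 0).any(axis=1) & (d1 < 0).any(axis=1))
        & ((d2 > 0).any(axis=1) & (d2 < 0).any(axis=1))
    )
    result = np.zeros(len(t1), dtype=bool)
    if not mixed.any():
        return result
    i = np.flatnonzero(mixed)
    line = np.cross(n1[i], n2[i])
    p1 = np.einsum("nij,nj->ni", t1[i], line)
    p2 = np.einsum("nij,nj->ni", t2[i], line)
    lo1, hi1 = _tri_intervals(p1, d1[i])
    lo2, hi2 = _tri_intervals(p2, d2[i])
    span = np.minimum(hi1, hi2) - np.maximum(lo1, lo2)
    norm = np.linalg.norm(line, axis=1) * scale
    result[i] = span > eps * norm
    return result


def self_intersects(m: TriMesh, eps: float = 1e-9) -> bool:
    """True when two non-adjacent triangles of the mesh interpenetrate."""
    tri = m.vertices[m.faces]
    centroids = tri.mean(axis=1)
    radii = np.linalg.norm(tri - centroids[:, None, :], axis=2).max(axis=1)
    tree = cKDTree(centroids)
    pairs = tree.query_pairs(2.0 * float(radii.max()), output_type="ndarray")
    if len(pairs) == 0:
        return False
    keep = (
        np.linalg.norm(centroids[pairs[:, 0]] - centroids[pairs[:, 1]], axis=1)
        < radii[pairs[:, 0]] + radii[pairs[:, 1]]
    )
    pairs = pairs[keep]
    # exclude adjacent faces (any shared vertex)
    fa, fb = m.faces[pairs[:, 0]], m.faces[pairs[:, 1]]
    shared = (fa[:, :, None] == fb[:, None, :]).any(axis=(1, 2))
    pairs = pairs[~shared]
    if len(pairs) == 0:
        return False
    hits = _tri_tri_overlap(tri[pairs[:, 0]], tri[pairs[:, 1]], eps)
    return bool(hits.any())


# ---------------------------------------------------------------------------
# repair


def _boundary_cycles(faces: np.ndarray) -> list[list[int]]:
    """Directed boundary-edge cycles (vertex index loops around holes)."""
    directed = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    und = np.sort(directed, axis=1)
    uniq, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    boundary_mask = counts[inv] == 1
    bdir = directed[boundary_mask]
    nxt = {int(u): int(v) for u, v in bdir}
    cycles = []
    while nxt:
        start, v = next(iter(nxt.items()))
        cycle = [start]
        nxt_v = nxt.pop(start)
        while nxt_v != start and nxt_v in nxt:
            cycle.append(nxt_v)
            nxt_v = nxt.pop(nxt_v)
        if nxt_v == start:
            cycles.append(cycle)
        # open walks (non-manifold boundary) are dropped; repair will re-report
    return cycles


def _consistent_winding(faces: np.ndarray) -> np.ndarray:
    """Flip faces so adjacent faces traverse shared edges in opposite order."""
    faces = faces.copy()
    edge_key = {}
    adjacency: dict[int, list[int]] = {i: [] for i in range(len(faces))}
    for fi, f in enumerate(faces):
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            k = (min(a, b), max(a, b))
            if k in edge_key:
                for fj in edge_key[k]:
                    adjacency[fi].append(fj)
                    adjacency[fj].append(fi)
                edge_key[k].append(fi)
            else:
                edge_key[k] = [fi]

    def directed_edges(f):
        return {(f[0], f[1]), (f[1], f[2]), (f[2], f[0])}

    visited = np.zeros(len(faces), dtype=bool)
    for seed in range(len(faces)):
        if visited[seed]:
            continue
        stack = [seed]
        visited[seed] = True
        while stack:
            fi = stack.pop()
            de_i = directed_edges(faces[fi])
            for fj in adjacency[fi]:
                if visited[fj]:
                    continue
                # consistent orientation: shared edge appears in opposite order
                if de_i & directed_edges(faces[fj]):
                    faces[fj] = faces[fj][::-1]
                visited[fj] = True
                stack.append(fj)
    return faces


def _face_components(faces: np.ndarray) -> np.ndarray:
    """Component label per face (faces connected via shared vertices)."""
    refs = np.unique(faces)
    remap = np.zeros(refs.max() + 1, dtype=np.int64)
    remap[refs] = np.arange(len(refs))
    f = remap[faces]
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
    cols = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
    g = sparse.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(len(refs), len(refs)))
    _, labels = connected_components(g, directed=False)
    return labels[f[:, 0]]


def repair_mesh(
    m: TriMesh,
    policy: str = "keep-all",
    merge_tolerance: float | None = None,
    hole_edge_cap: int = 100,
) -> TriMesh:
    """Repair toward a printable mesh.

    Steps: merge duplicate vertices (tolerance ``1e-6 x bbox diagonal`` by
    default), drop degenerate faces, close boundary-edge cycles (fans; holes
    larger than ``hole_edge_cap`` edges raise :class:`RepairError`), make the
    winding consistent and outward per component. ``policy='keep-largest'``
    keeps only the largest-|volume| connected component.

    Repairing an already-repaired mesh is a no-op.
    """
    if policy not in ("keep-all", "keep-largest"):
        raise ValueError(f"unknown policy {policy!r}")
    if m.n_faces == 0:
        raise ValueError("cannot repair an empty mesh")
    diag = float(np.linalg.norm(m.extents)) or 1.0
    tol = merge_tolerance if merge_tolerance is not None else 1e-6 * diag
    keys = np.round(m.vertices / tol).astype(np.int64)
    _, first_idx, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    verts = m.vertices[first_idx]
    colors = None if m.vertex_colors is None else m.vertex_colors[first_idx]
    order = np.argsort(first_idx)  # keep original vertex order
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    verts = verts[order]
    if colors is not None:
        colors = colors[order]
    faces = rank[inverse][m.faces]
    # degenerate faces: repeated indices or (near-)zero area
    distinct = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    faces = faces[distinct]
    area2 = np.linalg.norm(
        np.cross(verts[faces[:, 1]] - verts[faces[:, 0]],
                 verts[faces[:, 2]] - verts[faces[:, 0]]), axis=1,
    )
    faces = faces[area2 > (tol * tol)]
    if len(faces) == 0:
        raise RepairError("all faces degenerate after merging")
    # close holes
    cycles = _boundary_cycles(faces)
    big = [c for c in cycles if len(c) > hole_edge_cap]
    if big:
        residual = validate_mesh(TriMesh(verts, faces, m.unit),
                                 check_self_intersections=False)
        raise RepairError(
            f"hole with {max(len(c) for c in big)} boundary edges exceeds the "
            f"fill cap of {hole_edge_cap}", report=residual,
        )
    new_faces = []
    for cycle in cycles:
        if len(cycle) == 3:
            new_faces.append(cycle[::-1])
        else:
            centroid = verts[cycle].mean(axis=0)
            ci = len(verts)
            verts = np.vstack([verts, centroid])
            if colors is not None:
                colors = np.vstack([colors, colors[cycle].mean(axis=0)])
            for k in range(len(cycle)):
                new_faces.append([ci, cycle[(k + 1) % len(cycle)], cycle[k]])
    if new_faces:
        faces = np.vstack([faces, np.asarray(new_faces, dtype=np.int64)])
    # consistent, outward winding per component
    faces = _consistent_winding(faces)
    labels = _face_components(faces)
    for lab in np.unique(labels):
        sub = faces[labels == lab]
        vol = TriMesh(verts, sub, m.unit).signed_volume()
        if vol < 0:
            faces[labels == lab] = sub[:, ::-1]
    if policy == "keep-largest" and len(np.unique(labels)) > 1:
        vols = [
            abs(TriMesh(verts, faces[labels == lab], m.unit).signed_volume())
            for lab in np.unique(labels)
        ]
        best = np.unique(labels)[int(np.argmax(vols))]
        faces = faces[labels == best]
        refs = np.unique(faces)
        remap = np.zeros(refs.max() + 1, dtype=np.int64)
        remap[refs] = np.arange(len(refs))
        verts = verts[refs]
        colors = None if colors is None else colors[refs]
        faces = remap[faces]
    out = TriMesh(verts, faces, m.unit, colors)
    residual = validate_mesh(out, check_self_intersections=False)
    if residual.boundary_edge_count:
        raise RepairError(
            f"{residual.boundary_edge_count} boundary edges remain after repair",
            report=residual,
        )
    return out


# ---------------------------------------------------------------------------
# hollowing


def hollow_mesh(m: TriMesh, wall: float, pitch: float | None = None) -> TriMesh:
    """Replace the solid interior with a ``wall``-thick shell.

    A voxel distance field of the interior yields the inward-offset cavity
    surface, which is appended with reversed orientation (2 nested
    components). When the wall meets or exceeds the local inradius
    everywhere the solid is returned unchanged with a
    :class:`WallThicknessWarning`.
    """
    if wall <= 0:
        raise ValueError("wall thickness must be positive")
    report = validate_mesh(m, check_self_intersections=False)
    if not report.watertight:
        raise PrintabilityError("hollow_mesh requires a watertight mesh")
    if pitch is None:
        pitch = min(voxel.default_pitch(m), wall / 3.0)
    grid = voxel.make_grid(m.bounds, pitch)
    occ = voxel.mesh_fraction(m, grid) > 0.5
    depth = (distance_transform_edt(occ) - 0.5) * pitch
    if depth.max() <= wall:
        warnings.warn(
            f"wall {wall:g} meets or exceeds the interior inradius "
            f"({depth.max():g}); returning the solid unchanged",
            WallThicknessWarning, stacklevel=2,
        )
        return m
    cavity = voxel.field_to_mesh(depth, grid, m.unit, level=wall)
    return concatenate([TriMesh(m.vertices, m.faces, m.unit), cavity.flipped()])


# ---------------------------------------------------------------------------
# booleans


def _check_operands(a: TriMesh, b: TriMesh):
    if a.unit != b.unit:
        raise UnitError(f"operand units differ: {a.unit} vs {b.unit}")
    for name, mesh in (("a", a), ("b", b)):
        rep = validate_mesh(mesh, check_self_intersections=False)
        if not rep.watertight:
            raise PrintabilityError(
                f"boolean operand {name} is not watertight "
                f"({rep.boundary_edge_count} boundary edges)"
            )


def boolean_subtract(a: TriMesh, b: TriMesh, pitch: float | None = None) -> TriMesh:
    """Volumetric ``a - b``: voxelize both, combine, re-contour.

    Robust on marching-cubes meshes where exact polyhedral CSG produces
    sliver failures; accuracy is set by ``pitch`` (default 1/200 of a's
    bounding-box diagonal) and converges as the pitch is refined.
    """
    _check_operands(a, b)
    if pitch is None:
        pitch = voxel.default_pitch(a)
    grid = voxel.make_grid(a.bounds, pitch)
    fa = voxel.mesh_fraction(a, grid)
    fb = voxel.mesh_fraction(b, grid)
    field = np.minimum(fa, 1.0 - fb)
    if field.max() <= 0.5:
        raise EmptyResultError("subtraction annihilated the first operand")
    return voxel.field_to_mesh(field, grid, a.unit)


def boolean_intersect(a: TriMesh, b: TriMesh, pitch: float | None = None) -> TriMesh:
    """Volumetric ``a ∩ b`` on the same voxel engine as subtraction."""
    _check_operands(a, b)
    if pitch is None:
        pitch = voxel.default_pitch(a)
    grid = voxel.make_grid(a.bounds, pitch)
    field = np.minimum(voxel.mesh_fraction(a, grid), voxel.mesh_fraction(b, grid))
    if field.max() <= 0.5:
        raise EmptyResultError("operands do not intersect")
    return voxel.field_to_mesh(field, grid, a.unit)


# ---------------------------------------------------------------------------
# thin features


def ray_first_hit(m: TriMesh, origins: np.ndarray, directions: np.ndarray,
                  t_min: float = 0.0, chunk: int = 64) -> np.ndarray:
    """Distance along each ray to its first triangle hit (inf if none).

    Vectorized Moller-Trumbore over all faces, chunked over rays to bound
    memory; directions must be unit length.
    """
    tri = m.vertices[m.faces]
    v0 = tri[:, 0]
    e1 = tri[:, 1] - v0
    e2 = tri[:, 2] - v0
    origins = np.atleast_2d(origins)
    directions = np.atleast_2d(directions)
    out = np.full(len(origins), np.inf)
    for lo in range(0, len(origins), chunk):
        o = origins[lo:lo + chunk][:, None, :]
        d = directions[lo:lo + chunk][:, None, :]
        h = np.cross(d, e2[None])
        a = np.einsum("mfj,fj->mf", h, e1)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = 1.0 / a
            s = o - v0[None]
            u = f * np.einsum("mfj,mfj->mf", s, h)
            q = np.cross(s, e1[None])
            v = f * np.einsum("mfj,mfj->mf", q, d)
            t = f * np.einsum("mfj,fj->mf", q, e2)
            hit = (np.abs(a) > 1e-14) & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > t_min)
        t = np.where(hit, t, np.inf)
        out[lo:lo + chunk] = t.min(axis=1)
    return out


def _local_thickness(m: TriMesh, sample_faces: np.ndarray) -> np.ndarray:
    """Inward ray-cast thickness at the given face centroids."""
    tri = m.vertices[m.faces[sample_faces]]
    centroids = tri.mean(axis=1)
    normals = m.face_normals()[sample_faces]
    diag = float(np.linalg.norm(m.extents))
    eps = 1e-6 * diag
    return ray_first_hit(m, centroids - eps * normals, -normals, t_min=2 * eps)


def thin_feature_check(m: TriMesh, profile, build_axis=(0.0, 0.0, 1.0),
                       max_samples: int = 256) -> list[PrintWarning]:
    """Screen for features too thin for the printer profile.

    Local thickness is sampled by inward ray casting at (up to
    ``max_samples``) face centroids. Samples thinner than ``min_wall`` emit
    ``thin_wall`` warnings. A connected component that is predominantly
    thinner than ``min_rod_diameter``, elongated, and whose long axis lies
    within 45 degrees of perpendicular to ``build_axis`` emits one
    ``thin_rod_perpendicular`` warning — FDM rods printed across the layer
    direction are far weaker than those printed along it.
    """
    if m.n_faces == 0:
        raise ValueError("cannot check an empty mesh")
    axis = np.asarray(build_axis, dtype=float)
    axis /= np.linalg.norm(axis)
    sample = np.unique(np.linspace(0, m.n_faces - 1, min(m.n_faces, max_samples)).astype(int))
    thickness = _local_thickness(m, sample)
    centroids = m.vertices[m.faces[sample]].mean(axis=1)
    out: list[PrintWarning] = []
    for k in np.flatnonzero(thickness < profile.min_wall):
        out.append(PrintWarning("thin_wall", centroids[k], float(thickness[k]),
                                float(profile.min_wall)))
    labels = _face_components(m.faces)[sample]
    for lab in np.unique(labels):
        mask = labels == lab
        thin = thickness[mask] < profile.min_rod_diameter
        if thin.mean() < 0.5:
            continue
        pts = centroids[mask]
        centred = pts - pts.mean(axis=0)
        _, svals, vt = np.linalg.svd(centred, full_matrices=False)
        if svals[0] < 2.0 * max(svals[1], 1e-12):
            continue  # not elongated
        long_axis = vt[0]
        cosang = abs(float(np.dot(long_axis, axis)))
        if cosang < math.cos(math.radians(45.0)):
            measured = float(np.median(thickness[mask][thin]))
            out.append(PrintWarning("thin_rod_perpendicular", pts.mean(axis=0),
                                    measured, float(profile.min_rod_diameter)))
    return out
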