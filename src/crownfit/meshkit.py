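"""Triangle-mesh data model, STL/PLY I/O and exact surface distance queries.

All geometry is carried in millimetres internally; fit metrics are converted
to micrometres only at reporting time.  Meshes are cleaned on load (duplicate
vertices merged, degenerate faces dropped) so that downstream operations can
assume the :class:`TriangleMesh` invariants.

The closest point-on-surface query is exact: an accelerated path (k-d trees
with a bounding-sphere pruning bound) returns the same face and distance as a
brute-force scan over all triangles, with ties broken by the lowest face
index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import networkx as nx
import trimesh
from scipy.spatial import cKDTree

from .errors import ContentError, FormatError, MeshIOError, ValidationError

logger = logging.getLogger(__name__)

#: vertices closer than this (mm) are merged on load
MERGE_TOLERANCE = 1e-6
#: faces with area (mm^2) at or below this are dropped on load
DEGENERATE_AREA = 1e-12


@dataclass
class TriangleMesh:
    """Indexed triangle surface with a units label (default millimetres)."""

    vertices: np.ndarray  # (n, 3) float64, mm
    faces: np.ndarray  # (m, 3) int64
    units: str = "mm"

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValidationError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValidationError("faces must be an (m, 3) array")

    # -- basic derived quantities -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """Per-face vertex coordinates, shape (m, 3, 3)."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        tri = self.triangles()
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def face_normals(self) -> np.ndarray:
        """Unit normals following the winding order."""
        tri = self.triangles()
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(cross, axis=1)
        return cross / np.maximum(norm, 1e-300)[:, None]

    def validate(self) -> None:
        """Raise unless the mesh satisfies the shared invariants."""
        if self.n_vertices < 3 or self.n_faces < 1:
            raise ContentError(
                f"mesh too small: {self.n_vertices} vertices, {self.n_faces} faces"
            )
        if self.faces.min() < 0 or self.faces.max() >= self.n_vertices:
            raise ValidationError("face index out of range")
        if (
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        ).any():
            raise ValidationError("face repeats a vertex")
        if (self.face_areas() <= DEGENERATE_AREA).any():
            raise ValidationError("degenerate face (area below tolerance)")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), self.units)


@dataclass
class SurfacePoint:
    """A point constrained to a mesh triangle via barycentric coordinates."""

    position: np.ndarray  # (3,) mm
    face_index: int
    barycentric: np.ndarray  # (3,) nonnegative, sums to 1

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=np.float64)
        self.barycentric = np.asarray(self.barycentric, dtype=np.float64)

    def check(self, mesh: TriangleMesh, tol: float = 1e-9) -> None:
        tri = mesh.vertices[mesh.faces[self.face_index]]
        recon = self.barycentric @ tri
        if np.linalg.norm(recon - self.position) > tol:
            raise ValidationError("SurfacePoint position inconsistent with barycentric")


# ----------------------------------------------------------------------------------
# cleaning and I/O
# ----------------------------------------------------------------------------------

def clean_mesh(
    vertices: np.ndarray,
    faces: np.ndarray,
    merge_tol: float = MERGE_TOLERANCE,
    units: str = "mm",
) -> TriangleMesh:
    """Merge near-duplicate vertices and drop degenerate faces.

    Vertices are snapped to a grid of pitch ``merge_tol`` for the duplicate
    test; original coordinates of the first occurrence are kept.
    """
    vertices = np.asarray(vertices, dtype=np.float64).reshape(-1, 3)
    faces = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
    keys = np.round(vertices / merge_tol).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_vertices = vertices[np.sort(first)]
    new_faces = rank[inverse][faces]

    repeats = (
        (new_faces[:, 0] == new_faces[:, 1])
        | (new_faces[:, 1] == new_faces[:, 2])
        | (new_faces[:, 0] == new_faces[:, 2])
    )
    mesh = TriangleMesh(new_vertices, new_faces[~repeats], units)
    areas = mesh.face_areas()
    mesh = TriangleMesh(mesh.vertices, mesh.faces[areas > DEGENERATE_AREA], units)
    return mesh


def read_mesh(path, fmt: str = "auto", units: str = "mm") -> TriangleMesh:
    """Read an STL (binary or ASCII) or PLY mesh and clean it.

    STL files carry no units; the ``units`` label defaults to millimetres and
    is recorded loudly in the log.
    """
    file_type = None if fmt == "auto" else fmt
    try:
        raw = trimesh.load(str(path), file_type=file_type, process=False, force="mesh")
    except FileNotFoundError:
        raise MeshIOError(f"mesh file not found: {path}")
    except Exception as exc:  # trimesh raises a zoo of parse errors
        raise FormatError(f"cannot parse {path!s} as {fmt}: {exc}")
    if not isinstance(raw, trimesh.Trimesh) or len(raw.faces) == 0:
        raise ContentError(f"no triangle data in {path!s}")
    mesh = clean_mesh(raw.vertices, raw.faces, units=units)
    if mesh.n_faces == 0:
        raise ContentError(f"mesh {path!s} empty after cleaning")
    logger.info(
        "read %s: %d vertices, %d faces (units assumed %s)",
        path, mesh.n_vertices, mesh.n_faces, units,
    )
    return mesh


def scalars_to_rgb(values, vmin=None, vmax=None) -> np.ndarray:
    """Map scalars to 8-bit RGB with a linear blue-white-red diverging ramp.

    Values at ``vmin`` map to pure blue, the midpoint to white and ``vmax`` to
    pure red; the red-minus-blue channel difference is monotone in the value,
    which makes gradients readable and testable.
    """
    values = np.asarray(values, dtype=np.float64)
    lo = float(np.min(values)) if vmin is None else float(vmin)
    hi = float(np.max(values)) if vmax is None else float(vmax)
    span = hi - lo if hi > lo else 1.0
    t = np.clip((values - lo) / span, 0.0, 1.0)
    rgb = np.empty(values.shape + (3,))
    below = t <= 0.5
    s = np.where(below, 2.0 * t, 2.0 * (t - 0.5))
    rgb[..., 0] = np.where(below, s, 1.0)          # red ramps up then saturates
    rgb[..., 1] = np.where(below, s, 1.0 - s)      # green peaks at the midpoint
    rgb[..., 2] = np.where(below, 1.0, 1.0 - s)    # blue saturated then ramps down
    return np.round(rgb * 255).astype(np.uint8)


def write_mesh(mesh: TriangleMesh, path, fmt: str = "stl", vertex_scalars=None,
               ascii_stl: bool = False, vmin=None, vmax=None) -> None:
    """Write STL (no scalars) or PLY (optional per-vertex scalar colouring)."""
    mesh.validate()
    tm = mesh.to_trimesh()
    if fmt == "stl":
        if vertex_scalars is not None:
            raise ValidationError("STL cannot carry per-vertex scalars; use PLY")
        file_type = "stl_ascii" if ascii_stl else "stl"
        data = tm.export(file_type=file_type)
    elif fmt == "ply":
        if vertex_scalars is not None:
            vertex_scalars = np.asarray(vertex_scalars, dtype=np.float64)
            if len(vertex_scalars) != mesh.n_vertices:
                raise ValidationError("vertex_scalars length must equal vertex count")
            rgb = scalars_to_rgb(vertex_scalars, vmin=vmin, vmax=vmax)
            tm.visual.vertex_colors = np.column_stack(
                [rgb, np.full(len(rgb), 255, dtype=np.uint8)]
            )
        data = tm.export(file_type="ply", encoding="ascii")
    else:
        raise ValidationError(f"unsupported mesh format: {fmt}")
    mode = "wb" if isinstance(data, bytes) else "w"
    try:
        with open(path, mode) as fh:
            fh.write(data)
    except OSError as exc:
        raise MeshIOError(f"cannot write {path!s}: {exc}")


# ----------------------------------------------------------------------------------
# exact point-to-triangle distances
# ----------------------------------------------------------------------------------

def _closest_on_triangles(points: np.ndarray, tri: np.ndarray):
    """Exact closest point on each (point, triangle) pair.

    points: (k, 3); tri: (k, 3, 3).  Returns (dist, closest, bary), each of
    length k.  Robust to slim triangles: the in-plane projection is used only
    when its barycentric coordinates are all nonnegative, otherwise the best
    of the three clamped edge projections wins.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, points - a
    d00 = np.einsum("ij,ij->i", ab, ab)
    d01 = np.einsum("ij,ij->i", ab, ac)
    d11 = np.einsum("ij,ij->i", ac, ac)
    d20 = np.einsum("ij,ij->i", ap, ab)
    d21 = np.einsum("ij,ij->i", ap, ac)
    denom = d00 * d11 - d01 * d01
    safe = np.abs(denom) > 1e-300
    inv = np.where(safe, denom, 1.0)
    v = np.where(safe, (d11 * d20 - d01 * d21) / inv, -1.0)
    w = np.where(safe, (d00 * d21 - d01 * d20) / inv, -1.0)
    u = 1.0 - v - w
    inside = (v >= 0) & (w >= 0) & (u >= 0)

    proj = a + v[:, None] * ab + w[:, None] * ac
    best = np.where(inside[:, None], proj, np.inf)
    best_d2 = np.where(inside, np.einsum("ij,ij->i", points - proj, points - proj), np.inf)
    bary = np.column_stack([u, v, w])
    bary[~inside] = 0.0

    edges = ((a, b, (0, 1)), (b, c, (1, 2)), (c, a, (2, 0)))
    for s, e, (i0, i1) in edges:
        d = e - s
        l2 = np.einsum("ij,ij->i", d, d)
        t = np.einsum("ij,ij->i", points - s, d) / np.maximum(l2, 1e-300)
        t = np.clip(t, 0.0, 1.0)
        q = s + t[:, None] * d
        d2 = np.einsum("ij,ij->i", points - q, points - q)
        better = d2 < best_d2
        best_d2 = np.where(better, d2, best_d2)
        best = np.where(better[:, None], q, best)
        eb = np.zeros_like(bary)
        eb[:, i0] = 1.0 - t
        eb[:, i1] = t
        bary = np.where(better[:, None], eb, bary)

    return np.sqrt(best_d2), best, bary


def points_to_surface_bruteforce(points: np.ndarray, mesh: TriangleMesh,
                                 block: int = 256):
    """Reference implementation: scan all faces for every query point.

    Returns (distances, closest_points, face_indices, barycentric).  Ties are
    broken by the lowest face index.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    tri = mesh.triangles()
    m = len(tri)
    dist = np.empty(len(points))
    closest = np.empty((len(points), 3))
    fidx = np.empty(len(points), dtype=np.int64)
    bary = np.empty((len(points), 3))
    for start in range(0, len(points), block):
        chunk = points[start:start + block]
        k = len(chunk)
        pp = np.repeat(chunk, m, axis=0)
        tt = np.tile(tri, (k, 1, 1))
        d, cp, bb = _closest_on_triangles(pp, tt)
        d = d.reshape(k, m)
        best = np.argmin(d, axis=1)  # first (lowest-index) minimum
        rows = np.arange(k)
        dist[start:start + k] = d[rows, best]
        closest[start:start + k] = cp.reshape(k, m, 3)[rows, best]
        bary[start:start + k] = bb.reshape(k, m, 3)[rows, best]
        fidx[start:start + k] = best
    return dist, closest, fidx, bary


class SurfaceDistanceQuery:
    """Accelerated exact closest-point-on-surface queries.

    Candidate faces are pruned with the bound ``|p - centroid_f| - r_f`` where
    ``r_f`` is the face bounding-sphere radius: any face that could beat the
    nearest-vertex upper bound lies within ``d_vertex + max_f r_f`` of the
    query point, so the exact minimum is always among the candidates and the
    result equals a brute-force scan (ties to the lowest face index).
    """

    def __init__(self, mesh: TriangleMesh):
        mesh.validate()
        self.mesh = mesh
        self._tri = mesh.triangles()
        self._centroids = self._tri.mean(axis=1)
        self._radii = np.linalg.norm(
            self._tri - self._centroids[:, None, :], axis=2
        ).max(axis=1)
        # oversized faces would inflate the pruning radius for everyone, so
        # they are kept aside and checked exactly against every query point
        r_cut = max(3.0 * float(np.median(self._radii)), 1e-12)
        self._big = np.flatnonzero(self._radii > r_cut)
        self._small = np.flatnonzero(self._radii <= r_cut)
        self._rmax_small = float(self._radii[self._small].max()) if len(self._small) else 0.0
        self._vertex_tree = cKDTree(mesh.vertices)
        self._centroid_tree = cKDTree(self._centroids[self._small])

    def query(self, points: np.ndarray):
        """Return (distances, closest_points, face_indices, barycentric)."""
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        d_up, _ = self._vertex_tree.query(points)
        lists = self._centroid_tree.query_ball_point(
            points, d_up + self._rmax_small + 1e-12
        )
        counts = np.fromiter((len(l) for l in lists), dtype=np.int64, count=len(lists))
        pi = np.repeat(np.arange(len(points)), counts)
        fi = self._small[np.concatenate(
            [np.asarray(l, dtype=np.int64) for l in lists]
        )] if counts.sum() else np.empty(0, dtype=np.int64)
        if len(self._big):
            nb = len(self._big)
            pi_b = np.repeat(np.arange(len(points)), nb)
            fi_b = np.tile(self._big, len(points))
            pi = np.concatenate([pi, pi_b])
            fi = np.concatenate([fi, fi_b])
        d, cp, bb = _closest_on_triangles(points[pi], self._tri[fi])
        # segment argmin per query point; ties resolved to the lowest face index
        order = np.lexsort((fi, d, pi))
        pi_s = pi[order]
        firsts = np.flatnonzero(np.diff(pi_s, prepend=-1))
        sel = order[firsts]
        return d[sel], cp[sel], fi[sel], bb[sel]


def point_to_surface_distance(point, mesh: TriangleMesh):
    """Shortest Euclidean distance from a point to a mesh surface.

    Returns ``(distance_mm, SurfacePoint)`` where the surface point realizes
    the minimum.  For repeated queries against one mesh build a
    :class:`SurfaceDistanceQuery` instead.
    """
    q = SurfaceDistanceQuery(mesh)
    d, cp, fi, bb = q.query(np.asarray(point, dtype=np.float64))
    return float(d[0]), SurfacePoint(cp[0], int(fi[0]), bb[0])


def vertex_adjacency_graph(mesh: TriangleMesh) -> nx.Graph:
    """Undirected graph over vertex indices, edge weight = Euclidean length."""
    mesh.validate()
    g = nx.Graph()
    g.add_nodes_from(range(mesh.n_vertices))
    f = mesh.faces
    pairs = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    pairs = np.sort(pairs, axis=1)
    pairs = np.unique(pairs, axis=0)
    lengths = np.linalg.norm(
        mesh.vertices[pairs[:, 0]] - mesh.vertices[pairs[:, 1]], axis=1
    )
    g.add_weighted_edges_from(
        (int(i), int(j), float(w)) for (i, j), w in zip(pairs, lengths)
    )
    return g
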