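"""Margin landmarks, closed margin curves and the marginal ROI band.

The finish line ("marginal line") is the boundary curve where a restoration
meets the prepared tooth.  It is annotated in practice as a set of landmark
points (50 by convention); this module reconstructs an ordered closed curve
from such a set, resamples it at uniform arc length, and extracts the band of
mesh surface within a given height of the curve — the region used for
reference best-fit alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContentError, GeometryError, OrderingError, ValidationError
from .meshkit import SurfaceDistanceQuery, TriangleMesh

#: default number of annotated margin landmarks
DEFAULT_N_LANDMARKS = 50
#: ratio of ring-radius SD to mean above which ordering is refused
RING_TEST_LIMIT = 0.9


@dataclass
class LandmarkSet:
    """Unordered margin landmark points as annotated on a scan."""

    points: np.ndarray  # (n, 3) mm
    label: str = ""
    source: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if len(self.points) < 4:
            raise ValidationError("need at least 4 landmarks")
        d = np.linalg.norm(
            self.points[:, None, :] - self.points[None, :, :], axis=2
        )
        np.fill_diagonal(d, np.inf)
        if d.min() < 1e-6:
            raise ValidationError("coincident landmarks (closer than 1e-6 mm)")


@dataclass
class MarginCurve:
    """Ordered closed 3D polyline representing a finish line."""

    points: np.ndarray  # (n, 3) mm, implicit closing segment last->first
    closed: bool = True

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if len(self.points) < 3:
            raise ValidationError("a closed curve needs at least 3 points")
        seg = np.diff(self.points, axis=0, append=self.points[:1])
        if (np.linalg.norm(seg, axis=1) < 1e-12).any():
            raise ValidationError("consecutive curve points coincide")

    @property
    def arc_length(self) -> float:
        seg = np.diff(self.points, axis=0, append=self.points[:1])
        return float(np.linalg.norm(seg, axis=1).sum())

    def segments(self):
        """(starts, ends) arrays of the n closing-inclusive segments."""
        starts = self.points
        ends = np.roll(self.points, -1, axis=0)
        return starts, ends

    def copy(self) -> "MarginCurve":
        return MarginCurve(self.points.copy())


def read_landmarks(path, label: str = "") -> LandmarkSet:
    """Read a plain-text landmark file: one ``x y z`` triple per line.

    Lines starting with '#' are comments; blank lines are ignored.
    """
    pts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.split()
            if len(parts) != 3:
                raise ContentError(f"{path}:{lineno}: expected 'x y z', got {text!r}")
            try:
                pts.append([float(p) for p in parts])
            except ValueError:
                raise ContentError(f"{path}:{lineno}: non-numeric coordinate")
    if not pts:
        raise ContentError(f"{path}: no landmark points")
    return LandmarkSet(np.asarray(pts), label=label, source=str(path))


def write_landmarks(points: np.ndarray, path, header: str = "") -> None:
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for x, y, z in points:
            fh.write(f"{x:.9f} {y:.9f} {z:.9f}\n")


def _principal_frame(points: np.ndarray):
    """Deterministic right-handed principal-axes frame of a point cloud.

    Axis signs are fixed by making the largest-magnitude component of each of
    the first two axes positive, so the frame does not depend on input order.
    """
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    axes = vt.copy()
    for i in range(2):
        j = np.argmax(np.abs(axes[i]))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    axes[2] = np.cross(axes[0], axes[1])
    return centroid, axes, s


def order_landmarks(landmarks: LandmarkSet) -> MarginCurve:
    """Order ring-like landmarks into a closed margin curve.

    Points are projected onto their best-fit plane and sorted by polar angle
    about the projected centroid.  Non-ring geometry (collinear points, or
    ring-radius spread above 90% of the mean radius) and angular collisions
    are refused with an :class:`OrderingError` advising manual ordering.
    """
    pts = landmarks.points
    centroid, axes, s = _principal_frame(pts)
    if s[1] <= 1e-9 * max(s[0], 1e-300):
        raise OrderingError(
            "landmarks are collinear; provide a manually ordered curve"
        )
    uv = (pts - centroid) @ axes[:2].T
    radii = np.linalg.norm(uv, axis=1)
    mean_r = radii.mean()
    if mean_r <= 0 or radii.std() / mean_r > RING_TEST_LIMIT:
        raise OrderingError(
            "landmarks do not form a ring (radius spread too large); "
            "provide a manually ordered curve"
        )
    angles = np.arctan2(uv[:, 1], uv[:, 0])
    order = np.argsort(angles, kind="stable")
    sorted_angles = angles[order]
    gaps = np.diff(sorted_angles, append=sorted_angles[:1] + 2 * np.pi)
    if (gaps < 1e-6).any():
        raise OrderingError(
            "two landmarks collide in angular position; "
            "provide a manually ordered curve"
        )
    return MarginCurve(pts[order])


def resample_curve(curve: MarginCurve, n: int) -> MarginCurve:
    """Resample a closed curve at ``n`` equal arc-length positions.

    The first output point coincides with the curve's first point; total arc
    length is preserved to floating-point accuracy for matching chords.
    """
    if n < 4:
        raise ValidationError("resampling needs n >= 4")
    pts = curve.points
    seg = np.diff(pts, axis=0, append=pts[:1])
    lengths = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    total = cum[-1]
    targets = np.arange(n) * (total / n)
    idx = np.searchsorted(cum, targets, side="right") - 1
    idx = np.clip(idx, 0, len(pts) - 1)
    t = (targets - cum[idx]) / np.maximum(lengths[idx], 1e-300)
    nxt = (idx + 1) % len(pts)
    out = pts[idx] + t[:, None] * (pts[nxt] - pts[idx])
    return MarginCurve(out)


def points_to_polyline_distance(points: np.ndarray, curve: MarginCurve,
                                block: int = 1024):
    """Shortest distance from each point to a closed polyline.

    Distances are exact point-to-segment (not point-to-vertex).  Returns
    (distances, closest_points) in mm.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    starts, ends = curve.segments()
    d = ends - starts
    l2 = np.einsum("ij,ij->i", d, d)
    dist = np.empty(len(points))
    closest = np.empty((len(points), 3))
    for s0 in range(0, len(points), block):
        chunk = points[s0:s0 + block]  # (k, 3)
        # t[k, m] clamps the projection of each point onto each segment
        ps = chunk[:, None, :] - starts[None, :, :]
        t = np.clip(np.einsum("kmj,mj->km", ps, d) / np.maximum(l2, 1e-300), 0, 1)
        q = starts[None, :, :] + t[..., None] * d[None, :, :]
        diff = chunk[:, None, :] - q
        d2 = np.einsum("kmj,kmj->km", diff, diff)
        best = np.argmin(d2, axis=1)
        rows = np.arange(len(chunk))
        dist[s0:s0 + len(chunk)] = np.sqrt(d2[rows, best])
        closest[s0:s0 + len(chunk)] = q[rows, best]
    return dist, closest


def extract_margin_roi(mesh: TriangleMesh, curve: MarginCurve,
                       band_height: float = 0.5) -> TriangleMesh:
    """Extract the submesh within ``band_height`` mm of the margin curve.

    A face is kept when every one of its vertices lies within the band
    (3D point-to-polyline distance).  Original vertex coordinates are
    preserved; vertices are reindexed.
    """
    mesh.validate()
    if band_height < 0:
        raise ValidationError("band_height must be nonnegative")
    on_surface, _, _, _ = SurfaceDistanceQuery(mesh).query(curve.points)
    if on_surface.max() > 0.1:
        raise GeometryError(
            f"margin curve lies {on_surface.max():.3f} mm from the mesh "
            "(limit 0.1 mm); check alignment"
        )
    vdist, _ = points_to_polyline_distance(mesh.vertices, curve)
    in_band = vdist <= band_height + 1e-9
    # faces with a vertex on the curve itself always count as touching it,
    # so a zero-height band still yields the ring of faces along the margin
    touching = vdist <= 1e-9
    keep = in_band[mesh.faces].all(axis=1) | touching[mesh.faces].any(axis=1)
    if not keep.any():
        raise ContentError("empty margin ROI: no face fully inside the band")
    faces = mesh.faces[keep]
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriangleMesh(mesh.vertices[used], remap[faces], mesh.units)


def margin_plane(curve: MarginCurve, toward: np.ndarray):
    """Best-fit plane of a margin curve.

    Returns ``(origin, unit_normal)`` with the normal oriented so that the
    ``toward`` point (typically the mesh centroid) has positive height.
    """
    origin, axes, _ = _principal_frame(curve.points)
    normal = axes[2] / np.linalg.norm(axes[2])
    if np.dot(np.asarray(toward, dtype=np.float64) - origin, normal) < 0:
        normal = -normal
    return origin, normal


def extract_above_margin(mesh: TriangleMesh, curve: MarginCurve,
                         min_height: float, max_height: float | None = None,
                         criterion: str = "all"):
    """Submesh of faces lying at least ``min_height`` above the margin plane.

    Height is the signed distance from the best-fit plane of the margin
    curve, oriented toward the mesh interior.  Used to restrict internal-fit
    sampling to the region above the margin seal zone; an optional
    ``max_height`` selects a band (e.g. the seal zone itself, for alignment).
    ``criterion`` is "all" (every face vertex inside — conservative, for
    measurement ROIs) or "any" (at least one vertex inside — inclusive, so a
    narrow band never comes up empty on a coarse mesh).  Returns
    ``(submesh, kept_face_indices)`` so per-face metadata can be carried over.
    """
    mesh.validate()
    if criterion not in ("all", "any"):
        raise ValidationError("criterion must be 'all' or 'any'")
    origin, normal = margin_plane(curve, mesh.vertices.mean(axis=0))
    height = (mesh.vertices - origin) @ normal
    keep_v = height >= min_height - 1e-9
    if max_height is not None:
        keep_v &= height <= max_height + 1e-9
    if criterion == "all":
        keep = keep_v[mesh.faces].all(axis=1)
    else:
        keep = keep_v[mesh.faces].any(axis=1)
    if not keep.any():
        raise ContentError("no faces above the margin seal zone")
    kept_idx = np.flatnonzero(keep)
    faces = mesh.faces[keep]
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriangleMesh(mesh.vertices[used], remap[faces], mesh.units), kept_idx
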