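"""Rigid registration: Kabsch alignment and trimmed iterative closest point.

The alignment principle is "reference best fit": only correspondences whose
closest-point distance falls below a configurable inlier threshold drive the
rigid update, which makes the fit robust to regions that genuinely differ
between the two scans (the very discrepancies being measured).  No scaling is
ever estimated — fit discrepancies must not be absorbed by a scale factor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, RankError, ValidationError
from .margin import MarginCurve
from .meshkit import SurfaceDistanceQuery, TriangleMesh

#: default inlier threshold (mm) for trimmed ICP; the "predefined threshold"
#: of reference best-fit alignment is not standardized, so it is a visible knob
DEFAULT_INLIER_THRESHOLD = 0.5
DEFAULT_TOL = 1e-5
DEFAULT_MAX_ITER = 100


@dataclass
class RigidTransform:
    """Proper rigid motion p -> R p + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)

    def validate(self, tol: float = 1e-9) -> None:
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > tol:
            raise ValidationError(f"rotation not orthonormal (error {err:.2e})")
        if abs(np.linalg.det(self.rotation) - 1.0) > tol:
            raise ValidationError("rotation determinant is not +1 (improper)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    # 12-number structured-text record: row-major rotation then translation
    def to_record(self) -> list:
        return [*self.rotation.ravel().tolist(), *self.translation.tolist()]

    @classmethod
    def from_record(cls, numbers) -> "RigidTransform":
        numbers = np.asarray(numbers, dtype=np.float64).ravel()
        if numbers.size != 12:
            raise ValidationError("rigid transform record needs 12 numbers")
        t = cls(numbers[:9].reshape(3, 3), numbers[9:])
        t.validate(tol=1e-6)
        return t

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"rotation_row_major_then_translation": self.to_record()}, fh,
                      indent=2)

    @classmethod
    def load(cls, path) -> "RigidTransform":
        with open(path) as fh:
            data = json.load(fh)
        return cls.from_record(data["rotation_row_major_then_translation"])


@dataclass
class RegistrationResult:
    transform: RigidTransform
    inlier_rms: float  # mm
    inlier_fraction: float
    iterations: int
    converged: bool
    rms_history: list


def kabsch_align(source_points: np.ndarray, target_points: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping source points onto targets.

    Classic SVD solution with the determinant sign fix so only proper
    rotations are returned; no scale is estimated.
    """
    src = np.asarray(source_points, dtype=np.float64).reshape(-1, 3)
    tgt = np.asarray(target_points, dtype=np.float64).reshape(-1, 3)
    if len(src) != len(tgt):
        raise ValidationError("correspondence lists differ in length")
    if len(src) < 3:
        raise RankError("need at least 3 correspondences")
    cs, ct = src.mean(axis=0), tgt.mean(axis=0)
    h = (src - cs).T @ (tgt - ct)
    u, s, vt = np.linalg.svd(h)
    scale = max(np.linalg.norm(src - cs, axis=1).max(), 1e-300)
    if s[1] <= 1e-9 * scale * scale:
        raise RankError("correspondences are collinear or coincident")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(r, ct - r @ cs)


def apply_transform(obj, transform: RigidTransform):
    """Apply a rigid transform to a mesh, curve, or point array."""
    transform.validate(tol=1e-6)
    if isinstance(obj, TriangleMesh):
        return TriangleMesh(transform.apply(obj.vertices), obj.faces.copy(), obj.units)
    if isinstance(obj, MarginCurve):
        return MarginCurve(transform.apply(obj.points))
    return transform.apply(np.asarray(obj, dtype=np.float64))


def principal_axes_init(source: TriangleMesh, target: TriangleMesh,
                        n_check: int = 500) -> RigidTransform:
    """Centroid + principal-axes initialization with sign disambiguation.

    The four proper-rotation sign flips of the principal frame are tried and
    the one with the lowest initial RMS (on a deterministic vertex subsample)
    wins.
    """
    def frame(v):
        c = v.mean(axis=0)
        _, _, vt = np.linalg.svd(v - c, full_matrices=False)
        if np.linalg.det(vt) < 0:
            vt[2] = -vt[2]
        return c, vt

    cs, fs = frame(source.vertices)
    ct, ft = frame(target.vertices)
    step = max(1, source.n_vertices // n_check)
    sample = source.vertices[::step]
    query = SurfaceDistanceQuery(target)
    best = None
    for flip in ([1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]):
        r = ft.T @ np.diag(flip) @ fs
        cand = RigidTransform(r, ct - r @ cs)
        d, _, _, _ = query.query(cand.apply(sample))
        rms = float(np.sqrt(np.mean(d ** 2)))
        if best is None or rms < best[0]:
            best = (rms, cand)
    return best[1]


def trimmed_icp(source: TriangleMesh, target: TriangleMesh,
                init: RigidTransform | None = None,
                inlier_threshold: float = DEFAULT_INLIER_THRESHOLD,
                max_iter: int = DEFAULT_MAX_ITER,
                tol: float = DEFAULT_TOL) -> RegistrationResult:
    """Trimmed ICP of source vertices onto the target surface.

    Each iteration finds closest points on the target (exact point-to-triangle,
    ties to the lowest face index), keeps pairs within ``inlier_threshold`` mm,
    and applies a Kabsch update.  An update that would increase the inlier RMS
    is rejected and iteration stops, so the reported RMS history is
    non-increasing.  Deterministic for identical inputs.
    """
    source.validate()
    target.validate()
    if inlier_threshold <= 0:
        raise ValidationError("inlier_threshold must be positive")
    transform = RigidTransform.identity() if init is None else init
    transform.validate(tol=1e-6)

    query = SurfaceDistanceQuery(target)
    verts = source.vertices
    history: list = []
    best = None  # (rms, transform, inlier_fraction)
    prev_rms = np.inf
    converged = False
    iterations = 0

    for iterations in range(1, max_iter + 1):
        moved = transform.apply(verts)
        d, closest, _, _ = query.query(moved)
        inliers = d <= inlier_threshold
        if not inliers.any():
            raise AlignmentError(
                "trimmed ICP found zero inliers "
                f"(threshold {inlier_threshold} mm)",
                last_state=RegistrationResult(
                    transform, float("nan"), 0.0, iterations, False, history
                ),
            )
        rms = float(np.sqrt(np.mean(d[inliers] ** 2)))
        # a step is accepted when it improves the trimmed objective; the
        # accepted history is therefore non-increasing.  Worse intermediate
        # poses (the inlier set can grow as alignment improves) still update
        # correspondences but never displace the best state.
        if best is None or rms < best[0]:
            best = (rms, transform, float(np.mean(inliers)))
            history.append(rms)
        if abs(prev_rms - rms) < tol:
            converged = True
            break
        prev_rms = rms
        update = kabsch_align(moved[inliers], closest[inliers])
        transform = update.compose(transform)
    rms, transform, inlier_fraction = best
    return RegistrationResult(
        transform=transform,
        inlier_rms=rms,
        inlier_fraction=inlier_fraction,
        iterations=iterations,
        converged=converged,
        rms_history=history,
    )
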