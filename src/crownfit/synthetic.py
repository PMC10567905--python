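"""Synthetic abutment/crown cohorts with analytically known ground-truth fit.

No scan data ships with the toolkit, so every pipeline stage is exercised on
generated geometry: an idealized prepared molar — a frustum with a concave
chamfer margin band (1.0 mm wide by default) and a flat occlusal table with a
rounded edge — and crown intaglio surfaces built by offsetting that abutment
by a cementation spacer (40 μm by default, engaging 0.5 mm above the finish
line).  Controlled distortions emulate sintering misfit: occlusal doming,
uniform shrinkage about the centroid, margin extension error, isotropic
scanner noise, and an arbitrary seating transform.  Because every distortion
is applied analytically, the generator doubles as the oracle for
parameter-recovery tests.

Anatomic realism is deliberately out of scope: metric correctness is what is
being tested, and analytic gap oracles require simple geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import SpecError, ValidationError
from .margin import MarginCurve, resample_curve, write_landmarks
from .meshkit import TriangleMesh, write_mesh
from .registration import RigidTransform

#: smoothstep blend width (mm) for the spacer onset above the finish line
SPACER_BLEND = 0.1
#: radial width (mm) of the doming falloff transition, placed on the occlusal
#: edge fillet so labelled regions see either the full lift or none of it
DOMING_TRANSITION = 0.2


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


# ----------------------------------------------------------------------------------
# specs
# ----------------------------------------------------------------------------------

@dataclass
class AbutmentSpec:
    """Idealized prepared-tooth geometry (mm)."""

    base_radius: float = 4.5
    top_radius: float = 3.5
    height: float = 5.0
    chamfer_width: float = 1.0
    mesh_resolution: float = 0.1  # target edge length
    occlusal_fillet: float = 0.5  # rounding of the occlusal table edge

    def validate(self) -> None:
        if not (0 < self.top_radius <= self.base_radius):
            raise SpecError("need 0 < top_radius <= base_radius")
        if self.chamfer_width >= self.base_radius:
            raise SpecError("chamfer_width must be below base_radius")
        if self.height <= 0:
            raise SpecError("height must be positive")
        if self.mesh_resolution > self.chamfer_width / 2:
            raise SpecError(
                "mesh_resolution too coarse to represent the chamfer "
                f"({self.mesh_resolution} > {self.chamfer_width / 2})"
            )
        if self.occlusal_fillet >= self.top_radius:
            raise SpecError("occlusal_fillet must be below top_radius")


@dataclass
class CrownSpec:
    """Crown intaglio construction and distortion parameters."""

    spacer_um: float = 40.0
    spacer_start_height: float = 0.5  # mm above the finish line
    margin_extension_error: float = 0.0  # mm, radially outward
    occlusal_doming_um: float = 0.0
    radial_shrinkage: float = 0.0  # fraction, about the centroid
    noise_sd_um: float = 0.0
    seed: int = 0
    seating_transform: RigidTransform | None = None

    def validate(self) -> None:
        if self.spacer_um < 0 or self.noise_sd_um < 0:
            raise SpecError("spacer and noise SD must be nonnegative")
        if abs(self.radial_shrinkage) >= 0.05:
            raise SpecError("|radial_shrinkage| must be below 0.05")


@dataclass
class GroundTruth:
    """Analytic record of every distortion applied to one crown."""

    spacer_um: float
    spacer_start_height: float
    margin_extension_um: float
    occlusal_doming_um: float
    radial_shrinkage: float
    noise_sd_um: float
    table_radius: float  # mm; doming falloff is 1 inside this radius
    true_margin_abutment: MarginCurve
    true_margin_crown: MarginCurve
    region_labels: np.ndarray  # per intaglio face: axial/occlusal/margin_band

    def nominal_gap_um(self, z: np.ndarray, rho: np.ndarray) -> np.ndarray:
        """Noise-free designed gap at height z (mm above margin), radius rho."""
        spacer = self.spacer_um * _smoothstep(
            (np.asarray(z) - self.spacer_start_height) / SPACER_BLEND
        )
        lift = self.occlusal_doming_um * self._falloff(np.asarray(rho))
        return spacer + lift

    def _falloff(self, rho: np.ndarray) -> np.ndarray:
        return 1.0 - _smoothstep((rho - self.table_radius) / DOMING_TRANSITION)


@dataclass
class Abutment:
    mesh: TriangleMesh
    margin: MarginCurve
    face_labels: np.ndarray  # per face: margin_band/axial/occlusal/base
    spec: AbutmentSpec


@dataclass
class Crown:
    intaglio: TriangleMesh
    margin: MarginCurve
    truth: GroundTruth
    spec: CrownSpec


# ----------------------------------------------------------------------------------
# abutment construction
# ----------------------------------------------------------------------------------

def _profile(spec: AbutmentSpec):
    """Axisymmetric profile (r_i, z_i) from near the axis at the base, out to
    the margin rim and up over the preparation to the axis at the top.

    Returns (points (n,2), segment label per interval).  Segments: flat base
    cap, concave chamfer arc, conical/cylindrical axial wall, occlusal edge
    fillet, flat occlusal table.
    """
    res = spec.mesh_resolution
    w = spec.chamfer_width
    f = spec.occlusal_fillet
    pts, labels = [], []

    def add(points, label):
        for p in points:
            if pts and abs(pts[-1][0] - p[0]) < 1e-12 and abs(pts[-1][1] - p[1]) < 1e-12:
                continue
            if pts:
                labels.append(label)
            pts.append(p)

    # base cap: concentric rings at z = 0 from near the axis to the rim, so
    # cap triangles stay the same size as the rest of the mesh
    n = max(2, int(np.ceil(spec.base_radius / res)))
    r = np.linspace(spec.base_radius / n, spec.base_radius, n)
    add([(ri, 0.0) for ri in r], "base")
    # chamfer: concave quarter arc, centre (base_radius, w)
    n = max(3, int(np.ceil(w * np.pi / 2 / res)) + 1)
    theta = np.linspace(-np.pi / 2, -np.pi, n)
    add(list(zip(spec.base_radius + w * np.cos(theta), w + w * np.sin(theta))),
        "margin_band")
    # axial wall to the fillet start
    wall_from = np.array([spec.base_radius - w, w])
    wall_to = np.array([spec.top_radius, spec.height - f])
    n = max(2, int(np.ceil(np.linalg.norm(wall_to - wall_from) / res)) + 1)
    t = np.linspace(0, 1, n)
    add([tuple(wall_from + ti * (wall_to - wall_from)) for ti in t], "axial")
    # occlusal edge fillet: quarter arc, centre (top_radius - f, height - f)
    n = max(3, int(np.ceil(f * np.pi / 2 / res)) + 1)
    phi = np.linspace(0, np.pi / 2, n)
    add(list(zip(spec.top_radius - f + f * np.cos(phi),
                 spec.height - f + f * np.sin(phi))), "fillet")
    # flat occlusal table to the axis
    n = max(2, int(np.ceil((spec.top_radius - f) / res)) + 1)
    r = np.linspace(spec.top_radius - f, 0.0, n)
    add([(ri, spec.height) for ri in r], "occlusal")
    return np.asarray(pts), labels


def make_abutment(spec: AbutmentSpec | None = None) -> Abutment:
    """Build the watertight synthetic abutment mesh and its margin curve.

    The margin curve is the chamfer outer rim (the finish line), an exact
    circle of ``base_radius`` in the z = 0 plane.  Face labels partition the
    surface into margin_band (chamfer), axial (wall and the doming-transition
    part of the fillet), occlusal (table and inner fillet where the doming
    falloff is 1) and base (bottom cap).  Deterministic for a fixed spec.
    """
    spec = spec or AbutmentSpec()
    spec.validate()
    profile, seg_labels = _profile(spec)
    n_theta = max(12, int(np.ceil(2 * np.pi * spec.base_radius / spec.mesh_resolution)))
    theta = np.arange(n_theta) * (2 * np.pi / n_theta)
    cos_t, sin_t = np.cos(theta), np.sin(theta)

    # rings for every profile point with r > 0; a single apex vertex at r = 0
    verts = [np.zeros(3)]  # bottom cap centre
    ring_start = []
    apex_index = None
    for r, z in profile:
        if r > 1e-12:
            ring_start.append(len(verts))
            ring = np.column_stack([r * cos_t, r * sin_t, np.full(n_theta, z)])
            verts.extend(ring)
        else:
            apex_index = len(verts)
            ring_start.append(apex_index)
            verts.append(np.array([0.0, 0.0, z]))
    verts = np.asarray(verts)

    faces, labels = [], []
    nxt = (np.arange(n_theta) + 1) % n_theta
    # bottom cap fan (label 'base'), wound so normals point down/outward
    s0 = ring_start[0]
    for k in range(n_theta):
        faces.append([0, s0 + nxt[k], s0 + k])
        labels.append("base")
    # lateral strips between consecutive rings
    for i in range(len(profile) - 1):
        a, b = ring_start[i], ring_start[i + 1]
        lab = seg_labels[i]
        if lab == "fillet":
            # split the fillet by the doming falloff: full-lift part counts as
            # occlusal, the transition and below as axial
            r_mid = 0.5 * (profile[i, 0] + profile[i + 1, 0])
            lab = "occlusal" if r_mid <= spec.top_radius - spec.occlusal_fillet \
                + 1e-9 else "axial"
        if b == apex_index:
            for k in range(n_theta):
                faces.append([a + k, a + nxt[k], apex_index])
                labels.append(lab)
        else:
            for k in range(n_theta):
                faces.append([a + k, a + nxt[k], b + nxt[k]])
                faces.append([a + k, b + nxt[k], b + k])
                labels.append(lab)
                labels.append(lab)

    mesh = TriangleMesh(verts, np.asarray(faces, dtype=np.int64))
    mesh.validate()
    tm = mesh.to_trimesh()
    if tm.volume < 0:  # enforce outward winding
        mesh = TriangleMesh(verts, mesh.faces[:, [0, 2, 1]])
    rim = np.flatnonzero(
        (np.abs(profile[:, 0] - spec.base_radius) < 1e-9) & (np.abs(profile[:, 1]) < 1e-9)
    )[0]
    margin = MarginCurve(verts[ring_start[rim]:ring_start[rim] + n_theta])
    return Abutment(mesh, margin, np.asarray(labels), spec)


# ----------------------------------------------------------------------------------
# crown construction
# ----------------------------------------------------------------------------------

def _vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    tm = mesh.to_trimesh()
    n = np.asarray(tm.vertex_normals, dtype=np.float64)
    if tm.volume < 0:
        n = -n
    return n


def make_crown(abutment: Abutment, spec: CrownSpec | None = None) -> Crown:
    """Construct a crown intaglio surface from an abutment with known misfit.

    Construction order: spacer offset along outward vertex normals (zero below
    ``spacer_start_height`` above the finish line, blending in over 0.1 mm),
    occlusal doming lift, uniform shrinkage about the centroid, margin
    extension of the crown margin curve, per-vertex Gaussian noise, then the
    seating transform.  The ground-truth record captures the noise-free
    nominal gap.
    """
    spec = spec or CrownSpec()
    spec.validate()
    aspec = abutment.spec
    if spec.radial_shrinkage * aspec.base_radius > spec.spacer_um / 1000.0 + 0.01:
        raise SpecError(
            "radial_shrinkage would collapse the intaglio below the abutment "
            "by more than the spacer; reduce shrinkage or increase spacer"
        )

    normals = _vertex_normals(abutment.mesh)
    keep_faces = abutment.face_labels != "base"
    faces = abutment.mesh.faces[keep_faces]
    used = np.unique(faces)
    remap = np.full(abutment.mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    v = abutment.mesh.vertices[used].copy()
    n = normals[used]
    f = remap[faces]
    labels = abutment.face_labels[keep_faces]

    z = v[:, 2]
    rho = np.linalg.norm(v[:, :2], axis=1)
    spacer_mm = spec.spacer_um / 1000.0
    s = spacer_mm * _smoothstep((z - spec.spacer_start_height) / SPACER_BLEND)
    v = v + s[:, None] * n

    table_radius = aspec.top_radius - aspec.occlusal_fillet
    falloff = 1.0 - _smoothstep((rho - table_radius) / DOMING_TRANSITION)
    v[:, 2] += (spec.occlusal_doming_um / 1000.0) * falloff

    centroid = v.mean(axis=0)
    v = centroid + (1.0 - spec.radial_shrinkage) * (v - centroid)

    if spec.margin_extension_error != 0.0:
        # the physical rim extends too: displace vertices near the finish line
        # radially outward, fading out over 0.3 mm of height, so the margin
        # curve stays on the intaglio surface
        fade = np.clip(1.0 - z / 0.3, 0.0, 1.0)
        radial_v = v[:, :2] - centroid[:2]
        radial_v /= np.maximum(np.linalg.norm(radial_v, axis=1), 1e-12)[:, None]
        v[:, :2] += (spec.margin_extension_error * fade)[:, None] * radial_v

    # crown margin curve: shrinkage applies, then the extension error pushes it
    # radially outward in the margin plane
    m = abutment.margin.points.copy()
    m = centroid + (1.0 - spec.radial_shrinkage) * (m - centroid)
    if spec.margin_extension_error != 0.0:
        radial = m[:, :2] - np.mean(m[:, :2], axis=0)
        radial /= np.linalg.norm(radial, axis=1)[:, None]
        m[:, :2] += spec.margin_extension_error * radial

    truth = GroundTruth(
        spacer_um=spec.spacer_um,
        spacer_start_height=spec.spacer_start_height,
        margin_extension_um=spec.margin_extension_error * 1000.0,
        occlusal_doming_um=spec.occlusal_doming_um,
        radial_shrinkage=spec.radial_shrinkage,
        noise_sd_um=spec.noise_sd_um,
        table_radius=table_radius,
        true_margin_abutment=abutment.margin.copy(),
        true_margin_crown=MarginCurve(m.copy()),
        region_labels=labels.copy(),
    )

    if spec.noise_sd_um > 0:
        rng = np.random.default_rng(spec.seed)
        v = v + rng.normal(0.0, spec.noise_sd_um / 1000.0, size=v.shape)
    mesh = TriangleMesh(v, f)
    curve = MarginCurve(m)
    if spec.seating_transform is not None:
        spec.seating_transform.validate(tol=1e-6)
        mesh = TriangleMesh(spec.seating_transform.apply(mesh.vertices), mesh.faces)
        curve = MarginCurve(spec.seating_transform.apply(curve.points))
    return Crown(intaglio=mesh, margin=curve, truth=truth, spec=spec)


# ----------------------------------------------------------------------------------
# cohorts
# ----------------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Distributions (mean, SD) drawn per crown; truncated at ±3 SD and
    clipped to physical bounds."""

    label: str
    spacer_um: tuple = (40.0, 0.0)
    occlusal_doming_um: tuple = (0.0, 0.0)
    radial_shrinkage: tuple = (0.0, 0.0)
    margin_extension_mm: tuple = (0.0, 0.0)
    noise_sd_um: float = 0.0
    seating_rotation_sd_deg: float = 1.0
    seating_translation_sd_mm: float = 0.2


def _draw(rng, mean_sd, lo=None, hi=None) -> float:
    mean, sd = mean_sd
    x = rng.normal(mean, sd) if sd > 0 else mean
    x = float(np.clip(x, mean - 3 * sd, mean + 3 * sd))
    if lo is not None:
        x = max(x, lo)
    if hi is not None:
        x = min(x, hi)
    return x


def _random_seating(rng, rot_sd_deg: float, trans_sd_mm: float) -> RigidTransform:
    angle = np.radians(rng.normal(0.0, rot_sd_deg))
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    r = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
    t = rng.normal(0.0, trans_sd_mm, size=3)
    return RigidTransform(r, t)


def draw_crown_spec(cohort: CohortSpec, rng: np.random.Generator,
                    seed: int) -> CrownSpec:
    return CrownSpec(
        spacer_um=_draw(rng, cohort.spacer_um, lo=0.0),
        occlusal_doming_um=_draw(rng, cohort.occlusal_doming_um, lo=0.0),
        radial_shrinkage=_draw(rng, cohort.radial_shrinkage, lo=-0.0499, hi=0.0499),
        margin_extension_error=_draw(rng, cohort.margin_extension_mm, lo=0.0),
        noise_sd_um=cohort.noise_sd_um,
        seed=seed,
        seating_transform=_random_seating(
            rng, cohort.seating_rotation_sd_deg, cohort.seating_translation_sd_mm
        ),
    )


def generate_cohorts(abutment: Abutment, cohorts: list,
                     n_per_group: int = 30, master_seed: int = 0):
    """Generate crowns for each cohort in memory.

    Returns ``{label: [Crown, ...]}``.  Fully reproducible: per-crown seeds
    derive from ``master_seed`` through a spawned seed sequence.
    """
    if n_per_group < 2:
        raise ValidationError("need at least 2 crowns per group")
    out = {}
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(cohorts))
    for cohort, child in zip(cohorts, children):
        rng = np.random.default_rng(child)
        crowns = []
        for i in range(n_per_group):
            seed = int(rng.integers(0, 2**31 - 1))
            cspec = draw_crown_spec(cohort, rng, seed)
            crowns.append(make_crown(abutment, cspec))
        out[cohort.label] = crowns
    return out


def make_cohorts(out_dir, cohorts: list, n_per_group: int = 30,
                 master_seed: int = 0, abutment_spec: AbutmentSpec | None = None,
                 n_landmarks: int = 50) -> dict:
    """Write a reproducible file tree of synthetic cohorts.

    Per crown: intaglio STL, a 50-landmark margin file sampled at equal arc
    length from the true crown margin, and a JSON ground-truth record.  The
    abutment mesh and its margin landmarks are written once.  Byte-identical
    for identical ``master_seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    abutment = make_abutment(abutment_spec)
    write_mesh(abutment.mesh, out_dir / "abutment.stl", fmt="stl")
    write_landmarks(
        resample_curve(abutment.margin, n_landmarks).points,
        out_dir / "abutment_margin.xyz",
        header="abutment margin landmarks (mm)",
    )
    generated = generate_cohorts(abutment, cohorts, n_per_group, master_seed)
    manifest = {"abutment_mesh": "abutment.stl",
                "abutment_landmarks": "abutment_margin.xyz",
                "groups": {}}
    for label, crowns in generated.items():
        entries = []
        for i, crown in enumerate(crowns):
            stem = f"crown_{label}_{i:02d}"
            write_mesh(crown.intaglio, out_dir / f"{stem}.stl", fmt="stl")
            write_landmarks(
                resample_curve(crown.margin, n_landmarks).points,
                out_dir / f"{stem}.xyz",
                header=f"crown margin landmarks (mm), group {label}",
            )
            truth = crown.truth
            record = {
                "spacer_um": truth.spacer_um,
                "spacer_start_height_mm": truth.spacer_start_height,
                "margin_extension_um": truth.margin_extension_um,
                "occlusal_doming_um": truth.occlusal_doming_um,
                "radial_shrinkage": truth.radial_shrinkage,
                "noise_sd_um": truth.noise_sd_um,
                "seating_transform": crown.spec.seating_transform.to_record()
                if crown.spec.seating_transform else None,
            }
            with open(out_dir / f"{stem}.truth.json", "w") as fh:
                json.dump(record, fh, indent=2, sort_keys=True)
            entries.append({"mesh": f"{stem}.stl", "landmarks": f"{stem}.xyz",
                            "truth": f"{stem}.truth.json"})
        manifest["groups"][label] = entries
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
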