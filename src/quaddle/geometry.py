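"""Parametric triangle meshes: bodies, appendages, assembly, morphing.

Coordinate convention: right-handed, +z up, +y toward the viewer ("front").
Bodies are lathe meshes: a superellipse cross-section (exponent 2 = circle,
large exponents approach a square) swept along the z axis with a radius
profile that is either linear in z (cylinder/cone family) or a circular arc
(sphere).  Appendages start as straight tubes and are molded into bent,
tapered shapes by sweeping a circle along a circular-arc centerline.  All
builders are deterministic; no randomness enters geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .features import NONE, FeatureCatalogue, ObjectSpec, default_catalogue, validate_spec
from .textures import color_from_name

PART_LABELS = ("body", "head", "arm", "ear", "beak")

#: appendage length classes as multiples of the base length
LENGTH_SCALES = {"short": 0.7, "regular": 1.0, "long": 1.3}
#: appendage bend classes in degrees (positive bends upward)
BEND_ANGLES = {"up": 45.0, "down": -45.0, "straight": 0.0}
#: tip classes as a sharpness parameter (0 flat, 0.5 hemispheric, 1 pointed)
TIP_SHARPNESS = {"flat": 0.0, "straight": 0.0, "blunt": 0.5, "pointy": 1.0}

DEFAULT_SEGMENTS = 64
DEFAULT_RINGS = 32


class MeshError(ValueError):
    pass


@dataclass
class TriMesh:
    """Indexed triangle mesh with optional per-vertex UVs and per-face part labels."""

    vertices: np.ndarray                 # (N, 3) float64
    faces: np.ndarray                    # (M, 3) int64
    uvs: np.ndarray | None = None        # (N, 2) in [0, 1]
    part_labels: np.ndarray | None = None  # (M,) str

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.part_labels is None:
            self.part_labels = np.full(len(self.faces), "body", dtype=object)
        else:
            self.part_labels = np.asarray(self.part_labels, dtype=object)

    # -- queries ----------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        if self.n_vertices == 0:
            raise MeshError("empty mesh has no bounds")
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def face_normals(self) -> np.ndarray:
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        n = np.cross(b - a, c - a)
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        return np.divide(n, norm, out=np.zeros_like(n), where=norm > 0)

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def validate(self, min_area: float = 1e-12) -> None:
        if self.n_vertices == 0 or self.n_faces == 0:
            raise MeshError("mesh is empty")
        if not np.isfinite(self.vertices).all():
            raise MeshError("non-finite vertex coordinates")
        if self.faces.min() < 0 or self.faces.max() >= self.n_vertices:
            raise MeshError("face index out of range")
        if (self.face_areas() <= min_area).any():
            raise MeshError("degenerate (zero-area) triangle")

    # -- transforms -------------------------------------------------------
    def transformed(self, rotation: np.ndarray | None = None,
                    translation=(0.0, 0.0, 0.0), scale: float = 1.0) -> "TriMesh":
        v = self.vertices * scale
        if rotation is not None:
            v = v @ np.asarray(rotation, dtype=float).T
        v = v + np.asarray(translation, dtype=float)
        return TriMesh(v, self.faces.copy(),
                       None if self.uvs is None else self.uvs.copy(),
                       self.part_labels.copy())

    def relabeled(self, label: str) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy(),
                       None if self.uvs is None else self.uvs.copy(),
                       np.full(self.n_faces, label, dtype=object))

    @staticmethod
    def concatenate(meshes: list["TriMesh"]) -> "TriMesh":
        if not meshes:
            raise MeshError("nothing to concatenate")
        verts, faces, labels, uvs = [], [], [], []
        offset = 0
        have_uvs = all(m.uvs is not None for m in meshes)
        for m in meshes:
            verts.append(m.vertices)
            faces.append(m.faces + offset)
            labels.append(m.part_labels)
            if have_uvs:
                uvs.append(m.uvs)
            offset += m.n_vertices
        return TriMesh(np.vstack(verts), np.vstack(faces),
                       np.vstack(uvs) if have_uvs else None,
                       np.concatenate(labels))


def rotation_about(axis: str, degrees: float) -> np.ndarray:
    c, s = math.cos(math.radians(degrees)), math.sin(math.radians(degrees))
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)
    raise ValueError(f"unknown axis {axis!r}")


@dataclass(frozen=True)
class BodyProfile:
    """Lathe profile: superellipse cross-section swept along z.

    ``lateral`` selects the radius-vs-height law: "linear" interpolates
    r_bottom -> r_top; "arc" follows a circular arc (sphere-like) with
    amplitude max(r_bottom, r_top).
    """

    r_bottom: float
    r_top: float
    exponent: float = 2.0
    height: float = 1.0
    lateral: str = "linear"

    def __post_init__(self) -> None:
        if self.r_bottom < 0 or self.r_top < 0:
            raise ValueError("radii must be non-negative")
        if self.r_bottom == 0 and self.r_top == 0:
            raise ValueError("at least one radius must be positive")
        if self.exponent < 1:
            raise ValueError("cross-section exponent must be >= 1")
        if self.lateral not in ("linear", "arc"):
            raise ValueError("lateral must be 'linear' or 'arc'")

    def radius_at(self, t: float) -> float:
        """Cross-section radius at normalized height t in [0, 1]."""
        if self.lateral == "arc":
            return max(self.r_bottom, self.r_top) * math.sqrt(
                max(0.0, 1.0 - (2.0 * t - 1.0) ** 2))
        return self.r_bottom + (self.r_top - self.r_bottom) * t


#: named body shapes as profiles (height 1, max half-width 0.5)
BODY_PROFILES = {
    "sphere": BodyProfile(0.5, 0.5, 2.0, 1.0, "arc"),
    "cube": BodyProfile(0.5, 0.5, 8.0, 1.0),
    "cone": BodyProfile(0.5, 0.0, 2.0, 1.0),
    "cylinder": BodyProfile(0.4, 0.4, 2.0, 1.0),
    "inverted_cone": BodyProfile(0.0, 0.5, 2.0, 1.0),
}

HEAD_PROFILES = {
    "sphere": BodyProfile(0.25, 0.25, 2.0, 0.5, "arc"),
    "cube": BodyProfile(0.25, 0.25, 8.0, 0.5),
    "cone": BodyProfile(0.25, 0.0, 2.0, 0.5),
}


def _superellipse(theta: np.ndarray, exponent: float) -> tuple[np.ndarray, np.ndarray]:
    e = 2.0 / exponent
    c, s = np.cos(theta), np.sin(theta)
    return np.sign(c) * np.abs(c) ** e, np.sign(s) * np.abs(s) ** e


def _lathe(radii: np.ndarray, heights: np.ndarray, exponent: float,
           segments: int, close_bottom: bool, close_top: bool) -> TriMesh:
    """Sweep rings of a superellipse; zero-radius end rings collapse to apexes."""
    theta = np.linspace(0.0, 2.0 * math.pi, segments, endpoint=False)
    cx, cy = _superellipse(theta, exponent)
    verts: list[np.ndarray] = []
    ring_start: list[int | None] = []  # vertex offset per ring, None = apex index
    apex: dict[int, int] = {}
    for i, (r, z) in enumerate(zip(radii, heights)):
        if r <= 1e-12:
            apex[i] = len(verts)
            verts.append(np.array([0.0, 0.0, z]))
            ring_start.append(None)
        else:
            ring_start.append(len(verts))
            ring = np.column_stack([r * cx, r * cy, np.full(segments, z)])
            verts.extend(ring)
    faces: list[tuple[int, int, int]] = []
    for i in range(len(radii) - 1):
        lo, hi = ring_start[i], ring_start[i + 1]
        if lo is None and hi is None:
            continue
        if lo is None:  # apex below, fan upward
            a = apex[i]
            for j in range(segments):
                jn = (j + 1) % segments
                faces.append((a, hi + j, hi + jn))
        elif hi is None:  # apex above
            a = apex[i + 1]
            for j in range(segments):
                jn = (j + 1) % segments
                faces.append((lo + j, a, lo + jn))
        else:
            for j in range(segments):
                jn = (j + 1) % segments
                faces.append((lo + j, hi + jn, hi + j))
                faces.append((lo + j, lo + jn, hi + jn))
    if close_bottom and ring_start[0] is not None:
        c = len(verts)
        verts.append(np.array([0.0, 0.0, heights[0]]))
        lo = ring_start[0]
        for j in range(segments):
            jn = (j + 1) % segments
            faces.append((c, lo + jn, lo + j))
    if close_top and ring_start[-1] is not None:
        c = len(verts)
        verts.append(np.array([0.0, 0.0, heights[-1]]))
        hi = ring_start[-1]
        for j in range(segments):
            jn = (j + 1) % segments
            faces.append((c, hi + j, hi + jn))
    return TriMesh(np.array(verts), np.array(faces, dtype=np.int64))


def build_body(profile: BodyProfile, segments: int = DEFAULT_SEGMENTS,
               rings: int = DEFAULT_RINGS) -> TriMesh:
    """Lathe mesh of a body profile, centered on the z axis, base at z = -h/2."""
    if segments < 8:
        raise ValueError("segments must be >= 8")
    t = np.linspace(0.0, 1.0, rings + 1)
    radii = np.array([profile.radius_at(ti) for ti in t])
    heights = (t - 0.5) * profile.height
    mesh = _lathe(radii, heights, profile.exponent, segments,
                  close_bottom=True, close_top=True)
    return mesh.relabeled("body")


def _arc_centerline(s: np.ndarray, length: float, bend_deg: float
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Points, radial unit vectors, and binormals of a circular-arc centerline.

    The tube starts at the origin along +x and bends in the x-z plane by
    ``bend_deg`` over its full length (positive = up).  Mirroring the bend
    sign mirrors every produced point in z exactly.
    """
    v = np.zeros((len(s), 3))
    u = np.zeros((len(s), 3))
    if abs(bend_deg) < 1e-9:
        v[:, 0] = s
        u[:, 2] = 1.0
    else:
        phi = math.radians(bend_deg)
        sigma = 1.0 if phi > 0 else -1.0
        radius = length / abs(phi)
        psi = s / radius
        v[:, 0] = radius * np.sin(psi)
        v[:, 2] = sigma * radius * (1.0 - np.cos(psi))
        u[:, 0] = np.sin(psi)
        u[:, 2] = -sigma * np.cos(psi)
    b = np.zeros((len(s), 3))
    b[:, 1] = 1.0
    return v, u, b


def build_appendage(angle, length, tip, radius: float = 0.06,
                    base_length: float = 0.5, segments: int = 24,
                    rings: int = 12) -> TriMesh:
    """Tube swept along a circular arc with a shaped tip cap.

    ``angle`` is a bend class name or degrees; ``length`` a class name or a
    scale factor applied to ``base_length``; ``tip`` one of pointy (tapers to
    a single apex at the full arc length), blunt (hemispherical cap), or flat
    (disc).  The centerline endpoints are separated by exactly the requested
    length for a straight appendage.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    bend = BEND_ANGLES[angle] if isinstance(angle, str) else float(angle)
    scale = LENGTH_SCALES[length] if isinstance(length, str) else float(length)
    total = base_length * scale
    if tip == "pointy":
        cap_len, cap_kind = min(0.3 * total, 4 * radius), "cone"
    elif tip == "blunt":
        cap_len, cap_kind = min(radius, 0.5 * total), "hemisphere"
    elif tip == "flat":
        cap_len, cap_kind = 0.0, "disc"
    else:
        raise ValueError(f"unknown tip {tip!r}")

    # arc-length stations: tube body, then cap rings shrinking to the end
    s_tube = np.linspace(0.0, total - cap_len, rings + 1)
    r_tube = np.full(len(s_tube), radius)
    if cap_kind == "cone":
        n_cap = 6
        u = np.linspace(0.0, 1.0, n_cap + 1)[1:]
        s_cap = total - cap_len + u * cap_len
        r_cap = radius * (1.0 - u)
    elif cap_kind == "hemisphere":
        n_cap = 8
        beta = np.linspace(0.0, math.pi / 2.0, n_cap + 1)[1:]
        s_cap = total - cap_len + cap_len * np.sin(beta)
        r_cap = radius * np.cos(beta)
    else:
        s_cap = np.array([])
        r_cap = np.array([])
    s_all = np.concatenate([s_tube, s_cap])
    r_all = np.concatenate([r_tube, r_cap])

    pts, u_rad, b_vec = _arc_centerline(s_all, total, bend)
    alpha = np.linspace(0.0, 2.0 * math.pi, segments, endpoint=False)
    ca, sa = np.cos(alpha), np.sin(alpha)
    verts: list[np.ndarray] = []
    ring_start: list[int | None] = []
    apex: dict[int, int] = {}
    for i in range(len(s_all)):
        if r_all[i] <= 1e-12:
            apex[i] = len(verts)
            verts.append(pts[i])
            ring_start.append(None)
        else:
            ring_start.append(len(verts))
            ring = (pts[i][None, :]
                    + r_all[i] * (ca[:, None] * u_rad[i][None, :]
                                  + sa[:, None] * b_vec[i][None, :]))
            verts.extend(ring)
    faces: list[tuple[int, int, int]] = []
    for i in range(len(s_all) - 1):
        lo, hi = ring_start[i], ring_start[i + 1]
        if lo is None:
            continue
        if hi is None:
            a = apex[i + 1]
            for j in range(segments):
                jn = (j + 1) % segments
                faces.append((lo + j, a, lo + jn))
        else:
            for j in range(segments):
                jn = (j + 1) % segments
                faces.append((lo + j, hi + jn, hi + j))
                faces.append((lo + j, lo + jn, hi + jn))
    # base disc
    c = len(verts)
    verts.append(pts[0])
    lo = ring_start[0]
    for j in range(segments):
        jn = (j + 1) % segments
        faces.append((c, lo + jn, lo + j))
    # flat tip disc
    if cap_kind == "disc":
        c = len(verts)
        verts.append(pts[-1])
        hi = ring_start[-1]
        for j in range(segments):
            jn = (j + 1) % segments
            faces.append((c, hi + j, hi + jn))
    return TriMesh(np.array(verts), np.array(faces, dtype=np.int64))


# -- assembly ---------------------------------------------------------------

_EAR_TIP = {"straight": "flat", "pointy": "pointy", "blunt": "blunt"}


def assemble(spec: ObjectSpec, catalogue: FeatureCatalogue | None = None,
             segments: int = DEFAULT_SEGMENTS, rings: int = DEFAULT_RINGS) -> TriMesh:
    """Build the full object mesh: body, head, and any present accessories.

    The body sits at the origin; the head is centered on the body's top axis
    (overlapping 10% of its height to hide the seam); arms attach at
    mid-height on +/-x, ears on the head's top at +/-x, and the beak on the
    head's front (+y).  Faces carry their part label.
    """
    catalogue = catalogue or default_catalogue()
    validate_spec(spec, catalogue)
    v = spec.values
    app_seg = max(8, segments // 3)
    app_rings = max(4, rings // 3)
    parts: list[TriMesh] = []

    body = build_body(BODY_PROFILES[v["body_shape"]], segments, rings)
    parts.append(body)

    head_profile = HEAD_PROFILES[v["head_shape"]]
    head = build_body(head_profile, segments, rings).relabeled("head")
    head_base = 0.5 - 0.1 * head_profile.height
    parts.append(head.transformed(translation=(0, 0, head_base + head_profile.height / 2)))

    for side, sign in (("left", -1.0), ("right", 1.0)):
        if v[f"{side}_arm_angle"] != NONE:
            arm = build_appendage(v[f"{side}_arm_angle"], v[f"{side}_arm_length"],
                                  v[f"{side}_arm_tip"], radius=0.06,
                                  segments=app_seg, rings=app_rings)
            rot = rotation_about("z", 180.0) if sign < 0 else None
            parts.append(arm.transformed(rotation=rot,
                                         translation=(sign * 0.30, 0, 0)).relabeled("arm"))
        if v[f"{side}_ear_shape"] != NONE:
            ear = build_appendage(v[f"{side}_ear_angle"], v[f"{side}_ear_length"],
                                  _EAR_TIP[v[f"{side}_ear_shape"]], radius=0.05,
                                  base_length=0.35, segments=app_seg, rings=app_rings)
            # local +x becomes +z (pointing up), bend tilts toward +/-x
            rot = rotation_about("y", -90.0)
            parts.append(ear.transformed(rotation=rot,
                                         translation=(sign * 0.12, 0, head_base + 0.8 * head_profile.height)
                                         ).relabeled("ear"))
    if v["beak_shape"] != NONE:
        beak = build_appendage(v["beak_angle"], v["beak_length"], v["beak_shape"],
                               radius=0.05, base_length=0.4,
                               segments=app_seg, rings=app_rings)
        rot = rotation_about("z", 90.0)  # local +x becomes +y (front)
        parts.append(beak.transformed(rotation=rot,
                                      translation=(0, 0.15, head_base + 0.5 * head_profile.height)
                                      ).relabeled("beak"))
    return TriMesh.concatenate(parts)


# -- morphing ---------------------------------------------------------------

#: pattern kinds with a morphable stripe angle (degrees from horizontal)
PATTERN_ANGLES = {"horizontal": 0.0, "diagonal": 45.0, "vertical": 90.0}


@dataclass(frozen=True)
class MorphParams:
    """Continuous object parameters; categorical leftovers kept separately.

    ``continuous`` maps parameter names (body profile fields, per-part bend
    angle / length scale / tip sharpness, color hue and chroma, stripe angle)
    to floats; ``categorical`` holds non-morphable feature values.
    """

    continuous: dict[str, float] = field(default_factory=dict)
    categorical: dict[str, str] = field(default_factory=dict)

    def body_profile(self) -> BodyProfile:
        c = self.continuous
        arc = c.get("body_arc", 0.0)
        return BodyProfile(
            r_bottom=c["body_r_bottom"], r_top=c["body_r_top"],
            exponent=c["body_exponent"], height=c.get("body_height", 1.0),
            lateral="arc" if arc >= 0.5 else "linear")


def params_from_spec(spec: ObjectSpec, catalogue: FeatureCatalogue | None = None
                     ) -> MorphParams:
    """Extract the continuous parameter set realized by a categorical spec."""
    catalogue = catalogue or default_catalogue()
    validate_spec(spec, catalogue)
    v = spec.values
    cont: dict[str, float] = {}
    cat: dict[str, str] = {}
    bp = BODY_PROFILES[v["body_shape"]]
    cont.update(body_r_bottom=bp.r_bottom, body_r_top=bp.r_top,
                body_exponent=bp.exponent, body_height=bp.height,
                body_arc=1.0 if bp.lateral == "arc" else 0.0)
    for prefix in ("body", "head"):
        col = color_from_name(v[f"{prefix}_color"])
        cont[f"{prefix}_hue_deg"] = col.h
        cont[f"{prefix}_chroma"] = col.c
        pat = v[f"{prefix}_pattern"]
        if pat in PATTERN_ANGLES:
            cont[f"{prefix}_pattern_angle"] = PATTERN_ANGLES[pat]
        else:
            cat[f"{prefix}_pattern"] = pat
    cat["head_shape"] = v["head_shape"]
    for part, attrs in (("arm", ("angle", "length", "tip")),
                        ("ear", ("shape", "length", "angle")),
                        ("beak", ("shape", "length", "angle"))):
        sides = ("left", "right") if part in ("arm", "ear") else (None,)
        for side in sides:
            key = f"{side}_{part}" if side else part
            present = v[f"{key}_{attrs[0]}"] != NONE
            cat[f"{key}_present"] = "yes" if present else "no"
            if not present:
                continue
            cont[f"{key}_angle_deg"] = BEND_ANGLES[v[f"{key}_angle"]]
            cont[f"{key}_length_scale"] = LENGTH_SCALES[v[f"{key}_length"]]
            shape_val = v[f"{key}_tip"] if part == "arm" else v[f"{key}_shape"]
            cont[f"{key}_tip_sharpness"] = TIP_SHARPNESS[shape_val]
    for sub in ("fractal_identity", "fractal_size", "fractal_position"):
        cat[sub] = v[sub]
    return MorphParams(continuous=cont, categorical=cat)


def morph(spec_a: ObjectSpec, spec_b: ObjectSpec, t: float,
          catalogue: FeatureCatalogue | None = None) -> MorphParams:
    """Linear interpolation of the continuous parameter sets of two objects.

    Categorical (non-morphable) values come from ``spec_a`` for t < 0.5 and
    from ``spec_b`` otherwise; the endpoints reproduce the inputs exactly.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError("t must lie in [0, 1]")
    catalogue = catalogue or default_catalogue()
    pa = params_from_spec(spec_a, catalogue)
    pb = params_from_spec(spec_b, catalogue)
    cont: dict[str, float] = {}
    for key in pa.continuous.keys() | pb.continuous.keys():
        if key in pa.continuous and key in pb.continuous:
            cont[key] = (1.0 - t) * pa.continuous[key] + t * pb.continuous[key]
        elif key in pa.continuous:
            if t < 0.5:
                cont[key] = pa.continuous[key]
        else:
            if t >= 0.5:
                cont[key] = pb.continuous[key]
    cat = dict(pa.categorical) if t < 0.5 else dict(pb.categorical)
    return MorphParams(continuous=cont, categorical=cat)


def build_from_params(params: MorphParams, segments: int = DEFAULT_SEGMENTS,
                      rings: int = DEFAULT_RINGS) -> TriMesh:
    """Realize a (possibly interpolated) parameter set as a mesh.

    Continuous tip sharpness blends flat (0) through hemispheric (0.5) to
    pointed (1) caps; named class values reproduce :func:`assemble` geometry.
    """
    c = params.continuous
    parts = [build_body(params.body_profile(), segments, rings)]
    head_profile = HEAD_PROFILES[params.categorical.get("head_shape", "sphere")]
    head_base = 0.5 - 0.1 * head_profile.height
    parts.append(build_body(head_profile, segments, rings)
                 .relabeled("head")
                 .transformed(translation=(0, 0, head_base + head_profile.height / 2)))
    app_seg = max(8, segments // 3)
    app_rings = max(4, rings // 3)
    for side, sign in (("left", -1.0), ("right", 1.0)):
        key = f"{side}_arm"
        if params.categorical.get(f"{key}_present") == "yes":
            arm = _continuous_appendage(c[f"{key}_angle_deg"],
                                        c[f"{key}_length_scale"],
                                        c[f"{key}_tip_sharpness"],
                                        radius=0.06, base_length=0.5,
                                        segments=app_seg, rings=app_rings)
            rot = rotation_about("z", 180.0) if sign < 0 else None
            parts.append(arm.transformed(rotation=rot,
                                         translation=(sign * 0.30, 0, 0)).relabeled("arm"))
        key = f"{side}_ear"
        if params.categorical.get(f"{key}_present") == "yes":
            ear = _continuous_appendage(c[f"{key}_angle_deg"],
                                        c[f"{key}_length_scale"],
                                        c[f"{key}_tip_sharpness"],
                                        radius=0.05, base_length=0.35,
                                        segments=app_seg, rings=app_rings)
            parts.append(ear.transformed(rotation=rotation_about("y", -90.0),
                                         translation=(sign * 0.12, 0, head_base + 0.8 * head_profile.height)
                                         ).relabeled("ear"))
    if params.categorical.get("beak_present") == "yes":
        beak = _continuous_appendage(c["beak_angle_deg"], c["beak_length_scale"],
                                     c["beak_tip_sharpness"], radius=0.05,
                                     base_length=0.4, segments=app_seg, rings=app_rings)
        parts.append(beak.transformed(rotation=rotation_about("z", 90.0),
                                      translation=(0, 0.15, head_base + 0.5 * head_profile.height)
                                      ).relabeled("beak"))
    return TriMesh.concatenate(parts)


def _continuous_appendage(angle_deg: float, length_scale: float, sharpness: float,
                          radius: float, base_length: float,
                          segments: int, rings: int) -> TriMesh:
    if sharpness <= 0.0:
        tip = "flat"
    elif sharpness >= 0.75:
        tip = "pointy"
    else:
        tip = "blunt"
    return build_appendage(angle_deg, length_scale, tip, radius=radius,
                           base_length=base_length, segments=segments, rings=rings)


# -- normalization and UV mapping ------------------------------------------

def normalize(mesh: TriMesh) -> TriMesh:
    """Center the bounding box at the origin and scale the largest extent to 2."""
    if mesh.n_vertices == 0:
        raise MeshError("cannot normalize an empty mesh")
    lo, hi = mesh.bounds()
    center = (lo + hi) / 2.0
    extent = float((hi - lo).max())
    if extent == 0:
        raise MeshError("mesh has zero extent")
    scale = 2.0 / extent
    return TriMesh((mesh.vertices - center) * scale, mesh.faces.copy(),
                   None if mesh.uvs is None else mesh.uvs.copy(),
                   mesh.part_labels.copy())


def planar_uv(mesh: TriMesh) -> TriMesh:
    """Front planar projection: u = (x+1)/2, v = (z+1)/2, independent of y.

    Vertices mirrored in y receive identical UVs, so the texture appears
    symmetrically on the front and back of the object.
    """
    v = mesh.vertices
    uvs = np.column_stack([(v[:, 0] + 1.0) / 2.0, (v[:, 2] + 1.0) / 2.0])
    uvs = np.clip(uvs, 0.0, 1.0)
    return TriMesh(v.copy(), mesh.faces.copy(), uvs, mesh.part_labels.copy())
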