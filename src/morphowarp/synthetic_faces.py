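"""Parametric synthetic face cohorts.

Real 3D facial-expression scan collections are license-restricted, so this
module generates face-like surfaces with analytic ground truth: a domed
elliptical patch (a height field over a canonical (x, y) face plane,
roughly 120 mm wide by 160 mm tall) carrying a raised nose, eye sockets
and a mouth depression.  Sixteen standard anthropometric anchor points
(endocanthion/exocanthion left+right, sellion, pronasale, subnasale,
alare left+right, cheilion left+right, labiale superius/inferius,
gnathion, obelion left+right) are placed at fixed parameter positions and
snapped to mesh vertices, so landmarking error has an unambiguous truth.

Expression classes deform fixed regions of the canonical plane through
smooth cosine windows (mouth for Surprise, cheeks for Happy, mouth+eyes
with distinct sign patterns for Angry/Disgust/Fear, a global low-frequency
pattern for Sad), mirroring where human raters see each expression act.
Subjects within a class add a smooth random field; duplicate digitizations
add small isotropic localization noise.  Everything is deterministic under
the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh_io import LandmarkConfiguration, TriangleMesh

__all__ = [
    "EXPRESSION_CLASSES",
    "ANCHOR_NAMES",
    "SynthSpec",
    "make_base_face",
    "apply_expression",
    "digitize",
    "make_cohort",
]

EXPRESSION_CLASSES = ("Angry", "Disgust", "Fear", "Happy", "Sad", "Surprise")

# 16 anchor notations in fixed (homology) order, with canonical-plane
# positions (x lateral mm, y vertical mm); pronasale sits at the origin.
ANCHOR_NAMES = [
    "enl", "exl", "exr", "enr", "se", "pr", "su", "all",
    "alr", "chl", "chr", "ls", "li", "gn", "obl", "obr",
]
_ANCHOR_XY = {
    "enl": (-16.0, 25.0),   # endocanthion left
    "exl": (-40.0, 25.0),   # exocanthion left
    "exr": (40.0, 25.0),    # exocanthion right
    "enr": (16.0, 25.0),    # endocanthion right
    "se": (0.0, 33.0),      # sellion
    "pr": (0.0, 0.0),       # pronasale (apex nasi)
    "su": (0.0, -13.0),     # subnasale
    "all": (-11.0, -5.0),   # alare left
    "alr": (11.0, -5.0),    # alare right
    "chl": (-23.0, -35.0),  # cheilion left
    "chr": (23.0, -35.0),   # cheilion right
    "ls": (0.0, -28.0),     # labiale superius
    "li": (0.0, -43.0),     # labiale inferius
    "gn": (0.0, -64.0),     # gnathion
    "obl": (-13.0, 72.0),   # obelion left
    "obr": (13.0, 72.0),    # obelion right
}

_HALF_WIDTH = 60.0   # mm, |x| extent
_HALF_HEIGHT = 80.0  # mm, |y| extent

# Expression deformation regions in the canonical plane: (cx, cy, radius).
_MOUTH = (0.0, -35.0, 26.0)
_CHEEK_L = (-32.0, -14.0, 20.0)
_CHEEK_R = (32.0, -14.0, 20.0)
_EYE_L = (-28.0, 25.0, 17.0)
_EYE_R = (28.0, 25.0, 17.0)

# Per-class (region, weight) recipes.  Angry/Disgust/Fear all act on
# mouth+eyes but with distinct sign patterns so classes stay separable.
_CLASS_FIELDS: dict[str, list[tuple[tuple[float, float, float], float]]] = {
    "Surprise": [(_MOUTH, 1.0)],
    "Happy": [(_CHEEK_L, 1.0), (_CHEEK_R, 1.0)],
    "Angry": [(_MOUTH, -1.0), (_EYE_L, -0.6), (_EYE_R, -0.6)],
    "Disgust": [(_MOUTH, 0.7), (_EYE_L, -1.0), (_EYE_R, -1.0)],
    "Fear": [(_MOUTH, -0.6), (_EYE_L, 1.0), (_EYE_R, 1.0)],
}


@dataclass
class SynthSpec:
    """Study-design parameters for a synthetic cohort.

    Defaults mirror the cohort structure the method targets: six basic
    expression classes, 40 subjects per class, 500-point configurations,
    duplicate digitizations with ~0.1 mm localization noise, a few mm of
    expression signal over ~1 mm of within-class subject variation.
    """

    seed: int
    subjects_per_class: int = 40
    classes: tuple[str, ...] = EXPRESSION_CLASSES
    expression_amplitude: float = 3.0  # mm, peak class deformation
    subject_variation_sd: float = 1.0  # mm, smooth per-subject field
    digitization_sd: float = 0.1  # mm, per-coordinate digitizing noise
    replicates: int = 2
    mesh_resolution: int = 2000  # target vertex count

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory (no implicit randomness)")
        if self.subject_variation_sd < 0 or self.digitization_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for c in self.classes:
            if c not in EXPRESSION_CLASSES and c != "Neutral":
                raise ValueError(f"unknown expression class {c!r}")


def _dome_height(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Base facial dome plus nose bump, eye sockets and mouth hollow."""
    r2 = (x / 70.0) ** 2 + (y / 90.0) ** 2
    z = 40.0 * np.clip(1.0 - r2, 0.0, None) ** 0.8
    z += 14.0 * np.exp(-(x**2 + y**2) / (2 * 8.0**2))  # nose, peak at origin
    for ex in (-28.0, 28.0):
        z -= 3.5 * np.exp(-((x - ex) ** 2 + (y - 25.0) ** 2) / (2 * 9.0**2))
    z -= 2.5 * np.exp(-(x**2 + (y + 35.0) ** 2) / (2 * 11.0**2))
    return z


def make_base_face(spec: SynthSpec) -> tuple[TriangleMesh, LandmarkConfiguration]:
    """Build the neutral base face and its 16 ground-truth anchors.

    Returns a grid-triangulated height-field mesh with about
    ``spec.mesh_resolution`` vertices, and an anchor configuration whose
    points lie exactly on mesh vertices (vertex indices stored in
    ``meta['vertex_indices']``).  The pronasale anchor is the vertex of
    maximal outward protrusion by construction.
    """
    res = spec.mesh_resolution
    if res < 500:
        raise ValueError(
            f"mesh_resolution={res} too low to host 500 well-spaced landmarks"
        )
    aspect = _HALF_HEIGHT / _HALF_WIDTH
    nx = int(round(np.sqrt(res / aspect)))
    ny = int(round(res / nx))
    xs = np.linspace(-_HALF_WIDTH, _HALF_WIDTH, nx)
    ys = np.linspace(-_HALF_HEIGHT, _HALF_HEIGHT, ny)
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    gz = _dome_height(gx, gy)
    vertices = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    faces = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            a = j * nx + i
            b = a + 1
            c = a + nx
            d = c + 1
            faces.append((a, b, d))
            faces.append((a, d, c))
    mesh = TriangleMesh(vertices, np.array(faces, dtype=np.int64))

    indices = []
    for name in ANCHOR_NAMES:
        if name == "pr":
            idx = int(np.argmax(vertices[:, 2]))  # unique protrusion maximum
        else:
            tx, ty = _ANCHOR_XY[name]
            idx = int(np.argmin((vertices[:, 0] - tx) ** 2 + (vertices[:, 1] - ty) ** 2))
        indices.append(idx)
    if len(set(indices)) != 16:
        raise ValueError("anchor snapping collision; increase mesh_resolution")
    config = LandmarkConfiguration(
        vertices[indices],
        list(ANCHOR_NAMES),
        ["anchor"] * 16,
        {"vertex_indices": indices, "expression": "Neutral"},
    )
    return mesh, config


def _cosine_window(x, y, region) -> np.ndarray:
    cx, cy, radius = region
    d = np.sqrt((x - cx) ** 2 + (y - cy) ** 2)
    return np.where(d < radius, 0.5 * (1.0 + np.cos(np.pi * d / radius)), 0.0)


def expression_field(mesh: TriangleMesh, class_name: str) -> np.ndarray:
    """Per-vertex class displacement pattern, normalized to peak |.| = 1."""
    x, y = mesh.vertices[:, 0], mesh.vertices[:, 1]
    if class_name == "Sad":
        # global, low-frequency droop over the whole face
        f = -np.cos(np.pi * x / (2 * _HALF_WIDTH)) * np.cos(np.pi * y / (2 * _HALF_HEIGHT))
    else:
        f = np.zeros(len(x))
        for region, weight in _CLASS_FIELDS[class_name]:
            f = f + weight * _cosine_window(x, y, region)
    peak = np.abs(f).max()
    return f / peak


def _subject_field(
    mesh: TriangleMesh, rng: np.random.Generator, sd: float, support: np.ndarray
) -> np.ndarray:
    """Smooth random per-vertex field confined to the class region.

    The field is a random low-frequency cosine series windowed by the
    class support mask, rescaled so its sample sd over the supported
    vertices equals ``sd``: subjects of one expression class differ in
    how strongly and where within the class region they express it.
    """
    x = mesh.vertices[:, 0] / _HALF_WIDTH
    y = mesh.vertices[:, 1] / _HALF_HEIGHT
    f = np.zeros(len(x))
    for kx in range(3):
        for ky in range(3):
            cc, cs, sc, ss = rng.standard_normal(4)
            ax, ay = 0.5 * np.pi * kx * x, 0.5 * np.pi * ky * y
            f += (cc * np.cos(ax) * np.cos(ay) + cs * np.cos(ax) * np.sin(ay)
                  + sc * np.sin(ax) * np.cos(ay) + ss * np.sin(ax) * np.sin(ay))
    f = f * support
    inside = support > 0
    s = f[inside].std() if inside.any() else 0.0
    return f * (sd / s) if s > 0 else f


def apply_expression(
    mesh: TriangleMesh,
    class_name: str,
    amplitude: float,
    subject_seed: int,
    subject_sd: float = 0.0,
) -> TriangleMesh:
    """Deform the base face into one subject's expression.

    The class displacement field (peak magnitude exactly ``amplitude`` mm,
    along the height axis) is confined to the fixed class region; a smooth
    subject-specific random field with sd ``subject_sd``, windowed to the
    same region, is added on top, so the total displacement vanishes
    outside the class mask.  ``Neutral`` or ``amplitude == 0`` returns the
    input unchanged.
    """
    if class_name != "Neutral" and class_name not in EXPRESSION_CLASSES:
        raise ValueError(f"unknown expression class {class_name!r}")
    if class_name == "Neutral" or amplitude == 0:
        return TriangleMesh(mesh.vertices.copy(), mesh.faces.copy())
    f = expression_field(mesh, class_name)
    dz = amplitude * f
    if subject_sd > 0:
        rng = np.random.default_rng(subject_seed)
        dz = dz + _subject_field(mesh, rng, subject_sd, np.abs(f))
    vertices = mesh.vertices.copy()
    vertices[:, 2] += dz
    return TriangleMesh(vertices, mesh.faces.copy())


def digitize(
    config: LandmarkConfiguration,
    sd: float,
    seed: int,
    mesh: TriangleMesh | None = None,
) -> LandmarkConfiguration:
    """Simulate one digitization: isotropic Gaussian localization noise
    (per-coordinate sd ``sd``), then projection back onto ``mesh`` if one
    is supplied.  ``sd == 0`` is the identity."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    out = config.copy()
    if sd == 0:
        return out
    rng = np.random.default_rng(seed)
    out.points = out.points + rng.normal(0.0, sd, size=out.points.shape)
    if mesh is not None:
        from .semilandmarks import project_to_surface

        out.points = project_to_surface(out.points, mesh)
    return out


@dataclass
class CohortItem:
    mesh: TriangleMesh
    anchors: LandmarkConfiguration  # ground-truth positions on this mesh
    meta: dict = field(default_factory=dict)


def make_cohort(spec: SynthSpec) -> list[CohortItem]:
    """Generate ``subjects_per_class x classes`` expression meshes.

    Each item carries the deformed mesh, the ground-truth anchor
    configuration (anchor vertices tracked through the deformation) and
    metadata (subject id, expression class).  Deterministic under
    ``spec.seed``.
    """
    base_mesh, base_anchors = make_base_face(spec)
    idx = base_anchors.meta["vertex_indices"]
    items: list[CohortItem] = []
    for ci, cls in enumerate(spec.classes):
        for s in range(spec.subjects_per_class):
            subject_seed = (int(spec.seed) * 100003 + ci * 1009 + s * 7 + 1) % (2**31)
            mesh = apply_expression(
                base_mesh, cls, spec.expression_amplitude, subject_seed,
                spec.subject_variation_sd,
            )
            anchors = LandmarkConfiguration(
                mesh.vertices[idx],
                list(base_anchors.labels),
                ["anchor"] * 16,
                {
                    "vertex_indices": list(idx),
                    "subject": f"{cls}_{s:03d}",
                    "expression": cls,
                },
            )
            items.append(
                CohortItem(mesh, anchors, {"subject": f"{cls}_{s:03d}", "expression": cls})
            )
    return items
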