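"""Mesh and landmark-table I/O.

Geometry enters and leaves the package here: triangle surface meshes as
Wavefront OBJ (mm units, geometry only -- materials, groups, texture and
normal indices are ignored) and landmark configurations as CSV with columns
``label,kind,x,y,z``.  Face indices are 1-based on disk and 0-based in
memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TriangleMesh",
    "LandmarkConfiguration",
    "LANDMARK_KINDS",
    "read_obj",
    "write_obj",
    "read_landmarks",
    "write_landmarks",
]

LANDMARK_KINDS = ("anchor", "surface_semilandmark", "curve_semilandmark")

_MIN_FACE_AREA = 1e-12  # mm^2


class MeshValidationError(ValueError):
    """Raised when a mesh violates its structural invariants."""


class LandmarkValidationError(ValueError):
    """Raised when a landmark table violates its invariants."""


@dataclass
class TriangleMesh:
    """A triangle surface mesh: vertices (n, 3) in mm, faces (m, 3) 0-based."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError(
                f"vertices must be (n, 3), got {self.vertices.shape}"
            )
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError(f"faces must be (m, 3), got {self.faces.shape}")
        if not np.isfinite(self.vertices).all():
            raise MeshValidationError("non-finite vertex coordinate")
        n = len(self.vertices)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise MeshValidationError(
                f"face index out of range [0, {n}): "
                f"min={self.faces.min()}, max={self.faces.max()}"
            )
        areas = self.face_areas()
        if areas.size and areas.min() <= _MIN_FACE_AREA:
            bad = int(np.argmin(areas))
            raise MeshValidationError(
                f"degenerate face {bad} with area {areas[bad]:.3e} mm^2"
            )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """Face corner coordinates, shape (m, 3, 3)."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        t = self.vertices[self.faces]
        cross = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def face_normals(self) -> np.ndarray:
        t = self.vertices[self.faces]
        cross = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        norms = np.linalg.norm(cross, axis=1, keepdims=True)
        return cross / norms

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted one-ring vertex normals (unit length)."""
        t = self.vertices[self.faces]
        cross = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])  # 2*area*normal
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], cross)
        norms = np.linalg.norm(vn, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return vn / norms


@dataclass
class LandmarkConfiguration:
    """An ordered, labeled set of 3D points (mm).

    The point order is the homology order: it must be identical across all
    configurations in a study.  ``kinds`` tags each point as a fixed
    anatomical ``anchor`` or a sliding ``surface_semilandmark`` /
    ``curve_semilandmark``.
    """

    points: np.ndarray
    labels: list[str]
    kinds: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.labels = list(self.labels)
        self.kinds = list(self.kinds)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise LandmarkValidationError(
                f"points must be (k, 3), got {self.points.shape}"
            )
        if not (len(self.labels) == len(self.kinds) == len(self.points)):
            raise LandmarkValidationError("labels/kinds/points length mismatch")
        if not np.isfinite(self.points).all():
            raise LandmarkValidationError("non-finite landmark coordinate")
        for k in self.kinds:
            if k not in LANDMARK_KINDS:
                raise LandmarkValidationError(
                    f"unknown landmark kind {k!r}; expected one of {LANDMARK_KINDS}"
                )

    def __len__(self) -> int:
        return len(self.points)

    @property
    def anchor_mask(self) -> np.ndarray:
        return np.array([k == "anchor" for k in self.kinds])

    def subset(self, mask: np.ndarray) -> "LandmarkConfiguration":
        idx = np.flatnonzero(mask)
        return LandmarkConfiguration(
            self.points[idx],
            [self.labels[i] for i in idx],
            [self.kinds[i] for i in idx],
            dict(self.meta),
        )

    def copy(self) -> "LandmarkConfiguration":
        return LandmarkConfiguration(
            self.points.copy(), list(self.labels), list(self.kinds), dict(self.meta)
        )


class ObjParseError(ValueError):
    pass


def read_obj(path) -> TriangleMesh:
    """Read an ASCII Wavefront OBJ into a :class:`TriangleMesh`.

    Accepts ``f v``, ``f v/vt``, ``f v/vt/vn`` and ``f v//vn`` face dialects;
    texture/normal indices are discarded.  1-based file indices become
    0-based.  A malformed face line raises :class:`ObjParseError` naming the
    line; an out-of-range index raises :class:`MeshValidationError`.
    """
    vertices: list[list[float]] = []
    faces: list[list[int]] = []
    with open(path, "r", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            tag = tokens[0]
            if tag == "v":
                if len(tokens) < 4:
                    raise ObjParseError(f"line {lineno}: vertex needs 3 coordinates")
                try:
                    vertices.append([float(t) for t in tokens[1:4]])
                except ValueError as exc:
                    raise ObjParseError(
                        f"line {lineno}: bad vertex coordinate ({exc})"
                    ) from None
            elif tag == "f":
                if len(tokens) != 4:
                    raise ObjParseError(
                        f"line {lineno}: only triangular faces supported "
                        f"(got {len(tokens) - 1} corners)"
                    )
                corners = []
                for tok in tokens[1:]:
                    head = tok.split("/")[0]
                    try:
                        idx = int(head)
                    except ValueError:
                        raise ObjParseError(
                            f"line {lineno}: bad face index {tok!r}"
                        ) from None
                    if idx == 0:
                        raise ObjParseError(f"line {lineno}: OBJ indices are 1-based")
                    corners.append(idx - 1 if idx > 0 else len(vertices) + idx)
                faces.append(corners)
            # vt/vn/mtllib/usemtl/g/o/s: geometry-only pipeline, skipped
    if not vertices:
        raise ObjParseError(f"{path}: no vertices found")
    return TriangleMesh(np.array(vertices), np.array(faces, dtype=np.int64).reshape(-1, 3))


def write_obj(mesh: TriangleMesh, path) -> None:
    """Write a mesh as ASCII OBJ; round-trips through :func:`read_obj`."""
    if mesh.n_vertices == 0 or mesh.n_faces == 0:
        raise MeshValidationError("refusing to write an empty mesh")
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


_CSV_COLUMNS = ["label", "kind", "x", "y", "z"]


def read_landmarks(path) -> LandmarkConfiguration:
    """Read a landmark CSV (``label,kind,x,y,z``), preserving row order."""
    df = pd.read_csv(path, dtype={"label": str, "kind": str},
                     float_precision="round_trip")
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise LandmarkValidationError(f"{path}: missing column(s) {missing}")
    coords = df[["x", "y", "z"]].to_numpy()
    if not np.issubdtype(coords.dtype, np.number) or not np.isfinite(coords).all():
        raise LandmarkValidationError(f"{path}: non-numeric or non-finite coordinate")
    return LandmarkConfiguration(
        coords.astype(float), df["label"].tolist(), df["kind"].tolist()
    )


def write_landmarks(config: LandmarkConfiguration, path) -> None:
    df = pd.DataFrame(
        {
            "label": config.labels,
            "kind": config.kinds,
            "x": config.points[:, 0],
            "y": config.points[:, 1],
            "z": config.points[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
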