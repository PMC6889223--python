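"""Dense template construction and sliding semi-landmark relaxation.

The pipeline digitizes only 16 anatomical anchor points per face.  Dense,
geometrically homologous coverage comes from a 500-point template built
once on a reference face: the 16 anchors plus (by default) 484
semi-landmarks spread uniformly over the surface by farthest-point
sampling seeded at the pronasale (the nose tip, the most robust and
pose-invariant facial point).

For each target face the template is transferred by an anchor-driven
thin-plate-spline warp and projected onto the target surface; the
semi-landmarks are then *slid* along their local tangent planes (surface
kind) or tangent lines (curve kind) to minimize the TPS bending energy
between the template and the target configuration, re-projecting onto the
surface after every iteration.  Sliding along tangents rather than along
the curved surface itself keeps each iteration a single linear solve.
Six iterations are performed with an exponentially decaying step factor
from 100% down to 5%, recording the initial and final bending energies
E_i and E_f.  Anchors never move.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from .mesh_io import LandmarkConfiguration, TriangleMesh, read_obj
from .tps_warp import bending_energy_matrix, build_tps, warp_points

__all__ = [
    "LandmarkTemplate",
    "SlidingState",
    "build_template",
    "transfer_template",
    "project_to_surface",
    "slide",
    "sliding_schedule",
    "TemplateCapacityError",
]


class TemplateCapacityError(ValueError):
    """The mesh cannot host the requested number of spaced semi-landmarks."""


# ---------------------------------------------------------------------------
# closest-point projection


def _closest_point_chunk(points: np.ndarray, tri: np.ndarray):
    """Exact closest point on each triangle for each query point.

    Vectorized Voronoi-region case analysis (vertex / edge / interior).
    Returns (closest (q, m, 3), squared distance (q, m)).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    p = points[:, None, :]  # (q, 1, 3)

    ap = p - a
    d1 = np.einsum("mk,qmk->qm", ab, ap)
    d2 = np.einsum("mk,qmk->qm", ac, ap)
    bp = p - b
    d3 = np.einsum("mk,qmk->qm", ab, bp)
    d4 = np.einsum("mk,qmk->qm", ac, bp)
    cp = p - c
    d5 = np.einsum("mk,qmk->qm", ab, cp)
    d6 = np.einsum("mk,qmk->qm", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = d1 / (d1 - d3)
        w_ac = d2 / (d2 - d6)
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        denom = va + vb + vc
        v_in = vb / denom
        w_in = vc / denom

    q, m = d1.shape
    out = np.empty((q, m, 3))
    # interior (default)
    out[:] = a + v_in[..., None] * ab + w_in[..., None] * ac
    # edge BC
    mask = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    np.copyto(out, b + w_bc[..., None] * (c - b), where=mask[..., None])
    # edge AC
    mask = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    np.copyto(out, a + w_ac[..., None] * ac, where=mask[..., None])
    # edge AB
    mask = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    np.copyto(out, a + v_ab[..., None] * ab, where=mask[..., None])
    # vertex regions
    mask = (d6 >= 0) & (d5 <= d6)
    np.copyto(out, np.broadcast_to(c, out.shape), where=mask[..., None])
    mask = (d3 >= 0) & (d4 <= d3)
    np.copyto(out, np.broadcast_to(b, out.shape), where=mask[..., None])
    mask = (d1 <= 0) & (d2 <= 0)
    np.copyto(out, np.broadcast_to(a, out.shape), where=mask[..., None])

    d2q = np.einsum("qmk,qmk->qm", points[:, None, :] - out, points[:, None, :] - out)
    return out, d2q


def _project_brute(points: np.ndarray, tri: np.ndarray, chunk: int = 64):
    out = np.empty_like(points)
    face_idx = np.empty(len(points), dtype=np.int64)
    for start in range(0, len(points), chunk):
        sl = slice(start, start + chunk)
        cand, d2 = _closest_point_chunk(points[sl], tri)
        best = np.argmin(d2, axis=1)  # first minimum -> lowest face index
        out[sl] = cand[np.arange(len(best)), best]
        face_idx[sl] = best
    return out, face_idx


def project_to_surface(
    points: np.ndarray,
    mesh: TriangleMesh,
    return_faces: bool = False,
    method: str = "auto",
):
    """Project points onto the exact nearest point of the mesh surface.

    Every triangle is a candidate (vertex/edge/interior closest-point
    cases are all handled exactly); ties are broken by the lowest
    triangle index.  For large meshes a KD-tree prunes triangles that
    provably cannot hold the nearest point (the nearest-vertex distance
    bounds the answer, so only triangles whose centroid lies within that
    bound plus the largest centroid-to-corner radius need testing) --
    the result is identical to the full scan.  ``method`` is ``'auto'``,
    ``'brute'`` or ``'tree'``.  With ``return_faces=True`` also returns
    the owning triangle index per point.
    """
    if mesh.n_faces == 0:
        raise ValueError("cannot project onto an empty mesh")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.triangles()
    if method == "brute" or (method == "auto" and mesh.n_faces <= 512):
        out, face_idx = _project_brute(points, tri)
    else:
        from scipy.spatial import cKDTree

        centroids = tri.mean(axis=1)
        r_max = np.sqrt(((tri - centroids[:, None, :]) ** 2).sum(axis=2)).max()
        vtree = cKDTree(mesh.vertices)
        ctree = cKDTree(centroids)
        ub, _ = vtree.query(points)
        out = np.empty_like(points)
        face_idx = np.empty(len(points), dtype=np.int64)
        for i, (p, bound) in enumerate(zip(points, ub)):
            cand_idx = np.array(
                sorted(ctree.query_ball_point(p, bound + r_max + 1e-9)),
                dtype=np.int64,
            )
            cand, d2 = _closest_point_chunk(p[None, :], tri[cand_idx])
            best = int(np.argmin(d2[0]))
            out[i] = cand[0, best]
            face_idx[i] = cand_idx[best]
    if return_faces:
        return out, face_idx
    return out


# ---------------------------------------------------------------------------
# template


@dataclass
class LandmarkTemplate:
    """The dense reference configuration: 16 anchors + sliding points."""

    mesh: TriangleMesh
    anchors: LandmarkConfiguration
    semilandmarks: LandmarkConfiguration
    min_spacing: float = 1.5  # mm
    seed: int = 0
    mesh_path: str | None = None

    @property
    def n_points(self) -> int:
        return len(self.anchors) + len(self.semilandmarks)

    @property
    def config(self) -> LandmarkConfiguration:
        """Full configuration in homology order: anchors first, then semis."""
        return LandmarkConfiguration(
            np.vstack([self.anchors.points, self.semilandmarks.points]),
            self.anchors.labels + self.semilandmarks.labels,
            self.anchors.kinds + self.semilandmarks.kinds,
        )

    def to_json(self, path, mesh_path: str | None = None) -> None:
        cfg = self.config
        doc = {
            "mesh_path": mesh_path or self.mesh_path,
            "min_spacing": self.min_spacing,
            "seed": self.seed,
            "n_anchors": len(self.anchors),
            "labels": cfg.labels,
            "kinds": cfg.kinds,
            "points": cfg.points.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path, mesh: TriangleMesh | None = None) -> "LandmarkTemplate":
        path = Path(path)
        with open(path) as fh:
            doc = json.load(fh)
        if mesh is None:
            if not doc.get("mesh_path"):
                raise ValueError("template JSON has no mesh_path and no mesh supplied")
            mesh = read_obj(path.parent / doc["mesh_path"])
        pts = np.asarray(doc["points"], dtype=float)
        na = int(doc["n_anchors"])
        anchors = LandmarkConfiguration(
            pts[:na], doc["labels"][:na], doc["kinds"][:na]
        )
        semis = LandmarkConfiguration(pts[na:], doc["labels"][na:], doc["kinds"][na:])
        return cls(mesh, anchors, semis, float(doc["min_spacing"]), int(doc["seed"]),
                   doc.get("mesh_path"))


def _farthest_point_sample(
    vertices: np.ndarray, seed_idx: int, exclude: set[int], n: int
) -> list[int]:
    """Euclidean farthest-point sampling over mesh vertices, spreading
    outward from the seed vertex."""
    dist = np.linalg.norm(vertices - vertices[seed_idx], axis=1)
    dist[list(exclude)] = -np.inf
    chosen: list[int] = []
    for _ in range(n):
        idx = int(np.argmax(dist))
        if not np.isfinite(dist[idx]) or dist[idx] < 0:
            break
        chosen.append(idx)
        dist = np.minimum(dist, np.linalg.norm(vertices - vertices[idx], axis=1))
        dist[idx] = -np.inf
    return chosen


def build_template(
    mesh: TriangleMesh,
    anchors: LandmarkConfiguration,
    n_semi: int = 484,
    min_spacing: float = 1.5,
    seed: int = 0,
) -> LandmarkTemplate:
    """Build the dense template on a reference face.

    Semi-landmarks are seeded by farthest-point sampling over the mesh
    vertices starting at the pronasale anchor, which spreads them
    uniformly across the surface, then spacing-repaired so every pairwise
    gap is at least ``min_spacing`` mm.  Deterministic under ``seed``.
    """
    if "pr" not in anchors.labels:
        raise ValueError("anchor set must include the pronasale ('pr')")
    # hexagonal packing bound: each point claims ~ sqrt(3)/2 * s^2 of area
    capacity = mesh.area() / (np.sqrt(3.0) / 2.0 * min_spacing**2)
    if n_semi > capacity:
        raise TemplateCapacityError(
            f"mesh area {mesh.area():.0f} mm^2 cannot host {n_semi} semi-landmarks "
            f"at {min_spacing} mm spacing (capacity ~{int(capacity)})"
        )
    if n_semi == 0:
        semis = LandmarkConfiguration(np.empty((0, 3)), [], [])
        return LandmarkTemplate(mesh, anchors.copy(), semis, min_spacing, seed)

    vertices = mesh.vertices
    anchor_idx = anchors.meta.get("vertex_indices")
    if anchor_idx is None:
        anchor_idx = [
            int(np.argmin(np.linalg.norm(vertices - p, axis=1))) for p in anchors.points
        ]
    pr_idx = anchor_idx[anchors.labels.index("pr")]
    exclude = set(int(i) for i in anchor_idx)

    chosen = _farthest_point_sample(vertices, pr_idx, exclude, n_semi)
    # spacing repair: drop points violating min_spacing (farthest-first
    # order means earlier points have priority), then refill
    kept: list[int] = []
    pool = list(chosen)
    while pool:
        idx = pool.pop(0)
        pts = vertices[kept]
        if len(kept) == 0 or np.linalg.norm(pts - vertices[idx], axis=1).min() >= min_spacing:
            kept.append(idx)
    if len(kept) < n_semi:
        extra = _farthest_point_sample(
            vertices, pr_idx, exclude | set(chosen), 4 * (n_semi - len(kept))
        )
        for idx in extra:
            if len(kept) == n_semi:
                break
            gaps = np.linalg.norm(vertices[kept] - vertices[idx], axis=1)
            if gaps.min() >= min_spacing:
                kept.append(idx)
    if len(kept) < n_semi:
        raise TemplateCapacityError(
            f"could only place {len(kept)} of {n_semi} semi-landmarks at "
            f"{min_spacing} mm spacing"
        )
    semis = LandmarkConfiguration(
        vertices[kept],
        [f"semi_{i:03d}" for i in range(n_semi)],
        ["surface_semilandmark"] * n_semi,
        {"vertex_indices": [int(i) for i in kept]},
    )
    return LandmarkTemplate(mesh, anchors.copy(), semis, min_spacing, seed)


def transfer_template(
    template: LandmarkTemplate,
    target_mesh: TriangleMesh,
    target_anchors: LandmarkConfiguration,
) -> LandmarkConfiguration:
    """Transfer the template to a target face via an anchor-driven TPS.

    The 16 template anchors are mapped onto the (label-matched) target
    anchors with an exact-interpolation TPS (beta = 0); all semi-landmarks
    ride through the warp and are then projected onto the nearest point of
    the target surface.  Anchors are copied verbatim; output order equals
    the template's homology order.
    """
    order = []
    for lab in template.anchors.labels:
        try:
            order.append(target_anchors.labels.index(lab))
        except ValueError:
            raise ValueError(f"target anchors missing label {lab!r}") from None
    tgt_anchor_pts = target_anchors.points[order]

    model = build_tps(template.anchors.points, tgt_anchor_pts, beta=0.0)
    warped = warp_points(model, template.semilandmarks.points)
    projected = project_to_surface(warped, target_mesh)

    cfg = template.config
    points = np.vstack([tgt_anchor_pts, projected])
    return LandmarkConfiguration(
        points, cfg.labels, cfg.kinds, dict(target_anchors.meta)
    )


# ---------------------------------------------------------------------------
# sliding


def sliding_schedule(iterations: int = 6, start: float = 1.0, end: float = 0.05) -> np.ndarray:
    """Geometric step-factor decay from ``start`` to ``end``.

    For the default 6 iterations this is [1.0, 0.549, 0.302, 0.166,
    0.091, 0.05]: a full first step, 5% by the last.
    """
    t = np.arange(iterations)
    return start * (end / start) ** (t / (iterations - 1))


@dataclass
class SlidingState:
    """Bookkeeping for one sliding run."""

    step_factors: np.ndarray
    E_i: float = np.nan
    E_f: float = np.nan
    energy_trace: list[dict] = field(default_factory=list)

    @property
    def delta(self) -> float:
        """E_f - E_i over the complete run (negative = energy released)."""
        return self.E_f - self.E_i


def _barycentric(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    v0, v1 = b - a, c - a
    v2 = points - a
    d00 = np.einsum("ij,ij->i", v0, v0)
    d01 = np.einsum("ij,ij->i", v0, v1)
    d11 = np.einsum("ij,ij->i", v1, v1)
    d20 = np.einsum("ij,ij->i", v2, v0)
    d21 = np.einsum("ij,ij->i", v2, v1)
    denom = d00 * d11 - d01 * d01
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    return np.column_stack([1.0 - v - w, v, w])


def _surface_normals_at(points: np.ndarray, mesh: TriangleMesh,
                        vertex_normals: np.ndarray) -> np.ndarray:
    """Smooth surface normal at each (on-surface) point: barycentric
    interpolation of area-weighted vertex normals of the owning face."""
    proj, faces = project_to_surface(points, mesh, return_faces=True)
    tri = mesh.vertices[mesh.faces[faces]]
    bary = np.clip(_barycentric(proj, tri), 0.0, 1.0)
    vn = vertex_normals[mesh.faces[faces]]  # (n, 3 corners, 3)
    n = np.einsum("ik,ikj->ij", bary, vn)
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    return n / norms


def _tangent_frames(
    config: LandmarkConfiguration,
    slide_idx: np.ndarray,
    mesh: TriangleMesh,
    vertex_normals: np.ndarray,
) -> np.ndarray:
    """Per sliding point, a (3, 2) tangent basis.

    Surface semi-landmarks get two orthonormal tangent-plane vectors from
    the interpolated surface normal.  Curve semi-landmarks get a single
    tangent direction estimated from the neighbouring points of the same
    contiguous curve run (second column zeroed).
    """
    normals = _surface_normals_at(config.points[slide_idx], mesh, vertex_normals)
    frames = np.zeros((len(slide_idx), 3, 2))
    kinds = [config.kinds[i] for i in slide_idx]
    for row, (gi, n) in enumerate(zip(slide_idx, normals)):
        if not np.isfinite(n).all():
            raise ValueError(
                f"degenerate tangent frame at landmark {config.labels[gi]!r}"
            )
        if kinds[row] == "curve_semilandmark":
            t = _curve_tangent(config, gi)
            frames[row, :, 0] = t
        else:
            ref = np.eye(3)[np.argmin(np.abs(n))]
            t1 = np.cross(n, ref)
            t1 /= np.linalg.norm(t1)
            t2 = np.cross(n, t1)
            frames[row, :, 0] = t1
            frames[row, :, 1] = t2
    return frames


def _curve_tangent(config: LandmarkConfiguration, i: int) -> np.ndarray:
    """Polyline tangent from the adjacent curve points in homology order."""
    prev_pt = config.points[i - 1] if i > 0 and config.kinds[i - 1] == "curve_semilandmark" else None
    next_pt = (
        config.points[i + 1]
        if i + 1 < len(config) and config.kinds[i + 1] == "curve_semilandmark"
        else None
    )
    if prev_pt is None and next_pt is None:
        raise ValueError(
            f"degenerate tangent frame at landmark {config.labels[i]!r}: "
            "isolated curve semi-landmark"
        )
    a = prev_pt if prev_pt is not None else config.points[i]
    b = next_pt if next_pt is not None else config.points[i]
    t = b - a
    norm = np.linalg.norm(t)
    if norm <= 0:
        raise ValueError(
            f"degenerate tangent frame at landmark {config.labels[i]!r}: zero tangent"
        )
    return t / norm


def _config_energy(points: np.ndarray, B: np.ndarray) -> float:
    return float(np.einsum("ic,ij,jc->", points, B, points))


def slide(
    template: LandmarkTemplate,
    target_mesh: TriangleMesh,
    initial: LandmarkConfiguration,
    iterations: int = 6,
    schedule: np.ndarray | None = None,
    tol: float | None = None,
) -> tuple[LandmarkConfiguration, SlidingState]:
    """Relax semi-landmarks on the target by bending-energy minimization.

    Each iteration (1) estimates tangent frames at the current on-surface
    positions, (2) solves the linear minimization of the template
    bending-energy quadratic form over tangent displacements with anchors
    constrained to zero, (3) scales the step by the decaying schedule
    factor, and (4) re-projects onto the target surface.  Returns the
    homologous configuration plus a :class:`SlidingState` with the energy
    trace, E_i and E_f.

    ``tol``, if given, stops early once the relative energy change drops
    below it; by default the fixed number of iterations always runs.
    """
    cfg = template.config
    if initial.labels != cfg.labels or len(initial) != template.n_points:
        raise ValueError("initial configuration does not match template order")
    if schedule is None:
        schedule = sliding_schedule(iterations)
    schedule = np.asarray(schedule, dtype=float)
    if len(schedule) != iterations:
        raise ValueError("schedule length must equal iterations")

    B = bending_energy_matrix(cfg.points)
    anchor_mask = np.array([k == "anchor" for k in cfg.kinds])
    slide_idx = np.flatnonzero(~anchor_mask)
    ns = len(slide_idx)
    vn = target_mesh.vertex_normals()

    out = initial.copy()
    state = SlidingState(step_factors=schedule)
    state.E_i = _config_energy(out.points, B)
    prev_energy = state.E_i

    b_ss = B[np.ix_(slide_idx, slide_idx)]
    for it, step in enumerate(schedule):
        frames = _tangent_frames(out, slide_idx, target_mesh, vn)
        grad = (B @ out.points)[slide_idx]  # (ns, 3)
        m = np.einsum("ica,ij,jcb->iajb", frames, b_ss, frames).reshape(2 * ns, 2 * ns)
        g = np.einsum("ica,ic->ia", frames, grad).reshape(2 * ns)
        # PSD normal equations; a negligible ridge keeps the solve a fast
        # Cholesky even when curve tangents leave zero columns
        eps = 1e-12 * max(np.trace(m), 1.0) / len(m)
        try:
            t = scipy.linalg.solve(m + eps * np.eye(len(m)), -g, assume_a="pos")
        except scipy.linalg.LinAlgError:
            t, *_ = np.linalg.lstsq(m, -g, rcond=None)
        if not np.isfinite(t).all():
            bad = int(np.argmax(~np.isfinite(t)) // 2)
            raise ValueError(
                f"non-finite sliding solve at landmark "
                f"{cfg.labels[slide_idx[bad]]!r}"
            )
        disp = np.einsum("ica,ia->ic", frames, t.reshape(ns, 2))
        # monotone-descent guard: re-projection onto a curved surface can
        # restore more energy than the tangent step released; halve the
        # step until the projected update does not increase the energy,
        # reverting if no fraction helps
        start = out.points[slide_idx].copy()
        e_start = prev_energy
        e_pre = e_post = e_start
        trial = float(step)
        for _ in range(5):
            out.points[slide_idx] = start + trial * disp
            e_pre = _config_energy(out.points, B)
            out.points[slide_idx] = project_to_surface(out.points[slide_idx], target_mesh)
            e_post = _config_energy(out.points, B)
            if e_post <= e_start + 1e-12 * max(e_start, 1.0):
                break
            trial *= 0.5
        else:
            out.points[slide_idx] = start
            e_pre = e_post = e_start
            trial = 0.0
        state.energy_trace.append(
            {"iteration": it + 1, "step": trial,
             "energy_pre_projection": e_pre, "energy_post_projection": e_post}
        )
        if tol is not None and prev_energy > 0 and abs(prev_energy - e_post) < tol * prev_energy:
            break
        prev_energy = e_post

    state.E_f = _config_energy(out.points, B)
    return out, state
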