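import numpy as np
import pytest

from conftest import random_rotation
from morphowarp import semilandmarks as sl
from morphowarp import synthetic_faces as sf
from morphowarp.mesh_io import LandmarkConfiguration, TriangleMesh
from morphowarp.tps_warp import bending_energy_matrix


def planar_grid(nx=15, ny=19, half_w=60.0, half_h=80.0):
    xs = np.linspace(-half_w, half_w, nx)
    ys = np.linspace(-half_h, half_h, ny)
    gx, gy = np.meshgrid(xs, ys)
    verts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])
    faces = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            a = j * nx + i
            faces.append((a, a + 1, a + nx + 1))
            faces.append((a, a + nx + 1, a + nx))
    return TriangleMesh(verts, np.array(faces))


# ---------------------------------------------------------------------------
# projection


def test_point_on_face_unchanged(base_face):
    mesh, _ = base_face
    tri = mesh.triangles()[10]
    p = tri.mean(axis=0)
    out = sl.project_to_surface(p, mesh)
    np.testing.assert_allclose(out[0], p, atol=1e-12)


def test_projection_onto_plane_is_perpendicular_foot():
    mesh = planar_grid()
    p = np.array([[3.7, -12.2, 5.0]])
    out = sl.project_to_surface(p, mesh)
    np.testing.assert_allclose(out[0], [3.7, -12.2, 0.0], atol=1e-12)


def test_projection_matches_bruteforce_scan(base_face, rng):
    mesh, _ = base_face
    pts = rng.uniform(-70, 70, size=(60, 3))
    pts[:, 2] = rng.uniform(-10, 60, size=60)
    fast, f_fast = sl.project_to_surface(pts, mesh, return_faces=True, method="tree")
    brute, f_brute = sl.project_to_surface(pts, mesh, return_faces=True, method="brute")
    np.testing.assert_array_equal(fast, brute)
    np.testing.assert_array_equal(f_fast, f_brute)


def test_projection_vertex_edge_cases_against_optimizer(rng):
    """Exact closest points (vertex/edge/interior) vs constrained optimization
    over barycentric coordinates on every triangle."""
    from scipy.optimize import minimize

    mesh = TriangleMesh(
        rng.normal(size=(5, 3)) * 10,
        [[0, 1, 2], [0, 2, 3], [0, 3, 4]],
    )
    tri = mesh.triangles()
    for p in rng.normal(size=(10, 3)) * 15:
        best = np.inf
        for t in tri:
            def obj(bc):
                w = np.array([1 - bc[0] - bc[1], bc[0], bc[1]])
                return ((w @ t - p) ** 2).sum()
            res = minimize(obj, [0.3, 0.3], bounds=[(0, 1), (0, 1)],
                           constraints=[{"type": "ineq",
                                         "fun": lambda bc: 1 - bc[0] - bc[1]}],
                           method="SLSQP")
            best = min(best, res.fun)
        out = sl.project_to_surface(p, mesh)
        d = ((out[0] - p) ** 2).sum()
        # SLSQP satisfies constraints only to its own tolerance, so allow
        # a matching slack in the comparison
        assert d <= best * (1 + 1e-6) + 1e-8


def test_empty_mesh_rejected():
    mesh = TriangleMesh(np.zeros((3, 3)) + np.eye(3), np.zeros((0, 3), dtype=int))
    with pytest.raises(ValueError, match="empty"):
        sl.project_to_surface(np.zeros((1, 3)), mesh)


# ---------------------------------------------------------------------------
# template


def test_template_counts_and_spacing(base_face):
    from scipy.spatial.distance import pdist

    mesh, anchors = base_face
    tpl = sl.build_template(mesh, anchors, n_semi=84, min_spacing=1.5, seed=0)
    assert tpl.n_points == 100
    assert len(tpl.anchors) == 16
    assert pdist(tpl.semilandmarks.points).min() >= 1.5
    # semi-landmarks on the surface
    proj = sl.project_to_surface(tpl.semilandmarks.points, mesh)
    np.testing.assert_allclose(proj, tpl.semilandmarks.points, atol=1e-6)
    # anchors are not in the sliding set
    assert all(k == "surface_semilandmark" for k in tpl.semilandmarks.kinds)


def test_full_template_500_points(base_face):
    from scipy.spatial.distance import pdist

    mesh, anchors = base_face
    tpl = sl.build_template(mesh, anchors, n_semi=484, min_spacing=1.5, seed=0)
    assert tpl.n_points == 500
    assert pdist(tpl.semilandmarks.points).min() >= 1.5


def test_template_zero_semis(base_face):
    mesh, anchors = base_face
    tpl = sl.build_template(mesh, anchors, n_semi=0)
    assert tpl.n_points == 16


def test_template_capacity_error(base_face):
    mesh, anchors = base_face
    with pytest.raises(sl.TemplateCapacityError):
        sl.build_template(mesh, anchors, n_semi=484, min_spacing=50.0)


def test_template_json_round_trip(base_face, tmp_path):
    from morphowarp.mesh_io import write_obj

    mesh, anchors = base_face
    tpl = sl.build_template(mesh, anchors, n_semi=20, seed=5)
    write_obj(mesh, tmp_path / "ref.obj")
    tpl.to_json(tmp_path / "tpl.json", mesh_path="ref.obj")
    back = sl.LandmarkTemplate.from_json(tmp_path / "tpl.json")
    np.testing.assert_allclose(back.config.points, tpl.config.points)
    assert back.config.labels == tpl.config.labels
    np.testing.assert_allclose(back.mesh.vertices, mesh.vertices)


# ---------------------------------------------------------------------------
# transfer


def test_transfer_identity(base_face, small_template):
    mesh, anchors = base_face
    out = sl.transfer_template(small_template, mesh, anchors)
    np.testing.assert_allclose(out.points, small_template.config.points, atol=1e-8)
    assert out.labels == small_template.config.labels


def test_transfer_rigid_rotation(base_face, small_template, rng):
    mesh, anchors = base_face
    rot = random_rotation(rng)
    shift = np.array([12.0, -5.0, 30.0])
    tmesh = TriangleMesh(mesh.vertices @ rot + shift, mesh.faces)
    tanchors = LandmarkConfiguration(
        anchors.points @ rot + shift, anchors.labels, anchors.kinds, anchors.meta
    )
    out = sl.transfer_template(small_template, tmesh, tanchors)
    expected = small_template.config.points @ rot + shift
    np.testing.assert_allclose(out.points, expected, atol=1e-6)


def test_transfer_lands_on_target_surface(base_face, small_template):
    mesh, anchors = base_face
    item = sf.make_cohort(
        sf.SynthSpec(seed=8, subjects_per_class=1, classes=("Surprise",),
                     mesh_resolution=900)
    )[0]
    out = sl.transfer_template(small_template, item.mesh, item.anchors)
    proj = sl.project_to_surface(out.points[16:], item.mesh)
    np.testing.assert_allclose(out.points[16:], proj, atol=1e-6)


def test_transfer_missing_anchor_label(base_face, small_template):
    mesh, anchors = base_face
    bad = LandmarkConfiguration(anchors.points, ["q"] + anchors.labels[1:], anchors.kinds)
    with pytest.raises(ValueError, match="missing label"):
        sl.transfer_template(small_template, mesh, bad)


# ---------------------------------------------------------------------------
# sliding


def test_schedule_endpoints_and_values():
    s = sl.sliding_schedule(6)
    np.testing.assert_allclose(s, [1.0, 0.549, 0.302, 0.166, 0.091, 0.05], atol=5e-4)
    assert np.all(np.diff(s) < 0)


def test_slide_identity_target_no_motion(base_face, small_template):
    mesh, anchors = base_face
    initial = small_template.config
    out, state = sl.slide(small_template, mesh, initial)
    assert state.E_i < 1e-10
    assert state.E_f < 1e-10
    np.testing.assert_allclose(out.points, initial.points, atol=1e-6)


def test_slide_anchors_bitwise_fixed_and_energy_released(base_face, small_template):
    item = sf.make_cohort(
        sf.SynthSpec(seed=8, subjects_per_class=1, classes=("Happy",),
                     mesh_resolution=900)
    )[0]
    initial = sl.transfer_template(small_template, item.mesh, item.anchors)
    out, state = sl.slide(small_template, item.mesh, initial)
    np.testing.assert_array_equal(out.points[:16], initial.points[:16])
    assert state.E_f <= state.E_i
    assert len(state.energy_trace) == 6
    # each tangent update lowers the energy from its starting value
    before = state.E_i
    for tr in state.energy_trace:
        assert tr["energy_pre_projection"] <= before + 1e-12
        before = tr["energy_post_projection"]


def test_slide_first_iteration_matches_qp_oracle(base_face):
    """The tangent-space solve equals a brute-force quadratic program on a
    reduced template with a planar target (projection is then a no-op for
    in-plane motion, exposing the raw solve)."""
    mesh, anchors = base_face
    tpl = sl.build_template(mesh, anchors, n_semi=20, min_spacing=1.5, seed=1)
    target = planar_grid()
    t_anchors = LandmarkConfiguration(
        np.column_stack([anchors.points[:, 0], anchors.points[:, 1], np.zeros(16)]),
        anchors.labels, anchors.kinds,
    )
    initial = sl.transfer_template(tpl, target, t_anchors)
    out, state = sl.slide(tpl, target, initial, iterations=1, schedule=[1.0])

    # oracle: explicit QP over in-plane displacements of the 20 semis
    b = bending_energy_matrix(tpl.config.points)
    y = initial.points.copy()
    ns = 20
    n = 36
    e3 = np.kron(np.eye(3), b)
    u = np.zeros((3 * n, 2 * ns))
    for j in range(ns):
        u[0 * n + 16 + j, 2 * j] = 1.0  # e_x
        u[1 * n + 16 + j, 2 * j + 1] = 1.0  # e_y
    yv = y.T.ravel()
    t, *_ = np.linalg.lstsq(u.T @ e3 @ u, -u.T @ e3 @ yv, rcond=None)
    oracle = y.copy()
    oracle[16:, 0] += t[0::2]
    oracle[16:, 1] += t[1::2]
    np.testing.assert_allclose(out.points, oracle, atol=1e-6)


def test_slide_rigid_recovery(base_face, small_template, rng):
    """Transfer+slide of a rigidly moved template recovers the moved points."""
    mesh, anchors = base_face
    rot = random_rotation(rng)
    shift = np.array([-4.0, 9.0, 17.0])
    tmesh = TriangleMesh(mesh.vertices @ rot + shift, mesh.faces)
    tanchors = LandmarkConfiguration(
        anchors.points @ rot + shift, anchors.labels, anchors.kinds
    )
    initial = sl.transfer_template(small_template, tmesh, tanchors)
    out, state = sl.slide(small_template, tmesh, initial)
    expected = small_template.config.points @ rot + shift
    assert np.abs(out.points - expected).max() < 1e-4
    assert state.E_f < 1e-8


def test_slide_rejects_mismatched_configuration(base_face, small_template):
    mesh, _ = base_face
    cfg = small_template.config
    bad = LandmarkConfiguration(cfg.points[:-1], cfg.labels[:-1], cfg.kinds[:-1])
    with pytest.raises(ValueError, match="match template"):
        sl.slide(small_template, mesh, bad)


def test_curve_semilandmarks_slide_along_polyline(base_face):
    """Curve-kind semi-landmarks get a 1D tangent and still relax."""
    mesh, anchors = base_face
    tpl = sl.build_template(mesh, anchors, n_semi=20, min_spacing=1.5, seed=1)
    # tag a contiguous run as a curve
    for i in range(5):
        tpl.semilandmarks.kinds[i] = "curve_semilandmark"
    item = sf.make_cohort(
        sf.SynthSpec(seed=8, subjects_per_class=1, classes=("Happy",),
                     mesh_resolution=900)
    )[0]
    initial = sl.transfer_template(tpl, item.mesh, item.anchors)
    out, state = sl.slide(tpl, item.mesh, initial)
    assert state.E_f <= state.E_i
    assert np.isfinite(out.points).all()
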