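import numpy as np
import pytest

from conftest import random_rotation
from morphowarp import procrustes_stats as ps


def similarity_copy(shape, rng, scale=True):
    rot = random_rotation(rng)
    s = rng.uniform(0.5, 2.0) if scale else 1.0
    return s * shape @ rot + rng.normal(size=3) * 10


# ---------------------------------------------------------------------------
# OPA


def test_opa_similarity_copy_distance_zero(rng):
    a = rng.normal(size=(12, 3)) * 10
    b = similarity_copy(a, rng)
    aligned, d = ps.opa_align(a, b)
    assert d < 1e-10
    np.testing.assert_allclose(aligned, a, atol=1e-9)


def test_opa_identity(rng):
    a = rng.normal(size=(8, 3))
    aligned, d = ps.opa_align(a, a)
    np.testing.assert_allclose(aligned, a, atol=1e-12)
    assert d < 1e-12


def test_opa_matches_rotation_space_optimizer(rng):
    """Procrustes distance equals a brute-force minimum over a rotation
    parameterization (axis-angle) plus analytic scale/translation."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    a = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10.0]])
    b = a.copy()
    b[3] += [1.5, -2.0, 0.5]
    _, d = ps.opa_align(a, b)

    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)

    def obj(rv):
        r = Rotation.from_rotvec(rv).as_matrix()
        br = bc @ r.T
        s = (br * ac).sum() / (br**2).sum()
        return ((s * br - ac) ** 2).sum()

    best = min(
        minimize(obj, x0, method="Nelder-Mead",
                 options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000}).fun
        for x0 in (np.zeros(3), np.array([0.5, -0.2, 0.1]), np.array([-1.0, 1.0, 2.0]))
    )
    np.testing.assert_allclose(d**2, best, rtol=1e-6)


def test_opa_never_reflects(rng):
    a = rng.normal(size=(10, 3)) * 5
    b = a.copy()
    b[:, 0] = -b[:, 0]  # mirror image
    aligned, d = ps.opa_align(a, b)
    assert d > 1e-3  # a reflection would give d = 0


def test_opa_coincident_points_rejected():
    with pytest.raises(ValueError, match="coincident"):
        ps.opa_align(np.zeros((5, 3)), np.zeros((5, 3)))


# ---------------------------------------------------------------------------
# GPA


def test_gpa_rigid_copies_collapse(rng):
    base = rng.normal(size=(20, 3)) * 10
    configs = np.stack([similarity_copy(base, rng) for _ in range(6)])
    res = ps.gpa(configs)
    assert res.procrustes_distances.max() < 1e-8
    # unit centroid size and centered
    for a in res.aligned:
        assert abs(np.sqrt((a**2).sum()) - 1) < 1e-10
        assert np.abs(a.mean(axis=0)).max() < 1e-10
    np.testing.assert_allclose(res.consensus, res.aligned.mean(axis=0), atol=1e-9)


def test_gpa_two_shapes_consensus_equidistant(rng):
    a = rng.normal(size=(10, 3)) * 10
    b = a + rng.normal(scale=0.5, size=a.shape)
    res = ps.gpa(np.stack([a, b]))
    d0 = np.linalg.norm(res.aligned[0] - res.consensus)
    d1 = np.linalg.norm(res.aligned[1] - res.consensus)
    np.testing.assert_allclose(d0, d1, rtol=1e-6)


def test_gpa_similarity_and_order_invariance(rng):
    base = rng.normal(size=(15, 3)) * 10
    configs = np.stack([base + rng.normal(scale=0.8, size=base.shape) for _ in range(8)])
    res = ps.gpa(configs)
    transformed = np.stack([similarity_copy(c, rng) for c in configs])
    res_t = ps.gpa(transformed)
    assert np.abs(res.aligned - res_t.aligned).max() < 1e-8
    perm = rng.permutation(8)
    res_p = ps.gpa(configs[perm])
    assert np.abs(res.aligned[perm] - res_p.aligned).max() < 1e-8


def test_gpa_consensus_matches_frechet_mean_oracle(rng):
    """GPA consensus agrees with a direct optimization of the summed
    squared rotation-only Procrustes distances over mean shapes."""
    from scipy.linalg import orthogonal_procrustes
    from scipy.optimize import minimize

    base = rng.normal(size=(6, 3)) * 5
    configs = np.stack([base + rng.normal(scale=0.4, size=base.shape) for _ in range(10)])
    res = ps.gpa(configs)

    unit = []
    for c in configs:
        cc = c - c.mean(axis=0)
        unit.append(cc / np.sqrt((cc**2).sum()))

    def obj(flat):
        m = flat.reshape(6, 3)
        m = m - m.mean(axis=0)
        m = m / np.sqrt((m**2).sum())
        total = 0.0
        for x in unit:
            r, _ = orthogonal_procrustes(x, m)
            if np.linalg.det(r) < 0:  # no reflections
                u, s, vt = np.linalg.svd(x.T @ m)
                d = np.ones(3)
                d[-1] = -1
                r = (u * d) @ vt
            total += ((x @ r - m) ** 2).sum()
        return total

    sol = minimize(obj, res.consensus.ravel(), method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000,
                            "maxfev": 40000})
    # GPA consensus is already at the oracle optimum
    gpa_val = obj(res.consensus.ravel())
    assert gpa_val <= sol.fun + 1e-9


def test_gpa_input_validation():
    with pytest.raises(ValueError):
        ps.gpa(np.zeros((1, 5, 3)))


# ---------------------------------------------------------------------------
# Procrustes ANOVA


def _simulate_design(rng, k=20, g=6, s=3, r=2, subject_sd=1.0, error_sd=0.1,
                     class_sd=0.0, size=50.0):
    base = rng.normal(size=(k, 3)) * size
    data, e_l, i_l, r_l = [], [], [], []
    for ci in range(g):
        class_eff = rng.normal(scale=class_sd, size=(k, 3))
        for si in range(s):
            subj = base + class_eff + rng.normal(scale=subject_sd, size=(k, 3))
            for ri in range(r):
                data.append(subj + rng.normal(scale=error_sd, size=(k, 3)))
                e_l.append(f"c{ci}")
                i_l.append(f"c{ci}s{si}")
                r_l.append(ri)
    return np.stack(data), e_l, i_l, r_l


def test_anova_degrees_of_freedom_500_landmarks():
    """The balanced 6-class, 18-subject, 2-replicate design on 500
    landmarks has 7465 expression and 26,874 error df (shape dimension
    3*500 - 7 = 1493)."""
    k, g, n, r = 500, 6, 18, 2
    shape_dim = 3 * k - 7
    assert shape_dim * (g - 1) == 7465
    rng = np.random.default_rng(0)
    data, e_l, i_l, r_l = _simulate_design(rng, k=k, g=g, s=n // g, r=r)
    aligned = ps.gpa(data).aligned
    tab = ps.procrustes_anova(aligned, e_l, i_l, r_l)
    assert tab.effects["Expression"]["DF"] == 7465
    assert tab.effects["Error"]["DF"] == 26874
    assert tab.effects["Individual"]["DF"] == shape_dim * (n - g)


def test_anova_identical_replicates_zero_error(rng):
    data, e_l, i_l, r_l = _simulate_design(rng, error_sd=0.0)
    aligned = ps.gpa(data).aligned
    tab = ps.procrustes_anova(aligned, e_l, i_l, r_l)
    assert tab.effects["Error"]["SS"] < 1e-16
    # MS = SS/DF and additive decomposition
    total = sum(tab.effects[e]["SS"] for e in tab.effects)
    flat = aligned.reshape(len(aligned), -1)
    ss_total = ((flat - flat.mean(axis=0)) ** 2).sum()
    np.testing.assert_allclose(total, ss_total, rtol=1e-8)
    for e, row in tab.effects.items():
        np.testing.assert_allclose(row["MS"], row["SS"] / row["DF"], rtol=1e-12)


def test_anova_error_stratum_smallest_and_monotone(rng):
    """Error receives the smallest mean square, and the estimated error
    variance grows with the simulated digitization noise."""
    last = 0.0
    for sd in (0.05, 0.1, 0.2):
        data, e_l, i_l, r_l = _simulate_design(rng, error_sd=sd, subject_sd=1.0)
        aligned = ps.gpa(data).aligned
        tab = ps.procrustes_anova(aligned, e_l, i_l, r_l)
        ms = {e: tab.effects[e]["MS"] for e in tab.effects}
        assert ms["Error"] == min(ms.values())
        assert ms["Error"] > last
        last = ms["Error"]


def test_anova_unbalanced_rejected(rng):
    data, e_l, i_l, r_l = _simulate_design(rng)
    with pytest.raises(ValueError, match="unbalanced"):
        ps.procrustes_anova(data[:-1], e_l[:-1], i_l[:-1], r_l[:-1])


# ---------------------------------------------------------------------------
# PERMANOVA


def test_permanova_matches_skbio(rng):
    pytest.importorskip("skbio")
    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.distance import permanova as sk_permanova

    pts = rng.normal(size=(24, 4))
    pts[12:] += 1.0
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(axis=2))
    groups = ["a"] * 12 + ["b"] * 12
    f_ours, _ = ps.permanova(d, groups, n_perm=99, seed=0)
    res = sk_permanova(DistanceMatrix(d), groups, permutations=99)
    np.testing.assert_allclose(f_ours, res["test statistic"], rtol=1e-10)


def test_permanova_separated_clusters_minimal_p(rng):
    pts = np.vstack([rng.normal(size=(10, 3)), rng.normal(size=(10, 3)) + 100.0])
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(axis=2))
    groups = ["a"] * 10 + ["b"] * 10
    f, p = ps.permanova(d, groups, n_perm=999, seed=1)
    assert p == pytest.approx(1 / 1000)


def test_permanova_deterministic_and_label_invariant(rng):
    pts = rng.normal(size=(18, 3))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(axis=2))
    groups = np.array(["x"] * 6 + ["y"] * 6 + ["z"] * 6)
    r1 = ps.permanova(d, groups, n_perm=199, seed=5)
    r2 = ps.permanova(d, groups, n_perm=199, seed=5)
    assert r1 == r2
    renamed = np.array([{"x": "g1", "y": "g2", "z": "g3"}[g] for g in groups])
    r3 = ps.permanova(d, renamed, n_perm=199, seed=5)
    assert r1 == r3


def test_permanova_single_group_rejected(rng):
    pts = rng.normal(size=(6, 3))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(axis=2))
    with pytest.raises(ValueError, match="2 groups"):
        ps.permanova(d, ["a"] * 6, n_perm=9, seed=0)


# ---------------------------------------------------------------------------
# one-way coordinate ANOVA


def test_oneway_df_for_500_landmarks(rng):
    data = rng.normal(size=(5, 1500))
    f, df, p = ps.oneway_coordinate_anova(data)
    assert df == 1499


def test_oneway_all_equal_f_zero():
    data = np.ones((4, 30))
    data += np.arange(4)[:, None]  # within-level spread only
    f, df, p = ps.oneway_coordinate_anova(data)
    assert f == 0.0


def test_oneway_matches_scipy(rng):
    from scipy.stats import f_oneway

    data = rng.normal(size=(7, 12)) + np.arange(12)
    f, df, p = ps.oneway_coordinate_anova(data)
    ref = f_oneway(*[data[:, j] for j in range(12)])
    np.testing.assert_allclose(f, ref.statistic, rtol=1e-10)
    np.testing.assert_allclose(p, ref.pvalue, rtol=1e-8)
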