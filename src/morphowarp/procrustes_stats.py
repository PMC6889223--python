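"""Generalized Procrustes analysis and landmark-error statistics.

Shape analysis starts by removing position, orientation and size:
ordinary Procrustes alignment (OPA) superimposes one configuration onto
another by least squares; generalized Procrustes analysis (GPA)
iteratively aligns a whole sample to its consensus.  On the aligned
coordinates, a Goodall-type Procrustes ANOVA decomposes shape variation
across a balanced nested design (expression > individual > digitizing
replicate), with each factor's degrees of freedom multiplied by the shape
space dimension 3k - 7 (translation 3, rotation 3, scale 1 removed from
3k coordinates).  The localization (digitizing) error is the Error
stratum of that table.  Group differences are additionally tested with a
permutation PERMANOVA on the matrix of pairwise Procrustes distances, and
with a per-group one-way ANOVA across the flattened coordinate variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "GPAResult",
    "AnovaTable",
    "opa_align",
    "gpa",
    "procrustes_anova",
    "permanova",
    "oneway_coordinate_anova",
]

SHAPE_DIM_REMOVED = 7  # translation 3 + rotation 3 + scale 1 (3D similarity)


def _centroid_size(points: np.ndarray) -> float:
    c = points - points.mean(axis=0)
    return float(np.sqrt((c**2).sum()))


def opa_align(
    a: np.ndarray, b: np.ndarray, allow_scale: bool = True
) -> tuple[np.ndarray, float]:
    """Ordinary Procrustes superimposition of ``b`` onto ``a``.

    Optimal translation + rotation (+ scale if ``allow_scale``) by SVD
    with determinant correction, so reflections are never used.  Returns
    the aligned copy of ``b`` and the Procrustes distance (root summed
    squared differences after alignment).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("configurations must have equal landmark counts")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    nb = (bc**2).sum()
    if nb <= 0 or (ac**2).sum() <= 0:
        raise ValueError("all-coincident landmark configuration")
    u, s, vt = np.linalg.svd(bc.T @ ac)
    d = np.sign(np.linalg.det(u @ vt))
    dd = np.ones(3)
    dd[-1] = d
    rot = (u * dd) @ vt
    scale = (s * dd).sum() / nb if allow_scale else 1.0
    aligned = scale * bc @ rot + a.mean(axis=0)
    dist = float(np.linalg.norm(aligned - a))
    return aligned, dist


@dataclass
class GPAResult:
    """Procrustes-aligned sample: (n, k, 3) unit-centroid-size shapes."""

    aligned: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    procrustes_distances: np.ndarray
    n_iterations: int = 0


def _principal_axes_orient(aligned: np.ndarray, consensus: np.ndarray):
    """Rotate the whole aligned sample so the consensus sits in a
    deterministic principal-axes pose (removes the arbitrary global
    rotation left by GPA, making results order-invariant)."""
    c = consensus - consensus.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    rot = vt.T
    if np.linalg.det(rot) < 0:
        rot[:, 2] = -rot[:, 2]
    cr = c @ rot
    # sign convention per axis: positive third moment (fall back to the
    # largest-magnitude coordinate) on axes 1-2; axis 3 fixed by det=+1
    flips = np.ones(3)
    for ax in range(2):
        skew = (cr[:, ax] ** 3).sum()
        if abs(skew) < 1e-12:
            skew = cr[np.argmax(np.abs(cr[:, ax])), ax]
        if skew < 0:
            flips[ax] = -1.0
    flips[2] = np.linalg.det(rot * flips)
    rot = rot * flips
    return aligned @ rot, consensus @ rot


def gpa(configs: np.ndarray, allow_scale: bool = True, tol: float = 1e-10,
        max_iter: int = 100) -> GPAResult:
    """Generalized Procrustes analysis of n configurations (n, k, 3).

    Each configuration is centered and scaled to unit centroid size, then
    iteratively rotated onto the running consensus until the consensus
    stabilizes.  The output pose is normalized to the consensus principal
    axes so the result is invariant (to ~1e-8) to input order and to
    arbitrary similarity transforms of the inputs.
    """
    configs = np.asarray(configs, dtype=float)
    if configs.ndim != 3 or configs.shape[2] != 3:
        raise ValueError("configs must be (n, k, 3)")
    n = len(configs)
    if n < 2:
        raise ValueError("need at least 2 configurations")

    sizes = np.array([_centroid_size(c) for c in configs])
    aligned = np.stack([
        (c - c.mean(axis=0)) / (s if allow_scale else 1.0)
        for c, s in zip(configs, sizes)
    ])
    # rotation-only alignment of unit-centroid-size shapes: sizes stay
    # exactly 1 (partial-Procrustes convention)
    consensus = aligned[0].copy()
    n_it = 0
    for n_it in range(1, max_iter + 1):
        for i in range(n):
            aligned[i], _ = opa_align(consensus, aligned[i], allow_scale=False)
        new_consensus = aligned.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        if allow_scale:
            new_consensus /= _centroid_size(new_consensus)
        change = np.linalg.norm(new_consensus - consensus)
        consensus = new_consensus
        if change < tol:
            break
    else:
        raise RuntimeError(
            f"GPA did not converge in {max_iter} iterations (last change {change:.3e})"
        )

    aligned, consensus = _principal_axes_orient(aligned, aligned.mean(axis=0))

    flat = aligned.reshape(n, -1)
    diff = flat[:, None, :] - flat[None, :, :]
    dists = np.sqrt((diff**2).sum(axis=2))
    return GPAResult(aligned, consensus, sizes, dists, n_it)


@dataclass
class AnovaTable:
    """Procrustes ANOVA effects: SS, MS, DF, F, p per stratum."""

    effects: dict[str, dict] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.effects).T[["SS", "MS", "DF", "F", "p"]]

    def to_dict(self) -> dict:
        return {k: dict(v) for k, v in self.effects.items()}


def procrustes_anova(
    aligned: np.ndarray,
    expression: list[str],
    individual: list[str],
    replicate: list,
) -> AnovaTable:
    """Goodall-type nested Procrustes ANOVA on aligned coordinates.

    Design: expression (g levels) > individual (n subjects, nested in
    expression) > digitizing replicate (r per subject); must be balanced.
    Sums of squares are squared Procrustes deviations at each nesting
    level, summed over all 3k coordinates; degrees of freedom are the
    factor df times the shape-space dimension 3k - 7.  F tests each
    stratum over the one nested below it (Expression over Individual,
    Individual over Error).
    """
    aligned = np.asarray(aligned, dtype=float)
    n_obs, k, _ = aligned.shape
    expression = np.asarray(expression)
    individual = np.asarray(individual)
    replicate = np.asarray(replicate)
    if not (len(expression) == len(individual) == len(replicate) == n_obs):
        raise ValueError("factor length mismatch")

    subjects = pd.unique(individual)
    classes = pd.unique(expression)
    g = len(classes)
    n_subj = len(subjects)
    subj_class = {}
    for subj in subjects:
        cls = set(expression[individual == subj])
        if len(cls) != 1:
            raise ValueError(f"individual {subj!r} appears in multiple expressions")
        subj_class[subj] = next(iter(cls))
    reps_per_subj = {s: (individual == s).sum() for s in subjects}
    r_set = set(reps_per_subj.values())
    subj_per_class = {c: sum(1 for s in subjects if subj_class[s] == c) for c in classes}
    if len(r_set) != 1 or len(set(subj_per_class.values())) != 1:
        raise ValueError("unbalanced design: equal subjects/class and replicates/subject required")
    r = r_set.pop()
    s_per_class = next(iter(set(subj_per_class.values())))
    if r < 2:
        raise ValueError("need >= 2 replicates per subject for the Error stratum")

    flat = aligned.reshape(n_obs, -1)
    grand = flat.mean(axis=0)
    class_means = {c: flat[expression == c].mean(axis=0) for c in classes}
    subj_means = {s: flat[individual == s].mean(axis=0) for s in subjects}

    ss_exp = s_per_class * r * sum(
        ((class_means[c] - grand) ** 2).sum() for c in classes
    )
    ss_ind = r * sum(
        ((subj_means[s] - class_means[subj_class[s]]) ** 2).sum() for s in subjects
    )
    ss_err = sum(
        ((flat[i] - subj_means[individual[i]]) ** 2).sum() for i in range(n_obs)
    )

    shape_dim = 3 * k - SHAPE_DIM_REMOVED
    df_exp = shape_dim * (g - 1)
    df_ind = shape_dim * (n_subj - g)
    df_err = shape_dim * n_subj * (r - 1)

    ms_exp, ms_ind, ms_err = ss_exp / df_exp, ss_ind / df_ind, ss_err / df_err
    with np.errstate(divide="ignore"):  # zero Error SS gives F = inf
        f_exp = ms_exp / ms_ind
        f_ind = ms_ind / ms_err
    p_exp = float(scipy.stats.f.sf(f_exp, df_exp, df_ind))
    p_ind = float(scipy.stats.f.sf(f_ind, df_ind, df_err))

    return AnovaTable(
        {
            "Expression": {"SS": float(ss_exp), "MS": float(ms_exp), "DF": int(df_exp),
                           "F": float(f_exp), "p": p_exp},
            "Individual": {"SS": float(ss_ind), "MS": float(ms_ind), "DF": int(df_ind),
                           "F": float(f_ind), "p": p_ind},
            "Error": {"SS": float(ss_err), "MS": float(ms_err), "DF": int(df_err),
                      "F": None, "p": None},
        }
    )


def _pseudo_f(d2: np.ndarray, groups: np.ndarray, labels: np.ndarray) -> float:
    n = len(groups)
    a = len(labels)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for lab in labels:
        idx = np.flatnonzero(groups == lab)
        ng = len(idx)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(ng, 1)].sum() / ng
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(
    distances: np.ndarray,
    groups,
    n_perm: int = 9999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation MANOVA (Anderson pseudo-F) on a distance matrix.

    The pseudo-F is computed from squared distances; the p-value is
    ``(count of permuted F >= observed + 1) / (n_perm + 1)`` under random
    relabeling of group membership.  Deterministic under ``seed``.
    """
    distances = np.asarray(distances, dtype=float)
    n = len(distances)
    if distances.shape != (n, n) or not np.allclose(distances, distances.T):
        raise ValueError("distances must be a symmetric square matrix")
    groups = np.asarray(groups)
    if len(groups) != n:
        raise ValueError("groups length must match distance matrix")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() < 1:
        raise ValueError("empty group")

    d2 = distances**2
    f_obs = _pseudo_f(d2, groups, labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _pseudo_f(d2, groups[perm], labels) >= f_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return float(f_obs), float(p)


def oneway_coordinate_anova(data: np.ndarray) -> tuple[float, int, float]:
    """One-way ANOVA across the flattened coordinate variables.

    ``data`` is (samples, 3k); the 3k coordinate variables are the factor
    levels and the samples are the observations within each level, so a
    500-landmark study has df = 1499.  Returns (F, df_between, p).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be (samples, coordinates)")
    s, p = data.shape
    if s < 2:
        raise ValueError("need >= 2 samples per coordinate variable")
    col_means = data.mean(axis=0)
    grand = data.mean()
    ss_between = s * ((col_means - grand) ** 2).sum()
    ss_within = ((data - col_means) ** 2).sum()
    df1 = p - 1
    df2 = p * (s - 1)
    f = (ss_between / df1) / (ss_within / df2)
    pval = float(scipy.stats.f.sf(f, df1, df2))
    return float(f), df1, pval
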