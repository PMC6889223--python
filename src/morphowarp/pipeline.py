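"""End-to-end pipeline: simulate -> template -> warp+slide -> GPA ->
ANOVA/PERMANOVA -> PCA -> LDA.

Every stochastic stage derives its seed from the global seed plus the
stage name, so a rerun of the same configuration bit-reproduces every
artifact (verified by the checksum manifest written alongside).
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classify, features, procrustes_stats, semilandmarks, synthetic_faces
from .mesh_io import write_landmarks, write_obj

__all__ = ["RunConfig", "run_pipeline", "derive_seed"]

logger = logging.getLogger(__name__)


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Configuration for one full pipeline run."""

    seed: int
    classes: tuple[str, ...] = synthetic_faces.EXPRESSION_CLASSES
    subjects_per_class: int = 3
    replicates: int = 2
    expression_amplitude: float = 3.0
    subject_variation_sd: float = 1.0
    digitization_sd: float = 0.1
    mesh_resolution: int = 2000
    n_semi: int = 484
    min_spacing: float = 1.5
    iterations: int = 6
    schedule_start: float = 1.0
    schedule_end: float = 0.05
    beta: float = 0.0
    pca_select: str = "bartlett"  # bartlett | broken_stick | integer
    cv_scheme: str = "split"  # split | loocv
    train_frac: float = 0.70
    metric: str = "euclidean"  # euclidean | cosine
    n_perm: int = 999

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("config must provide a seed")
        self.classes = tuple(self.classes)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "seed" not in doc:
            raise ValueError(f"{path}: config missing mandatory 'seed'")
        return cls(**doc)

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["classes"] = list(doc["classes"])
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


@dataclass
class PipelineResult:
    outdir: Path
    anova: procrustes_stats.AnovaTable
    permanova_f: float
    permanova_p: float
    pca: features.PCModel
    n_pcs_used: int
    report: classify.ClassReport
    sliding_states: list = field(default_factory=list)
    checksums: dict = field(default_factory=dict)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir) -> PipelineResult:
    """Run the whole flow, writing flat CSV/JSON artifacts under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lm_dir = outdir / "landmarks"
    lm_dir.mkdir(exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    spec = synthetic_faces.SynthSpec(
        seed=derive_seed(config.seed, "simulate"),
        subjects_per_class=config.subjects_per_class,
        classes=config.classes,
        expression_amplitude=config.expression_amplitude,
        subject_variation_sd=config.subject_variation_sd,
        digitization_sd=config.digitization_sd,
        replicates=config.replicates,
        mesh_resolution=config.mesh_resolution,
    )
    base_mesh, base_anchors = synthetic_faces.make_base_face(spec)
    cohort = synthetic_faces.make_cohort(spec)
    logger.info("simulate: %d meshes (%d classes x %d subjects)",
                len(cohort), len(config.classes), config.subjects_per_class)

    template = semilandmarks.build_template(
        base_mesh, base_anchors, n_semi=config.n_semi,
        min_spacing=config.min_spacing,
        seed=derive_seed(config.seed, "template"),
    )
    write_obj(base_mesh, outdir / "template_mesh.obj")
    template.to_json(outdir / "template.json", mesh_path="template_mesh.obj")
    logger.info("template: %d points (%d anchors + %d semi-landmarks)",
                template.n_points, len(template.anchors), len(template.semilandmarks))

    schedule = semilandmarks.sliding_schedule(
        config.iterations, config.schedule_start, config.schedule_end
    )
    configs, expr, subj, reps, states = [], [], [], [], []
    for item in cohort:
        for rep in range(config.replicates):
            dig_seed = derive_seed(
                config.seed, f"digitize:{item.meta['subject']}:{rep}"
            )
            anchors = synthetic_faces.digitize(
                item.anchors, config.digitization_sd, dig_seed, mesh=item.mesh
            )
            initial = semilandmarks.transfer_template(template, item.mesh, anchors)
            slid, state = semilandmarks.slide(
                template, item.mesh, initial,
                iterations=config.iterations, schedule=schedule,
            )
            name = f"{item.meta['subject']}_rep{rep}"
            slid.meta.update(item.meta, replicate=rep)
            write_landmarks(slid, lm_dir / f"{name}.csv")
            configs.append(slid.points)
            expr.append(item.meta["expression"])
            subj.append(item.meta["subject"])
            reps.append(rep)
            states.append(state)
            logger.info("warp %s: E_i=%.4g E_f=%.4g", name, state.E_i, state.E_f)

    gpa_res = procrustes_stats.gpa(np.stack(configs))
    n_obs, k, _ = gpa_res.aligned.shape
    flat = gpa_res.aligned.reshape(n_obs, -1)
    np.savetxt(outdir / "aligned.csv", flat, delimiter=",")

    anova = procrustes_stats.procrustes_anova(gpa_res.aligned, expr, subj, reps)
    with open(outdir / "anova.json", "w") as fh:
        json.dump(anova.to_dict(), fh, indent=1)
    logger.info("anova: SS=%s", {k_: round(v["SS"], 6) for k_, v in anova.effects.items()})

    # PERMANOVA and classification use one configuration per subject
    # (first replicate) so observations are independent
    first_rep = np.array(reps) == 0
    sub_dist = gpa_res.procrustes_distances[np.ix_(first_rep, first_rep)]
    sub_expr = np.array(expr)[first_rep]
    perm_f, perm_p = procrustes_stats.permanova(
        sub_dist, sub_expr, n_perm=config.n_perm,
        seed=derive_seed(config.seed, "permanova"),
    )
    with open(outdir / "permanova.json", "w") as fh:
        json.dump({"F": perm_f, "p": perm_p, "n_perm": config.n_perm}, fh, indent=1)

    pca = features.fit_pca(flat[first_rep])
    nonzero = pca.eigenvalues[: pca.n_nonzero]
    if config.pca_select == "broken_stick":
        n_pcs = max(features.broken_stick_count(nonzero), 2)
    elif config.pca_select == "bartlett":
        n_pcs = max(features.bartlett_count(nonzero, int(first_rep.sum())), 2)
    else:
        n_pcs = int(config.pca_select)
    # the point of the PCA reduction is a stable, nonsingular within-class
    # scatter: keep p comfortably below the training fold's within-class
    # degrees of freedom (80% margin)
    n_samples = int(first_rep.sum())
    n_train = int(config.train_frac * n_samples) if config.cv_scheme == "split" else n_samples - 1
    cap = max(int(0.8 * (n_train - len(config.classes))), 2)
    n_pcs = min(n_pcs, pca.n_nonzero, cap)
    scores = pca.scores[:, :n_pcs]
    eig_table = np.column_stack([
        pca.eigenvalues, pca.proportions, np.cumsum(pca.proportions)
    ])
    np.savetxt(outdir / "pcs.csv", np.column_stack([scores]), delimiter=",")
    np.savetxt(outdir / "eigenvalues.csv", eig_table, delimiter=",",
               header="eigenvalue,proportion,cumulative", comments="")
    logger.info("pca: %d non-zero PCs, %d retained", pca.n_nonzero, n_pcs)

    report = classify.cross_validate(
        scores, sub_expr, scheme=config.cv_scheme, train_frac=config.train_frac,
        seed=derive_seed(config.seed, "classify"), metric=config.metric,
    )
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)
    logger.info("classify: accuracy %.2f%%", 100 * report.accuracy)

    checksums = {
        p.name: _checksum(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "checksums.json"
    }
    with open(outdir / "checksums.json", "w") as fh:
        json.dump(checksums, fh, indent=1)

    return PipelineResult(
        outdir, anova, perm_f, perm_p, pca, n_pcs, report, states, checksums
    )
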