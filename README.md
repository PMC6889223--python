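# morphowarp

Dense homologous 3D facial landmarking by **multi-point thin-plate-spline
warping with sliding semi-landmarks**, plus the downstream
geometric-morphometrics statistics and expression classification.

## What problem this solves

Landmark-based shape analysis of the human face needs hundreds of
corresponding points per surface, but only ~16 facial points (pronasale,
endo-/exocanthion, cheilion, ...) have anatomical definitions that can be
digitized reliably. `morphowarp` builds a 500-point template — 16
anatomical anchors plus 484 surface semi-landmarks spread from the
pronasale by farthest-point sampling — on one reference face, and carries
it to every target face automatically:

1. **Warp**: a 3D thin-plate spline h(p) = Ψ(p)K + pΓ with kernel
   Ψ_w(p) = ‖p − s_w‖, fitted to the 16 anchor pairs (exact interpolation
   at β = 0), maps all semi-landmarks to the target, followed by exact
   closest-point projection onto the target surface.
2. **Slide**: six iterations relax the semi-landmarks along their local
   tangent planes to minimize the TPS **bending energy** between template
   and target (a linear solve per iteration, anchors fixed), with a
   geometrically decaying step 100% → 5% and re-projection after every
   step; the energy drops from E_i to E_f ≤ E_i.

The resulting configurations are geometrically homologous and feed the
standard chain: generalized Procrustes analysis (GPA), Goodall-type
nested **Procrustes ANOVA** for digitization error (DF = (3k−7) × factor
df), **PERMANOVA** on Procrustes distances, covariance **PCA** with
broken-stick / Bartlett retention, and multi-class **LDA** (canonical
variates, Σ̂_b Φ = λ Σ̂_w Φ) with nearest-centroid classification.

Real facial-scan collections are license-restricted, so the package ships
a parametric synthetic-face generator (`synthetic_faces`) with analytic
ground truth: six expression classes deforming fixed facial regions,
per-subject variation, and noisy duplicate digitizations — every stage is
testable offline.

## Worked example

Run the whole pipeline on a synthetic cohort (6 expressions × 8 subjects,
digitized twice, 100-point template, ~900-vertex meshes):

```python
from morphowarp.pipeline import RunConfig, run_pipeline

cfg = RunConfig(seed=42, subjects_per_class=8, replicates=2,
                mesh_resolution=900, n_semi=84, n_perm=999)
res = run_pipeline(cfg, "out/")
print(res.anova.to_frame())
```

prints (about half a minute on one core):

```
                  SS            MS       DF          F    p
Expression  0.008918  6.087392e-06   1465.0  10.660589  0.0
Individual  0.007027  5.710183e-07  12306.0  85.566731  0.0
Error       0.000094  6.673369e-09  14064.0        NaN  NaN
```

Reading the table: shape variation is decomposed over the nested design
expression > individual > digitization replicate, each stratum's DF
multiplied by the shape-space dimension 3k − 7 = 293 (k = 100 points).
The Error stratum — pure digitization/landmarking noise — carries by far
the smallest mean square (6.7e-09 vs 5.7e-07), i.e. the automatic
landmarks are reproducible well below the level of real between-subject
differences, and the expression effect stands out above individuals
(Goodall F ≈ 10.7). The same run reports `PERMANOVA F=10.551 p=0.0010`
(group separation on Procrustes distances), retains 13 of 47 PCs by
Bartlett's test, classifies the held-out 30% at 75% accuracy at the
default signal-to-variation level, and logs the bending-energy drop of
each slide (e.g. `E_i=0.4610 → E_f=0.4532` for the first face).

The same flow is scriptable from the shell:

```sh
morphowarp run --config run.yaml --out out/
morphowarp simulate --spec spec.yaml --out cohort/
morphowarp template --mesh ref.obj --anchors ref_anchors.csv --out tpl.json
morphowarp warp --template tpl.json --target face.obj \
                --anchors face_anchors.csv --out landmarks.csv
morphowarp gpa / anova / permanova / pca / classify ...
```

All artifacts are flat CSV/JSON; a rerun with the same config reproduces
them bit-for-bit (checksums written alongside).

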