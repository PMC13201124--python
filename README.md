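# ith3d — intratumoral-heterogeneity scoring of CT lesions

`ith3d` quantifies how spatially fragmented the internal subregions
("habitats") of a lung nodule are on CT, and feeds that quantity into a
stacking-ensemble classifier for preoperative prediction of visceral
pleural invasion (VPI) in lung adenocarcinoma. It is aimed at radiomics
researchers who want a testable, fully synthetic-data-verifiable
implementation of the ITH-score construction: per-voxel local radiomic
descriptors from a small sliding window, unsupervised k-means subregion
clustering, connected-component analysis, and a dimensionless dispersion
score.

## The score

For a lesion whose in-mask voxels are partitioned into clusters
l = 1..n_c, with V_total the total voxel count, m_l the number of
connected components of cluster l (26-connectivity: faces, edges,
corners) and V_l,max the size of its largest component,

    3D ITH score = 1 − (1/V_total) · Σ_l ( V_l,max / m_l )

The 2D score is the same construction on the largest axial slice with
2×2 windows and 8-connectivity, with areas S in place of volumes V. Both
scores lie in [0, 1): a score of 0 means every subregion is one connected
block; the score rises as subregions shatter into many dispersed pieces.
Component sizes are raw voxel counts, so the score is invariant under
uniform voxel spacing, axis flips and rotations, and cluster relabeling.

Descriptors per voxel cover first-order statistics and the gray-level
texture-matrix families (GLCM, GLRLM, GLSZM, GLDM, NGTDM), computed in
closed form over the 2×2(×2) window and z-scored per lesion; clustering
uses k-means with the cluster count fixed a priori at n_c = 6.

## Worked example

Score a synthetic nodule phantom with six planted subregions, two of them
split in two fragments each:

```python
from ith3d import (make_phantom, separable_phantom_spec,
                   analytic_ith_on_labels, compute_ith)
from ith3d.score import ITHConfig

spec = separable_phantom_spec(6, fragments=(1, 1, 1, 1, 2, 2), seed=7)
lesion, planted = make_phantom(spec)
result = compute_ith(lesion, ITHConfig(nc=6, seed=7))
print(f"planted 3D ITH score : {analytic_ith_on_labels(planted):.4f}")
print(f"pipeline 3D ITH score: {result.score_3d:.4f}")
```

prints

```
planted 3D ITH score : 0.2171
pipeline 3D ITH score: 0.2171
```

The planted score is computed analytically from the ground-truth label
map (8 fragments across 6 subregions → score 0.2171); the pipeline —
descriptor extraction, clustering, component counting — recovers it
exactly on this separable phantom. The 2D score of the same phantom is
high (0.99): the phantom is layered, so its largest axial slice lies
inside a single subregion and the fixed six-cluster partition fragments
pure noise — a useful reminder that the single-slice score depends
strongly on what the chosen slice contains.

Train and evaluate the VPI stacking ensemble on a synthetic cohort with
the published class imbalance (13.4% VPI-positive):

```python
from ith3d.cohorts import CohortSpec, make_cohort, split_cohort
from ith3d.ensemble import PipelineConfig, fast_grids, train_stack
from ith3d.metrics import evaluate

table = make_cohort(CohortSpec(n=1301, prevalence=0.134, seed=0))
dev, ext = split_cohort(table)          # centers 1+2 develop, center 3 external
model = train_stack(dev, PipelineConfig(seed=0, grids=fast_grids()))
rep = evaluate(model.predict_proba(ext), ext["vpi"].to_numpy())
print(f"AUC={rep.auc:.3f}  PR-AUC={rep.pr_auc:.3f}  accuracy={rep.accuracy:.3f}")
```

prints

```
AUC=0.745  PR-AUC=0.374  accuracy=0.866
```

With the planted effect sizes (3D ITH score strongest, then nodule size
and density) the external AUC of 0.745 is well above chance, and the
PR-AUC of 0.374 is well above the 0.134 prevalence — the pattern, not the
magnitude, of the published findings; magnitudes depend entirely on the
planted effect strengths.

The same pipeline is scriptable from the shell:

```
ith3d synth phantom --out-dir ph --subregions 6 --seed 3
ith3d score --image ph/image.nii.gz --mask ph/mask.nii.gz --out scores.csv
ith3d synth cohort --out cohort.csv --n 1301 --seed 2
ith3d train --cohort cohort.csv --out model.joblib --fast
ith3d evaluate --model model.joblib --cohort cohort.csv --out eval.json
ith3d explain --model model.joblib --cohort cohort.csv --out-dir report
```

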