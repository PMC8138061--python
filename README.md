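# msdiffusion

Single-shell diffusion-MRI analysis of white-matter lesions: classical DTI,
single-shell HARDI (ssHARDI) microstructure including an ODF-energy
statistic, deterministic tractography maps, 3D lesion / contralateral-NAWM
/ core–shell ROI construction, and SVM-based feature ranking — exercised
end to end on synthetic multi-tensor DWI phantoms.

## Who this is for

Multiple-sclerosis lesions damage tissue along two partly independent
axes: diffusivity (demyelination and cellularity change raise MD and RD)
and orientation structure (axonal injury and inflammation increase
intra-voxel orientational complexity).  A clinical single-shell
acquisition (b = 1000 s/mm², 3 b0 + 45 directions, 2 mm isotropic) can
feed both classical tensor metrics and sub-voxel HARDI models.  This
package implements that combined analysis as a reusable, fully tested
pipeline for methodologists who want to study which diffusion features
carry which kind of lesion contrast — without needing patient data, since
a phantom generator with known ground truth is part of the package.

## The eleven features

Per voxel, from one single-shell acquisition:

| family | features | model |
| --- | --- | --- |
| DTI | MD, FA, AD, RD | log-linear least-squares tensor fit |
| ssHARDI | ODI, ICVF, density, diameter | linearized dictionary fit (Watson sticks + van Gelderen cylinders + ball, per-voxel NNLS) |
| ssHARDI | ODF_energy | analytic Q-ball ODF; energy = Σᵢ log(pᵢ²) with pᵢ the normal density fitted to the voxel's ODF amplitudes |
| tractography | FDi, FTi | FACT streamlines (35° angular threshold); pass-through and endpoint counts |

ROI-level analysis builds lesion / mirrored contralateral NAWM pairs
(26-connectivity components, exact left–right flip, lesion-overlap
exclusion) and erosion-defined core / single-voxel shell splits, extracts
ROI-mean feature tables, ranks features by linear SVM recursive feature
elimination (C = 1, 100 constructions), and evaluates nested top-k models
by stratified 10-fold cross-validation with McNemar and DeLong model
comparisons.

## Worked example

```python
import numpy as np
from msdiffusion import make_gradient_table, simulate_dwi, compute_feature_maps
from msdiffusion.phantom import Lesion, default_phantom
from msdiffusion.pipeline import subject_rois

gtab = make_gradient_table(n_dirs=45, n_b0=3, b=1000.0, seed=7)
spec = default_phantom(
    lesions=(Lesion(center=(10, 20, 8), radius=3.0,
                    eigvals=(1.2e-3, 0.6e-3, 0.6e-3)),),
    grid_shape=(40, 40, 16), snr=30,
)
dwi, truth = simulate_dwi(spec, gtab, seed=1)
maps = compute_feature_maps(dwi, truth["wm_mask"])   # all 11 features
rois = subject_rois(truth, dwi.voxel_size)

pair = rois.pairs[0]
for name in ("MD", "FA", "RD", "ODI", "ODF_energy"):
    print(name, maps[name].values[pair.lesion_mask].mean(),
          maps[name].values[pair.nawm_mask].mean())
```

Output (one demyelination-like lesion, SNR 30):

```
   feature     lesion       NAWM
        MD  0.0007977  0.0007717
        FA      0.413     0.7975
        RD  0.0005961  0.0003035
       ODI     0.1412    0.02357
ODF_energy     -14.47      -14.7
lesion voxels: 123  core: 19  shell: 104
```

The lesion's elevated radial diffusivity halves FA and raises RD roughly
twofold against the mirrored NAWM ROI, while ODI picks up the apparent
dispersion increase — the expected signature of a diffusivity-dominated
lesion.  The 123-voxel lesion is large enough to encapsulate a 3×3×3
cube, so it splits into a 19-voxel core and a 104-voxel single-voxel-thick
shell (19 + 104 = 123: core and shell always partition the lesion).

Cohort-level studies use the two built-in conditions:

```python
from msdiffusion import orientation_contrast_cohort, simulate_cohort
from msdiffusion.pipeline import cohort_tables, rank_and_evaluate
from msdiffusion.features import FEATURE_NAMES

subjects = simulate_cohort(orientation_contrast_cohort(seed=11))
tables = cohort_tables(subjects)
ranker, curve = rank_and_evaluate(tables["lesion_nawm"], FEATURE_NAMES, seed=11)
print(ranker.summary(FEATURE_NAMES).head(4))
```

which on the orientation-dominated condition ranks `ODF_energy`, `FA`,
`RD`, `ODI` in the top four (mean ranks 1.00, 2.10, 2.90, 4.00 for
seed 11), and on the diffusivity-dominated core–shell condition puts `MD`
and `RD` in the top three — the qualitative ordering expected when lesion
contrast is orientational vs. diffusivity-driven.

A command-line interface mirrors the library:

```bash
msdiffusion simulate --seed 3 --out sim/
msdiffusion rois --lesions sim/lesion_labels.nii.gz --wm sim/wm_mask.nii.gz --out rois/
msdiffusion fit-dti --dwi sim/dwi.nii.gz --mask sim/wm_mask.nii.gz --out maps/
msdiffusion track --dwi sim/dwi.nii.gz --mask sim/wm_mask.nii.gz --out maps/ --fa-stop 0.15 --angle 35
```

## Documentation

`docs/methods.md` describes the models, defaults, phantom design and its
limitations in detail.
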