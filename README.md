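# cytomorph

Quantitative 4D morphometry of dividing cells from membrane-marker
time-lapse volumes.

Large dividing cells — the motivating system is *Drosophila* primary
spermatocytes expressing a plasma-membrane marker (PLCδ-PH-GFP), imaged by
spinning-disk microscopy at 0.166 µm/px in XY, 1 µm Z spacing, one stack
per minute — undergo a stereotyped sequence during division: the roughly
spherical cell elongates along the spindle axis at anaphase, a cleavage
furrow ingresses, and the cell pinches into two daughters. Because volume
is conserved, division *requires* new plasma membrane: a sphere dividing
into two spheres of half its volume gains a factor 2^(1/3) ≈ 1.26 of
surface area. `cytomorph` measures this whole sequence from image stacks
and provides the statistics to compare genotypes (e.g. wild type against
exocyst-mutant cells whose elongation and furrowing fail).

The pipeline:

1. **Synthetic scenes** (`cytomorph.scene`) — 4D movies of dividing cells
   with *analytically known* geometry: two spherical lobes bridged by a
   circular-arc neck whose waist radius controls furrow ingression, a
   bright membrane shell, spindle-like internal features, anisotropic
   voxels, PSF blur and read noise. Ground-truth labels and exact
   per-frame descriptors accompany every movie, so segmentation and
   morphometry are benchmarked against closed forms.
2. **Segmentation** (`cytomorph.segmentation`) — 3D Gaussian filtering
   (σ\_xy = 0.166 µm, σ\_z = 0.2 µm by default) followed by a seeded 3D
   watershed on the intensity landscape; for movies, seeds for frame *t*
   are obtained by eroding the labels of frame *t−1*, with bright internal
   features (spindles) masked out of the seeds.
3. **Morphometry** (`cytomorph.morphometry`) — per cell and frame:
   - volume = Σ voxel volumes;
   - surface area = Σ exposed voxel-face areas;
   - aspect ratio = (max pairwise distance between surface positions) /
     (diameter of the largest inscribed sphere, via the 3D Euclidean
     distance transform): 1 for a sphere, 2 for two just-touching equal
     spheres;
   - convex hull volume ratio CHVR = hull volume / cell volume, a global
     measure of furrow ingression: 1 for convex cells, 1.1 when the
     concavity holds 10% of the volume, 1.25 for two tangent equal
     spheres;
   - furrow diameter = equivalent-circle diameter of the narrowest
     cross-section along the long axis.
4. **Alignment & statistics** (`cytomorph.alignment`) — traces are aligned
   at the "shoulder" of the aspect-ratio curve (the first time point whose
   forward 10-min window slope exceeds the backward one by 20% in wild
   type, 60% in mutants); the same inflection on CHVR calls cytokinesis
   onset. Cohorts are averaged with SEM, and genotypes compared with a
   pooled-variance two-sample Student t-test on per-cell percent changes.

## Worked example

Calibration of the voxel descriptors against closed forms (20 voxels per
lobe radius here; accuracy improves with resolution):

```sh
$ cytomorph calibrate --resolution 20
            shape  chvr_analytic  chvr_voxel  ar_analytic  ar_voxel  surface_um2_analytic  surface_um2_voxel_faces
           sphere           1.00      1.0000          1.0    1.0395                113.10                   170.64
  tangent_spheres           1.25      1.2535          2.0    2.0684                226.19                   338.58
dumbbell_chvr_1.1           1.10      1.1036          2.0    2.0629                218.49                   317.16
```

The voxel CHVR matches the analytic value to well under 1%; the aspect
ratio carries the sub-voxel bias of the distance-transform minor axis
(4% at 20 voxels/radius, halving as resolution doubles). The exposed-face
surface area is deliberately the stated voxel-face estimator — it
overestimates smooth areas by a shape-stable factor (3/2 for a sphere), so
*ratios* between cells are preserved.

Cohort comparison on synthetic traces (8 wild-type vs 8 arrest cells,
1% descriptor noise):

```python
from cytomorph import (AlignmentSpec, align_and_average, compare_groups,
                       peak_rate, percent_change, simulate_trace_cohort)

wt = align_and_average(simulate_trace_cohort(8, "wildtype", seed=1))
mut = align_and_average(simulate_trace_cohort(8, "mutant_arrest", seed=2),
                        AlignmentSpec(slope_ratio_threshold=0.60))
sa = percent_change(wt, "surface_area")
t, p = compare_groups(wt, mut, "surface_area")
```

which prints, formatted:

```
wild type  surface area change 0-25 min: +24.8% +/- 0.9%
wild type  volume change 0-25 min:       -0.2%
wild type  peak surface-area rate:       14.3 um^2/min
arrest     surface area change 0-25 min: +0.9% +/- 0.5%
wild type vs arrest (pooled Student t):  t = 24.1, p = 8.49e-13
```

Wild-type cells add ~25% surface area at constant volume (the idealized
division predicts +26%); arrested cells add essentially none, and the two
cohorts separate decisively. The full image pipeline runs the same way
from the shell:

```sh
cytomorph simulate --out run/          # movie + ground truth
cytomorph segment --movie run/movie --truth-labels run/truth_labels --out run/seg
cytomorph measure --labels run/seg --out run/trace.csv
cytomorph align --traces wt run/trace.csv --out run/aligned
```

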