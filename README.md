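# lvtraj

4D shape-trajectory morphometrics of cyclic left-ventricular (LV) motion.

Time-resolved landmark models of the heart (e.g. feature-tracked cine MR
surfaces) describe each case as an ordered sequence of 3-D configurations
over one cardiac cycle.  Classical statistical shape analysis compares
static shapes; `lvtraj` compares *motions*.  It is written for researchers
in cardiac statistical shape modeling / geometric morphometrics who want to
test whether a disease group (e.g. myocardial infarction, MI) moves
differently from controls, and how well motion descriptors classify disease
status.

## The method

Given per-case landmark sequences (endocardial and epicardial surfaces,
cycle ED → ES → ED), the pipeline is:

1. **Temporal registration.**  A piecewise-linear time warp pins each
   case's end-systole at 35% of a normalized cycle (ED fixed at 0/100%);
   each landmark coordinate is represented as a truncated Fourier series
   (5 harmonics) and resampled at 30 uniform frames, so frame *t* is
   homologous across cases (ED = frame 1, nominal ES = frame 11).
   End-systole is detected on registered data as the minimum of the cavity
   volume, integrated over a closed surface triangulation.

2. **Linear-Shift parallel transport.**  Working in size-and-shape space
   (SSS: translation + rotation removed) or shape space (SS: also scale),
   a plain GPA + PCA of repeated cycles mixes inter- and intra-individual
   variation.  Linear Shift removes the inter-individual part: with the
   grand mean **CT** (from a whole-sample GPA) and per-case cycle means
   **LT**ᵢ (from per-case GPAs, OPA-aligned to CT), each frame *x*ᵢₜ is
   re-expressed as a deformation of the common template,

   &nbsp;&nbsp;&nbsp;&nbsp;*x̃*ᵢₜ = CT + (OPA(*x*ᵢₜ → LTᵢ) − LTᵢ),

   followed by a common GPA and a joint PCA over all case-frames.  Nearby
   PC scores then mean "same deformation", not "same anatomy".

3. **Trajectory attributes.**  Each case's 30-point path in the space of
   the first 3 PCs is a geometric object with
   *size* (centroid size of the path; one-way ANOVA, adjusted R²),
   *orientation* (angle of the ED→ES vector in the PC1/PC2 and PC1/PC3
   planes, in [0°, 360°); ANOVA) and
   *shape* (paths superimposed as 30-landmark configurations with scaling,
   PCA'd; MANOVA via Wilks' Λ with Rao's F, plus a permutation test of
   multivariate dispersion).  Per-frame PC-score ANOVAs with
   Benjamini–Hochberg flags localize group differences in cycle time.

4. **Classification.**  Every feature set (angles, trajectory size, 15
   trajectory-shape PCs, PC1/PC2/PC3 and PC1–PC10 evaluated at all 30
   homologous times, plus traditional EDV/ESV/EF from volume integration)
   is scored by 1,000 stratified random train/test splits of a linear SVM
   (features z-scored on the training part only), reporting mean accuracy,
   specificity, sensitivity and ROC AUC (Control = negative, MI =
   positive).

A synthetic LV motion generator (`lvtraj.simulate`) produces two-surface,
open-based spheroidal hearts with cyclic contraction, group-specific
amplitude and shape-change, inter-individual anatomy jitter, rigid motion,
variable raw frame counts and landmark noise — with exact per-case
EDV/ESV/EF ground truth — so the whole pipeline is testable without any
external data.

## Worked example

```python
import numpy as np
from lvtraj import (RegistrationSpec, SimulationSpec, generate_cohort,
                    register_sequence, run_ls_pca)
from lvtraj.classify import FeatureSet, compute_traditional_indicators, run_repeated_svm
from lvtraj.trajectory import anova_adjusted, trajectories, trajectory_size

spec = SimulationSpec(n_per_group=30, seed=42)          # 30 Controls + 30 MI
cohort = generate_cohort(spec)

reg = RegistrationSpec()                                # 30 frames, ES at 35%, 5 harmonics
endo = [register_sequence(c.endo, reg) for c in cohort]

vols = compute_traditional_indicators(endo, cohort[0].mesh)
print(vols.groupby("group")[["edv", "esv", "ef"]].mean().round(2))

ds = run_ls_pca(endo, mode="sss")                       # Linear Shift + GPA + PCA
print("PC1 variance share: %.1f%%" % (100 * ds.pc_model.explained_fraction[0]))

trajs = trajectories(ds, n_axes=3)
sizes = [trajectory_size(t) for t in trajs]
res = anova_adjusted(sizes, ds.group_labels())
print("trajectory size ANOVA: F=%.1f  p=%.2e  adj R2=%.3f"
      % (res.statistic, res.p_value, res.r_squared_adj))

features = FeatureSet("pc1_10_all_times", ds.case_scores(10).reshape(ds.n_cases, -1))
report = run_repeated_svm(features, ds.group_labels(), n_runs=200, seed=0)
print("SVM (PC1-10 at all 30 times): accuracy=%.3f  AUC=%.3f"
      % (report.means["accuracy"], report.means["auc"]))
```

Output:

```
            edv    esv    ef
group
Control  124.63  22.07  0.82
MI       129.57  59.88  0.54
PC1 variance share: 97.1%
trajectory size ANOVA: F=287.3  p=3.86e-24  adj R2=0.829
SVM (PC1-10 at all 30 times): accuracy=0.999  AUC=1.000
```

Reading it: the generator programs Controls to contract harder than MI, so
measured EF separates the groups (0.82 vs 0.54, in ml for the volumes);
after transport, 97% of deformation variance is the cyclic
contraction/relaxation axis (PC1 in SSS is dominated by size change);
trajectory size — how much shape change a heart traverses per beat —
separates the groups with a large effect (adjusted R² 0.83); and the
repeated-split SVM on PC scores at all homologous times classifies nearly
perfectly on this clean synthetic contrast.

The same pipeline runs from the shell:

```bash
lvtraj simulate --n-per-group 30 --seed 42 --out data/
lvtraj run-all --dataset data/ --n-runs 1000 --seed 42 --out results/
```

which writes per-case attribute tables, the group-test table, per-frame
ANOVA tables, the classification summary and a provenance log (config
hash, stage seeds, versions) under `results/`.

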