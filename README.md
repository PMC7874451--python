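# morpholong

Longitudinal 3-D geometric morphometrics of facial soft tissue.

Orthodontic treatment subtly reshapes the face over months. Quantifying
that change requires more than calipers: faces must be represented as dense
corresponding landmark sets, superimposed so that only shape (or shape plus
size — form) remains, and tested with statistics that respect the
repeated-measures design of "the same patients imaged at baseline, three
months, six months". `morpholong` implements that pipeline end to end for
researchers in craniofacial biology and orthodontics:

* **Quasi-landmarking** — map a fixed template (anthropometric mask) of k
  quasi-landmarks onto each facial surface via five anchoring landmarks,
  a 3-D thin-plate-spline warp, and closest-surface projection; or ingest
  pre-mapped configurations from any dense-registration tool.
* **Symmetric-component GPA** — superimpose every configuration together
  with its reflected relabeling (Generalized Procrustes Analysis: remove
  location, orientation and size; det = +1 rotations only) and analyze the
  symmetric component ½(X + reflect(X)).
* **Restricted-permutation PERMANOVA** — partition the matrix of pairwise
  Procrustes distances D into sequential sums of squares for stage, group
  and stage × group via the Gower-centered matrix G = −½ J D⁽²⁾ J, with
  pseudo-F = (SS_term/df_term)/(SS_res/df_res), partial
  R² = SS_term/(SS_term + SS_res), and p-values from permutations
  constrained within participants (stage terms) or across whole subjects
  (group term): p = (#{F* ≥ F} + 1)/(B + 1), exact enumeration when the
  permutation group is small.
* **Localization** — the same model per quasi-landmark, with mm
  displacement magnitudes, raw and BH-adjusted p, and heatmap meshes
  (magnitude, R², −log10 p, significance mask) written as colored PLY.
* **Disparity** — Procrustes variance PV_g = (1/n_g)Σ‖x_i − x̄_g‖² per
  stage-by-group cell, with permutation tests on |ΔPV|.
* **Synthetic cohorts** — a generator of bilaterally symmetric longitudinal
  face cohorts with known displacement fields, subject effects, noise and
  nuisance transforms, so every claim above is testable against ground
  truth (the original study's images are private).

## Worked example

```python
import numpy as np
from morpholong import (
    SimulationParams, make_template, simulate_cohort, superimpose_cohort,
    PermutationScheme, permanova, pairwise_posthoc, pairwise_distance_matrix,
    per_landmark_analysis,
)

template = make_template(k_half=353, seed=1)            # k = 716 quasi-landmarks
params = SimulationParams(seed=1, target_magnitudes=(1.32, 0.21))
design, configs, truth = simulate_cohort(template, params)   # 43 subjects x T0/T1/T2

sup = superimpose_cohort(design, configs, template)     # symmetric-component GPA
scheme = PermutationScheme(subjects=design.subjects, n_perms=1999, seed=1)

print(permanova(pairwise_distance_matrix(sup["shapes"]), design, scheme).round(4))
print(pairwise_posthoc(sup["shapes"], design, scheme).round(4))
pl = per_landmark_analysis(sup["shapes"], design, scheme,
                           mm_scale=sup["mm_scale"], n_perms=0)
print(pl["summary"].round(3))
```

Output (seed 1):

```
              df      SS        F  partial_R2       p
stage          2  0.0234  52.8782      0.4623  0.0005
group          1  0.0011   4.7804      0.0374  0.1065
stage:group    2  0.0000   0.0623      0.0010  0.9555
Residual     123  0.0272      NaN         NaN     NaN
Total        128  0.0517      NaN         NaN     NaN

           PD  partial_R2       p
pair
T0-T1  0.0262      0.4490  0.0005
T0-T2  0.0304      0.5231  0.0005
T1-T2  0.0043      0.0213  0.0005

       mean_mm  sd_mm  median_mm
pair
T0-T1    1.303  1.078      0.910
T0-T2    1.512  1.250      1.068
T1-T2    0.218  0.170      0.155
```

Read: facial shape changes strongly across stages (pseudo-F ≈ 52,
p = 1/2000, the permutation floor) while treatment modality and its
interaction are null, as injected. The stage-pair Procrustes distances
(0.026, 0.004, 0.030) show change concentrated in the first interval —
the T0–T1 : T1–T2 rate ratio is ≈ 6 — and the per-landmark mean magnitudes
recover the injected 1.32 mm and 0.21 mm fields to within a few percent.

The same sequence is available as numbered drivers: `analysis/01_…` through
`analysis/04_…` simulate the cohort, quantify mapper accuracy, run the full
report bundle (tables, heatmap PLYs, magnitude figures) and compare
estimates with ground truth. A `morpholong` CLI wraps the individual stages
(`simulate`, `map`, `gpa`, `permanova`, `perlandmark`, `disparity`, `run`).

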