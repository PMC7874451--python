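# Methods

`morpholong` analyzes longitudinal change in facial soft tissue with
spatially dense geometric morphometrics: each face is a configuration of k
corresponding quasi-landmarks in mm, and the questions — does mean facial
shape change across treatment stages, where on the face, and does shape
variance change — are answered with Procrustes superimposition and
restricted-permutation tests. This note records the model, the conventions,
and the design decisions where the design was genuinely open.

## Quasi-landmark correspondence

Correspondence across faces is established by mapping a fixed template (an
anthropometric mask of k quasi-landmarks) onto every target surface. The
mapper is deliberately transparent: (1) least-squares similarity alignment
(Umeyama closed form, rotation restricted to det = +1) of the template's five
anchoring landmarks — right/left exocanthion, pronasale, right/left
cheilion, digitized in that fixed order — onto the subject's anchors; (2) a
3-D thin-plate-spline warp with kernel U(r) = r (scipy's `RBFInterpolator`,
linear kernel, degree-1 polynomial part) driven by the five anchor pairs;
(3) projection of every warped landmark to the closest point on the target
mesh. Ties in the projection resolve deterministically to the lowest
triangle index. Template order is preserved, so landmark i corresponds
across subjects by construction.

This 5-anchor mapper is not a dense nonrigid registration: with the default
1.5 mm smooth per-subject deformation of the synthetic cohort, its residual
against the true correspondence is about 0.6 mm RMS (exact when the target
is a similarity image of the template, ~0.2 mm RMS at 0.5 mm deformation;
see `analysis/02_map_quasilandmarks.py`). Cohorts mapped with an external
dense-registration tool can therefore enter the pipeline directly as
pre-mapped configuration CSVs, bypassing this module. An iterative
mesh-to-mesh refinement loop was deliberately left out to keep the mapping
deterministic and dependency-free.

## Symmetric-component superimposition

Faces are treated as bilaterally symmetric about the midsagittal plane
(x = 0 after anchor standardization). Each configuration is paired with its
reflected relabeling (x negated, bilateral landmark slots swapped, midline
slots fixed), and originals plus reflections are superimposed jointly by
Generalized Procrustes Analysis. Conventions:

* classic GPA — every configuration centered and fixed at unit centroid
  size each iteration (no variable-scaling partial-Procrustes step);
  rotations from SVD restricted to det = +1, so reflections enter only via
  the explicit relabeling; convergence when the mean shape moves < 1e-10,
  max 100 iterations (typically 2–4).
* the symmetric component of each observation is the landmark-wise average
  of its superimposed original and superimposed reflection; all downstream
  statistics use it. The asymmetric remainder is discarded (asymmetry is
  out of scope).
* Procrustes distance (PD) is the Euclidean norm of the coordinate
  difference between shapes in the common frame — the linearized
  small-variation surrogate for full Procrustes distance. This makes PD,
  the distance matrix, and coordinate-space sums of squares exactly
  consistent; the discrepancy from the chord distance is O(PD³), negligible
  at the PD ≈ 0.01–0.03 scale of these analyses.
* form coordinates are shape coordinates multiplied by the observation's
  centroid size (mm); form analyses rerun the identical machinery on them.
* mm reporting scale: per-landmark displacements in shape units are
  converted to mm by the grand mean centroid size of the dataset. No
  universal rescaling rule exists for Procrustes data; this choice is
  recorded in the run log (`mm_scale_rule`).

## Restricted-permutation PERMANOVA

The model is a distance-matrix MANOVA with sequential (Type I) sums of
squares in the fixed order stage, group, stage × group, computed from the
Gower-centered squared-PD matrix via projection-matrix traces. With
Euclidean PD this partition equals the coordinate-space linear-model
decomposition exactly (asserted in the tests). Pseudo-F is
(SS_term/df_term)/(SS_res/df_res).

Because the three stages are repeated measures on the same participants,
exchangeability holds only within subject. Permutation rules per term:

* stage and stage × group: stage labels shuffled independently within each
  participant;
* group (a between-subject factor, which a within-subject shuffle cannot
  move): whole-subject relabeling — subjects exchange group labels. Both
  rules are configurable, and a single-rule within-participant-only mode is
  available.

p-values use the "larger or equal" convention. With sampled permutations,
p = (#{F* ≥ F_obs} + 1)/(B + 1), counting the identity, so p ≥ 1/(B+1) and
never 0; the default B is 10,000. When the restricted permutation group has
≤ 1024 elements the group is enumerated exhaustively and p = #{F* ≥ F}/N is
exact (the identity is a group member, so no +1). Subjects observed at a
single stage contribute no shuffling and are logged.

Partial R² follows the coefficient of partial determination,
SS_term/(SS_term + SS_residual). In the balanced full-crossing design
(every subject at every stage) the centered stage, group and interaction
subspaces are mutually orthogonal, so this equals the reduced-model-refit
form (SSE_reduced − SSE_full)/SSE_reduced; the tests verify the equality
explicitly on an orthogonal worked design.

Post-hoc pairwise stage comparisons rerun the model on the subset of
subjects observed at both stages; the magnitude of change is the PD between
the two stage mean shapes. Per-landmark localization refits the same model
with each quasi-landmark's 3 coordinates as the response (projection
matrices are shared across landmarks, so all k tests vectorize), reporting
the stage term's partial R², raw permutation p, and Benjamini–Hochberg
adjusted p; raw p is the default for maps and for the p ≤ α significance
mask, with the BH column alongside. Per-landmark displacement magnitudes
are reported in mm as mean (SD) across the face.

Procrustes variance (morphological disparity) of a group is
PV_g = (1/n_g) Σ‖x_i − x̄_g‖² over superimposed coordinates. Pairwise
variance differences are tested by permuting group-mean-centered residual
vectors among groups, with a two-sided statistic |ΔPV| and the same +1
p-value convention; singleton groups get a variance but no test.

## Synthetic cohort

The generator reproduces the study conditions as its defaults: 43 subjects
(22 extraction / 21 non-extraction), stages T0/T1/T2, k = 716 quasi-landmarks
(one-tenth the 7160-point mask; statistical behavior is k-insensitive,
runtime is not — the full scale is available). Each observation is

    template + subject deformation + cumulative stage field + noise,
    then a random similarity nuisance transform.

* Template: landmarks sampled on a smooth parametric face-like height field
  and mirrored across x = 0 — exactly symmetric by construction — with
  parametric-zone region labels (nasal, labial, buccal, temporal, other).
  Zone boundaries are a modeling choice exposed in the source; no
  quantitative region definitions exist to copy.
* Stage effect: region-wise amplitudes along template surface normals,
  default buccal −1.5 mm and temporal −1.0 mm (invagination) versus labial
  +1.5 mm with an extra +0.5 mm on the lower lip (protrusion); the T1→T2
  increment is one-sixth of T0→T1, concentrating change in the first
  interval. The field is projected orthogonal to the similarity group at
  the template (net translation, infinitesimal rotations, scaling removed)
  before use: a field component along those directions would be absorbed by
  superimposition and make stated amplitudes unidentifiable in shape space.
  Optional calibration rescales the two fields to exact target mean
  per-landmark magnitudes (used with 1.32 and 0.21 mm in the acceptance
  run). The fields actually applied are returned verbatim as ground truth.
* Subject deformation: a smooth low-rank Gaussian radial-basis field
  (20 mirrored centers, 40 mm length scale), mirrored coefficients so the
  field is exactly symmetric, rescaled to 1.5 mm RMS. This makes
  between-subject variation (PD ≈ 0.03) exceed the stage effect
  (PD ≈ 0.01–0.025), which is precisely the regime that motivates
  within-participant permutation.
* Noise: iid Gaussian, 0.2 mm per coordinate, breaking exact symmetry the
  way digitization error would. Nuisance: rotation ≤ 15°, translation
  ≤ 50 mm, scale 0.9–1.1.
* No group effect is injected by default — treatment modality is a null
  factor, matching the study's finding — so the group term doubles as a
  negative control.

What the generator does not emulate: real surface texture and capture
artifacts, expression and posture variation, asymmetric change, age or BMI
covariates, and any realistic covariance of facial regions beyond the
smooth subject field. Passing tests therefore demonstrate correctness of
the statistical machinery under known truth, not clinical validity on real
faces.

## Numerical choices and degenerate inputs

Rank-deficient design blocks are handled by SVD-based projectors with a
relative tolerance, so collapsed terms get df = 0 and no test. Constant
responses (zero total SS) raise rather than return NaN tables. Duplicate
TPS controls and coplanar control sets are rejected before factorization.
Equidistant surface projections tie-break to the lowest triangle index.
GPA's global orientation is arbitrary; only rotation-invariant quantities
(distances, variances, per-landmark magnitudes) are reported. All
randomness flows from a single seed through `numpy.random.default_rng`;
report CSVs are written with fixed float formatting, so identical seeds
give byte-identical bundles.

## Problem sizes in the shipped runs

The default test and analysis runs use the one-tenth-scale template
(k = 716) or smaller (k = 100–130 for calibration sweeps), 1999 permutations
for main tables and 199 for per-landmark maps and Monte-Carlo sweeps
(500 null replicates for Type-I calibration, 200 for power). These sizes
were chosen as the smallest at which the Monte-Carlo bands in the tests are
meaningful; the full-scale settings (k = 7160, 10,000 permutations) are a
flag away and change runtime, not code paths.

## Known limitations

* The 5-anchor TPS mapper is a transparent stand-in for dense nonrigid
  surface registration; its correspondence error (~0.6 mm RMS under the
  default subject deformation) is visible in mapped-cohort analyses, which
  is why pre-mapped configurations are accepted directly.
* PD is the linearized Procrustes distance; at PD ≳ 0.1 the chord-distance
  discrepancy would no longer be negligible.
* The group term's subject-level permutation assumes a balanced design
  (same stage layout per subject); unbalanced cohorts fall back to
  within-subject shuffles for that term, with a warning.
* Per-landmark tests share one permutation stream across landmarks, which
  is standard and fast but induces slight dependence between neighboring
  landmarks' Monte-Carlo errors.
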