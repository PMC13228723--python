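# Methods

## The B-score

Knee osteoarthritis changes the shape of the distal femur in a stereotyped
way: articulating surfaces broaden and flatten, and osteophytic ridges grow
around their borders.  Given a population of femoral surfaces segmented
with a *corresponded* template (every bone represented by the same N
ordered surface points), each bone is a point in a 3N-dimensional shape
space and this structural change is largely captured by a single axis.

The B-score formalizes that axis as a z-score.  From a training population
split into a non-OA group (KL grades 0–1) and an OA group (KL ≥ 2), all
shapes are brought into a common frame by generalized Procrustes analysis
(GPA) and

- the origin is the mean healthy shape `mu_H`,
- the direction is `v = (mu_OA − mu_H)/‖mu_OA − mu_H‖`,
- the unit is `sigma_H`, the standard deviation (n−1 denominator) of the
  healthy shapes' scalar projections onto `v`.

Any corresponded shape `s` then scores `B(s) = ((s − mu_H)·v)/sigma_H`.
By construction the healthy training group has mean 0 and SD 1; values
above about +2 correspond to radiographic OA, and adult populations span
roughly −2 to +8.  The projection is computed in the raw aligned 3N
landmark space rather than in a truncated PCA coefficient space: the two
are identical when all modes are kept, and the raw space avoids committing
to a truncation.

### Alignment conventions

Pose alignment is rigid (rotation + translation) by default and size is
**not** normalized away — surface broadening is partly a size effect the
score must see.  Both choices sit behind `AlignmentSpec`.

A query shape carrying an arbitrary pose is aligned (when `align=True`)
onto the **GPA consensus** of the scale's training population, which is
stored in the scale, not onto `mu_H`.  At a GPA fixed point each training
shape's aligned pose *is* its optimal Procrustes pose onto the consensus,
so re-scoring a raw training shape through the public API reproduces its
training-time projection exactly and the mean-0/SD-1 property survives
re-alignment.  Aligning onto `mu_H` instead would perturb every pose
slightly and break that exactness.  To make this hold to machine precision,
`generalized_procrustes` returns the consensus that the final transforms
were actually computed against (the pre-update mean at convergence).

## The CT re-parameterization pipeline

A CT-trained segmentation model produces surfaces with a different vertex
arrangement than the scale-defining (MR-trained) model, so its output
cannot be projected onto `v` directly.  The pipeline transfers a
CT-parameterized surface into the reference parameterization:

1. **Rasterize** the CT surface into a binary voxel volume (default 1 mm
   isotropic, 4 voxels padding).  Occupancy is decided by the parity of +z
   ray crossings at voxel centers, with a deterministic sub-nanometre
   irrational lattice offset so rays never hit mesh edges exactly; for the
   watertight, consistently oriented meshes the operation requires this
   equals the winding-number rule.  World units are mm; `origin` is the
   center of voxel (0,0,0).
2. **Segment the volume with the reference shape model.**  The signed
   Euclidean distance field of the volume (negative inside) is computed
   from two EDTs; each model point takes a capped Newton step along the
   field gradient to its zero crossing (cap 10 mm; points with no crossing
   keep their position with zero weight), and a regularized pose + PCA
   coefficient fit (coefficients clipped at ±3 SD per mode) is re-solved;
   iterate until mean point motion < 0.01 mm (converged) or 100 iterations
   (flagged).  Pose is initialized from the occupied-voxel centroid and
   principal axes; the four proper sign combinations plus the identity are
   each given a short 8-iteration trial fit and the candidate with the
   lowest mean |SDF| wins — the trial fits matter because a nearly
   symmetric bone can make the raw pre-fit score prefer a mirrored pose.
3. **Re-project** every fitted point onto the original CT surface
   (closest point, exact; ties to the lowest face id), recovering surface
   detail the regularized fit smoothed away.  Projecting model points onto
   the CT surface (rather than CT points onto the model) keeps the output
   in the reference parameterization.  For large CT meshes an exact
   KD-tree-pruned search is used: candidate faces are all faces whose
   centroid ball could beat the current best distance, so no face is
   missed.
4. **Smooth** with 5 Taubin λ|μ passes (λ = 0.5, μ = −0.53) on the
   reference topology, mitigating projective anomalies without the volume
   shrinkage of plain Laplacian smoothing.
5. **Project and normalize** exactly as the MR branch does.

Each geometric stage is independently switchable for ablation.  Two
failure modes are first-class results rather than exceptions at the cohort
level: volumes whose anatomy lies partly outside the grid are excluded as
*out-of-field* — detected up front when the segmentation mask touches the
grid boundary (the standard field-of-view truncation signal), or during
the fit when more than half the model points find no surface crossing
within the search cap — and fits whose mean absolute surface distance
exceeds 2× the voxel spacing are excluded as *poor-quality searches*.
Excluded records carry diagnostics and never a B-score.

The alternating weighted fit with per-mode clipping is not guaranteed
monotone; if the corresponded-point solver reports divergence inside the
volume fit, the volume fit stops and flags non-convergence instead of
raising.

## Synthetic study design

No clinical imaging is used.  The generator fabricates a femur-like cohort
with known ground truth:

- **Template** — a radially displaced icosphere (642 vertices at 3
  subdivisions): an ellipsoidal shaft end plus two condylar lobes.  The
  lobes are deliberately unequal (15 vs 12 mm, offset asymmetrically), as
  the medial and lateral femoral condyles are; the asymmetry anchors the
  principal-axis frame so pose initialization cannot confuse a bone with
  its mirror image.  Anatomical realism beyond "shaft, two articular caps,
  a rim" is a non-goal.
- **Healthy variation** — five smooth displacement fields (overall size,
  shaft elongation, condylar spread, bend, and spread along the OA
  deformation direction itself), unit per-vertex RMS, with SDs
  (1.2, 0.8, 0.5, 0.3, 0.4) mm; coefficients are clipped at ±3 SD.  The
  fifth mode encodes that healthy knees spread on either side of the mean
  in the healthy-to-OA direction of shape space; it is what makes the
  lowest radiographic grades overlap on the B-score axis and it keeps the
  scale's unit stable across training realizations.
- **OA deformation field** — per unit severity `g`: caps pushed 1.2 mm
  inward along normals (flattening), condylar region pushed 1.0 mm
  outward horizontally (broadening), a 1.5 mm outward-normal ridge around
  the cap border (osteophytes), all with C¹ smooth angular weights and
  exactly zero on the shaft.  Feature widths (ridge Gaussian width 0.25
  rad, centered 0.75 rad off the cap axes) are kept at or above the
  template's own edge length (~0.27 rad) so every generated feature is
  resolvable by the correspondence that measures it — real dense femoral
  correspondences resolve real osteophytes the same way; unresolvable
  sub-mesh-scale features would only measure discretization error.
- **Severity by grade** — pseudo-KL grades drawn from the mixture
  (19, 31, 30, 16, 3)/99 of a mixed clinical analysis population; grade
  means of `g` are (0, 0.5, 1.5, 3, 5) with 20 % relative SD, `g = 0` for
  grade 0.  This calibration puts grades 0/1 in an overlapping band around
  B = 0 and grades 2–4 progressively above +2, with the full population
  inside roughly −3 to +9 — the curvilinear B-vs-KL pattern seen
  clinically.
- **Paired observations** — the MR-like observation is the truth in the
  reference parameterization plus noise; the CT-like observation is an
  independent remeshing of the truth surface onto a welded UV-sphere
  layout (80×160, ≈ 12.6 k vertices ≈ 1.4 mm spacing, matching the density
  of real segmentation-model meshes) by radial raycasting from the
  centroid, plus its own noise.  The CT vertex count never equals the
  reference count, so re-parameterization is genuinely exercised.
- **Observation noise** — displacement along vertex normals only
  (tangential noise is unidentifiable on a surface), default SD 0.2 mm per
  modality (sub-voxel segmentation error).  The noise field mixes a
  spatially smooth random component (70 % of variance, quadratic in the
  direction vector) with iid jitter: segmentation models err coherently
  over regions, and purely iid noise would be nearly invisible to the
  B-score because it averages out over the projection.
- Every subject draws from its own spawned random stream, so truth shapes
  are bit-identical whether or not observations are generated, and asset
  training (which needs only truth shapes) can skip the remeshing cost.

**What passing tests show, and what they do not.**  The synthetic cohort
exercises every computational property of the chain — exactness of the
scale, correctness of the statistics, accuracy of the re-parameterization
under a genuinely alien vertex layout, pose invariance, exclusion
accounting.  It does not contain intensity images, segmentation-model
errors correlated with disease severity, cartilage, or true anatomical
shape statistics, so agreement numbers on synthetic cohorts characterize
the geometry pipeline, not clinical performance.

## Numerical choices

- Rasterization resolution defaults to 1 mm (roughly CT voxel scale);
  accuracy is nearly flat from 2 mm down to 0.5 mm because the limiting
  factor is mesh discretization, not the voxel grid.
- The signed distance field is `edt(empty) − edt(occupied)`, zero-crossing
  midway between boundary voxel centers (±h/2 of the true surface).
- Quartiles use linear interpolation; box-plot whiskers sit at the
  farthest data within 1.5 IQR of the box, points beyond are fliers.
- Lin's CCC uses population (1/n) moments — the original convention, which
  matters at small n.  Bland–Altman limits use the normal 1.96 multiplier
  and the bias CI `±1.96·s_d/√n`; this convention reconciles the printed
  clinical summary it is validated against to last-digit rounding.
- Regression moments are accumulated with exactly rounded summation so
  reports are bit-identical under record permutation.
- GPA converges when the consensus RMS change drops below 1e-10.
- B-scores outside [−10, +15] trigger a warning (typical adult range is
  −2 to +8); they are still returned.

## Known limitations

- A residual negative bias of order 0.05–0.1 B-units remains between the
  CT branch and ground truth on noise-free synthetic cohorts: any
  piecewise-linear CT mesh chords inside convex features, so the remeshed
  surface carries slightly less osteophyte than the truth, and the B-score
  is sensitive to coherent sub-0.1 mm surface displacement along its axis.
  The effect shrinks with CT mesh density and is well inside the
  smallest-detectable-difference of the published scale (0.25).
- The geometric model-to-volume fit stands in for intensity-based
  appearance-model search; no appearance statistics are modelled.
- Repeated timepoints of a subject are treated as independent in the
  agreement statistics; no clustering correction is applied.
- STL I/O drops vertex correspondence (triangle soup); only PLY/OBJ are
  valid for corresponded shapes, and reading STL flags the loss.
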