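# Methods

This note documents the measurement model, the numerical choices behind
it, what the synthetic data do and do not emulate, and the limitations a
user should know about.

## The 3D gap area

A tibial plateau fracture is modelled as a set of rigid bone fragments
whose articular (joint-facing) surfaces carry *fracture lines*: the parts
of each fragment's articular boundary that face another fragment rather
than the intact plateau rim. The 3D gap area is the total area of a
surface spanning all fracture lines. For the canonical case of two
fragments separated by an in-plane gap `g` and an axial step-off `s`
along a fracture of chord length `c`, the spanning surface is a ruled
strip and the area is exactly `c·sqrt(g² + s²)`; the measure therefore
aggregates gap and step-off displacement in all planes into one number
with units of mm².

## Measurement pipeline

1. **Segmentation.** Voxels at or above the bone threshold (226 HU by
   default) form the bone mask; connected components (26-connectivity by
   default) become fragments, ordered by size, with components below
   `min_voxels` (default 50) discarded as speckle. Fragments that touch
   in the mask can be separated explicitly with `split_fragment`, which
   re-labels a fragment across an oriented plane (voxels exactly on the
   plane go to the positive side) — the programmatic equivalent of manual
   separation in clinical segmentation software.
2. **Meshing.** Each fragment's binary sub-mask is iso-surfaced by
   marching cubes at level 0.5 with vertices mapped to world mm, then
   relaxed with a Taubin shrink/dilate smoother. The clinical recipe's
   "smoothing factor 0.4" is mapped to the shrink weight λ = 0.4 with the
   dilate weight ν chosen so that 1/λ − 1/ν = 0.05 (mild net dilation
   guard), for 10 alternating passes. Smoothing preserves vertex count
   and changes enclosed volume by well under 2%.
3. **Articular delineation.** The faithful path is an explicit per-vertex
   annotation (the analogue of manual brush marking); the patch is then
   exactly the triangles whose three vertices are flagged. For unattended
   runs a heuristic marks triangles whose outward normal lies within 45°
   of the proximal axis and whose centroid sits in the top 15% of the
   fragment's proximal extent, keeping the largest edge-connected
   component. The heuristic is an engineering convenience for phantoms
   and screening, not a solution to anatomical articular recognition.
4. **Contours.** Patch boundary edges (edges used by exactly one patch
   triangle) are chained into polylines deterministically: open chains
   start at the lexicographically smallest endpoint, loops at the
   smallest remaining vertex, ties toward the smaller vertex index. An
   edge used by more than two patch triangles is reported as non-manifold.
5. **Trimming to fracture lines.** A contour vertex is classified
   *fracture* when (a) it lies within `d_max` (default 7.5 mm) of another
   fragment's contour and (b) the nearest opposing point is reciprocally
   about as close to the opposing side as the vertex is
   (`reciprocal_tol`, default 0.4 mm). Reciprocity is what stops the
   fracture run from leaking around the plateau rim near the fracture
   corners, where rim points are close to the opposing *corner* without
   facing any opposing run. Residual corner hooks are then peeled off
   each run end while the opposing distance exceeds the run minimum by
   `end_prune_tol` (default 0.15 mm), bounded to 5 mm of arc per end so a
   genuinely widening fracture line cannot be eaten beyond the
   rim-ambiguity scale. Distances are evaluated against contours densely
   resampled at 0.25 mm.
6. **Line conditioning.** Each fracture line is smoothed by a centred
   5-point moving average and simplified by 3D Douglas–Peucker at
   0.25 mm (half a voxel at the reference resolution). The moving
   average matters: voxel meshes carry a half-voxel staircase, and
   simplification anchored at raw staircase extremes would bias the line
   position by up to half a voxel per side, whereas the staircase mean
   tracks the true face position closely. Sharply turning end segments
   (> 45°) left over after simplification are dropped as rim spurs.
7. **Loop closure.** Free endpoints are joined greedily, closest pair
   first (lexicographic tie-break); the two ends of one original line may
   only pair when no cross-line pairing remains, so two independent
   fracture clefts close into two separate loops rather than being
   bridged. Straight closure segments complete each loop.
8. **Surface construction.** Each loop is projected onto its best-fit
   (principal-component) plane using in-plane axes derived from the
   geometry itself (centroid → farthest point), making the construction
   equivariant under rigid motion; the projected simple polygon is
   triangulated by ear clipping without Steiner points, and the triangles
   are lifted back to the original 3D coordinates so that out-of-plane
   step-offs inflate the area exactly as the ruled-surface analysis
   predicts. Loops whose points are collinear within `degeneracy_tol`
   (0.25 mm RMS) contribute zero area — this is what maps two coincident
   fracture lines (an undisplaced crack) to 0 mm². Projected rings that
   self-cross only by sub-voxel slivers (a vertex within 0.75 mm of the
   crossed segment) are repaired by deleting the offending vertex, at
   most 5% of the loop; macroscopic self-intersections are an error.
   The total gap area is the sum over loops of the summed 3D triangle
   areas.

Whether the original interactive software builds a minimal, lofted, or
plane-projected surface is not recoverable; the plane-projection
construction was chosen because it is deterministic, oracle-checkable
against ruled surfaces, and reproduces the ruled-strip area for the
displacements that define the measure.

## Prognostic statistics

* Group boundaries 150 / 550 / 1000 mm² are half-open on the right
  (≤ 150 excellent, (150, 550] good, (550, 1000] moderate, > 1000 poor);
  the published integer ranges are printed for a continuous quantity, so
  the half-open convention is the natural reading. The published
  convention is internally inconsistent exactly at 550 mm² — the "good"
  range ends at 550 while the high-risk flag fires at ≥ 550 — and both
  behaviours are preserved verbatim rather than silently reconciled.
* The critical cut-off maximizes Youden's J = sensitivity + specificity − 1
  over the candidate thresholds; ties resolve to the smallest cut-off.
  ROC curves are empirical over all observed thresholds (positive call:
  gap area ≥ threshold), AUC by the trapezoidal rule.
* Kaplan–Meier curves, log-rank tests and Cox regression are computed by
  lifelines and statsmodels behind the package's own interfaces. Cox tie
  handling defaults to Breslow with Efron available. Constant covariates
  are an error; runaway coefficients (|β| > 20 or SE > 100) raise a
  separation flag in the result rather than being reported silently.
  Wald 95% intervals are reported as exp(β ± 1.96·SE).
* Reduction adequacy is the inclusive 2 mm rule: a reduction is adequate
  when both the maximum residual gap and step-off are ≤ 2 mm.

## Synthetic data

**Phantoms** are idealized solids (cylinder r = 25 mm, h = 30 mm by
default; boxes available) cut by vertical planes and displaced rigidly by
(g, 0, s) per fragment, voxelized at 0.5 mm with bone at 700 HU against
−1000 HU air, with optional Gaussian HU noise and an optional sinusoidal
("lumpy") articular surface to stress the best-fit-plane construction.
The phantom returns the exact label volume, analytic per-cut areas
(chord × √(g² + s²)), and analytic articular annotations (vertices within
one voxel of each fragment's own articular top). Phantoms deliberately
trade anatomical realism for analytic truth: they have flat or gently
lumpy articular surfaces, a single rim, no trabecular texture, no
metal/beam-hardening artefacts and no comminution. Passing the phantom
grid therefore demonstrates the geometric fidelity of the spanning-area
computation, not clinical segmentation robustness. Across the g, s ∈
{0..5} mm grid at 0.5 mm voxels the measured area stays within 10% of
truth (observed worst case ≈ 6%); displacement combinations approaching
`d_max` = 7.5 mm are the measure's design limit, beyond which opposing
lines are no longer recognized as facing.

**Cohorts** draw gap areas log-normal (median 420 mm², log-SD 1.0 —
matching the reported native-knee median), assign groups through the
classifier, and draw exponential event times at a baseline hazard of
0.0025/year in the excellent group scaled by group hazard ratios
1 / 1.7 / 6.8 / 14.3, with administrative censoring uniform on 1–18
years. The baseline was calibrated once so the overall conversion
fraction lands near the reported ~11%. Covariates (age 53.1 ± 14.4,
29% male, BMI 26.3 ± 4.6, 19.6% smokers, 30% inadequate reduction) are
drawn independently and have no effect on hazard unless a coefficient is
configured — real confounding structure is *not* emulated, so the Cox
adjustment in tests verifies machinery, not epidemiology. At n = 10⁵ the
sampling SE of the good-group log-HR (~0.04) exceeds 10% of its true
value (ln 1.7 ≈ 0.53), so recovery tests assert agreement within
max(10%, 3·SE) rather than a bare percentage.

## Numerical choices and degenerate inputs

* Voxel centres sit at `origin + index·spacing`; axes are (x, y, z) with
  z proximal; all areas are computed in world mm.
* Thresholding is inclusive (≥ 226 HU keeps a voxel at exactly 226).
* An empty mask labels to zero fragments (not an error); a fragment of
  fewer than 8 voxels cannot be meshed; a single fragment, or trimming
  that finds no facing contours, yields a gap area of exactly 0 with
  zero loops.
* All chaining, closure, and triangulation orderings are fixed by
  geometry (lexicographic or distance-based tie-breaks), so a given
  input reproduces byte-identical outputs; reports embed a configuration
  hash and contain no wall-clock times.
* Problem sizes in the test-suite and acceptance script (36 phantoms of
  ~0.9 M voxels, cohorts of 2·10⁴–10⁵, 1000 log-rank null replicates)
  were chosen to give stable statistics at interactive runtimes on a
  single CPU.

## Known limitations

* The articular heuristic assumes the proximal axis is known and the
  articular surface is the top of the fragment; oblique scan orientations
  should be normalized on read (done for NIfTI/DICOM) or annotated.
* `d_max` bounds the measurable displacement between opposing fracture
  lines; fractures displaced beyond it need a larger `d_max`, at the cost
  of admitting more rim ambiguity.
* The proximity/reciprocity trimming rule is a geometric reconstruction
  of an interactive manual step; its parameters (`d_max`,
  `reciprocal_tol`, `end_prune_tol`) are exposed for sensitivity
  analysis.
* Cohort-level clinical quantities (observed AUC, hazard ratios,
  survival percentages of the real patient population) depend on patient
  data that is not distributable; the package reproduces the in-table
  arithmetic and recovers configured parameters from simulations instead.
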