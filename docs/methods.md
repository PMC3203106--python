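# Methods

## Measurement model

The pipeline quantifies early mammary-rudiment (MR) growth from transversal
serial sections (5–6 µm) of BrdU-labelled mouse embryos.  Its unit of
measurement is the stained **pixel**, not the cell: the DAB immuno-precipitate
saturates, so both daughters of a labelled cell stain as strongly as their
mother and pixel area tracks labelled mass.  The BrdU⁺ fraction of all
nuclear (DAB ∪ hematoxylin) pixels in a compartment is the proliferation-rate
proxy at 2 h post-label, and the cell-tracing signal at 24 h.

### Compartment geometry

Segmentation is semi-manual by design: the rudiment contour, optional neck
contour, basement-membrane polyline, centre point and dorsal/ventral
orientation are inputs.  From them:

- **Ectoderm**: tissue on the outer side of the basement membrane, refined
  with a region-based (Chan–Vese) active contour (µ = 0.1, level-set
  tolerance 1e-4, cap 200 iterations).  The image is median-filtered with a
  7 px window first so the three intensity classes (background, cytoplasm,
  nuclei) collapse to two; otherwise the two-phase contour separates nuclei
  from everything else instead of tissue from background.  Arms are split
  at the attachment-zone columns where the (2 px dilated) rudiment meets
  the band; on sections where the rudiment no longer reaches the band the
  split falls back to the annotated centre column, with a warning.
- **Core/periphery**: on central sections only, the rudiment is eroded by
  unit-disk steps (equivalently, Euclidean-distance thresholds) and the
  level whose core:whole area ratio is closest to 1:3 is kept, ties toward
  the smaller core.  The 1:3 figure is interpreted as core:whole (so
  periphery:core = 2:1) and is configurable, since the phrase "1:3 area
  ratio" admits both readings.  A mask that empties before any usable ratio
  returns an empty core with a warning rather than an error.
- **Mammary mesenchyme**: a 15 µm dilation band around the epithelium
  (disk radius rounded to pixels; an error below one pixel), minus
  epithelium and ectoderm, restricted below the membrane.
- **Dermal mesenchyme**: the window between a line through the MR centre
  parallel to the local basement membrane and a parallel line 65 µm deeper.
  "Parallel to the ectoderm" is underdefined for a curved membrane, so the
  local direction is the principal axis of the membrane vertices within
  ±100 µm of the centre.  Windows running off the image are clipped with a
  warning.

### Volumetry

Per-section epithelial areas are plotted against nominal cumulative depth
(section index × thickness; lost sections leave gaps, no renumbering) and
fitted with Levenberg–Marquardt least squares (relative parameter tolerance
1e-8, 500 evaluations).  Two dome models are provided because the original
functional form is not recorded anywhere: a Gaussian A·exp(−(z−z₀)²/2σ²)
(default for dome-shaped rudiments; volume A·σ·√2π) and a parabola
k·max(0, R² − (z−z₀)²) (exact for spheres and ellipsoids of revolution;
volume 4/3·k·R³).  The model name is stored in the output for provenance.
Initialisation: amplitude = max area, centre = argmax depth, width = a
quarter of the depth span — robust for unimodal profiles.  All-zero
profiles return volume 0 without fitting; profiles with fewer than three
positive samples are under-determined and raise a convergence error
carrying the last residual.  Trapezoidal integration of complete profiles
is kept as the model-free baseline; no shrinkage correction is applied and
no stereological variance is estimated.

### Influx arithmetic

Unlabelled ectodermal cells enter the rudiment with the same probability as
labelled ones, so the fold increase of labelled rudiment pixels divided by
the ectodermal labelled fraction estimates total influx, and multiplying by
the rudiment's own labelled fraction converts it to an expected volume fold
increase: ΔV_exp = ((B₂₄−B₂)/B₂) / f_ect × f_mr.  The estimator slightly
overestimates the influx contribution because the few labelled resident
cells also divide; `simulate_influx` reproduces both properties (exact
unbiasedness without proliferation, overestimation of the influx-driven
fold with it) with binomial sampling of labelling, influx and divisions.
Fold increases are (X₂₄−X₂)/X₂ throughout, so "doubling" is 1.0; the
hypertrophy bound ((r+g)/r)³ is reported as the volume *ratio* (≈1.73 for
r = 5, g = 1), matching how "≈1.7-fold" is conventionally quoted.  The
proliferation-contribution estimate
(embryo_fold / ect_over_mr_ratio − 1)/(mr_fold − 1), clipped to [0, 1], is
one defensible reconstruction of an under-specified calculation; the
interpretation string is embedded in the result and the value is treated as
indicative only.

Reported tables round ΔV to two decimals.  When printed reference values
are supplied, cells that cannot be reproduced from the (rounded) printed
inputs are flagged `exp_consistent = False` rather than forced; with the
bundled thirteen measurement rows, all thirteen observed and nine of
thirteen expected cells agree at two decimals, the remainder differing by
0.01–0.10 because the printed fractions are rounded to two digits.

### 3D reconstruction

Consecutive sections are registered to the first section by non-reflective
similarity transforms (rotation, uniform scale, translation; det > 0)
estimated in closed form (Umeyama) from three control points.  Images are
resampled bilinearly, label masks nearest-neighbour.  The aligned stack is
converted to inverted grayscale (1 − ITU-R 601 luma / 255) and thresholded
at 0.65, which isolates the near-black DAB precipitate; 3D components use
26-connectivity on anisotropic voxels (pixel × pixel × section thickness)
and a size window (default 0.3×–3× the expected nucleus volume) removes
speckle and artefacts.  Touching nuclei are split by a
distance-transform-seeded geodesic partition: seeds are maxima of the
anisotropy-aware Euclidean distance transform, de-duplicated greedily by
physical distance (so nuclei stacked in consecutive sections keep separate
seeds while in-plane plateau duplicates are suppressed), and voxels are
assigned by watershed of the negated distance map within the foreground —
a stand-in with the same goal as evolving generalized Voronoi diagrams,
operating in 3D, and validated on constructed fusion phantoms.  The split
preserves the foreground voxel set exactly.  Iso-surfaces are marching-cubes
meshes of zero-padded binary masks at the 0.5 level in µm coordinates.

### Statistics

Mean ± sample SD with group size; two-sided Student's t-tests (paired when
BrdU-exposure conditions match, classic equal-variance pooling otherwise,
Welch behind a flag); one-way ANOVA across the five rudiments; asterisks at
p < 0.05; no multiple-testing correction, matching the convention of the
tables these functions reproduce.  Identical constant samples report p = 1
(no evidence of difference) rather than NaN.

## The phantom generator

The phantom emulates what the measurements need and nothing more: a
single-layered ectoderm band (18 µm) across the image top, an ellipsoid
rudiment (default semi-axes 55 × 45 × 40 µm, volume ≈ 4.1 × 10⁵ µm³ — the
E13.5 scale) embedded through the basement membrane, an optional neck
cylinder, a 15 µm mammary-mesenchyme band and a 65 µm dermal window, with
elliptical nuclei (radius 2.5–2.8 µm) placed on jittered grids wholly
inside their compartments and labelled by independent Bernoulli draws.
Default labelling fractions are 0.22 (ectoderm), 0.045 (rudiment) and 0.20
(mesenchyme) — the 2 h pulse rates of the system being emulated.  Rendering
uses four flat colours (DAB brown, hematoxylin blue, pale cytoplasm,
near-white background) plus ±3 grey levels of noise, chosen so colour
thresholding is exact by construction.  Sections are 5 µm at 1 µm/pixel on
a 190 × 256 canvas; stacks are bit-identical under a fixed seed.

What the phantom does **not** model — stain intensity gradients, touching
compartments with ambiguous boundaries, tissue deformation between
sections, out-of-focus blur, chromatin texture — means that passing phantom
tests demonstrates the correctness of the geometry, counting and inference
machinery, not robustness to real-slide stain variability; on real material
the colour thresholds are user-set, as in any manual-thresholding workflow.
Nucleus ground truth is per-section (a nucleus spans one 5–6 µm section, as
in real material at this thickness); coincidental in-plane overlap of
nuclei in consecutive sections therefore fuses 3D components, which is the
realistic workload for the splitting stage rather than an artefact.

## Problem sizes and runtimes

The test suite runs phantoms of 4–21 sections at 190 × 256 px: large enough
for ≥500 ectoderm nuclei (binomial checks at 3 SE), full coverage of a
50 µm sphere at 5 µm sections, and stable Chan–Vese behaviour, while the
whole suite completes in well under a minute.  The estimator validation
uses 150–200 simulation replicates of a 2000-cell rudiment.  These sizes
are the package's defaults for self-tests; all are configurable.

## Known limitations

- The active-contour refinement assumes the ectoderm lies above the
  basement membrane in image coordinates (surface up), the orientation the
  annotation convention fixes.
- The dermal window excludes somites only by line placement; additional
  manual exclusion masks can be intersected by the caller when that is not
  sufficient.
- Whether pooled or single-sided ectoderm fractions feed the influx
  arithmetic is a caller choice; the tabulation exposes both (`ECTODERM`
  aggregate row and per-arm rows), with pooling as the default reading.
- The nucleus splitter is a geodesic-partition stand-in, not a
  reimplementation of evolving generalized Voronoi diagrams; on heavily
  blurred (re-registered) stacks it can leave an occasional fusion
  unsplit.
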