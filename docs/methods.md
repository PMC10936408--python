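# Methods

This note records the models, parameter choices and numerical decisions
behind `beadframe`, and what the synthetic phantoms do and do not
demonstrate about real data.

## Coordinate and unit conventions

Pixel coordinates are 0-based `(x = column, y = row)` and refer to pixel
centers. Lengths along the optical axis (depths, radii, attenuation
lengths) are in micrometres; in-plane quantities are in pixels and are
converted through the instrument pixel scale. An `AffineTransform` maps
`p -> L p + t`; affine fits solve the x and y rows as two independent
3-parameter linear systems, because displacements along the two axes are
treated as independent throughout the pipeline.

## Physical bead model

A fiducial bead is modeled as a sphere of constant emissivity and radius
`R` whose center sits at depth `zc` below the current optical surface. The
excitation laser illuminates a thin layer `[zs, zs + dz]` below the
surface, and emission from depth `z` is attenuated by the substrate as
`exp(-z / tau)`. For in-plane distance `rho` from the center the sphere
chord spans `zc ± sqrt(R² - rho²)`; intersecting it with the excited layer
gives the closed-form brightness profile

    I(rho) = A * tau * (exp(-a/tau) - exp(-b/tau)) + B,

with `[a, b]` the clipped chord. Both observation regimes fall out of the
same expression: a surface cutting through the bead (`|zc| < R`) and a
fully embedded bead emitting just under the surface (`zc > R`).

Defaults: `zs = 2 um`, `dz = 5 um` (the excited layer sits a few microns
below the block face and is thin compared to the 15 um sectioning),
`tau = 30 um` (substrate attenuation length; with these values the profile
shapes span flat-topped disks to soft-edged caps, matching the variety of
projected bead images). `zs`, `dz` and `tau` are instrument/substrate
properties, so they are frozen per sample and not fitted per bead.

**Fitting.** The fit is maximum likelihood under Poisson counting
statistics (`sum(mu - k log mu)`), over six parameters: `x0, y0, R, zc,
A, B`. Initialization is moment-based (border-median background, intensity
centroid, equivalent-area radius, amplitude scaled to the observed peak).
Optimization is a Nelder–Mead simplex run twice — the second start from the
first optimum breaks out of the collapsed simplex that the strong `R`/`zc`
degeneracy tends to produce; noiseless renderings then recover parameters
to machine precision, and the degeneracy shows up only as an inflated
radius variance (~5% at high S/N) while centers stay accurate to ~0.01 px.
Degenerate cutouts (no significant peak, or a fitted radius below 1.5 px —
a noise spike, not a sphere) return a failure sentinel
(`fit_quality = inf`), never an exception mid-catalog. The S/N statistic is
`peak * sqrt(area) / sqrt(background + peak)`.

**False positives.** Following the catalog-level rule, fits whose radius
exceeds 5x the per-catalog average radius are flagged (small tissue
fragments fit the polar-symmetric model poorly and run away in radius);
failed fits are flagged outright.

## Tile preprocessing

* **Dark**: iterative 3-sigma-clipped mean over pooled pixels. Appropriate
  for a photomultiplier-style detector whose thermal signal is a constant
  pedestal. Correction is opt-in; slide-scanner-like modalities leave it
  off.
* **Flatfield**: per-pixel median (mean optional) over a tile stack,
  normalized to median 1. With spatially uncorrelated content the sampling
  noise of the per-pixel median is `1.25 * CV / sqrt(n_tiles)`, which is
  why ≥ 20 tiles are required by default and ~500 give the 2% regime; with
  fewer tiles a stored calibration can be supplied (the response is stable
  over days to weeks).
* **Distortion**: displacement field `D(p)` (grade-3 bivariate polynomial
  per axis, coordinates normalized about the field center) such that a raw
  pixel `p` observed world coordinate `center + M (p - center) + D(p)`.
  Overlap data only constrain differences `D(p) - D(p - s)` up to a
  per-pair constant, so the constant and pure-linear (magnification) parts
  are unobservable from overlaps; the basis therefore has zero value and
  zero gradient at the field center — physically, distortion vanishes at
  the center and grows toward the corners — and `magnification_x/y` are
  explicit fields defaulting to 1. Local misalignments of 50%-overlap pairs
  are measured by sub-pixel phase correlation on Hann-apodized 32 px
  patches every 8 px (the apodization suppresses a patch-edge bias of
  several tenths of a pixel on smooth scenes); the polynomial coefficients
  and per-pair constants are solved jointly by linear least squares.
  Correction is pull-based (corrected pixel samples the raw position
  solving `c(p) = q`, inverted by fixed-point iteration to < 0.01 px),
  bilinear by default, nearest-neighbor for label images; pixels mapping
  outside the raw frame get confidence 0.

## Stitching

Pairwise displacements are integer-valued (no sub-pixel resampling at this
stage) and minimize `sum(w_a w_b (a-b)²) / sum(w_a w_b)` over the overlap,
with the confidence maps as weights. The whole search surface is computed
exactly by expanding the masked SSD into three FFT cross-correlations; the
top candidates are re-scored directly so the result is identical to a
brute-force search (ties break toward the reported offset). The search
window defaults to ±16 px, about 4 standard deviations of the relative
stage-positioning error at the down-scaled phantom geometry. Overlaps are
declared information-poor — and the microscope's reported offset retained —
when their weighted variance is below an absolute floor or below
`poisson_factor` (default 3 in the counts-based stitching chain) times the
mean, i.e. indistinguishable from pure counting noise, when almost no valid
weight overlaps, or when the optimum pins to the search boundary.

Global placement is breadth-first from the tile with the highest mean
intensity (always inside the sample); a tile reachable from several placed
neighbors receives the weighted average of the implied positions, with
inverse-residual weights as the positioning-error proxy. Placement is
single-pass; disconnected tiles fall back to reported positions shifted
consistently into the placed frame. Assembly accumulates
`intensity x confidence` and `confidence` stage buffers and divides —
overlap averaging with no nonlinear blending, so seams on flat-fielded
constant scenes are exactly flat.

## Serial-section alignment

Within each bead track (transitive closure of mutual-nearest-neighbor
matches between consecutive slices; tracks spanning < 2 slices discarded),
every observation pair `(i, j)` contributes a row `Delta_j - Delta_i =
x_j - x_i` with weight `1/(var_i + var_j)`. The system is sparse and solved
per axis with LSQR; the reference slice (default 0) is pinned to (0, 0) —
any other gauge differs by a global constant. The sparse solution matches a
dense least-squares solve to better than 1e-8 on 50-slice systems. Formal
per-slice uncertainties come from the diagonal of `(C^T C)^{-1}` scaled by
the residual variance. Offsets are written into store metadata; pixels are
never resampled at this stage.

## Cross-modal federation

The transformation model is strictly affine (6 degrees of freedom) — the
sections can deform slightly, but over ~1 cm fields an affine keeps
sub-cellular precision and every coefficient has a physical reading
(rotation, scale, shear).

* **Coarse orientation**: both images are block-averaged (default factor
  32; 4–8 at phantom scale) and each of the four flip hypotheses is scored
  by exact masked normalized cross-correlation over all displacements
  (five FFT correlations per hypothesis; overlaps below 25% are excluded).
  Plain NCC rather than whitened phase correlation, because blob-dominated
  microscopy content has little high-frequency power. On nearly
  point-symmetric samples the intensity level may leave the flip ambiguous,
  so the ranked candidate list can be returned and the downstream bead
  matcher used as the tiebreaker (the pipeline does this). The reference
  image may be the median over slices (suppresses beads, appropriate when
  tissue dominates) or the mean (keeps the beads — persistent at fixed xy —
  as sharp anchors, more robust on small or symmetric samples; the pipeline
  and benchmarks use the mean).
* **Slice identification**: the per-slice matched-bead count `N(Z)` is
  computed by running the refinement against every slice catalog, a
  Gaussian with a constant floor is least-squares fitted to it, and the
  available slice closest to the fitted maximum wins. A flat or weak
  profile (peak below 4 matches or not above the median + 1) yields an
  orphan result — a physical section cut above the first imaged plane has
  no volume counterpart, and this is a value, not an exception.
* **Refinement**: iterate nearest-neighbor matching (one-to-one, closest
  wins) and weighted affine fitting to a fixed point (cap 10 iterations;
  convergence = unchanged match set). The first match uses a wide radius
  (~3x the expected initial error), subsequent matches a third of it. The
  best iteration by (match count, −median residual) is returned, so the
  reported match count never decreases against earlier iterations. For
  small fields with critically few beads a rigid (rotation + translation)
  model, solved in closed form by weighted Procrustes, replaces the full
  affine and is then compounded with the well-determined slide-to-volume
  transform; one further refinement pass against the volume beads follows
  where possible, and a degenerate refinement falls back to the unrefined
  compound with a warning.
* **Errors**: Cartesian distances in um between reference bead centers and
  reprojected modality centers; the package reports the per-pair distances,
  their cumulative distribution and the median.

## Cell segmentation

Probability maps (background / nucleus / cytoplasm per pixel) are an input
contract — they come from an upstream trained network and are synthesized
by the fixture generator for testing. Nuclei: Gaussian smooth (sigma 1 px
at ~1 um/px), Otsu threshold, distance-transform local maxima (minimum
separation 4 px) and watershed. Cells: the same procedure on the sum of the
nuclear and cytoplasmic channels, but watershed-seeded at the nucleus
labels, which guarantees exactly one cell per nucleus sharing its centroid;
containment of the nucleus in its cell is enforced exactly. Features are
per-label mean intensities over all channels plus areas from the zeroth
moment (pixel counts). Tiling for network-sized inputs uses 256 px tiles at
a 50 px stride with edge tiles shifted inward; duplicated detections from
overlapping tiles are merged keeping the instance whose centroid lies
farthest from its tile border. Evaluation matches predicted to true objects
one-to-one, greedily by descending IoU with a strict IoU > 0.5 criterion,
and reports pixel-wise and object-wise F1 (empty predictions score 0).

## Synthetic phantoms

The default phantom is deliberately down-scaled so the full chain runs in
seconds: 8x8 tiles of 128 px at 2 um/px (a ~1.9 mm stage), 20 slices of
15 um, 120 beads of radius 45 ± 2 um spanning the block depth (~30 visible
per slice), a central tissue region of smooth anisotropic bumps, optional
small bright fragments as detector confusers, optional substrate
autofluorescence texture (sum of random plane waves) that makes overlaps
informative everywhere, per-slice stage drift (1.5 um/slice in x plus
0.5 um jitter — a monotone drift in one axis, as a microtome pushing into
the block produces), stage-positioning errors of 7.5 um SD (the 5–10 um
regime), flatfield and grade-3 distortion fields, a 10-count dark pedestal
and Poisson counting noise. The native instrument geometry (0.56 um/px,
2,080 px tiles) is available by configuration.

Bead emission is rendered through the same chord-integral model the fitter
uses, but with 2x2 subpixel supersampling (the fitter evaluates at pixel
centers), so rendering and fitting are deliberately not the identical
discretization; an exact pixel-center rendering is available for
noiseless-recovery tests. The slide modality is rendered by evaluating the
scene at affinely mapped coordinates (no interpolation), under a random
flip and similarity perturbation (rotation SD 0.03 rad, scale SD 1%,
translation SD 10 px) recorded as ground truth.

What the phantoms do **not** emulate: real tissue morphology and contrast,
optics point-spread functions beyond the layer-emission model, mechanical
deformation of cut sections (the affine model is exercised only against
affine truth), bead clumping or damage, and modality-specific noise beyond
Poisson/Gaussian. Passing tests therefore demonstrate the correctness and
internal consistency of the algorithms under the stated physical model and
noise, not segmentation or registration quality on arbitrary real samples.

## Benchmark / reproduction runs

`beadframe.benchmarks.federation_run` drives the chain per seed on the
default 20-slice phantom: volume and slide bead catalogs enter at the
fitted-center precision level (ground-truth centers plus isotropic 0.25 px
jitter — the quarter-pixel contract the profile fitter meets), while the
coarse orientation match runs on actually rendered images; the small field
is a 300 px crop (~10% of the slide area, typically 4–10 beads) with its
own rigid perturbation. Reported figures are per-seed means of per-slide
medians, in um. `scripts/acceptance.py` averages 10 derived seeds
(~2 minutes on one CPU); the test suite uses 3 seeds for the same checks.
Problem sizes throughout the tests (tile counts, slice counts, bead
numbers, 500-bead centering samples, 10-seed segmentation fixtures) were
chosen so the whole suite completes in a few minutes while keeping the
statistical bounds meaningful.

## Known limitations

* Rotation between consecutive volume slices is not modeled (2-DOF
  translations only), matching the serial-section acquisition geometry;
  cross-modal transforms carry the full 6 DOF.
* The distortion calibration cannot observe absolute magnification from
  overlaps; `magnification_x/y` must come from an external scale reference
  if needed.
* The `R`/`zc`/amplitude degeneracy of the bead model inflates radius
  uncertainty at finite S/N (~5% at high S/N); centers are unaffected.
* Global placement is single-pass breadth-first; a full simultaneous
  least-squares over all tile pairs would be strictly better on
  pathological graphs but is unnecessary at the achieved accuracy.
* The N(Z) Gaussian is fitted to raw counts (no Poisson weighting); with
  ≥ 20 beads per slice the peak is unambiguous.
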