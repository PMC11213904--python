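# Methods

This note documents the models, conventions and numerical choices behind
`fullfield`, and what the synthetic fixtures do and do not establish.

## Optical model of the display

The display is a section of a cylinder of radius *r* = 11 in = 27.94 cm
subtending a 120° chord angle about its axis, tilted τ = 10° relative to
the scanner-bore axis, with a usable surface of 58.5 cm (arc) × 44 cm
(height).  The observer lies supine with a single cyclopean eye on the
mid-sagittal plane at distance *d* from the screen-surface centre along
the radius (13.5–16.5 cm depending on head size and cushioning; 15 cm
nominal).  All visual angles are monocular; binocularity and per-subject
head pose are deliberately out of scope.

Closed forms used throughout:

* surface arc length: `s = r·θ` with θ in radians;
* horizontal visual angle of the screen, with eye offset `e = r − d`
  from the axis: `2·atan2(r·sin(θ/2), r·cos(θ/2) − e)`.  This passes
  175° at d = 15 cm and 168°–182° over the 16.5–13.5 cm range;
* vertical visual angle: the vertical section of a cylinder is a
  straight segment of length *H* = 44 cm, tilted by τ about the screen
  centre, so the subtended angle is
  `atan(H/2·cosτ/(d − H/2·sinτ)) + atan(H/2·cosτ/(d + H/2·sinτ))`.
  This is an envelope figure (the tilt pivot and vertical eye position
  are idealised); it spans 106.5°–117.3° over the stated distances and
  the module documents it as an approximation;
* perspective camera: `tan(hfov/2) = aspect·tan(vfov/2)`, giving the
  120.2° horizontal FOV of the 105°-vertical 4:3 render camera.

### Projector pose

The mirror periscope makes the projector act as a virtual pinhole behind
and below the bore.  We model it **on the bore axis** at axial distance
`z = r/tan(incidence)` behind the screen centre, aimed at the screen
centre, with incidence 18.2° onto the untilted bore wall (28.2° onto the
tilted screen).  An on-axis source preserves azimuth around the bore,
which is what makes a low-parameter calibration model work at grazing
incidence.  The frustum half-angles and a vertical aim offset are free
installation parameters; the reference defaults (hfov 50.49°, vfov
53.21°, aim −0.0369 in tangent units) are solved so that the traced
footprint of the screen spans exactly 828 × 284 px of the native
1024 × 768 raster — the installation this package models.  Note the
**bounding extent** of the lit region is what spans 828 × 284 (≈30% of
the raster); the curved band inside it lights only ≈18% of the pixels.

`trace_projector_ray` intersects each pixel's ray with the tilted
cylinder (quadratic in the axis-orthogonal plane) and takes the nearest
intersection lying on the screen sector; `surface_to_pixel` is its exact
algebraic inverse.  The pair is the optical ground truth against which
the calibration-driven warp is tested.

## Calibration and warp

Calibration measures projector-pixel coordinates of ≥3 points per screen
edge (corners and midpoints, i.e. known arc-length fractions along the
top and bottom outlines).  `fit_calibration` recovers the four pose
parameters by Levenberg–Marquardt on reprojection error.  We also fit a
circular arc through each edge's points; the arcs validate the
measurement (collinearity, crossing edges, top/bottom swap — the
projector-near edge must image wider) and summarise the active region.

A design alternative — interpolating purely in 2-D between the fitted
arcs (equal-angle horizontally, linear between arcs vertically) — was
implemented and measured against the ray-traced truth: perspective
foreshortening between the near and far edges leaves residuals of up to
~28 px under the reference pose, far outside tolerance.  The shipped
warp therefore ray-traces the fitted physical model for every output
pixel, which satisfies the wallpaper rule exactly on the display
surface: source x proportional to surface arc length, source y
proportional to surface height, so the 4:3 aspect of the source is
preserved on the physical surface and off-screen pixels are exactly
black.  With noise-free calibrations the fit recovers the generating
pose to machine precision; with 0.5 px measurement noise the warp stays
within 1 raster px of the truth across plausible pose jitter.

Resampling is bilinear by default, with a nearest-neighbour option for
binary patterns (no gray halos).  `unwarp_image` maps each source pixel
forward and samples the warped raster; source pixels whose sampling
neighbourhood touches unlit raster are flagged in a mask, not
extrapolated.  The warp → unwarp round trip on a structured scene stays
above 30 dB PSNR in the mask interior, the loss being ordinary double
resampling at a ~2.7× vertical compression.  A 4k projector raster is a
pure rescale of the map (×3.125 vertically for 2400/768).

## Eccentricity mapping and stimuli

The source canvas is pasted onto the surface like wallpaper, so canvas
pixels are uniform in surface arc length.  Eccentricity (visual degrees
from fixation) maps to canvas radius proportionally — `ecc/halfwidth ×
(canvas width/2)` evaluated at the nominal 15 cm distance — which is
exact in the same approximation in which surface arc is proportional to
visual angle.  One isotropic pixels-per-degree scale (the horizontal
one) is used for drawing rings and discs; the canvas is nearly isotropic
in cm/px (17.5 horizontal vs 17.45 vertical).

* **Eccentricity rings** — five bands (≤1.8°, 2.0–5.6°, 6.3–16.5°,
  18.5–50.3°, ≥55.3°) drawn as polar checkerboards.  Check size scales
  log-radially with constant angular subdivisions (24 sectors, 2 radial
  steps per octave by default); the alternation states are black/white,
  inverted, and random-colour at 4 Hz.  The check dimensions themselves
  are a package choice (not constrained by the protocol).
* **Phase scrambling** — conjugate-symmetric random phase offsets (the
  phases of a real white-noise field) are added per channel; the DC term
  is untouched, so the amplitude spectrum and mean luminance are
  preserved to numerical precision.  The offset field is shared across
  colour channels by default (preserving inter-channel structure), with
  an independent-channels switch.
* **Postcards** — the whole image (never a crop) is bicubically rescaled
  to 205 × 154 px (44° wide; 171 × 129 for face/object bounding boxes)
  and centred in a padded 1024 × 768 canvas.
* **Scotomas** — hard-edged central discs at diameters {0, 29, 58, 88,
  140}° (protocol values; the rounded running-text variant
  {0, 30, 58, 88, 138}° is selectable).  Diameter 0 is the identity.
* **Item arrays** — 13 items per array: 3 of 113 px on a 100 px-radius
  ring, 6 of 178 px at 275 px, 4 of 295 px pinned at the canvas corners
  (inset 130 px; corner items may crop at the canvas edge).  Ring radii,
  inset and the ±8 px jitter are package choices sized so a jitter-free
  layout has positive clearance everywhere; jitters are rejection-
  sampled until no two item discs overlap, and an unsatisfiable spec
  raises with the attempt count.
* **Luminance matching** — exact histogram specification by rank: each
  image's sorted pixel values are replaced by the set-average sorted
  distribution (plain histogram equating, not a full spatial-frequency
  equating pipeline).

## Run designs

TR is 2.0 s everywhere and every run must total a whole number of TRs.

* retinotopy: 7 conditions (horizontal/vertical meridians + 5 rings) × 7
  blocks of 6 s, 7 interleaved 6 s fixation blocks, 6 s lead-in/out:
  348 s = 174 TRs.
* exp2: 7 conditions × 3 epochs of 12 s blocks each followed by 6 s
  fixation; 6 trials per block (1.5 s + 0.5 s; 5 unique images + 1
  adjacent repeat for the one-back task); 15 unique images per condition
  split across its 3 blocks without reuse.
* exp3: 20 conditions (4 contents × 5 scotomas) × 2 epochs of 8 s blocks
  with 5 rest blocks inserted per epoch; 5 trials per block (1.1 s +
  0.5 s; 4 unique + 1 repeat).

The published totals for exp2/exp3 (195 and 208 TRs) exceed the bare
block arithmetic (189 and 200); the residual is modelled as 6 s/8 s
lead-in and lead-out fixation.  That placement is an assumption and is
flagged as such, not asserted.  Block order is an independent uniform
permutation per epoch, rejection-resampled so no condition label repeats
back to back, including across epoch boundaries.

## GLM and derived maps

The design matrix holds one column per condition — a boxcar at 16×
supersampled resolution convolved with a canonical double-gamma HRF
(response gamma shape 6, undershoot shape 16, ratio 1/6, unit peak,
peaking near 5 s; the kernel id is recorded on outputs) — plus
standardised motion regressors and an intercept.  Zero-variance nuisance
columns are dropped with a warning; rank deficiency raises and names the
collinear columns.

Fitting is voxel-wise least squares with one Cochrane–Orcutt iteration:
AR(1) coefficients from OLS residuals (binned to 0.01 for vectorised
prewhitening), then a whitened refit.  Betas are converted to percent
signal change **of the estimated baseline** (the intercept coefficient)
rather than the raw temporal mean — the raw mean contains task variance
and biases PSC by 1–3%; the intercept convention recovers planted
amplitudes exactly in the noise-free limit.  Contrast t-maps use
`c·(X′wXw)⁻¹·c` with the voxel's whitened design.  Thresholding is
voxel-wise uncorrected p (the ROI-definition convention); conjunction
ROIs take the minimum pairwise contrast statistic, which is provably the
intersection of the pairwise threshold masks.  tSNR is mean/SD per voxel
(sample SD); constant series are reported infinite with a count.
Winner-take-all preference maps break exact ties toward the lowest
condition index with zero strength; group maps average betas across
subjects before the argmax.  The ROI ANOVA is the balanced two-way
(size × content) fixed-effects model on per-subject cell means, with
η² = SS_effect/SS_total.  Spatial smoothing is assumed done upstream
(volumes are treated as preprocessed); no cluster correction is applied.

## Synthetic data

The BOLD simulator generates
`y = baseline·(1 + Σ_c β_c·x_c/100) + drift + AR(1) noise` with the same
peak-normalised convolved boxcars as the design matrix, Legendre-
polynomial drift (order 2, SD 0.5 baseline units by default) and
baseline 100, so planted βs are in PSC units by construction.  The
retinotopic population assigns each voxel one preferred band at
`base + margin` PSC against `base` elsewhere.  Default simulation scale
(a few hundred voxels × 174–208 TRs) keeps the full suite in minutes on
one CPU.

What the simulator does **not** emulate: hemodynamic nonlinearity,
physiological (cardiac/respiratory) noise spectra, motion, spatial
autocorrelation, susceptibility dropout, and between-subject
variability.  Passing tests therefore establish the correctness of the
algorithms under their own assumptions — recovery of planted structure,
exactness of closed forms, constraint satisfaction — not the empirical
effect sizes of any scanned population.  Procedural "scenes", "faces"
and "objects" are schematic drawings with naturalistic (power-law)
amplitude spectra standing in for photographs; they exercise the
pipeline but carry no claim of perceptual validity.

## Numerical conventions

Angles are degrees at API boundaries and radians internally; physical
coordinates are cm with the origin at the screen-surface centre; unit
conversion is fixed at 2.54 cm/in.  Images are float arrays in [0, 255]
row-major (y, x); PNG I/O quantises to uint8.  All generators are pure
functions of (spec, seed) and reproduce byte-identical outputs.
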