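# fullfield

Toolkit for **ultra-wide-angle (full-field) visual fMRI**: modelling and
calibrating a curved projection screen inside the scanner bore, warping
stimuli onto it, generating wide-field stimulus sets, sequencing blocked
fMRI runs, and running the first-level analysis that turns the resulting
time series into eccentricity-preference and category-selectivity maps.

## The problem

Human vision spans roughly 220°, but a standard scanner projection
setup stimulates only the central 10–20°.  Bouncing the projector off
angled mirrors onto a cylindrical screen wrapped around the head makes
a ~175°-wide display possible — at the cost of serious geometry: the
projector strikes the tilted, curved screen at a grazing angle, so a
rectangular image must be computationally warped into the small curved
region of the raster that actually lands on the screen, stimuli must be
drawn in visual-degree units that respect the cylindrical mapping, and
the analysis must chart voxels by their preferred eccentricity out to
the far periphery.

This package implements that whole chain as a library, testable end to
end on synthetic data.

## The core models

**Screen optics.** The screen is a cylinder section of radius
*r* = 11 in = 27.94 cm and chord angle θ = 120°, tilted 10° in the
bore, viewed from *d* = 13.5–16.5 cm.  Key closed forms:

- arc length: *s* = *r*·θ = 58.5 cm;
- horizontal visual angle with eye offset *e* = *r* − *d*:
  2·atan2(*r*·sin θ/2, *r*·cos θ/2 − *e*) → 175° at *d* = 15 cm
  (168°–182° across the distance range);
- render-camera relation tan(hfov/2) = aspect·tan(vfov/2) → a 105°
  vertical FOV at 4:3 is 120.2° wide, matched to the 120° chord.

**Warp.** A virtual projector on the bore axis at grazing incidence
(~18° on the bore, ~28° on the tilted screen) is ray-traced through the
native 1024 × 768 raster; only an 828 × 284 px bounding region reaches
the screen.  Calibration measures a few screen-outline points in
projector-pixel coordinates and recovers the projection model by
nonlinear least squares; the warp then pastes the source image onto the
surface like wallpaper (source x ∝ surface arc length), preserving the
4:3 aspect on the physical screen, with off-screen pixels black.

**Analysis.** Per-condition boxcars convolved with a double-gamma HRF,
motion nuisance + intercept, AR(1)-prewhitened least squares with betas
in percent signal change; contrast t-maps, minimum-statistic
conjunction ROIs, tSNR, ROI overlap removal, a balanced two-way
(size × content) ANOVA with η², and winner-take-all eccentricity
preference maps with top1 − top2 strength.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```bash
python examples/02_warp_calibration.py
```

prints (abridged):

```
calibration fit RMS: 0.18 px
active on-screen region: 828 x 284 px (of the native 1024 x 768 raster)
lit raster fraction: 18.1% (bounding extent 29.9%)
warp -> unwarp PSNR: 32.0 dB
```

Reading: six simulated calibration clicks (0.3 px noise) recover the
projection model to sub-pixel accuracy; the on-screen bounding region
matches the installation's 828 × 284 px; warping a scene onto the
screen and inverting it loses little detail (>30 dB), so the displayed
image is a faithful wallpaper of the source.

```bash
python examples/06_preference_map.py
```

```
winner-take-all recovery of planted band preference: 100.0%
mean preference strength (top1 - top2): 0.89 PSC
```

Reading: simulating a 174-TR retinotopy run over 500 voxels with a
planted 1-PSC preference margin per voxel and refitting the whole
GLM → preference-map chain recovers every voxel's preferred
eccentricity band.

The other examples cover the geometry report (`01`), every stimulus
class (`03`), the three run protocols and their 174/195/208-TR timings
(`04`), and GLM amplitude recovery under AR(1) noise (`05`).  A thin
CLI (`fullfield geom-report`, `warp-calibrate`, `warp-apply`,
`stim-build`, `design-build`, `analyze-tsnr`, `analyze-glm`) wraps the
same calls for shell use.

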