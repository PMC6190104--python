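# Methods

## Problem setting

A visual-servoing microinjection station must, from live bright-field video:
(1) focus the microscope on the embryo, (2) locate the embryo's centre,
(3) locate its own pipette tip, and (4) move the tip onto the centre.  This
package implements those four stages as pure image computations and drives
them with a synthetic-scene generator, so correctness is measured against
known ground truth rather than by eye.

## Synthetic scenes

A scene is rendered as: geometry → defocus blur → illumination → sensor
noise → clamp to 8-bit.  The embryo is two concentric ellipses — a dark
membrane annulus (default intensity 80, thickness 10 px) around a yolk disc
(150) on a bright background (200) — matching the bright-field appearance of
a chorionated embryo.  Granular texture (Gaussian, σ = 15 gray levels,
seeded) is placed in the yolk only; the chorion envelope is smooth.  This
fine-scale texture is what defocus attenuates, so focus measures respond to
blur even inside an otherwise flat disc.  The pipette is a dark filled taper
from an image edge to its tip; its shaft extends beyond the frame so
translating the tip keeps it attached to its entry edge.

*Defocus* is an isotropic Gaussian PSF with
`sigma(z) = sigma_at_focus + blur_slope·|z − focal_z|`
(defaults 0.8 px + 0.004 px/µm).  The linear growth is the simplest model
that is minimal exactly at focus and strictly increasing on either side,
giving the unimodal focus curves a real through-focus series shows.  A
Gaussian at focus of σ ≈ 0.8 px corresponds to the diffraction-limited spot
of a 0.1-NA, 4× system sampled at ~2 µm/px.

*Illumination* is a multiplicative gain field (bilinear between four corner
gains, or radial) applied after rendering and before noise, so a shadow dims
object and background alike while the sensor noise floor stays constant.
The severity of a field is `1 − min(gain)`; the fixture suite ramps the
darkest corner linearly from 1.0 down to 0.4 (a 60% falloff), spanning even
to strongly shadowed fields.  The real system's nonuniformity is not
characterized quantitatively anywhere we can calibrate to; the ramp is a
design choice recorded in every scene's truth record.

*Sensor noise* is additive Gaussian (default σ = 2, typical of an industrial
CMOS at bright-field exposure), applied after blur, before clamping.  Noise
and texture streams both derive from the scene seed, so identical parameters
give byte-identical rasters.

What the generator does **not** emulate: photorealistic embryo morphology
(animal pole, perivitelline detail), debris and meniscus artifacts,
out-of-plane objects, vignetting beyond the gain field, shot-noise intensity
dependence, and motion blur.  Passing tests therefore demonstrate
correctness of the algorithms under controlled degradations — not
performance on any particular microscope.

## Focus measures

Brenner gradient (horizontal, two-pixel baseline), Tenengrad (standard
±1/±2 Sobel stencils), and normalized variance, all accumulated in float64.
The normalized variance divides by the mean only — not the pixel count — as
its defining formula states; along a stack the frame area is constant, so
only relative values matter.  Sums run over pixels whose operands lie fully
inside the image (no padding), making every score a pure function of
observed pixels; this changes absolute values, never the argmax.  Peak
narrowness is quantified as the full width at half maximum of the normalized
curve, linearly interpolated between samples; a curve that never falls below
half maximum on a side has no measurable width and raises `OpenWidthError`.

On the standard synthetic stack (31 frames, 200 µm apart, 192×192 scene) all
three measures peak at the true focal frame, and the Brenner peak is the
narrowest (FWHM ≈ 499 µm vs ≈ 531 µm Tenengrad and ≈ 4269 µm normalized
variance) — the property that makes it the preferred search signal.  The
same ordering holds on noise-free stacks (481/543/4281 µm), so it is not an
artifact of the noise setting.  The Brenner criterion, having no smoothing,
carries the largest relative noise floor of the three; at noise levels
several times higher than the default its normalized tails rise enough to
widen its FWHM past Tenengrad's even though its intrinsic (noise-free) peak
is the narrowest.

## Two-phase autofocus

The coarse phase steps by 200 µm, classifying each consecutive score triplet
as increasing / decreasing / indeterminate with a tolerance of
`epsilon_rel × running maximum` (default 0.02; below the ~1% frame-noise
jitter of the Brenner score this invites false rise-then-fall detections far
from focus).  After a rise followed by a confirmed fall, the controller
backtracks **three** coarse steps and fine-scans forward by 50 µm until the
fine triplet falls.  Three steps, not two: a falling triplet is first
confirmed two coarse frames past the coarse peak sample, and the true peak
can sit up to one further coarse step below that sample, so a two-step
backtrack can start the fine scan above the true peak and miss it.  The
three-step window always brackets the ±1-coarse-step neighbourhood of the
coarse argmax, which is what guarantees agreement with an exhaustive
fine-grid scan to within one fine step.

If the very first coarse triplet is decreasing the scan direction reverses
once (start above focus); a profile monotone over the whole range reports
`converged=False` with the best z seen.  Captures are cached by position, so
revisiting a coarse-grid z during the fine scan is free; the trace and
evaluation count reflect distinct captures.  Over 50 seeded stages the
controller matches the 121-capture fine-grid oracle in 50/50 runs using
~23 captures on average.

The fine step must stay below the optical depth of field,
`DF = 10⁻³·7/(A·M) + λ/(2A²)` mm, evaluated literally.  For A = 0.1, M = 40,
λ = 550 nm this gives ≈ 29 µm; the 50 µm default fine step mirrors the
reference hardware configuration rather than this bound, and both are
configurable.

## Embryo detection

`T(i,j) = A(i,j) − param1` with `A` the weighted mean of the b×b
neighbourhood (Gaussian by default, σ tied to b by the usual block-size
convention; uniform available), replicate-padded at borders.  Pixels above
their threshold map to 255, others to 0; the membrane, darker than its local
surroundings, maps to 0.

Contour extraction labels the dark phase 8-connected after a single 3×3
morphological closing (computed on an edge-replicated pad so border-touching
regions stay border-touching).  The closing exists because a one-pixel noise
break in a thin detected ring would otherwise sever it and promote the inner
membrane edge to "largest closed contour", biasing the fitted axis low by
twice the membrane thickness.  Components touching the border are excluded —
a region running off the frame (pipette shaft, shadowed corner) cannot be a
closed contour, and the embryo never touches the frame.  The surviving
component with the most boundary pixels is hole-filled so its boundary is
the outer contour only, and a direct algebraic least-squares ellipse
(conic fit with ellipse constraint) gives centre, full axis lengths, and
orientation; collinear or under-determined point sets raise.

The circulation tries `b` ascending (default 9, 13, 19, 25, 31, 39) with
`param1` ascending inside (default 5, 7) and accepts the first fit whose
major axis lies in `[L_min, L_max]` (default 0.45–0.95 × the shorter image
dimension — an embryo fills much of the field at injection magnification).
First-acceptance with ascending b makes the result deterministic and
reports the *minimal* workable block size, which grows (never shrinks) with
illumination severity.  The starting block size of 9 was chosen from
synthetic sweeps: the outer membrane contour was recovered in 60/60 scenes
at b = 9, while b = 5 occasionally let the detected ring break under the
strongest gradients.  Larger blocks (≥ 13) sometimes merge the membrane band
with yolk texture into irregular blobs whose algebraic fit collapses to a
small ellipse; those land outside the acceptance band and are skipped by the
circulation — which is precisely the suitability role the band plays.

Global Otsu thresholding (between-class-variance maximization) is included
as the non-adaptive baseline behind the same contour/ellipse stages.  Under
even illumination the two routes agree to within 2 px of centre; under a
60% falloff the single global threshold merges the embryo with shadowed
background and the baseline fails outright, while the adaptive route is
unaffected (worst centre error 0.05 px, worst axis error 0.9% over 120
scenes spanning the ramp).

## Pipette-tip tracking

SSD matching `e = Σ(f − g)²` expands to `Σf² + Σg² − 2Σgf`; with the
template fixed, the cross-correlation term carries the position information,
and normalizing by the window energy, `M = Σg·f / √(Σf²)`, cancels
multiplicative illumination change.  Both measures are evaluated at every
valid origin with exact direct (non-FFT) correlation so scores are
reproducible to the last bit and ties break deterministically toward the
first row-major origin.  Identically zero windows score 0 by convention, so
flat dark regions never win.  The template is stored with offsets `(L, H)`
from its origin (top-left) to the tip; a match at (row i, col j) yields
`tip = (j + L, i + H)`.  Axis convention: i indexes rows (y), j columns (x),
L is horizontal, H vertical.  Rotation and scale invariance are out of scope
because the pipette is rigidly mounted; its orientation never changes.

In simulation the template is acquired from a clean, evenly-lit,
noise-free reference render of the scene's pipette — the analogue of the
operator imaging the needle once under good conditions and marking the tip.
Tip recovery on noisy (σ = 5), unevenly lit scenes is sub-pixel-exact in the
seeded fixtures.

## Servo pipeline

Per scene: (optional) autofocus on a simulated stage → adaptive detection →
tip localization → displacement `(dx, dy) = centre − tip` → the move is
simulated by re-rendering the scene with the pipette tip translated by
(dx, dy) under the same illumination and a fresh noise draw → the tip is
re-measured and the residual distance to the commanded centre recorded.
A residual ≤ 10 px counts as a successful injection — about half the
apparent diameter of a 20 µm injection tip at the working magnification.
Axial penetration and deposition have no image-space consequence here and
are recorded as no-op events; the choice of injection depth is likewise not
modelled.  Stage failures are recorded per scene, never raised, and the
suite report (JSON/CSV, one row per scene with axes, (b, param1), centre,
tip, residual, success) is byte-deterministic for a fixed suite and config.

## Problem sizes

Scenes are 256×256 px (embryo semi-major ~77–95 px), focus stacks 192×192,
autofocus stages 128×128 over a 0–6000 µm range.  The acceptance script uses
31-frame stacks, 50 autofocus stages, 20 detection scenes, 8 tip scenes and
the 14-scene injection suite.

## Known limitations

- Single embryo per field; no chorion-vs-yolk sub-segmentation or tracking.
- The acceptance band on L assumes the embryo fills roughly half the frame;
  heavily cropped or multi-embryo fields need a custom band.
- The tip template is scene-derived in simulation; on a real station it must
  be re-acquired when the pipette is replaced.
- Synthetic severity is a linear/radial gain ramp; real shadows can be
  structured (slide edges, neighbouring embryos) and may require larger
  block sizes than the synthetic sweeps suggest.
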