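# Methods

## Problem setting

AO-SLO records the parafoveal retina at the photoreceptor plane:
a bright cone mosaic crossed by dark vessel shadows in which bright
blood cells move. Two motion scales corrupt the video. Between frames,
the eye translates and rotates the whole field (interframe motion).
Within a frame, because the image is raster-scanned over ~31 ms, eye
motion during the scan warps the image nonrigidly (intraframe motion),
predominantly along the horizontal axis, which is perpendicular to the
fast scanning mirror in the emulated system. Motion-contrast mapping is
exquisitely sensitive to both: any residual misregistration makes
static cone mosaic masquerade as temporal signal.

## Synthetic scene and video model

The generator produces videos whose statistical structure matches what
the pipeline assumes, with every applied distortion recorded as ground
truth.

**Cone mosaic.** Hexagonal lattice with spacing 6 px, per-cone
positional jitter uniform in ±20 % of the spacing, Gaussian profiles
(σ = 1.6 px, peak 110) over a uniform background of 100. At the emulated
sampling (~0.5 µm/px for a 2.8° / 400-px field) a 6-px spacing is a
parafoveal cone spacing of ~3 µm, at the dense end of the realistic
range; what matters for the pipeline is that the background carries
high-frequency texture comparable to real mosaics.

**Vessel.** A smooth random centerline: waypoints evenly spaced across
the width with a cumulative random vertical walk, interpolated by a
cubic spline, arc-length resampled to 1-px nodes. The mask is a
distance threshold at half the vessel width (default 9 px ≈ a small
arteriole/venule); the shadow multiplies intensities by 0.35 with a
1.5-px soft edge.

**Particles.** Bright movers (intensity 190, Gaussian blobs of
σ ≈ 0.3·width confined to the vessel mask) advected along the
centerline at 4 px/frame with wraparound, at 2 per 100 px of
centerline. At 32 Hz and ~0.5 µm/px this is ~0.25 mm/s, a plausible
capillary leukocyte speed at the slow end (slow movers keep several
particles in the field at the short simulated durations).

**Motion.** Each frame after the first receives (i) an intraframe
free-form warp: control-point displacements on a 6×6-interval B-spline
grid drawn N(0, 3 px), with the horizontal component scaled by the
anisotropy factor 2; (ii) a rigid transform with translation
N(0, 3 px) per axis and rotation N(0, 0.3°); (iii) optionally,
sinusoidal fast-axis resampling; (iv) Gaussian sensor noise (SD 3) and
clipping to [0, 255]. Warps are drawn independently per frame rather
than from a continuous eye-motion trace — a deliberate simplification:
registration sees each frame in isolation, so temporal correlation of
the truth would not change what the stages are tested on.

The first frame carries zero motion, so the reference frame equals the
undistorted scene. Real reference frames are themselves distorted; this
choice trades that realism for exact oracles (recovered transforms and
ROI coordinates compare directly against truth). Composition per frame
is particles → intraframe warp → rigid → scan sampling → noise,
matching physical causality (retina moves, scanner samples, sensor adds
noise). Generation uses a single resampling pass,
`frame(p) = img(T(p) + d(T(p)))`, to avoid compounding interpolation
error.

**Ground-truth field convention.** The stored dense field is the
*sampling* displacement d used in backward warping
(`frame(p) = clean(p + d(p))`). A recovered forward deformation d_fw is
therefore scored by the composition residual
`d_fw(p) + d(p + d_fw(p))`, the endpoint error of recovered-then-true
mapping against the identity — zero iff the recovery inverts the
applied warp exactly.

**What the generator does not model.** Optical PSF / wavefront
residuals, photoreceptor reflectance dynamics, erythrocytes darker than
the shadow, continuous intra-scan motion trajectories (and hence
shear/tear patterns tied to scan-line timing), and vessel networks
(a single vessel per scene). Passing tests therefore demonstrate
correctness of the algorithms under the modeled distortion classes, not
clinical performance on real recordings.

## Desinusoiding

Forward model: pixel i of a row samples the retina at
x_i = (W−1)(1−cos(π s_i))/2 where the uniform time samples s_i cover
the central `scan_fraction` (default 0.9) of the half period, min–max
normalized to span [0, W−1]. Correction interpolates each row from
those positions back to the integer grid with a cubic spline, clipped
to [0, 255]. There is no scanner calibration input; the correction is
exact inverse of the package's own forward model, verified by the
round-trip property (< 1 gray level on smooth images away from a 2-px
border). The stage is off by default and enabled when the generator's
scan model is.

## Rigid stabilization

Per frame: minimize the mean squared intensity difference to the first
frame over (θ, t_x, t_y), on a 3-level anti-aliased pyramid, Powell
search per level (parameter tolerance 1e−4) on cubic-spline-interpolated
intensities, translation initialized by phase correlation at the
coarsest level. The first frame is the fixed reference for *all* pairs
(no sequential propagation), matching the elastic stage and avoiding
drift. Recovery on noise-free phantoms is ~1e−3 px / 1e−3°,
comfortably below the 0.1 px / 0.05° requirement.

Validity masks flag pixels sampled within the source pixel footprint
(half-pixel slack, so sub-millipixel jitter cannot shave off border
rows); out-of-bounds samples are filled with the frame mean but never
enter an MSE. The crop is the maximal axis-aligned rectangle inside the
intersection of all masks (histogram dynamic program). Both experiment
branches share this output, so E(−)/E(+) geometry is identical.

## Consistent elastic registration

Deformations are cubic B-spline free-form fields: displacement
d(p) = Σ_kl c_kl B₃(y/h_y − (k−1)) B₃(x/h_x − (l−1)) on a control grid
with one padded border ring; zero coefficients give the identity.
Images are backward-warped, out(p) = in(p + d(p)).

Forward and backward deformations are estimated jointly. Energy terms,
per level:

- **Image**: masked MSE in both directions, intensities normalized to
  [0, 1] so the weights have a stable meaning across stacks.
- **Consistency**: mean squared composition residual in both orders,
  ‖d_b(p) + d_f(p + d_b(p))‖² evaluated exactly (B-spline evaluation at
  the warped points), in px².
- **Regularization**: bending energy — mean squared second differences
  (xx, yy, 2·xy) of each dense displacement component.

Defaults w_img = 1, w_cons = 1, w_reg = 0.1 were fixed by the
warp-recovery property (3-px warps recovered to < 0.5 px mean endpoint
error; no hallucinated warps above 0.3 px on motion-free noisy stacks)
and then left alone. Gradients are analytic up to two standard
approximations: image gradients are sampled by linear interpolation at
the warped positions, and the consistency chain term uses the Jacobian
of the partner field sampled from its dense finite differences
(verified < 1 % against finite differences of the full energy).

Optimization is L-BFGS-B on the concatenated coefficients, coarse-to-
fine over (image scale, grid intervals) = (1/4, 4) → (1/2, 8) → (1, 16),
up to 60 iterations per level — convergence traces showed no measurable
accuracy gain beyond that on the recovery oracles, at twice the cost —
with coefficients carried between levels by value rescaling plus a
least-squares refit of the finer basis to the coarser dense field.
Levels coarser than 12 px or with control spacing under ~1.5 px are
skipped for small inputs. The accepted-energy trace is recorded per
level and is non-increasing (L-BFGS line search accepts only
improvements). A level whose line search finds no acceptable step —
which can happen on nearly-flat landscapes where gradient approximation
error dominates the true gradient — keeps its incoming coefficients and
hands off to the finer levels; only if every level fails are identity
deformations returned, with a warning. Landmark and anti-fold terms of the full
bidirectional formulation are omitted: no landmarks exist in this use,
and folds are excluded by the bending term at the amplitudes the
generator produces.

Stack stabilization registers frames 2..T to frame 1 — exactly T−1
pairwise runs — and replaces each frame by its forward-deformed image.

## Motion contrast

D_k = I_{k+1} / max(I_k, ε) with ε = 1 gray level; the map is the
population variance over k at each pixel. Ratio direction and ε are
conventions (direction is immaterial to the null; the floor prevents
blow-ups in dark shadows); population rather than sample variance
differs only by the constant (T−2)/(T−1) and cancels in any CNR.
Variance is taken on raw ratios, not log-ratios. Display rendering
clips at the 1st/99th percentiles and rescales to 0–255; CNR is
invariant under positive affine display maps, so this choice cannot
affect conclusions (tested to machine precision).

For pure sensor noise the off-vessel ratio variance is ≈ 2σ²/I², the
analytic null the tests check; residual warps inflate it by moving
mosaic texture across pixel boundaries — the mechanism that makes
CNR(E+) exceed CNR(E−).

## CNR and the paired comparison

Foreground = 1-px Bresenham rasterization of the vessel polyline;
background = all 6·400 pixels of the six squares pooled into a single
region (rather than averaging per-square statistics — the difference is
the within-/between-square variance decomposition and is documented
precisely because the convention is a choice). Means and population SDs
feed CNR = (f−b)/√(δf²+δb²); a fully constant map is defined to have
CNR 0. CNR is computed on the 8-bit display rendering, matching how
gray values are read off rendered images in practice. The paired
comparison reports per-condition mean ± SD (sample SD, as cohort tables
do), per-video E(+)/E(−) ratios with mean ± SD, and a two-sided paired
t-test (p defined as 1 when all differences vanish).

## Experiment sizes

The paired experiment runs at 128×128 px and 16 frames with 5 videos —
sizes chosen so a full run completes in minutes on one CPU while
keeping ≥ 15 division images per map and enough field for the full ROI
protocol after cropping. The structural 63-registration contract is
exercised at 64×64 with a reduced schedule, where only the count, not
the accuracy, is at stake. ROI suggestion requires room for six
disjoint 20×20 squares beside the vessel; fields smaller than ~100 px
may not admit it, in which case the generator leaves the suggested ROI
set empty.

## Known limitations

- Single-vessel scenes; no capillary networks or branching.
- Independent per-frame warps understate temporally correlated
  distortion; the elastic stage is agnostic to this, but downstream
  temporal statistics of the truth are not realistic.
- The reference frame is idealized (undistorted); with a distorted
  reference, all deformations would compose with the reference's own
  warp, which this package does not attempt to estimate.
- MSE similarity assumes stable illumination; intensity flicker between
  frames would bias both registration stages.
- The desinusoid model is self-consistent, not calibrated to any
  physical scanner.
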