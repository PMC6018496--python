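# Methods

## Tracking model

The tracker is a kernelized correlation filter: ridge regression over all
cyclic shifts of a padded target window, trained and evaluated in the
Fourier domain. The desired response is a periodic 2-D Gaussian peaked at
the zero shift with bandwidth `sigma_factor * sqrt(h*w) / padding`
(`sigma_factor = 0.1`), i.e. a fixed fraction of the *un-padded* target
size, so the regression demands a sharp peak within the target footprint.
Features are zero-mean grayscale intensities at pixel resolution by default
(cell size 1 keeps the cyclic-shift interpretation exact); per-cell HOG
features (cell 4, 9 unsigned orientation bins, L2-Hys block normalisation)
are available for textured targets. A Hann taper suppresses the artificial
edges that cyclic shifts introduce at the window boundary.

Two conventions worth noting, both pinned down by brute-force oracle tests
on small instances (explicit circulant matrices and explicit kernel-matrix
solves, agreement to 1e-8):

* With rows of the sample matrix defined as right/down cyclic shifts of the
  patch, the primal Fourier solution is
  `w_hat = a_hat . b_hat / (a_hat* . a_hat + lambda)` — the numerator is
  *not* conjugated under this shift convention.
* The dual solution `alpha_hat = b_hat / (k_hat + lambda)` needs no
  conjugation of `k_hat` either: for inner-product kernels the kernel
  matrix over cyclic shifts is symmetric circulant.

### Kernel choice

`linear`, `polynomial` (`(<x,z> + c)^d`, default c=1, d=3) and `gaussian`
(`exp(-||x-z||^2 / (sigma^2 N))`, default sigma=0.2 on unit-scaled gray
features) kernels are implemented; all reduce to FFT cross-correlations.
The **default is the Gaussian kernel**. The linear kernel is slightly more
accurate on richly textured recordings, but on low-texture scenes (a small
dark target on a nearly uniform background — exactly what the synthetic
benchmark renders) the linear ridge is ill-conditioned: the regression
target's spectrum is broad while the patch autocorrelation spectrum decays
to the noise floor, so `alpha_hat = b_hat/(k_hat + lambda)` amplifies
high-frequency noise and the model can diverge after a re-initialisation.
The Gaussian kernel's correlation map is bounded in (0, 1] with a strong
DC component, which keeps the division well conditioned. Both remain one
config switch apart (`kcf: {kernel: {kind: linear}}`).

### Detection cap

The response argmax is searched over displacements of at most
`(window - target)/2` pixels during tracking (`max_shift` in
`kcf_core.detect`): a larger displacement would mean the target had left
the search window entirely, so such peaks are necessarily spurious.
Unrestricted search remains the default of `detect()` itself and is what
the shift-recovery tests exercise.

### Loss rule and re-detection

Loss is detected by the displacement rule: if the proposed centroid moves
less than `T = 3` px between consecutive frames, the target is considered
lost (a stuck box barely moves; a flying insect does). Background
subtraction — per-pixel median of the first 20 frames, absolute
differencing at threshold 25 (8-bit), one pass of 3x3 morphological
opening, 8-connected components with a 20 px minimum area — then searches
the full frame. On success the filter is re-trained from scratch at the
component centroid (status `redetected`); on failure the previous position
is held (status `lost`) and re-detection is retried next frame.

Two consequences of this rule at the scales used here are deliberate and
documented rather than hidden:

* A genuinely hovering target also triggers the rule; the re-detection then
  simply confirms the position. Setting `T = 0` disables the rule entirely,
  reducing the loop to a pure correlation filter.
* At the synthetic benchmark's pixel scale (~0.2 px/mm) ordinary flight
  speeds displace the centroid by only 1-3 px per frame, so the rule fires
  often and a large share of frames are BS-confirmed (`redetected`). This
  is the honest behaviour of a displacement threshold defined in pixels;
  the per-frame accuracy is unaffected.

Model adaptation linearly interpolates dual coefficients and template with
`eta = 0.02` per tracked frame; `eta = 0` freezes the first-frame model.

## Two-view 3-D reconstruction

Cameras are zero-skew pinholes looking along the tunnel's `-z` (top view)
and `+y` (side view) axes, with the optical axis through the tunnel-frame
origin; `standoff_mm` is the distance from the optical centre to the origin
plane. Each observation gives two linear ray constraints; the stacked 4x3
system for one synchronized frame pair is solved by `lstsq`. With two
identical cameras this coincides with averaging the two abscissa estimates
(the literal matching rule, available as `mode="average_abscissa"`), but
least squares is defined for asymmetric geometries too. Synchronization is
assumed exact (hardware-triggered cameras); frames are matched 1:1 by
index. Lost frames are propagated as lost, with optional linear gap filling
of up to `k` frames.

No lens distortion is modelled: intrinsics are assumed to come from an
upstream calibration that already corrects it.

## Synthetic scenes

`synthetic_scene` emulates the measurement situation, not its photometry:

* **Flight**: a second-order random walk (damped Gaussian acceleration,
  default sigma 1.2 mm/frame, damping 0.97) plus a constant wind drift of
  6.67 mm/frame along `-x` (0.4 m/s at 60 fps), reflected at the tunnel
  walls inset by 100 mm. The release heading follows the drift direction
  with random transverse jitter — wind-tunnel insects fly upwind toward the
  odour source — which also guarantees the early frames used for the
  background median are not contaminated by a lingering target.
* **Target**: an anti-aliased dark ellipse (intensity 60 on a 200
  background) whose apparent size follows inverse depth (nominal radius
  25 mm, roughly a butterfly's wing half-span) and whose semi-axes
  oscillate in antiphase (amplitude 0.2, period 8 frames) to emulate
  wingbeat deformation.
* **Occluders**: axis-aligned opaque slabs; a frame whose target centre is
  behind a slab (world-space test) omits the target, and the returned
  visibility flags match the rendering exactly. Binary opacity is the
  simplest geometry that produces the occlusion failure mode.
* **Similar-colour zone**: a background band repainted with the target's
  own intensity, sized in image space for the flight height it is
  calibrated to, so a crossing target blends in seamlessly (only rendered
  in the top view — the side camera sees the floor edge-on).
* **Noise**: i.i.d. Gaussian pixel noise (sigma 2 on the 8-bit scale).
* **Determinism**: one integer seed; the flight, top-view noise and
  side-view noise consume `default_rng([seed, k])` for k = 0, 1, 2.

Default cameras render 480x360 images with `f_px = 3.5/7.2 * width`
(scaling a 3.5 mm lens on a 7.2 mm sensor) at a 1.5 m standoff, which puts
the whole tunnel in view at ~0.2 px/mm. The benchmark scenes use 200-frame
open-centre flights and 110-frame deterministic straight flights for the
occlusion and similar-colour cases; these sizes keep the full pipeline
(render, track both views, fuse) at a few seconds per scene.

What passing these tests shows — and does not show. The generator covers
geometry, occlusion, low contrast, deformation and sensor noise, so it
exercises the loss/re-detection logic and the reconstruction end to end.
It does not emulate motion blur, illumination change, shadows, wing
translucency, perspective-dependent shape, or plant motion; success here
is necessary, not sufficient, for field recordings.

## Evaluation conventions

* Error distance: per-frame Euclidean pixel distance to the ground-truth
  centroid; summaries report min/mean/max.
* Success rate: percentage of frames not flagged lost whose error is at
  most `tol` px (default 20, config-exposed — there is no canonical
  definition of "success"), over all matched frames, reported to one
  decimal with half-away-from-zero rounding.
* Marker-distance validation: the packaged ball-distance table (five
  suspended ping-pong balls, ten pairs of calculated vs tape-measured
  distances in mm) is summarised by mean, *population* (divide-by-n)
  standard deviation, min and max of the absolute errors; population std is
  the convention consistent with the table's printed summary. Two of the
  ten printed per-pair relative errors are internally inconsistent with
  error/actual and are flagged by `inconsistent_rows()` rather than
  reconciled.

## Numerical choices

* `lambda = 1e-4` (regularisation), exposed in config.
* FFTs are complex; responses take the real part after an explicit
  imaginary-part sanity check (`< 1e-6` of the response scale).
* The Gaussian kernel's squared distance is clipped at zero against FFT
  round-off before exponentiation.
* Component-size ties in background subtraction resolve to the lowest
  label (scan order); all loops are free of randomness, so identical
  inputs give identical trajectories.
* `build_circulant` guards its explicit matrix at 4096 total elements; it
  exists as a test oracle, never as the fast path.

## Known limitations

* Single target only; no scale adaptation (the box size is fixed at
  initialisation), no subpixel peak interpolation.
* The S &lt; T rule cannot distinguish hovering from loss; see above.
* Re-detection trusts the largest moving component, which is wrong if a
  second moving object out-sizes the target.
* The background model is static; slow illumination drift would erode the
  differencing margin.
* Video-container input depends on the locally available imageio plugins;
  image sequences (PNG/PGM/TIFF) are the lossless, always-available path.
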