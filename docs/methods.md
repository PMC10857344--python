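# Methods

This note records the model, the numerical schemes, the synthetic-data
conditions and the design choices behind `lumenfit`, in the order the
pipeline runs.

## Contour model

A lumen cross-section boundary is a closed periodic cubic B-spline. The D
free control points (default D = 10) sit on radial rays from the section
center at angles φᵢ = 2πi/D; control point i is at signed distance
R·dᵢ·Δs along its ray, so the shape is carried entirely by the
dimensionless vector d while R (dimensionless) and Δs (mm/pixel) fix the
scale. Negative dᵢ land on the opposite ray (φᵢ + π), which is how the
model represents boundaries that pass close to, or on the far side of, the
section center.

Closure uses a uniform integer knot vector with the first `degree` control
points wrapped cyclically (C_D = C₀, C_{D+1} = C₁, C_{D+2} = C₂), giving a
C²-continuous closed curve with exactly D degrees of freedom, evaluated on
the parameter interval [3, D + 3]. Degree-0 basis functions are indicators
of the half-open span tᵢ ≤ t < tᵢ₊₁ and 0/0 terms in the de Boor recursion
are taken as zero — the standard conventions.

Two representational facts worth knowing:

* For even D the map d ↦ curve is exactly two-to-one: d and −roll(d, D/2)
  trace the identical curve. The LS fitter canonicalizes its result to the
  representative with nonnegative sum when both lie within bounds.
* Adversarial d can self-intersect the contour. This is permitted; the
  rasterizer applies the even-odd rule and downstream area computations
  flag rather than reject such polygons.

Sampling of the curve is uniform in the spline parameter, not in arc
length; the metrics module resamples to uniform arc length whenever two
contours are compared.

## Image-formation model

A cross-section image of (2N+1)² pixels (default N = 7, i.e. 15×15) with
pixel centers at (iΔs, jΔs) is modeled as I = a + b·(f ⊛ h): the unit
indicator f of the enclosed region, blurred by an isotropic Gaussian PSF of
standard deviation w (default w/Δs = 0.65) and scaled into the normalized
intensity range by background level a and lumen step b. Intensities are
not clipped to [0, 1]; a + b may exceed 1. The PSF width is treated as a
known constant of the acquisition (a configuration input, e.g. measured
from edge blur beforehand); it is not estimated.

The convolution has no closed form for a B-spline region, so `render`
evaluates it semi-analytically on a supersampled grid (default 8 scanlines
and 8 sample columns per pixel):

1. the contour polygon (512 curve samples) is intersected with each
   scanline, giving even-odd inside-intervals;
2. the 1-D Gaussian convolution along x is exact per interval — a
   difference of normal CDFs — evaluated at the supersampled x positions;
3. the second 1-D convolution across scanlines is a discrete Gaussian
   quadrature (truncation 4σ, zero padding: the indicator vanishes outside
   the lumen);
4. the result is averaged over each pixel's footprint (the detector
   integrates over its area, which is also what makes the w → 0 limit
   reproduce the per-pixel area fraction of the region).

The scheme was chosen over plain binary supersampling + discrete filtering
because it is smooth in the contour parameters below the subpixel scale.
With a binary raster the LS objective is piecewise constant between
subpixel flips, finite-difference gradients vanish, and gradient-based
optimization stalls far from the optimum; with the semi-analytic scheme a
noiseless self-rendered image is recovered to ~1e-7 per parameter. Accuracy
is governed by the scanline count: renderings at supersample 16 vs 32 agree
to better than 1e-3 RMS, and the integral of (I − a)/b conserves the
polygon's shoelace area to well under 2% for interior contours.

Parts of the lumen outside the image extent are clipped (they occur in real
data when a vessel leaves the field of view); rasterization then warns and
proceeds.

Axis convention: array index 0 is the image row = world y (upward),
index 1 the column = world x (rightward); row 0 is y = −NΔs.

## Synthetic data generator

The generator emulates contrast-enhanced cross-sections of a single bright
lumen on a darker background at the configuration used throughout
(15×15 pixels, Δs = 1 mm, R = 11, w/Δs = 0.65). Per example:

* a ~ U[0, 0.2], b ~ U[0.2, 0.3] (normalized intensities);
* d: ten i.i.d. U[0, 1] draws treated as a circular sequence and smoothed
  with the 3-tap lowpass kernel [0.15, 0.7, 0.15], which installs the
  neighbor correlation real smooth contours exhibit; then with probability
  0.25 one uniformly chosen element is replaced by a U[−0.2, 0.1] draw,
  producing the occasional concave/near-center boundary at roughly the
  rate such shapes occur in real limb MRA sections.

Smoothing precedes the replacement draw, so replaced elements keep their
full [−0.2, 0.1] range. Marginals therefore span [−0.2, 1.0] exactly.
Note that with R = 11 the larger d values put parts of the contour outside
the 15×15 extent — deliberately so; truncated lumens are a real failure
mode and the estimator must cope with them, though those boundary portions
are fundamentally unidentifiable from the image.

The noisy variant adds a zero-mean random fractal-like texture patch to
each rendered image: spectral synthesis with an isotropic power-law
spectrum P(f) ∝ f^(−β), default β = 2.5 and standard deviation 0.03 in
normalized intensity. This reproduces the smooth, cloud-like background
variation of real angiographic sections qualitatively; both β and the
amplitude are exposed in `NoiseConfig` since no quantitative reference
spectrum exists for the textures such sections exhibit. Noise is additive
after rendering, so noisy and noiseless datasets from the same seed share
identical targets.

Splits: the test fraction (default 10%) is carved off the end of the
(i.i.d.) example sequence, then the validation fraction (default 20%) off
the end of the remainder — with the 10,000-image default: 7,200 train,
1,800 validation, 1,000 test. The 20% validation share follows the
protocol's textual statement; 10% is a documented alternative some of the
reported training-set sizes imply.

What the generator does **not** model: spatially varying lumen/background
levels beyond the fractal texture, calcifications and streak artifacts,
neighboring vessels, anisotropic or spatially varying PSFs. Passing the
synthetic tests therefore demonstrates correct identification under the
model's own assumptions, not robustness to every clinical nuisance.

## Least-squares identification

`fit_image` minimizes the sum of squared intensity residuals over
p = (a, b, d) with SLSQP under box bounds a ∈ [0, 0.3], b ∈ [0.1, 0.5],
dᵢ ∈ [−0.3, 1.0]; R, w, Δs, D are fixed and known. Default initialization:
a, b at bound midpoints, every dᵢ at 0.3 (midpoint of the [0.2, 0.4]
range found to be a robust start). The model inside the loop is rendered at
the same supersampling as the default forward render (8), so a noiseless
self-rendered image is an exact fixed point of the objective; the reported
objective is re-evaluated at the returned parameters and equals an
independent recomputation to 1e-10. This is a local method: convergence to
the global optimum is not guaranteed, bad backgrounds genuinely defeat it,
and `converged=False` is a result, not an exception. Two guards blunt the
most common stalls: when the achieved objective stays above a threshold the
fit retries from up to `n_restarts` start points drawn from the
initialization range (deterministic), and a poor solution sitting in the
mirrored parameter branch — for even D, d and −roll(d, D/2) trace the
identical curve, but the asymmetric d-bounds pin the negative copy at the
lower edge — is re-polished from its equivalent positive-branch
representation. One fit takes on the
order of seconds (hundreds of renders); the CNN exists because of exactly
this cost.

`fit_spline_to_polygon` converts an observer-marked polygon into model
coordinates by minimizing the mean contour distance over d (derivative-free
Powell search; the metric is smooth in d because both curves are resampled
to uniform arc length first). Initialization reads the polygon's radius at
each control angle. Typical self-consistency residuals are below 0.001 mm;
observer polygons converted this way sit at mDist ≈ 0.01 mm.

## CNN regressor

Architecture (fixed by contract): three 3×3 same-padded convolutions with
8 kernels and ReLU, flatten, dense 64–32–16 with ReLU, linear output of
D units — 119,290 trainable weights at the default 15×15/D = 10. An
optional flag extends the head by two units to also predict (a, b); by
default the network predicts shape only and learns to ignore intensity
variation.

Implementation is plain numpy (the network is small enough that a
framework would be overhead): Glorot-uniform initialization with zero
biases, im2col-free convolution as nine shifted matrix products, float32
arithmetic, Adam (lr 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-7), MSE loss averaged
over batch and outputs, mini-batches of 64 with per-epoch reshuffling, at
most 500 epochs, early stopping on validation MSE with patience 15 and
best-weight restoration. The backward pass is verified against float64
finite differences to 1e-10. Training the full protocol takes ~7 minutes
single-core; inference is sub-millisecond per image — the speed asymmetry
versus seconds-per-image LS fitting is the method's point.

Measured behavior (computed by the tests and the acceptance script, not
asserted from the literature): on the full 10,000-image noiseless protocol
the held-out pooled error standard deviation lands near 0.02 with
negligible mean bias. At 2,000 images training becomes
optimization-variance limited — individual seeds land anywhere between
~0.024 and ~0.058 depending on which plateau the optimizer escapes — so the
scaled-down test pools errors across three seeds rather than gambling on
one.

## Contour metrics

Contours are compared after resampling to fixed cardinalities at uniform
arc length: 100 query points and 500 dense reference points per contour.
The mean contour distance sums, over both directions, each query point's
distance to the nearest dense vertex of the other contour (point-to-vertex,
matching the definition as a minimum over a point set) and divides by the
total query count; it is symmetric by construction. The Dice coefficient
rasterizes both enclosed regions (even-odd) on a shared 800×800 grid
spanning the joint bounding box plus a 5% margin — the margin is an
implementation decision; a fixed physical extent would serve equally.
Enclosed area uses the shoelace formula on the 500-point resampling, with
the raster count retained as a cross-check (they agree to ~1%).

Resampling twice at the same cardinality is exactly idempotent only when
the resampled polygon has equal edge lengths; on smooth contours
corner-cutting shifts repeat positions by the chord error (~1e-5 mm at
these densities), which bounds the metrics' resolution.

## Centerlines, frames and cross-section extraction

Externally produced centerline point lists (vesselness filtering,
thinning and skeleton parsing are out of scope) are approximated by a
cubic smoothing spline per coordinate (smoothing parameter = residual
budget, 0 interpolates), resampled at a 0.5 mm arc step with analytic unit
tangents. Frames are propagated by the double-reflection
rotation-minimizing algorithm from an initial normal (default: the world
axis least aligned with the first tangent, projected); frames stay
orthonormal and right-handed to 1e-9 and accumulate far less twist than
discrete Frenet frames on nonplanar curves.

Cross-sections are sampled by trilinear interpolation (order-1
`map_coordinates`; the interpolation order is a documented choice) at the
(2N+1)² points p + iΔs·n + jΔs·b per centerline point; out-of-volume
samples take a constant fill (0 after normalization) and are flagged in a
validity mask. Volume geometry (spacing, origin, direction cosines) comes
from the NIfTI/MetaImage header via SimpleITK; all world coordinates are
mm. CT volumes are preprocessed by clipping to [−300, 800] HU and mapping
affinely to [0, 1].

End-to-end validation uses a synthetic tube phantom (straight blurred
cylinder of known radius): the chain volume → centerline → frames →
sections → LS fit recovers the radius to well under 5%.

## Problem sizes and runtimes

Defaults were sized so the whole verification cycle runs comfortably on a
single CPU core: one render ≈ 9 ms; one LS fit ≈ 1–3 s; dataset generation
≈ 9 ms/image; CNN training ≈ 2.9 s/epoch at 7,200 training images (the
full protocol stops after ~150 epochs). The test suite trains the
scaled-down 2,000-image variant three times (~6 minutes total); the
acceptance script runs the full protocol once (~10 minutes).

## Known limitations

* Single closed boundary per section: no bifurcations, no multi-lumen
  sections, no plaque/bright-spot submodels.
* The LS route fails on backgrounds locally brighter than the lumen; this
  is inherent to the intensity model, and the CNN route is the remedy.
* Contour portions outside the image extent are unidentifiable; estimates
  there reflect the training prior, not the data.
* The fractal noise model is a qualitative stand-in for real background
  texture; no claim of spectral fidelity to any scanner is made.
* w is assumed known and constant per image; estimating it is out of scope.
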