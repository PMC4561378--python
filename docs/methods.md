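# Methods

This note documents the models implemented in `mamseg`, the numerical
choices behind them, what the synthetic phantoms do and do not emulate, and
the known limitations.

## Problem setting

A cropped mammographic sub-image (rescaled to [0, 1] grayscale) contains one
mass lesion.  The goal is a closed boundary of that mass, plus shape
descriptors of the boundary that can feed a benign/malignant classifier.
Because mass margins may be obscured and the interior may contain low-signal
areas, region-based level-set evolution can converge to different minima
from different starting contours.  The toolkit quantifies that dependence:
it builds a reproducible "proposed" initial contour from the image itself,
evolves it alongside a loose operator-style enclosing contour, and compares
the two outcomes descriptor by descriptor.

## Weighted TV scale-space smoothing

The smoother minimizes `E(I) = ∫ g|∇I| + λ|I − I₀|` by explicit gradient
descent

    ∂I/∂t = div( g ∇I / |∇I| ) − λ (I − I₀)/|I − I₀|,

where `g = 1/(1 + γ|∇G_θ∗I₀|²)` is computed once from the input.  The L1
fidelity preserves contrast; small λ means weak fidelity and hence stronger
smoothing, while `g` suppresses diffusion across strong edges so the mass
margin survives every smoothing level.

Numerics.  The TV term uses the standard adjoint pair — forward differences
for the gradient inside the flux, backward differences for the divergence —
because the central/central pairing decouples odd and even pixels and
amplifies noise instead of removing it.  Both absolute values are
regularized as `sqrt(u² + ε²)` with `eps_reg = 0.02`; the effective
diffusivity is then bounded by `1/eps_reg` and the explicit step is stable
for `dt ≲ eps_reg/4`.  Defaults: `dt = 0.005`, `max_iters = 500`, stopping
at relative L2 change `< 1e-4` per step (typically ~250 iterations on a
208×208 image, well under a second).  Instability is detected by the
solution leaving [−10, 11] (the continuous flow obeys a maximum principle,
so any such excursion is a discretization artifact) and reported with the
offending `dt`.  Edge-indicator defaults `γ = 100`, `θ = 1.5` px: with
[0, 1]-scaled intensities a mass edge has a smoothed gradient of roughly
0.1–0.3 per pixel, so `γ = 100` maps edges to `g ≈ 0.1–0.5` while flat
texture stays near `g ≈ 1`; much smaller γ leaves edges effectively
unweighted.  Boundaries are mirrored everywhere.

## Iso-level search space

Thresholds are `T = I_max · W` with equally spaced weights `w_k = k/N`,
`N = 24` by default; thresholds below `I_min` select empty regions and are
dropped with a warning.  At each level, marching squares traces the
iso-contours at sub-pixel resolution; open contours (touching the image
border) are discarded, as are contours with fewer than 8 vertices.  Nesting
is resolved by point-in-polygon containment: the parent of a contour is the
smallest-area contour strictly enclosing it, which yields a forest ordered
by area.

The mass margin shows up as a *dense* run of nested contours: many
consecutive thresholds cross the same steep intensity ramp.  Density is
operationalized as an absolute bound on the gap between the mean radii of
consecutive contours (measured about the centroid of the chain's outermost
contour, which is stable even when a chain leaf is the contour of an
interior low-signal area): a run is dense where gaps are ≤ `max_gap`
(default 3 px), and the longest dense run with at least `min_run = 5`
contours becomes the search band.  A uniform intensity ramp spreads N = 24
contours over the whole image (gaps of 4–5 px or more) and is correctly
rejected.  The absolute bound was chosen over a relative (median-gap) rule
because a sharp edge concentrates *all* contours at nearly equal small
gaps, where any data-driven quantile splits the band in half.  The band
mask is the morphological closing (disk radius 3) of the member contour
outlines.

## Proposed initial contour

From the centroid of the innermost band contour, `m = 360` uniformly spaced
rays (1° sampling) are intersected with every band contour
(vectorized ray–segment intersection).  The gradient magnitude of the
smoothed image (central differences) is sampled bilinearly at every
crossing; per ray the crossing with the largest gradient is kept, ties
broken toward the reference point.  Rays with no crossing get a radius
interpolated circularly from their angular neighbours and are flagged.

Radial clipping: with `r_ave` the mean radius and `r_std` the sample
standard deviation (m−1 denominator), every radius with
`r_i ≥ r_ave + n·r_std` is replaced by `r_ave` (n = 1 by default; n = 2
available).  Replacement is evaluated against the *original* mean and
deviation in a single pass — the rule is not iterated.  The clipped hit
points, ordered by angle and closed, form the initial contour; a
self-intersecting result is rejected with the offending angle named.

## Contour evolution

Both models embed the contour as the zero level of φ (positive inside) and
recompute the region means c₁ (inside) and c₂ (outside) every iteration
with the arctan-regularized Heaviside `H_ε(z) = ½(1 + (2/π)·arctan(z/ε))`,
ε = 1 px.

**Chan-Vese.**  `∂φ/∂t = δ_ε(φ)[μ κ − ν − λ₁(I−c₁)² + λ₂(I−c₂)²]` with
`δ_ε(z) = ε/(π(ε² + z²))` and curvature κ from the regularized
second-order central-difference formula.  Defaults μ = 0.2, ν = 0,
λ₁ = 2.5, λ₂ = 1 (λ₁ > λ₂ weights the foreground variance more, which
makes initialization differences measurable); λ₁ = λ₂ = 1 is the natural
comparison setting.  `dt = 2.0`: the Dirac factor confines updates to a
narrow band around the zero level, so the front advances at roughly a
quarter pixel per iteration; smaller steps make slow fronts
indistinguishable from convergence.  φ is reset to a signed distance
function every 25 iterations (sign-preserving, so the contour itself is
untouched); an optional narrow-band mode restricts updates to |φ| ≤ 6 px
and agrees with full-domain evolution to Jaccard ≥ 0.99 on test phantoms
(full-domain remains the reference semantics).  Stopping compares the
foreground mask with the mask 25 iterations earlier; the run ends when the
windowed change falls below 0.1% of the foreground, or at
`max_iters = 1500`.  Losing either sign of φ raises a contour-vanished
error with the iteration index; non-finite φ raises an instability error.

**SPF (selective local/global, SBGFRLS).**  Each iteration applies
`φ += dt·α·spf(I)·|∇φ|` with
`spf = (I − (c₁+c₂)/2)/max|I − (c₁+c₂)/2| ∈ [−1, 1]`, then binarizes φ to
±1 and Gaussian-filters it (`σ_g = 1`), which replaces both the length
penalty and reinitialization.  Defaults α = 5, dt = 1, same windowed
stopping.  The sign of α sets the growth direction; the full
geodesic-style SPF equation (with the extra transport and curvature terms)
is intentionally not implemented — the Gaussian-regularized form is the
model in use.

The final mask is {φ > 0} restricted to its largest 4-connected component
(optional hole filling, off by default, since interior low-signal areas
may legitimately be excluded).  The reported c₁/c₂ of a finished
segmentation are the plain means over the binary partition, not the
Heaviside-weighted ones (whose slowly decaying arctan tails bias them
toward the global mean).

## Shape descriptors

The boundary of the mask is traced by marching squares at level 0.5 (the
longest loop is the outer boundary; border-touching masks trigger a
warning), oriented counter-clockwise, and resampled by arc length to
N = 512 points.  The centroid distance function is
`r(n) = dist(boundary(n), centroid)` with the centroid taken over the
foreground *pixels* (centre of mass of the binary image, not of the
boundary).  From r(n):

- boundary moments `F₁ = √μ₂/m₁`, `F₂ = μ₄^{1/4}/m₁`, `F₃ = |F₁ − F₂|`
  (`m_p`, `μ_p` the raw/central contour-sequence moments).  F₃ is stored
  as a magnitude: the signed difference can be negative while all
  practical uses treat it as a roughness indicator;
- Fourier descriptors `FD_i = |a_i|/|a₀|`, i = 1..60, with
  `a_i = (1/N)Σ r(n)e^{−j2πin/N}`; a Parseval identity check
  (`Σ|a_i|² = mean r²`) guards the normalization, and N = 512 comfortably
  satisfies the N ≥ 2k+2 requirement for k = 60;
- convexity SC = foreground pixel count / pixel count of the rasterized
  convex hull of the foreground pixel centers.  The pixel convention is
  exact for convex rasterized shapes (a disk gives SC = 1) and matches a
  brute-force hull-membership count;
- rectangularity SR = shoelace area of the sub-pixel boundary polygon /
  area of its minimum rotated rectangle (rotating calipers via shapely).
  Using the *same* polygon for numerator and denominator cancels the
  half-pixel offset between pixel counts and marching-squares contours;
  mixing conventions biases a disk from π/4 ≈ 0.785 down to ≈ 0.77.
  Both SC and SR expose the other convention through `area_mode`.

F₁–F₃ and the FDs are translation- and scale-invariant by construction and
start-point-invariant because only DFT magnitudes are used; rotation
invariance holds up to rasterization jitter (worst for thin shapes with
half-pixel stair-stepping).

## Agreement metrics

Percentage differences are reported as magnitudes,
`%Δ = |b − a|/mean(a, b) × 100` (bounded by 200 for non-negative inputs);
the signed variant is available via a flag.  The Fourier-descriptor
distance is the Euclidean norm over the 60 components.  Bland-Altman
analysis uses bias ± 1.96·SD (sample SD) limits of agreement and counts
points outside them; Pearson r, the least-squares slope and a two-sided
t-test p-value (n − 2 df) summarize cohort correlation.

## Synthetic phantoms

A phantom is a spiculated disk, boundary
`r(θ) = R(1 + A·cos(fθ + φ₀))`, rendered at 208×208 with the mass centre
jittered ≤ 10 px, on a correlated Gaussian background
(σ = 8 px smoothing).  Class presets:

| parameter | distinct | ill-defined |
|---|---|---|
| edge blur σ (px) | 0.5 | 4.0 |
| contrast | 0.45 | 0.35 |
| background texture sd | 0.03 | 0.05 |
| spiculation amp / lobes | 0.08 / 7 | 0.12 / 9 |
| interior low-signal areas | 0 | 3 (Gaussian depressions, depth 0.3) |

One seed drives all stochastic elements; phantoms are bit-reproducible.
These values were fixed once as a plausible rendering of the two margin
classes: a sharp bright mass versus a heavily blurred one whose interior
depressions can trap a contour.

What the phantoms do **not** emulate: X-ray physics, detector noise
statistics, overlapping ductal structure, pectoral muscle or skin-line
gradients, and multi-mass fields.  Passing the phantom suites therefore
demonstrates correctness of the algorithms and the *direction* of the
margin-class effect, not clinical-grade accuracy on real mammograms.

The sensitivity experiment runs the full pipeline per phantom from both
initializations (proposed; and the truth contour's convex hull offset
outward 12 px, standing in for an operator's loose ROI), compares the two
final masks, and aggregates per margin class.  Per-phantom failures (e.g.
no dense band on a pathological draw) are recorded and skipped.  With ten
phantoms per class the proposed-vs-manual Jaccard mean is consistently and
strictly higher for the distinct class under both models — the qualitative
ordering expected of margin-dependent initialization sensitivity.  Problem
sizes throughout (208×208 images, 10 phantoms per class, 24 threshold
levels, 360 rays, 512 boundary samples) were chosen as the smallest that
exercise every code path convincingly.

## Known limitations

- The "dense band" rule is a deliberate stand-in for full contour-tree
  analysis of the iso-level map; images whose mass edge is weaker than the
  background texture gradient can fail band extraction (reported as an
  error rather than guessed).
- Explicit time stepping is simple and robust but not fast; no
  multiresolution or semi-implicit acceleration is provided.
- One mass per image; no multiphase segmentation; 2-D only.
- Descriptors assume a simply traced outer boundary; masks touching the
  image border are processed with a warning but may be clipped.
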