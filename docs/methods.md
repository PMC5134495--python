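# Methods

`lenssr` models the image-processing chain of a lensless microfluidic cell
counter: a CMOS sensor records the diffracted shadows of cells flowing in a
channel bonded directly to the die, with no magnifying optics.  Because the
pixel pitch and the cell diameter are both of order micrometres, single-cell
shadows are heavily pixelated; the package recovers high-resolution (HR)
single-cell images from single low-resolution (LR) frames with learned
priors, recognizes the cell type by structural similarity against an HR
reference library, and counts cells per type across the frame sequence.

## Degradation model and training decomposition

The imaging physics enters through two pieces.

**Contrast law.** Shadow contrast falls with the cell-to-sensor distance
`d_obj` as

    C(d_obj) = alpha / (1 + (d_obj / D)^phi),

with contrast amplitude `alpha`, characteristic distance `D` and shape
parameter `phi`.  `C(0) = alpha` and the curve is strictly decreasing for
`phi > 0`.  The published system states the functional form only; the
numeric defaults used by the synthetic chain (`alpha = 1`, `D = 100` µm,
`phi = 1.5`, `d_obj = 10` µm by default, range 5–30 µm as allowed by a
30 µm channel) are this package's own choices, set once so the channel
height spans a visible contrast range.  They parameterize synthetic data
only.

**Resampling decomposition.** Both SR engines are trained from an HR library
alone.  Each HR image (side `M = m·t`, magnification `t = 4`) is bicubic
down-sampled to LR (`m = 12` or `20`), bicubic up-sampled back to `M`
(`lr_int`), and the signed residual `hf = hr − lr_int` — the detail that
interpolation cannot recover — is the learning target.  The identity
`lr_int + hf = hr` holds to machine precision by construction, and tests
assert it at 1e−12.

The resampler is the separable Keys cubic convolution kernel with
`a = −0.5` (Catmull–Rom), the de-facto "bicubic".  Grid alignment is
pixel-centered (output center `u` maps to input `(u + 0.5)/s − 0.5`),
borders replicate, and downsampling widens the kernel by `t`
(anti-aliasing), mimicking the pixel-aperture averaging of a physical
sensor; both choices are configurable.  Each 1-D operator's rows are
normalized to unit sum, so constants are preserved exactly and both
operators are exactly linear — properties the test suite checks directly,
along with agreement with an explicit kernel double-sum oracle at probe
pixels (1e−10).

## ELM engine (random features + closed-form ridge)

A single-hidden-layer network in which only the output weights are learned.
For every interior pixel of `lr_int` a 14-feature column is extracted from
its 3×3 patch: the nine intensities in raster order plus five derivative
features from fixed stencils — ∂x = (E−W)/2, ∂y = (S−N)/2, ∂xx = E−2P+W,
∂yy = S−2P+N, ∂xy = (SE−SW−NE+NW)/4.  Centers span the interior, so a 48×48
image yields 46×46 = 2116 columns and a `p`-image library 2116·p columns.

With random input weights `A ~ U(−1,1)` (L×14), biases `B ~ U(0,1)` and the
logistic activation, the hidden representation is `H = sigmoid(AX + B)` and
the output weights solve the ridge problem in closed form:

    beta = T Hᵀ (I/C + H Hᵀ)⁻¹,

where `T` holds the `hf` values at the same interior pixels and `C` (default
512) balances the fit against `‖beta‖`.  Defaults `L = 20`, `d = 14`.  The
L×L form is implemented exactly as written; tests verify it against an
independent augmented least-squares ridge solve to 1e−9.  At inference the
LR input is up-sampled, features extracted, `beta·sigmoid(A x + B)` added at
every interior pixel (the 1-px border, which has no centered patch, stays
bicubic), and the result clamped to [0,1].  A zero `beta` therefore
reproduces bicubic interpolation exactly — also asserted.

With `L = 20` the model explains only ~20% of the residual variance on the
phantom library; that is a property of the architecture, not of the fit (a
generic ridge solver reaches the same training error).  The gain it buys is
correspondingly modest but consistent.

Feature rows are fed at their natural scales; an optional standardization
flag exists but is off by default — on degraded inputs it hurt
generalization in our benchmarks, because the scaler is fitted on clean
training statistics.

## CNN engine (three convolutional layers, hand-rolled backprop)

The second engine maps `lr_int` to `hr` directly with three convolutions —
patch extraction `F1 = relu(W1*Y + B1)` (64 filters, 5×5), non-linear
mapping `F2 = relu(W2*F1 + B2)` (32 filters, 1×1), reconstruction
`F3 = W3*F2 + B3` (one 3×3 filter).  Convolutions are cross-correlations
with 'same'-size replicate padding, so one output pixel depends on a
(5+1+3−2)² = 49-pixel input neighborhood, verified in tests by single-pixel
perturbation.  Forward pass, backpropagation (including the folding of
replicate-padding gradients back onto edge pixels) and the momentum update

    v ← 0.9·v − eta·∂L/∂θ,   θ ← θ + v

are implemented in plain float64 numpy; analytic gradients match central
finite differences to 1e−4 relative on every parameter of a toy net.

The loss is the mean squared error between `F3(Y_i)` and `X_i`, normalized
per masked pixel and averaged over the library (full batch per iteration,
deterministic given the seed).  A 3-px border — the half-width of the
receptive field — is excluded so padding artifacts do not bias the fit.
Training aborts with a diagnostic if the loss exceeds 10× its initial value
for 100 consecutive iterations.

**Numerical choices that matter.**

* *Initialization scale.* Filters start from `N(0, init_sigma²)` with zero
  biases, default `init_sigma = 0.05`.  The much smaller scale of 1e−3
  familiar from the SRCNN lineage is tied to schedules of ~10⁸ gradient
  steps: from a near-zero start the gradient into each filter stack scales
  with the *product* of the other layers' magnitudes, and we verified
  empirically that full-batch momentum SGD then stays pinned to the
  constant-output plateau (the loss equals the variance about the mean, flat
  to four digits) for thousands of iterations.  At the few-hundred-iteration
  budgets this package targets, a data-matched initialization is the
  equivalent condition; the scale is configurable for users with long
  schedules.
* *Learning rate.* Default `eta = 0.1` on the per-pixel mean loss.  The
  stability ceiling is set by the bias-direction curvature (`eta ≈ 1.5`
  diverges outright); `eta ≥ 0.5` is formally stable but kills most ReLUs in
  the first iterations and strands the network at the constant plateau.
  `eta = 0.1` trains to below the bicubic reference loss within ~600
  iterations on a 15-image library.
* *Network width.* Very narrow variants (e.g. `n2 = 4`) can lose every
  second-layer ReLU to early negative updates and stall permanently;
  gradient-correctness tests use toy widths, convergence tests use the
  default 64/32 architecture.
* *Restarts.* Even at default width, training quality varies with
  initialization luck (how many ReLUs die early).  The acceptance benchmark
  therefore trains three random restarts and keeps the model with the
  lowest final training loss — selection on training loss only, never on
  held-out scores.
* Whole images are the training samples — library images are only 48–80 px,
  so sub-patch sampling would add machinery without benefit.

## MSSIM metric and classification

Reconstruction quality and recognition both use the mean structural
similarity index in its standard form: Gaussian-weighted local moments
(11×11 window, σ = 1.5), stabilizers `C1 = (0.01·L)²`, `C2 = (0.03·L)²`
with dynamic range `L = 1` on our intensity scale, averaged over all
window positions fully inside the image (no padding enters the score).
The implementation is cross-checked in tests against both a scalar-loop
evaluation of the defining formula (1e−10) and
`skimage.metrics.structural_similarity` with matching settings.

A recovered HR cell is classified by scoring it against every entry of the
HR library and taking the type of the maximal score; ties break by
lexicographic type order, then entry id.  MSSIM is not translation
invariant, so library entries are rendered near-centered (±2 px jitter),
matching how queries arrive — centered crops around a detection centroid.

## Detection, tracking and counting

Moving cells are found in `|frame − background|` (background = first,
cell-free frame by default; a rolling median is available).  The threshold
follows the `mean + k·std` rule (`k = 4`), computed with sigma clipping:
the statistics start from the median + k·1.4826·MAD and are then iterated
over sub-threshold pixels only.  Without clipping the threshold grows with
the number of cells in the frame — cell pixels are exactly the outliers the
statistics should exclude — and faint cells flicker in and out of
detection.  The binary mask is cleaned by a 3×3-cross opening (a full
square erases the 1–2-px rings that small ring-shaped cells produce),
labeled with 8-connectivity, and components closer than a merge radius
(0.6 × crop size, growing as 0.9·√area for large parents) are unified:
a cell whose interior dips below threshold otherwise fragments.  Components
outside the `[min_area, max_area] = [4, 400]` px² gate are dropped, and a
`crop_size`-sided LR crop (replicate-padded at frame edges) is taken around
each intensity-weighted centroid.

Counting follows the "newly appeared cells per frame" rule.  Flow runs
along columns, so a detection matches an open track of age `a` when it lies
within `a·v·0.5` of the track's expected position `a·v` downstream
(`v` = expected displacement, default 6 px/frame); the directional gate is
essential — a direction-free radius lets a cell entering one lane over
steal an existing track.  Tracks survive one missed frame before retiring,
so a single detection dropout is not double-counted.  Every unmatched
detection is a new cell: its crop is magnified to library size (by the
selected SR engine, or plain bicubic) and classified, and the per-type
tallies accumulate.

Group summaries report, for per-group count pairs `(a_g, b_g)`: the ratio
of the per-type mean counts (`mean_ratio`, the headline figure, equivalent
to the percentage split), the mean, sample standard deviation (n−1) and
coefficient of variation of the per-group ratios, two-decimal rounding for
reporting, and half-up integer rounding of mean counts.

## Synthetic phantoms: what they emulate, and what they do not

Three cell types with distinct morphology on a bright (0.9) background, as
dark shadows: **rbc** — small disc (diameter 0.32× the image side) with a
dim rim (0.35) and brighter center (0.55), the transmission appearance of a
biconcave red cell; **wbc** — medium disc (0.42×, level 0.45) with an
offset, darker, granular nucleus; **hepg2** — large blob (0.60×, level
0.35) with a sinusoidally perturbed boundary and internal texture.  Edges
are sharp (~0.6 px sigmoid at HR scale), as microscope-grade library images
are; with soft edges a 4× decimation leaves almost no learnable
high-frequency content and the SR-versus-bicubic comparison degenerates to
noise.  Body levels are dark because lensless shadows are high-contrast;
faint phantoms made temporal-difference detection marginal rather than
testing the counting logic.

The degradation chain applies, in order: contrast scaling about the
background by `C(d_obj)/alpha`; Gaussian blur with σ = 0.05·d_obj px (a
linear proxy for diffraction spread — no wave-optics propagation is
simulated); bicubic decimation by `t`; additive Gaussian sensor noise
(σ = 0.01); clamping.  At `d_obj = 0` with zero noise the chain reduces
exactly to decimation.

Flow scenes place cells in stratified lanes spaced wider than the largest
phantom, with entry frames staggered so cells sharing a lane stay
column-separated, translate them rightward at constant velocity with ≤1 px
jitter, and remove them at the far edge; frame 0 is always cell-free.
Sprites are sized by the same per-type fractions as the library relative to
the detection crop, so detection crops classify against a
matched-geometry library.  The event log (type, entry frame, per-frame
centroid) is the ground truth for the exact-recovery tests.

What passing these tests does **not** show about real data: phantoms are
rotationally stereotyped, noise is white and Gaussian, blur is isotropic,
cells never touch or occlude, illumination is uniform, and the SR training
distribution (clean decimation) differs from the test distribution only in
the ways the chain itself models.  Real shadow images add diffraction
fringes, debris, focus drift and overlapping cells, none of which are
emulated; absolute MSSIM values on phantoms are therefore not comparable to
values measured on captured images.

## Problem sizes used by the test suite and acceptance script

Library of 30 phantoms per type at 48×48 (the documented library size);
ELM trained on all 90 pairs (190,440 feature columns) in closed form; the
convolutional engine trained on a 15-image subset for 600 iterations
(reaching below the bicubic reference loss); 21 held-out phantoms for the
SR comparison; 30 queries for classification accuracy; 12-cell two-type
flow sequences of 80 frames at 48×120 for count recovery.  One full
acceptance run takes under two minutes on one CPU.

## Known limitations

* The ELM engine's capacity (`L = 20`) bounds its gain; it sharpens edges
  but cannot restore texture.
* The counting rule assumes unidirectional, roughly constant flow; stalled
  or reversing cells would be recounted after `max_missed_frames`.
* Overlapping/occluded cells are out of scope (detection merges them).
* The CNN trainer is full-batch; libraries of thousands of images would
  need mini-batching it does not implement.
* 8/16-bit PNG/TIFF only; sensor raw formats are not read.
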