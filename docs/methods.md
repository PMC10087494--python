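# Methods

## Problem and model

A cone-beam CT scan of a breathing patient acquires one 2-D projection
`P_t` at a time while the gantry rotates (full-fan, 360°, 6°/s, 11
frames/s → 660 projections in 60 s).  Reconstructing one volume per
projection from a single view each is hopelessly under-determined unless
structure is imposed.  This package decouples the problem into

    CBCT_dyn(x, t) = CBCT_ref(x + D(x, t)),

a static reference volume warped by a time-resolved displacement field, and
represents both parts with coordinate networks ("implicit neural
representations", INRs):

* **Spatial INR** `Φs(x|θ)`: an MLP mapping a Fourier-feature-encoded 3-D
  coordinate (normalized to [−1,1]³ over a fixed physical box) to the
  attenuation at that point.  Because the representation is grid-free, any
  output resolution can be rendered at inference time.
* **Motion prior**: a PCA respiratory motion model built from the
  inter-phase deformation fields of a prior 10-phase 4D set registered to
  its end-expiration (EE) phase.  Per Cartesian direction, the mean field
  `PC0` and the top n = 3 principal components are kept, each scaled to one
  standard deviation of the training coefficient so unit weights are O(1):

      D(t) = PC0 + Σ_dim Σ_n w[dim,n](t) · PC[dim,n].

* **Temporal INRs** `Φt[dim,n](t|φ)`: nine independent small MLPs of the
  scalar normalized time, one per component weight.

All networks use Gaussian random Fourier feature (GRFF) encodings,
`γ(x) = [sin(2πBx), cos(2πBx)]`, with `B ~ N(0, σ_B²)` frozen at
initialization, and Swish activations (`y·sigmoid(y)`); the output layers
are linear.

## Three-stage optimization

The joint objective is the projection-domain sum of squared differences

    argmin_{θ,φ} Σ_t ‖ A Φs(x + D(t)) − P_t ‖²,

with `A` the cone-beam forward projector.  Optimizing it from scratch is
fragile, so the fit proceeds in stages:

1. **FDK pre-conditioning.**  The lowest-decile breathing-signal frames
   (the EE subset, default fraction 0.1) are reconstructed with FDK and the
   spatial INR is fitted to that volume by voxelwise least squares.
2. **EE fine-tuning.**  The spatial INR is tuned against the EE projections
   through the forward projector (no motion model yet).
3. **Joint fit.**  All projections drive both θ and φ.  Each iteration
   renders the reference on the optimization grid, samples a minibatch of 8
   frames, composes each frame's DVF from the temporal-INR weights, warps,
   forward-projects, and backpropagates through projector, warp, and both
   networks (all gradients hand-derived; see "Implementation").

Optimizer: Adam at initial learning rate 0.002 for every network, with
cosine decay to 2 % over stages 2 and 3.  Stage iteration defaults are
500/500/4000 (full preset); desk-scale runs use 2000 joint-stage
iterations with 400–500 iterations in each preconditioning stage.  The
temporal
INRs are initialized so that the composed displacement is exactly zero
(final-layer biases set to the least-squares weights canceling `PC0`),
making the start of stage 3 consistent with the static assumption of stages
1–2; without this the reference volume drifts early in training while the
weights are still near zero.

## Comparators

* **Conventional PCA baseline (`pcacv`)**: a fixed reference volume
  reconstructed from the EE subset by ART with total-variation
  regularization (relaxed view-wise algebraic updates alternated with
  smoothed-TV descent; λ = 0.4, 20 alternations, 10 TV steps each), then an
  independent per-projection nonlinear conjugate-gradient fit (scipy's
  Polak–Ribière CG, analytic gradient, ≤ 60 iterations, warm-started from
  the previous frame) of the 9 component weights.  A wide clip (±100, a
  divergence guard) bounds the weights; with 1-SD-scaled components,
  legitimate weights along low-variance modes reach tens of units.
* **Polynomial-temporal INR (`inrpoly`)**: the same spatial INR, with
  per-voxel motion coefficient grids weighted by powers of normalized time,
  `D(x,t) = Σ_{k≤p} t^k M_k(x)` (default p = 3), jointly optimized under
  the same projection loss.  No motion prior; each voxel's trajectory is a
  free polynomial, which cannot represent multi-cycle breathing.

## Synthetic dynamic-thorax phantom

The study conditions are generated, not downloaded.  The phantom is a
parametric thorax of smooth implicit shapes (body, two lungs, heart, spine,
and a 15 mm-radius spherical tumor seated in the lower lobe of the right
lung with ≥ 2 coarse-grid voxels of lung clearance), with attenuations
air 0, lung 0.005, soft tissue 0.020, tumor 0.028, bone 0.045 mm⁻¹ —
inside the usual CBCT display window [0, 0.05] mm⁻¹.  Organ edges are
smoothed over 3 mm so the same implicit anatomy rasterizes consistently at
any grid resolution.

**Motion** is constructed low-rank: `D(x,t) = Σ_k c_k(t) b_k(x)` with K = 3
analytic, SI-dominant basis fields (diaphragm-driven SI mode, AP chest-wall
mode, and a mid-thorax second-order mode), zero at the body shell and
spine.  Because the ground-truth motion lies exactly in a rank-3 space, a
PCA model built from noiseless inter-phase fields represents the intra-scan
motion exactly, making end-to-end parameter recovery a well-posed check.
The prior 4D set samples one 5 s sin² breathing cycle at 10 phases with
coefficient tracks proportional to sin², sin⁴ and sin⁶ of the phase —
three linearly independent shapes, so the prior excites all K basis fields.
(A second-harmonic sin²(2φ) track would *not* qualify: it is identically a
combination of sin² and sin⁴, which silently reduces the prior motion
space to rank 2 and puts baseline-shift motion outside the model span.)

**Scenarios** (magnitudes are this package's documented choices; the study
they emulate describes them only qualitatively): S1/S2 mid-scan baseline
steps of +3/+8 mm; S3 period 5 → 3.5 s; S4 ±30 % amplitude modulation plus
a 3 mm linear drift; S5 simultaneous amplitude and period modulation; S6 a
single slow monotone excursion (non-periodic motion / fast-rotation
analog); S7 = S1 with the tumor diameter halved; S8 = S1 with the tumor
shifted 6 mm along each axis (inter-scan changes applied to the onboard
reference only).  The surrogate signal s(t) equals the SI coefficient
c₁(t) (mm); every scenario starts at EE (s(0) = 0).  Patient-study analogs
S1-P…S4-P alias onto the same closed forms.

What the phantom does **not** emulate: realistic organ texture, scatter
and beam-hardening physics (only optional Poisson transmission noise),
hysteresis loops between inhale and exhale, cardiac motion, and
out-of-model deformation (the rank-K construction is exact by design).
Passing tests therefore demonstrate correct mechanics and recovery under
the stated model, not clinical-grade robustness.

## Scan geometry and projector

Full-fan circular geometry: source–isocenter 1000 mm, source–detector
1500 mm, rotation axis SI.  Gantry angle per frame N is
`α_N = rotation_speed / frame_rate · (N−1)`.  The forward projector is
ray-driven with trilinear (Joseph-style) sampling at a fixed step of half
the smallest voxel spacing; the backprojector is the exact adjoint of the
same discretization (verified against a dense matrix oracle on 8³ grids),
which keeps algebraic updates and INR gradients consistent with the
forward model.  FDK uses cosine weighting, a band-limited ramp filter with
raised-cosine apodization of the top octave only (a full-band Hann window
costs too much resolution at desk-scale detector pitches), and
distance-weighted backprojection with full-scan (Δα/2) normalization.

## Evaluation protocol

Per frame: relative error `RE = √(Σ(μ_rec−μ_GT)²/Σμ_GT²)` on the
evaluation grid; tumor DICE `2|A∩B|/(|A|+|B|)`; and the center-of-mass
error (COME, mm) between mask centroids.  The reconstructed reference is
segmented by thresholding at the midpoint of the lung and tumor
attenuation presets after 1-voxel Gaussian smoothing (speckle in iterative
reconstructions otherwise bridges components), keeping the connected
component that overlaps a dilated tumor-neighborhood seed the most; the
mask is then propagated through each frame's solved DVF (trilinear warp of
the indicator, re-binarized at 0.5) and compared with the ground-truth
masks.  SI centroid trajectories are extracted for plots.

## Numerical choices

* Networks run in float32; projector and warps in float64 via numba
  kernels.  All randomness (encoder matrices, initializations, minibatch
  order, noise) derives from explicit seeds; a master seed fans out to
  per-component sub-seeds by name hashing, so runs are bit-reproducible.
* Presets: the full preset follows the published sizes (spatial 4×256,
  temporal 256/100/100, 128 features, σ_B 2.5 for the phantom study and 4
  for the patient-style preset).  The desk-scale preset uses hidden 64,
  temporal 64/32/32, and 64 Fourier features — 32 features proved too
  band-limited to localize the 30 mm tumor transversely.
* The spatial INR output is linear and may go slightly negative; values
  are clipped to zero only at export/inference, never inside the loss.
* A fixed physical output scale (0.02 mm⁻¹, soft tissue) maps network
  outputs to attenuation so the MLP learns O(1) values; without it,
  convergence on mm⁻¹-scale targets is an order of magnitude slower.
* PCA rank guard: per-direction components with singular values below
  1e−7 of the leading one are stored as exact zeros and skipped in
  projection, keeping weight estimation well conditioned when the training
  motion excites fewer than n modes along a direction.
* Warps clamp out-of-bounds samples to edge values (no NaNs); the
  interpolant's position gradient is zero in the clamped region.
* Degenerate inputs: constant breathing signal → EE extraction keeps all
  frames and warns; empty masks, all-zero ground truth, single-view FDK →
  explicit errors; NaN training loss aborts with the iteration number.

## Desk-scale problem sizes

The shipped tests and the acceptance script run a scaled-down version of
the full protocol, chosen to exercise every mechanism at workstation cost:
ground truth simulated at 64³ × 3 mm (the full study uses 128³), 64²
detector at 4.7 mm pitch (vs 512² at 1.17 mm), 220 projections over the
same 60 s / 360° rotation (vs 660), optimization grid 32³ × 6 mm
(vs 64³), desk-scale network preset, and 2000 joint-stage iterations.
Comparative-ordering checks use a further-reduced 48³/24³ configuration.
The full-scale preset and geometry remain available through the
configuration.

## Known limitations

* The reference/motion split has a weakly-determined mode: a small static
  displacement of the reference can be traded against a constant offset in
  the weight tracks with little change in projection loss.  Segmenting the
  tumor from the *reconstructed* reference and propagating it with the
  *solved* DVFs (the protocol above) cancels most of this ambiguity, but
  residual millimeter-scale transverse bias at desk scale traces to it.
* The demons registration mode is a pragmatic substitute validated on
  translations and smooth phantom deformations only; quantitative motion
  studies here use the ground-truth-DVF bypass, which the phantom's
  low-rank construction makes exact.
* ART+TV step sizes were fixed once on the static fixture (λ = 0.4, TV
  step 0.1× the mean algebraic update) and are not adaptive.
* The patient-data pathway (clinical projection formats, scatter
  correction) is out of scope.
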