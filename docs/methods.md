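# Methods

`skinstrain` estimates muscle activity from the deformation of a skin-like
surface observed as a time-ordered sequence of noisy 3D scans. The pipeline
has four stages: (1) EMG-derived activity as the supervised target, (2)
temporally constrained non-rigid registration of a template mesh to the scan
sequence, (3) Green–Lagrange surface strain of the registered surface, and
(4) MLP regression from per-vertex strain invariants to per-muscle activity.
A synthetic deforming-tube simulator with analytic ground truth stands in for
capture hardware and a finite-element muscle model, and drives all tests.

## Muscle activity from EMG

The activity drive follows a first-order tracking recursion toward the
rectified EMG summed over a trailing window of n samples,

    a_k = a_{k-1} + Δt (S_k − a_{k-1}) / D,    S_k = Σ_{j=k−n}^{k−1} |e_j|,

with an asymmetric time constant D: 0.04 s while the windowed sum exceeds
the current level (rise) and 0.07 s otherwise (fall). Defaults n = 3,
Δt = 0.01 s. Normalized activity is A_k = a_k / a_MVC where a_MVC is the
peak of the same recursion on a maximal-voluntary-contraction trial. For
constant rectified input c the recursion has fixed point a* = n·c, which the
tests pin to 0.1%.

Two ambiguities in the published form of this recursion are resolved here
and flagged rather than silently absorbed: the summand is printed as |e_k|
under a sum over j (read as Σ|e_j| over the window — the only reading in
which the sum does anything), and the rise/fall switch compares an otherwise
undefined quantity "i_k" against a_{k-1} (read as that same windowed sum,
the only candidate on comparable scale). Stability requires Δt/D_rise < 2;
the constructor enforces it.

## Non-rigid registration with a temporal constraint

Each template vertex x_i carries an affine transform composed with a global
rigid pose, X_i = [T_i; t_i][R_r; t_r]. Per frame the energy

    E = w_C E_C + w_F E_F + w_S (E_ACAP + E_consist + E_smooth) + w_T E_T

is minimized in an ICP loop. E_C is the closest-point term with the
displacement projected onto the (previous-frame-rotated) template normal, so
it drives out-of-surface motion only; E_F is the full 3D residual of matched
dot markers and supplies the in-surface (sliding) information. The spatial
terms are: as-conformal-as-possible (distance of each T_i to its closest
scaled rotation, computed per vertex by SVD and frozen per ICP iteration in
local–global fashion), consistency of neighbouring affine maps evaluated at
the neighbour's position, and one-ring smoothness of (T, t). E_T penalizes
the squared per-vertex velocities and accelerations of the transform
parameters.

Positions and velocities are expressed through Newmark-β integration

    [T t]_k  = [T t]_{k−1} + ΔT [Ṫ ṫ]_{k−1} + ½ΔT²((1−β)[T̈ ẗ]_{k−1} + β[T̈ ẗ]_k)
    [Ṫ ṫ]_k = [Ṫ ṫ]_{k−1} + ΔT((1−γ)[T̈ ẗ]_{k−1} + γ[T̈ ẗ]_k)

and the per-frame unknowns are the current accelerations [T̈; ẗ]. With
correspondences and the ACAP linearization frozen, every term is quadratic
in the accelerations, so each ICP iteration is a single sparse linear
least-squares solve (normal equations, sparse LU, a 1e-12 relative Tikhonov
guard on the diagonal). A step that would increase the total energy is
reverted and the iteration stops, so recorded energy histories are
non-increasing; convergence is declared at a relative energy decrease below
1e-4 or 50 iterations. Registering a sequence is a filtering pass: the
previous frame's state initializes and regularizes the next.

### Parameter units and defaults

Raw squared accelerations at 100 Hz are numerically enormous (a 1 mm
position correction costs ẗ ≈ 8·10⁴ mm/s²), so `w_T` and `w_v` are specified
in *position-increment units*: internally they are scaled by (βΔT²/2)² and
(βΔT/2γ)² respectively, making `w_T = 1` comparable to 1 mm² of
closest-point residual at any frame rate. Likewise an entry of T̈ moves a
vertex through a lever arm of order its distance from the mesh centroid, so
the penalty on T-derivatives is additionally scaled by the mean squared
centroid distance (`w_lin` is relative to that scale); without this the
linear-transform channel is several orders of magnitude underdamped and the
filtering loop diverges.

Defaults: w_C = 1, w_F = 10, w_S = 0.1, w_T = 3000, w_v = 0.1, w_lin = 10,
β = 0.4, γ = 0.9. The Newmark pair deliberately departs from the classical
average-acceleration scheme (β = ¼, γ = ½): that scheme is non-dissipative,
and inside the closed registration loop its predictor amplifies the previous
frame's acceleration correction by ≈(1−β)/2β = 3× per frame, which a 1-D
closed-loop analysis (and the full system) shows to be marginally unstable;
γ > ½ introduces the algorithmic damping that stabilizes it. w_S = 0.1 keeps
the spatial prior's shrinkage bias at the 0.01–0.1 mm level on the mesh
resolutions used here while still suppressing vertex-level noise. All
weights are exposed in `RegistrationParams`.

With `w_T = 0` frames are registered independently: the previous transforms
only initialize the solve and no kinematic state is extrapolated
(extrapolating an undamped Newmark state diverges). Velocities and
accelerations of that variant are obtained by central finite differences of
the positions.

### Rigid pre-alignment and markers

Each frame starts with weighted rigid ICP (closest points at w_C, marker
pairs at w_F, weighted Kabsch) initialized at the previous pose; when the
temporal constraint is active, the pose increment is shrunk by 1/(1+w),
the closed form of a quadratic penalty on the pose change. Markers are
detected as connected components of vertices whose RGB color differs from
their one-ring mean by more than a contrast threshold (default 0.5; the
measure is difference-based and thus invariant to global color offsets),
each component represented by the vertex nearest its mean position. Marker
pairing is mutual-nearest-neighbour with a gate at `factor ×` the previous
frame's median matching distance; the carried median is floored at half the
mean edge length so a perfect frame cannot collapse the gate to zero.

## Surface strain

For each vertex, a deformation gradient F is fitted by least squares mapping
reference edge vectors to current edge vectors within a radius (default
2.5× the mean edge length), augmented with the unit-normal pair
n_ref → n_cur scaled to the mean edge length. Then E = ½(FᵀF − I) and the
reported scalar is the first invariant tr E (sum of principal strains),
which is invariant under rigid motion and objective (depends on F only
through FᵀF).

Inside `strain_field` the edge vectors are first projected onto their
respective tangent planes. On a curved surface, raw edge chords span all of
3-space, and their out-of-plane components otherwise contaminate the
direction the normal row is meant to pin — on a tube whose radius scales by
s this inflates tr E from the correct (s²−1)/2 by up to ~70%, independent of
mesh resolution. The projection is a no-op on planar patches, so the
standalone `deformation_gradient` (which keeps the raw regression) still
recovers a consistent affine neighbourhood map exactly. Vertices with too
few neighbours or a degenerate neighbourhood are flagged NaN, never
fabricated. Heat maps color the invariant linearly white → red over
[0, max].

## The simulator

A structured tube (default 24 rings × 40 stations, radius 20 mm, length
120 mm, open ends) whose radius bulges radially as
u_r(z, t) = B · Σ_m a_m(t) · w_m(z), with B = 5 mm and C¹ cosine-squared
axial windows (half-width 0.18 L) centred at 0.35 L and 0.65 L — two muscle
bellies at distinct stations. The default activity profile rises smoothly
and monotonically from 0 to 1 over the sequence (the surface gradually
expands with activity); sequences are sampled at 100 Hz for one second.
Ground-truth positions follow from the analytic displacement field;
velocities and accelerations from the time-derivatives of a cubic spline
through the activity samples (consistent with central differences of the
positions to O(Δt²)); ground-truth surface strain from the closed-form
principal stretches λ_θ = r/r₀ and λ_z = √((1+r_z²)/(1+r₀_z²)), giving
tr E = (λ_θ² + λ_z² − 2)/2. Markers are painted at quasi-uniform vertices in
material coordinates (dark dots on a light ground), so the true marker
correspondence is the identity on indices. Targets add i.i.d. isotropic
per-vertex Gaussian noise (default σ = 0.5 mm), independent across frames;
everything is deterministic given the seed.

What the simulator does *not* emulate: occlusion and holes, outliers or
structured (depth-correlated) noise, large tangential sliding, global rigid
motion, texture blur, or the fiber-level mechanics of a real muscle. Tests
passing on it therefore demonstrate the estimator's numerical behaviour
under the stated noise model, not performance on real scans.

## Predictor

A three-hidden-layer MLP (defaults 512/128/32, ReLU, linear 2-unit output)
maps a frame's strain-invariant vector — restricted to a reliable axial band
of the template — to the two muscles' normalized activity. Training is plain
SGD on the MSE with all frames of one action as a single batch (one gradient
step per action per epoch, action order shuffled per epoch), He-scaled
Gaussian weight initialization, inverted dropout (default 0.2) on the hidden
activations, learning rate 1e-3, 500 epochs by default. Inputs are
standardized per feature on the training set; dropout is off at inference,
so prediction is deterministic. The trained model serializes to JSON
(config, weights, normalization statistics).

## Evaluation harness

`run_table1_experiment` simulates once, registers three ways — with the
temporal constraint, without it, and without it followed by a causal
7th-order 10 Hz Butterworth filter (initialized at the first frame's steady
state, so DC gain is exactly 1) — and reports per-axis errors against the
analytic truth over all vertices and frames. Errors are reported as
root-mean-square deviations so units match the raw quantities (mm, mm/s,
mm/s²); the squared values are written alongside. Strain accuracy is the
mean absolute percentage error of the invariant, with entries where
|truth| < 1e-4 masked (the percentage is undefined at zero) and the mask
count reported.

On the default study conditions the temporal constraint reduces velocity and
acceleration errors below both baselines by roughly 3× and 6× respectively,
and the strain MAPE ordering (with TC < filtered < without TC) follows.
Its cost is a low-pass attenuation of the true motion worth roughly 8–14% of
the instantaneous deformation amplitude, which at this noise level (σ =
0.5 mm, after spatial regularization) leaves the with-TC *position* error on
the motion axes above the frame-independent baseline's — with much larger
measurement noise the comparison flips. This trade-off is intrinsic to
regularizing velocities and accelerations toward zero; penalizing deviation
from a motion model (or inequality constraints) would relax it and is the
natural next step.

## Problem sizes and numerical choices

The test suite and the acceptance script use reduced problem sizes chosen to
exercise the full pipeline: energy oracles on a 10-vertex tube;
zero-noise identifiability on a 2016-vertex tube over 50 frames (0.05 mm
RMS, bound 0.1 mm); the three-variant experiment on a 224-vertex tube over
100 frames at σ = 0.5 mm for three seeds; predictor recovery from nine
40-frame actions (six train, three held out) with strain from 756-vertex
tubes. Correspondence ties are broken by KD-tree traversal order (exact ties
have measure zero for noisy data); the marker gate accepts everything on the
first frame (previous median = ∞); isolated vertices get zero normals and
are excluded from the closest-point term.

## Known limitations

- The temporal prior is second-order and zero-targeted; it trades position
  fidelity of fast motion for velocity/acceleration accuracy (see above).
- Global rigid motion is estimated by shrunk-increment rigid ICP, not a full
  trajectory optimization; scenes with fast rigid motion will lag.
- The strain estimator assumes a locally affine deformation over the
  neighbourhood radius; strain features narrower than that radius are
  smoothed out (visible on coarse meshes as an underestimated peak).
- The predictor is trained and evaluated within one movement pattern;
  nothing here supports cross-movement generalization.
- Frame rate must be constant; meshes must share vertex order with the
  template after registration (template-based correspondence).
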