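# Methods

## Model

A dynamic scene is represented by two coordinate-based networks sharing a
multiresolution hash embedding.  The motion network receives the joint
spatiotemporal coordinate (x, t), embedded by one (d+1)-dimensional hash
grid, and outputs a displacement vector δx; the scene network receives the
motion-adjusted spatial coordinate x + δx, embedded by a d-dimensional hash
grid, and outputs the per-channel scene value.  Because the scene network
is independent of time, every frame of the reconstruction is a deformation
of a single static scene — the model exploits temporal redundancy and, by
the same token, cannot represent appearing/disappearing features or on/off
dynamics (see Limitations).

Training minimises the mean squared difference between each raw
measurement and the corresponding forward-model rendering of the scene at
that measurement's time, summed over the acquisition, by full-batch Adam.
The forward models (below) are linear in the scene and deterministic, and
every gradient in the package is an analytically derived vector–Jacobian
product: multilinear-interpolation derivatives for the hash grids, the
usual backward pass for the MLPs, and conjugate-filter adjoints for the
Fourier-space physics.  Gradient correctness is pinned by finite-difference
tests at 1e-4 relative tolerance.

### Hash embedding

Each level i of N stores a table of learnable feature rows; a query
coordinate in the unit hypercube is multilinearly interpolated from the
2^d surrounding vertices of that level's grid (resolution
floor(base · scale^i) cells per axis).  Coarse levels are indexed densely;
levels whose vertex count exceeds the table size fall back to XOR-prime
spatial hashing with accepted collisions.  Defaults: N = 8 levels, base
resolution 8, growth 1.5, 2 features per level, table size 2^16, uniform
init in ±1e-4.  These hyperparameters are package choices (exposed in
`HashGridConfig`); the small init keeps early renders near the network
bias, which helps the coarse-to-fine start.  Coordinates are normalised
per axis to [0, 1] with pixel-centre sampling ((j + 0.5)/n); out-of-range
motion-adjusted coordinates are clamped, matching a zero-flux boundary,
and clamped components receive zero coordinate gradient.

### Coarse-to-fine granularity

Level i of N is weighted by w_i = ½ − ½ cos(π · trunc(αN − i)) with trunc
clamping to [0, 1], so fine levels are exactly silent until the
granularity α grows.  During fitting α ramps linearly from 0 to 1 over the
first 80% of the epochs (the ratio of the current epoch to the ramp's end
epoch) and stays at 1 afterwards.  One shared α drives both networks;
per-network overrides are exposed but unused by default.

### Networks and output maps

Motion: two hidden ReLU layers of width 32; final layer linear and
zero-initialised, so training starts from the exactly static model.  The
raw output is bounded by max_displacement · tanh(·) (default 0.1 of the
field of view) to keep early training from throwing coordinates far
outside the scene.  Scene: two hidden ReLU layers of width 128; the output
map fixes the physical range per modality — softplus for fluorescent
density (nonnegative), identity for the DPC absorption/phase pair, sigmoid
for RGB intensity.  Hidden activation and output maps are package
conventions; width/depth follow the published recipe.

## Forward models

All three renderers share Fourier conventions (unnormalised forward DFT,
1/N inverse, frequency origin at index 0) and expose exact adjoints,
verified by ⟨Ax, y⟩ = ⟨x, Aᵀy⟩ dot tests at 1e-6.

**DPC.**  Four half-circle illumination patterns; each background-
normalised image is H_u F(o_u) + H_p F(o_p) back-transformed, with the
weak-object transfer pair computed from source–pupil cross-correlations:
H_u = −(C(u) + conj(C(−u)))/B, H_p = i(C(u) − conj(C(−u)))/B, where
C(u) = Σ S P* P(·+u) and B = Σ S|P|².  H_u is real, H_p purely imaginary
with H_p(0) = 0, and mirrored half-circles flip the sign of H_p; all three
properties are asserted by tests.  Precomputed transfer stacks can also be
supplied directly.  The DPC loss adds Tikhonov regularisation
(weight 1e-4) on the rendered absorption/phase values; the package applies
it to the mean square rather than the raw sum so the weight is
raster-size-invariant, consistent with the mean-squared data term.

**3D SIM.**  15 raw images per plane (3 orientations × 5 phases).  The
illumination of measurement i is decomposed into three harmonic bands —
constant, fundamental (carrying the three-beam axial cos(2π ν_z z)
modulation), and doubled lateral frequency — each multiplied into the
density volume, filtered by its band OTF, and summed.  Keeping the axial
modulation in the band-1 illumination with one shared detection OTF is
algebraically identical to axially shifting the band-1 OTF (the model is
linear); per-band OTF arrays remain loadable for systems that provide
them.  The default OTF is computed numerically from the defocused pupil
(unit DC gain).  Measurements sharing (orientation, phase) across depth
planes are grouped and rendered in one pass at the group's mean time, so
20 planes (300 raw images) need only 15 scene evaluations; the residual
intra-group motion is an accepted approximation and goes untracked.
Acquisition ordering (z-innermost by default) is configurable.

**Rolling-shutter DiffuserCam.**  A single raw image in which each sensor
row integrates the scene convolved with a caustic PSF over that row's
exposure window.  The scene is discretised at T time points with a binary
shutter map S(row, t) built from the row readout time and exposure
(dual-shutter centre-outward readout as a flag); rendering row chunks (20
consecutive rows by default) needs only the scenes whose shutter overlaps
the chunk, and reassembling all chunks reproduces the full-frame sum
exactly (bit-for-bit, asserted).  Convolution is circular via FFT.

## Optimisation

Adam (β = 0.9/0.999, ε = 1e-8) with initial learning rates 1e-5 for the
motion network (5e-5 for DiffuserCam) and 1e-3 for the scene network,
decaying exponentially as lr0 · 0.1^(epoch/epochs) to one tenth at the
end.  Epoch counts are configurable; package defaults are 500.  Fitting is
full-batch: one gradient step per epoch over all measurements and pixels,
with scenes rendered once per unique time point and shared across the
render units that need them.  Training arithmetic is float32 by default
(float64 available via `dtype`); runs are bit-reproducible given the seed,
and a run aborts with a diagnostic if the loss exceeds 1e3 × its initial
value for 50 consecutive epochs.

The static baseline (`fit_static`) keeps every setting but freezes the
motion network (which is zero-initialised, hence δx ≡ 0) and sets all time
points to zero — the conventional motion-blind reconstruction.

## Synthetic data

Phantoms: hard-disk beads at rejection-sampled non-overlapping centres,
spline tubules dilated to tube width, and bar resolution targets; all
deterministic per seed.  Motion families, all anchored to zero displacement
at the first time point except the absolute-time `linear` kind:

* rigid — spatially constant shift, smoothstep time profile, peak =
  magnitude (px);
* linear — shift = magnitude · t · direction;
* deformable — per-axis Gaussian-smoothed white noise fields at four
  control times, cubic-interpolated in t, peak |δx| normalised to the
  magnitude within 1%;
* periodic — one smoothed field modulated by sin(2π · frequency · t).

Measurements are rendered by pull-warping the phantom (bilinear sampling
at x + δx*, clamped borders — the same convention the model uses) through
the forward model, plus optional additive Gaussian noise.  What the
generator does **not** emulate: shot/read-noise statistics of real
cameras, optical aberrations, illumination-parameter miscalibration, and
scenes whose content changes over time.  Passing recovery tests therefore
demonstrates correctness of the joint estimation machinery under the
model's own assumptions, not robustness to those real-data effects.

Recovery scoring: scene PSNR at the first time point over an interior
region (excluding a border of the maximum true displacement, capped at
100 dB), and motion errors — relative to the first frame, to quotient out
the model's scene/motion translation ambiguity — weighted by the dilated
phantom support, because displacement carries no information where the
scene is empty and the model correctly leaves it at zero there.

## Desk-scale study conditions

The shipped studies run on one CPU in minutes; sizes were fixed as the
package's own benchmark conditions:

* rigid-motion recovery: 64×64 DPC, T = 4, 8 beads of radius 3 px, 3 px
  rigid motion, scene width 64, 1000 epochs, learning rates 1e-3 (motion)
  and 1e-2 (scene), displacement bound 0.2, five seeds.  The motion:scene
  learning-rate *ratio* matters more than the absolute values: with the
  motion rate at or above the scene rate, the scene network fits the four
  measurements essentially exactly (data loss ~1e-8) while the motion is
  still ~30% short — the scene-overfitting failure mode the coarse-to-fine
  process is designed against, and a reminder that the (scene, motion)
  decomposition is identified by the training dynamics, not by the data
  alone.  Keeping the motion network an order of magnitude slower than the
  scene network restores accurate recovery;
* coarse-to-fine comparison: 48×48 DPC, 3 px deformable motion
  (smoothness 8 px), 500 epochs, α-scheduled vs α ≡ 1;
* degradation ladders: 32×32 (motion magnitude and noise, T = 4) and a
  cycled-illumination DPC time series (vibration frequency; the 4-pattern
  sequence repeated four times, 16 time samples) — with only 4 samples a
  continuous-time motion model can interpolate any sampled vibration, so
  the frequency study needs the denser series, mirroring the 15-time-point
  acquisitions of the full-scale vibration experiments;
* temporal interpolation: 32×32 cycled-illumination series (16 samples),
  five beads, 3 px linear motion; the frame rendered at the acquisition
  midpoint — which falls between two measurement times — must place the
  bead centroid midway between its rendered endpoint positions.  Two
  conditions make interpolation meaningful at this scale: the motion
  grid's time axis is capped at the sampling resolution
  (``HashGridConfig.time_resolution``), since any temporal vertex no
  measurement touches keeps its (near-zero) initialisation and a finer
  time axis therefore *under-shoots* between samples; and the beads carry
  a placement margin of radius + peak displacement, since content
  crossing the clamped border is appearing/disappearing structure that
  the model class excludes.

The toy learning rates are larger than the production defaults because
the runs are three orders of magnitude shorter than a GPU-scale
reconstruction; the production defaults remain the package defaults.

## Numerical choices and degenerate inputs

Chunked coordinate evaluation is semantics-free (pure function of inputs;
asserted to BLAS rounding).  α outside [0, 1] is clamped with a warning;
non-finite coordinates raise; incomplete SIM acquisitions raise listing
the missing (z, orientation, phase) triples; a source pattern with zero
energy in the pupil raises (background normalisation undefined); zero
beads give a blank phantom; magnitude-zero motion gives exactly zero
fields.  Ties in bead packing are resolved by rejection sampling with a
deterministic generator.

## Limitations

The scene network's time independence excludes appearing/disappearing
features and switching dynamics by construction.  Joint recovery degrades
as deformable motion grows, as vibration frequency approaches the
sampling limit of the acquisition, and as measurement noise grows — the
degradation ladders quantify all three trends.  The desk-scale studies
use reduced rasters and epoch budgets; they exercise every code path of
the full-scale method but do not demonstrate super-resolution quality on
real microscope data.
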