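# Methods

`flow4dsr` is a desk-scale re-implementation of a generalized
super-resolution framework for 4D Flow MRI: synthetic paired training data
are generated from known velocity fields, small convolutional networks
learn to double the spatial resolution of noisy low-resolution velocity
volumes, and bagging/stacking ensembles fuse several such base learners.
Everything runs on one CPU in minutes; the velocity fields come from
analytic flow phantoms rather than patient-specific CFD.

## Flow phantoms

Each "model" (the analogue of one patient-specific CFD case) is a
`FlowSample`: a time-resolved 3-component velocity field (cm/s) on a
uniform isotropic grid with a static fluid mask. Four compartments with
deliberately disparate hemodynamics are provided:

| compartment | geometry | spacing | peak speed |
|---|---|---|---|
| cerebro | straight Poiseuille tubes, small calibre (r 1.5–3 mm) | 0.5 mm | 20–80 cm/s |
| aortic | Poiseuille and stenotic (Gaussian-narrowed) tubes, r 8–13 mm | 1.25 mm | 80–250 cm/s |
| cardiac | ellipsoidal chamber with a swirling internal flow | 1.25 mm | 50–150 cm/s |
| dissection | two-lumen tube (fast true / slow false lumen, joined at entry and exit tears) | 1.25 mm | 100–200 cm/s |

The stenotic tube rescales the axial parabolic profile slice-by-slice so
the discrete volumetric flux is conserved along the axis (continuity; the
throat jet exceeds the inlet peak). Time dependence is a raised-cosine
systolic waveform scaling the base field per frame. All generators are
pure functions of their parameters and a seed. The dissection compartment
is never used for training; it serves as the unseen-domain probe.

These phantoms emulate the *role* of CFD — ground-truth velocity fields
with compartment-dependent scales and geometries — but not its physics:
no secondary/retrograde flow, no turbulence, no wall motion, and the
fields are locally smooth. Passing the desk-scale experiment therefore
demonstrates that the pipeline's mechanics (synthesis, filtering,
training, ensembling, evaluation) behave as designed, not that the
networks reach clinical-grade accuracy on real hemodynamics.

## Synthetic 4D Flow MRI

Phase-contrast encoding maps each velocity component to the phase of a
complex signal, `s_c = M * exp(i*pi*v_c/VENC)`, with the magnitude image
`M` derived from the fluid segmentation (1.0 inside, 0.05 outside;
optional Gaussian partial-volume smoothing, off by default). VENC is set
per frame to 1.2x the frame's peak speed rounded up to the nearest
10 cm/s, so VENC always exceeds the maximum velocity (no aliasing) and
the velocity-to-noise ratio varies over the cardiac cycle. Zero-mean
Gaussian noise is added independently to the real and imaginary channels;
its sigma realizes a requested SNR against the mean fluid magnitude
(`SNR_dB = 20*log10(mean_fluid(|s|)/sigma)`). Low-resolution volumes are
produced by centered k-space truncation: keep the central `(N/2)^3` block
of the 3D FFT, inverse transform, and divide by 8 so constants are
preserved; output spacing doubles. Decoding inverts the phase map;
a magnitude threshold (0.5) separates fluid from background, where the
noise-dominated signal decodes to essentially uniform random phases.
Training pairs are HR noise-free / LR noisy at a fixed 1:2 factor, with
the SNR of each (sample, frame) drawn uniformly from 12–20 dB (the SNR
range is a package default; it is the kind of value a mid-field clinical
acquisition produces, chosen once).

## Patch pipeline

Low-resolution 12^3 input patches (3 velocity components + magnitude) are
tiled at stride 12 with the co-located 24^3 noise-free HR target. A patch
is kept only if at least 5% of the HR reference voxels are non-stationary
(inside the fluid mask with speed > 1e-6 cm/s) — the filter is evaluated
on the noise-free reference so it is independent of the noise draw.
Training patches are augmented by rigid 90/180/270-degree rotations about
z (lattice and velocity vectors rotate together, preserving the speed
field). Splitting is model-wise 6:2:2 per compartment: a phantom's
patches never appear in more than one split. Velocities are normalized by
the frame VENC for training (standard phase-contrast normalization to
[-1, 1]), and predictions rescaled.

## Networks and loss

The base learner maps the 4-channel LR patch to 3 SR velocity components
at doubled resolution: a 3x3x3 input convolution, a stack of
channel-preserving blocks (residual by default; dense and cross-stage-
partial variants share the same I/O contract), a trilinear x2 core
upsampling layer, optional post-upsampling blocks, and a zero-initialized
3x3x3 output convolution. A global skip adds the trilinear upsampling of
the input velocities, so an untrained network reproduces trilinear
interpolation exactly and training learns only the correction (global
residual learning, standard in super-resolution). The networks are
implemented in numpy with hand-written backpropagation (`_nn.py`):
shift-and-GEMM convolutions, exact adjoint trilinear upsampling, and Adam.
Gradients are verified against finite differences in the test suite.

The loss splits the velocity-matching MSE into fluid and non-fluid
regions: `l_total = mean_batch( w_c * MSE_fluid + MSE_nonfluid )
+ lambda * sum(w_i^2)` with `lambda = 5e-7` on the convolution weights.
The compartment weight `w_c = Nc / (S_c * sum_i 1/S_i)` (Nc compartments
present in the batch, S_c patches of compartment c) makes `S_c * w_c`
constant: every compartment contributes equally to a batch regardless of
imbalance. The batch reduction is a mean (not a sum) so the gradient
scale is independent of batch size. Since synthesis guarantees zero
velocity outside the fluid mask, the non-fluid term is a denoising prior
that drives the background's random phases to zero.

Training uses Adam with an initial learning rate of 1e-4 at full scale
(library default) and a learning-rate decay of 2, implemented as halving
on a validation-loss plateau (patience 5 epochs).

## Ensembles

*Bagging*: each base learner trains on a bootstrap resample (with
replacement, resample size = training-set size) with its own
initialization seed; fusion is soft voting — the unweighted voxelwise
mean. *Stacking*: an 8-layer convolutional feed-forward meta-learner
consumes the concatenated base outputs (3*n_base channels at 24^3) and
emits the fused 3-component prediction; its final layer is
zero-initialized with a mean-skip, so the untrained meta reproduces soft
voting and training can only move away from it if the loss improves. The
meta-learner trains on the validation split's base outputs (limiting
leakage from the bases' training data; configurable), with the same
compartment-weighted loss, bases frozen.

Whole-volume prediction tiles the LR volume with 12^3 patches at stride
8, crops a 2-LR-voxel border on faces interior to the volume, and
averages overlaps; an untrained network's stitched output equals global
trilinear interpolation (verified in the tests).

## Evaluation

* Relative speed error `RE = mean tanh(||V'-V|| / (||V|| + 1e-4)) * 100`
  over the reference fluid mask. The tanh saturates the penalty where the
  reference speed is small, and makes RE depend only on the voxelwise
  norms (rotation invariant).
* Per-component RMSE over the fluid region and its complement.
* Per-component OLS of predicted on reference velocity after normalizing
  both by the shared max-|reference| scale: slope k (1 = unbiased) and
  R^2.
* Downsample-and-recover: a native-resolution volume is k-space truncated
  by two (optionally with added complex noise), super-resolved back, and
  compared to the native data — the protocol used when no finer reference
  exists. Plain trilinear interpolation of the LR volume is the reference
  baseline.

## The desk-scale experiment

`reproduce_desk` (also `flow4dsr reproduce-desk` and
`scripts/acceptance.py`) runs the full pipeline at sizes chosen so the
whole experiment completes in roughly ten minutes on one CPU core:

* 5 phantoms per training compartment (3 train / 1 val / 1 test), 3 time
  frames; one dissection phantom held out entirely → ~150 augmented
  training patches;
* 2 base learners, 12 channels, 2 residual blocks before the upsampling
  layer and none after (at this problem size, capacity spent at LR
  resolution converges fastest per unit compute; the zero-initialized
  output convolution still operates at HR), batch 8;
* 60 base epochs and 8 meta epochs at learning rate 1e-3 — the shortened
  schedule uses a proportionally larger step than the full-scale default
  (1e-4 over 60/80 epochs at ~10^5 patches), matching the optimization
  budget rather than the epoch count;
* evaluation at the systolic frame of each held-out phantom, 15 dB
  complex noise, identical LR input for every method.

Training dynamics at this scale have two phases: the network first learns
to cancel the background's noise-dominated decoded phases (the large
non-fluid loss term), then gradually improves fluid fidelity at the
vessel wall, where k-space ringing and partial-volume smoothing dominate
the error of the trilinear baseline. The experiment's acceptance is
directional — ensembles must beat trilinear interpolation in RE and in
regression slope — not a reproduction of any full-scale error level,
which would require patient-specific CFD data and GPU-scale training.

## Numerical choices and edge cases

* float32 on disk and in network arithmetic; float64 in metrics.
* Axis order (x, y, z), voxel-center sampling; trilinear upsampling
  aligns HR voxel i with LR coordinate (i+0.5)/2 − 0.5, edge-clamped.
* Odd k-space dimensions are edge-padded (high side) to even before
  cropping; HR volumes are trimmed to even shapes when pairing.
* Zero-signal voxels decode to zero velocity (arg(0) := 0).
* Empty fluid mask in a loss patch contributes 0 with a warning; empty
  regions in RMSE report NaN; constant reference components report NaN
  regression entries.
* Patch extraction on a volume smaller than one patch returns an empty
  list with a warning; a compartment with a single phantom goes entirely
  to the training split with a warning.
* Bootstrap indices, noise, initialization, shuffling, and splits all
  derive from explicit seeds; repeated runs are bit-identical.

## Known limitations

* The phantoms' smoothness makes trilinear interpolation a strong
  baseline; measured improvements are necessarily modest compared to what
  full-scale training on CFD data reports.
* Magnitude images are binary segmentation-derived maps, not anatomical
  contrast; no eddy currents, Maxwell terms, coil sensitivities, or
  motion.
* The numpy network engine targets 12^3/24^3 patches at ≤ 32 channels;
  it is not a general-purpose deep-learning stack.
* Exact full-scale architecture hyperparameters (layer counts, kernel
  sizes of the published reference network) are exposed as configuration
  rather than asserted.
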