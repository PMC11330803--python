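# Methods

This note documents the models, conventions and design choices behind
`rt4dcbct`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open decisions were made.

## Synthetic 4-D thorax phantom

**Anatomy.** Body, two lungs, a diaphragm dome and a tumor are soft-edged
ellipsoids with attenuation values (mm⁻¹) of 0.020 (soft tissue), 0.004
(lung), 0.025 (diaphragm) and 0.030 (tumor). Edges are smoothed with a
tanh profile of ~6 mm width: hard voxel edges would make the
warp-consistency target (trilinear resampling vs. analytic evaluation)
interpolation-limited rather than model-limited. The default grid is 64³
voxels at 4 mm spacing (a 256 mm field of view, isocentre-centred);
everything is configurable upward.

**Motion.** Displacement fields use the pull-back convention (the warped
image at `x` samples the reference at `x + d(x)`) with voxel-centre
sampling, matching standard resampling semantics. The per-phase field is a
linear combination of nine fixed, smooth basis fields:

* a principal superior–inferior mode: the signed tumor/diaphragm excursion
  `max_displacement` (default (1.2, 3.6, −12) mm — AP ≈ 30 % and LR ≈ 10 %
  of the SI excursion) times a taper that is 1 below the carina level and
  falls smoothly to 0 at the lung apex; its coefficient is the breathing
  amplitude `a`;
* a quadratic anterior chest-wall term (coefficient `a²`, amplitude one
  third of the SI excursion) localised near the sternum;
* seven sub-millimetre harmonic perturbation fields whose coefficients are
  sine/cosine harmonics of the phase angle, vanishing at the reference
  phase.

The harmonic terms play the role of the inhale/exhale asymmetry and
registration irregularities present in real 4D-CT-derived DVFs. They are
deliberately constructed so that the nine non-reference phase fields are
*linearly independent*: a purely amplitude-driven phantom would produce a
rank-1 (or rank-2) DVF stack whose PCA spectrum collapses, whereas real
Table-style information curves decay gradually and reach 100 % only at
full rank (8 components for 9 mean-centered fields).

Phase volumes are produced by *analytically* evaluating the reference
attenuation at the displaced coordinates, so volumes and stored DVFs are
exactly consistent by construction; numerically warping the reference with
the stored DVF reproduces each phase volume to NCC ≥ 0.99 on the interior
(the residual is trilinear-interpolation error only). The breathing trace
template is `a_i = (1 − cos(2πi/n))/2` over n = 10 phases: phase 0 is the
zero-amplitude reference and the cycle is smooth and periodic. Ten phases
is the conventional 4D-CT binning; it is a modelling default, not a
constraint.

**What the phantom does not emulate:** realistic CT numbers and organ
shapes, cardiac motion, genuine hysteresis loops (the harmonic terms break
phase symmetry but are not a physiological hysteresis model), scatter and
beam hardening. Consequences for interpretation: passing tests show the
*pipeline* recovers low-dimensional smooth motion from projections under
the stated noise model; they do not certify performance on clinical
projections.

## PCA motion model

The stack of flattened DVFs (3N-vectors, N voxels) is mean-centered and
decomposed by SVD of the (phases × 3N) matrix rather than the 3N × 3N
covariance — identical results, tractable memory. The full spectrum is
retained for the information curve even when the synthesis truncation
order is k = 3; "information (%)" is the cumulative explained-variance
ratio × 100, reported to two decimals. Projection of a DVF onto the model
is the inner product with the eigen-fields, which is the least-squares
optimum under orthonormality.

Coefficient sampling for training-set generation expands each component's
per-phase range by ±15 % and samples independently and uniformly per
component. The uniform choice maximises coverage of the stated range; the
±15 % expansion covers motion slightly beyond the binned phase amplitudes
(breathing crosses bin boundaries). An alternative reading — scaling whole
coefficient trajectories by a ±15 % factor — is what the temporal sequence
builder uses (below); the box sampler is the general-purpose API.

## Projector

Cone-beam geometry: source on a circle of radius SAD = 1000 mm about the
volume z (SI) axis, flat detector at SDD = 1500 mm, gantry angle 0° by
default (source on +y). These values are typical linac CBCT numbers; the
angle at which all projections are simulated is configurable but fixed
within an experiment. The default experiment detector is 64×64 at 7 mm
pitch, chosen so the projected bounding box of the volume (including its
air corners at maximum magnification) fits on the panel.

The production projector is Siddon's exact-intersection traversal of the
piecewise-constant voxel volume (numba-compiled); every pixel is the exact
radiological path integral to the pixel centre. A dense midpoint
ray-marching integrator over the same volume model is kept purely as a
test oracle; the two agree to < 0.5 % and the Siddon value is exact for
the analytic uniform-cube case.

Noise is applied in the intensity domain and converted back to line
integrals: `I = Poisson(I0·exp(−p)) + N(0, σe²)`, clamped at one photon so
the log stays defined, then `p' = −ln(I/I0)`. Defaults `I0 = 1e5`,
`σe² = 10`. The clamp matters only for line integrals beyond ~11.5 at the
default flux, far above anything the phantom produces.

Intensity correction between simulated DRRs and measured projections
defaults to moment matching, `(I − mean_DRR)/σ_DRR · σ_Proj + mean_Proj`,
which exactly equalises first and second moments — the purpose of the
correction. A literal variant that reuses the per-pixel value in place of
the DRR mean (and therefore does not equalise moments) is implemented
behind `mode="as-printed"` for comparison. Statistics are
per-image; per-set statistics can be supplied by the caller. In the
simulation-only experiments both sides are simulated, so the per-image
z-score applied before the network subsumes this step.

## ConvLSTM regressor

Gate equations as standard: `i, f, o = σ(W_x∗X_t + W_h∗H_{t−1} + b)`,
`G_t = tanh(·)`, `C_t = f∘C_{t−1} + i∘G_t`, `H_t = o∘tanh(C_t)`, all
convolutions 3×3 stride 1. Terminology used here: "hidden channels" is
the per-gate feature count (default 40 at full scale) and "cell layers"
the number of stacked ConvLSTM layers (default 2). "Valid" padding cannot
be applied inside the recurrence (the hidden map would shrink every
step), so gate convolutions use same padding and the unpadded convolution
lives in the head's pooling stage.

Head: the final hidden map of the top layer passes through one 2×
down-sampling stage — a learned 3×3 stride-2 convolution by default, with
max/average/no pooling available for ablations — then two fully connected
layers of width 1024 and k = 3. ReLU follows the first dense layer.

The network, backpropagation through time and ADAM are implemented
directly on NumPy arrays (channels-last maps, im2col + GEMM convolutions).
Gradients are validated against central finite differences for every
parameter tensor and pooling variant, and the cell against a scalar LSTM
oracle at 1×1 spatial size (1e−10).

**Targets and loss.** Raw coefficients span orders of magnitude across
components, so targets are standardised per component before the loss and
the weighting `w = [2/6, 1/6, 1/6]` acts in standardised space; reported
coefficient-recovery errors are therefore also standardised (comparable
across components), and "relative MAE" normalises by the per-component
range of the true test coefficients. Input frames are z-scored per image.
Optimiser: ADAM, initial learning rate 1e−3, halved every 50 epochs
(the decay schedule itself is a free choice), batch size 8.

**Temporal sequence construction.** Training needs temporally ordered
frames, while the sampling design produces independent coefficient draws.
Frames are therefore ordered along simulated breathing traces: a
continuous phase variable advances through repeated cycles
(24 frames/cycle by default, ~4 s cycle at ~6 fps); the cycle trajectory
is the periodic linear interpolation of the per-phase PCA coefficients,
scaled per cycle by a factor drawn uniformly from the ±15 % expanded
range, plus small per-frame per-component jitter (3 % of the component
range). Every frame is rendered once; training samples are causal sliding
windows of T = 4 frames labelled by the final frame's coefficients.

## Reconstruction and experiment driver

A phased volume is `warp(reference, synthesize(q))`; a projection stream
is reconstructed with a causal sliding window (each reconstruction is
labelled by its window's final frame — real-time semantics). Test-time
projections receive the same noise model as training unless configured
otherwise. The experiment driver reports, per phase: interior-volume NCC
(both for predicted and for exact truncated coefficients — the latter is
the upper bound), mid-coronal-slice SSIM/PSNR/RMSE, and coefficient
MAE/MAPE; plus standardised and range-relative coefficient MAEs.

**Desk-scale defaults** (the study conditions of the shipped experiment):
64³ phantom, k = 3, 300 frames (297 four-frame sequences, ~10 % held out
for validation), 64×64 detector, ConvLSTM with 8 hidden channels and
2 cell layers, 12 epochs. This trains in a few minutes on one CPU while
leaving the pipeline's accuracy head-room clearly visible (mean NCC
≈ 0.999 against an oracle bound ≈ 0.9995). The full-scale settings
(40 channels, 900 samples, 200 epochs) remain the defaults of
`NetworkConfig`/`TrainingConfig` and are fully configurable.

## Metrics

MAE, RMSE, MAPE and PSNR are the standard definitions;
`PSNR = 10·log₁₀(MAX²/MSE)` with MAX defaulting to the reference image's
maximum (identical images report +∞, serialised as null). NCC is the
standard zero-normalised cross correlation in [−1, 1]. SSIM is the
single-scale Gaussian-window form (σ = 1.5, 11×11 support,
C1 = (0.01L)², C2 = (0.03L)²); multi-scale averaging over a dyadic
pyramid is available behind a flag. SSIM agrees with an
independent reference implementation to 1e−4. MAPE masks reference
entries with |T| ≤ 1e−6·max|T| instead of dividing by values arbitrarily
close to zero (the third PCA coefficient crosses zero). Planar metrics
use the mid-plane slice (coronal: fixed mid-y).

## Numerical choices and degenerate inputs

* PCA rank cut-off: singular values below 1e−12 of the largest are treated
  as zero; requesting k above the rank clamps with a warning.
* Warping uses trilinear pull-back interpolation with zero (air) fill
  outside the grid; consistency metrics are evaluated on the interior
  (4-voxel margin) to exclude fill effects.
* Siddon traversal tolerances: 1e−12 on ray parameters; rays missing the
  volume contribute exactly 0.
* Noise clamping at 1 photon; constant-image inputs to NCC raise, to the
  intensity correction warn and return the target-mean image.
* Forget-gate biases initialise to +1 (standard recurrent-network
  practice); other parameters are Glorot-uniform from the run seed.
* All stochastic stages (phantom→simulation→training→evaluation) derive
  from explicit integer seeds; end-to-end runs are bit-reproducible on a
  fixed platform.

## Known limitations

* The phantom's motion lies exactly in a low-dimensional linear space, so
  k = 3 truncation error is smaller than for clinical DVF stacks; the
  reported reconstruction quality is an upper bound on what identical
  settings would achieve on real data.
* One fixed projection angle is assumed known and identical between
  training and application; angular mismatch is not modelled.
* The noise model is monochromatic Poisson+Gaussian without scatter,
  detector blur or bowtie effects.
* Training at desk scale uses hundreds (not thousands) of sequences and
  a small network; the architecture scales, but wall-clock figures do
  not transfer.
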