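# rt4dcbct

Real-time four-dimensional cone-beam CT (4D-CBCT) estimation from
single-angle X-ray projections, for researchers working on image-guided
radiotherapy of moving targets (lung SBRT in particular).

Instead of reconstructing each breathing phase from a full 360° projection
sweep, the package estimates the *motion state* from a handful of
consecutive projections acquired at one fixed gantry angle:

1. **PCA motion model.** Per-phase deformation vector fields (DVFs)
   relating every 4D-CT phase to the 0% reference phase are flattened to
   3N-vectors and decomposed with a mean-centered PCA:

   `DVF(i) = mean + Σ_{j=1..k} q_j(i) · p_j ,  k = 3`

   The orthonormal eigen-fields `p_j` are fixed; the three coefficients
   `q_j` ("PCA labels") describe any breathing state.

2. **Projection simulation.** Sampled coefficient trajectories along
   breathing traces (amplitudes expanded ±15 %) are turned into DVFs,
   the reference volume is warped, and digitally reconstructed
   radiographs (DRRs) are ray-traced at one gantry angle (Siddon's exact
   traversal). Quantum noise is added as
   `I = Poisson(I0·exp(−p)) + N(0, σe²)` with `I0 = 1e5`, `σe² = 10`,
   and intensity statistics can be moment-matched to measured projections.

3. **ConvLSTM regression.** A convolutional LSTM (gates
   `i, f, o = σ(W_x∗X_t + W_h∗H_{t−1} + b)`, candidate `G = tanh(·)`,
   `C_t = f∘C_{t−1} + i∘G_t`, `H_t = o∘tanh(C_t)`; 3×3 kernels, stacked
   cell layers, convolutional-pooling head with fully connected layers
   1024 → 3) maps a window of T = 4 consecutive DRR frames to the three
   coefficients. Training minimises the weighted loss
   `L = (1/N) Σ ‖w∘(y − G(x))‖²` with `w = [2/6, 1/6, 1/6]`, so the
   dominant first coefficient is estimated most accurately.

4. **Reconstruction.** Each predicted coefficient vector synthesises a
   DVF that warps the reference volume into the phased CBCT volume; a
   causal sliding window over the incoming projection stream covers the
   whole respiratory cycle.

A synthetic 4-D thorax phantom (soft-edged ellipsoid anatomy with a
superior–inferior dominant, smoothly varying displacement field and a
movable tumor) provides volumes, ground-truth DVFs and breathing traces,
so the entire pipeline runs and is tested without any external data.
Externally supplied volumes/DVFs in NIfTI or MetaImage format are accepted
through the same interfaces. The ConvLSTM itself — forward pass,
backpropagation through time and the ADAM optimizer — is implemented
directly on NumPy arrays and verified against finite differences and a
scalar-LSTM oracle.

## Worked example

```python
from rt4dcbct.phantom import BreathingTrace, default_spec, generate_4dct
from rt4dcbct.motion import fit_pca, information_curve

spec = default_spec(48)                      # 48³ voxels over a 256 mm FOV
volumes, dvfs = generate_4dct(spec, BreathingTrace.cos2(10))
model = fit_pca(dvfs[1:], k=3)               # 9 non-reference phase DVFs
for n, cum, inc in information_curve(model):
    print(f"{n}  {cum:6.2f}  {inc:5.2f}")
```

prints the cumulative / incremental information (%) per PCA label:

```
1   98.47  98.47
2   99.09   0.62
3   99.40   0.32
4   99.68   0.27
5   99.83   0.15
6   99.94   0.11
7   99.99   0.05
8  100.00   0.01
```

The first mode (diaphragm-driven SI motion) dominates; eight components
describe the nine mean-centered phase fields completely, which is the
expected rank bound. The full experiment is one call:

```python
from rt4dcbct.reconstruction import ExperimentConfig, run_experiment
report = run_experiment(ExperimentConfig(seed=0))
print(round(report["mean_ncc"], 4), round(report["mean_ssim"], 4))
# 0.9986 0.9931
```

i.e. phase volumes reconstructed from ConvLSTM-predicted coefficients
correlate with the ground-truth phases at NCC ≈ 0.999, with mid-coronal
SSIM ≈ 0.993, after a few minutes of CPU training at desk scale.

A command-line interface mirrors the library (`rt4dcbct phantom`,
`fit-pca`, `sample`, `simulate`, `train`, `predict`, `reconstruct`,
`evaluate`, `run`); see `rt4dcbct --help`.

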