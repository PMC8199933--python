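# Methods

## The imaging model

The measurement system is an 8-channel MIT bench: eight identical 30-turn
coils (radius 0.025 m) spaced 45° apart on a circle of radius 0.11 m around
a circular imaging field of radius 0.1 m, driven one at a time with 1 A rms
at 10 MHz. Each excitation yields 7 receive-coil readings, so one full
cycle produces a 56-component vector of boundary phase differences. The
conductivity image lives on a 67×67 uniform lattice spanning [−R, R]²; a
pixel is active iff its center lies within R of the origin (boundary
inclusive), which keeps exactly 3409 pixels. This mask convention was
fixed by a brute-force scan over the candidate conventions (strict vs
inclusive inequality, mask radius R vs R ± h/2, edge- vs cell-centered
lattices): the edge-centered inclusive-≤ convention is the only simple one
producing 3409 at side count 67. It also yields 797 active pixels at the
scaled-down side count 33.

Displacement currents are neglected (the permittivity term is irrelevant at
the conductivity contrast modelled here), and the forward map is the
standard first-order linearization of the eddy-current problem: the phase
perturbation of pair (i, j) is `ω ∫ A_i(r)·A_j(r) Δσ(r) dr`, with each coil
modelled as a magnetic dipole normal to the imaging plane (vector potential
azimuthal about the coil center, magnitude ∝ turns·I·area/d²). Discretized
on the grid this gives the 56×3409 sensitivity matrix. The model is exactly
reciprocal — row (i, j) equals row (j, i) — and reproduces the soft-field
effect: central columns of S carry roughly an order of magnitude less norm
than peripheral ones. Absolute phase units are unrecoverable without the
full field solve and are deliberately absorbed into a single calibration
scale (the response peak of a reference anomaly placed at half radius is
set to 1) followed by dataset min-max normalization; only the spatial
structure of S matters to every algorithm downstream.

Measurement rows are ordered excitation-major with receivers enumerated
cyclically from the exciter, (i, i+1) … (i, i+7 mod 8). This is the one
ordering under which rotating the conductivity by 45° counterclockwise is
*exactly* a forward roll of the 56-vector by 7 positions, which the
data-augmentation scheme exploits. The residual error of that equivalence
on rasterized phantoms is pure re-gridding error: it falls from ≈40 % worst
case on a 21×21 grid to <5 % on the 67×67 grid. Tests of rotation
equivariance therefore run on the standard grid.

## Phantoms and the synthetic corpus

Phantoms are a homogeneous background of 0.25 S/m (soft-tissue-like) with
spherical anomalies of 0.05 S/m (hematoma-like), radius 0.02 m, rasterized
as their equatorial disks on the coil plane (a pixel takes the anomaly
value iff its center is strictly inside the disk). The single-anomaly
corpus sweeps the anomaly center over a polar grid with 9° angular steps
and 0.1 cm radial steps from the center out to 7.0 cm — 71 × 40 = 2840
placements. (Sweeping literally until the disk touches the boundary would
reach 8.0 cm; 7.0 cm is the radial limit consistent with the 2840-placement
corpus and is the package default.) The ρ = 0 row is retained at every
angle: the placements coincide spatially but their rotation-augmented
measurement vectors differ. Two-anomaly samples place a partner at center
separations {0, R, 2R, 3R} (R the anomaly radius) and orientation multiples
around a coarsened base sweep, dropping pairs that leave the field; the
sweep density is a configuration knob. Rotation augmentation re-rasterizes
the image at θ + k·45° and rolls the stored voltage by 7k, avoiding
re-simulation.

Voltages and conductivities are min-max normalized to [0, 1] with one
global (min, max) per block. Because phantom conductivity is two-valued,
the image block maps onto exactly {0, 1} — anomaly 0, background 1 — so
the generator's sigmoid output pixel acts as a soft anomaly classifier.
Noise is additive white Gaussian on the 56-vector with power
`signal_power / 10^(SNR_dB/10)`, seeded per draw; the empirical SNR of the
generator matches the requested level to within 0.1 dB over 10⁴ draws.

**What the generator does not emulate.** The forward model is a fixed
linear operator: it omits the conductivity-dependence of the sensing field
(the very nonlinearity that makes real MIT hard), coil self-impedance,
electronics drift, and geometric miscalibration. Phantoms are binary disks,
not anatomically textured media. Passing the reconstruction study therefore
shows that the training pipeline, the augmentation bookkeeping, and the
model comparison behave correctly under the stated noise model — it does
not certify performance on measured data or on strongly nonlinear contrast.

## Networks and training

All networks are fully connected, implemented in numpy with hand-derived
backpropagation and Adam (β₁ = 0.9, β₂ = 0.999); gradient correctness is
pinned by central-difference tests at 10⁻⁴ relative tolerance. The
full-scale generator is {56, 128, 256, 512, 1024, 2048, 4096, 3409} with
activations [relu, relu, relu, tanh, tanh, tanh, sigmoid] (the published
per-layer activation counts only fit the published size list if the input
layer counts as the first ReLU layer — harmless, since ReLU is the identity
on [0, 1] inputs). The discriminator is {3409, 512, 128, 1} with leaky-ReLU
(slope 0.2) hidden units and a sigmoid output. Weights are He-initialized
from a seeded generator; every training routine is bit-reproducible given
its config and seed.

Stage 1 pretrains the generator on `‖σ − G(V)‖² + λ_w‖θ‖²` (λ_w = 10⁻⁵ by
default; the published protocol states L2 regularization without a
coefficient) with batch 50 for up to 1000 epochs at full scale. Stage 2
alternates k = 1 discriminator ascent steps on
`(1/M) Σ [log D(σ) + log(1 − D(G(V)))]` with one generator descent step on
`(1/M) Σ log(1 − D(G(V)))`, batch 4000 at full scale. Log-loss gradients
are taken with respect to the discriminator's pre-sigmoid logit for
numerical stability. A non-saturating generator loss (−log D(G(V))) is
available behind a config flag and off by default. The learning rate is
not part of the published protocol; defaults are 10⁻⁴ (full scale) and
10⁻³ (desk profile), chosen once for stable convergence at each scale.

After every adversarial epoch the held-out validation set is scored with
per-dimension MSE. Training stops early when the generator's adversarial
loss (−mean log D(G(V))) drops below the discriminator's cross-entropy and
validation MSE is below 0.05; otherwise it runs to the epoch cap (500 full
scale, 40 desk) and records the stop reason. The generator returned is the
validation-MSE-best checkpoint seen during stage 2, with the pretrained
initialization as the first candidate — adversarial updates are kept only
when cross-validation says they helped. This guard matters: in this
linear-surrogate setting the pure adversarial gradient does not reduce
pixel MSE once stage 1 has converged, and without checkpoint selection
stage 2 can drift the generator off the supervised optimum.

## Baselines

**Tikhonov.** `σ̂ = (SᵀS + λI)⁻¹ Sᵀ V` solved by a positive-definite
factorization; the solution satisfies the normal equations to 10⁻⁸. λ is
selected by a deterministic grid search (17 log-spaced points, 10⁻⁶…10²)
minimizing mean normalized-image RMSE on the validation split, and is
logged with every experiment; noisier validation data select weakly larger λ.

**BPNN.** The classic pre-deep-learning fully-connected reconstructor: a
single sigmoid hidden layer sized by the geometric-mean rule
`round(√(n_in · n_out))` (437 units at full scale, 211 at desk scale),
sigmoid output, trained with the identical supervised L2/Adam protocol as
stage 1. Defining the BPNN as the generator architecture minus stage 2 was
considered and rejected: with the validation-MSE checkpoint guard the two
models coincide whenever the adversarial stage fails to reduce validation
MSE, which makes the three-way comparison degenerate; the historical
BPNN-vs-GAN comparisons this package mirrors used an independently designed
shallow network. The trainer itself is architecture-generic — handed the
generator's spec and seed it reproduces the GAN's pretrained initialization
exactly, and a test pins that identity.

## Metrics

All indices are computed on the normalized [0, 1] images over active
pixels. RMSE is per-pixel; SSIM is the single-window global form with
c₁ = (0.01·L)², c₂ = (0.03·L)², L = 1 (the formula's means, variances and
covariance are taken over the whole masked vector — no sliding window);
PSNR uses peak 1, making `PSNR = −20 log₁₀ RMSE` an identity, which
reproduces published RMSE↔PSNR table pairs to within 0.01 dB; CC is the
Pearson correlation and is undefined (raised as an error) for constant
images. A perfect reconstruction reports PSNR = ∞. The evaluation harness
draws noise per (SNR level, sample) from seeded streams so every model sees
identical noisy inputs.

## Problem sizes of the shipped study

The default (desk) study uses the 33×33 grid (797 pixels), a 600-placement
single sweep (radial step 0.5 cm) plus ≈880 two-anomaly pairs, one rotation
copy (2984 samples total), an 80/10/10 split, a {56, 256, 512, 797}
generator and {797, 128, 32, 1} discriminator, 120 pretraining epochs, 40
adversarial epochs at batch 500, and 200 fresh test phantoms (half single-,
half two-anomaly, centers uniform in radius and angle) scored at
SNR ∈ {∞, 80, 40, 20} dB. These sizes are the package's chosen
desk-scale operating point; the `paper` profile restores the full-scale
settings above.

## Known limitations

- The linear sensitivity surrogate understates the difficulty of real MIT;
  absolute conductivity calibration is out of scope by construction.
- Stage 2 is distribution-matching, not paired: with a converged stage 1 it
  mostly validates the adversarial machinery (discriminator convergence to
  D ≈ 0.5, loss bookkeeping, stopping) rather than improving MSE.
- Single 2-D slice only; no multi-slice or volumetric grids.
- Rotation augmentation is exact only for the measurement roll; the image
  re-rasterization carries ±2 pixels of disk-area jitter.
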