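# mitgan

GAN-based image reconstruction for **magnetic induction tomography (MIT)**.

MIT images the electrical conductivity inside a body without contact: an
array of coils takes turns driving an alternating current, the induced eddy
currents perturb the voltages picked up by the remaining coils, and a
reconstruction algorithm recovers the internal conductivity map from those
boundary measurements. The inverse problem is severely ill-posed — an
8-coil array yields only 56 phase-difference measurements per frame, from
which a 3409-pixel conductivity image must be recovered — and the
electromagnetic "soft-field" effect makes the center of the field nearly
invisible to linear methods.

This package is aimed at researchers studying learned reconstruction for
electromagnetic tomography. It provides, end to end:

- an 8-coil measurement model on a circular imaging field (radius 0.1 m,
  67×67 lattice, 3409 active pixels) with a reciprocity-symmetric linearized
  sensitivity matrix `V = S Δσ` built from magnetic-dipole coil fields;
- synthetic conductivity phantoms (0.25 S/m tissue background, 0.05 S/m
  spherical anomalies of radius 2 cm) swept over polar placement grids,
  with 45°-rotation data augmentation that rotates the image while rolling
  the measurement vector 7 positions;
- a two-stage GAN reconstructor, implemented from scratch in numpy:
  a fully-connected generator `G: V ∈ [0,1]⁵⁶ → σ ∈ [0,1]³⁴⁰⁹` pretrained by
  Adam on the supervised loss `‖σ − G(V)‖₂² + λ‖θ‖₂²`, then fine-tuned
  adversarially against a discriminator `D` via the minimax value

  ```
  min_G max_D  E_σ[log D(σ)] + E_V[log(1 − D(G(V)))]
  ```

  whose optimum is `D*(x) = p_σ(x) / (p_σ(x) + p_G(x)) = 1/2` when the
  generated and true image distributions coincide;
- baselines: single-step Tikhonov regularization
  `σ̂ = (SᵀS + λI)⁻¹ Sᵀ V` and a classic single-hidden-layer
  fully-connected (BPNN) reconstructor;
- the four standard image-quality indices — RMSE, global SSIM, PSNR
  (unit-peak convention, so `PSNR = −20 log₁₀ RMSE`), and the Pearson
  correlation coefficient — plus an SNR-sweep benchmarking harness.

## Worked example

The scaled-down study profile (33×33 grid, 797 active pixels, ≈3000
training samples, shrunk networks) trains all three reconstructors and
scores them on 200 fresh random phantoms at four noise levels:

```python
from mitgan.study import desk_profile, run_study
from mitgan.metrics import reports_to_frame

result = run_study(desk_profile(seed=1))
print(reports_to_frame(result.reports).round(3).to_string(index=False))
```

which prints (about three minutes on one CPU):

```
   model  snr_db  n_samples  rmse  ssim   psnr    cc
     GAN     inf        200 0.091 0.914 21.829 0.920
    BPNN     inf        200 0.160 0.659 16.334 0.724
Tikhonov     inf        200 0.169 0.644 15.577 0.682
     GAN    80.0        200 0.091 0.914 21.830 0.920
    BPNN    80.0        200 0.160 0.659 16.334 0.724
Tikhonov    80.0        200 0.169 0.644 15.577 0.682
     GAN    40.0        200 0.091 0.914 21.832 0.920
    BPNN    40.0        200 0.160 0.659 16.332 0.723
Tikhonov    40.0        200 0.170 0.642 15.540 0.679
     GAN    20.0        200 0.098 0.900 21.114 0.906
    BPNN    20.0        200 0.161 0.658 16.310 0.723
Tikhonov    20.0        200 0.220 0.519 13.437 0.531
```

The rows show the consistent ordering GAN < BPNN < Tikhonov in RMSE and the
reverse in CC/SSIM at every noise level, and that the learned reconstructors
degrade gracefully to 20 dB SNR while the linear inverse collapses: the deep
two-stage reconstructor suppresses both the artifact haze of the regularized
linear inverse and the hot pixels of the shallow supervised net.

The same pipeline is scriptable from the shell:

```sh
mitgan generate --profile desk --seed 1 --out runs/desk
mitgan train    --profile desk --seed 1 --out runs/desk
mitgan evaluate --profile desk --seed 1 --out runs/desk   # writes metrics.csv
mitgan render   --profile desk --seed 1 --out runs/desk   # truth vs models PNG
```

`--profile paper` switches to the full-scale protocol (67×67 grid, 2840
single-anomaly placements at 9°/0.1 cm steps, the
{56 128 256 512 1024 2048 4096 3409} generator, 1000 pretraining epochs);
expect hours on one CPU.

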