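# spectden

Denoising fast myocardial-perfusion SPECT projections with an
attention-guided conditional GAN, together with everything needed to
exercise the method without clinical data: a synthetic cardiac phantom
cohort, a parallel-beam acquisition simulator with Poisson noise and
list-mode-equivalent count thinning, OS-EM reconstruction, and the full
quantitative evaluation protocol (NMSE/SSIM/PSNR in a heart VOI, polar-map
intensity ratio, a defect-extent surrogate, Bland-Altman and joint
regression analysis).

Myocardial-perfusion SPECT acquisitions are slow (minutes per study); cutting
the time per projection view from 10 s to 1-7 s raises patient throughput
and reduces motion artifacts but floods the projections with Poisson noise.
The approach implemented here trains, per acquisition-time level, a
conditional GAN whose generator G maps a fast projection stack to an
estimate of the full-time (FT) stack:

    L = argmin_G max_D ( L_ADV(G, D) + lambda * L1(G) ),   lambda = 100,

with a 3D attention-gated U-Net generator (gates reweight the skip-connection
features so regions beyond the local receptive field can modulate them), a
conditional patch discriminator D on (fast, candidate) pairs, and optionally
a binary patient defect flag embedded as four constant slices appended to the
input stack (AttGAN-def). Denoised projections are reconstructed with OS-EM
(5 iterations, 4 subsets, attenuation corrected) and compared against the
Gaussian-filtered (sigma 0.6 voxel) FT reconstruction. Plain U-Net (L1 only)
and cGAN (gates off) baselines nest structurally inside the full model.

The package is aimed at researchers in emission-tomography image processing
who want a fully inspectable, CPU-scale reference implementation of this
pipeline — every component, including the neural-network engine, is numpy
code in this repository.

## Worked example

One desk-scale experiment: 50 synthetic subjects (32^3 phantoms, 16 views,
10 s/view at 2e4 counts per view), thinned to 1 s/view (p = 0.1), one
35/5/10 train/validation/test fold, attention-GAN with 3 levels and 16
filters trained 50 epochs:

```python
from spectden.cv_harness import toy_denoising_experiment

res = toy_denoising_experiment(seed=0)   # ~2 min on one CPU core
for metric in ("nmse", "ssim", "psnr", "ir_abs_err", "pds_abs_err"):
    print(f"{metric:12s} attgan {res.mean('attgan', metric):8.4f}"
          f"   fast {res.mean('fast', metric):8.4f}")
```

prints

```
nmse         attgan   0.0604   fast   0.3301
ssim         attgan   0.9108   fast   0.7020
psnr         attgan   4.5825   fast  -2.8023
ir_abs_err   attgan   0.1097   fast   0.0940
pds_abs_err  attgan   5.8532   fast   6.7381
```

Reading: over the ten held-out subjects, denoising cuts the normalized mean
square error against the filtered full-time reference by a factor of about
five relative to the count-rate-scaled raw fast images, raises structural
similarity and peak SNR, and reduces the defect-extent surrogate error; the
polar-map intensity-ratio error is comparable between the two at this seed
and improves on average across seeds. (PSNR values use the printed-formula
convention with MAX rather than MAX^2 in the numerator, so their absolute
level is lower than the standard definition by 10*log10(MAX).)

The same pipeline is scriptable from the shell:

```
spectden phantom generate --n 4 --seed 7 --grid 32 --out cohort/
spectden project --phantom cohort/subject000.json --views 16 --rebin 2 --out ft.npz
spectden thin --in ft.npz --time 1 --out fast.npz
spectden recon --in fast.npz --iters 5 --subsets 4 --out vol.nii
spectden experiment run --config experiment.yaml --out results/
```

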