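# prcpet — CNN positron-range correction for Ga-68 preclinical PET

Ga-68 is increasingly used in small-animal PET (theranostics work pairs
it with Lu-177), but its energetic positrons travel ~3.5 mm on average
before annihilating, blurring images far more than F-18. `prcpet` is a
self-contained pipeline that

1. builds voxelized digital phantoms (a procedural brain surrogate, a
   5-rod contrast phantom over a TBR series, a cold-sphere spill-over
   phantom, and a 20-rod Derenzo-style resolution phantom),
2. simulates each phantom twice with an image-domain forward model —
   once as **Ga-68** (range blur + PSF + Poisson noise) and once as
   **back-to-back 511-keV gammas** (PSF + noise only, i.e. a
   range-free reference),
3. trains convolutional networks (CNN1 = 3-layer super-resolution
   style; CNN2 = 4-layer; CNN3 = CNN2 with dense connections and deep
   supervision; all valid-convolution, pure numpy) on 32×32 patch pairs
   to map Ga-68 images to their gamma references, and
4. evaluates corrections with NEMA-style metrics: RMSE, PSNR, per-rod
   recovery coefficients (RC, CV_RC) and spill-over ratios (SOR,
   CV_SOR).

The core quantities are

    RMSE = sqrt( Σ_v (I_gamma − I_test)² / V )        PSNR = 20·log10(I_max / RMSE)
    RC   = AVG_target / AVG_uniform                   CV_RC  = sqrt((SD_t/AVG_t)² + (SD_u/AVG_u)²)
    SOR  = AVG_cold / AVG_hot                         CV_SOR = sqrt((SD_c/AVG_c)² + (SD_h/AVG_h)²)

with ROI and line-profile procedures described in `docs/methods.md`.

## Worked example

Run the desk-scale study (0.8 mm voxels, 20 phantom configurations,
CNN1, 1500 SGD iterations; ~8 min on one CPU):

```bash
prcpet all --output-dir run1 --seed 1 --scale desk --arch CNN1
```

or from Python:

```python
from prcpet import RunConfig, run_pipeline
manifest = run_pipeline(RunConfig(output_dir="run1", seed=1,
                                  scale="desk", architectures=("CNN1",)))
```

The run writes phantoms and image pairs (NIfTI + JSON sidecars), patch
stores (HDF5), a checkpoint `CNN1.npz`, `metrics.csv`/`metrics.json`
and a `manifest.json` capturing every resolved parameter and derived
seed. With seed 1 the evaluation table contains (abridged):

```
volume        metric   ga68     CNN1-corrected
brain08       rmse     1.63     1.28
rod5_tbr10    rmse     16.94    14.23
rod5_tbr10    rc_4mm   0.567    0.665
rod5_tbr10    rc_6mm   0.695    0.944
rod5_tbr10    rc_10mm  0.859    1.034
sphere1       sor      0.420    0.287
```

Reading this: on every held-out volume the corrected image is closer to
the range-free gamma reference (lower RMSE); rods of 4 mm and above
recover contrast (RC rises toward 1), while the 2-mm rod stays largely
unresolved; and spill-over into the cold sphere drops from the Ga-68
level toward the gamma level — the blur really is being inverted, not
merely sharpened cosmetically. Absolute numbers depend on the desk
preset's grid and training budget (see `docs/methods.md`).

CLI subcommands `phantoms`, `simulate`, `dataset`, `train`, `correct`
and `evaluate` run the individual stages; `--scale full` switches to
the full-resolution 30-configuration study.

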