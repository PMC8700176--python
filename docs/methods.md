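# Methods

`prcpet` studies whether compact convolutional networks can undo the
positron-range blur of Ga-68 in preclinical PET. Ga-68's mean positron
energy (0.83 MeV) gives a mean annihilation displacement of about
3.5 mm — several voxels on a small-animal scanner — so Ga-68 images are
markedly softer than images formed from back-to-back 511-keV gamma
emission at the decay voxel, which carries no positron range at all.
Simulating each phantom twice, once per emission mode, yields perfectly
aligned (blurred, reference) image pairs; networks trained on patches of
these pairs learn a deconvolution that is then applied slice-by-slice to
whole volumes.

## Forward model

The scanner chain (block detectors, sinograms, rebinning, OSEM) is
deliberately replaced by an image-domain model; the correction method
only consumes reconstructed image pairs, not raw data.

* **Positron range.** An isotropic 3D displacement whose magnitude is
  exponential, p(r) = (1/τ)·e^(−r/τ) with τ = 3.5 mm, so the mean
  displacement equals τ. The corresponding image kernel is the 3D
  density e^(−r/τ)/(4πτr²) integrated per voxel: midpoint quadrature
  far from the origin, 10³ subsamples where the 1/r² factor varies
  quickly (r < 3 voxels), and an analytic inscribed-sphere mass plus a
  16³-subsampled corner correction at the central voxel. The support is
  truncated where the magnitude CDF reaches 99.9% (≈ 24 mm) and the taps
  renormalized to unit mass; requesting a larger truncation loss raises
  an error. The parameterization is pluggable; the exponential law is a
  single-knob stand-in for the true Ga-68 spectrum-weighted range
  profile (which is more sharply peaked at zero), adequate because the
  correction task only needs a realistic, heavy-tailed, multi-voxel
  blur.
* **System resolution.** An isotropic Gaussian PSF, FWHM 1.5 mm
  (≈ crystal pitch / 1.5), applied in both emission modes.
* **Counting statistics.** Expected counts per voxel are
  activity × voxel volume × scan duration (1200 s) × sensitivity
  (4·10⁻⁴ detected counts per decay, chosen so a 20-min five-rod scan
  collects ≈ 10⁷ counts); the observed image is an independent Poisson
  draw per voxel, seeded per (phantom, emission mode) from the run seed.
  Attenuation, scatter, randoms and dead time are out of scope.

Convolution is zero-padded; phantom plans leave a transaxial margin of
at least the kernel support, so in-plane mass loss is negligible, while
the 80-mm phantoms fill the axial field of view end-to-end (as the
study grids do) and lose some mass at the axial faces — the metrics
only use the central 50 mm.

## Phantoms

Four families on isotropic grids (0.4 mm at full scale):

* **brain** — a procedural surrogate with a hot cortical shell,
  white-matter interior (gray:white = 4:1), two deep hot blobs and two
  cold ventricle-like cavities, normalized to 3.7·10⁶ Bq total. The
  exact voxel data of a physical brain phantom is not shipped; the
  networks only need diverse structured activity, and diversity comes
  from 2 translations × 2 rotations × 5 seeded smooth deformation
  fields (low-frequency sinusoidal displacements, ≈ ±2 mm). Transforms
  are applied to the sampling coordinates, so an integer-voxel
  translation shifts the discrete grid exactly.
* **rod5** — 50 mm cylinder, 80 mm long, rods of 2/4/6/8/10 mm at
  1.69·10⁶ Bq/mL; background = rod activity / TBR for
  TBR ∈ {0,2,4,5,8,10,16,20}, with TBR = 0 meaning a cold background.
* **sphere1** — the same cylinder, uniformly hot, with a 10-mm cold
  (water) sphere placed at half the cylinder radius off-axis so that a
  10-mm hot reference disc fits diametrically opposite.
* **rod20** — elliptical cylinder (55 × 50 mm axes) with four
  Derenzo-style quadrant sectors of five rods each (2/3/4/5 mm,
  triangular 2+3 clusters, pitch 2d); rods alternate between
  1.69·10⁶ ("white") and 8.44·10⁵ Bq/mL ("gray") within a sector. Rod
  positions are configuration constants chosen for containment and
  non-overlap (both are checked at construction), not measured values.

The default plan enumerates 30 configurations: 20 brain + 8 rod5 +
sphere1 + rod20.

## Networks and training

All layers are valid (no-padding) convolutions, so a 32×32 input patch
shrinks to 20×20 (CNN1: kernels 9-1-5, channels 64-32-1) or 18×18
(CNN2: 7-5-3-3, 64-64-32-1). CNN3 is CNN2 with deep supervision: a 1×1
prediction head on every hidden stage, center-cropped to the output
size, each contributing a companion loss (weight 0.3, configurable),
plus dense connections that concatenate all earlier feature maps —
center-cropped to the current spatial size — into each layer's input.
Exact kernel/channel counts are design choices consistent with the
stated output sizes and the architectures' source lineages
(super-resolution CNN; MRI-to-CT CNN; its deeply-supervised variant).
Whether dense connections span all layer pairs or only adjacent ones is
ambiguous in the source; all pairs is implemented.

Weights are Xavier-initialized (variance 2/(fan_in+fan_out)), biases
zero; training is classical momentum SGD, batch 128, learning rate
0.01, momentum 0.9, with seeded epoch reshuffling. The loss is the
Euclidean distance between prediction and the gamma label patch,
recorded as the per-patch squared-error sum averaged over the batch.
One numerical choice matters: the optimizer divides the gradient by the
label pixel count (i.e., optimizes the per-pixel mean). With the raw
per-patch sum, the very first SGD updates at these hyperparameters
already exceed the Xavier weight scale and training diverges; the
per-pixel normalization fixes the step-size semantics independent of
label size while optimizing the same objective up to a constant.
Training runs a fixed iteration budget (no early stopping) and aborts
with a diagnostic if the loss becomes non-finite.

Patches come from a deterministic raster grid — stride 14 for training
volumes, 21 for testing — rather than random crops, so dataset sizes
follow the closed form ⌊(W−32)/stride⌋+1 per axis; a seeded
random-offset mode is not needed for the shipped experiments. Patches
whose input is entirely zero (air) are dropped. Each volume is
normalized by its own global maximum before patching (scale recorded).
Because the gamma reference is sharper, its maximum exceeds the Ga-68
maximum, so rescaling corrected volumes by the input's scale leaves a
small systematic global dimming; the scale-invariant metrics (RC, SOR,
CV) are unaffected and the RMSE comparisons tolerate it. The
phantom-level split is fixed: 80% of brain configurations and
TBR ∈ {0,4,5,8} train; the remaining brains and TBR ∈ {2,10,16,20}
test; sphere1 and rod20 are evaluation-only and are never patched.

Whole-volume correction runs the network fully convolutionally on each
axial slice, reflect-padded by the total shrinkage so output matches
input shape, rescaled by the stored normalization and clamped at zero.

## Metrics

* RMSE = √(Σ(I_ref − I_test)²/V) over all V voxels; PSNR =
  20·log₁₀(I_max/RMSE) with I_max taken from the gamma reference
  (configurable; the definition leaves the source ambiguous).
* RC per rod: slices over the central 50 mm of the five-rod volume are
  averaged; the maximum-intensity pixel of each rod (searched within
  the rod's label footprint dilated by one voxel, first-in-raster-order
  tie-break) anchors an axial line profile over the same 50 mm;
  RC = profile mean / mean of a 10-mm disc on the averaged uniform
  cylinder of the sphere phantom. CV_RC adds the two relative SDs in
  quadrature.
* SOR: 10-mm discs on the cold sphere (center slice) and on the hot
  cylinder in the same slice; SOR = AVG_cold/AVG_hot, CV_SOR in
  quadrature. A pixel belongs to a disc if its center lies inside; an
  exactly-zero cold mean flags the CV as degenerate (None) instead of
  propagating NaN.

## Scale presets and problem sizes

The `desk` preset (default) runs the whole study on one CPU in minutes:
0.8 mm voxels on 128×128×100 grids (102.4 mm field of view, 80 mm
axial), 10 brain configurations (8 train / 2 test) plus all 8 TBRs,
sphere1 and rod20 (20 phantoms), CNN1 with 1500 SGD iterations
(≈ 3.4 epochs over ≈ 57k training patches). The `full` preset restores
0.4 mm voxels, 250×250×200 grids (brain 250×250×290), all 30
configurations and a long training budget. One run seed derives all
stage sub-seeds (simulation noise, initialization, shuffling), making
every stage bit-reproducible in isolation.

At desk scale the directional findings reproduce: correction lowers
RMSE against the gamma reference on every held-out volume, raises RC
for rods ≥ 4 mm (the 2-mm rod stays essentially unrecovered), and moves
SOR from the Ga-68 value toward — but not past — the gamma value.
Absolute values are not comparable to a full Monte Carlo + full-training
study: the coarser grid, the simplified single-exponential range law and
the short training budget all inflate blur-related numbers (e.g. SOR).

## Limitations

* The simulator omits attenuation, scatter, randoms and reconstruction
  artifacts; real OSEM noise is spatially correlated, Poisson noise
  here is not. Passing tests show the correction inverts the modeled
  degradation, not scanner-specific behavior.
* The brain surrogate is smoother and more symmetric than real
  neuroanatomy; generalization claims are limited to the phantom
  families simulated.
* The exponential range law has the right mean but not the true Ga-68
  annihilation-distance profile shape.
* The 2-mm rods sit near the resolution limit at 0.8 mm voxels; their
  RC values are dominated by discretization.
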