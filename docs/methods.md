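# Methods

## Problem and model

`flimstain` synthesises bright-field H&E-stained appearance from label-free
fluorescence-lifetime (FLIM) acquisitions. A FLIM field is a pair of
co-located rasters: photon-count intensity and fitted lifetime τ (ns).
Because lifetime is intensity-independent and sensitive to the molecular
microenvironment, it separates cell populations (e.g. macrophages at long
lifetimes, red blood cells at very short ones) that intensity alone cannot.

The translation network is a conditional GAN in the pix2pix mould. The
generator G is a U-Net mapping a FLIM-derived input f to an RGB image
s = G(f) ∈ [0, 1]; the discriminator D is a patch-based classifier scoring
(candidate, condition) channel concatenations. Losses:

- adversarial: standard conditional cross-entropy, real → label 1
  (`loss_D = −[E log D(h|f) + E log(1 − D(s|f))]`,
  `loss_G_adv = −E log D(s|f)`);
- reconstruction: pixel-mean L1 between s and the true H&E h;
- perceptual: DISTS, `1 − Σ_ij (η_ij T_ij + θ_ij S_ij)` over a feature
  hierarchy, with the texture term T comparing global feature-map means and
  the structure term S comparing global covariances.

Total objective: `α·L_adv + β·L1 + λ·DISTS` with defaults α = 0.1, β = 1,
λ = 5; Adam (β1 = 0.5, β2 = 0.999), learning rate 1e-4 divided by 10 every
60 epochs, 300 epochs in the full profile, horizontal-flip and ±15°
rotation augmentation.

## Input formats

Three network-input constructions are supported and compared:

1. **intensity** — globally normalised photon counts, inverted so tissue is
   dark on white (1 channel);
2. **α-FLIM** — lifetime false-coloured over a fixed [1.0, 5.0] ns display
   range, with normalised intensity appended as an alpha channel (4);
3. **IW-FLIM** — the same false-colour RGB multiplied pixelwise by
   normalised intensity (3).

By construction IW-FLIM equals the α-FLIM RGB times its alpha channel
pixelwise; the test suite asserts this identity exactly. Raw exports are
clamped to [0, 2000] counts and [0, 5] ns before any formatting.
Intensity normalisation bounds are per cohort (per TMA core), defaulting to
the clamp bounds when no cohort statistics exist. Lifetimes below the 1.0 ns
display floor saturate at the first colour-map entry. The built-in colour
map is a 256-entry blue→cyan→green→yellow→red table generated from fixed
linear anchors; any 256×3 CSV may be substituted.

## Numerical core

No GPU deep-learning framework is assumed: the networks, their training
and the DISTS loss run on a small reverse-mode autodiff engine
(`flimstain.nn`) over numpy, with convolution as im2col matrix
multiplication. This keeps every result bit-reproducible for a fixed seed
on a fixed platform. The U-Net decoder uses 3×3 convolution followed by
pixel shuffle (depth-to-space) rather than transposed convolution — cheaper
at equal capacity and free of checkerboard artefacts. The generator's
output head is initialised toward white (bias 1.2 before the scaled tanh),
a data-mean initialisation reflecting that H&E fields are dominated by
bright background; it substantially shortens the burn-in of short training
runs. Scores of exactly 0/1 in the adversarial logs are epsilon-guarded
(1e-8). DISTS constants c1 = c2 = 1e-6 are pure numerical guards.

DISTS feature extractors are pluggable and deterministic: a tiny fixed
two-map 2×2-mean extractor used by the brute-force oracle tests; a
VGG16-topology extractor with fixed-seed orthogonal kernels (works fully
offline, no downloaded weights); and a lightweight 3-stage variant used
during CPU-scale training. Map weights η, θ are uniform and normalised to
Σ(η+θ) = 1 — the convention under which DISTS of an image with itself is
exactly 0 — unless a weight file is supplied; re-learning them on
perceptual data is out of scope.

## Registration

H&E targets are luminance-converted, contrast-stretched (1st/99th
percentiles → 0/1) and bicubically resampled to the FLIM grid (e.g.
0.22 µm → 0.455 µm). The H&E→FLIM alignment is a global 6-parameter affine
estimated by maximising Mattes mutual information (50 bins, dense sampling,
3-level pyramid with shrink 4/2/1) via SimpleITK; dense sampling makes the
estimate deterministic. Because repetitive cellular texture makes the MI
surface multi-modal, the optimiser is multi-started on the coarse level
from seven initial rotations (0, ±5°, ±10°, ±15°) and the best coarse
similarity is refined through the full pyramid. A control-point
least-squares affine is available as a fallback. On degraded phantoms
(|rotation| ≤ 15°, |shift| ≤ 20 px, scale 0.9–1.1, noise sd 0.05) the
estimator recovers the warp to sub-pixel corner error in ≥ 90% of seeded
trials; residual failures are wrong-mode locks of the dot-lattice texture.

Patches of 256×256 (64×64 in the desk profile) are cut on a regular grid;
a patch is dropped iff its background fraction strictly exceeds 0.75.
Background is defined on the FLIM side — normalised intensity < 0.05 —
since signal-free regions carry no photons (threshold configurable; the
H&E side may be used instead).

## Evaluation metrics

- NRMSE = ‖ref − test‖₂ / ‖ref‖₂ over all pixels/channels (lower better).
- NMI = (H1 + H2) / H12 on 256-bin greyscale histograms, range [1, 2]
  (higher better; this normalisation is the one whose [1, 2] range matches
  the values typically measured between stained tissue image pairs, ≈ 1.1).
- PSNR = 10·log10(1/MSE) dB with peak 1.0; identical images report +inf.
- MSSIM: Gaussian-windowed SSIM (11×11, σ 1.5, K1 0.01, K2 0.03,
  data range 1), RGB scored per channel and averaged.

NRMSE and PSNR are monotone transforms of the same MSE up to the reference
norm, so their rankings over a noise ladder are mutually reversed — used as
a consistency test.

## Lifetime signatures

Given an annotation mask (pathologist or phantom), per-cell lifetime
histograms use 0.05 ns bins over [0, 5] ns (configurable; no binning is
canonical). The signature reports both the peak (modal-bin centre, ties
broken toward lower lifetime for determinism) and the pixel-weighted mean;
per-type pooling sums cell histograms, so the type mean equals the
pixel-weighted mean of cell means.

## Phantom generator

The phantom emulates the features the pipeline exercises: seven typed cell
populations with Gaussian lifetime distributions centred on reported
lung-tissue values (RBC 0.251, fibroblast 0.376, tumour 0.424, lymphocyte
0.471, neutrophil 0.659, plasma 0.690, macrophage 2.42 ns; σ = 0.05 ns),
Poisson photon noise around per-compartment brightness means (nucleus
brighter than cytoplasm ×0.5; macrophages bright, RBCs dim), and an H&E
rendering computed from geometry alone by Beer–Lambert optical-density
mixing (haematoxylin nuclei, eosin cytoplasm, white background). Cell
centres are rejection-sampled so nuclei never overlap while cytoplasm may
touch; default densities give ≈ 30–35% tissue coverage so that 64×64
patches pass the 75%-background filter the way confluent tissue does. All
randomness comes from a Philox counter-based generator keyed on the spec
seed, making phantoms bit-identical across platforms.

Because the H&E rendering depends only on geometry — never on lifetime or
intensity — a network cannot shortcut by copying colours; it must learn the
lifetime/intensity → stain mapping. What the phantom does **not** emulate:
instrument response and photon-decay fitting, optical blur and chromatic
effects, stain variability, tissue-level spatial organisation (glands,
stroma), and registration residuals beyond a global affine. Passing tests
therefore demonstrate the correctness and trainability of the pipeline, not
clinical-grade staining on real tissue.

## Problem sizes and profiles

The `full` profile is the full-scale recipe (256×256 patches, 8-level
U-Net with 64 base features, 300 epochs) and is GPU-scale. The shipped
`desk` profile — 64×64 patches, 3-level U-Net with 16 base features,
batch 2, 20 epochs, 128 training pairs, the 3-stage light DISTS extractor —
is the package's CPU-scale reference configuration used by the tests and
the acceptance script; it reaches held-out MSSIM ≈ 0.73–0.76 versus
≈ 0.34–0.40 untrained across seeds. Registration properties use 256²
phantoms; signature recovery uses the default 7-type spec on 256² fields.

## Known limitations

- The affine estimator can lock onto a wrong lattice mode on periodic
  textures (~1 failure in 20 trials at the stressed warp ranges).
- Training at full profile on CPU is impractical; the engine is
  single-threaded numpy and makes no attempt at GPU execution.
- The evaluation defaults compute metrics on RGB; NMI converts to
  greyscale first (option to do so for others is not provided).
- Checkpoints store the generator only; resuming restarts the
  discriminator and optimiser state fresh.
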