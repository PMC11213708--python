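# flimstain

Label-free virtual H&E staining from fluorescence-lifetime imaging (FLIM).

FLIM records, per pixel, both autofluorescence intensity and the fitted
fluorescence decay time (lifetime, ns) of unstained tissue. `flimstain`
turns such acquisitions into images that look like routine
haematoxylin-and-eosin histology, so that tissue can be read by a
pathologist — and cells classified by their lifetime signatures — without
chemical staining. The package implements the full pipeline:

- **FLIM I/O and post-processing** — intensity/lifetime TIFF pairs, raw
  clamping to [0, 2000] counts and [0, 5] ns, per-cohort global intensity
  normalisation (`flimstain.flim_core`);
- **network input formats** — inverted greyscale intensity, α-FLIM
  (false-colour lifetime over a fixed [1.0, 5.0] ns range + intensity as
  alpha) and IW-FLIM (intensity-weighted false-colour lifetime)
  (`flimstain.stain_formats`);
- **co-registration and patching** — bicubic H&E downsampling to the FLIM
  grid, mutual-information affine registration, 256×256 patch extraction
  with a strict >75%-background filter (`flimstain.coregister`);
- **conditional GAN** — U-Net generator and patch discriminator trained
  with `α·L_adv + β·L1 + λ·DISTS` (α = 0.1, β = 1, λ = 5), Adam
  (β1 = 0.5), lr 1e-4 ÷ 10 every 60 epochs (`flimstain.gan_model`,
  `flimstain.dists`, `flimstain.training`). The networks run on a small
  bundled numpy autodiff engine — no GPU framework required;
- **evaluation** — NRMSE, normalised mutual information, PSNR and mean
  SSIM between virtual and true staining, with per-format ranking tables
  (`flimstain.eval_metrics`);
- **lifetime signatures** — per-cell and per-type lifetime histograms,
  peak and mean lifetimes from annotation masks (`flimstain.signatures`);
- **tissue phantom** — a deterministic generator of paired
  FLIM/H&E/annotation fields with seven cell types carrying distinct
  lifetime distributions, the test substrate for everything above
  (`flimstain.phantom`).

## Worked example

Generate phantoms, cut patches, train a desk-scale model and extract
signatures:

```bash
flimstain phantom --out data --n-fields 4 --size 256 --seed 0
python -c "from flimstain.config import profile_config; \
profile_config('desk', flim_dir='data', he_dir='data', out_dir='out', \
pixel_size_he=0.455).to_yaml('desk.yaml')"
flimstain preprocess --config desk.yaml
flimstain train --config desk.yaml
flimstain signatures --config desk.yaml --field-id phantom-0 --out sigs
```

Or in Python:

```python
import flimstain as fs

sample = fs.generate_phantom(fs.PhantomSpec(image_size=(256, 256), seed=5))
per_type, per_cell = fs.summarise_cell_types(
    fs.clamp_flim(sample.flim), sample.annot)
for s in per_type:
    print(f"{s.cell_type:11s} peak {s.peak_lifetime:.3f} ns  "
          f"mean {s.mean_lifetime:.3f} ns  ({s.n_pixels} px)")
```

prints the seven cell types in increasing lifetime order, recovering the
generator's means to within a few hundredths of a nanosecond:

```
rbc         peak 0.275 ns  mean 0.253 ns  (1217 px)
fibroblast  peak 0.375 ns  mean 0.376 ns  (1614 px)
tumour      peak 0.425 ns  mean 0.424 ns  (5511 px)
lymphocyte  peak 0.475 ns  mean 0.471 ns  (1516 px)
neutrophil  peak 0.675 ns  mean 0.660 ns  (2150 px)
plasma      peak 0.675 ns  mean 0.692 ns  (2242 px)
macrophage  peak 2.425 ns  mean 2.419 ns  (3910 px)
```

Red blood cells are shortest-lived and macrophages longest — the ordering a
lifetime-based cell classifier relies on.

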