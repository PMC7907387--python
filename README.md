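# msikit

Headless preprocessing and spectral-similarity pseudocoloring for MALDI
mass spectrometry imaging (MSI) data.

MSI records one mass spectrum per pixel of a tissue section. Before such
data can be explored, the spectra must be normalized, freed of signals that
do not come from the tissue — the sprayed MALDI matrix (e.g. DHB) and
isolated hotspot artifacts — and usually reduced to picked peaks. `msikit`
implements that preprocessing chain and a rendering engine that colors
every pixel by the similarity of its spectrum to a chosen reference pixel,
so that regions of shared molecular composition light up together. It is a
library plus CLI for people who want these steps scriptable and
reproducible: batch processing, pipelines, and method validation on
synthetic data.

## What it computes

* **Data model & I/O** — a `w x h` pixel grid with an `n x d` intensity
  table over spectral pixels and a shared m/z axis; read/write of imzML
  (continuous and processed mode) and a documented HDF5 store; m/z
  cropping, mean spectra `mu = (1/|p+|) * sum p_{i,j}`, channel images.
* **Normalization** — per-spectrum (intra) and per-dataset (inter) scaling
  factors: mean or median of the nonzero intensities, or median fold
  change against a median reference spectrum (default).
* **Matrix/artifact cleaning** — pixel spectra are embedded into 2-D
  (truncated SVD when `d > 1000`, then UMAP), density-clustered, and
  labelled sample / matrix / artifact by spatial heuristics (or by a
  scripted polygon/coordinate selection); the matrix mean spectrum is then
  subtracted from every pixel, clamped at zero, with optional pixel
  removal and an artifact-first iterative mode.
* **Peak picking** — local maxima of the mean spectrum above a threshold
  `z_t`, with FWHM-style extents `[l, r]`, optional upper-limit
  winsorizing at the `z_w`-th highest value, valley truncation, per-pixel
  peak sums, and greedy deisotoping at 1.00335 Da spacing.
* **Similarity rendering** — spectra are reduced to 8-bit
  (`round(255 * s / max(s))`, at most 256 distinct values per spectrum)
  and each pixel is scored against a reference pixel by the inverse
  angular distance

      c' = round(255 * (1 - (2/pi) * arccos( p' . p'_ref / (|p'| |p'_ref|) )))

  then min-max normalized and mapped through a "fire" (or "gray") lookup
  table to a PNG, together with the 256-bin histogram of the similarity
  values. Browsing (single channel) and grouping (mean over a channel set)
  modes share the same plumbing.
* **Synthetic phantoms** — a generator for ground-truthed MSI images
  (sample regions, matrix background, artifact hotspots, isotope
  satellites, multiplicative and additive noise) used throughout the test
  suite. See `docs/methods.md` for the full model.

## Worked example

Run the whole pipeline on the built-in default phantom (64 x 64 pixels,
500 channels, dominant matrix signature, 40 artifact hotspots):

```
$ echo '{"seed": 0, "output_dir": "out"}' > config.json
$ msikit run config.json
{"stages": ["convert", "normalize", "clean", "pick", "render"]}
```

The manifest (`out/manifest.json`) records the resolved configuration and
SHA-256 hashes of every artifact. For this run:

* `n_pixels: 4056` — the 40 planted artifact hotspots were detected in the
  first embedding pass and removed (4096 - 40);
* `labels.csv` counts 1588 matrix and 2468 sample pixels, exactly the
  planted partition;
* `n_channels: 44` — after subtracting the matrix mean spectrum, picking
  at the default relative threshold `z_t = 0.019` reduces 500 channels to
  44 peaks. The head of `out/peaks.csv`:

```
mz_v,l,r,v,apex,height
102.0,10,12,11,11,0.98483
103.0,15,17,16,16,0.492535
104.0,20,22,21,21,0.246348
...
```

  The triplets at 1 Da spacing with halving heights (0.98 -> 0.49 -> 0.25)
  are a planted peak and its two isotope satellites; running the `pick`
  stage with `deisotope` enabled collapses each triplet to its
  monoisotopic member.
* `out/render.png` is the similarity map for the central reference pixel:
  pixels of the same phantom region as the reference render bright,
  the other region and the matrix border render dark.

Individual stages are available as subcommands (`convert`, `normalize`,
`clean`, `pick`, `render`, `synth`), e.g.

```
msikit synth phantom.h5 --seed 1
msikit pick phantom.h5 picked.h5 --zt 0.019 --zw 50 --deisotope --peaks-out peaks.csv
msikit render picked.h5 map --mode similarity --ref 32,32 --colormap fire
```

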