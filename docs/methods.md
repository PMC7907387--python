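# Methods

`msikit` is a headless toolkit for preparing MALDI mass spectrometry imaging
(MSI) data and rendering dynamic spectral-similarity pseudocolor maps. This
note documents the data model, each processing stage, the synthetic phantom
that the tests are built on, and the numerical and design choices that were
genuinely open.

## Data model

An MSI dataset `I` is a `w x h` pixel grid in which the *spectral pixels*
`p+` (the positions where the instrument actually acquired a spectrum) carry
`d` intensity values on a shared, strictly increasing m/z axis. Non-spectral
pixels are implicitly zero. Coordinates `(i, j)` and channel indices `k` are
1-based throughout the public API, matching the imzML convention; array
internals are 0-based and conversion happens exactly once at each API
boundary. Intensities are stored as float32 (the common imzML payload
precision); statistics are accumulated in float64.

Datasets round-trip through continuous-mode imzML (`.imzML`/`.ibd`) and
through an HDF5 store with the layout

    /<dataset_id>/mz            float64 (d,)
    /<dataset_id>/coords        int64   (n, 2)
    /<dataset_id>/intensities   float32 (n, d)
    attrs: width, height, schema_version

There is no community standard for MSI in HDF5, so this layout is our own
and versioned; several datasets may share one store, keyed by `dataset_id`.
Processed-mode imzML (per-pixel m/z lists) is read by forming the union of
all observed m/z values (optionally merging values closer than a tolerance,
default 0) and zero-filling absent channels.

## Preprocessing

**Common m/z axis.** When several datasets must share an axis, the pooled
channel positions are smoothed with a Gaussian kernel of user-chosen
bandwidth (Da) and the local maxima of the resulting density define the
common vector. This is a deliberate simplification of kernel-based
clustering aligners: it captures the same behaviour (nearby ion species
collapse onto one channel) with a single interpretable parameter. `align`
then adds each original channel's intensity to its nearest common channel
within a tolerance and drops channels farther away, so total ion current is
conserved whenever the tolerance covers every channel.

**Normalization.** Per-spectrum intensity variation is an inherent property
of MALDI data, so an intra-sample normalization (one positive factor per
spectrum) precedes everything else. Three estimators are provided:

* `mean` / `median` — statistic of the spectrum's *nonzero* intensities.
  MSI spectra are sparse; including zeros would let the zero count, not the
  signal level, set the factor.
* `mfc` (default) — median fold change: the median, over channels nonzero
  in both, of the ratio between the spectrum and the dataset's per-channel
  median spectrum. Restricting to channels nonzero in both sides is our
  choice; it keeps the fold-change well defined on sparse spectra.

All-zero spectra are left unchanged with a logged warning rather than
divided by an undefined factor. Inter-sample normalization applies the same
three estimators to each dataset's mean spectrum against the per-channel
median of all mean spectra, yielding one factor per dataset. With two
datasets where B = 3A the factors come out as 0.5 and 1.5 (the symmetric
reference sits between them); the normalized outputs coincide, which is the
property that matters for comparative work.

## Matrix and artifact removal

Spectral pixels fall into three categories: sample (tissue), matrix (ions
from the sprayed MALDI matrix, dominating off-tissue areas), and artifact
(isolated hotspot pixels resembling neither). Cleaning works on a 2-D
embedding of the pixel spectra:

1. **Embedding.** UMAP to 2-D, preceded by truncated SVD to 100 components
   (configurable) when `d > 1000` — the linear pre-step buys a large runtime
   saving at negligible cost to the embedding. A seed is mandatory and the
   embedding is deterministic for a fixed seed.
2. **Clustering.** DBSCAN on the embedding with a radius expressed as a
   fraction of the embedding span (default 0.05) and `min_samples = 5`. The
   span-relative radius makes the parameter independent of UMAP's arbitrary
   units and large enough to bridge the local tears UMAP introduces inside
   one homogeneous cloud (with a small absolute radius the cloud fragments
   into dozens of micro-clusters). Noise points are attached to the nearest
   cluster centroid.
3. **Labelling heuristics.** A cluster is *artifact* if its pixels are
   spatially scattered — mean nearest-neighbour distance in the pixel grid
   above `hotspot_dist` (default 3.5 px; contiguous tissue/matrix areas sit
   near 1, isolated hotspots are several pixels apart by definition) — or
   if it is tiny (below `min_matrix_frac` of the pixels). Among the
   remaining clusters, the one with the largest fraction of pixels on the
   image border frame (`border_px`, default 4) is *matrix*; everything else
   is *sample*. If fewer than two compact clusters exist, everything is
   labelled sample and a warning is logged — the heuristic refuses to guess.
4. **Subtraction / removal.** The mean spectrum of the matrix (or artifact)
   pixels is subtracted channel-wise from *every* spectrum, clamped at zero
   (we subtract from the matrix pixels themselves too; the text basis for
   the procedure says "all pixels" and the clamp makes this harmless).
   Labelled pixels can also be removed outright; the grid dimensions stay.
5. **Iteration.** Strong artifacts sit far away in the high-dimensional
   space and can compress the rest of the embedding. `iterative_clean`
   therefore removes artifacts after a first pass, re-embeds, and only then
   detects and subtracts matrix on the cleaner second embedding.

A polygon selection in embedding space (even-odd rule) or an explicit
coordinate list replaces the interactive lasso of GUI tools, so manual
classification stays scriptable and reproducible.

## Peak picking and deisotoping

Peaks are picked on the dataset **mean spectrum only**, never per pixel. A
peak is a strict local maximum whose apex height exceeds `z_t`; in a flat
apex run the leftmost channel is the apex (determinism). Thresholds are
conventionally quoted on the unit-max scaled mean spectrum
(`scale_to_unit_max`), which is what makes a fixed threshold meaningful
before and after matrix subtraction. The extent `[l, r]` is the contiguous
run of channels at or above 50% of the apex height. The wording "first
channel left and right of the maximum with an intensity of 50%" is
ambiguous (at-or-above vs first-below); we use the at-or-above run, the
common FWHM reading, and document rather than claim it. The representative
channel `v` is the integer median of `{l..r}`, lower-middle on even runs.
Extents of adjacent peaks that would overlap are truncated at the valley
minimum between the apexes (leftmost minimum on ties) so peak intervals
never overlap. Per-pixel peak intensity is the plain sum over `[l, r]`;
`reduce_to_peaks` collapses the channel axis to one such sum per peak.

Upper-limit winsorization caps the mean spectrum at its `z_w`-th highest
value, taming towering outlier peaks so that a threshold can be placed
sensibly.

Deisotoping is greedy by descending height (ascending m/z on ties, so the
monoisotopic member of an equal-height pair survives): each kept peak at
mass m suppresses any not-yet-kept peak within `tol` of `m + n * 1.00335`
Da for `n = 1..max_iso` (default 3). The spacing constant is the C13-C12
mass difference at charge 1, the MALDI norm; both are configurable.

## Similarity rendering

Rendering operates on the 8-bit byte representation: each spectrum is
scaled by 255 over its own maximum and rounded, so one spectrum carries at
most 256 distinct values. Per-spectrum max scaling cannot distort
Similarity mode because the angular metric is invariant to per-vector
scale. Rounding is half-away-from-zero everywhere, for deterministic,
language-independent byte values.

Three modes produce a raw field `c'` over the spectral pixels:

* **Similarity**: `c' = [255 * (1 - (2/pi) * arccos(cos(p', p'_ref)))]`,
  the inverse angular distance between each byte spectrum and a reference
  pixel's byte spectrum. It compares peak *profiles*, not magnitudes, and
  is symmetric in the two pixels. Zero-norm pixels (and non-spectral
  pixels) score 0 — maximally dissimilar, matching the black background —
  rather than leaving the angle undefined.
* **Browsing**: the byte value of one channel.
* **Grouping**: the rounded mean byte value over a channel set `M`. Taken
  literally, a formula that multiplies a mean of 0-255 byte values by 255
  would overflow the byte range; we read the byte values there as 255 times
  a unit-normalized intensity, the only reading under which a one-channel
  group reduces exactly to Browsing.

`c'` is min-max normalized to `c''` over the spectral pixels only (zeros of
non-spectral pixels would otherwise pin the minimum); a constant field maps
to zero. `c''` passes through a colour lookup table to RGB. The "fire"
scale is a documented stand-in — black, red, yellow, white control points
at 0, 96, 192, 255 with linear RGB interpolation — since the exact stops of
the original scale are not published; "gray" is bit-exact identity on the
value channel. Every render also produces the 256-bin histogram of `c''`
(the colour-legend histogram); its counts always sum to `|p+|`.

## The synthetic phantom

No public MSI datasets accompany the procedures above at desk scale, so all
quantitative validation runs on phantoms with known ground truth. The
default phantom is a fully spectral 64 x 64 grid with 500 channels at
0.2 Da spacing (m/z 100-199.8) containing:

* a **matrix signature** — 8 Gaussian peaks (sigma 1 channel) of height 50
  added to *every* pixel, emulating matrix sprayed over the whole slide;
  pixels outside the sample regions (including a guaranteed 4-px border
  frame) carry only this signature and are labelled matrix;
* **two rectangular sample regions** with 6 region-specific peaks each, of
  height 10 — deliberately an order of magnitude below the matrix, so the
  matrix dominates the mean spectrum exactly as a strong matrix does;
* **40 artifact hotspots** (~1% of pixels), pairwise at least 3 px apart,
  carrying an extra shared 5-peak signature boosted 5x over the matrix
  height;
* **isotope satellites**: every planted peak gets 2 satellites at 1.00335
  Da spacing with height ratio 0.5 per step, to exercise deisotoping;
* **log-normal per-spectrum scaling** (sigma 0.25), the multiplicative
  variability that intra-sample normalization removes;
* **additive Gaussian noise** (sigma 0.05), clipped at zero.

Randomness is split into a geometry stream (planted channels, artifact
positions; `geometry_seed`) and a noise stream (`seed`), so varying the
seed resamples noise under an identical ground-truth layout. Planted peak
channels are placed on a jittered lattice that guarantees full separation
of every peak-plus-satellite footprint.

What the phantom does **not** emulate: mass-accuracy drift, detector
saturation, correlated (structured) noise, smooth within-tissue biological
gradients, partial-volume mixtures at region boundaries, and realistic
isotope envelopes. Passing tests therefore demonstrate that the algorithms
recover the structure they are designed for under controlled conditions,
not that they are robust to every pathology of real acquisitions — the
within-region homogeneity in particular makes the clustering task cleaner
than on real tissue.

## Validation design

* Exact-arithmetic checks: the 8-bit transform maps a 512-channel strictly
  increasing spectrum to exactly 256 distinct values; the similarity of any
  nonzero spectrum with itself is exactly 255.
* Peak picking is verified against an independent brute-force scan that
  re-derives local maxima, half-height extents and valley truncation
  channel by channel (200 random spectra across 10 seeds, plus a
  derandomized property test; zero discrepancies tolerated).
* On the default phantom (seed 0), automatic classification after mfc
  normalization must reach matrix F1 >= 0.95 and artifact recall >= 0.9,
  and the artifact-first iterative pass must not lower the matrix F1.
  Normalization precedes embedding because the log-normal per-spectrum
  scale otherwise dominates Euclidean distances — pipeline order, not
  tuning.
* Matrix subtraction must strictly reduce the fraction of normalized
  similarity values in the middle half-range [64, 191] for three fixed
  reference pixels (the histogram-contrast effect), with artifact pixels
  removed beforehand as the cleaning pipeline does; kept artifacts pin the
  min-max normalization and empty the mid-range on both sides.
* The similarity field computed from bytes must correlate with the field
  computed from the float32 originals at Pearson r >= 0.99.

Problem sizes in the suite (64 x 64 x 500 for the study phantom, 32 x 32 x
160 for unit fixtures, spectra of 150 channels for the picker oracle) were
chosen as the smallest sizes at which each effect under test is cleanly
expressed.

## Known limitations

* The automatic classifier is a pair of declared heuristics (spatial
  scatter, border contact), not a reconstruction of any particular GUI
  tool's unpublished rules; on tissue with matrix-free interior holes or
  tissue touching the image border, manual polygon selection is the
  intended fallback.
* The common-axis builder assumes peak positions cluster tighter than the
  kernel bandwidth; it does not model mass drift along the acquisition.
* Mean-spectrum subtraction can in principle remove genuine tissue signal
  that co-occurs on matrix channels, and nothing in the procedure can rule
  that out; the original unprocessed dataset should always be retained.
* UMAP embeds duplicate spectra near, but not at, the same point (its
  repulsion term keeps all points apart), so closeness guarantees are
  neighbourhood-level, not exact.
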