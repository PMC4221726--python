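# Methods

## Image model and normalization

All filters operate on single-channel 2D intensity rasters in [0, 1].
Integer images are rescaled by their dtype range (8-bit by 255, 16-bit by
65535); float images supplied to the library are used as-is so that the
filters' contrast behavior (below) is exact, while float files loaded from
disk are min–max scaled at read time. Gradients are central differences of
a Gaussian-smoothed image (default smoothing sigma 1.0 px) with
edge-replicated borders; smoothing keeps the per-pixel gradient direction
stable against pixel noise without displacing the membrane edges at the
scales involved (cell radii ≥ 10 px, membrane ~3 px).

## Filter geometry

The sliding-band filters sample each of `n_lines` rays (angles 2πi/N) at
integer radii, each sample rounded to the nearest pixel; no interpolation
is used, so a single precomputed offset table is shared by the per-pixel
evaluators, the full-image vectorized filter, and the brute-force test
oracle, and all three agree to machine precision. The band of width `Bw`
centered at radius `r` covers radii `r − ⌊Bw/2⌋ … r + ⌈Bw/2⌉ − 1`
(exactly `Bw` samples); `r` ranges over `[r_min, r_max]`.

Conventions for degenerate cases:

- a zero-magnitude gradient contributes cosine 0 (TSBF is unaffected — its
  magnitude factor is already 0);
- samples outside the image, or at radius < 1, are dropped and the band
  mean renormalized over the remaining samples (clipped-band convention);
- a band with no valid sample is skipped; a ray with no valid band
  contributes 0 to the outer mean;
- plateau ties in non-maximum suppression keep the lexicographically
  smallest (row, col) and suppress the rest, making detection output
  deterministic and guaranteeing a minimum Chebyshev separation of
  `window_half_width + 1` between centers.

Pixels closer than `r_max + ⌈Bw/2⌉` to an image edge are computed on the
clipped support and flagged; detections there carry a border flag rather
than being dropped, since chamber-edge counting conventions are a protocol
question, not a filter question.

Default parameters are the study settings for ~10–22 px cell radii:
`r_min = 8`, `r_max = 30`, `n_lines = 32`, `band_width = 6` (the width of
the blurred cell edge), `omega = 1`. `omega` is a single global scalar;
no spatially varying weight is implemented. The NMS window side defaults
to `2·r_min + 1 = 17` (two maxima closer than one minimum cell radius
cannot be distinct cells) and the response threshold to mean + 2·std of
the response map, which sits far above the TSBF noise floor but below
every cell-center response in the benchmark conditions; both are exposed
as parameters/flags.

## Synthetic scenes

The generator emulates what the detector actually faces in a counting
chamber under bright field: a mid-gray background (0.6), cells as dark
membrane annuli (thickness 3 px, contrast 0.3 below background) whose
interior is nearly at background (+0.02), optical blur (Gaussian, sigma
1.5 px), additive Gaussian noise (sigma 0.02), and optionally a linear
multiplicative illumination ramp. Dark-field scenes use bright Gaussian
blobs (sigma = radius/2) on a dark background — the classical rounded
convex region. Placement is rejection sampling with pairwise separation
`r_i + r_j + 4` px (non-overlap; a scalar minimum separation can be given
instead). Everything is driven by one integer seed and is bit-reproducible.

The default benchmark is 15 scenes of 256×256 px with 10–20 cells each
(drawn per scene) and radii uniform in 10–22 px; this size keeps a full
benchmark run under a minute on one CPU while leaving every cell several
band-widths from its neighbors. What these scenes deliberately do *not*
contain: intensity variation along a membrane, clumped/overlapping cells,
debris and corrupted-cell texture, shot noise, chamber grid lines. Passing
the benchmark therefore demonstrates the geometry and noise behavior of
the filters, not robustness to clumping or debris — the real-culture
failure modes (clumps counted as one by eye but several by the detector,
corrupted cells in decline phase) are out of the model.

## Counting protocol

Chamber density: mean count per 1 mm² square at 0.1 mm depth × dilution ×
10⁴ = cells/mL. ERT is |method − truth| / truth at one density; TERT is
the unweighted mean of ERT over the sampled densities (here: over
benchmark images / growth timepoints). Growth curves average replicate
samples within a timepoint and are sorted by time. Center matching (for
diagnostics beyond counts) is greedy nearest-first one-to-one within a
pixel tolerance.

## Numerical behavior and known limitations

- **Flat-top response.** The TSBF response is nearly constant over a
  plateau around each true center: a point a few pixels off-center still
  sees the membrane within every ray's sliding range, and the integer-
  radius sampling interacts with the membrane's two blurred edge-gradient
  peaks (which can fall between integer radii at some cell radii). The
  in-disc argmax therefore wanders up to ~5 px from the planted center on
  noisy benchmark scenes (mean ≈ 1.6 px) even though counts are exact or
  near-exact; localization, not detection, is the soft spot. Sub-pixel
  localization is intentionally not attempted.
- **SBF on ideal rings.** On the uniform-contrast synthetic annulus the
  plain SBF localizes ring centers essentially perfectly, because the
  blurred inner membrane edge is a clean convergence zone reachable from
  the center (band samples extend down to radius `r_min − ⌊Bw/2⌋`). The
  membrane-only SBF behavior seen on real bright-field cells requires
  intensity variation along the membrane, which this renderer does not
  model; the TSBF's practical advantages here are its near-zero noise
  floor and linear contrast response.
- **Contrast behavior.** TSBF is equivariant (TSBF(aI + b) = a·TSBF(I) for
  a > 0); CI/SBF are invariant. This is exact, and property-tested.
- **Baselines.** The Laplacian-of-Gaussian baseline uses one scale
  (default matched to the mid-range cell radius, sigma = r/√2) and the
  same NMS; the intensity-threshold baseline binarizes dark objects
  (e.g. at an Otsu threshold) and returns connected-component centroids.
  Both under-perform the TSBF on the benchmark — LoG because a single
  scale cannot serve radii 10–22 px and the ring (not a filled blob) only
  weakly matches its kernel, thresholding because noise and illumination
  fragment or merge the membrane components.
- **Feasibility of placement.** A scalar minimum separation of
  `2·r_max + 4` px cannot pack 20 cells into a 256×256 frame (random
  sequential placement jams first); the per-pair non-overlap rule is the
  default for this reason.
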