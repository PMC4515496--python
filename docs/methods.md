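# Methods

## Problem and model

On a right-subcostal B-mode scan the liver parenchyma (LP) and the renal
cortex (RP) are nearly isoechoic in a healthy subject; fat infiltration
raises liver echogenicity while the kidney stays stable, so the difference
of representative brightness, HRI-diff = I_LP − I_RP, is a monotone marker
of steatosis severity. The pipeline automates the two operator-dependent
steps: finding comparable LP/RP regions on the same frame, and reducing
each region's speckled intensity distribution to a single representative
value.

## Fuzzy stretching

The stretch bounds are derived from image statistics rather than fixed
percentiles. With mean x_m, extremes x_l/x_h and distances
d_min = x_m − x_l, d_max = x_h − x_m, the adjustment distance is

```
ad = 255 − x_m   if x_m > 128
   = d_min       else if x_m ≤ d_min
   = d_max       else if x_m ≤ d_max
   = x_m         otherwise
```

giving a triangular membership supported on [x_m − ad, x_m + ad] with peak
at the midpoint. Numerical choices:

- **Clamping.** The cascade can push I_max above 255 or I_min below 0
  (e.g. x_m = 100, ad = 120); both are clamped to [0, 255] *before* the
  peak is computed, since 8-bit intensities outside that range are
  meaningless and the α-cut ratio I_min/I_max presupposes I_min ≥ 0.
- **α-cut comparison** is inclusive (membership exactly equal to the cut
  qualifies).
- **Degenerate triangle** (peak coincides with a support endpoint): the
  affected flank is 0 except μ(I_mid) = 1, avoiding a 0/0.
- **Empty qualifying set**: no intensity present in the image reaches the
  α-cut (common on piecewise-constant inputs); stretching degrades to plain
  min–max normalization (γ = x_l, β = x_h), logged.
- **γ = β**: no contrast to stretch; the image passes through unchanged.
- x_m is kept at full float precision; rounding happens only at the final
  8-bit output.
- γ/β are scanned over the 256-bin histogram of values present — identical
  to a per-pixel scan, cheaper.

## Binarization and object labeling

Binarization thresholds at the mean of strictly positive pixels (the
stretch maps the dark far field to 0, which must not drag the threshold
down); equality passes. Connected bright objects use 8-connectivity. The
boundary tracer starts at each region's top-most, left-most pixel and
rotates its probe clockwise in 45° steps from the backtrack direction; on a
convex stretch that consults at most a five-heading, 180° fan around the
current heading. The circuit closes when the tracer is back at its start
about to repeat its first move; a trace that exceeds
max(4·(H+W), 8·area+8) steps without closing is discarded as divergent
(defensive only — a valid 8-connected component always closes; the bound is
proportional to area because boundary pixels of ragged components are
legitimately visited several times). Region pixel membership is computed by
an 8-connected fill, which is the verifiable contract (tests compare the
partition against an independent connected-components oracle).

Objects with area outside [200, 20000] px cannot be fascia, membrane or
kidney fat at scan resolution and are removed (strict outside, inclusive at
the bounds).

## Landmark identification and membrane restoration

The original software's discrimination rules are not published, so the
landmark heuristics are explicit and configurable: **fascia** = top-most
retained region spanning ≥ 40% of the image width; **kidney fat** =
bottom-most retained region with centroid in the right half; **membrane** =
wide region(s) strictly between them (falling back to any in-between region
when no wide one survives).

The limiting membrane is the faintest landmark and can fragment below the
area floor. If a membrane candidate already exists the restoration stage is
a no-op (idempotent). Otherwise the corridor between fascia and kidney fat
is re-binarized at its own positive-pixel mean, the result is bridged with
the retained bright mask by morphological closing (disk, radius 5 px,
configurable), merged back *within the corridor only*, relabeled and
re-filtered. A corridor with no recoverable membrane raises an extraction
failure naming the landmark.

ROI logic: liver = per-column band strictly between the fascia's lower
envelope and the membrane's upper envelope; kidney = the field enclosed by
the perirenal-fat annulus (fill-holes minus the annulus) below the
membrane's lower envelope; both are intersected with the complement of all
retained bright objects, so the masks never touch a bright structure.

## SOM cluster analysis

Input feature: scalar pixel intensity normalized by 255 — the only feature
the quantification uses. Defaults: 4×4 grid; α₀ = 0.9 decaying ×0.9 per
stage; initial radius 2 (Chebyshev, square neighbourhood) shrinking by 1
per stage; 5 passes per stage; stop when α < 0.2 or r ≤ 0. Weights
initialize as seeded uniform draws over the sample range and every update
is a convex combination, so trained weights never leave the input range.
Ties in the winner search break to the first node in row-major order.

Training uses a seeded subsample of at most 4096 ROI pixels (a 1-D
intensity distribution is fully characterized at that sample size), then
all ROI pixels are assigned to winner nodes vectorized. Node weights are
mapped back to 0–255 and quantized into bins of width 8; nodes sharing a
bin merge into one cluster, absorbing speckle-induced node splitting. The
representative intensity is the mean of the largest cluster (ties: lower
bin). Cluster counts report all nonempty clusters.

Quantification deliberately samples the **original** image inside the ROIs:
the stretch rescales brightness per image, so stretched representatives
would not be comparable across scans, while the severity bands live on the
raw intensity scale.

The liver map trains with the configured seed and the kidney map with
seed+1, keeping the two analyses independent but the whole run
deterministic for one seed.

## Severity bands

The method quantifies; it does not learn cutoffs. Default bands are the
midpoints between the reference class means of HRI-diff
(1.791, 8.435, 22.025): normal < 5.113 ≤ mild < 15.230 ≤ moderate. A
negative HRI-diff grades normal with a logged note. Bands are configuration
and reported as such in every run's metadata. No "severe" band ships: no
reference values exist for it, and an explicit cutoff would be invented.

## Phantom generator

The generator emulates only what the extractor relies on: a bright fascia
band near the top (rows 6–12% of height, full width), a liver field below
it, a bright parabolic limiting-membrane band (~2% of height thick, bowing
downward, centred at 50–60% of height), kidney-level tissue below, and a
bright perirenal-fat ellipse annulus (centre 80% height / 64% width)
enclosing the renal-cortex field. Background is 10, so positive-pixel
binarization is exercised. Speckle is multiplicative Gaussian,
value = mean·(1 + cv·N(0,1)), clipped and rounded; the default cv is 0.1.

What it does **not** emulate: Rayleigh speckle statistics, attenuation with
depth, acoustic shadowing, refraction, probe-dependent geometry, vessels
and ligaments inside the parenchyma. Passing tests therefore demonstrate
that the algorithm chain is implemented correctly and recovers known
contrasts under speckle — not that the landmark heuristics are robust to
the full variability of clinical scans.

Default phantom size is 512×384: it keeps every structure within the
[200, 20000] px object-size window at the same proportions as a full
1024×768 scan while keeping the test suite and the acceptance script fast.

## Known limitations

- Single-image HRI-diff moves in steps of the 8-level quantization bin
  (±5 intensity units of per-image dispersion at 10% speckle); class-level
  statements should average over several frames, as the cohort tooling
  does.
- The landmark heuristics assume the right-subcostal layout (fascia above
  liver above membrane above kidney); other views fail fast with a named
  extraction error rather than producing a silent misreading.
- On phantoms whose parenchyma is unimodal, nonempty cluster counts
  (typically 2–4) are lower than on clinical tissue, whose texture spreads
  the map over more bins.
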