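# Methods

## Scope and data model

The package quantifies meibomian-gland (MG) morphology from three
co-registered rasters: an 8/16-bit grayscale meibography image, an
integer gland label map (0 = background, k ≥ 1 = gland), and a binary
tarsus mask. Segmentation itself is out of scope — the label and tarsus
masks are inputs, produced upstream by whatever segmentation method the
user trusts. All arrays are row-major and 0-based; row 0 is the top of the
image, and "vertical" means along rows. No geometric transforms are
applied anywhere: masks must already be co-registered with the image.

Label maps are canonicalized on entry: labels are renumbered 1..K in
raster-scan order of each component's topmost-leftmost pixel (deterministic
across platforms), and every label must be a single 8-connected component.
8-connectivity is fixed, not configurable: thin tilted glands fragment
under 4-connectivity. Gland pixels outside the tarsus are a hard error —
the density definition presumes glands ⊆ tarsus, and silent clipping would
make density quietly wrong.

## Morphology indices

Let a gland be the pixel set G with |G| = A (area).

- **Height.** `h = max(row) − min(row) + 1`. The inclusive extent is used
  so a single-pixel gland has height 1 and `width × height = area` holds
  exactly for rectangles; the exclusive variant `max − min` is available
  via `inclusive=False` for sensitivity checks.
- **Width.** `w = A / h`, an average width along the gland.
- **Perimeter.** The count of gland pixels with at least one 4-neighbor
  outside the gland; the image border counts as outside, and a pixel of a
  different gland also counts as outside. This is a boundary-*pixel* count
  (the natural reading of "a pixel at the edge"), not a contour length —
  Crofton-style estimators are deliberately not used.
- **Minimum external rectangle.** The minimum-area rotated rectangle
  enclosing the *pixel centers* (the pixel at (r, c) is the point (r, c)).
  Rotating calipers over the scipy convex hull: the optimum has a side
  collinear with a hull edge, so each edge direction is tested; ties in
  area are broken by the smallest long-axis angle (determinism). An
  axis-aligned run of h pixels therefore has rectangle side h − 1; this
  center convention is what makes the rectangle closed forms exact, and the
  ±1 px center-vs-extent offset is absorbed by documented test tolerances.
  Degenerate cases: a single pixel yields height 1; collinear pixel sets
  yield the hull-segment extent. The rectangle's *longer* side is taken as
  its "height": glands are elongated, and the rectangle measures length
  along the gland axis (which side the original system used is not
  determinable; the long side is the geometrically meaningful choice).
- **Tortuosity.** `τ = P / (2 H_rect) − 1`. For a filled h×w rectangle
  this gives the closed form `(2h + 2w − 4) / (2(h − 1)) − 1`, used as an
  analytic fixture in the tests.
- **Density.** Summed gland area over tarsus area.
- **Aggregation.** Eyelid-level means are unweighted over glands; glands
  touching the image border are included. The "both eyelids" value of each
  index is the unweighted mean of the two eyelid-level values (the
  gland-count-weighted/pixel-pooled alternative is available via
  `combine_eyelids(..., pooled=True)`).

A digitization caveat on tortuosity: for a thin stripe nearly every pixel
is a boundary pixel, so lateral meandering with a slope below one pixel
per row does not change the perimeter count at all. Tortuosity is
therefore flat in the sinusoid amplitude at small slopes and strictly
increasing once displacement between consecutive rows exceeds a pixel —
the tests assert exactly this (non-decreasing, then strictly increasing)
rather than strict monotonicity from zero.

## Vagueness

`V = mean gray(glands) − mean gray(tarsus ∖ glands)`, computed on the raw
grayscale input (no preprocessing). Pixels outside the tarsus never enter
either mean. V is signed and unclamped — glands darker than background give
negative values. It is invariant under adding a constant to the image and
scales linearly with intensity rescaling; these identities are tested to
1e-9. The heat-map rendering maps a subjects × cells value grid through a
fixed colormap (`magma`) and a fixed value range (default 0–60, the
typical 8-bit vagueness scale), so figures are reproducible; the rendering
is purely presentational.

## Synthetic generator

A gland is a sinusoid-displaced vertical stripe: rows `top ≤ r < top + L`,
columns `|c − (center + A sin(2π P (r − top)/L))| ≤ w/2`. This is the
simplest family spanning the morphologies of interest — straight (A = 0),
twisted (A > 0), and fragmented (an optional split of a stripe into two
vertically separated pieces, each then its own labeled gland). The tarsus
is the canvas inset by a margin — real tarsal curvature is presentational
and irrelevant to pixel-ratio indices. Intensities are flat
foreground/background levels plus clipped additive Gaussian noise; blur
and speckle are out of scope (a washed-out image is represented simply by
a smaller foreground/background contrast).

Rendered glands occupy exactly L rows by construction, and ground truth
records per-gland extents, areas and the exact pixel-count density, so the
pipeline can be validated against identities rather than against another
estimator. Placement assigns each gland a column slot; the sinusoid
amplitude is clamped to the slot (≥ 2 px inter-gland gap) and to the
connectivity slope bound (per-row lateral step ≤ 0.9 × stripe width); amplitude
yields, width never does — width carries the group effect). A
configuration whose widths cannot fit their slots is an error.

Cohorts are paired: per subject, a control eye is drawn from the eyelid
parameter distributions and the research eye reuses those draws times
multiplicative group effect factors (length, width, amplitude, count)
times one lognormal jitter per parameter family per subject
(sd 0.06 on the log scale — a mild within-pair asymmetry, the paired
analogue of measurement/biological noise). With all factors at 1 the two
eyes are identically distributed, giving a valid null. All randomness
derives from one root seed through named substreams (parameters, jitter,
noise, metadata), so a seed reproduces a cohort byte for byte.

Full-scale defaults (chosen once to emulate a realistic meibography
cohort): 26 subjects; 300×640 canvas with a 10 px tarsus margin; upper-lid
gland length 150 ± 20 px, lower-lid 90 ± 15 px; stripe half-width ≈ 11–12
± 1.5 px (total ≈ 23 px); foreground/background 140/112 (contrast 28 gray
levels, vagueness scale ≈ 28); noise sd 8; gland count 10–14 per lid
(density ≈ 0.15–0.25); follow-up intervals uniform over the four bins
(0,3], (3,6], (6,12], (12,24] months; TBUT and TMH drawn per eye from
typical paired dry-eye-cohort distributions, independent of morphology (so
clinical correlations are null by construction). Because amplitude is
slot-clamped, default tortuosity sits near 0.15–0.3 — the generator
reproduces the *relative* behavior of the index, not any particular
clinical value.

## Statistics

- **Normality.** One-sample KS statistic against a normal with the
  sample's own mean and SD. Estimated parameters make the textbook KS
  p-value anticonservative, so the default p-value is Lilliefors-corrected
  by Monte Carlo: 10,000 simulated standardized-normal samples per sample
  size (fixed internal seed — the null table is part of the method, cached
  per n), `p = (1 + #{D* ≥ D}) / (10001)`. The naive KS p is available via
  `method="ks"`. Agreement with an established Lilliefors implementation is
  cross-checked in the tests.
- **Paired comparison.** Differences research − control; normal-looking
  differences (p ≥ 0.05) go to the paired t-test and are summarized as
  mean ± SD, otherwise Wilcoxon signed-rank and median (IQR). Zero
  differences are dropped (signed-rank convention); an all-zero difference
  vector short-circuits to p = 1 with a degeneracy flag; constant non-zero
  differences are non-testable for normality and route to Wilcoxon. The
  exact signed-rank null is used up to 25 nonzero differences, the normal
  approximation with continuity correction above. Fewer than 3 complete
  pairs is an error, not a silent NaN.
- **Stratification.** Follow-up bins (0,3], (3,6], (6,12], (12,∞) months
  (left-open/right-closed); bins with < 3 pairs are reported descriptively
  without a p-value. Each record is treated as one subject-visit.
- **Correlations.** Spearman by default — several parameters summarize as
  median (IQR), i.e. non-normal — with pairwise deletion; Pearson behind a
  flag. No multiple-testing correction is applied by default, matching the
  single-comparison-per-cell reporting style this mirrors.
- **Missing data.** Pairwise deletion per parameter; n is reported per row.

## Validation studies and problem sizes

`calibration.py` holds the independent routes: a python-loop brute-force
perimeter, an exhaustive 0.5°-grid enclosing-box search, a full 2^n
sign-assignment enumeration of the signed-rank null, and the rectangle
closed forms. The replicate studies (type-I error under null effects;
sign-recovery and power under length ×0.85 / width ×0.94, i.e. height
×0.85 and density ×0.80) run 100–200 seeded replicates of a 26-subject
cohort on a scaled-down generator config (150×260 canvas, 7–9 glands per
lid, lengths 60/42 px) — the package's chosen replicate-study size; the
statistical structure is identical to the full-scale defaults, only the
rasters are smaller.

What passing these studies shows — and does not. The generator's flat
intensities, rectangular tarsus and exactly known masks isolate the index
definitions and the statistical machinery; they do not exercise
segmentation error, illumination gradients, blur, or gland morphologies
outside the sinusoid-stripe family. Results on real meibography inherit
whatever bias the upstream segmentation carries.

## Known limitations

- Tortuosity is a global outline statistic (perimeter vs rectangle); it is
  not a centerline arc-length tortuosity and saturates for thin glands
  (see the digitization caveat above).
- The two sides of the minimum rectangle coincide for nearly square
  glands; the "longer side" convention then approaches a coin flip between
  two similar values — immaterial for elongated glands, noisy for blobs.
- The Monte-Carlo Lilliefors table is resolution-limited at p ≈ 1e-4
  (10,000 draws); p-values below that are reported at the table floor.
- `combine_eyelids` assumes both eyelids measured on the same scale; no
  per-eyelid size normalization is attempted.
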