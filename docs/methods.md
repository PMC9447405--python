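# Methods

## Pipeline model and assumptions

`spotquant` models a scanned spotted array as a rows × columns lattice in
which every rectangular grid cell contains at most one fluorescent spot.
The grid is *declared by the user*, not detected: the image is assumed to
be axis-aligned and evenly spotted, so an equal integer partition of the
usable region (margins excluded) localizes the spots. Cell heights/widths
are `floor(extent / n)` with the remainder pixels pushed one each to the
trailing rows/columns — a deterministic rule with exact pixel
conservation (every pixel of the usable region belongs to exactly one
cell). There is no rotation or keystone correction; scans that need
registration must be corrected upstream.

Colour scans are collapsed to luminance as `0.3 R + 0.59 G + 0.11 B`,
computed in floating point and rounded half-up, before analysis. 16-bit
scans are processed natively by default; `rescale_to_8bit` (min–max to
[0, 255]) is provided for users who want to mirror 8-bit-only analysis.

## Thresholding

All threshold selectors operate on a 256-bin histogram (8-bit: one value
per bin; 16-bit: equal-width bins of 256 native levels) and share one
convention set:

* a threshold `t` labels pixels `> t` foreground, `≤ t` background;
* among equally good thresholds the smallest is returned;
* a single-occupied-bin histogram has no two-class split and returns a
  degenerate signal (`None`) rather than a number.

Otsu's selector maximizes the between-class variance
`σ²_B(t) = ω₀ ω₁ (μ₀ − μ₁)²` by exhaustive evaluation over the 255
candidate splits (vectorized over cumulative sums, so cost is O(bins)).
The comparators — histogram mean, isodata (Ridler–Calvard fixed point),
triangle (largest perpendicular distance to the tail–peak line, histogram
mirrored so the long tail lies left of the peak), li (minimum
cross-entropy fixed point, class means clamped at 0.5 grey levels so the
logarithm stays defined), and yen (maximum correlation criterion) — span
the clustering, statistical and entropy families of classic automatic
thresholding. They exist for method comparison; Otsu is the default
production path. The test suite cross-checks all six against
scikit-image's implementations (agreement within 2 grey levels on random
Gaussian-mixture histograms) and Otsu additionally against an
independent brute-force argmax.

### Local vs global application

`binarize_global` computes one threshold from the whole-image histogram.
On images with a non-uniform background this erases faint spots: any
spot whose peak lies below the global threshold has no foreground at
all. `binarize_local` computes the threshold independently inside each
grid cell, so only the *local* background competes with the spot. The
package treats local mode as the production path and keeps global mode
for the contrast experiment.

### Empty-cell rules

A cell is declared empty (all-background mask, `empty` flag) when any of
the following hold:

* the cell histogram is degenerate (constant cell);
* the Otsu foreground covers fewer than `min_area` = 4 pixels — a real
  spot at the default geometry (radius 8–12 px) covers > 200 px;
* the foreground/background mean contrast is below `min_contrast` = 8
  grey levels (8-bit scale; scaled ×256 for native 16-bit input).

The contrast rule is the load-bearing one for negative controls: Otsu
always finds *some* split, and on a noise-only cell that split keeps a
large foreground (far above any sensible `min_area`) whose class-mean
separation is ≈ 1.6 σ for Gaussian noise of scale σ. Eight grey levels
therefore rejects noise-only cells up to σ ≈ 5 while keeping genuine
spots of amplitude ≳ 10. Both parameters are overridable per call and
via the CLI.

## Quantification

Per non-empty cell:

* `bg_estimate` — median of the cell's background-labelled pixels
  (median rather than mean: robust to the spot's blurred skirt and to
  background outliers). If a mask is all-foreground the minimum cell
  intensity is used and a warning logged.
* `fg_mean` — mean of foreground pixels; `net_intensity = max(0,
  fg_mean − bg_estimate)` is the headline statistic. Mean-minus-median
  is insensitive to spot size variation; the integrated alternative
  `fg_sum = max(0, Σ foreground − bg·area)` is reported alongside for
  users who prefer integrated intensity.
* QC flags: `empty` (no foreground — always paired with all-zero
  statistics), `saturated` (≥ 1% of foreground pixels at the bit-depth
  maximum), `edge_clipped` (foreground touches the cell border).

Because the background is estimated locally and subtracted, net
intensities are invariant to a constant illumination offset (verified to
within 1 grey level of rounding in the tests) and, on dilution series,
monotone in the true amplitude.

## Validation statistics

* **Spearman's rank correlation.** On tie-free data the exact
  rank-difference formula `r = 1 − 6Σd²/(N(N²−1))` is used; with ties
  (zeros from empty spots tie routinely) the statistic is the Pearson
  correlation of average-rank vectors, which coincides with the formula
  in the tie-free case. Two-sided significance comes from the
  t-approximation `t = r√((N−2)/(1−r²))` on N − 2 df; `|r| = 1` maps to
  p = 0 by convention, and an exact permutation p-value is available for
  N ≤ 10. Under the null the t-approximation rejects at 5.0% ± 1% at
  N = 20 (checked over 10,000 replicates in the acceptance suite).
* **Regression.** Ordinary least squares via `scipy.stats.linregress`;
  R² = 1 − SS_res/SS_tot.
* **Two-group comparison.** Mann–Whitney U by default (exact enumerated
  null for small tie-free samples, normal approximation with tie
  correction otherwise, as dispatched by scipy), Welch's t as an option.
  The choice of default is this package's, documented rather than
  presumed to match any particular external software.

## Synthetic scan generator

The generator emulates what matters to the pipeline about a scanned
array: per-cell spots of known amplitude with slightly jittered centres
and radii (default cell 40 px, radius 8–12 px — stated constants, not
measured facts), three shape families (disc; random-axis ellipse;
star-convex "irregular blob" with a low-order harmonic boundary,
exercising arbitrary spot shapes), a Gaussian point-spread blur
(σ = 1 px, blurred mask renormalized to unit peak so a noiseless disc
centre equals background + amplitude exactly), a background field
(uniform / left-to-right linear gradient / centred quadratic bowl), and
additive Gaussian noise. All randomness flows from one integer seed;
a fixed seed reproduces the image bit-identically.

It does **not** emulate optical vignetting, scanner noise spectra,
print-needle artifacts, comet tails, dust, or grid misalignment — so
passing the synthetic validation shows the algorithmic chain is correct
and self-consistent, not that real scans of any particular instrument
will reach the same correlation.

Three canned condition sets:

* **Antigen panel** — the 31-condition layout: six analytes (CENP-B,
  Cytokeratin-6, GPC, P2, Proteoglycan and the IgG positive control),
  each a five-step two-fold dilution series, plus a PBS negative control
  (amplitude 0), on a 7 × 5 grid. Amplitudes are proportional to
  concentration *within* each analyte, scaled so each series' top
  concentration maps to 200 grey levels and capped at 90% of the
  bit-depth maximum. The per-analyte gain is the physically sensible
  model (analytes differ in antibody titer and labelling efficiency) and
  keeps every dilution step above the detection floor.
* **Gradient demo** — 7 × 10 = 70 spots with amplitudes evenly spanning
  15–220 grey levels shuffled over the grid, on a linear background
  gradient of 40 grey levels (base 10), noise σ = 3. Nine amplitudes lie
  below the gradient amplitude; this is the constructed failure mode for
  global thresholding and the standard validation image.
* **CD14-style antibody panel** — nine conditions × five replicate
  spots: five dilution standards (200 → 12.5 grey levels, two-fold),
  two high "LN-like" samples (160, 140) and two low "HC-like" samples
  (45, 35), 4% replicate-to-replicate amplitude jitter, uniform
  background 25, noise σ = 2. Geometry (five replicates, standards plus
  two high and two low samples) mirrors a sandwich-assay panel; the
  levels themselves are this package's defaults, chosen once.

## Numerical choices

* All intensity quantisation uses round-half-up; images are clipped to
  the bit-depth range after noise addition.
* The Otsu argmax takes the first (smallest) maximizer; float ties on
  analytically flat plateaus resolve identically because the flat
  region's statistics are computed from identical quantities.
* Degenerate inputs: constant images/cells → all-background with a
  `degenerate`/`empty` flag; all-foreground masks → minimum-intensity
  background fallback with a logged warning; `r = ±1` → p = 0;
  constant vectors are rejected for regression and rank correlation.
* Problem sizes: validation arrays are 280 × 400 px (70 spots) and
  360 × 200 px (45 spots); the type-I calibration uses 10,000 replicates
  at N = 20; the Otsu oracle sweep uses 200 random mixture histograms.
  These sizes make the full suite run in seconds while leaving the
  statistics well-resolved.

## Known limitations

* No automatic grid registration: misaligned or rotated scans must be
  corrected before analysis.
* The empty-cell contrast rule assumes approximately Gaussian cell
  noise; heavy-tailed speckle could defeat it.
* Net intensity is mean-based; spots with strong within-spot intensity
  structure are summarized, not modelled.
* 16-bit histograms use 256 equal-width bins, so thresholds on 16-bit
  data are quantized to 256-level steps.
* The comparator thresholds reproduce the classic algorithms, not any
  specific external tool bit-for-bit (agreement with scikit-image is
  within 2 grey levels, not exact, because binning and tie conventions
  differ).
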