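# spotquant

Quantification of fluorescent protein-microarray images: grid-based spot
localization, per-cell Otsu binarization, local background subtraction, and
the validation statistics used to compare quantification routes.

Protein and antigen microarrays report the abundance of tens to hundreds of
analytes as the fluorescence of printed spots. Turning a scanned slide into
per-spot numbers is complicated by two things: spots vary in shape and
brightness, and the background is rarely uniform — a single whole-image
threshold erases faint spots sitting on bright background regions.
`spotquant` addresses this the way interactive array-analysis apps do: the
user declares the grid (rows × columns), each grid cell is assumed to hold
one spot, and the spot/background decision is made *locally*, inside each
cell, with Otsu's method. It is aimed at anyone who has a scanned array
image (TIFF/PNG/JPEG, 8- or 16-bit) and wants reproducible net spot
intensities as a CSV, without a commercial scanner suite.

## Method

For each grid cell with intensity histogram `p(i)` over 256 bins, Otsu's
threshold maximizes the between-class variance of the two-class split at
`t`:

```
σ²_B(t) = ω₀(t) ω₁(t) [μ₀(t) − μ₁(t)]²
```

where `ω₀, ω₁` are the class probabilities of pixels ≤ t and > t and
`μ₀, μ₁` their mean intensities; pixels above the threshold are foreground.
The spot's background level is the median of the cell's background pixels,
and the reported net intensity is

```
net = max(0, mean(foreground) − median(background))
```

Cells whose foreground is too small (< 4 px) or whose foreground/background
contrast is below the noise floor are flagged empty. Five classic
comparator threshold selectors (mean, isodata, triangle, li, yen) are
included for method comparison; Otsu is the production path.

Agreement between two quantification routes is measured with Spearman's
rank correlation, computed on tie-free data from the rank differences
`d_i`:

```
r = 1 − 6 Σ d_i² / (N (N² − 1))
```

(average-rank Pearson when ties are present), with a two-sided p-value
from the t-approximation on N − 2 degrees of freedom, plus ordinary
least-squares regression (slope, intercept, R²) and a Mann–Whitney /
Welch two-group comparison.

A synthetic-scan generator renders seeded array images — spots of
disc/ellipse/irregular shape on uniform, linear-gradient or quadratic
backgrounds with Gaussian noise — together with exact ground truth, so the
whole pipeline can be validated with no external data.

## Worked example

Render a seeded 7×10 demonstration array (70 spots, amplitudes 15–220 grey
levels, a 40-grey-level left-to-right background gradient, noise σ = 3),
quantify it, and validate against the generator's ground truth:

```
$ spotquant synth --kind gradient-demo --seed 42 --out-image array.png --out-truth truth.csv
$ spotquant calculate --image array.png --rows 7 --cols 10 --out results.csv
(1,1) 188.43
(1,2) 80.26
(1,3) 101.37
...
```

Each line is one spot's net intensity at its (row, column) position — the
first spot's foreground mean is 200.4 with a local background of 12, hence
188.4 net. `results.csv` holds the full table (`fg_mean`, `fg_sum`,
`fg_area`, `bg_estimate`, `net_intensity`, QC flags).

```
$ spotquant validate results.csv truth.csv --json
{
  "n": 70,
  "spearman_r": 0.9997900446155192,
  "p_value": 1.478991996321782e-116,
  "slope": 0.9203118863017596,
  "intercept": -0.19960186296631832,
  "r_squared": 0.9995951066894779
}
```

The 70 estimated net intensities rank-correlate with the true spot
amplitudes at r ≈ 0.9998 (R² ≈ 0.9996): local-Otsu quantification recovers
the ground truth despite the background gradient. The slope ≈ 0.92 < 1
reflects the expected edge-pixel dilution of the foreground mean.

```
$ spotquant compare-methods --image array.png --rows 7 --cols 10 --truth truth.csv
method,spots_detected,n_cells,mae_vs_truth
isodata,70,70,9.565557786282797
li,70,70,13.394606436000208
mean,70,70,20.730633256038363
otsu,70,70,9.56295522250958
triangle,70,70,26.269951065842605
yen,70,70,31.854487468072076
```

In local mode every method finds all 70 spots on this image, but Otsu
(with isodata close behind) has the smallest mean absolute amplitude
error. Running `calculate` with `--mode global` instead recovers only 53
of the 70 spots — the faint-spot loss that motivates per-cell
thresholding.

The same operations are available from Python (`spotquant.quantify_array`,
`spotquant.spearman`, `spotquant.render_gradient_demo`, …); see
`docs/methods.md` for the model details and parameter defaults.

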