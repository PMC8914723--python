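# Methods

## Problem and model

The package discriminates foreign materials (FMs) from fresh-cut vegetables
in NIR absorbance spectra (1000–2500 nm) and evaluates reduced band sets on
multispectral image cubes. The discriminant is PLS1 regression of the 0/1
class code on the spectra, fit by NIPALS: per component a weight vector
w = Xᵀy/‖Xᵀy‖, score t = Xw, X-loading p = Xᵀt/tᵀt and y-loading
q = yᵀt/tᵀt, followed by deflation X ← X − tpᵀ, y ← y − qt. The regression
vector is β = W(PᵀW)⁻¹q mapped back to the raw variable scale, with the
intercept from the centering means. Classification thresholds the predicted
score at 0.5, the midpoint between the class targets; exact ties go to the
FM class (the conservative direction for a safety screen). Vegetable = 0 is
the *positive* class throughout — sensitivity counts vegetables recognised
as vegetables, specificity counts FMs caught — which inverts the common
positive-is-target convention and is therefore stated on every report type.

NIPALS was chosen over SIMPLS because its score/loading factorisation
matches the X = TPᵀ + E_x, y-decomposition form directly and is easy to
verify against independent oracles (full-rank PLS1 equals ordinary least
squares; scikit-learn's `PLSRegression` reproduces the predictions — both
are test assertions, never the implementation). Variables are always
centered; per-variable autoscaling is off by default and **on** when the β
vector is read as the *weighted* regression coefficient for WRC selection,
which needs all variables on a common scale. Whether to autoscale before
the other models is genuinely open in this domain; centering-only was
chosen because the water-band amplitudes carry real information that unit
variance scaling would flatten.

Undefined confusion metrics (zero denominators) raise instead of returning
0 or 100: a sentinel silently corrupts model-comparison tables.

## Latent-variable count

The LV count is the smallest one minimising stratified k-fold
cross-validated misclassification (default 10 folds, seeded). Parsimony
tie-break: when several counts reach the minimum, the smallest wins.

## Waveband selection

* **WRC** — interior local extrema of |β| on the autoscaled model, ranked
  by magnitude and accepted greedily under a pairwise separation of
  ≥ 30 nm. The separation default is set just below the ~40 nm gap between
  the two close water-region picks a practitioner would keep apart.
* **VIP** — Wold VIP with unit-norm weights and SSYₐ = qₐ²·tₐᵀtₐ, so that
  mean(VIP²) = 1 exactly (an asserted identity). Cut-offs 0.8–1.5 in steps
  of 0.1 are scanned; each keeps variables with VIP ≥ cut-off, refits, and
  is scored by CV accuracy; the winner maximises accuracy with ties to the
  fewest variables.
* **SFS** — greedy forward selection; the criterion is stratified k-fold CV
  misclassification of a PLS-DA on the candidate set with LVs =
  min(|set|, 5). Default 20 folds. Stops at zero error or the feature
  budget.
* **SPA** — projection chains from *every* start column of the centered
  matrix (add the column of maximal residual norm against the span of the
  chosen ones); every chain prefix between the minimum (2) and maximum (10)
  size is scored by CV misclassification; minimum error wins, ties to fewer
  variables, then the lexicographically smallest index tuple.
* **iPLS (forward)** — the grid is tiled into equal contiguous intervals
  (width 1 makes them single wavelengths); the interval minimising the CV
  error of a ≤ 5-LV PLS-DA on the union is added until the error stops
  strictly decreasing.

Greedy CV ties are common under planted perfect separability (whole bands
reach zero error). They are broken by the **mean decision margin** — how
far CV predictions sit on the correct side of the 0.5 baseline — then by
the lower index. This keeps every run deterministic and lands tied
selections on band centers rather than on whichever zero-error wavelength
happens to come first.

Reduced models are refit on *raw* (unpreprocessed) spectra restricted to
the selected bands and scored on a held-out stratified test partition.

## Synthetic study conditions

No public spectra exist for this problem, so a generator defines the study
conditions. Each material is a deterministic band sum — Gaussian bands on a
linear baseline — multiplied by a per-spectrum log-normal scatter factor
exp(N(0, 0.05)) and perturbed by additive white noise N(0, 0.01 AU) per
wavelength. This is the minimal model producing exactly the artefacts SNV
and MSC are designed to remove, so preprocessing is meaningfully testable.

Band *positions* follow standard NIR assignments: vegetable water bands at
1450/1940 nm plus the 1190 nm combination band; cellulose/C–H features near
1490/1730 nm for wood, paper and insects; plastic CH₃ features near 1156 nm
with peaks over 1720–1770 nm; metal and stone nearly featureless.
Amplitudes are package fixtures, chosen once so that (a) vegetable water
bands dominate every FM feature and (b) the water-band regions are the
*only* wavelengths separating vegetables from every FM simultaneously —
each FM band overlaps some other material's range. Consequence: planted
recovery is well-defined, and selectors are expected to return at least one
wavelength within ±25 nm of 1450 or 1940 nm.

Default sizes: 1557 grid points over 1000–2500 nm (the generator default);
analyses and the acceptance script run at 389 points with 140 vegetable +
160 FM samples — the same class ratio as the 280+320 design at half scale,
on a 4×-coarser grid, which keeps the all-starts SPA scan and the 20-fold
SFS scan comfortable on one CPU. A "wet tissue" mimic FM shares the
vegetable signature everywhere except the 1450 nm band; it exists to make
band-combination choices consequential in the imaging stage.

What the generator does **not** emulate: radiative-transfer effects,
specular highlights, detector nonlinearity, wavelength-correlated noise,
within-class biological variability beyond the scatter factor. Passing
tests therefore demonstrate algorithmic correctness and qualitative
behaviour (which bands matter, why six bands beat five), not instrument-
level accuracy on real produce.

## Imaging stage

Scenes are one vegetable slab with 3–5 FM objects lying on it (painter's
semantics: an FM covers the produce pixels beneath it; an object fully
covered by later objects is an error). Cubes default to 900–2500 nm at
5.876 nm spacing (273 bands). The detection pipeline per band combination:

1. **Extract** the band nearest each requested wavelength (offset ≤ half
   the band spacing by construction).
2. **Background removal** — Otsu threshold on the across-band *minimum*
   image by default. The minimum image collapses all materials into one
   population well above the dark belt; single-band histograms here have
   three or more modes and Otsu's bimodal split then discards the darker
   FMs (the real-world failure mode where FMs resembling the background are
   removed with it). A fixed-level alternative is available.
3. **Per-pixel classification** with a PLS-DA trained on band-restricted
   spectra (mirroring the reduced-model refit), thresholded at 0.5; a 3×3
   median filter (default on, configurable) removes isolated noise flips
   without relabeling background.
4. **Object scoring** — FM pixels grouped by 8-connectivity; blobs under
   5 px discarded; a truth FM is detected iff a surviving blob overlaps its
   mask by ≥ 1 px; surviving blobs touching no truth FM count one false
   positive each. The overlap rule, connectivity and blob floor are
   invented plumbing (only object counts are externally specified) and all
   three are exposed in configuration.
5. **Aggregation** — overall accuracy = 100·Σ detected / Σ total across
   scenes; combinations ranked by accuracy with ties toward fewer bands,
   so ranking is independent of input order.

## Numerical choices and degenerate inputs

Weight vectors with near-zero norm stop the NIPALS loop (error on the first
component, truncation afterwards). Autoscaling refuses constant variables;
SNV/range-normalization refuse constant spectra; MSC refuses slopes below
1e−12. Savitzky–Golay (default window 11, polyorder 2) requires a uniform
grid and divides by the grid spacing, giving derivatives per nm independent
of grid resolution; edges use polynomial extrapolation within the terminal
window. The spectra CSV serialises floats by `repr`, which round-trips
float64 exactly. Wavelength grids of length 1 are permitted so single-band
selections remain representable; file readers still require ≥ 2 columns.

## Known limitations

* SPA's all-starts scan is O(J²·max_vars) in time; beyond a few thousand
  variables a start-column subsample would be needed.
* The VIP cut-off scan can prefer broad selections when whole bands tie at
  100 % CV accuracy; on real (noisier) data the scan behaves as intended.
* MSC against the pooled mean reference removes some between-class
  multiplicative signal (visible as a slightly lower MSC row in the
  preprocessing comparison); per-class references are not implemented.
* Detection counts depend on the invented ≥ 1 px overlap rule; with
  touching FM objects a single blob can detect several truth objects.
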