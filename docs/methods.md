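# Methods

This note describes the models and procedures implemented in
`plastiscan`, the assumptions behind them, the parameters that matter,
and what the synthetic test bed does and does not establish.

## Spectral data model

A hyperspectral image is an absorbance cube indexed `(row, col, band)`
with a strictly monotone wavenumber axis in cm⁻¹. The default grid —
used when an ENVI header carries no band centers — is 1250 to 3594 cm⁻¹
in 4 cm⁻¹ steps (587 bands), the working range of FPA-based μFTIR
transmission measurements; the default pixel pitch is 11 μm. Cubes are
read and written in the ENVI convention (ASCII header + flat binary,
interleaves BSQ/BIL/BIP, float32/float64, both byte orders). Integer
raster types are rejected deliberately: absorbance exports are float,
and a narrow surface is a testable surface. Image coordinates are
`(row, col)`, 0-based, origin top-left, everywhere — including exported
centroids. Cubes are assumed to hold absorbance; a `transmittance=True`
flag on `read_envi` applies `−log₁₀` on load for instruments that export
transmittance.

## Synthetic spectra

The generator produces the *observed* absorbance of a polymer layer of
dimensionless thickness `d` from a per-class band table:

    A_ideal(ν) = d · Σ_k h_k · w_k² / ((ν − c_k)² + w_k²) + b
    A_obs(ν)   = c_TA · (1 − exp(−A_ideal/c_TA))
                 + a_Mie · sin(2πν/P + φ) + s·(ν − ν₀) + ε(ν)

Lorentzian band shapes are the physical convention for IR absorption
lines (centers `c_k`, half-widths at half-maximum `w_k`, heights `h_k`
in absorbance units). The three distortion terms emulate the failure
modes that make pixel classification hard in practice:

* **Total absorption (TA)** — the smooth exponential saturation toward
  the ceiling `c_TA` reproduces how thick particles first shift relative
  peak ratios and, in the limit, flatten every band to the same level. A
  smooth model was chosen over hard clipping because the information
  loss in real spectra is gradual; the ratio of two peak heights
  approaches 1 continuously as `d` grows.
* **Mie-type baseline distortion** — an additive low-frequency sinusoid
  (amplitude `a_Mie`, period `P`, phase `φ`) plus a linear slope `s`
  captures the baseline oscillation caused by scattering at particles
  comparable in size to the wavelength. Severe *resonant* Mie effects
  (peak position shifts, derivative-like peak deformation) are out of
  scope.
* **Noise** — i.i.d. Gaussian per band, standard deviation `σ` in
  absorbance units.

Default sampling ranges (the "study conditions" of all tests and the
acceptance script) are: thickness 0.5–2.0, `a_Mie` 0–0.08 AU, `P`
600–1500 cm⁻¹, slope ±2·10⁻⁵ AU/cm⁻¹, `c_TA` 1.5–2.5 AU, `σ` = 0.008 AU.
These describe a moderately adverse measurement: baseline wobble
comparable to weak bands, saturation ceilings where strong bands of
thick particles visibly clip, and noise about 1–8% of typical band
heights.

**Band tables.** The 21 polymer templates (plus a broad-band "Other"
matrix template) are a curated, deliberately *synthetic* set: 3–4 bands
each, positioned loosely where characteristic vibrations of the polymer
family live (C–H stretches near 2850–2960 cm⁻¹, carbonyls near
1710–1750 cm⁻¹, nitrile at ~2240 cm⁻¹, …) but tuned for mutual
distinguishability, not for spectroscopic fidelity. They are ground
truth for testing the machinery; they are not a reference library and
must not be used to identify real spectra.

**Scenes.** A scene spec plants ellipse and fiber shapes on a substrate
of pure Gaussian noise around zero (the state of background pixels after
instrument background correction). Distortion parameters are drawn once
per particle — a physical particle has one thickness and one scattering
geometry — while noise is drawn per pixel. Overlaps resolve by draw
order (later wins). Matrix coverage is expressed as the fraction
matrix/(matrix+particle) of non-substrate pixels and painted as small
"Other"-class blobs. Fibers are rasterized with bridge pixels on
diagonal steps so that a planted fiber is edge-connected and therefore
recoverable as a single particle; the fiber-fragmentation phenomenon
(out-of-focus fiber segments) is instead exercised explicitly through
the merge operation.

## Random decision forest

Trees are exact greedy CART: at each node the split minimizing the
weighted Gini impurity `(n_L·G_L + n_R·G_R)/n` is chosen among the
candidate bands, with thresholds at midpoints of consecutive distinct
values. Candidate bands are a fresh random draw per node of
`features_per_split` indices (default `⌈√p⌉ = 25` of 587); bands that do
not vary within the node are skipped in favor of later draws so a node
is only made a leaf when nothing varies at all. Each tree sees a
bootstrap resample of the training rows (disable with
`bootstrap=False`). Defaults: 100 trees, unlimited depth, `min_leaf=1` —
the conventional random-forest configuration; all are exposed in
`RDFConfig`.

Determinism is a design goal, so every tie is specified: among
equal-impurity splits the lowest band index wins, then the lowest
threshold; equal vote counts go to the earlier class in the fixed class
order; and training rows are canonically reordered by a digest of their
bytes before any random draw, which makes the fitted forest invariant to
the order in which training spectra are supplied. One documented
consequence of the lowest-band tie-break: on tiny separable data sets
several zero-impurity splits can tie and the forest may prefer a
low-index noise band over a "semantic" band — harmless for accuracy on
held-out data, but the reason unanimous-vote guarantees are only stated
for in-bag training data.

The split search is implemented without a class dimension: sorting the
node's samples per candidate band and tracking occurrence ranks gives
the left/right sums of squared class counts via two cumulative sums,
which is what makes 100-tree forests on ~2000 × 587 data train in
seconds. A single-tree, all-features, no-bootstrap configuration is
bit-for-bit checkable against an exhaustive brute-force CART, and the
test suite does exactly that; the brute-force oracle keeps the same
arithmetic shape of the score so exact ties resolve identically.

Feature representation is the raw resampled absorbance vector. Spectra
on foreign grids are linearly interpolated onto the model axis (edge
values beyond the raw range; an error if the raw axis covers less than
90% of the target range). Unit-norm scaling and a Savitzky–Golay first
derivative are available as preprocessing options but default to off —
raw bands keep the model self-contained and the defaults reproducible.

Models persist as versioned JSON containers (class order, axis,
preprocessing, config, tree arrays); loading refuses a foreign format or
version. JSON keeps the file text-only and byte-reproducible.

### Label-noise audit

Reference sets labeled by several independent annotators are audited by
training one forest per annotator and predicting every other annotator's
spectra. A spectrum is flagged when more than `majority_fraction`
(default 1/2) of the cross-models contradict its own label: with four
annotators that means at least 2 of 3, with two annotators the single
cross-model decides. Flags are review candidates, not automatic
corrections.

## Image pipeline

1. **Substrate detection.** Signal score = per-pixel spectral standard
   deviation; threshold `median + k·MAD` with `k = 3` by default. The
   comparison is non-strict (`≤`) so an exactly flat cube is all
   substrate even when the MAD is zero. Because the threshold is a
   robust quantile of a noise distribution, a tail of background pixels
   (≈2% at `k = 3`) survives it by construction; the default is
   deliberately permissive so faint particles are not lost. For counting
   on clean synthetic scenes the stricter `k = 6` together with
   `min_pixels = 2` suppresses noise singletons — the configuration used
   in the end-to-end tests and the acceptance script. An Otsu threshold
   on the score is available as an alternative.
2. **Classification.** Non-substrate pixels are classified in one batch;
   the label map stores the argmax class, the probability map the
   winning vote fraction (NaN on substrate).
3. **Lateral post-processing.** Per pass, each non-substrate pixel takes
   the modal class of the non-substrate labels in its 8-neighborhood
   plus itself, updated synchronously. The current label wins ties;
   substrate is never created nor consumed. Default one pass. The
   asymmetry — 8-neighborhood smoothing but 4-connectivity detection —
   is intentional: smoothing should see all spatial neighbors, particle
   identity requires shared edges.
4. **Particle detection & characterization.** Connected components per
   class under 4-connectivity; ids in raster-scan order of each
   component's first pixel; components below `min_pixels` (default 1)
   dropped. Geometry from pixel centers: centroid, principal axes of the
   second-moment matrix, length/width = span of projections + one pitch
   (a single pixel is pitch × pitch, never zero-sized), orientation =
   major-axis angle against the row direction folded to [0°, 180°), 0°
   on isotropic ties. Reliability = mean winning vote fraction over the
   particle's pixels, taken from the *raw* classification by default
   (post-processing overwrites labels, not confidence); a flag switches
   to post-filter agreement.

Editing operations implement the dual-control step: `merge_particles`
joins same-class fragments (optionally with operator-supplied bridge
pixels) under a fresh id; `edit_particle_pixels` adds/removes pixels,
rejecting edits that would empty the particle and either rejecting or
re-splitting (per flag) edits that disconnect it. CSV export is RFC 4180
with `.` decimals and 6-decimal numeric fields.

## Validation machinery

Monte Carlo cross-validation holds out a random `test_fraction`
(default 10%) per split, stratified per class with largest-remainder
allocation so the total test count is exactly `round(f·N)`, retrains on
the remainder and accumulates test predictions into per-split confusion
matrices; defaults are 20 splits. Headline measures are computed on the
*pooled* matrix (entrywise sum over splits) — per-split accuracies are
reported alongside so dispersion stays visible. Per-class measures are
one-vs-rest sensitivity, specificity and precision; global measures are
accuracy and Cohen's kappa. Undefined ratios (empty truth row, empty
prediction column, `p_e = 1`) are NaN, never silently zero. "Other" is a
regular 22nd class in every computation.

## Problem sizes in tests and the acceptance script

The acceptance-level runs use: a 22 × 100 reference library under the
default distortion ranges for the 20 × 10% cross-validation; a 256 × 256
× 587 scene with 30 well-separated particles over ≥ 8 classes for the
end-to-end recovery check; 22 × 30 libraries with 8 splits and 30 trees
for the noise-degradation grid (σ ∈ {0, 0.01, 0.05, 0.1} AU over three
seeds); 4 annotator sets of 8 × 25 separable spectra with 5% flips for
the audit; 1000 random confusion matrices and 200 random 50 × 50 label
maps for the oracle comparisons. These sizes were chosen as the smallest
at which each property is meaningfully exercised.

## What passing tests do and do not show

The synthetic generator produces class-conditional spectra with fixed
band positions, smooth saturations, and well-behaved noise. Real
environmental spectra add weathering shifts, additive/pigment bands,
resonant Mie peak deformation, mixed pixels at particle boundaries, and
matrix heterogeneity far beyond one broad-band template. Perfect or
near-perfect recovery on the synthetic bed therefore validates the
*machinery* — I/O, split search, vote accounting, masking, connectivity,
geometry, metric formulas — not field performance of the shipped band
tables. Conversely, the degradation tests (noise grid, TA saturation)
show the pipeline fails gracefully rather than abruptly. The model
assigns exactly one class per pixel; spectral unmixing of overlapping
materials is explicitly out of scope.

## Known limitations

* No OPUS or other instrument-native readers; generic ENVI only.
* No GUI; particle editing is programmatic by design.
* The forest offers no gradient-boosting or deep alternatives.
* Orientation is undefined (reported 0°) for isotropic pixel sets.
* Windowed band-integral descriptors exist as a preprocessing hook but
  are off by default and not tuned.
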