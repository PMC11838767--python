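# Methods

## The labeling model

A metabolic ¹⁵N pulse makes newly synthesized protein isotopically heavy.
`plaquetime` parameterises a deposit of Aβ1–42 by two quantities:

* **ρ** — the probability that any single nitrogen atom in a molecule
  synthesized during the pulse is ¹⁵N. This is the *tissue* relative isotope
  abundance, which sits well below the dietary enrichment because newly made
  amino acids are diluted by pre-existing unlabeled pools. It is exposed as
  a parameter everywhere (generator default 0.15, see below).
* **f** — the fraction of molecules in the deposit synthesized during the
  pulse. This is the per-ROI quantity the spectral pipeline estimates, and
  the quantity that carries the deposition-time information.

The deposit's isotopologue envelope is the two-component mixture
`(1 − f)·E_nat + f·E_lab(ρ)`. Its mean mass is exactly affine in `f`
(`mixture_envelope` preserves this identity to machine precision; it is a
tested invariant), with full-label shift `N · (m¹⁵N − m̄_N)` where `m̄_N` is
the natural mean nitrogen mass — 54.64 Da for Aβ1–42 (N = 55). Note this is
slightly below the naive `N · (m¹⁵N − m¹⁴N)` = 54.84 Da because natural
nitrogen already contains 0.364% ¹⁵N.

Envelopes are computed on **nominal-mass bins** (unit offsets from the
monoisotopic species) by iterative convolution of per-atom isotope
distributions, with exponentiation-by-squaring over atom counts, a pruning
floor of 1e-10 per convolution step, and renormalisation. Bin masses are
abundance-weighted means. Fine isotopic structure is deliberately not
modelled: neither instrument mode in the intended workflow (linear TOF at
R ≈ 1000, reflector at R ≈ 15000 near m/z 4512) can resolve it, so
nominal-mass binning matches what the fitting stage sees. Atomic masses and
abundances ship as a package CSV; the ¹⁵N–¹⁴N difference is taken from that
table, never hard-coded.

### A note on the two-point mixture and bimodality

The mixture model becomes *bimodal* when the labeled cluster sits further
from the natural cluster than the instrument linewidth, i.e. when
`55ρ ≳ FWHM`. At ρ near full enrichment the two clusters are ~54 Da apart
and the envelope centroid stops being a useful single-peak statistic at
intermediate `f`; likewise the 4th/3rd isotopologue ratio in the low-mass
cluster is nearly flat in `f` because the labeled cluster contributes
nothing there (this insensitive regime is exercised and documented in the
tests). At the default ρ = 0.15 the labeled cluster (+8.2 Da) merges with
the natural envelope under linear-mode smoothing (FWHM ≈ 4.5 Da), the
centroid is strictly monotone in `f`, and the 4th/3rd ratio rises
monotonically with `f`. Real tissue, with its continuous distribution of
per-molecule enrichment, is smoother still; the two-point mixture is the
harder case.

## Spectral pipeline (linear mode)

Per ROI: TIC normalisation → main-peak detection (highest interior local
maximum in a 4460–4580 m/z search window, ties toward lower m/z) →
symmetric fit-range selection → linear baseline correction → bounded
split-Gaussian fit → centroid.

Numerical choices that matter:

* **Fit range.** The window grows symmetrically from the apex until the
  intensity falls below 2% of the apex on both flanks or the half-range
  reaches 5 provisional FWHMs, whichever is first. The stop test runs on a
  5-sample moving average: at SNR 20 the per-sample noise (5% of apex)
  exceeds the 2% threshold, and a raw single-sample rule truncates the
  window mid-peak essentially at random.
* **Baseline.** A straight line through the outer 10% of window points on
  each side, subtracted, negatives clipped to zero. Noiseless recovery of a
  planted linear baseline is exact to better than 1%.
* **Peak model.** A split Gaussian — independent left/right flank sigmas,
  shared amplitude and center — fitted by bounded least squares
  (amplitude ≤ 2× apex, center inside the window, widths between the grid
  step and the window width). FWHM = √(2 ln 2)(wL + wR) exactly. A fit is
  *accepted* when it converges and R² > 0.95 (configurable). Noiseless
  single-peak envelopes reach R² ≥ 0.999; pure-noise windows are rejected
  essentially always. Mid-label-fraction *mixture* envelopes are shouldered
  and reach only R² ≈ 0.92–0.97 — a model-mismatch property of the
  synthetic two-point mixture, not a data-quality problem — so the
  synthetic closed loop uses all converged centroids by default and reports
  the gate per ROI (`age_stage(min_r2=...)` restores strict gating).
* **Centroid.** Intensity-weighted mean of the baseline-subtracted,
  zero-clipped trace between the baseline intersections flanking the apex.
  The intersection points are taken where the *fitted curve* falls below 2%
  of the fitted amplitude: a Gaussian meets the baseline only
  asymptotically, and bounds defined on the noisy measured trace (first
  zero sample) jitter with both the noise and the grid step. The weights
  remain the measured trace (config can switch to fitted-curve weights).
  The centroid is invariant to intensity scaling and hence to TIC
  normalisation.

**Label-fraction calibration.** `CentroidCalibration` renders noiseless
mixture envelopes at 21 values of `f` through the *same* centroid pipeline
and inverts measured centroids by monotone interpolation. The measured
centroid is monotone but slightly curved in `f` (window truncation of a
skewed envelope); a straight-line inversion leaves a systematic ±0.04 bias
near the ends of the `f` range, which interpolation removes. The fitted
line (slope ≈ 8.7 Da per unit `f` at ρ = 0.15) is retained for reporting.

## Reflector mode: isotopologue areas

Resolved spectra are not fitted with the single-peak model. Each expected
ladder position (1-Da spacing from the monoisotopic m/z) is matched to a
detected local maximum within ±0.3 Da and integrated between the local
minima separating it from neighbouring peaks. The peak list is kept above
`max(5% of max, 6 × MAD-estimated noise sd)` with a prominence requirement —
on a ~7000-sample grid, dozens of noise excursions exceed any small fixed
fraction of the maximum and would otherwise corrupt the integration bounds.
The 4th/3rd area ratio is indexed 1-based from the **first detected** peak;
this matters: at high `f` with high ρ the natural monoisotopic peak
vanishes and the indexing re-anchors to the labeled cluster, which is why
the ratio jumps discontinuously near `f = 1` in that regime. Noiseless
ratios agree with the isotopologue-model probability ratios to ≲0.1%.

## Group-level statistics

* **Center vs periphery.** Pairing is exact by construction (both
  subregions measured in the same plaque), so the contrast is fitted as a
  mixed model on the per-plaque differences with a random intercept per
  animal (REML). In the balanced paired design this yields the identical
  fixed effect and test as the long-format model with subregion fixed
  effect, plaque variance component and animal intercept, and it is far
  more stable with 3 animals. When the REML score is singular at the
  zero-variance boundary the fit retries with a gradient-free optimizer;
  with < 3 animals the method degrades to a paired t-test (tagged in the
  output). Monte-Carlo calibration at the study geometry (3 animals ×
  8 plaques, residual sd 0.5): type-I error 3–5% at nominal 5%, power ~100%
  for a 2-Da shift at p < 0.01.
* **Cortex vs hippocampus.** Paired t-test across animals on per-animal
  region means; computed even at n = 2 animals (df = 1, wide CI).
* **Age vs LCO maturity.** Pearson r per animal (≥ 3 complete plaques)
  plus a pooled row. Sign conventions: under pulse-chase, higher centroid
  (more label) = older; older plaques are structurally more mature, so both
  the 4th/3rd ratio and the 500/580 ratio rise with age and the planted
  correlation is positive.

## Transcriptomics chain

Probe QC removes probes whose geometric-mean count falls below a floor
(default 10) and probes flagged as Grubbs outliers (two-sided, α = 0.05, on
log-scale values within each ≥3-probe target) in more than 20% of ROIs —
floor and fraction follow platform convention, as the vendor defaults are
unpublished, and every exclusion is logged with its reason. Targets
collapse to genes by geometric mean over surviving probes (pseudocount +1,
subtracted back, so all-zero probes give zero). Quantile normalisation is
the classic rank-mean algorithm with average-rank ties; tie-free columns
share exactly the same value multiset afterwards and the operation is
idempotent (ties receive interpolated reference values — the documented
caveat). Per-gene Pearson correlation against the plaque-age coordinate
uses a vectorised t-transform with Benjamini–Hochberg correction across all
testable genes; constant genes are excluded with a log entry. ORA is the
one-sided hypergeometric upper tail against GMT sets intersected with the
QC-surviving universe, BH within each ontology slice, pass at
p ≤ 0.05 ∧ q ≤ 0.05; the selection feeding ORA is p < 0.05 split by
correlation sign (configurable).

## Imaging

* **Unmixing** is per-pixel non-negative least squares against the two
  reference emission spectra. For exactly two endmembers the active-set
  solution is closed-form and fully vectorised; it is cross-checked against
  the generic NNLS solver in the tests. Exact mixtures return zero
  residual; at SNR 20 abundance RMSE is < 5% of peak.
* **Emission ratio**: nearest channels to 500 and 580 nm; for z-stacks the
  plane with the highest within-mask mean ratio is selected; the max-ratio
  pixel marks the core and intensities are averaged over a radius-2 disc
  restricted to the mask. Invariant to global intensity scaling.
* **Plaque typing**: connected Aβ⁺ components (pixel-level Otsu by
  default), positivity = component mean unmixed abundance above threshold.
  Automatic thresholds are found on the *component means* via the
  largest-gap split (histogram Otsu is unreliable on ~10 samples), with the
  q threshold determined among h-positive components only, since
  q-positivity is graded within LCO-stained plaques. q⁺h⁻ is not a defined
  class and is flagged. Types: Aβ⁺h⁺q⁺ (compact/cored), Aβ⁺h⁺q⁻
  (fibrillar), Aβ⁺h⁻q⁻ (diffuse).
* **Rings**: Euclidean distance from each plaque's mask boundary (not its
  centroid — plaques differ in size), ring k = (10(k−1), 10k] µm, k ≤ 3;
  any pixel within 30 µm of two or more plaques is contested and removed
  from every profile; plaque interiors are excluded. Ring areas around a
  20-µm disc match analytic annuli within 3% at 1-µm pixels. Aggregation is
  plaque → type-within-image → image-within-animal, invariant to
  enumeration order.

## Synthetic-data generator: what it emulates

Defaults encode the study conditions: 3 animals, 8 plaques per region
(cortex, hippocampus), pulse-chase scheme, linear mode R = 1000 at SNR 20
and reflector mode R = 15000; 32 emission channels spanning 480–690 nm;
10-µm rings to 30 µm; 1000 genes with 25-gene planted sets at r = ±0.8.

Parameter choices that required judgement:

* **ρ = 0.15**: tissue RIA under a highly enriched diet is diluted by
  unlabeled amino-acid pools; 0.15 also keeps the linear-mode envelope
  unimodal, the regime where the centroid is a meaningful estimator.
* **f_center = 0.7 ± 0.10, periphery offset −0.2**: plaques present after
  the chase nucleated during or near the pulse, so centers (the oldest
  material) are predominantly labeled and the later-accreted periphery less
  so; plaque-to-plaque spread reflects staggered nucleation times.
* **Reflector SNR 150 vs linear SNR 20**: reflector ROI spectra in the
  workflow are TIC-normalised averages over an entire plaque raster
  (hundreds of pixels × 200 shots), so their noise is far below
  single-spectrum level.
* **Counts**: negative-binomial (α = 0.02) on log-linear means; planted
  genes receive a latent profile with the stated log-scale correlation to
  age; library-size factors are log-normal (sd 0.2). Dispersion 0 switches
  off all count noise (null genes become exactly constant), a degenerate
  mode used in tests. NB counting noise attenuates a planted log-scale
  r = −0.8 to about −0.74 on the count scale.
* **Emission references** are two-Gaussian parametric shapes with maxima
  pinned at 500/580 nm and weak red shoulders — only the peak positions are
  specified by the dyes' known behaviour; the shapes are synthetic.
* **Marker profiles** are piecewise-constant per 10-µm ring (matching the
  analysis resolution): HOMER1 deficits (0.60/0.80/0.95 of background for
  the compact type, shallower for the others) and LAMP1 elevations
  decaying outward, ordered by plaque maturity.

What the generator does **not** emulate: tissue autofluorescence, 3-D
plaque geometry, instrument drift, matrix peaks, spatial autocorrelation of
expression, or a continuous per-molecule enrichment distribution. Passing
closed-loop tests therefore establishes that the estimators recover the
structures the generator plants at realistic noise levels — not that they
are robust to every artefact of real acquisitions.

## Known limitations

* Age is a *relative* score (Da of centroid shift, or a rank); no calendar
  calibration is attempted because none is identifiable from a single
  pulse-chase design.
* The 4th/3rd ratio is informative only where the labeled and natural
  envelopes overlap (low ρ or high `f`); its insensitive regime is
  documented above.
* The split-Gaussian R² gate is a single-peak criterion and is reported,
  not enforced, on synthetic mixture envelopes (see above).
* Quantile normalisation's multiset identity holds exactly only for
  tie-free columns.
* Registration is landmark-based only; plaque matching is
  mutual-nearest-neighbour under a distance cap and will drop genuinely
  ambiguous pairs rather than guess.
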