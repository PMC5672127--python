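# Methods

## The single-marker method

A panel of six steroids — 7-hydroxycholesterol, 7-ketocholesterol,
4-cholesten-3-one, 7-dehydrocholesterol, cholesterol and stigmasterol — is
quantified by HPLC-DAD from a *single* calibrated standard, cholesterol.
Each analyte's detector response is linear, `Y = a·X + b` (Y peak area in
mAU·min, X concentration in µg/mL). When `|a/b| > 100` the intercept is
within the noise of the fit and the calibration collapses to the one-point
form `X = Y/a`. Under that condition each analyte's slope can be replaced by
the reference slope times a dimensionless **relative correction factor**

    f_{K/S} = a_K / a_S,

so the concentration of any analyte K follows from the reference calibration
alone:

    X_K = Y_K / (f_{K/S} · a_S).

`relative_correction_factor` warns (never silently corrects) when a line
fails the `|a/b| > 100` check. Factors are carried at full double precision
internally and rounded to 4 decimals only for display, matching the
precision at which such factors are conventionally reported; sample contents
are displayed at 1 decimal.

The conventional **external-standard** route, `X = (Y − b)/a` per analyte,
is implemented alongside. The per-analyte relative error
`RE% = 100·(X_QAMS − X_ES)/X_ES` is the method's accuracy criterion; for a
well-calibrated panel it stays below 2%.

### Peak location by relative retention time

Because only the reference standard is injected, analyte peaks are located
by the retention-time ratio `R = t_K / t_S`. A uniform rescaling of all
retention times — the first-order effect of a flow-rate or dead-volume
change — cancels in the ratio, which is what makes the assignment portable
across instruments. The assignment algorithm:

1. The reference peak is the largest-area peak inside the reference's
   absolute retention window (the whole trace by default). The reference is
   the dominant constituent of the material, so area is the robust
   criterion, and its retention time must be known before any ratio exists.
2. Every (analyte, peak) pair within a fractional ratio tolerance is
   collected; pairs are taken greedily by smallest deviation, ties broken
   toward the larger peak, and no peak is used twice. An exact
   deviation-and-area tie raises an ambiguity error rather than guessing.
3. The tolerance defaults to 0.05 (5%): routine run-to-run ratio RSDs for
   this assay family are well under 1%, and even across instruments and
   flow rates stay under ~5%, so a 5% window separates the panel's ratios
   (nearest spacing ≈ 0.14 on the default layout) without risking swaps.

DAD spectra provide an optional confirmation channel:
`spectral_similarity` computes the cosine of mean-centred UV spectra (scale
invariant, so dilution does not affect it), for resolving near-coeluting
candidates.

## Surrounding chromatography toolchain

* **Baseline** — rolling minimum followed by a same-window rolling mean.
  Chosen over polynomial fitting because sterol traces are sparse-peaked:
  a window ≳ 8 peak sigmas stays under the peaks while tracking slow drift.
  Window default 1.0 min against default peak σ = 0.05 min.
* **Peak detection** — local maxima of the baseline-corrected signal above a
  height threshold; bounds extend to the baseline crossing or, for fused
  peaks, to the valley minimum between apexes (perpendicular-drop
  convention, the usual workstation default), so areas partition a fused
  envelope. Width at half height by linear interpolation of the half-height
  crossings.
* **Integration** — trapezoidal rule on the clipped, baseline-corrected
  signal, with endpoint interpolation so that adjacent intervals add
  exactly.
* **Noise & S/N** — noise is the sd of a linearly detrended, peak-free
  region (≥ 20 points); the region and the convention matter because S/N is
  defined here as baseline-corrected *height* over noise sd (one of several
  conventions in use; none is canonical). LOD and LOQ are the concentrations
  at S/N 3 and 10, obtained from a through-origin fit of height vs
  concentration — height, not area, so LOQ/LOD = 10/3 exactly.
* **System suitability** — theoretical plates `N = 5.54 (t_R/w_½)²`
  (half-height formula) with the conventional floor 3500, and resolution
  `Rs = 2(t₂−t₁)/(w₁+w₂)` on baseline widths with floor 1.5.
* **Validation statistics** — everything reduces to
  `RSD% = 100·s/mean` with the sample (n−1) standard deviation, the
  convention for small analytical replicate sets. Default pass thresholds
  (2.0% stability, 3.1% durability, 1.19% within-lab / 2.0% cross-lab
  factor reproducibility, 2% method relative error) are observations about a
  validated method of this kind, exposed as arguments, not hard-coded
  specifications.

## Synthetic data generator

`qams.synth` emulates the study's acquisitions with known ground truth:

* Peaks are Gaussians with area = slope × concentration. On each analyte's
  own detection channel (205/240/280 nm) the slope is its published
  calibration slope; on other channels it defaults to 10% of that (an
  invented but DAD-plausible cross-channel response that ensures the
  reference peak is present, and dominant, on every channel).
* Default elution layout (4.5, 6.0, 7.5, 9.0, 10.5, 12.5 min, σ = 0.05 min)
  is synthetic — the published assay reports no retention times — and gives
  plates ≈ 4×10⁴ and pairwise resolution ≈ 7.5, comfortably above the 3500
  / 1.5 suitability floors.
* Noise is additive white Gaussian (default sd 0.2 mAU) and drift is linear
  (default 0.5 mAU/min): the simplest model that exercises the baseline and
  noise estimators. Retention jitter is multiplicative: a shared per-run
  factor (sd 0.3%, emulating flow variation, which cancels in retention
  ratios by construction) plus an independent per-peak factor (sd 0.05%).
* The calibration series uses injection-volume fractions
  0.25–3× of the 20 µL reference volume (8 levels), and the batch study
  draws per-batch concentrations uniformly within ranges that mirror the
  content spread of genuine material (reference sterol ~2–4 mg/mL in the
  extract, minor sterols 4–80 µg/mL), with a 2.0 g / 2 mL sample prep.
* Everything is reproducible bit-for-bit under a fixed seed; channels of
  one run share their retention jitter (same injection) but not their noise.

What passing on this generator does **not** show: robustness to tailing or
overloaded peaks, gradient baselines, co-eluting matrix interferences, or
detector saturation — none of which the generator produces.

## Problem sizes

The end-to-end checks run an 8-level calibration series plus 14 batches
(the study's structure) at 0.005-min sampling over 15 min (3001 points per
channel, 3 channels), and 50 single-batch replicates for the assignment
success rate; the whole suite completes in a few seconds.

## Numerical and design choices

* OLS via `numpy.linalg.lstsq` on the explicit design matrix; R² is the
  ordinary coefficient of determination. Degenerate designs (all
  concentrations equal, < 3 points) are rejected.
* The reference's own correction factor is *set* to 1, never computed, so
  rebuilds and uniform slope rescalings cannot drift it; the reciprocal
  identity `f_{K/S}·f_{S/K} = 1` holds to 1e-12.
* Out-of-range external-standard inversions warn but return the value:
  sample extracts legitimately fall outside the standards' fitted range.
* Files are CSV with a `#` metadata block; floats are serialized with the
  shortest representation that round-trips the IEEE double, so
  read∘write is the identity.
* The calibration and quantification cores are scikit-learn-style
  estimators (`LinearCalibration`, `QamsQuantifier`) so they compose with
  sklearn model-selection tooling; the chromatography pipeline itself
  (I/O, peak processing, simulation, CLI) is function-shaped.

## Known limitations

* Only linear, unweighted calibration; no weighted or nonlinear response.
* No peak-shape deconvolution: strongly fused peaks are split at the valley,
  which biases both areas when overlap is severe.
* Retention-time-difference location (as opposed to ratios) is deliberately
  not implemented — it is not portable across flow rates.
* No inferential ES-vs-QAMS hypothesis test is provided; the comparison is
  by relative error only, which is what the method's acceptance bound is
  stated in.
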