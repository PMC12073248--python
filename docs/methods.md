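# Methods

## The screening model

A ligand-fishing screen compares two conditions: the extract alone
("control") and the extract pre-incubated with the target enzyme ("enzyme"),
each injected in replicate (three per condition by default). If a component
binds the enzyme, the complex is removed before injection (by filtration),
so the component's molecular feature — its (m/z, retention time, peak area)
triple — loses area in the enzyme condition. The screen is therefore a
many-feature two-group comparison with a one-sided scientific question
(decreases are the signal of interest) run with two-sided statistics plus a
signed decision rule.

### Feature matching

Runs are aligned by greedy nearest-neighbour grouping: seed features are
taken in descending area order; each other run contributes at most its
closest unused feature within the mass tolerance (10 ppm) and the RT window
(0.3 min), ranked by ppm distance and tie-broken by RT distance. Every
feature is used exactly once; leftovers become single-condition groups, so a
compound completely consumed by the enzyme is not silently lost. Consensus
coordinates are area-weighted means. No RT warping is attempted — the RT
window absorbs instrument drift at the scale this workflow targets.

### Statistics

Per matched feature, areas are log-transformed (intensity noise is
multiplicative) and compared by one-way fixed-effects ANOVA with asymptotic
F-distribution p-values; with two groups this is the two-sample pooled-
variance t-test squared. Correction for the many parallel tests uses the
Benjamini–Hochberg step-up, implemented directly from its definition
(q_(i) = min_{j≥i} (m/j) p_(j), capped at 1) so it can be verified exactly
against a brute-force oracle; statsmodels' implementation is used as an
independent cross-check in the test suite, never as the implementation.

Fold changes are log₂ of the ratio of condition means, with each mean
floored at a pseudo-count of half the smallest nonzero area in the analysis.
The floor (rather than an additive shift of both means) leaves well-measured
ratios untouched — control 100/enzyme 10 reports exactly −3.32 — while
keeping features absent on one side finite.

Decision rule: **binder** iff q ≤ α (default 0.05) and log₂FC ≤ −0.585
(a 1.5-fold decrease); the mirrored positive case is reported as
**increased** (a degradation-product signature), everything else as
**unchanged**. Features with fewer than two detected observations in either
condition get p = 1 and an `underpowered` flag instead of being dropped.
A second, stricter level (`strict_alpha`, default 0.001) is exposed in the
configuration for reporting "differentiating" features.

### QC

PCA on the runs × features matrix of centred log₂ areas; the silhouette of
the condition labels on the first two score coordinates summarises
control/enzyme separation. The silhouette scales with the fraction of
features that carry a condition effect — a screen with 10 affected features
out of 210 separates cleanly in recall terms while showing a modest
silhouette (~0.2), whereas a matrix where half the features change yields
> 0.5.

## Mass arithmetic

All constants live in `ligandfish.formula`: monoisotopic masses C 12 (exact),
H 1.00782503, N 14.00307401, O 15.99491462, S 31.97207117, P 30.97376200 Da;
electron 0.00054858 Da; and the charge-carrier (proton) mass
1.00727646 Da = m(H) − m(e), from which both adduct shifts derive, so
m/z([M+H]+) − m/z([M−H]−) = 2 × 1.00727646 exactly. The ppm sign convention
is (theoretical − experimental)/theoretical × 10⁶ (measured high ⇒ negative
error). DBE = C − H/2 + N/2 + P/2 + 1; half-integer values (odd-electron
species) are reported as-is. The formula grammar deliberately excludes
isotope labels, charges and parentheses — malformed input is rejected with
the offending token named, not guessed at.

The packaged 44-compound chamomile library carries each compound's published
adduct m/z and DBE alongside its formula. Recomputation reproduces the
published DBE column completely and the published 4-decimal theoretical
masses for 30 of 44 rows (32 within 1e-4); for the remainder the published
mass column is internally inconsistent with the row's own formula (for
several rows the published ppm-error column actually agrees with the
formula-derived mass, identifying the printed mass as a transcription
error). The package always trusts the formula.

## Chromatogram operations

Difference traces are treated-minus-control with linear interpolation onto
the treated grid; consumed components appear as negative excursions. Peak
detection (scipy `find_peaks`) thresholds prominence as a fraction of the
trace's maximum absolute intensity (default 0.01) so defaults transfer
across intensity scales, and requires a minimum width (default 0.05 min);
peak bounds are found by strict descent from the apex to the enclosing
minima and areas are trapezoidal. On difference traces, maxima of |signal|
are sought so both signs are reported; `find_negative_peaks` returns the
negative subset ordered by |area|.

The mzML reader is a minimal ElementTree-based parser for the common
encoding subset (32/64-bit float arrays, no compression or zlib) and returns
centroided scans; EIC extraction sums centroid intensities within a ±ppm
window per scan.

## Assay reduction

Remaining activity = 100 × (A_sample − A_sample,bg)/(A_control −
A_control,bg), with absorbances at 450 nm (dopachrome formation). Values
above 100% (enzyme activation) are preserved internally; the reported
inhibition is max(0, 100 − remaining) — clamping happens at reporting time
only. Dose–response series (≥ 4 distinct concentrations) are fitted with a
four-parameter logistic, inh(c) = bottom + (top − bottom)/(1 + (IC50/c)^h),
by bounded least squares (scipy `curve_fit`); non-convergence falls back to
a coarse (IC50, h) grid with min/max plateaus and is flagged, a response
spanning < 5 percentage points yields no IC50 at all, and an IC50 outside
the tested range is flagged extrapolated. Mass concentrations (mg/mL) are
converted to µM via IUPAC-2021 average atomic weights.

## The synthetic test bed

`ligandfish.synth` generates every input the pipeline consumes, as a pure
function of (scenario, seed):

- **Feature runs.** Per compound, replicate and condition: m/z = true m/z ×
  (1 + ε·10⁻⁶) with ε ~ N(0, 3 ppm); RT = true RT + N(0, 0.05 min); area =
  base × (1 − decrease, enzyme side only) × unit-mean log-normal noise with
  CV 0.10. Base areas are log-uniform over 10^4.5–10^6: 1.5 decades of
  dynamic range whose floor stays above the workflow's 1%-of-maximum area
  filter, because the generator emulates the *exported feature lists* of an
  acquisition pipeline that has already applied that floor.
- **Rosters.** The default scenario uses the 43 negative-mode library
  compounds at their published retention times, with the ten compounds
  reported as enzyme-interacting (gluconic, malic and citric acids, the
  feruloyl-hexose isomers, protocatechuoyl-glucose, the three
  chlorogenic-acid isomers, and apigenin rhamnoglucoside) decreased by 60%.
  The benchmark scenario spikes 10 binders among 200 synthetic nulls with
  > 30 ppm pairwise mass spacing so recall/FDR measurement cannot be
  confounded by accidental isobars.
- **Traces.** Gaussian peaks (σ 0.05 min) at true RTs, enzyme side scaled by
  1 − decrease; noiseless by construction (they exercise subtraction
  arithmetic, not the detector).
- **Dose–response.** 4PL evaluations over an 8-step 3-fold ladder plus
  Gaussian noise, clamped at 0.

What the generator does *not* emulate — and what passing tests therefore do
not demonstrate about real data: isotope envelopes and adduct cross-talk,
correlated (batch/drift) noise, RT warping beyond i.i.d. jitter, detector
saturation, and matrix effects such as co-elution suppressing genuine
binders (the motivating study itself notes aglycones were masked this way).

## Problem sizes and operating characteristics

The shipped study conditions are: benchmark recall/FDR at 210 compounds ×
6 runs (recall ≥ 0.9, empirical FDR ≤ 0.1 at seed 1); null error control
over 100 seeded screens of 500 null features each (share of analyses with
≥ 1 binder call ≤ α + 3σ Monte-Carlo margin); BH equality with a
brute-force oracle over 1000 random p-vectors; IC50 recovery noiseless
within 1% and median-of-20-seeds within 15% at 5-point noise. These sizes
were chosen as the smallest at which the Monte-Carlo margins are meaningful.

## Known limitations

- Matching is greedy, not globally optimal; pathological feature densities
  (closer than the tolerance) can split groups. The benchmark sidesteps
  this by construction; real data with near-isobaric co-eluting compounds
  (e.g. positional isomers 0.003 min apart) will merge or split groups.
- Two conditions only; the ANOVA generalises to k groups but the decision
  rule and fold change assume control/enzyme.
- The 4PL fallback grid is coarse by design (it exists to flag, not to
  replace, a failed fit).
- Annotation is library-driven: compounds absent from the library can only
  ever be "unknown" — formula generation from exact mass is out of scope.
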