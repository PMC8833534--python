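# Methods

## The model

`protonsel` predicts, per patient, the organ-at-risk (OAR) mean doses a photon
(VMAT) and a proton (IMPT) plan *would* deliver, using only delineation
geometry, and converts them into the ΔNTCP profile used for model-based proton
therapy selection.

**Geometry.** All structures are binary masks on one shared voxel grid with
physical spacing (masks must be pre-resampled; resampling is out of scope).
Target expansion uses the voxel-center criterion: a voxel is in the expanded
target iff its center lies within the margin (Euclidean, in mm, per-axis
anisotropic spacing honoured) of some voxel center of the input mask,
implemented with an exact Euclidean distance transform. Expansion is fully
3-D and isotropic in physical space. The elective target PTV_5425 is unioned
with the boost target PTV_7000 at load time so "inside 54.25 Gy volume,
outside 70 Gy volume" is well defined for exclusive-ring inputs. Overlap
percentages are voxel counts (uniform voxel volume); sub-voxel accuracy is a
grid-resolution question, not a modelling one. A useful discrete-geometry
fact: two-step expansion by margins *a* then *b* is contained in (not equal
to, not a superset of) one-step expansion by *a + b*, because the triangle
inequality only bounds the two-step distance from above; both contain the
expansion by max(*a*, *b*). Overlap features are invariant to padding the grid
with empty space.

**Dose models.** Per OAR o, modality t and margin m:

D̄(o,t) = β₀ + β₁·pct_in70(o,m) + β₂·pct_in54_out70(o,m) + ε,  ε ~ N(0, σ²)

fitted by OLS. R² is in-sample (apparent); no cross-validation is applied
since margin selection mimics the original screening procedure. The residual
SD uses the n−3 denominator (three estimated parameters); coefficient 95% CIs
are t-based. Degenerate inputs are errors, not silent numbers: a
zero-variance response (R² undefined) and a rank-deficient design each raise
a typed error naming the OAR/margin cell, and the grid fit records such
failures per cell without aborting the remaining cells. Margin selection
takes the highest-R² cell per OAR/modality; exact ties break to the smallest
margin (cheapest geometry). Predictions are clamped to [0, 70] Gy — 70 Gy is
the boost prescription and a physical ceiling for a mean dose in this
schedule; negative linear predictions floor at 0.

**Post-hoc adjustments.** Three ways to shift the operating point toward
sensitivity: (1) `rescale` multiplies predicted doses by a factor (e.g. 0.85
on IMPT); (2) `ci_bound` re-predicts with the chosen 95% CI bound of *all
three* coefficients simultaneously (lower for IMPT, upper for VMAT) — the
intercept is included because the prediction bound, not a slope-only bound,
is what drives the decision; (3) `sd_shift` subtracts k·σ̂ from predicted
doses (per-model σ̂ by default; a pooled σ̂ over the selected models —
√(Σ SSR / Σ df) — is available by configuration), clamped at 0 Gy. Each can
be restricted to a subset of OARs (e.g. salivary glands only).

**NTCP and decision rule.** Four logistic models (grade ≥2/≥3 dysphagia and
xerostomia), each NTCP = 1/(1+e^(−S)) with S = intercept + Σ β_o·D̄_o +
baseline-complaint term. Model coefficients are configuration (the clinical
protocol models are not re-derived here); a clearly-labelled synthetic
fixture set ships for testing. ΔNTCP = 100·(NTCP_VMAT − NTCP_IMPT) percentage
points; negative values are preserved and can never satisfy a criterion.
Default thresholds: single grade ≥2 ≥ 10; single grade ≥3 ≥ 5; summed
grade ≥2 ≥ 15 with a per-endpoint minimum of 5; summed grade ≥3 ≥ 5 with a
per-endpoint minimum of 3.75. All comparisons are inclusive (≥). The
per-endpoint minimum is read as a *contribution filter*: an endpoint below
the minimum does not count toward the sum. The alternative reading (both
endpoints must pass the minimum for the summed criterion to be evaluable)
yields identical decision boundaries for the boundary sweeps we verify, but
the contribution-filter reading keeps the grade ≥3 summed criterion
non-vacuous when one endpoint is negative.

**Missing organs.** A surgically absent OAR is carried as an explicit flag
and propagates as NaN through prediction. At the NTCP stage the default
policy is to abort with a typed error; an opt-in `impute_zero` policy
substitutes 0 Gy and records an audit warning — imputing zero dose biases
NTCP downward for that model and should be a conscious choice.

**Comparison modes.** `predicted` compares predicted VMAT vs. predicted IMPT
(pure delineation-only operation); `hybrid` substitutes an existing clinical
VMAT plan's doses on the photon side, leaving the proton side predicted — for
referring centers that already hold a VMAT plan, and strictly more accurate
because the VMAT prediction is the larger error source.

**Evaluation.** Positive class is "qualifies for PT". Sensitivity,
specificity, PPV, NPV and accuracy come with 95% CIs — Wilson score by
default (well-behaved at extreme proportions), Clopper–Pearson by flag; the
choice is a convention, both are exposed. Measures with a zero denominator
are reported as undefined, never as 0. Subgroup robustness splits the cohort
in half by treatment order (n//2 and n−n//2; a learning-curve check) or by
tumor location, flagging subgroup values outside the whole-cohort CI.
Calibration of continuous predictions reports the squared Pearson correlation
between predicted and actual (a regression-R² variant is available by flag)
and residual (predicted − actual) mean and SD.

## The synthetic generator

Two tiers share one generative dose model.

*Voxel phantoms* rasterize axis-aligned ellipsoids (voxel-center-inside test)
for two nested targets and up to eight OARs, with validation that structures
fit inside the grid and that the boost target is contained in the elective
target. They exercise mask I/O, expansion and feature extraction end to end.

*Feature-level cohorts* skip voxels entirely. Per patient and OAR a latent
organ–target distance d₇₀ is drawn (per-OAR mean, SD 7 mm, plus a
patient-level extent shift with SD 10 mm shared across OARs, plus a
tumor-location shift — laryngeal tumors sit far from the salivary glands and
close to the inferior constrictor). Containment follows a probit curve in
the margin: pct_in70(m) = 100·A·Φ((m − d₇₀)/s) with width s = 5 mm and
amplitude A ~ U(0.7, 1); the elective target reaches the organ a gap
~ U(2, 6) mm earlier, which makes pct_in70 non-decreasing in margin and
pct_in70 + pct_in54_out70 ≤ 100 by construction. Actual planned doses are the
true linear model at the true margin (VMAT: margin 10 mm, slope 0.52/0.36
Gy/%, residual SD 2.5 Gy; IMPT: margin 5 mm, slope 0.62/0.40, residual SD
1.5 Gy; photon intercepts 3.6–7.6 Gy above ~1.5–4 Gy proton intercepts) plus
homoscedastic Gaussian noise, clamped to [0, 70] Gy. Qualification labels are
computed by running the NTCP models and threshold rule on the actual doses.
Baseline complaint levels and tumor locations are drawn from configurable
frequencies.

The defaults were chosen once to make the cohort realistic for this decision
problem — in particular a ≈70% PT qualification prevalence, matching reported
model-based-selection rates, achieved through the latent-distance
distribution (the gap between photon and proton plans is largest for organs
at intermediate distance, smallest for distant or fully engulfed organs) —
and are not tuned per experiment. Random-number consumption order is fixed
and documented in the module docstring so seeds are portable.

What the generator does *not* emulate: real contour shapes and inter-organ
spatial correlation beyond the shared patient shift, heteroscedastic or
skewed planning residuals, inter-planner variability, and any nonlinearity
in the dose–overlap relationship. Passing tests therefore demonstrate the
correctness and statistical behaviour of the machinery under the model's own
assumptions, not clinical performance on real patients.

## Numerical choices and problem sizes

- Distance-criterion tolerance: 1 µm absolute slack on the margin comparison,
  guarding float ties at exactly-margin distances; far below any voxel size.
- OLS via statsmodels; normal-equation agreement is asserted to 1e-8 relative
  in tests.
- Exhaustive decision-rule verification uses a 21⁴-point grid (step 1.25 over
  [0, 25]⁴, crossing every threshold boundary) plus dense ±0.05 probes around
  each configured threshold, checked against an independent brute-force
  enumerator of the four criteria.
- Recovery tests use cohorts of n = 151: in the noiseless limit the margin
  grid must recover the true margins and coefficients to 1e-8 and end-to-end
  decisions must equal the generative labels exactly; with the configured
  noise, 95% CI coverage of the true coefficients is checked over 200
  replicates against a binomial band.
- CLI floating-point output is printed at 6 significant digits so repeated
  runs are byte-identical.

## Known limitations

- Apparent (in-sample) R² for margin selection can favour overfit margins on
  small cohorts; the original procedure is mirrored deliberately.
- The linear dose–overlap model cannot represent saturation near full
  containment; clamping handles the extremes crudely.
- Resampling masks to a shared grid, DICOM RTSTRUCT rasterization and any
  actual dose computation are out of scope.
- The decision rule is exactly the configured protocol; institutions with
  different thresholds must supply their own `ThresholdConfig` and NTCP
  coefficients, and dose models must be refit on local planning data before
  any clinical use.
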