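# Methods

This note documents the statistical procedures implemented in `braindex`,
the modelling choices made where the design was genuinely open, and what the
synthetic-data results do and do not establish.

## Harmonization: from raw phenotypes to deviation scores

Each regional phenotype is regressed (OLS, per phenotype, intercept always
included) on a covariate set — age in years, sex coded 0/1, and intracranial
volume (ICV) by default — and the residuals are mapped through a rank-based
inverse-normal transformation: the value with (tie-averaged) rank *r* among
*n* non-missing entries becomes Φ⁻¹((r − c)/(n − 2c + 1)) with the Blom
constant c = 3/8. The result is a per-subject deviation vector with
approximately N(0, 1) marginals regardless of the raw phenotype
distributions. Missing entries stay missing at every step; nothing is
imputed.

Open choices, and how they were resolved:

* **Reference sample.** Default: regression coefficients and ranks use the
  whole sample, matching the behaviour of the established regional
  vulnerability index implementations. A `reference="controls"` mode
  estimates coefficients on controls only, Blom-transforms the control
  residuals, and maps everyone else through the control empirical
  distribution by linear interpolation (clamped at the control extremes).
  The flag makes an ambiguity in the construct's verbal definition explicit
  rather than hiding it.
* **ICV scope.** ICV is regressed from all tissue classes by default;
  `icv_tissues=` restricts it (e.g. to volumes only), the common alternative
  convention.
* **Rank variant and ties.** Blom offset with average ranks: deterministic,
  symmetric, standard in the heritability literature. An all-tied column maps
  to zeros with a warning.
* **Signed deviations.** The deviation magnitude |Z| measures how atypical a
  subject is, but the signed Z is what enters the dot product downstream; an
  absolute-value variant would change the index and is deliberately not
  offered.

Note that residualization is estimated, so a covariate-free column's ranks
can be perturbed at the margin by noise-level fitted coefficients; rank
preservation is exact only for the transform itself and for affine
covariate rescalings.

## ENIGMA Dot Product

EDP = (1/N) Σᵢ Pᵢ·Eᵢ over the phenotypes shared between the deviation matrix
and the effect vector. With missingness, the sum runs over the subject's
available phenotypes and N is their count — per-subject renormalization
keeps the scale comparable across subjects at the cost of a slightly
different variance for incomplete profiles. The effect vector is an input
(two-column TSV), not a bundled constant: the published meta-analytic values
are not redistributable here, and the synthetic pipeline plants its own.
EDP is reported raw; z-scaling for group plots happens in the analysis stage
so the defining formula stays pure. Whole-brain comparison biomarkers are the
per-tissue means of the deviation columns (thickness, subcortical volume,
FA).

## Quantile Regression Index

For each phenotype, `value ~ intercept + slope·age` is fitted by minimizing
the check loss ρ_τ(u) = u·(τ − 1{u<0}) at τ = 0.05, 0.50, 0.95 over the
whole sample. The minimization is solved exactly as a linear program. The
implementation solves the dual (max y'ν s.t. X'ν = 0, τ−1 ≤ ν ≤ τ), whose
two equality-constraint marginals recover −(intercept, slope) of the primal
vertex solution; inputs are standardized internally for conditioning
(quantile regression is affine-equivariant, so the solution maps back
exactly), and a primal-formulation fallback guards the rare solver failure.
Constant response short-circuits to (c, 0). The solution is deterministic
given input order; for degenerate data with a non-unique optimum the solver
vertex is returned rather than an enumerated canonical one.

Scoring is strict: value **<** predicted 5th percentile → +1 (older than
expected — all phenotypes in the panel decline with age); value **>**
predicted 95th percentile → −1; boundary equality → 0. Crossed quantile
lines (5th above 95th at some age) are possible since no non-crossing device
is imposed; they are scored by the same rules and logged with phenotype and
age range. Tissue QRIs are means of region scores; the whole-brain QRI is the
unweighted mean of the three tissue QRIs (missing if any tissue has no scored
region). Fits use age only by default; `stratify_by_sex=True` fits and scores
within sex strata, covering the plausible alternative convention.

Under a pure aging-plus-noise null the scoring rule is calibrated by
construction: ~5% of region scores are +1 and ~5% are −1 (in-sample coverage
of an exact τ-quantile fit deviates from τ only by O(p/n)), and the
whole-brain QRI averages to ~0. `scripts/acceptance.py` recomputes this.

## Group-severity analysis

Biomarkers are residualized on age and sex over the cohort, z-scaled, then
averaged per group with standard errors. The 4-point correlation between
group-mean severity and group-mean biomarker is reported as signed r and r²
with an explicit df = 2 caveat and no p-value — four points support
description, not inference. Individual symptom correlations pool the three
depression groups by default (a flag includes controls); t and p come from
the exact t-distribution with n − 2 df, and every reported (r, t, p) triple
satisfies t = r√(n−2)/√(1−r²) identically. A constant biomarker is reported
as zero z-scores with a warning (detected against the input's value scale,
since OLS leaves ~1e-15 rounding noise in a constant column's residuals).

## Cognition pattern analysis

The deficit profile is the per-test pooled-variance two-sample t of the
pooled depression groups versus controls on age/sex-corrected scores,
oriented so worse case performance is positive. Model-1 profiles regress
each corrected cognitive score on a corrected biomarker within controls or
within the pooled cases; the slope t (identical to the correlation t in
simple regression) is reported with a **deficit-sign convention**: the sign
is flipped so that "higher biomarker accompanies worse performance" is
positive, matching the deficit profile's orientation. Consequence:
vulnerability-directed indices (EDP, QRI) correlate positively with the
deficit pattern when coupled, while integrity-directed biomarkers (mean
thickness, volume, FA — higher is healthier) correlate negatively;
`deficit_sign=False` gives the raw slope t.

Profile comparison reports the Pearson correlation of two 9-long t-vectors
(df = 7, annotated — mechanical inference at this n is fragile), each
profile's mean ± SD of |t|, and a two-sided paired t-test across tests on
|t| (magnitudes, since association strength is the quantity of interest; a
flag pairs signed t). Identical profiles give a degenerate flag with
paired p = 1.

## Synthetic cohort generator

The generator emulates the statistical structure of a large middle-to-older
aged epidemiological imaging cohort with four depression groups:

* **Phenotypes** (33 thickness + 24 FA + 7 subcortical volume, bilateral
  averages, realistic per-class baselines): value = baseline + age·β_age +
  sex·β_sex + ICV·β_icv + deficit_scale·severity·Eᵢ + ε, ε ~ N(0, noise_sd).
  Default covariate slopes move each phenotype by a substantial fraction of
  the unit noise SD across the realistic covariate ranges (ages uniform on
  45–80; ICV log-normal, ~1.5×10⁶ mm³ with 8% CV), so residualization has
  real work to do.
* **Severity** is continuous: group mean (defaults 0.3 / 1.2 / 2.0 / 3.0 on
  the 0–4 scale) + N(0, 0.5) jitter, clipped to [0, 4] — continuous so that
  individual-level symptom correlations are exercisable, not just group
  contrasts.
* **Effect vector**: 64 signed effects, 90% negative (deficits), magnitudes
  uniform on [0.03, 0.25] — the small, heterogeneous, predominantly negative
  regime of large psychiatric meta-analyses. Drawn once from a fixed internal
  stream, so it is a reproducible package constant independent of the cohort
  seed.
* **Cognition**: each test score is −coupling·v + N(0, 1), where v is the
  subject's *realized deficit alignment* (1/N)Σ(plant + noise)ᵢ·Eᵢ,
  standardized across the cohort so couplings are in SD units. Coupling the
  realized alignment rather than the group label is what makes controls carry
  a cognition–vulnerability association — the property the pattern analysis
  is designed to detect. Defaults: coupling 0.25 in Matrix, ReactionTime and
  FluidIntelligence; 0 elsewhere.
* **Determinism**: one `numpy` Generator seeded from the config; identical
  configs give bit-identical cohorts, and the seed is written into every
  output file header plus a manifest with the config hash.

Default scale is 2000 subjects per group — large enough that the planted
gradient and the 3-of-9 cognition pattern are recovered in ≥ 90% of seeds
while a full pipeline run stays in the tens of seconds.

What the generator does **not** emulate: site/scanner effects, non-linear
aging, phenotype-phenotype residual correlations (regions are independent
given the latent severity), non-Gaussian measurement error, missing data
mechanisms, ordinal symptom items, or diagnostic misclassification. Passing
tests therefore show that the estimators recover the structure they assume,
with correct null calibration — not that real cohort effect sizes (which are
an order of magnitude weaker, e.g. individual severity correlations of
r ≈ 0.04) would be detected.

## Numerical and reporting choices

* OLS via `numpy.linalg.lstsq`; rank-deficient covariate designs are
  rejected with the offending covariate named.
* p-values floored at the smallest positive double instead of 0, so
  log-transforms stay finite; perfect fits report infinite t without
  overflow.
* Tables are written as TSV with `%.10g` floats and a `# seed=` header;
  reruns with the same configuration are bit-identical. The pipeline
  configuration hash excludes the output directory and log level.
* Pipeline stages read their inputs from the run directory, so any
  downstream stage can be resumed from disk without recomputation.

## Known limitations

* The quantile-regression tie-break for degenerate optima is the solver's
  vertex choice (deterministic given input order), not a canonical
  enumeration of the optimal face.
* The controls-referenced transform clamps out-of-range cases at the extreme
  control quantiles, compressing the tails when cases deviate far beyond the
  control range.
* The 4-point group-mean correlation and 9-point pattern correlation are
  reported with df annotations but remain descriptive statistics on tiny
  supports.
* No site harmonization, no nonlinear age terms, and no multiple-comparison
  machinery beyond raw p-values — matching the analysis design the package
  implements, not general best practice for new studies.
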