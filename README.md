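# braindex

Individual-level brain structural vulnerability and brain-aging indices from
tabular regional neuroimaging phenotypes, with the group-severity and
cognition pattern-matching analyses built on top of them.

Large neuroimaging consortia publish *group-level* regional deficit patterns
for psychiatric disorders — e.g. the pattern of cortical thinning, white-matter
fractional-anisotropy (FA) reduction and subcortical volume loss seen in major
depressive disorder (MDD). `braindex` translates such a pattern to the
*individual*: it scores how similar one person's brain is to the published
deficit pattern, and compares that score's behaviour against a normative
brain-aging index and simple whole-brain averages. It is aimed at researchers
working with derived ROI tables (cortical thickness, subcortical volumes,
tract-wise FA) from epidemiological imaging cohorts.

## The indices

**ENIGMA Dot Product (EDP).** Each subject's regional phenotypes are
residualized for age, sex and intracranial volume, and the residuals are
mapped through a rank-based inverse-normal (Blom) transformation, giving a
deviation vector *P* with approximately standard-normal components. Given a
meta-analytic signed effect-size vector *E* over the same N phenotypes
(deficits negative), the index is the normalized dot product

    EDP = (1/N) * Σᵢ Pᵢ · Eᵢ

Deviation *in the deficit direction* (Pᵢ and Eᵢ of the same sign) increases
the score, so higher EDP = greater resemblance to the disorder pattern.

**Quantile Regression Index (QRI).** A linear analog of the "brain age"
construct. For every phenotype, quantile regressions of the value on age are
fitted at the 5th, 50th and 95th percentiles over the whole sample (solved
exactly as a linear program). A subject's regional value below the fitted 5th
percentile line for their age scores **+1** (structure "older" than
expected), above the 95th scores **−1**, otherwise **0**. Regional scores are
averaged within tissue class, and the whole-brain QRI is the mean of the
three tissue QRIs, so all QRIs lie in [−1, 1].

**Analyses.** Group-mean biomarker profiles across the four cohort groups
(control, subclinical, single-episode, recurrent) versus group-mean symptom
severity; individual biomarker–severity correlations (r, t, p); the
per-cognitive-test case-control deficit t-profile; per-test
biomarker→cognition regression t-profiles ("model 1"); and pattern
correlations between profiles with paired mean-|t| comparisons.

Because real cohort data of this kind are access-controlled, the package
ships a first-class synthetic cohort generator that plants a severity-graded
deficit along the effect vector and couples cognition to each subject's
realized deficit alignment, so every stage is testable end to end.

## Worked example

```python
import numpy as np
import braindex as bx

cohort = bx.simulate_cohort(bx.CohortConfig(seed=42))   # 2000 per group
z = bx.harmonize(cohort.phenotypes, cohort.covariates)  # P vectors
edp = bx.compute_edp(z, cohort.effect_vector)

print(edp.groupby(cohort.labels["group"]).mean().loc[list(bx.GROUPS)].round(4))
```

```
control       -0.0142
subclinical   -0.0057
single         0.0040
recurrent      0.0160
```

The group-mean EDP rises strictly from controls to recurrent cases, mirroring
the planted severity gradient; across the four (mean severity, mean EDP)
points the correlation is r² = 0.998, and within the pooled depression groups
the individual EDP–severity correlation is r = 0.489 (t = 43.5, n = 6000).

```python
deficit = bx.cognitive_deficit_profile(cohort.cognition, cohort.labels,
                                       cohort.covariates)
prof = bx.biomarker_cognition_profile(edp, cohort.cognition, cohort.labels,
                                      cohort.covariates, subset="controls")
cmp = bx.compare_profiles(prof, deficit)
print(f"pattern_r={cmp.pattern_r:.2f}  mean|t|={cmp.mean_abs_t_a:.1f}")
```

```
pattern_r=0.97  mean|t|=3.9
```

The three tests carrying a planted deficit (Matrix, ReactionTime,
FluidIntelligence; deficit t = 7.4, 9.5, 8.0 versus |t| ≤ 1.3 elsewhere)
dominate both profiles: the EDP–cognition association pattern *in controls*
matches the case-control deficit pattern (pattern_r = 0.97), and EDP carries
more association strength than whole-brain mean thickness (mean |t| 3.9 vs
2.4) — the qualitative signature the indices are designed to expose.

The same run end to end, from a shell:

```bash
braindex all --seed 42 --outdir out/       # all stages + report.json + figures
braindex simulate --seed 42 --outdir out/  # or stage by stage
```

`out/report.json` records the configuration hash, seed, versions, collected
warnings and all headline statistics; tables are TSV with a seed header.
An effect-size vector for real data is supplied as a two-column TSV (see
`examples/effect_vector_template.tsv`); the synthetic pipeline uses its own
planted vector.

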