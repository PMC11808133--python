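# exposcan

Exposure-wide survival analysis for chronic-disease epidemiology: an
end-to-end pipeline that screens hundreds of baseline exposures against a
time-to-event outcome with Cox proportional-hazards models, builds
composite per-domain risk scores from the surviving factors, crosses them
with a polygenic risk score, estimates mediation through blood biomarkers,
runs two-sample Mendelian randomization, and quantifies the preventable
disease burden as PCA-weighted population attributable fractions. A
synthetic-cohort generator with exact ground truth makes the whole chain
reproducible and testable without access to any real cohort.

The intended users are epidemiologists and biostatisticians who want a
tested, scriptable implementation of this analysis family — the kind of
study that takes a biobank of ~10⁵–10⁶ participants with hundreds of
phenotype fields and asks *which modifiable factors are associated with
incident disease, how do they combine, and how much disease would their
removal prevent?*

## The statistics in brief

* **Exposure-wide scan.** For each modifiable variable X, a Cox model
  `h(t) = h₀(t)·exp(βX + γ'Z)` adjusted for age, sex and assessment
  center; significance at the Bonferroni threshold α/m (0.05/255 =
  1.96×10⁻⁴ in the motivating setting). The proportional-hazards
  assumption is tested via scaled Schoenfeld residuals
  (Grambsch–Therneau, Kaplan–Meier time transform); violators are refit
  with an X × log(t) interaction. Significant hits with pairwise r² > 0.9
  are pruned, keeping the smaller p-value.
* **Domain risk scores.** Protective factors are recoded as risks
  (HR < 1 → complement); each domain's factors enter one multivariable
  Cox fit, and the weighted score is S = Σ X_k β_k / Σ β_k ∈ [0, 1],
  cut into favorable / moderate / unfavorable tertiles.
* **Gene–environment.** Participants are cross-classified by polygenic
  score tertile × score tertile (nine groups) and modelled against the
  low-genetic-risk / favorable reference, plus within-stratum contrasts.
* **Polygenic score.** PRS_j = (Σ_i β_i G_ij − mean)/SD.
* **Mendelian randomization.** Instruments at p < 5×10⁻⁸ (5×10⁻⁶
  fallback); inverse-variance-weighted, weighted-median and MR-Egger
  estimators with Cochran's Q and the Egger intercept as diagnostics.
* **Mediation.** Difference method: mediation = total − direct, with
  percentile-bootstrap confidence intervals.
* **Attributable fractions.** Levin's formula
  PAF = P(HR−1)/(P(HR−1)+1) per domain under a conservative
  (unfavorable-only) and an optimistic (unfavorable + moderate)
  counterfactual, weighted by √communality from a PCA of the domain
  scores, and summed (after rounding each to two decimals) into an
  overall PAF.

See `docs/methods.md` for conventions, defaults and validation limits.

## Worked example

Run the bundled demo profile (5,000 participants, 21 variables across
seven domains, ten planted effects) end to end:

```bash
exposcan --outdir demo_run --seed 7 run-all
```

which prints:

```
generated cohort: 5000 participants, 1014 events
preprocessed: 4992 participants kept, 8 removed, 0 variables dropped
scan: 11 of 21 variables significant at p < 0.00238 (8 adverse, 3 protective)
scores built for domains: socioeconomic_status, medical_history, psychosocial, physical_measures, lifestyle
gene-environment grids written for 5 domains
mediation table: 30 rows
MR: IVW estimate 0.3725 (se 0.0338)
overall weighted PAF (model 1): 37.93%
overall weighted PAF (model 2): 60.28%
```

Reading the output: the scan recovers 11 significant factors at the
Bonferroni threshold 0.05/21 ≈ 2.4×10⁻³ — the ten planted effects plus
one null variable dragged to marginal significance by the within-domain
correlation (ρ = 0.2) with its two truly causal neighbors, exactly the
behavior a marginal exposure scan exhibits on correlated phenotypes.
The MR stage recovers the simulated causal effect 0.4 within one standard
error (0.3725 ± 0.0338). The PAF table (`demo_run/paf.csv`) then reports,
for example under the conservative counterfactual:

```
domain                p_pop    hr      unweighted_paf  communality  weighted_paf
medical_history       0.279    1.776   17.77           0.330        10.21
psychosocial          0.292    1.423   11.01           0.490         7.70
...
overall                                                             37.93
```

i.e. 27.9% of participants sit in the unfavorable medical-history
tertile with a fitted hazard ratio of 1.78 versus everyone else, giving
an unweighted PAF of 17.8%, down-weighted to 10.2% by the domain's PCA
communality (0.33). The planted effects in the demo are deliberately
strong, so these PAFs are larger than those seen in observational
cohorts. Every stage writes plain CSV/JSON plus a manifest of config
hash, seed and row counts; rerunning the same config reproduces the
outputs byte for byte.

The same stages are available individually (`generate`, `preprocess`,
`ewas`, `scores`, `gxe`, `mediate`, `mr`, `paf`) and as library functions
(`exposcan.ewas.run_scan`, `exposcan.paf.paf_report`, ...).

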