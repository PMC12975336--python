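# drugmr

Drug-target Mendelian randomization (MR) from GWAS summary statistics:
correlated-instrument IVW/Egger/MVMR, cross-ancestry fixed-effect
meta-analysis, product-of-coefficients mediation, approximate-Bayes-factor
colocalization, SMR/HEIDI/GSMR, analytic MR power, and a synthetic
two-sample GWAS generator with known ground truth.

## Who this is for

Genetic epidemiologists asking what modulating a drug target does to
downstream biology. The motivating use case: variants in the gene encoding a
drug's protein target (e.g. *HMGCR* for statins) proxy pharmacological
modulation; two-sample MR against disease outcomes (e.g. type 2 diabetes)
and omics panels (gut microbial taxa, metabolites, circulating proteins)
then screens for causally downstream signatures, with colocalization and
HEIDI separating shared causal variants from linkage, and mediation
quantifying how much of the drug-outcome effect flows through a molecular
intermediate.

## The statistics

Instruments are variants within ±1000 kb of the target gene's transcription
start site with exposure *P* < 1×10⁻⁸, greedily clumped at *r*² < 0.3
against a reference-panel LD matrix; exposure effects are rescaled to a
1-SD *decrease* of the exposure (the pharmacological direction). Because
cis instruments are correlated, estimators weight by the inverse of
Ω = D ρ D, where ρ is the LD correlation and D = diag(σ_Y):

- **IVW**: θ̂ = (β_Xᵀ Ω⁻¹ β_Y) / (β_Xᵀ Ω⁻¹ β_X), SE = (β_Xᵀ Ω⁻¹ β_X)^(−1/2),
  optionally inflated by max(1, √(Q/(n−1))) (multiplicative random effects).
- **MR-Egger**: GLS of β_Y on (1, β_X) after orienting β_X ≥ 0; the
  intercept tests directional pleiotropy.
- **MVMR**: θ̂ = (B_Xᵀ Ω⁻¹ B_X)⁻¹ B_Xᵀ Ω⁻¹ β_Y for several exposures jointly.
- **Cochran's Q**: (β_Y − θβ_X)ᵀ Ω⁻¹ (β_Y − θβ_X) ~ χ²(n−1).
- **Meta-analysis**: fixed-effect inverse-variance pooling of per-ancestry
  log-ORs; FDR (Benjamini–Hochberg) within feature families.
- **Mediation**: indirect = α·β with SE √(α²σ_β² + β²σ_α² − σ_α²σ_β²);
  proportion mediated = indirect / total.
- **Coloc**: Wakefield log-ABFs, priors p1 = p2 = 1×10⁻⁴, p12 = 1×10⁻⁵;
  colocalized iff PP₄ > 0.7.
- **SMR/HEIDI**: T_SMR = z_X²z_Y²/(z_X² + z_Y²) ~ χ²₁; multi-SNP SMR and
  HEIDI refer sums of dependent statistics to weighted-χ² nulls via
  Satterthwaite matching; HEIDI *P* > 0.05 is consistent with one shared
  causal variant.
- **GSMR**: correlated IVW with iterative heterogeneity-outlier removal
  (reverse MR of disease on molecular traits, instruments clumped at
  *r*² < 0.05, *P* < 5×10⁻⁸).
- **Power**: Φ(√NCP − z_{1−α/2}) + Φ(−√NCP − z_{1−α/2}) with
  NCP = n·r²·K(1−K)·effect².

## Worked example

Two ancestry-specific MR estimates of a fatty-acid exposure on type 2
diabetes — OR 1.29 (95% CI 1.07–1.55) and OR 2.28 (1.51–3.44) — pooled by
fixed-effect meta-analysis on the log-odds scale:

```bash
drugmr meta --odds-ratio 1.29,1.07,1.55 --odds-ratio 2.28,1.51,3.44
```

```json
{
 "theta_meta": 0.3505870742786861,
 "se_meta": 0.086211251566304,
 "pvalue": 4.770307403230727e-05,
 "odds_ratio": 1.4199008912438376,
 "or_ci_low": 1.1991537801341685,
 "or_ci_high": 1.6812843976770588,
 "i_squared": 0.8364294261043993
}
```

The pooled OR is 1.42 (1.20–1.68): both cohorts point the same way, and the
I² of 0.84 reflects the stronger European estimate. The SEs are
reconstructed from the CIs as (ln U − ln L)/(2·1.959964).

Minimum detectable effect at 80% power for a binary outcome
(n = 50,000, 10% cases, instrument r² = 1%):

```bash
drugmr power --n-outcome 50000 --case-fraction 0.1 --r2 0.01
```

```json
{
 "log_or": 0.41763535600749213,
 "odds_ratio": 1.518366910072777,
 "feasible": true
}
```

i.e. the design can detect an OR of about 1.52 per SD of exposure.

An end-to-end simulated screen (instrument selection → IVW/Egger →
cross-ancestry meta → FDR → mediation → coloc/SMR/HEIDI) runs from a YAML
config:

```bash
drugmr screen --config examples/screen.yaml --out results/screen
```

See `python -m drugmr.cli --help` (or `drugmr --help`) for the full
subcommand list: simulate, harmonize, clump, mr, meta, mediate, coloc, smr,
gsmr, power, screen.

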