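# Methods

## Model and assumptions

The package implements two-sample summary-data Mendelian randomization for
drug-target questions. The causal diagram is: genetic variants G in a
drug-target gene region → exposure X (e.g. LDL-C, unit variance) →
outcome Y (disease liability) and molecular mediators M on the X→Y path.
All estimators consume marginal per-variant associations (β̂, σ) estimated
in *disjoint* cohorts for X, M and Y (the two/three-sample assumption,
which removes sample-overlap bias), plus an LD correlation matrix from a
reference panel of the matching ancestry.

Core assumptions, stated once and relied on throughout:

- **Instrument validity.** Variants affect Y only through X (and M). The
  screen additionally removes instruments with genome-wide-significant
  outcome associations (P < 5×10⁻⁸) as a pleiotropy guard; the MR-Egger
  intercept tests directional pleiotropy; GSMR removes heterogeneity
  outliers. This filter is *not* applied when re-estimating the total
  effect inside mediation: there, instrument–outcome association is exactly
  what the causal model predicts, and filtering on it would select against
  the signal being measured.
- **NOME (no measurement error in the exposure).** GLS weights
  Ω = D ρ D use outcome SEs only. With strong cis instruments the
  exposure-side noise is a few percent; its neglect makes CIs slightly
  anticonservative (measured 95% CI coverage ≈ 0.92–0.95 in the
  recovery study below — a known property of IVW, not a bug).
- **Single causal variant per trait per region** for coloc and HEIDI, as
  those methods require.

## Decision thresholds (defaults)

| parameter | default | role |
|---|---|---|
| instrument P | 1×10⁻⁸ | exposure significance for instrument entry |
| clumping r² | 0.3 | LD ceiling within the gene region (reverse MR: 0.05) |
| window | ±1,000,000 bp | cis window around the gene TSS |
| outcome P | 5×10⁻⁸ | screen-stage exclusion-restriction guard |
| coloc priors | p1 = p2 = 1×10⁻⁴, p12 = 1×10⁻⁵ | per-SNP causal-configuration priors |
| coloc effect prior SD | 0.15 (quantitative), 0.2 (binary log-odds) | Wakefield ABF scale |
| PP₄ rule | > 0.7 (strict) | colocalization call |
| HEIDI rule | P > 0.05 passes | single-shared-variant consistency |
| HEIDI eligibility | QTL P < 1.57×10⁻³, r² with top in [0.05, 0.9], ≤ 20 SNPs | |
| GSMR outlier P | 0.01 | per-instrument heterogeneity removal |
| FDR | 0.05, BH within feature family | multiplicity control |

"LD < 0.3" style thresholds are interpreted as r², the clumping convention;
both r and r² views are trivially interconvertible in config. Exposure
effects are rescaled to a 1-SD *decrease* (divide by the exposure SD, flip
signs) so estimates read as the effect of pharmacological lowering.

## Numerical choices

- **PSD conditioning.** Sample LD matrices from small panels (a few hundred
  reference individuals) are routinely indefinite after subsetting. Every
  matrix entering a solve is eigenvalue-floored at 1×10⁻¹⁰, rescaled to
  correlation form (which preserves semi-definiteness, unlike overwriting
  the diagonal), and re-symmetrized. A perfectly duplicated instrument pair
  therefore collapses gracefully to its single-SNP estimate instead of
  crashing the solve.
- **Clumping determinism.** Candidates sort by (p, chrom, pos); equal
  p-values break toward the smaller position, so output is independent of
  input row order.
- **Variance model.** IVW defaults to fixed-effect for ≤ 3 instruments and
  multiplicative random effects (SE × max(1, √(Q/(n−1)))) above that,
  matching common correlated-instrument practice; both are selectable.
- **Weighted-χ² tails** (multi-SNP SMR, HEIDI) use two-moment Satterthwaite
  matching: T ~ c·χ²(ν), c = Σλ²/Σλ, ν = (Σλ)²/Σλ², over eigenvalues λ of
  the relevant correlation matrix. Exact (Davies-type) inversion is out of
  scope; calibration simulations bound the approximation (HEIDI rejection
  0.04–0.06 at nominal 0.05).
- **HEIDI covariances.** b_i = β_Yi/β_Xi; var(b_i) = σ_Yi²/β_Xi² +
  b_top²·σ_Xi²/β_Xi²; cov(b_i, b_j) = ρ_ij(σ_Yiσ_Yj + b_top²σ_Xiσ_Xj)/(β_Xiβ_Xj);
  cov(d_i, d_j) assembled by the usual difference identity against the top
  QTL. These delta-method forms are validated by null calibration rather
  than external software.
- **Mediation SE.** The subtractive product-of-coefficients variance
  α²σ_β² + β²σ_α² − σ_α²σ_β² can go negative near α = β = 0 (it is the
  unbiased estimator of the product variance); the implementation then
  falls back to the first-order delta SE √(α²σ_β² + β²σ_α²) and sets a
  provenance flag. The subtractive SE ≤ first-order SE ≤ exact Monte-Carlo
  SD always, which the tests assert.
- **Palindromic variants** (A/T, C/G) are resolved by allele frequency:
  dropped when either frequency is missing or either MAF exceeds 0.42,
  otherwise oriented so the frequencies agree. Multi-allelic positions are
  dropped and logged.
- **CIs** use the normal quantile 1.959964 everywhere; ORs are
  exp-transforms at the reporting layer.

## The synthetic generator

`drugmr.simulate` emulates the statistical structure of a drug-target
multi-omics MR study with full ground truth:

- **Genotypes**: a latent Gaussian threshold model per haplotype gives
  Hardy–Weinberg-consistent 0/1/2 dosages with AR(1) or block LD. The
  realized dosage correlation is mildly attenuated relative to the latent
  target (tetrachoric attenuation); this is harmless because the analysis
  uses LD estimated from a simulated reference panel drawn from the same
  process — the system is self-consistent, as in real data.
- **Phenotypes**: X = Σγ_jG_j + ε scaled to ≈ unit SD; each mediator
  M = α·X + δᵀG + ε with its own causal variants (required for
  multivariable identification); outcome liability θ·X + Σβ_m·M_m + ε,
  returned as-is (quantitative) or dichotomized at the prevalence quantile
  (binary). Binary GWAS use vectorized per-variant logistic regression
  (log-odds scale) or a linear-probability shortcut rescaled by 1/(K(1−K))
  for large calibration suites; the two agree to high correlation at
  realistic effect sizes (tested).
- **Cohorts** for exposure, mediators and outcome are disjoint draws from
  named substreams of one master seed, so stages are independently
  reproducible and the two-sample assumption holds by construction.
- **Fast path**: large replicate studies draw marginal estimates directly
  from their asymptotic distribution β̂ ~ N(ρ·γ, σ²ρ/n) on the
  standardized-genotype scale; tests cross-check this against the
  individual-level generator.

What the generator does *not* emulate: realistic human LD maps, allele
frequency spectra, imputation uncertainty, population stratification,
sample overlap, or winner's-curse instrument selection. Passing tests
demonstrate correctness of the estimators under the stated model, not
robustness to those real-data pathologies.

## Reference studies (sizes chosen as package defaults)

- Null calibration: 10,000 replicates, 10 AR(1)-correlated instruments
  (ρ = 0.5, marginal effects ≈ 0.1 SD), n = 50,000 per arm. IVW type-I
  ≈ 0.05; generalized Q ≈ 0.05 under exact homogeneity (the Q null must
  hold the observed exposure effects fixed — with exposure-side noise Q is
  genuinely inflated, which is a property of the statistic, not the test
  bed).
- HEIDI: 2,000 replicates, 30-variant AR(1) region (ρ = 0.8), one causal
  variant with 5% exposure variance at n = 20,000, outcome n = 50,000.
- Recovery: θ = 0.35 over 1,000 replicates; |bias| ≪ 0.01,
  coverage ≈ 0.93–0.95 (see NOME note above).
- Mediation: 40 individual-level three-sample studies, n = 20,000 per
  cohort, two uncorrelated LD blocks (exposure genetics in one, mediator
  genetics in the other), planted proportion 25% (direct 0.3, α = 0.5,
  β = 0.2).
- Colocalization: 200 replicates per scenario, 100-variant AR(1) region,
  1% explained variance per trait, n = 20,000 per trait; distinct-variant
  scenarios enforce r² < 0.01 between the two causal variants.

## Known limitations

- No weighted-median/mode estimators, Steiger filtering or winner's-curse
  correction; no SuSiE-style multi-signal colocalization; no genome-wide
  clumping across chromosomes; no liftover.
- The power module's NCP approximation treats the MR test as a z-test with
  variance 1/(n·r²·K(1−K)); a two-sample logistic simulation oracle in the
  tests bounds its error at the few-percent level in the realistic regime.
- Reported per-variant p-values below ~1×10⁻³²⁰ are clamped to the smallest
  positive double.
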