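# Methods

## Model

`mrkit` performs two-sample summary-data Mendelian randomization. For
instrument j of J, the exposure GWAS supplies the per-allele effect
γ̂ⱼ ~ N(γⱼ, σ²_Xⱼ) and the outcome GWAS supplies Γ̂ⱼ ~ N(Γⱼ, σ²_Yⱼ), with
the two noise terms independent because the samples do not overlap. The
working model is

    Γⱼ = β γⱼ + αⱼ

where β is the causal effect of the exposure on the outcome (log-odds scale
for binary traits, raw units otherwise) and αⱼ is the horizontal-pleiotropy
contribution of instrument j. All estimators consume the harmonized
quadruples (γ̂ⱼ, σ_Xⱼ, Γ̂ⱼ, σ_Yⱼ); exponentiation to odds ratios happens
only at reporting time, controlled by the outcome's `trait_type`.

## Instrument processing

**Variant filter.** Only biallelic single-base (A/C/G/T) variants with an
rs-number identifier enter the analysis; indels, ambiguous allele strings
and positional identifiers are dropped with per-rule counts. The filter is
idempotent.

**Selection and clumping.** Candidates need P < 5×10⁻⁸ against the
exposure (the conventional genome-wide bar; a relaxed 5×10⁻⁶ is provided
for rare outcomes that lack genome-wide hits). Greedy clumping consumes
candidates in ascending p-value order, keeping a variant iff its r² with
every already-kept variant is below 0.001; this reproduces the dominance
convention of standard clumping tools and equals the lexicographically
first maximal independent set in that order. LD comes from a local pairwise
r² table; absent pairs read as r² = 0, self-pairs as 1.

**Proxies.** An instrument missing from the outcome GWAS may be replaced by
the outcome-present variant with the highest r² ≥ 0.8 (ties: smaller
outcome p-value, then lexicographic rsid). The proxy's effect estimate is
used as-is, without rescaling by r²: with r² this high the attenuation is
below the estimates' own noise, and the substitution is recorded in the
audit trail so users can inspect it.

**Harmonization.** Outcome records are aligned onto the exposure's effect
allele: direct match kept; swapped alleles negate the outcome beta and
complement its EAF; strand complements (A↔T, C↔G) are resolved and then
treated the same way. Palindromic A/T and C/G variants cannot be resolved
from allele labels, so they are aligned purely by effect-allele frequency —
both EAFs on the same side of 0.5 count as concordant, opposite sides
negate the outcome beta — and only when the minor-allele frequency is
≤ 0.42 in *both* samples (the conservative reading; a config switch
`palindrome_maf_both_samples=False` checks the exposure only). Palindromes
with a missing EAF on either side are dropped, since frequency alignment is
undefined without it. Every input instrument receives exactly one audit
action (`kept`, `allele_flipped`, `proxy_substituted`, `dropped_*`), so the
audit partitions the input.

**Instrument strength.** The mean per-SNP approximate F-statistic
(1/J) Σ (γ̂ⱼ/σ_Xⱼ)², with F > 10 as the conventional adequacy bar. Note
E[(γ̂/σ_X)²] = (γ/σ_X)² + 1, which the generator's calibration accounts
for.

## Estimators

**IVW with multiplicative random effects** (primary). The inverse-variance
weighted mean of the Wald ratios with first-order weights wⱼ = γ̂ⱼ²/σ²_Yⱼ,
algebraically the weighted regression of Γ̂ on γ̂ through the origin with
weights σ_Yⱼ⁻². Cochran's Q uses the same weights; the overdispersion
φ̂ = Q/(J−1) multiplies the squared fixed-effect SE but is floored at 1, so
heterogeneity can widen the CI but never shrink it below the fixed-effect
value. CIs and p-values use normal quantiles. J = 1 degrades to the Wald
ratio with a warning.

**Weighted median.** Order the Wald ratios, normalize the first-order
weights, and interpolate the cumulative-midpoint curve sⱼ = Σ_{k≤j}w_k −
wⱼ/2 at s = 0.5. Consistent when valid instruments carry ≥ 50% of the
weight. The SE comes from a parametric bootstrap (default 1000 replicates)
that redraws γ̂* and Γ̂* from their sampling distributions independently;
the bootstrap generator is always explicitly seeded.

**MR-Egger.** Weighted regression of Γ̂ on γ̂ *with* intercept after
orienting every SNP to γ̂ⱼ ≥ 0 (a stateless sign convention equivalent to
effect-allele recoding). The slope estimates β under InSIDE (pleiotropy
independent of instrument strength); the intercept estimates the mean
directional pleiotropy, with intercept P < 0.05 read as evidence of
pleiotropy. Coefficient SEs carry a multiplicative overdispersion
max(1, χ²_resid/(J−2)) and use normal reference quantiles — a deliberate,
documented choice; with the instrument counts this package targets
(J ≳ 50) the difference from a t reference is negligible. I²(GX) =
(Q_GX − (J−1))/Q_GX with Q_GX the σ_X⁻²-weighted dispersion of γ̂ measures
regression-dilution attenuation of the slope (values near 1 are good); it
is reported clipped at 0 with the raw value retained.

**MR-PRESSO.** Residuals are measured against leave-one-out IVW estimates
so an outlier cannot mask itself. The global test compares the observed
weighted RSS with n_sim (default 1000) parametric simulations under the
no-pleiotropy model; p-values use the add-one estimator
(1 + #{RSS* ≥ RSS})/(n_sim+1), bounded below by 1/(n_sim+1). Per-SNP
outlier tests use the same simulated terms, Bonferroni-multiplied by J
(conservative; the multiplicity rule is a documented choice). Note the
implied detectability floor: flagging requires n_sim > J/α − 1, so J = 50
at α = 0.05 needs n_sim ≥ 1000. The corrected estimate is IVW-MRE on the
non-flagged instruments — identical to plain IVW when nothing is flagged —
and the distortion test compares the corrected-vs-full shift against
removing equally many randomly chosen instruments.

## Study orchestration

A direction run chains filter → select → clump → proxy → harmonize → F →
estimators → PRESSO, each stage labelled in errors and logged in a JSON
audit trail. Bi-directional runs flag instruments shared between the two
directions (identical rsid or r² ≥ 0.8) and rerun the affected direction
without them as a sensitivity analysis. The confounder screen applies the
same battery to lifestyle/socio-economic traits, reporting mean differences
for continuous traits and ORs for binary ones; valid instruments should
show null associations there. Family-wise error defaults to Bonferroni
0.05/16 (eight traits × two directions → per-test 0.003125, displayed
0.0031); the family size is configurable. IVW p-values are classified into
`bonferroni` / `nominal` / `null` tiers.

**Power.** For a binary outcome, the noncentrality of the IVW test is
approximately z = |ln OR|·√(n·r²_GX·K(1−K)) with n the outcome sample size,
K its case fraction and r²_GX the exposure variance explained by the
instruments. Power is the exact two-sided rejection probability
Φ(z−c) + Φ(−z−c), c = z_{1−α/2}, so power at OR = 1 equals α. Because power
depends on the inputs only through z, `min_detectable_or` solves once for
z* by bracketed root-finding and maps back, which makes the √2 scaling of
ln(OR) under information doubling exact; the OR is returned at full
precision and rounded only for display.

## Synthetic data

The generator emulates the statistical structure of consortium GWAS summary
files, not their genomic detail: true effects γⱼ uniform on a magnitude
range (default 0.06–0.10 log-odds), independent Gaussian noise in the two
samples, and pleiotropy αⱼ per regime — `none`, `balanced` (zero-mean
normal), `directional` (nonzero mean, InSIDE holds), `inside_violating`
(αⱼ coupled to γⱼ − γ̄), plus planted outliers with a fixed extra effect.
Allele pairs, EAFs (uniform 0.05–0.95 so the palindrome rule fires both
ways), strand flips, allele-order swaps, and outcome-table omissions with
an in-LD proxy (r² drawn from [0.8, 1.0], same alleles, independent noise)
exercise the bookkeeping stages. `target_mean_F` calibrates σ_X so the
expected mean F, mean(γ²)/σ²_X + 1, hits the target.

Preset study conditions (each deterministic given its seed):

| preset | J | purpose |
|---|---|---|
| `valid_strong` | 100 | recovery of β = 0.2 with strong instruments (σ_X = 0.002) |
| `valid_110` | 110 | realistic battery, mean F calibrated to 89.3, all bookkeeping on |
| `null_balanced` | 100 | β = 0, balanced pleiotropy (τ = 0.02); type-I error |
| `directional_inside` | 100 | mean pleiotropy 0.05, InSIDE holds; Egger intercept |
| `inside_violating` | 100 | pleiotropy coupled to strength; negative control |
| `presso_outliers` | 50 | 5 outliers at 10×σ_Y; PRESSO detection |
| `proxy_rich` | 60 | 15% of instruments missing, proxies available |
| `palindrome_mix` | 80 | 50% palindromic variants, both MAF branches |

The estimator-validation presets use σ_X = 0.002 (mean F ≈ 1700) rather
than the F ≈ 89 of the realistic battery: MR-Egger's slope is attenuated by
the factor I²(GX) ≈ var(γ)/(var(γ)+σ²_X), and with a uniform positive γ
distribution at F ≈ 89 that attenuation (~55%) would swamp the estimator's
own sampling error, telling us about the γ-distribution's shape rather than
about the implementation. Strong instruments make all three estimators'
biases small relative to Monte-Carlo noise, which is what a correctness
check needs; the realistic-F preset still exercises the full pipeline and
the F calibration itself.

What the generator does *not* emulate: LD structure beyond one proxy per
omitted SNP, winner's-curse selection of instruments, sample overlap,
population stratification, and genotype-level data. Passing tests
demonstrate estimator and pipeline correctness under the stated sampling
model, not robustness to those real-data complications.

## Numerical choices and degenerate inputs

* P-values of exactly 0 in input files are floored to the smallest positive
  double, with a warning; reported p inconsistent with |beta/se| by more
  than a decade triggers a warning, not a failure (many GWAS report
  non-Wald tests).
* Duplicate rsids within one file keep the smallest p-value (logged).
* Ties in clumping and proxy choice break deterministically (p-value, then
  rsid), so every pipeline stage is reproducible bit-for-bit given a seed.
* Monte-Carlo p-values (PRESSO global, outlier, distortion) use the add-one
  estimator and are therefore never 0.
* Degenerate cases raise typed errors: zero γ̂ in a Wald ratio, J below an
  estimator's minimum (1 for IVW, 3 for weighted median and Egger, 4 for
  PRESSO), zero variance in γ̂ for Egger, and an emptied instrument set at
  harmonization. `estimate_all` converts the J-minimum cases into
  "not applicable" entries instead of failing the battery.

## Problem sizes

The validation suite uses 500 replicates for recovery and Egger-intercept
studies, 1000 for type-I error, and 100 for PRESSO detection (n_sim = 1000
each); these sizes put the Monte-Carlo SE comfortably below the effects
being measured while keeping the whole suite and the acceptance script in
the seconds-to-minutes range on a single CPU.

## Known limitations

* First-order Wald-ratio weights throughout (no second-order or exact
  weights); fine for the instrument strengths targeted here.
* No Steiger direction filtering, multivariable MR, mode-based or robust
  IVW variants, or correlated-instrument models.
* Binary exposures are analysed per unit log-odds of the exposure, the
  standard caveat for binary-exposure MR; no rescaling is attempted.
* The LD interface is a local pairwise table; there is no reference-panel
  computation or remote query.
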