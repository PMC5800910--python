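# Methods

## Genotype-effect model and normalization

Each panel SNP acts multiplicatively on a biomarker's geometric-mean level:
one copy of the effect allele multiplies the expected level by the allelic
effect `a > 0`. Raw genotype multipliers `(1, a, a^2)` are rescaled by
`m = p^2 a^2 + 2p(1-p)a + (1-p)^2` (`p` = effect-allele frequency), so the
Hardy–Weinberg-weighted mean of the triple `(e0, e1, e2)` is exactly 1.
Consequences used throughout:

* `e2/e1 = e1/e0 = a` — normalization preserves the ratio structure;
* the population mean of the combined genetic effect `G` tends to 1 under
  HWE, so correction leaves cohort-mean levels approximately unchanged;
* `(a, p)` and `(1/a, 1-p)` describe the same SNP with the alleles swapped
  and give the reversed triple, which is how the packaged panel resolves the
  published tables' mixed allele orientation (for 8 of the 11 SNPs the
  listed allele is the level-*decreasing* one; effects are always stored by
  count of the increasing allele, whose frequency is the published one).

A variant normalization against observed genotype proportions
(`normalize_empirical`) is provided for cohorts out of HWE; it constrains
the observed-mass-weighted mean to 1 instead.

The packaged panel stores the published per-SNP `(a, p)` and recomputes
exact triples at load time; the published 2-dp triples are retained only as
reference metadata (they are prints of unrounded internal estimates — one
homozygous cell sits at 1.4350 and prints as 1.43 — so validation compares
at ±0.02 per cell, and all 33 cells agree at that tolerance).

## Effect estimation

Per-SNP effects are estimated marginally — ordinary least squares of
`log(level)` on the effect-allele count, back-transformed with `exp` — one
simple regression per SNP, without covariate adjustment. SNPs on different
genes are treated as unlinked, which matches the simulator; a joint
multiple-regression mode exists as a sensitivity flag. Orientation is
flipped (`count -> 2 - count`) when the slope is negative so reported
effects are always ≥ 1. Normalization of a fitted effect uses the observed
effect-allele frequency (HWE weights), or observed genotype proportions in
empirical mode.

## Correction

`corrected = raw / G`, with `G` the product of the subject's panel
multipliers. Missing genotypes contribute 1 (mean imputation under the
mean-one normalization) and are counted per subject; a `missing="drop"`
mode blanks the corrected value instead. Corrected values that fall below
the assay detection floor (0.005) are kept as computed and flagged:
correction is an analytic transformation, not a measurement, so re-flooring
would discard information. The measurement floor itself is applied at read
time (values < 0.01 become 0.005), mirroring the source laboratory's
handling of below-curve readings.

## Risk models

Unconditional logistic regression of the incident-cancer indicator on each
exposure, per 1 SD of log level (`z = (log x - mean)/sd`); the markers are
strongly right-skewed, so a per-unit OR would be dominated by the tail, and
the published continuous ORs (1.09–1.65) are consistent with a standardized
scale. Covariate models are nested: Model 1 crude; Model 2 age + sex;
Model 3 adds BMI, smoking, drinking, physical activity and family history.
The three-marker combination defaults to the re-standardized equal-weight
sum of the per-marker z-scores; a "joint" mode uses the in-sample logistic
linear predictor on the three z-scores instead (neither weighting is
identifiable from the published grid, so the simple one is the default).
Follow-up time is deliberately ignored in the OR grid — the source analysis
used logistic regression despite cohort follow-up — while the concordance
grid uses the survival structure.

Numerical notes: fits use Newton–Raphson to tight tolerance; binary
predictors with an empty predictor-by-outcome cell are rejected by name
(their MLE diverges — quasi-complete separation), as are outcome vectors
without variation.

## Discrimination

Harrell's C over comparable pairs: a pair is comparable when the smaller
follow-up time belongs to an event; tied times contribute only when exactly
one subject is an event (the event subject then needs the higher score);
tied scores earn half credit. Pair counts are accumulated per subject in a
compiled O(n²) loop, which makes leave-one-out jackknife exact and cheap:
removing subject *i* removes exactly *i*'s own pair contributions. The 95%
CI is normal with jackknife SE, truncated to [0, 1].

Risk scores come from Cox proportional-hazards fits (Efron tie handling,
via lifelines); for a univariate exposure the Cox linear predictor is a
monotone transform of the exposure, so C is identical either way (a tested
invariant, and a shortcut used in the repeated-seed experiments).

Raw-vs-corrected comparisons use the *paired* jackknife on the per-subject
difference of leave-one-out C values, with a two-sided normal p — both
scores are computed on the same subjects and are strongly correlated, which
the paired test exploits. A subject-resampling bootstrap (fixed seed,
percentile p) is available as an alternative. The paired jackknife's type-I
error is verified at the nominal 5% over 500 null replicates in the test
suite.

## Synthetic cohort generator

The generator is the exact inverse model of the correction and fixes the
study conditions:

| knob | default | basis |
| --- | --- | --- |
| `n_subjects` | 9,808 | source cohort size |
| `target_incidence` | 0.01754 | 172 cases / 9,808 (17.54/1,000) |
| `followup_years` | 5 | 2008–2013 follow-up window |
| `baseline_level` (geometric mean, ng/ml or u/ml) | AFP 2.7, CA19-9 7.8, CEA 1.8 | published medians |
| `log_sd` (non-genetic log-scale SD) | 1.0, 1.0, 0.7 | published IQR ratios, `ln(Q3/Q1)/1.349` |
| `disease_effect` (per-SD OR of the latent level) | 1.6, 1.2, 1.1 | published crude ORs |
| site weights | 39, 35, 64, 20, 14 | published liver/stomach/colorectal/esophagus/pancreas counts |
| covariates | age 62.0 ± 7.8; BMI 24.3 ± 3.3; 46.9% male; sex-dependent smoking/drinking | published baseline marginals |

Genotypes are Binomial(2, p) per SNP (no linkage disequilibrium, no
population stratification); a variant listed in two panels is drawn once.
Observed level = baseline × G × exp(σZ); the genotype-free latent component
is retained so tests can check that correction with the true panel recovers
it to machine precision. Disease risk is logistic in the z-scored *latent*
log levels with slopes `log(disease_effect)` and an intercept calibrated by
root-finding to the target incidence — the genetic multiplier is pure
non-disease variance by construction, encoding the premise that correction
removes noise. Event times are uniform within follow-up (incidence density
is not modelled; Cox here is only a vehicle for C), censoring at the
horizon; covariates are independent of genotypes and of outcome apart from
the sex-linked smoking/drinking prevalences.

### What the simulation can and cannot show

Passing tests show the machinery is correct and that correction helps *in
expectation* at the study's scale: over 100 simulated cohorts the mean C
and mean OR of every corrected exposure exceed their raw counterparts. They
do not show a per-cohort guarantee. With the published effect sizes the
genetic share of log-level variance is small (log-scale SD ≈ 0.08 for AFP,
0.38 for CA19-9, 0.16 for CEA against total noise ≈ 1.0/1.0/0.7), so with
~172 events the expected corrected-minus-raw difference is only ~0.3–0.4 of
its own sampling SD; any single cohort — including, plausibly, the original
one — has a substantial chance of showing the reverse ordering for a given
marker. The generator also omits features of real data: assay error
distinct from biological noise, covariate–marker correlations, non-lognormal
tails, per-site heterogeneity, and any SNP–disease pathway other than
through the biomarker.

## Reported summaries

The baseline table uses Student's t-test for normal continuous variables,
Mann-Whitney U for the biomarkers (fixed by list, not by a normality test,
so reporting is deterministic), and Pearson chi-squared *without* continuity
correction for categoricals (the uncorrected statistic reproduces the
published smoking p = 0.027 from its 2×2 counts; the corrected one does
not). Cumulative incidence is `1000 × events/total` at 2 dp; the
correction summary reports `100 × (mean_raw − mean_corrected)/mean_raw`
per marker. The pipeline writes all tables plus a provenance log (seed,
config hash, counts) and is byte-identical across runs at a fixed seed.

## Known limitations

* Allele bases for 7 of the 11 SNPs' effect-increasing alleles are not
  recoverable from the published table; they are stored as "the allele
  other than the listed one", which VCF reading resolves via the listed
  base. Two published rsids (rs3760775/rs3670775) share a position and are
  kept as printed, flagged as a likely typo.
* No dosage/probabilistic genotypes, no imputation from reference panels,
  no LD modelling, no per-site (cancer-type) analyses.
* The published absolute ORs and C values are properties of the real,
  undeposited cohort; the package reproduces the published arithmetic and
  the direction of the correction benefit, not those exact numbers.
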