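# Methods

`hfiprev` estimates the prevalence of a fully penetrant autosomal-recessive
disease — hereditary fructose intolerance (HFI), caused by biallelic
pathogenic variants in *ALDOB* — from carrier screens and population
allele-count databases, and provides the surrounding panel analytics:
cross-population allele-frequency comparison, screening-panel design by
cumulative allele frequency, and genotype–phenotype association testing in
case series. This note records the model, its assumptions, the numerical
conventions, and what the synthetic-data generators do and do not emulate.

## Prevalence model

Let `q` be the total pathogenic allele frequency across a curated P/LP
panel at one locus. Under Hardy–Weinberg random mating and full penetrance,
carrier frequency is `2q(1−q)` and disease prevalence is `q²`.

Three estimators consume a screened cohort of `N` individuals with `C`
unaffected carriers (`C_m` male of `N_m`, `C_f` female of `N_f`). Diagnosed
patients and their relatives are excluded *before* counting, so every
carrier is heterozygous and contributes exactly one pathogenic allele.

**Method 1 — carrier frequency.** With `f = C/N`, a random couple is
carrier×carrier with probability `f²` and their child is affected with
probability `f²/4`.

**Method 2 — sex-stratified couples.** The same risk from the two strata:
`(C_m/N_m)(C_f/N_f)/4`. Algebraically identical to Method 1 when both
sexes carry at the same rate; the difference measures sex imbalance in the
screen, not biology.

**Method 3 — Bayesian allele-count posterior.** The `C` carrier alleles
among `n = 2N` typed alleles give a binomial likelihood for `q`. With the
Haldane (improper Beta(0,0)) prior the posterior is `Beta(C, n−C)`; the
reported point estimate is the posterior mean of the *prevalence*,

    E[q²] = C(C+1) / (n(n+1)),

and the 95% credible interval is the central interval of `q²`, i.e. the
squared 2.5%/97.5% Beta quantiles. Both are closed-form; a Monte-Carlo
pass (default 10⁵ posterior draws, seeded) recomputes the interval by
sampling and must agree with the analytic endpoints — it is kept as a
diagnostic, the reported numbers are deterministic. The Haldane choice is
deliberate: `E[q²]` under Beta(C, n−C) is the estimator that regenerates
the published cohort table exactly (see "Reference values" below). The
Jeffreys prior Beta(½,½) is available via `prior="jeffreys"`; Haldane is
degenerate at `C = 0` or `C = n`, and those boundary inputs require
Jeffreys.

**Per-population panel estimates.** When only per-variant allele counts
`(AC_i, AN_i)` are available (gnomAD-style tables), each variant gets an
independent posterior `q_i ~ Beta(AC_i + ½, AN_i − AC_i + ½)` — Jeffreys by
default here because rare panels legitimately contain `AC_i = 0` variants,
which must contribute proper prior mass `½/(AN_i+1)` rather than break the
model. The total frequency is `q = Σ q_i` (rare-variant regime: no
double-heterozygote correction), the point estimate the deterministic
`(Σ E[q_i])²`, and the interval the Monte-Carlo quantiles of `(Σ q_i)²`
(the sum of independent Betas has no convenient closed form).

**Averaging.** Cross-method and cross-cohort summaries are arithmetic
means of prevalence *probabilities*, never of the 1-in-X denominators;
averaging denominators would be a harmonic mean of probabilities and
overweight the smallest estimates.

**Display convention.** Probabilities print as `1/⌊1/p⌋` — the denominator
truncated toward zero, so a displayed risk never overstates the estimate.
Truncation (not rounding) is what regenerates every published display cell
(e.g. carrier frequency 61/20,919 = 1/342.93 prints `1/342`). Values of
`1/p` within 1e-9 relative of an integer snap to it so exact rationals are
not mangled by floating point. Full-precision probabilities are always
emitted alongside display strings; truncation is presentation-only.

### Reference values

From the four published count quadruples (20,919 children, 12,783/8,136
m/f, 36/25 carriers; 10,031 parents, 5,006/5,024, 11/16 carriers) the
pipeline regenerates the published table bit-exactly as display strings:
carrier frequencies 1/342 and 1/371, couple risks 1/117604 and 1/138026,
Method 1 1/470416 and 1/552104, Method 2 1/462233 and 1/571594, Method 3
1/462839 and 1/532412 with intervals (1/803692 ~ 1/293566) and
(1/1270634 ~ 1/277464), averages 1/465133 and 1/551573, overall 1/504678.
The single one-unit discrepancy (child interval upper endpoint 1/293566
vs the published 1/293567) is consistent with Monte-Carlo noise or
rounding in the original computation; all analytic endpoints otherwise
match exactly. Note the published parent cohort totals are internally
inconsistent by one individual (5,006 + 5,024 = 10,030 ≠ 10,031);
`CohortCarrierCounts` therefore permits the sex strata to undercount the
total (individuals of unrecorded sex), and the pooled quantities use the
total.

## Allele-frequency comparison

Per-variant comparisons between two populations are Pearson chi-square
tests on the 2×2 allele table `[[AC_a, AN_a−AC_a], [AC_b, AN_b−AC_b]]`,
with Yates continuity correction on by default (the stock behaviour of
`chisq.test` in R, the environment such analyses are usually run in); a
flag exposes the uncorrected statistic. Variants typed in only one
population are skipped, never imputed as zero: absence of a record is
absence of typing, not observed absence. The Bonferroni multiplier is the
number of comparisons actually performed. Significance for the reported
direction uses the adjusted p at α = 0.05 by default; both raw and
adjusted p are always emitted so other thresholds can be applied
downstream. When an expected cell count is below 5 the routine logs a
recommendation to use the exact test; it does not silently switch, since
cross-population allele tables are usually large enough and silent test
switching makes results irreproducible across runs with slightly different
counts.

Hotspot ranking sorts by descending AF with ties broken lexicographically
by variant id, making top-k sub-panels deterministic. Coverage of a top-k
sub-panel is `Σ_topk AC / Σ_all AC` — for a sum, greedy top-k is the
optimal k-subset, so this is also the best achievable k-variant coverage.

## Genotype–phenotype association

Patients in a recessive case series carry two pathogenic alleles; each is
grouped by variant site (carrying ≥ 1 copy, with a separate
`"<site> (homozygote)"` label restricted to homozygotes), by unordered
mutation-type pattern (`missense+missense`, `frameshift+splicing`, …), and
by zygosity. Every group is tested against the rest of the cohort for each
phenotype in a 24-term clinical-manifestation vocabulary; phenotype flags
are present / absent / not assessed, and not-assessed patients never enter
a table — denominators are always assessed patients only.

The exact test is Fisher's two-sided test under probability-mass ordering
(the sum of probabilities of all tables at the observed margins no more
probable than the observed one); the asymptotic alternative is the
Yates-corrected chi-square. Both p-values are reported; `test_used`
follows the standard small-sample rule (Fisher when any expected cell
< 5). Degenerate margins return p = 1 with a warning rather than an
error, so a screen over many sparse combinations completes. The
Bonferroni family is the set of tests emitted by one screen invocation,
and screen output is deterministically ordered (grouping, label,
phenotype), independent of patient input order.

## Synthetic-data generators

The study-scale inputs (clinical exome carrier screens, per-population
AC/AN tables, a 68-patient case series) are not publicly distributable,
so generators emulate each with the structure the analysis assumes. All
are pure functions of `(config, seed)`; each generator consumes its own
numpy `default_rng([seed, stream])` sub-stream so adding one call never
perturbs another's draws.

* **Cohorts** draw two independent pathogenic alleles per individual at
  total frequency `q` (Hardy–Weinberg). Affected individuals (two
  pathogenic alleles) are *generated and then excluded* from totals and
  carrier counts — the exclusion rule itself is exercised, not bypassed.
* **AF tables** draw `AC ~ Binomial(AN, af·scaler)` per variant and
  population.
* **Patient series** draw alleles from the spectrum normalised over the
  panel, with a `homozygote_excess` probability of forcing the second
  allele equal to the first — emulating the enrichment of homozygotes
  (founder alleles, consanguinity) that recessive case series show beyond
  the random-mating expectation `Σ w_i²`. Phenotype flags are Bernoulli
  with log-odds = logit(baseline) + log odds ratios of the matching
  genotype features; missingness is applied independently.

The `paperlike` preset fixes the study conditions used throughout the
tests: a 20,919-individual screen at the observed male fraction; an AF
spectrum whose ten hotspot variants (A338V 1:1887, N120Kfs\*32 1:3226,
A338G 1:8333, …, A150P 1:20833) are calibrated to carry exactly 90% of the
total pathogenic frequency (total q ≈ 1.5×10⁻³, carrier frequency ≈
1/326 — the regime of the emulated screen); a 24-phenotype model whose
four cardinal gastrointestinal phenotypes use the observed case-series
rates (87%, 78%, 54%, 59%) and assessment completeness (39–40 of 68
assessed), with the remaining phenotypes at a 20% baseline and 40%
missingness; and `homozygote_excess = 0.42`, which yields the observed
~51% homozygote fraction given the spectrum's `Σ w_i² ≈ 0.15`.

What the generators do **not** emulate: linkage and haplotype structure,
population stratification within a cohort, genotyping error,
ascertainment bias of a referral cohort (all individuals are exchangeable
draws), and correlated phenotype assessment (flags and missingness are
independent across phenotypes). Passing tests therefore demonstrate that
the estimators are correct and calibrated *under the stated model*, not
that real referral cohorts satisfy that model.

## Numerical and testing choices

* Point estimates are always analytic; Monte-Carlo is confined to
  interval estimation and must agree with closed forms where they exist
  (relative error < 1% at 10⁶ draws is verified in the suite).
* Interval calibration is checked by parameter recovery: 500 simulated
  screens at study scale, requiring the 95% interval to cover the true
  `q²` at 95% ± 2%.
* Family-wise error of the association screen is checked on 200 null
  replicates (genotype-independent phenotypes) — the fraction of screens
  with any Bonferroni-significant flag must stay at or below α plus
  binomial noise. Discreteness of the Fisher test makes Bonferroni
  markedly conservative here (observed rate ≪ α), which is expected.
* Power of the screen is checked with a planted odds-ratio-8
  homozygote→nausea enrichment at n = 68 (baseline 0.25, 10%
  missingness), requiring detection at raw p < 0.05 in ≥ 80% of 200
  replicates.
* Percent displays round half away from zero, which reproduces the
  published mutation-type split 26/22/21/15/6/2/2/1/1/1/1 for the
  81-variant panel.
* The packaged panel file is a synthetic emulation: literature-named
  hotspot alleles carry their real labels, filler rows are clearly
  synthetic, and the mutation-type composition matches the published
  81-variant curation. HGVS strings are opaque identifiers; no syntactic
  HGVS validation is attempted.
* Replicate counts and simulation sizes above were chosen as the smallest
  that make the binomial tolerances meaningful; they are the package's
  test conditions, not tuning knobs.

## Known limitations

* No penetrance modelling, de-novo mutation rate, consanguinity
  adjustment, or non-autosomal inheritance; prevalence is `q²` exactly.
* The per-population estimator ignores covariance between variants
  (independent posteriors) and the `2q(1−q)` vs `2q` distinction —
  negligible in the rare-variant regime it is meant for, increasingly
  wrong as `q` grows.
* Bonferroni is the only multiplicity strategy; with highly discrete
  exact tests it is conservative, and the screen's power claims hold for
  the raw-p decision rule.
* The comparison module assumes the two populations' allele counts are
  independent samples; overlapping cohorts would invalidate the test.
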