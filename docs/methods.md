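# Methods

## The classification model

POCD is defined per subject and follow-up interval from a battery of
six neuropsychological tests.  Each test has an orientation (+1 higher
= better, −1 higher = worse); the default battery marks visual verbal
learning as +1 and the five time/latency-based instruments (concept
shifting, Stroop, memory scanning, letter-digit, reaction time) as −1.
Orientation is an explicit configuration choice — it cannot be inferred
from data — and is recorded in the battery YAML.

For test *i*, the deficit-oriented change score is
Δᵢ = oᵢ·(post − pre).  The control group, tested at the same intervals,
supplies the expected change (practice effect) and its variability:
mean and **sample SD (n−1)** of the control change scores.  With 25
controls the denominator choice is material, and the n−1 form is the
standard reliable-change-index convention.  The patient's Z is
(Δᵢ − meanᵢ)/sdᵢ; a test is positive when z ≤ −1.96 (the comparison is
inclusive, reading "at least 1.96 SD lower" literally), and POCD means
≥ 2 positives of 6.  Thresholds (`z_threshold`, `min_positive`) are
parameters, with 1.96 and 2 as defaults.

Degenerate calibrations raise: fewer than two complete controls for any
test × interval, or a zero change-score SD (the Z is then undefined).
The default missing-data policy requires all six patient tests; a
permissive mode (`max_missing=1`) exists but is never the default,
mirroring the usual exclusion of patients unable to complete the
battery.  Incidence is reported with explicit numerator and denominator
and formatted to one decimal place (29/99 → 29.3%); internal values are
never rounded.

The classification is scale- and shift-invariant per test and monotone
in deterioration; the test suite asserts all three properties plus
equality with a brute-force reimplementation.

## The association models

All models consume a 2 (POCD status) × 3 (AA/AG/GG) count table with G
the effect allele.

* **Allelic / dominant / recessive** collapse the table to 2×2
  (allelic: two alleles per subject).  OR = ad/bc with the **Woolf CI**
  exp(log OR ± 1.96·SE), SE = √(1/a+1/b+1/c+1/d).  Woolf was chosen
  because it exactly reproduces the bundled study's printed dominant
  and recessive CIs at both timepoints.  The Haldane–Anscombe +0.5
  adjustment is applied to all four cells only when some cell is zero,
  and is flagged in the result; a wholly zero row or column raises.
* **Additive** is a per-allele logistic trend, not Cochran–Armitage
  (which yields a test, not an OR): a grouped-binomial ML fit of
  logit P(case) = β₀ + β₁·g, g ∈ {0,1,2}, by Newton–Raphson on the
  exact gradient and observed information (convergence |Δβ₁| < 1e-10,
  ≤ 50 iterations).  Separation (diverging |β₁| or vanishing weights)
  and rank deficiency (a single non-empty genotype class) raise with a
  diagnostic.  With one empty genotype class the fit reduces exactly to
  the 2×2 closed form, which the tests exploit as an oracle, alongside
  a profile-likelihood grid search and a GLM cross-check.
* **P-values** come from the Pearson chi-square without continuity
  correction (Yates available by flag; the convention is not fixed by
  the bundled study, and p-values are displayed, not used for any
  decision inside the package).  A warning is emitted when an expected
  cell count falls below 5.
* **HWE** uses 1 df: three genotype classes minus one constraint minus
  one estimated allele frequency.

Display rounding: two decimals, three below 0.1 (so a lower bound of
0.078 keeps its precision); significance in reports means the 95% CI
excludes 1.

## Bundled data and its inconsistencies

`pocdkit.datasets` ships the genotype/allele counts of a published
elderly-surgery POCD cohort (rs6265), used by the examples and the
reproduction tests.  Several of that study's *summary* values are
arithmetically inconsistent with its own counts, and
`consistency_report()` recomputes and flags each one rather than
imitating it:

* the day-7 allelic OR is published as 0.67, but the allele counts give
  0.47 — coincidentally the published CI lower bound; both published
  allelic CIs also fail to match the Woolf intervals their counts
  imply;
* the published HWE statistic 4.402 (p = .11) cannot be derived from
  any published genotype set (pooled day-7 counts give χ² = 1.232,
  p = 0.27); p = .11 at 4.402 would require 2 df, which is not the
  standard test;
* the month-3 additive CI is printed as "0.32−0.302", an evident typo
  (only the point estimate 0.65 is meaningful);
* the month-3 genotype rows sum to 25/74 subjects, not the stated group
  sizes 18/81 (the allele totals 50/148 confirm 25/74).

Some published two-decimal values appear truncated rather than rounded
(e.g. a recessive OR of 0.7778 printed as 0.77, chi-square p-values of
0.918/0.938 printed as .91/.93); the audit tolerance is one unit in the
last printed digit so truncation alone is not flagged.

## The synthetic cohort generator

The generator emulates the study design the analysis assumes: 99
patients and 25 age/sex-matched controls by default, genotypes drawn as
two independent alleles at p_G = 0.51 (the pooled patient allele
frequency), and a latent binary "surgical insult" per patient with
logit⁻¹(β₀ + β₁·g) risk — defaults β₀ = −0.095 (AA risk ≈ 0.48) and
β₁ = −0.9 per G allele, matching the additive effect size the
association stage should recover (exp(−0.9) ≈ 0.41).

Scores are simulated on an arbitrary standardized scale (mean 50,
residual SD `noise_sd` = 10): the RCI arithmetic is scale-free, so only
structure matters.  Residuals at each timepoint are exchangeably
correlated across the six tests (ρ = 0.3 by default — the 2-of-6 rule's
false-positive rate depends on ρ, so it is a visible parameter, and the
null-calibration test runs at both ρ = 0 and 0.3).  Follow-up scores
add a per-test practice effect (default +2 raw units per interval,
identical at day 7 and month 3, i.e. the learning effect saturates
after the first repeat) and, for insulted patients, subtract a deficit
of `decline_magnitude` (default 2.5) control change-score SDs in each
test's deficit direction.  The change-score SD under this noise model
is noise_sd·√2.  An insult persists to month 3 with probability
`persistence` (default 0.6, chosen so simulated incidence falls from
roughly 29% to 18% between the follow-ups as in the modelled design).
Demographics (age, sex, education) are decorative: generated for
realism of the Table-1 stage but never causal.

One top-level `numpy.random.default_rng(seed)` drives every draw, so an
identical config and seed give a bit-identical cohort (asserted
byte-wise through the CLI).

What the generator does **not** emulate: real battery score
distributions (unknown — all scales are stand-ins), test-specific
reliabilities or floor/ceiling effects, covariate-driven risk (surgery
type, anesthesia), or genotype-dependent practice effects.  Passing
tests therefore show the *algorithms* are correct under the assumed
structure, not that the assumed structure matches any particular real
battery.

## Problem sizes used in the checks

The reproduction checks on the bundled counts are closed-form and
instant.  The stochastic checks use: 10 000 draws for Hardy-Weinberg
proportions; 200 seeds for the HWE rejection rate, the null per-test
positive rate and the null POCD incidence; 100 random small cohorts for
the brute-force classifier oracle; 50 random tables for the MLE/grid
agreement (grid spacing 1e-6); and 500 cohorts of 4 000 patients for
parameter recovery (mean β̂ within 0.05 of −0.9, Wald CI coverage
required to land in 93–97%).

## Known limitations

* Single SNP, unadjusted models only: no covariate-adjusted logistic
  regression, haplotypes, or exact (Fisher/mid-p) CIs.
* The RCI uses mean-change adjustment only — no regression-based
  practice-effect models.
* The additive-model Wald CI can be anti-conservative in very sparse
  tables; the Haldane policy applies only to the 2×2 collapses.
* The CLI ingests tabular genotypes (0/1/2 or counts), not VCF.
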