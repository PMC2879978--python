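# Methods

## Index formulas and their non-negativity

All components feeding the indices are bounded in [0, 1]: rates by
construction, and effect sizes by choice of measure — squared Cramér phi
(φc² = χ²/(n·(min(r,c)−1))) for contingency tables and partial eta
squared (η² = SS_effect/(SS_effect + SS_error)) for two-timepoint
repeated-measures ANOVA.  Differential (subgroup) effects enter as a
multiplicative discount `(1 − differential)` rather than a subtraction,
so every index is a product of [0, 1] factors scaled to [0, 100] and
cannot go negative.  `legacy_index` implements the older subtractive
convention for comparison; the test suite demonstrates it going negative
on component sets where the differential effect exceeds the positive one.

Display convention: components at three decimals, indices at one
decimal.  The three composite impacts are defined as products of the
*reported* (one-decimal) indices divided by 100.  This matches the
arithmetic under which the published impact values are exactly
reproducible; combining full-precision indices can differ in the last
reported decimal (e.g. 8.05 → 8.1 rather than 8.0).

## Two-timepoint mixed ANOVA

With exactly two timepoints, the within-subject part of a mixed ANOVA
reduces to analyses of the normalized difference contrast
w_i = (follow-up_i − baseline_i)/√2.  With groups j = 1..g of sizes n_j,
group means w̄_j, unweighted grand mean w̄_u and harmonic mean size n_h:

* SS_time = g·n_h·w̄_u²   (df 1)
* SS_interaction = n_h·Σ_j (w̄_j − w̄_u)²   (df g−1)
* SS_error = Σ_j Σ_i (w_ij − w̄_j)²   (df N−g)

Unweighted-means (Type III) sums of squares are used because the cohorts
of interest are strongly unbalanced (e.g. 993 women vs 267 men); group
means therefore enter with equal weight.  Ungrouped, the formulas
collapse to the paired t-test identities F_time = t² and
η²_time = t²/(t² + n − 1), which the tests verify against an independent
paired-t computation; grouped, they are verified against a brute-force
cell-mean/subject-mean decomposition and, on balanced designs, against
pingouin's mixed ANOVA.  Degenerate inputs (zero change variance
everywhere) return η² = 0 with a `degenerate` flag rather than NaN.
Incomplete pairs are dropped pairwise; each statistic in the pipeline
uses its own maximal complete subset (missing cells are never imputed
or treated as zero).

## Representativeness

Demographic representativeness compares enrollees with the eligible
population.  The engine builds a participant-vs-nonparticipant × category
table from the eligible marginals and applies the φc² machinery.  This
construction is a documented convention: published representativeness
effect sizes are generally not reconstructible from printed marginals
because the exact comparison population and table layout are rarely
stated.  Results are therefore flagged `convention_dependent`, and the
engine accepts externally supplied effect sizes (`overrides`) whenever a
published value should be carried through instead; the provenance log
records which components were computed versus supplied.  Note that the
construction requires each category's enrollment not to exceed its
eligible mass; inflated test cohorts (larger than the population model
implies) must supply the representativeness value externally.

## Eligibility, phases, and age bins

Eligible members = N_adults · (p_obese + p_overweight · p_comorbid):
all obese adults plus overweight adults with ≥ 1 comorbid condition.
Phase-1 eligibility means enrollment ≥ 84 days (12 weeks) before data
collection; phase-2 ≥ 365 days; both boundaries inclusive.  The 84-day
reading of "12 weeks" is a stated convention — day-level rules in the
source databases are unknown.  Ages bin into six half-open ten-year
groups starting at 18 ({[18,25), [25,35), …, [65,∞)}), the minimal
scheme consistent with the reported group labels.  Completion flags are
taken from the input file, not inferred from behavioral requirements
(visit counts, food logs), which the data model does not carry.

The setting-continuation denominator is restricted to sites approved at
least one year before data collection: younger sites have not yet faced
the continuation decision.  The component-implementation numerator is
the mean count of implemented components across responding sites.

## Synthetic cohort generator

The generator emulates the data-generating process the analysis assumes;
its defaults are the study conditions:

* **Enrollment**: 80% female; age-bin weights (0.001, 0.07, 0.24, 0.37,
  0.28, 0.039) concentrating enrollment at 45–54.9 years with few
  enrollees 65+ and almost none under 25.  The eligible population is
  54.1% female; its age distribution over the six bins is not published,
  so a plausible adult distribution (0.10, 0.17, 0.19, 0.20, 0.16, 0.18)
  is fixed as a synthetic convention.
* **Baseline weight**: log-normal per sex, μ = ln(median) and
  σ = ln(q75/q25)/(2·z₀.₇₅), matching the published medians/IQRs
  (women 220.8 lb, men 269.9 lb).  Secondary measures (height, blood
  pressure, body fat, waist) are normal draws per sex with per-measure
  missingness probabilities mirroring the published table gaps (waist
  missing ~44%, body fat ~24%, …).
* **Attrition**: completion is Bernoulli given sex — phase 1 at .748
  (F) / .837 (M), phase 2 marginally at .395 / .514 nested within phase-1
  completion — with a small additive age trend (+0.02 per bin above the
  modal bin, centered so marginal rates are preserved) reflecting the
  reported rise of completion with age.
* **Weight change**: negated gamma (a skewed "loss" distribution) per
  sex and phase, shape solved from the IQR/median ratio and scale from
  the median.  A two-parameter family cannot match median and both
  quartiles simultaneously; realized quartiles land within ~0.5 lb of
  the targets.  The sex-by-time interaction is a knob: per-sex change
  distributions are mean-centred to their pooled mean and separated by
  `interaction_magnitude` pounds per phase (0 = exact null; `None` =
  the calibrated per-sex gap, which reproduces the published per-sex
  medians).  End-of-phase weight is floored at 55% of baseline as a
  physiological bound on gamma tails.  No age-by-time weight effect is
  modeled (the reported age differentials are near the "small"
  benchmark).
* **Sites**: 31 of 352 potential; 14 independent Bernoulli components
  with probabilities (nine at 1.0, four at 0.7875, one at 0.65) whose
  sum averages 12.8, the least-implemented being the home-exercise-log
  component; 18/31 of sites approved ≥ 1 year pre-collection, of which
  14/18 continue.

One integer seed drives everything through per-component sub-streams
(`numpy.random.SeedSequence.spawn`), so the same seed yields
byte-identical CSV output and adding a component never perturbs earlier
draws.

What the generator does **not** emulate: site-level random effects on
attrition or outcomes (only marginal rates are published), monthly
trajectories between the three timepoints, correlation between
missingness and outcomes (missingness is completely at random per
measure), and joint sex×age completion structure beyond the product
form.  Passing tests therefore demonstrate correctness of the pipeline
under these idealized conditions, not robustness to clustered or
informatively missing real-world data.

## Descriptive summaries

A measurement is summarized as median (IQR) when |adjusted
Fisher–Pearson sample skewness| > 1.0, else mean (SD); the threshold is
a convention (the source analyses state only that skewed data get
median/IQR).  Quartiles use linear interpolation between order
statistics so fixtures are bit-reproducible.  Percent weight change is
computed per participant and then summarized, not as a ratio of
summaries.  Change columns keep the sign convention that negative
change is improvement.  Cells with fewer than two complete observations
render as a not-available marker.

## Problem sizes and numerics

Convergence-style tests use a single shared synthetic cohort of
n = 20,000 (completion rates within ±0.02, baseline median within
5 lb); the null-interaction check runs 20 seeds at n = 2,000, where the
η² < .01 criterion holds with margin.  Oracle-equivalence tests use 50
random fixtures at n ≤ 12 and ≤ 3 groups, where brute-force
decompositions are exact to 1e-9 relative.  Chi-square tests apply no
continuity correction and no exact-test fallback, the plain reading for
samples in the hundreds to thousands.  φc² is clipped at 1.0 against
floating-point overshoot; tables with an all-zero margin raise rather
than return 0/0.

## Known limitations

The representativeness construction and the eligible age distribution
are conventions, not recovered facts; published phase-2 completion
figures are mutually inconsistent at the margins (the per-sex rates and
the overall rate cannot all hold under the published sex split), so the
generator calibrates to the per-sex rates and reports whatever overall
rate they imply (≈ .42 rather than .457).  Outcome and
representativeness effect sizes for the original cohort are reference
inputs, not recomputable quantities.
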