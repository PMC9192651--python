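# Methods

## Case coding

Every case carries 16 categorical risk factors plus a cause-of-death
label (SIDS / internal / external, collapsible to SIDS / non-SIDS).
Age at death is banded 0–2, 3–6 and 7–11 months; gestational age at
<37 weeks, birth weight at <2500 g, maternal age at ≤19 / 20–34 / ≥35
years, siblings at 0 / 1 / ≥2.  Two kinds of missingness are kept
distinct throughout: `unknown` (the factor applies but was not
ascertained; allowed only for sleep position, breastfeeding, passive
smoking and vaccination) and `NA` (structurally undefined: co-sleeping
and sleep position exist only for deaths during sleep).  In CSV files the
literals `unknown` and `NA` encode these states.

One transcription ambiguity in the packaged validation cases: the source
table's age row is a run of digits compatible with either (case-4 = 1,
case-5 = 10) or (case-4 = 11, case-5 = 0) months.  We code case-4 as 11
and case-5 as 0 months, because case-5's profile (co-sleeping, prone,
passive smoking) and diagnostic outcome are most consistent with the
youngest band.  A maternal age printed as "35–" is coded as the ≥35
level, the only consistent reading.

## Replicate cohort generator

The training cohort is available only as marginal count tables, so the
generator reconstructs a 64-case cohort (41 SIDS, 11 internal, 12
external) whose per-factor marginal counts equal the packaged
specification *exactly for every seed*; only the arrangement of values
across records is randomized (seeded permutations).  Within the SIDS
group, co-sleeping and breastfeeding are assigned jointly with age band
to match the published age-stratified case counts — these joints are
printed data, and honoring them lets an onset model fitted on the
replicate cohort reproduce the published incidence grid.  All other
cross-factor dependence is deliberately absent: the source prints only
marginals, and inventing correlations would be worse than omitting them.
Factor marginals are specified at SIDS-versus-others granularity (the
granularity at which they are published); internal/external labels are
assigned to the 23 non-SIDS cases by seeded permutation.

Consequences for testing: marginal-level checks (group sizes, count
tables, onset-model inputs) are exact and deterministic, but any
statistic that depends on an unprinted joint — notably the diagnostic
models' validation concordance — reflects the synthetic joint, not the
real cohort, and is reported rather than asserted.

## Diagnostic models

CPTs are estimated by counting: row = (count + α)/(total + α·k), with
α = 0 by default to mirror pure count-based tables.  The unsmoothed
training data contain deterministic rows (all 41 SIDS deaths were
sleep-related), so a non-sleep profile yields a SIDS posterior of exactly
0; α > 0 is the documented remedy when strictly interior posteriors are
required.  Rows whose parent configuration never occurs become uniform.
Two policies govern informational missingness: `as_state` (default for
diagnosis; `unknown` is a modelled category, as the training tables
report it) and `exclude` (records with missing values are dropped from
the CPTs they touch and missing evidence is marginalized; this is the
convention the onset model's arithmetic uses).

The shipped network structures are editable JSON assets.  Models 2–3 are
retrospective: outcome → each factor, plus structural edges
death-during-sleep → co-sleeping / sleep-position so that `NA` is
deterministic given a non-sleep death.  Model 1 is causal; a fully
general 16-parent outcome CPT would need 2·10⁶ rows from 64 records, so
the causal structure keeps small parent sets (age feeds the
sleep-environment layer; death-during-sleep, co-sleeping and infection
symptoms are the outcome's parents) and leaves the remaining factors as
roots.  The pipeline is structure-agnostic: any DAG over the declared
variables can be supplied.

Inference is exact.  `posterior_ve` (variable elimination, greedy
min-size ordering) is the production path; `posterior_enumeration`
(brute-force summation) is the independent oracle it is tested against.
Ties in any argmax are broken by declared state order.  Evidence with
zero probability raises rather than returning NaNs.  Numeric reproduction
of the published per-case validation posteriors is out of reach by
construction — it would require the unpublished individual-level training
joint — so validation testing asserts report completeness and coherence
only.

## Onset-incidence model

Parameters: prior rate 0.3/1000 live births/year (derived as the total
SUID incidence 0.49/1000 × the 64% SIDS share, rounded to one decimal);
population age distribution uniform per month of the first year (3/12,
4/12, 5/12 across the three bands); case proportions from the 41 SIDS
cases with `unknown` excluded from denominators (passive smoking: 21
exposed of 30 known); control proportions from the packaged population
tables.  Co-sleeping and breastfeeding are age-stratified because their
reference data are published per band; sex, gestational age, birth weight
and passive smoking use a single stratum.  Where a control source
publishes both counts and percentages we use the counts (e.g. co-sleeping
cases 12/13 in the youngest band, although the printed percentage 91.7
corresponds to 12/13 only after rounding elsewhere); where only
percentages are published (passive smoking 33.1/66.9, breastfeeding at
7–11 months) we use the percentages.

The update multiplies the age-band prior by one likelihood ratio per
assigned factor level; unassigned factors are neutral and contribute
exactly 1.  This rate-space product is the first-order form of the exact
posterior-odds update; the exact form is also implemented
(`posterior_exact`) and the two agree within 1% relative for rates below
5/1000, which covers every cell of the grid.

Display rounding follows the published precision pattern: one decimal for
rates ≥ 0.25, two decimals below; the grid's ratio columns are computed
from the *rounded* cells (so 2.4/0.02 = 120.0).  Known deviations from
the published grid under this arithmetic, none larger than one unit in
the last printed digit for incidence cells: group A at 3–6 months
computes 0.15 (printed 0.14), group C at 7–11 months computes 0.08
(printed 0.09).  Two ratio cells differ beyond printed precision: the
3–6-month D/A ratio computes 10.0 (printed 11.0, not derivable from
either rounded or unrounded cells) and the 7–11-month D/A ratio computes
10.5 from the rounded cells 0.21/0.02 (printed 10.0).  These are reported
as computed.

## Surveillance statistics

Rates are deaths/live-births × 1000; the variability table reports the
across-region arithmetic mean, sample SD (n−1 denominator; the published
values are consistent with either denominator at printed precision) and
CV = SD/mean × 100, rounded to 2/2/1 decimals.  Recomputing CV from the
published rounded means and SDs reproduces the published values to within
one unit in the last digit (the unknown-cause row gives 32.3 vs the
printed 32.2, a rounding-chain artifact).  Regions with zero SUID deaths
are flagged rather than propagating NaNs through subcategory ratios.

Fisher's 2×2 exact test is delegated to scipy (two-sided,
point-probability rule — the common statistical-package default; the
source names the test but not the sidedness rule).  The Freeman–Halton
R×C generalization is implemented by full enumeration of fixed-margin
tables (allowed up to a table total of 200) with a seeded Monte-Carlo
fallback for larger tables; both are cross-checked against an independent
binomial-product enumeration oracle.

## Region generator

Region rates are gamma-distributed around the subcategory means
(defaults 0.11 / 0.07 / 0.31 per 1000 for SIDS / asphyxia / unknown, the
published across-region means) with rate CVs defaulting to the published
dispersion (0.727 / 0.714 / 0.322); counts are Poisson with mean
births × rate/1000, and live births are uniform on 30,000–400,000 per
region (seven-year prefecture-scale totals).  Observed rate CVs therefore
slightly exceed the rate-level CVs because Poisson noise adds on top; the
generator is used for pipeline and invariance testing, not for asserting
published dispersion values.  With zero dispersion the generator returns
identical rates and expected (unsampled) counts, so downstream CVs are
exactly zero.

## Problem sizes used in testing

The property batteries use 200 random networks of up to 8 nodes × 3
states for the variable-elimination/enumeration comparison (tolerance
1e-9), 10,000 ancestrally sampled records for CPT parameter recovery
(tolerance ±0.02), an exhaustive sweep of all 2×2 tables with total ≤ 12
plus 200 random 2×2/2×3 tables with totals ≤ 40 for the exact tests, and
400 simulated regions for generator mean recovery.  These sizes give
comfortable statistical resolution for the stated tolerances while
keeping the full suite fast.

## Limitations

The synthetic cohort carries no real joint structure beyond the printed
constraints; nothing validated on it speaks to the predictive accuracy of
the diagnostic models on real forensic data.  The shipped network
topologies are plausible transcription-style structures, not a claimed
reconstruction of any particular published figure, and the original
CPT-construction software's estimation and missing-data conventions are
proprietary and not reproduced.  The onset model assumes conditional
independence of factors given case status (naive-Bayes form), uses
population controls rather than matched surviving infants, and reports no
interval estimates.
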