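# Methods

This note documents the models, procedures and numerical choices behind
`fqvigil`, and what the synthetic experiments do and do not establish.

## Data model

A case report carries demographics (sex, age, country, reporter type),
one or more outcome flags (died, life-threatening, hospitalised, disabled,
other serious, non-serious), indications, drug mentions (normalised
lowercase name, suspect/concomitant role, ATC codes, optional start date)
and reaction mentions (MedDRA-style preferred term, optional event date).
The term dictionary maps each PT to exactly one primary high-level group
term and one primary system organ class; the implied HLGT → SOC relation
must itself be functional. A synthetic mini-dictionary of 29 PTs across
seven SOCs ships with the package; the licensed MedDRA hierarchy is not
redistributed.

Drug roles beyond suspect/concomitant (e.g. "interacting") collapse to
concomitant: the analyses only ever distinguish suspect drugs. Outcome
flags collapse to one ordered severity class with precedence
critical (died or life-threatening) > serious (hospitalised, disabled or
other serious) > non-serious, so multi-flag reports get a single level
suitable for use as a regression factor.

## Preprocessing

Deduplication matches reports on an exact composite key: rounded age, sex,
country, receive date, the sorted set of suspect drug names, sorted
indications and sorted reaction PTs. Missing values act as a distinct
matching token (duplicates typically share their missingness pattern).
Within a key group the lexicographically smallest case id is retained —
a deterministic, order-invariant rule. Only suspect drugs enter the key
because concomitant lists are the least reliably coded field. No fuzzy or
probabilistic linkage is attempted; with a finite key space, occasional
chance collisions between genuinely distinct reports are possible and are
treated as duplicates, which is the behaviour of any exact-key rule.

Exclusion then removes any case carrying a drug — in any role — whose ATC
code starts with N05 (psycholeptics), N06 (psychoanaleptics) or N07B
(drugs used in addictive disorders); a psychotropic coded as suspect would
confound psychiatric endpoints at least as strongly as a concomitant one.

Exposure classification is mutually exclusive: a case whose only drug
mention is a single FQ is that FQ's monotherapy stratum; anything else
containing an FQ is combination therapy, subtyped with precedence
multiple FQs > FQ + other antibiotics (any non-FQ drug under ATC J01) >
FQ + other medications. Cases without an FQ form the background
comparator. Age groups are 0–17 / 18–34 / 35–64 / 65+ with missing age
kept as its own "unspecified" level.

## Disproportionality

For each (exposure, term) pair at PT, HLGT or SOC level, the 2×2 table
counts cases (not reactions): a report contributes once to the event side
if at least one of its PTs maps to the term at that level. The comparator
for each stratum is every case outside it; a pooled `all_fq` row compares
all FQ-exposed cases against the background. ROR = ad/bc with the log-Wald
95% CI using z = 1.959963984540054. When any cell is zero, 0.5 is added to
all four cells (Haldane–Anscombe) and the row is flagged; signal
evaluation still requires a ≥ 3 on the uncorrected count. Screening
displays only pairs with a ≥ 3 and applies no multiplicity adjustment —
the signal rule (ROR > 1, CI lower bound > 1, ≥ 3 cases) is the
traditional per-pair criterion, and users should treat the flagged set as
hypothesis-generating. Choosing mutually exclusive exposure strata (rather
than counting combination cases toward each constituent FQ) is the main
reproduction-sensitivity point of per-drug RORs and is deliberate: it
keeps strata disjoint so stratum counts partition the dataset.

## Descriptive statistics

Stratified tables report counts with column percentages rounded to two
decimals half-up (matching how published demographic tables round).
Between-group tests: Pearson chi-square Σ(O−E)²/E without continuity
correction, with an advisory flag (and automatic switch in `choose_test`)
to the Fisher exact test when any expected cell is below 5. The two-sided
Fisher p uses the probability-ordering definition — the sum of
hypergeometric probabilities of all tables with the observed margins no
more probable than the observed one; other two-sided definitions
(doubling, central) exist and give different values on asymmetric tables.
Fatal-case characterisation restricts to reports with the `died` flag
inside an optional SOC/PT filter and ranks PT frequencies with
alphabetical tie-breaks, so the ranking is permutation-invariant.

## Time-to-onset

TTO is the whole-day interval from the earliest suspect-FQ start date to
the earliest event date among reactions in the analysed SOC. Day-0
(same-day) onsets are valid; reports missing either date are dropped with
an accounting, and negative intervals are dropped as inconsistent rather
than clamped — they indicate data errors, not instantaneous onset.
Group comparisons use the Wilcoxon rank-sum test: for groups of ≤ 20 each,
the exact permutation distribution of the midrank sum is computed by
dynamic programming on doubled midranks (exact in the presence of ties;
deviations compared in integer arithmetic, so no floating-point boundary
issues); larger groups use the tie-corrected normal approximation with
continuity correction. The Kruskal–Wallis omnibus is tie-corrected with a
chi-square reference (df = k−1); pairwise post-hoc comparisons reuse the
rank-sum test with one Benjamini–Hochberg family per matrix. BH is the
standard step-up: sort ascending, scale by m/i, enforce monotonicity from
the top, cap at 1. Note BH is not idempotent in general — re-adjusting an
adjusted vector rescales it again; only special inputs (e.g. constant
vectors) are fixed points.

## Imputation and risk factors

Missing age and sex are completed by k-nearest-neighbour imputation
(default k = 5) under Gower distance over sex, age, country, reporter,
exposure category and severity class: numeric contributions are
range-scaled absolute differences, categorical contributions 0/1
mismatches, averaged over the features observed for the target. Numeric
aggregation is the donor median, categorical the mode with alphabetical
tie-break; donor-distance ties break by case id, so the procedure is
fully deterministic and a seed argument is accepted only for interface
uniformity. Observed values are never altered.

Risk factors are screened with univariate logistic regressions of a binary
case-level outcome (e.g. "has ≥ 1 PT with primary SOC psychiatric
disorders") on one factor at a time, fitted by Newton iterations
(iteratively reweighted least squares; tolerance 1e-8, ≤ 50 iterations).
References: ciprofloxacin (exposure), monotherapy (therapy type), male
(sex), 0–17 (age group), non-serious (severity). Reference rows are
emitted with OR fixed at 1 and no CI. Perfect separation (a level with
zero or all events) is flagged and not fitted. One BH family spans all
non-reference levels of the whole screen: the adjustment here is for
multiplicity across the univariate screen, not covariate adjustment — the
models are deliberately univariate, and no multivariable model is implied.
"Unspecified" remains a modelled level rather than being dropped.

## Synthetic report generator

The generator is the ground-truth engine for every validation: for
exposure stratum e and preferred term t, the reporting odds are
ψ(e,t) × q(t), where q is the baseline odds in the background stratum and
ψ is the planted reporting odds ratio (ψ = 1 when unplanted, ψ = 0
suppresses the event entirely). Because the event mechanism is
multiplicative on the odds scale, ψ is exactly the population ROR of the
pair against the pooled remaining strata whenever those are left at ψ = 1.
Events are drawn independently per PT given exposure — no PT–PT
correlation — which suffices for validating a marginal 2×2 method.
Cases with no drawn event receive a filler background PT ("drug
ineffective") so every report has a reaction; the filler term is not a
screened endpoint.

Defaults are chosen to mirror the published FQ report cohort: the exposure
mix follows the observed per-FQ report totals with a 50% non-FQ
background; sex/country/reporter/outcome marginals follow the cohort's
demographic tables; per-drug age profiles differ (moxifloxacin reports
skew elderly, ciprofloxacin younger) and severe outcomes concentrate in
the elderly, giving the imputation and regression stages a realistic
dependence structure; planted ψ values echo the magnitude of the headline
FQ safety signals (anxiety ≈ 6, panic attack ≈ 17, photophobia ≈ 12.5),
with two moxifloxacin-specific anterior-segment terms planted at large ψ
(200 and 100) as scaled-down stand-ins for extreme-tail iris findings that
would need a database-scale comparator to reproduce numerically.
Onset days are round(lognormal(μ, σ)) per exposure, default median 2 days
(σ = 1) with gemifloxacin delayed at 7.5 days, placing realistic mass at
0–7 days. Duplicates are exact clones of all matching-key fields under a
fresh case id (fraction 0.05), so deduplication can find them exactly; a
psychotropic concomitant drug is added to 3% of cases to exercise the
exclusion filter; missingness is per-field MCAR (age 18%, sex 7%, dates
25%). All randomness derives from one seed via counter-derived
sub-streams, so e.g. missingness masks never perturb event draws and the
same seed yields byte-identical output.

What the generator does **not** emulate: reporting delays and stimulated
reporting, PT co-occurrence structure, indication-dependent channelling,
dose/duration, country-specific coding habits, and informative (non-MCAR)
missingness. Passing tests therefore validate the estimators and the
pipeline plumbing under a clean reporting model — not robustness to the
biases of real spontaneous data.

## Validation experiments and problem sizes

The experiment module fixes the study conditions used by the test suite
and the acceptance script:

- **Recovery**: planted ψ = 5 with baseline odds 0.02 and exposure
  probability 0.2 at n = 100 000; the estimate must fall in [4.5, 5.5]
  (a band wide relative to the Wald SE at those counts) in ≥ 95% of 100
  replicates.
- **CI coverage**: the 95% Wald interval contains ψ in 93–97% of 500
  replicates at n = 20 000. Wald log-OR intervals are known to undercover
  slightly at moderate counts (~94% here), which the band accommodates.
- **Null calibration**: with all ψ = 1, the signal rule fires for ≤ 4% of
  screened (exposure, PT) pairs — 100 seeds × 8 independent null PTs at
  n = 20 000, so the Monte-Carlo rate concentrates near the nominal
  one-sided 2.5% — and the CIs cover 1 in 93–97% of pairs.
- **Logistic recovery**: a planted age-group odds multiplier of 2.5
  (18–34 vs 0–17) at n = 50 000 with balanced age groups, so the reference
  stratum carries enough events for a well-conditioned Wald interval;
  recovered within [2.0, 3.0].
- **Oracles**: the Fisher p is checked against an exact-rational
  hypergeometric enumeration over every 2×2 table with all margins ≤ 12;
  the exact Wilcoxon p against brute-force rank-assignment enumeration for
  group sizes ≤ 8; the 2×2 logistic OR against ad/bc to 1e-6; BH against
  the hand-applied step-up rule.

The published-arithmetic checks run on a synthetic margin-faithful cohort
(44 895 cases) whose asserted marginal counts equal the published cohort
totals; only those margins are faithful, and the cohort exists to verify
the descriptive operations' counting and rounding, not to stand in for
real data. Headline RORs against the full reporting database (e.g. the
overall psychiatric ROR or the extreme iris-term RORs) are **not**
reproducible at desk scale because the non-exposed comparator cells are
never published; they are deliberately out of scope.

## Known limitations

- Exact-key deduplication cannot separate true duplicates from chance key
  collisions, and will not find duplicates that differ in any key field.
- Per-drug RORs depend on the mutually-exclusive exposure convention; a
  convention counting combination cases toward each constituent FQ would
  give different per-drug rows.
- The Wald CI and the Haldane–Anscombe correction are conventional but not
  optimal at very small counts; no shrinkage (EBGM/IC) methods are
  provided, as ROR is the sole statistic in scope.
- kNN imputation helps only to the extent that age/sex correlate with the
  observed features; under weak correlation its k-donor sampling noise can
  exceed the gain over marginal imputation.
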