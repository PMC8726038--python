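# Methods

This note documents the statistical procedures, the synthetic-data model,
and the design choices the package makes where the underlying workflow left
the design open.

## Instruments and scoring

Items carry an explicit direction: NRS (0–10), the EQ-5D-3L dimensions
(1–3), and the HOOS-PS total are higher-is-worse; OHS items and total
(0–48), EQ VAS (0–100), and the 7-point anchor are higher-is-better.
Direction recoding reflects a higher-worse value onto `min + max − value`,
an involution, so multi-item analyses (Cronbach α) always operate on a
common higher-is-better scale.

Instrument totals are **complete-case** by default: the OHS total and the
HOOS-PS 0–100 rescaling are absent whenever any constituent item is absent.
This mirrors per-question denominators that differ item by item in routine
registry data, and it keeps every reported n auditable.  The OHS's official
rescue rule (mean imputation for up to two missing items) is available as
`score_ohs_total(..., impute_missing=True)` but is off by default.
HOOS-PS items are modelled on the standard 0–4 scale with a linear 0–100
rescaling; the published nomogram transformation is out of scope because the
triage rule never uses the HOOS-PS.  EQ-5D index values are value-set
dependent and likewise out of scope; only raw dimensions and the EQ VAS are
handled.

## Triage semantics

A rule is an ordered list of worse-side threshold criteria grouped under the
clinical criteria *pain* and *crutches*.  The allocation policy is a plain
disjunction — any crossed criterion sends the patient to hospital — chosen
because the clinical intent of the rule is liberal: every patient who might
need a physical examination should be seen.  Missing rule items are treated
as not crossed but are reported per patient; a patient with *every* rule
item missing is `UNALLOCATABLE`, routed operationally by a configurable
default (hospital, the conservative side) and excluded from the hospital
proportion's denominator.  Only patients with a returned questionnaire at
the triage timepoint are evaluated at all.

For the two-cohort allocation comparison the package builds the 2×2
hospital/video table and reports **both** the uncorrected Pearson chi-square
and the continuity-corrected (Yates) variant, falling back to Fisher's exact
test when an expected cell is below 5 or a margin is zero.  The two variants
disagree visibly at these sample sizes (p ≈ .166 vs ≈ .187 on the
201/502 vs 150/313 table), so reporting one number silently would hide a
method choice; the corrected value is the headline by default.  The
Monte-Carlo calibration check uses the uncorrected variant, which is the
nominally calibrated one.

## Clinimetric selection

The six quality checks run in a fixed order — distribution, floor,
responsiveness, journey, correlation, homogeneity — so that redundancy
pruning and homogeneity operate only on otherwise-valid questions.  The
order is logged in every report.  Numerical choices:

* **Quartiles** use linear interpolation between order statistics
  (`numpy`'s default); the method is configurable and recorded because
  statistics packages differ in their quantile conventions.
* **Floor effect** flags strictly above 15% (15 of 100 passes, 16 fails).
* **Responsiveness** uses a Wilcoxon signed-rank test implemented in the
  package: zero differences are discarded, the exact tie-aware null
  distribution of the positive-rank sum is used for ≤ 25 nonzero pairs
  (dynamic programming over the 2ⁿ sign assignments; counts stay below 2⁵³
  so float arithmetic is exact), and the normal approximation with
  continuity and tie corrections beyond.  All-zero differences give p = 1.
  The rank-biserial correlation (W⁺−W⁻)/(W⁺+W⁻) is kept as the effect size.
* **Correlation** uses Spearman with average ranks and pairwise-complete
  deletion; Cronbach α uses listwise-complete rows — mirroring the
  different per-question denominators each analysis naturally has.
  Flagged pairs (|ρ| at or above the cutoff) form a graph; within each
  connected component exactly one question is kept.  The default keeper is
  the most responsive question (largest |rank-biserial|, ties broken
  lexicographically); an explicit keep-list reproduces an expert choice
  deterministically.
* **Two profiles.** The stated criterion for redundancy is |ρ| ≥ 0.7, but
  the workflow's documented removals occurred at 0.659 and −0.676 —
  consistent only with a 0.6 cutoff.  Rather than silently resolving the
  discrepancy, both profiles ship: `stated` (0.7, responsiveness keeper)
  and `paper` (0.6, keep-list = NRS activity).
* **Journey.** Respondents are split by whether their 3-month score crosses
  the question's threshold, and each group's 12-month scores are
  summarised.  The question is flagged when the worse group's 12-month
  median no longer crosses ("scored well" later); a more lenient
  worse-side-quartile policy is available.  The *removal* step additionally
  requires the worse group to reach `journey_min_group` (default 5)
  patients: trajectories of a handful of patients carry a warning, not a
  verdict.  This guard reflects how tiny journey groups are handled in
  practice — a group of one cannot overturn a question.
* **Homogeneity.** α = k/(k−1)·(1 − Σ item variances / variance of totals),
  sample variances (n−1).  For groups of ≥ 3 items, an item is a removal
  candidate only when deleting it *strictly* raises α **and** the deleted α
  clears 0.7; two-item groups cannot lose an item.  α is undefined (NaN)
  when the total score has zero variance.

Every removal records the earliest stage that fired, and re-running the
selection on the retained rule is a fixed point (no further removals).

## Synthetic cohorts

The generator is a latent-Gaussian (ordinal-probit / Gaussian-copula)
model.  Patient i at timepoint t has latent severity
`s_it = μ_t + b_i + u_it`, with a persistent patient effect
`b ~ N(0, 1.1²)` and occasion noise `u ~ N(0, 0.25²)`; preoperative mean
μ_PRE = 2.2 latent units above the postoperative plateau
(μ_M3 = μ_M12 = 0).  Item j's latent is `z_jt = λ_j s_it + e_jt` with
loading λ (0.8 for most items; 0.65 for EQ-5D q4 and OHS q8/q12 so the pain
group's internal consistency stays mid-range; 0.5 for the anchor).  The
residual vector e is correlated across items (base 0.10, engineered blocks
below) and is 97% persistent across timepoints, giving item-level
3→12-month correlations near 0.95.  Ordinal scores arise by cutting the
item latent at per-item, per-timepoint cutpoints placed from explicit
category probabilities (severity-ordered, so a worse latent maps to a worse
score under either item direction); the EQ VAS uses a rounded linear map.

The default configuration emulates the study conditions: training n=746
(surgery 2016–2017) and test n=482 (2018); nonresponse 0.2% / 5.5% / 7% at
the three timepoints with a 0.4% per-item skip (deceased rate 0, consistent
with the printed response-rate arithmetic); demographics with age ≈ 66,
BMI ≈ 26, 41% male, 55% ASA I, and the four-level Charnley mix.  Marginal
category profiles reproduce the published 3-month medians/IQRs
qualitatively: OHS question 10 is quasi-degenerate at its best score (88%
modal mass), EQ-5D question 1 has no mass on "confined to bed" after
surgery, floors stay below 15% everywhere, and every preoperative profile
sits far enough from its 3-month profile that responsiveness p-values are
vanishingly small at n ≈ 700.  Residual-correlation blocks engineer the two
redundant pairs (NRS rest–NRS activity 0.75, NRS activity–OHS q1 0.65 on
the residual scale), which lands their observed Spearman correlations in
the 0.62–0.73 band — above the replication cutoff, with the rest of the
matrix staying clearly below it.

**Calibration.** The probability of crossing at least one final-rule
threshold at 3 months is monotone in a rigid shift of the 3-month
cutpoints, so bisection on a common-random-numbers Monte-Carlo estimate
(20 000 draws) hits any attainable target; the study-like fixture targets
0.29.  The fixture applies the same shift to the 12-month cutpoints so the
recovery plateau (12 months not worse than 3 months in distribution) is
preserved.

**What the generator does not emulate.** Real 3-to-12-month trajectories
regress toward recovery more than the fixture's strongly persistent
residuals do — the fixture is built so that threshold-crossers still cross
at 12 months, which is what makes the journey stage's "no removal" outcome
reproducible by construction rather than a coin flip.  Real cohorts also
contain informative missingness, clustered comorbidity, and EQ-5D index
structure, none of which are modelled.  Passing tests therefore demonstrate
that the *procedures* behave correctly under known structure, not that the
synthetic cohorts are interchangeable with clinical data; the group alphas,
for example, sit near 0.65 (pain) and 0.55 (crutches) rather than the
0.82/0.63 a real pain construct produced.

**Problem sizes.** The calibration uses 20 000 Monte-Carlo draws
(standard error ≈ 0.003 at a 0.29 rate); the parameter-recovery check uses
100 replicate cohorts of 1000 patients per target rate, restricted to the
six rule items; the null-calibration check uses 500–1000 replicate cohort
pairs at the study's sizes.  These sizes put every Monte-Carlo conclusion
several standard errors inside its acceptance band while keeping a full
run in seconds.

## Baseline comparison

Continuous variables are screened per sample with Shapiro–Wilk at α = .05
(the specific normality check is a package choice; it is configurable):
both-normal pairs get Welch's t-test (pooled available), anything else the
asymptotic Mann-Whitney U with tie correction and continuity.  Categorical
variables get Pearson's chi-square, or Fisher's exact for 2×2 tables with
an expected cell below 5.  ASA is compared as I vs II–IV, gender as
male/female, Charnley on its four levels.  Degenerate inputs (identical
constant samples) report p = 1 with the method recorded.

## Known limitations

* The selection procedure fixes a stage order the workflow itself never
  stated; a different order could in principle prune a different question
  (the shipped order applies redundancy pruning only to otherwise-valid
  questions, which is the conservative reading).
* The journey stage's strictness is essentially untested by real data —
  no question was ever removed for journey reasons — so its default policy
  (median re-crossing, minimum group size 5) should be treated as a
  reasoned convention.
* Triage validity against clinician judgment (sensitivity/specificity of
  video allocation) is out of scope: the package reproduces and stress-tests
  the tool-building workflow, not its clinical validation.
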