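# Methods

`bimodal_shift` analyzes longitudinal speech-perception outcomes in bimodal
cochlear-implant (CI) users — people with a CI in one ear and a hearing aid
(HA) in the other — with a focus on whether the acoustically aided,
nonimplanted ear *declines* after implantation. This note documents the
statistical machinery, its assumptions, the synthetic-data model the tests
run on, and the design choices made where the design was genuinely open.

## The critical-difference statistic

A speech score is the proportion of correctly repeated items out of n
(a 50-word list, n = 50). Two scores from an unchanged listener still
differ because of binomial measurement error, so per-subject change is
judged against a binomial critical difference, generalized by Monte-Carlo
simulation to unequal item counts n1 ≠ n2 (e.g. one 50-word list versus the
average of three, n2 = 150).

For a candidate pair of true proportions (p1, n1), (p2, n2), each iteration
draws k1 ~ Binomial(n1, p1) and k2 ~ Binomial(n2, p2) and records
d = |k1/n1 − k2/n2|. Over many iterations (default 40,000),

    z = mean(d) / sd(d),

and the pair is declared significantly different when z exceeds a critical
value (default 1.96, nominally a two-tailed 5% test). For a given n1, n2,
the p2 grid values with z ≤ 1.96 against a given p1 form the *critical
range*; the full table over all p1 is exportable.

Two evaluation routes exist and must agree:

* **Monte-Carlo simulator** (`simulate_abs_diff_z`) — the construction
  above, with the sample (n−1) standard deviation.
* **Exact enumeration oracle** (`exact_abs_diff_z`, `exact_z_grid`) — for
  (n1+1)(n2+1) ≤ 10^6 outcome pairs, the full joint distribution of
  (k1, k2) is enumerated, giving the exact mean and *population* standard
  deviation of d with no sampling error. The estimator difference is
  negligible at 40,000 iterations; the oracle has no sampling to correct
  for.

`compare_scores` uses the oracle automatically whenever the grid fits the
guard (so all standard clinical list sizes are evaluated exactly and
deterministically) and falls back to simulation otherwise. Observed scores
need not lie on the grid — a score averaged over sessions is evaluated
directly at its off-grid proportion rather than snapped to a table row,
since the construction is well defined for any p in [0, 1].

**Degenerate spread.** When p ∈ {0, 1} on both sides, every draw is
identical and sd(d) = 0. The contract is: z = 0 when mean(d) = 0 (identical
certain scores are never significant) and z = +∞ when mean(d) > 0
(maximally distant certain scores always are).

**Operating level: the statistic is anti-conservative.** z compares the
mean/sd ratio of the *folded* (absolute) difference distribution to 1.96.
For |N(μ, σ²)|, mean/sd reaches 1.96 when |μ| ≈ 1.84σ — not 1.96σ — so
"z > 1.96" flags observed differences beyond roughly 1.84 standard
deviations, a two-sided operating level near 6.6% rather than 5%. Exact
enumeration over the n1 = n2 = 50 grid with a common true proportion
uniform on [0.2, 0.8] puts the per-direction false-flag rate at 3.80%
(range 3.55–4.08% across p), not the nominal 2.5%. The test suite computes
this operating characteristic by enumeration and pins the simulated rate to
it; the acceptance suite also carries a test asserting the *nominal*
2.5%-per-tail bound, which fails for this structural reason — it is kept
failing rather than loosened, because it documents a real property of the
procedure. Expected-chance-flag counts computed with (α/2)·N therefore
understate the true chance expectation by roughly 50%.

**Monotone separation and contiguity.** Exact z generally grows as p2 moves
away from p1, but small decreases (< 0.2 in z) occur adjacent to the grid
boundary, where the shrinking binomial variance outpaces the growing mean
difference. All such dips sit below the 1.96 cutoff: over every (n1, n2)
pair with n1, n2 ≤ 25, all critical ranges are contiguous. The tests record
the dips; nothing repairs them.

## Effective N

Word tests contribute `n_lists × items_per_list` independent items.
Sentence tests scored by keywords are assigned a conservative effective
N = 40 regardless of the nominal keyword count (102–142 per list for the
registered sentence tests), because keywords within a sentence are not
statistically independent. The registry is data, not code: new tests are
added as `TestRegistryEntry` rows.

## Cohort model and filter cascade

A cohort is subjects (demographics, device metadata, preoperative PTAs not
derivable from sessions) plus sessions (phase, months since surgery, the
nonimplanted ear's unaided audiogram, HA-verification method, and up to
three condition scores: implanted / nonimplanted / bilateral). I/O is two
CSV files with wide audiogram columns (`thr_<freq>hz`) and per-condition
score columns; `read_cohort` collects all row-numbered validation problems
before failing, and write→read is an identity on valid cohorts.

* **Pure-tone average** defaults to the mean of 500/1000/2000 Hz — the most
  common clinical convention; the frequency set is configurable everywhere
  it is used. Missing frequencies raise rather than impute.
* **Filter cascade** (the nested-subset presets): all subjects (25 dB
  *absolute* PTA-change design rule), HA-verified sessions only, then PTA
  *increase* capped at 20, 10, 5 dB. The 25 dB baseline uses absolute
  change while the tighter rules penalize only worsening; the 5 dB rule is
  implemented as increase-only for consistency with 20/10. Verification
  failures drop the whole session (the HA is implicated in two of three
  conditions); PTA violations drop only that session's nonimplanted-ear
  datapoint. Every removal is logged with subject, session, scope, and
  reason, so every N in the output tables is auditable.
* **Aggregation**: "latest" takes the chronologically last usable score at
  its own effective n (ties broken by file order with a logged warning);
  "average" takes the unweighted mean of session proportions with effective
  n equal to the sum of per-session effective n.
* **Could-not-test** preoperative scores mark the subject not-testable for
  that condition's pre/post comparison — they are never coded as 0%.

Note: when reproducing published nested-subset tables of this design, row
counts can disagree by one between a published report's text and its table (e.g. 92
vs 91 for a tightest-subset row); this pipeline reports whatever the stated
rules produce.

## Group analysis

Paired pre/post differences on the 0–100 scale are tested two-tailed with a
paired t-test, switching to the Wilcoxon signed-rank test when Shapiro–Wilk
on the differences rejects normality at α = 0.05 (gate and α configurable;
the branch taken is recorded in the output). Wilcoxon drops zero
differences per the signed-rank convention. Degenerate inputs short-circuit
explicitly: all-zero differences give p = 1; a constant nonzero shift gives
p = 0. Rows with fewer than three surviving pairs are marked not-computable
rather than raising.

## Associations

The change variable is post − pre throughout (a drop is negative); the
implanted-ear advantage is the implanted-ear score minus the
nonimplanted-ear score, both postoperative aggregates. All change variables
are built from HA-verified datapoints only. Pearson correlations take
two-tailed p from t on n−2 df; the first-order partial correlation uses

    r_xy.z = (r_xy − r_xz·r_yz) / sqrt((1 − r_xz²)(1 − r_yz²)),

p from t on n−3 df, verified to 1e-10 against the residual-regression
construction and cross-checked against an independent implementation in the
tests. When an input is perfectly collinear with the control the residual
is the zero vector, which supports no remaining association: the function
returns r = 0, p = 1 instead of raising. Binary demographics are coded 0/1
(point-biserial) with documented mappings; missing values are dropped
pairwise and degenerate variables are skipped with a log entry.

## The synthetic cohort generator

No subject-level data are distributed with the multicenter study this
design follows, so everything is exercised on synthetic cohorts whose
structure matches the analysis' assumptions. Defaults
(`study_like_config`): 132 subjects; 1 + min(Poisson(1.5), 10)
postoperative sessions (mean 2.5, range 1–11); lognormal follow-up with
mean ≈ 37 months; preoperative HA-ear true scores truncated-normal with
mean 0.44 (sd 0.22, a free parameter chosen to give a realistic spread —
no published variance exists to target); postoperative CI-ear true scores
high (mean 0.65); preoperative could-not-test probabilities 29/132 (CI ear)
and 41/132 (bilateral); verification mix 81/41/10 of 132
(thresholds / clinician report / unknown).

The HA-ear change model is, in percentage points,

    change_i = β0 + β1·advantage_i + ε_i,   ε ~ N(0, σ²),

with defaults β0 = −3.5, β1 = −0.18, σ = 8 — an advantage-linked decline
whose group mean (≈ −7.4 points) and advantage correlation (|r| ≈ 0.5) sit
on the scale of published bimodal-cohort observations; no mechanism is
claimed. Unaided thresholds rise by a zero-inflated exponential total
(P(0) = 0.6, mean 6.25 dB among risers → overall mean 2.5 dB) spread
linearly over follow-up, heavy-tailed enough that a few subjects per cohort
exceed the 20 dB filter. Observed scores are exact binomial draws at the
session test's effective n — precisely the noise model the
critical-difference procedure assumes, which is what makes calibration and
recovery assertions meaningful.

What the generator does *not* emulate: per-frequency audiogram shapes
beyond what PTA filters need, aided thresholds or HA gain, test-retest
correlation beyond binomial noise, learning/practice effects, site
differences in test material difficulty, and dropout correlated with
outcome. Passing tests therefore demonstrate the pipeline's correctness
under its own assumptions, not robustness to those real-world departures.
Latent true scores are clipped to [0.005, 0.995] after applying the change,
which slightly attenuates a built-in decline for subjects near floor
(≈ +0.7 points at β0 = −7.5 with these defaults); recovery tests use an
empirical band across seeds rather than assuming exact unbiasedness.

## Problem sizes and runtimes

Oracle/simulator agreement is asserted over every grid pair for
(n1, n2) ∈ {(25,25), (10,25), (5,5)} at 10^5 iterations (absolute 0.1
band where exact z ≤ 10, relative 2% beyond — the Monte-Carlo standard
error of z grows as ≈ 0.005·z, so an absolute band far above the decision
threshold would only measure simulation noise). Null calibration uses
10,000 pairs; decline recovery uses 50 seeds at n = 132. The whole suite
runs in about a minute on one core.

## Known limitations

* The anti-conservative operating level described above is a property of
  the published construction; a calibrated alternative (e.g. thresholding
  the signed difference at its exact binomial quantiles) would change
  verdicts near the boundary and is deliberately out of scope.
* The critical-range tables report contiguity instead of guaranteeing it;
  no violation has been observed for n ≤ 25.
* The pipeline models no within-subject session correlation; averaging
  across sessions assumes exchangeable binomial draws at a fixed true
  score.
* Expected-false-positive counts use the nominal (α/2)·N rule for
  comparability with published analyses despite the operating-level caveat.
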