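# Methods

## Setting and observation model

Two sources document the same children's fever episodes independently.
Parents keep a real-time diary in a mobile app (ecological momentary
assessment): timestamped entries carrying an optional body temperature
(0.1 °C resolution), ternary yes/no/unanswered flags for physician
visit, antipyretic and antibiotic use, and a "child healthy" marker. A
pediatric office keeps structured per-visit fever records: each row is
one episode, either *acute* (the child presented febrile at the visit)
or *past* (reported retrospectively when the physician asked about
fever since the last visit), with visit date, maximum temperature, and
medication flags.

The data are clustered: families (identified by a shared 8-character
lowercase code) contain child profiles, which contain episodes, which
contain entries. Every indicator is attached to its level; aggregating
across levels changes the answer, which is why the report carries the
full accounting at all three.

## Episode segmentation

A fever episode is a maximal run of one profile's entries in which no
inter-entry gap exceeds `gap_hours` (default 48). The comparison is
strict: a gap of exactly 48 h stays within the episode; anything longer
opens a new one. Consequences worth stating:

* entries with no fever-relevant content still count for timing — the
  rule operates on timestamps, not content;
* the "child healthy" button would naturally end an episode, but users
  forget to press it, so the gap rule is authoritative. A healthy
  marker followed within the gap by further entries is surfaced as a
  count (`healthy_marker_conflicts`) in the report but never splits an
  episode.

Episode aggregates: maximum temperature is the maximum of submitted
values (missing if none); each binary flag is true iff any entry
answered yes. Unanswered flags coerce to "no" (*negation coercion*) —
the registry's questions are informative-mandatory but technically
voluntary, so non-submission and negation are deliberately conflated at
episode level, and the completeness indicator is what captures the
non-submission.

## Profile linkage

Identifiers differ across sources, so children are linked within each
family code by gender and month/year of birth (the app stores no day).
Per family: adults are set aside; profiles with identical
(gender, month/year) collapse to the earliest-created profile
(synonymous duplicates — two caregivers registering the same child on
two devices before synchronization); remaining children are matched
one-to-one maximizing matched pairs, preferring full (gender AND
birth-date) agreement, then earlier office registration. If exactly one
child and one patient remain unmatched in a family they are linked
regardless of agreement: the original adjudication used children's
names, which a de-identified pipeline cannot, and without this fallback
a matched pair could never disagree on both fields at once. Which
source is *wrong* on a mismatch is deliberately not decided; mismatches
are reported symmetrically, and a missing app birth date is incomplete,
not discordant.

Profile-level DQIs over the matched links: completeness =
submitted/matched, concordance = (matched − mismatched)/matched.

## Episode matching

Nothing in either export says which office record corresponds to which
diary episode, so correspondence is a declared convention with explicit
windows: acute records pair with the app episode whose interval
contains the visit date, else the nearest app episode starting within
±7 days; past records pair with the most recent app episode ending at
most 60 days before the reporting visit. Both windows are parameters,
and `analysis/04_window_sensitivity.py` quantifies their influence.

Rather than a sequential greedy pass, the pairing solves a
maximum-cardinality assignment (scipy `linear_sum_assignment`) with a
dominant base weight per admissible pair and small bonuses for
containment over proximity and nearer over farther. This guarantees the
maximum possible number of pairs (verified against an exhaustive oracle
on small instances), determinism, and invariance to input order. One
office visit closes at most one app episode.

Agreement grading on paired episodes: binary flags compare post-
coercion; temperatures agree only exactly at the shared 0.1 °C
resolution (|Δ| < 0.05 °C) and are not comparable if either side is
missing. Temperature differences are signed app-minus-office.

## Indicators and statistics

Completeness and concordance are binomial k/n with exact two-sided 95%
Clopper–Pearson intervals from beta quantiles; exact intervals are
conservative (empirical coverage ≥ nominal, property-tested).
Completeness is computed in both directions (app agreements against the
office episode total and vice versa). The acute-versus-past difference
in temperature agreement is tested with a Yates continuity-corrected
chi-square on the 2×2 table (the continuity term capped so a table at
its expectation scores 0); temperature-difference distributions are
compared acute-vs-past with a two-sided Mann–Whitney test (exact
enumeration for tie-free samples up to n = 20, tie-corrected normal
approximation with continuity otherwise, via scipy). Quartiles use the
inclusive linear-interpolation convention. The conventional 95% DQI
threshold is configurable and reported as a pass/fail flag per
indicator; p-values below 0.001 render as "<.001". No multiple-testing
adjustment is applied, matching the study design.

## Synthetic cohorts

The generator emulates the two-source setting with known ground truth.
Per child, true episodes arrive with exponential inter-arrival plus a
minimum spacing of 9 days between an episode's end and the next start,
so ground-truth episodes remain identifiable by the 48 h rule
(segmentation round-trip is exact, and a past report 2–5 days after an
episode cannot leapfrog into a neighbouring episode's window). Each
episode draws a true maximum temperature from a truncated normal (mode
39.2 °C, sd 0.6, range 38.0–42.4 °C, snapped to the 0.1 °C grid) and
true medication/visit flags.

Recording channels: an episode leads to an acute office visit with
probability 0.34; app recording probability is 0.623 given acute and
0.777 otherwise; a non-acute episode becomes a past office report with
probability 0.253 when app-recorded and 0.04 when not; 21% of families
install the app and never enter anything. These values are back-solved
from the study's cross-registry episode accounting so that the default
cohort (676 families, 16 months) reproduces its topline shape
(≈1452 app / ≈953 office / ≈686 paired episodes, acute/past and
in-app coverage splits). Per-variable submission probabilities are
*unknown* in reality; the defaults approximate the observed marginal
response rates and are documented as approximations. Temperatures get
N(0, 0.3 °C) app noise, N(0, 0.2) office noise for acute records, and
N(+0.4, 0.3) for past records — recalled temperatures are biased
upward. Demographic errors (gender flip 0.7%, birth-date error 1.2%,
missing 0.8%) and structural anomalies (duplicate profiles, non-patient
siblings, adult profiles, never-registered children) corrupt the
linkage surface at roughly the observed rates.

`expected_dqi` gives the analytic expectations implied by a
configuration. For a binary flag with prevalence π and submission
probabilities q_a, q_o, agreement fails only when exactly one channel
submits a true yes: E = 1 − π(q_a(1−q_o) + q_o(1−q_a)); the visit
variable composes this over the acute/past mixture (acute office
records are visits by definition). Temperature agreement multiplies
both submission probabilities by the probability that two independently
noised copies of a grid-valued truth round to the same 0.1 °C cell,
computed by summing products of normal-CDF differences over the grid.
The pipeline recovers these expectations within three binomial standard
errors pooled over 20 seeds (property-tested). The expectation ignores
the rare (≈0.1% at defaults, zero when `p_office_report_past_noapp=0`)
mispairing where an unrecorded episode's past report falls into a
neighbouring episode's window.

What the generator does **not** emulate: behavioural change over time
(education effects, declining use), within-episode temperature
trajectories, correlated submission across variables, seasonal fever
clustering, and visit-date transcription errors. Passing tests
therefore demonstrate that the pipeline measures what the model
generates — not that real parents behave like the model.

## Reconstructed study cohort

`feverdq.cohort.reference_cohort()` is a deterministic synthetic
dataset built to the published marginal counts: the profile exclusion
cascade (1047 → 1012 comparable), demographic error counts (6 gender,
11 birth-date, 1 both, 8 missing), the episode Venn partition
(133/85/953 = 681 acute + 272 past office; 686 paired = 424 acute +
262 past; 766 app-only; 29 unidentifiable), and the per-variable
agreement tables on the 686 paired episodes. Episodes sit on a sparse
55-day slot grid so segmentation and pairing recover the intended
structure exactly; every published rate, interval, chi-square and
coverage fraction then falls out of the ordinary pipeline. Two printed
marginals are internally inconsistent with the agreement counts they
accompany (the corresponding-episode antipyretic and visit margins of
the office, and the office temperature-response margin); the
reconstruction prioritizes the corresponding-episode agreement counts,
which are what every indicator consumes.

## Numerical and design choices

* Timestamps are timezone-naive local time at minute resolution.
* Ternary flags serialize as `yes`/`no`/empty; empty means unanswered.
* Temperature plausibility bounds [34.0, 43.5] °C are a configurable
  validation default bracketing the observed range (36.2–42.4 °C).
* The office visit table carries an optional per-record physician-visit
  flag (acute records default to yes, past to no): past episodes can
  involve visits elsewhere, and the observed office visit margins
  exceed the acute count, so the flag cannot be derived from the
  acute/past kind alone.
* Report JSON has fixed key order and no timestamps: byte-identical
  across runs on identical inputs. Internal rates are never rounded;
  rendering follows the 1-to-2-decimal percent conventions of the
  domain's reporting style.
* Problem sizes in tests (synthetic cohorts of 60–150 families, 20-seed
  recovery runs) are chosen to exercise every code path with tight
  statistical tolerances while keeping the whole suite in a few
  seconds.

## Known limitations

* Linkage is deterministic; genuinely ambiguous families (same-sex
  twins born in one month) cannot be told apart and will collapse as
  synonymous duplicates — exactly as the real pipeline would.
* The pairing convention is validated by conservation and oracle
  properties, not against a gold-standard correspondence, because none
  exists in either source.
* Which source errs on a demographic or episode-level disagreement is
  not adjudicated.
* The Mann–Whitney statistic on the reconstructed cohort depends on the
  synthetic difference patterns, not on unpublished raw differences;
  it is reported but is not a reproduction target.
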