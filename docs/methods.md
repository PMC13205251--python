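# Methods

This note documents the models, rules and numerical conventions
implemented in `promlock`, the design choices made where the methodology
was genuinely open, and what the synthetic validation does and does not
demonstrate.

## Unit of analysis and eligibility

The unit of analysis is the *treatment episode* (one patient, one
institution, one course of definitive treatment). Episodes enter the
analysis cohort when their free-text histology label maps to the Malignant
or Intermediate tier of a three-tier tumor-behavior framework and a time
anchor can be derived. The behavior mapping is user-supplied data
(`behavior_mapping.csv`), not code: labels are matched case- and
whitespace-insensitively, and any label that is unmapped, empty, or
explicitly flagged ambiguous resolves to Unclear and is excluded. The
package ships only a small illustrative mapping for simulated cohorts.

Exclusions carry exactly one primary reason, screened in order: behavior
tier (BENIGN / UNCLEAR) before anchor availability (NO_ANCHOR). An
unanchored benign episode is therefore logged BENIGN.

## Hierarchical time anchor

T0 is the start of definitive treatment, taken strictly by availability:
surgery date, else radiotherapy start, else systemic-therapy start. The
hierarchy is *not* chronological — a present surgery date anchors the
episode even if a radiotherapy start date precedes it. "Valid and
interpretable" is operationalized as an ISO-parseable date within
[1990-01-01, run date]; dates outside that range are treated as missing
(this applies to all three anchor fields, since the plausibility argument
is the same for each). Unparseable date strings are record-level input
errors that name the episode, not silent missings.

## Locked windows and selection rules

All offsets are whole days (observation date − T0); day 0 counts as
pre-treatment, on the view that a questionnaire completed on the morning
of surgery reflects the pre-treatment state. Window bounds are inclusive
on both ends.

| window | bounds (days) | target | fallback |
|---|---|---|---|
| baseline | −90 .. +14 | 0 | +15 .. +90 (flagged early-post) |
| 12 months | 180 .. 365 | 270 | — |
| 24 months | 660 .. 820 | 730 | — |

Follow-up selection minimizes |day − target|; an exact tie breaks to the
earlier day (deterministic, and favors data closer to the anchor period).
Baseline selection is two-step: within the preferred window, pre-treatment
observations (day ≤ 0) win, taking the one nearest T0; only if none exists
is the post-treatment observation nearest T0 taken; only if the preferred
window is empty is the fallback window consulted (earliest day), and the
assignment flagged early-post. Among several pre-treatment observations we
take the one *closest to T0*, not the most negative offset; this is an
interpretive choice, documented here rather than asserted as the only
reading of "closest to T0 with preference given to pre-treatment".

An observation with both metrics missing is never selectable even when it
is nearest the target. Several observations on the same day collapse to
the one with more non-missing metrics, then the first by input order
(logged). A window is *evaluable* when the selected observation carries at
least one of the two metrics; evaluability denominators are always the
full eligible cohort.

## Traffic-light classification

Thresholds (all configurable; defaults are the prespecified operational
values):

* absolute state — index RED < 0.75, GREEN ≥ 0.85; VAS RED < 50,
  GREEN ≥ 70. RED if *any* present metric is below its RED bound; GREEN
  only if *both* metrics are present and meet their GREEN bounds;
  otherwise YELLOW. A single-metric window can be RED or YELLOW but never
  GREEN — GREEN is kept a strong, two-metric claim.
* change — minimal important differences of 0.03 (index, utility units)
  and 5 (VAS points); improvement is Δ ≥ +MID in either paired metric,
  deterioration Δ ≤ −MID in either. The flags are deliberately
  non-exclusive (one metric can improve while the other deteriorates).
* ceiling — a high baseline is index ≥ 0.90 and/or VAS ≥ 80; it is both a
  reporting stratifier and an ingredient of the downgrade rule.

Final color: absolute RED always wins. Absolute GREEN becomes YELLOW only
when the episode meaningfully deteriorated from a high baseline. Absolute
YELLOW escalates to RED on meaningful deterioration; this reading of
"deterioration suggesting transition toward an unacceptable state" as
deterioration itself is the most conservative total rule, and the
escalation is a config switch (`escalate_on_deterioration`) because
stricter variants (e.g. requiring proximity to the RED bound) are
defensible. Episodes without a computable baseline pair are classified on
absolute state alone — change is undefined there, and keeping them in the
denominator matches the reporting convention in which change rows have
smaller denominators than traffic-light rows.

All threshold comparisons are exact at the instrument's native precision:
index values are compared as integer hundredths and VAS as integers, so
boundary semantics (0.75 is not RED; 0.85 with VAS 70 is GREEN; Δ exactly
±MID triggers) never depend on float representation.

## Stability classes

Among episodes evaluable at both follow-ups, five classes are assigned by
first-match rules over (final color at 12 m, final color at 24 m, change
flags between the two follow-up observations, same MIDs): persistent low
(RED at both), stable high (GREEN at both without deterioration), late
decline (deterioration without improvement, or color worsening without
improvement), late improvement (the mirror), mixed (everything else).
The class *names and ingredients* are fixed by the framework; the exact
rule set is the package's own concrete realization — it is total and
deterministic over all 3×3×2×2 input combinations (verified by
enumeration), the rule order is load-bearing (an improving RED→RED episode
stays persistent low), and it is isolated behind a single function so
alternative rule sets can be swapped. Color ordering is
RED < YELLOW < GREEN. When the two follow-ups hold disjoint single metrics
(no paired metric), both change flags are treated as false and the colors
alone decide.

## Statistical comparisons

Categorical rows use the Pearson chi-square statistic without continuity
correction at every table size, including 2×2 — this convention exactly
reproduces the published benchmark p-values recomputable from the count
tables (0.373, 0.014, 0.041, 0.420, 0.139, 0.103, 0.036). All-zero
category columns are dropped before testing; degenerate tables raise
rather than return NaN. Continuous rows use the two-sided Mann–Whitney U
test: exact enumeration of the permutation distribution (midranks under
ties) when the pooled sample size is ≤ 12, and the normal approximation
with tie-corrected variance and continuity correction above that. The
crossover at 12 keeps the exact path under ~1,000 enumerated assignments
while covering the sample sizes where the normal approximation is
materially inaccurate. Quartiles use linear interpolation between order
statistics (a convention choice; other interpolation rules shift IQRs by
small amounts). Percentages are reported to 2 decimals and p-values to 3;
no multiple-testing adjustment is applied. "Unknown" covariate levels are
shown descriptively but excluded from test tables by default, so
significance is never driven by differential missingness coding.

When an institution has no eligible episodes (or only one institution is
present), descriptive rows are still produced and every test is marked
not applicable.

## Synthetic cohort generator

The generator emulates the salient features of routine-care PROM capture
in a two-institution sarcoma network; it is the package's test bed, not a
claim about any real site.

Latent health h(t) ∈ [0, 1] per episode: constant h0 before T0, then a
dip of depth `dip` recovering exponentially at rate `recover_rate`/day
toward `plateau`, minus an optional linear decline of `decline_slope`/day
starting at `decline_onset`. Four archetypes parameterize this curve:

| archetype | h0 | dip | recovery /day | plateau | late decline |
|---|---|---|---|---|---|
| STABLE_HIGH | U(0.92, 1.0) | U(0.03, 0.12) | U(0.02, 0.05) | = h0 | none |
| DIP_RECOVER | U(0.92, 1.0) | U(0.30, 0.50) | U(0.008, 0.02) | = h0 | none |
| LATE_DECLINE | U(0.90, 1.0) | U(0.15, 0.35) | U(0.01, 0.03) | = h0 | onset U(365, 550) d, slope U(0.0008, 0.002)/d |
| PERSISTENT_LOW | U(0.45, 0.65) | U(0.10, 0.30) | U(0.005, 0.02) | U(0.25, 0.45) | none |

The near-ceiling h0 ranges for the high-functioning archetypes reproduce
the high-ceiling baseline distributions (median index near 1.00) typical
of this population; the PERSISTENT_LOW plateau sits well below the latent
level whose noiseless index readout equals the RED threshold
((0.75 − floor)/(1 − floor) = 0.84375 at the default floor), so the
archetype geometry cleanly separates designed-unacceptable trajectories
from the rest.

Observed PROMs map h affinely onto the instrument scales: index =
floor + (1 − floor)·h + Gaussian noise, clamped to [floor, 1.00] and
rounded to 2 decimals; VAS = 100·h + noise, clamped to 0..100, integer.
The index floor defaults to −0.60 (value sets permit utilities worse than
dead; the floor is configurable because no single instrument floor is
canonical). Default noise: SD 0.05 (index), 7 (VAS).

Visits follow a jittered schedule (defaults at days −30, 45, 120, 270,
365, 550, 730 with SDs 20–45 d) plus uniformly timed extra visits
(binomial, rate 0.15 per scheduled slot). A visit yields any PROM with
probability `logistic(logit(p_observe) + mnar_slope·(h − 0.5))`:
`mnar_slope = 0` is MCAR at `p_observe` (default 0.10, putting
locked-window evaluability in the 10–20% range that matches the sparse
capture the pipeline is designed for); positive slopes make sicker
episodes quieter ("treatment-fatigue" missingness). Metric-level dropout
(index or VAS individually missing, default 5% each) is separate and
MCAR, keeping the two mechanisms separable. Default sizes are 410 + 319
episodes with anchor-source probabilities 0.90/0.066/0.023 (remainder
unanchored) and a tier mix whose eligible fraction is ~68% malignant; the
capture process itself is only loosely calibrated to published
evaluability rates, since no distributional description of the real
process exists.

Internally all timing is integer day offsets from a per-episode T0;
calendar dates are materialized only on export (ISO-8601), avoiding
timezone and calendar ambiguity. Identical config + seed reproduce all
three output tables byte-for-byte.

What the generator does *not* emulate: EQ-5D-5L dimension-level responses
or value-set scoring (the index is consumed directly); oncologic events
(recurrence, death) as explicit processes — late decline is a
phenomenological slope; institution-level case-mix differences (both
simulated institutions draw from the same archetype mix unless configured
otherwise). Passing tests on synthetic cohorts therefore demonstrate that
the *pipeline machinery* is correct and that the missingness mechanisms
have the designed effects — not that any real institution's data would
behave this way.

## Validation problem sizes

The recovery check uses a 2,000-episode cohort (1,000 per institution)
with visits exactly at the window targets, full capture, no metric
dropout, small noise (index SD 0.01, VAS SD 2) and archetype mix 50/30/20
STABLE_HIGH/DIP_RECOVER/PERSISTENT_LOW: the pipeline's 24-month RED
proportion must fall inside the exact (Clopper–Pearson) 99% binomial CI
around the designed 20%. The MNAR-bias check runs 20 replicate pairs of
300-episode cohorts (`p_observe` 0.35, slope 0 vs 3) and applies a
one-sided sign test to the direction of the RED-proportion difference.
These sizes give comfortable statistical margins while keeping the whole
validation under a minute on one CPU.

## Known limitations

* The behavior-mapping content is input data; the package cannot validate
  the clinical correctness of a user's tier assignments.
* Thresholds and MIDs are pragmatic operational rules, not
  patient-anchored validated cutoffs; the package exposes them as
  configuration rather than endorsing them.
* The stability rule set is one concrete realization of a framework whose
  published description fixes names and ingredients but not rules;
  alternative realizations would change class counts.
* No risk adjustment or multivariable modelling of RED-status predictors
  is included; comparisons are benchmarking signals, not performance
  rankings.
* Figures (stacked bars, box plots) are not generated; all outputs are
  tables and JSON.
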