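# Methods and design notes

## Model

Each of the five nutritional diagnoses (protein-energy malnutrition, iron
deficiency anemia, vitamin B12 / folic acid / thiamine deficiency) is
modeled as its own discrete Bayesian subnet. A subnet's diagnosis node has
the three states `present`, `at_risk`, `absent`; its evidence nodes are the
discretized findings relevant to that diagnosis. Risk is a *state of the
diagnosis node*, not a separate node: the system reports a single
probability triple per diagnosis, which is what a three-state node produces
directly and is the simplest structure consistent with the intended output.

The qualitative structure couples causes and consequences in the way a
clinician would narrate them: dietary adequacy (and, where relevant, time
since surgery, vomiting, blood loss, diarrhea) *drives* the diagnosis node;
serum markers and physical signs/symptoms are *read off* it as children.
The feeding of markers to subnets is data, not code — it lives entirely in
the JSON spec files under `src/nutridss/data/` so that dietitians can
revise variables, arcs or probabilities without touching the engine:

| subnet | causes (parents) | findings (children) |
|---|---|---|
| iron deficiency anemia | intake, blood loss | hemoglobin, hematocrit, MCV, ferritin, paleness, weakness |
| vitamin B12 deficiency | intake, surgery time | serum B12, MCV, paresthesia |
| folic acid deficiency | intake | serum folate, MCV |
| thiamine deficiency | intake, surgery time, vomiting | paresthesia |
| malnutrition | intake, diarrhea | albumin, hair loss, nail/skin changes, weakness |

Assumptions worth stating: subnets are queried independently (no
cross-diagnosis arcs); evidence variables are conditionally independent
given their parents within a subnet; all variables are discrete; and the
CPTs are elicited/authored, never learned from data (structure and
parameter learning are out of scope by design).

### Placeholder CPTs

No conditional probabilities of the original clinical system are available,
so every shipped CPT is a placeholder marked `"cpt_provenance":
"placeholder"` in the file metadata. The authoring policy is deliberate:

* **weakly informative everywhere** — no probability is 0 or 1, so no
  evidence combination is impossible;
* **decisive likelihoods only for a subnet's private findings** (its serum
  marker, its owned signs): e.g. P(hemoglobin low | anemia present) = 0.85
  versus 0.03 when absent;
* **mild likelihood ratios (≲2) for findings shared between subnets**
  (MCV appears in three subnets, paresthesia and weakness in two): a
  finding common to several deficiencies has low specificity for any single
  one, and a strong likelihood in a subnet that is not its main driver
  would double-count the evidence;
* **serum markers are highly specific**: a 3% false-low rate in
  diagnosis-free patients.

The package's correctness claims attach to the inference engine and the
validation mathematics, never to these numbers; replacing them with
expert-elicited values is a data edit.

## Discretization

* Labs: `value < lower → low`, `value > upper → high`, and the **closed**
  interval `[lower, upper] → normal` — boundary values are normal (made
  explicit because a value *at* the reference limit is conventionally
  reported as within range).
* Intake: daily energy `< 1600 kcal → inadequate`, else `adequate`.
  1600 kcal/day is the minimum recommended for adequate macro- and
  micronutrient intake in this population. Direct kcal input takes
  precedence; otherwise energy is estimated from Food-Guide-Pyramid portion
  counts via the shipped kcal-per-portion table.
* Time since surgery: half-open bands `[0, 6)`, `[6, 24)`, `[24, ∞)`
  months. Thiamine depletion is an early event (stores last weeks, classic
  trigger is persistent vomiting in the first months); B12 depletion is
  late (hepatic stores last years); three bands capture both directions.
* Signs/symptoms: boolean flags map to `present`/`absent`. Nail changes
  and skin changes are pooled into one evidence node (`nail_skin_changes`,
  present if either flag is set) because they enter the malnutrition subnet
  as a single finding.
* Missing measurements contribute **no** evidence — never imputed, logged
  at DEBUG level. Units must match the declared unit exactly; there is no
  silent conversion (a `UnitMismatchError` names the marker and expected
  unit).

Reference intervals are configurable per marker and gender stratum (with
`any` as fallback); the shipped table stratifies hemoglobin, hematocrit and
ferritin by sex and uses common adult intervals. An age-band dimension is
supported by the schema but not populated in the defaults. An optional
average-weight-loss evidence variable is deliberately not present in the
shipped subnets; adding it is a spec-file edit.

## Inference

Exact posteriors by variable elimination: node CPTs become factors with
evidence axes sliced out; variables are eliminated by the **min-degree**
heuristic on the current factor graph with lexicographic tie-breaks, which
makes the computation (including floating-point rounding) independent of
evidence insertion order. Probabilities stay in linear space — subnets have
≤ 10 nodes, so underflow is not a concern and linear arithmetic is directly
comparable with the enumeration oracle. Junction trees and approximate
inference would buy nothing at this scale.

`enumerate_posterior` recomputes any posterior by summing the chain-rule
joint over all completions of the evidence (guarded to ≤ 2²² joint
assignments). It is the *independent reference implementation*: the test
suite requires total-variation agreement within 1e-10 on randomized
networks, and the recovery experiment re-checks the argmax label on every
synthetic case.

Zero-probability evidence raises a typed `ImpossibleEvidenceError` carrying
the offending evidence set — returning a uniform or NaN distribution would
silently corrupt downstream validation statistics. Inside a diagnosis
report the error is recorded per subnet and the other four diagnoses are
still computed.

The suggested label is the posterior argmax with exact ties resolved by the
priority `present > at_risk > absent` (the clinically cautious direction).
An optional display cutoff (`--min-report-prob`) can blank low-confidence
labels in CSV output, but labels themselves are always pure argmax — the
probability triple, not the label, is the deliverable.

## Validation statistics

* **Agreement** is exact label match on the three-state scale: calling a
  patient `at_risk` when the reference says `present` is a disagreement.
  Rates are reported raw and rounded.
* **Consensus**: unanimity → majority → adjudication, with per-entry
  provenance. Unresolved ties block export (`IncompleteConsensusError`)
  rather than defaulting. A single-rater panel passes through unchanged,
  making consensus idempotent.
* **Binary collapse**: `present` and `at_risk` are both positive — the
  clinical contrast of interest is *presence of risk or diagnosis* versus
  absence. Sensitivity and specificity use the plain ratios; an empty gold
  class leaves the statistic undefined (`None` plus a note), never 0/1.
* **ROC/AUC**: the continuous score is the positive posterior mass
  `P(present) + P(at_risk)`. Curve points at every distinct threshold
  (ties grouped), anchored at (0,0) and (1,1); area by the trapezoidal
  rule. The standard error is the Hanley–McNeil closed form
  `SE² = [A(1−A) + (n₊−1)(Q₁−A²) + (n₋−1)(Q₂−A²)]/(n₊n₋)`,
  `Q₁ = A/(2−A)`, `Q₂ = 2A²/(1+A)`; the 95% CI is `A ± 1.96·SE` clipped to
  [0, 1]. Exact binomial or DeLong intervals are legitimate alternatives
  and will differ near A = 1; the classical closed form was chosen for
  transparency and testability (the suite pins AUC to the Mann–Whitney
  identity `A = U/(n₊n₋)`, exactly for tie-free data and via midranks with
  ties).
* Diagnoses are validated independently with no multiple-testing
  correction — five separate descriptive summaries, not a family of
  hypothesis tests.

## Synthetic cohorts

The generator emulates the *design* of a 15-case, four-expert evaluation
with everything observable: latent truth, evidence, raw values, panels.

* **One global assignment per patient.** Evidence nodes are shared between
  subnets (one patient has one MCV), so subnets are ancestrally sampled in
  a fixed order (iron, thiamine, malnutrition, B12, folate) and a node
  already assigned by an earlier subnet is kept, not resampled. The order
  fixes which subnet "owns" each shared finding (iron owns MCV and
  weakness, thiamine owns paresthesia). Shared root nodes (`intake`,
  `surgery_time`) must be identical across subnet files — checked at load.
  Consequence: for a non-owner subnet a shared finding is generated by a
  neighbouring mechanism, which the mild shared-finding CPTs (above) are
  designed to tolerate.
* **Raw-value emission.** Each sampled lab state is emitted uniformly from
  an interval that discretizes back to exactly that state (`low` from
  [0.5·lower, 0.98·lower], `normal` from the closed reference interval,
  `high` from [1.02·upper, 1.5·upper]; analogous intervals for kcal and
  months). This guarantees the round-trip invariant
  `discretize(emit(state)) == state` by construction. Uniform emission is
  the simplest distribution with that property; marginal lab distributions
  are *not* clinically realistic and are not meant to be.
* **Panels.** Each rater reproduces the gold label with probability
  `1 − e` per diagnosis, otherwise errs uniformly over the two remaining
  states. The default error rates {iron 0.10, folate 0.07, B12 0.20,
  thiamine 0.13, malnutrition 0.08} are calibrated so expected agreement
  reproduces the published expert assertiveness band (90/93/80/87/92%).
  The uniform-error structure is replaceable via `rater_errors` profiles.
* **Recovery experiment.** Every synthetic case is diagnosed from its raw
  values; per diagnosis the report gives engine accuracy against latent
  truth, the enumeration oracle's accuracy on identical evidence (equal by
  oracle equivalence), their label agreement, and the majority-class
  baseline.

What passing these suites shows: the engine computes Bayes-correct
posteriors, the discretizer and emitter are inverse to each other, the
statistics are implemented correctly, and the whole pipeline runs end to
end. What it does **not** show: that the placeholder CPTs are clinically
calibrated, or how the system would perform on real patients — that
requires expert-elicited probabilities and a genuine case series.

## Problem sizes and numerics

Default experiment sizes: cohorts of 15 (study design) in examples, 100–500
cases in the test suites, 500 for recovery and round-trip checks; 100
random networks (≤ 8 nodes, 2–3 states) for oracle equivalence; 1000 score
sets for the AUC identity; 200 replicates of 60 labels for panel
calibration. These sizes give stable statistics (binomial SEs well below
the asserted tolerances) while the whole suite runs in seconds.

Tolerances: CPT rows must sum to 1 within 1e-9 (auto-renormalization is
available but off by default — spec files are hand-edited, and silent
renormalization would hide authoring errors); posterior normalization 1e-9;
oracle equivalence 1e-10 total variation; evidence-order invariance 1e-12.
All tie-breaks (elimination order, topological order, argmax) are
lexicographic or by fixed priority, so every computation is deterministic.

## Known limitations

* Placeholder CPTs: outputs are structurally meaningful but not clinically
  calibrated.
* The five-subnet architecture cannot represent cross-diagnosis
  dependence (e.g. combined deficiencies sharing one macrocytic picture);
  a shared-finding model would need a merged network with explicit
  combination rules.
* Hanley–McNeil/normal CIs are crude near AUC = 1 (they collapse to a
  point when SE = 0); exact binomial or DeLong methods are preferable for
  publication-grade intervals.
* Only Roux-en-Y gastric bypass is modeled; other procedures have different
  deficiency profiles. Osteoporosis and zinc deficiency are not modeled.
* The generator emits complete evidence; real cases have missing labs.
  The engine handles missingness (it simply enters less evidence), but the
  recovery statistics do not measure its effect.
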