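# Methods

## The care-pathway model

Out-of-hospital management of a chronic disease is modelled as a set of
recurring pathway tasks executed jointly by a specialist, a general
practitioner and a case manager around a self-monitoring patient. Eight
task kinds are in the engine's scope — risk assessment, hierarchical
management (stratification), regular follow-up, abnormal-condition
intervention, medication guidance, lifestyle guidance, health education and
compliance management. Diagnosis precedes enrollment and is performed in
hospital, so it is not an engine task. COPD has two further exclusions that
mirror how such pathways are deployed in practice: the management level is
read directly off the risk-assessment grid (no separate stratification
task) and medication guidance is left to care providers.

Knowledge is declarative: YAML rules with a positive-conjunctive condition
over a published fact schema and a task-emitting action. The evaluator
forward-chains to fixpoint so that task generation can cascade (e.g. a
stratification task enables the follow-up rule). The dialect is monotonic —
negation-as-failure is excluded, and absence tests are expressed as
pre-computed boolean facts such as `no_bp_record_7d` — which makes the
derived task set independent of rule ordering. Termination follows from the
at-most-once firing contract on `(rule_id, dedup_key)`; the default dedup
key of a periodic rule embeds the scheduling-period index (anchored on the
enrollment date), giving once-per-period semantics. Ties among
equal-priority rules break lexicographically by `rule_id` for
reproducibility.

## Clinical parameters

All thresholds live in `EngineConfig` and are configurable; defaults are
standard guideline values:

| parameter | default | unit |
|---|---|---|
| BP target | < 140 / 90 | mmHg |
| urgent single BP | SBP ≥ 180, DBP ≥ 110, SBP < 90, DBP < 60 | mmHg |
| weekly BP warning | 7-day mean ≥ target with ≥ 3 readings | — |
| BG targets (FBG / PBG) | < 7.0 / < 10.0 | mmol/L |
| hypoglycemia / severe hyperglycemia | < 3.9 / ≥ 16.7 | mmol/L |
| PEF notice / urgent zone | < 80% / < 60% of personal best | — |
| CAT scale warning | score ≥ 10 | — |
| HTN level II follow-up | 14 (configurable 14–28) | days |
| compliance window / low threshold | 7 / 0.5 | days / fraction |

Stratification: HTN level I iff the trailing 7-day mean BP meets target,
else II. T2DM banding refines "at BG target" into three monotone levels:
I when both fasting and postprandial means are at target, II when exactly
one is, III when neither is or any hypoglycemic reading occurred. COPD uses
the 2×2 grid of symptom burden (CAT ≥ 10) × exacerbation risk (≥ 2
exacerbations or ≥ 1 hospitalization in 12 months), ordered I–IV. With
fewer than 3 relevant readings the most intensive level is assigned and
flagged provisional, mirroring the initial management period before formal
classification. Calendar arithmetic uses 3 months = 90 days and
1 month = 30 days; all windows are half-open `[start, end)`.

Multimorbidity merging takes the minimum follow-up interval, the per-kind
maximum monitoring frequency, and the set union of lifestyle items;
conflicting prescriptions (e.g. "increase exercise" vs "moderate
exercise") resolve to the most conservative variant as declared by conflict
groups in the HM merge ruleset.

## The synthetic cohort

The simulator emulates the statistical shape the evaluation methodology
assumes, with a known ground truth: demographics (age 58 ± 12.3 y, 57.1%
male) and disease mix (77.3% HTN, 12.9% T2DM, 4.4% HM, 5.4% COPD) match a
realistic telehealth population; each patient submits disease-appropriate
record kinds under a Bernoulli compliance model (mean 0.7, SD 0.15 across
patients).

Outcome dynamics are a design choice, not an empirical claim: daily values
follow patient baseline + confounder effects + treatment effect + AR(1)
deviations (coefficient 0.7). Baselines are SBP 145 (10) mmHg, FBG 8.5
(1.5) mmol/L, PEF 320 (40) L/min. Each completed intervention phases the
true effect in linearly over 30 days; the default injected effects are
−5 mmHg SBP, −1.5 mmol/L FBG, +5 L/min PEF. Treatment propensity is
logistic in standardized age, ordinal management level, an abnormal-warning
indicator and standardized management time — exactly the four-confounder
causal graph the estimators assume — with each confounder also entering the
outcome (defaults: 0.4/2.0, 0.4/2.0, 0.8/4.0, 0.3/−1.5 on the
treatment-logit and outcome scales respectively), so the naive contrast is
biased by construction (≈ 1.2 mmHg toward zero at the defaults). An
episode-level generator (`simulate_causal_rows`) draws directly from this
structural model for estimator validation at scale; the longitudinal
generator embeds the same structure in full record streams. The ground
truth (true effects, baselines, treatment log) is written to a separate
manifest that neither the engine nor the estimators read.

What passing tests on this cohort do **not** show: the simulator has no
informative missingness beyond the compliance model, no provider behavior
change over time, no measurement-device error structure, and a constant
(homogeneous) treatment effect, so recovery here demonstrates estimator
correctness under the assumed causal graph, not robustness to real-world
violations of it.

## Estimation and numerical choices

* Paired *t*: t = mean / (sd/√n), df = n − 1, two-sided p from the t
  distribution; degenerate (zero-variance or n < 2) inputs raise. p-values
  across spans are reported uncorrected, flagged in output metadata; the
  nominal significance level is two-sided 5%.
* Before/after windows: `[enrollment, +14 d)` and `[span, span + 14 d)`;
  patients lacking records in either window are excluded.
* Causal extraction: one treated episode per intervention (outcome = mean
  over the following month); control episodes are intervention-free 2-week
  windows, at most one per patient per 30-day block, placed
  seed-deterministically to limit within-patient dependence. The
  abnormal-warning confounder comes from the warning log when provided and
  is otherwise re-derived from the records via the urgent thresholds.
* Propensity model: main-effects logistic MLE (statsmodels Logit; Newton,
  falling back to BFGS under quasi-separation). Age and management time are
  standardized with fixed population constants (58/12.3 y, 360/210 d) so
  scores are comparable across subsets.
* PSM: 1:1 nearest-neighbor on the raw score, with replacement; ties break
  by a seed-controlled shuffle; optional caliper (default off; a treated
  unit with no in-caliper control raises a positivity error). PSS: 5
  equal-frequency strata; strata missing a class are dropped and counted;
  the ATE is the retained-share-weighted mean of stratum contrasts.
* Refuters: placebo (treatment permuted, expect ≈ 0), random common cause
  (independent noise covariate added to the propensity model, expect a
  small shift), subset (80% resamples, expect stability); pass tolerances
  default to 0.5 outcome units and are configurable.

## Problem sizes

Tests and the acceptance script use 5000 episodes for estimator recovery,
a 150-patient / 90-day longitudinal cohort for the before/after and
descriptive analyses, and 3000 requests for the efficiency metrics — sizes
at which Monte-Carlo error is comfortably inside the assertion tolerances
while the whole suite runs in seconds.

## Known limitations

The bundled rulesets reconstruct the pathway-task inventory faithfully but
cannot be verified rule-for-rule against any deployed system; warning
thresholds and the T2DM banding are standard-guideline reconstructions and
deliberately configurable. PSM as implemented averages over treated units
(the ATT); under the homogeneous-effect simulation ATT = ATE, but the two
diverge under effect heterogeneity. OWL/RDF serialization, service
endpoints, UIs and messaging integrations are out of scope.
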