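# nutridss

Bayesian-network decision support for **nutritional diagnosis after
Roux-en-Y gastric bypass**.

Bariatric surgery predictably causes malabsorption, and the classic
long-term consequences are protein-energy malnutrition and deficiencies of
iron, vitamin B12, folic acid and thiamine. `nutridss` implements an
intelligent decision-support system for the *nutrition diagnosis* step of
the Nutrition Care Process: given a patient's demographics, biochemical
markers, food-intake adequacy and signs/symptoms, it computes for each of
the five standard diagnoses the posterior probability that the condition is
**present**, that the patient is **at risk** of developing it, or that it is
**absent** — and suggests (never dictates) a categorical label. The audience
is dietitians and clinical-informatics teams following bariatric patients,
plus anyone who needs a small, fully-verifiable discrete Bayesian-network
engine with a validation toolkit.

## The model

Each diagnosis *D* has its own subnet: a discrete Bayesian network whose
joint distribution factorizes by the chain rule,

```
P(X1, ..., Xn) = Π_i P(Xi | parents(Xi)),
```

with `D ∈ {present, at_risk, absent}` linked to evidence variables —
discretized labs (`low/normal/high` against reference intervals),
food-intake adequacy (`inadequate` below 1600 kcal/day), time since surgery,
and sign/symptom flags. Entering evidence *e* and applying Bayes' theorem
gives the posterior `P(D | e)`, computed exactly by **variable elimination**
(min-degree heuristic, lexicographic tie-breaks) and cross-checked in the
test suite against brute-force enumeration of the joint.

Validation follows the standard protocol for diagnostic decision support:
expert raters label each case on the three-state scale; disagreements
resolve by consensus (unanimity → majority → adjudication) into a gold
standard; the system is scored by exact-match agreement and — after
collapsing `present`/`at_risk` into "positive" — by sensitivity
`TP/(TP+FN)`, specificity `TN/(TN+FP)`, and an ROC curve on the score
`s = P(present) + P(at_risk)` with trapezoidal AUC, Hanley–McNeil standard
error and a 95% normal CI clipped to [0, 1].

No real cohort ships with the package. The conditional probability tables
in `src/nutridss/data/` are **placeholders** (weakly informative,
literature-plausible, marked as such in each file's metadata); the
correctness claims attach to the engine and the validation mathematics, and
a synthetic-cohort generator with known latent truth exercises every
pipeline stage end to end.

## Worked example

```python
from nutridss import DiagnosisEngine, PatientCase

case = PatientCase.model_validate({
    "patient_id": "example_01",
    "gender": "female", "age": 38, "months_since_surgery": 30,
    "labs": {
        "hemoglobin":  {"value": 10.8, "unit": "g/dL"},
        "ferritin":    {"value": 8.0,  "unit": "ng/mL"},
        "mcv":         {"value": 78.0, "unit": "fL"},
        "vitamin_b12": {"value": 450.0, "unit": "pg/mL"},
        "folic_acid":  {"value": 5.1,  "unit": "ng/mL"},
        "albumin":     {"value": 4.1,  "unit": "g/dL"},
    },
    "intake": {"energy_kcal": 1350},
    "signs": {"paleness": True, "hair_loss": True},
    "symptoms": {"weakness": True, "blood_loss": False, "paresthesia": False,
                 "vomiting": False, "diarrhea": False},
})

report = DiagnosisEngine().diagnose(case)
for diag, r in report.results.items():
    p = r.posterior.distribution
    print(f"{diag:24s} present={p['present']:.3f} at_risk={p['at_risk']:.3f} "
          f"absent={p['absent']:.3f}  label={r.label}  score={r.score:.3f}")
```

prints

```
malnutrition             present=0.109 at_risk=0.531 absent=0.360  label=at_risk  score=0.640
iron_deficiency_anemia   present=0.957 at_risk=0.043 absent=0.000  label=present  score=1.000
vitamin_b12_deficiency   present=0.038 at_risk=0.380 absent=0.581  label=absent  score=0.419
folic_acid_deficiency    present=0.029 at_risk=0.384 absent=0.586  label=absent  score=0.414
thiamine_deficiency      present=0.004 at_risk=0.067 absent=0.928  label=absent  score=0.072
```

Reading it: low hemoglobin and ferritin with microcytosis, paleness and
weakness in a patient with inadequate intake make iron deficiency anemia
nearly certain (`present` 0.957); the same poor intake puts her *at risk*
of malnutrition (0.531) while normal B12/folate levels and the absence of
paresthesia leave the remaining diagnoses `absent`. The `score` column is
the positive posterior mass `P(present)+P(at_risk)` that the ROC analysis
thresholds. The label is suggestive, not authoritative — the full triple is
always reported.

### sklearn composition

The engine is also exposed as estimators: `CaseDiscretizer` (a transformer)
and `BayesianNetworkClassifier` (a classifier with `predict_proba` /
`predict`, fitted by validating and freezing the expert-specified network):

```python
from sklearn.pipeline import Pipeline
from nutridss import BayesianNetworkClassifier, CaseDiscretizer, KnowledgeBase

kb = KnowledgeBase.load()
pipe = Pipeline([
    ("discretize", CaseDiscretizer()),
    ("clf", BayesianNetworkClassifier(kb.network("iron_deficiency_anemia"),
                                      query="iron_deficiency_anemia")),
]).fit([])
pipe.predict_proba([case])        # posterior triples, one row per case
```

### Command line

```bash
nutridss simulate --n 15 --seed 7 --out study/          # cases.csv, gold.csv, panel.csv
nutridss diagnose --cases study/cases.csv --out reports.csv --format csv
nutridss validate --system reports.csv --gold study/gold.csv \
                  --out validation.json --roc-plot roc/
```

## Layout

```
src/nutridss/
  network.py     discrete nodes, CPTs, validation, joint, ancestral sampling
  inference.py   variable elimination + enumeration oracle, argmax labelling
  knowledge.py   subnet JSON loading, reference ranges, discretization
  engine.py      per-case diagnosis reports, binary collapse, risk score
  estimators.py  sklearn-style CaseDiscretizer / BayesianNetworkClassifier
  validation.py  agreement, consensus, sensitivity/specificity, ROC/AUC
  cohort.py      synthetic patients, simulated panels, recovery experiment
  io.py, cli.py  file formats and the nutridss command
  data/          five subnet specs, reference ranges, JSON schema
docs/methods.md  modelling and design notes
```
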