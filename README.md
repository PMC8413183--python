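# uveaclass

A toolkit for uveitis classification criteria: a deterministic rule engine
for published criteria/exclusion rule sets evaluated under three-valued
(Kleene) logic, plus the machine-learning pipeline used to derive such
criteria — feature recoding, shadow-feature (Boruta-style) selection,
per-stratum multinomial lasso regression, and distillation of the fitted
model into a human-readable rule system that makes the same decisions.

Three rule sets ship as data (JSON rule DSL): SpA/HLA-B27-associated
anterior uveitis, Fuchs uveitis syndrome, and acute retinal necrosis.
Because the underlying multi-disease patient database is not public, a
synthetic cohort generator produces labeled case collections from rule
sets so the whole pipeline is testable end to end.

## Layout

| module | role |
| --- | --- |
| `uveaclass.clinical_vocab` | case data model, vocabulary registry, CSV/JSON cohort I/O |
| `uveaclass.criteria_engine` | rule expression trees, Kleene evaluation, exclusion dominance, rule DSL |
| `uveaclass.synthetic_cohort` | labeled synthetic cohorts with noise/missingness and stratified splits |
| `uveaclass.ml_derivation` | binary recoding, Boruta-style selection, multinomial lasso (own FISTA solver) |
| `uveaclass.rule_distillation` | decision-tree student → DNF rules, agreement auditing |
| `uveaclass.evaluation` | accuracy/misclassification reports with Wilson 95% CIs, pipeline driver |

Rule sets, the vocabulary registry and JSON Schemas live under
`src/uveaclass/data/`.

## Quick start

```python
import numpy as np
from uveaclass import shipped_rulesets, classify_case, generate_cohort, CohortSpec

rulesets = shipped_rulesets()
cohort = generate_cohort(CohortSpec([(rs, 1.0) for rs in rulesets],
                                    n_cases=500, flip_noise=0.05, seed=1))
result = classify_case(cohort.cases[0], rulesets)
print(result.verdicts, result.final_labels)
```

Verdict semantics: a true exclusion dominates (`excluded`); otherwise
criteria `T` → `classified`, `U` → `indeterminate`, `F` →
`criteria_not_met`. Unknown findings propagate as Kleene `U`; exclusions
require positive evidence, so an untested patient is never excluded.

## CLI

```sh
uveaclass simulate --config config.json --out cases.csv          # synthetic cohort
uveaclass classify --cases cases.csv --rules spa_hla_b27 --out verdicts.json
uveaclass derive   --cases cases.csv --class anterior --out model.json
uveaclass distill  --model model.json --cases cases.csv --out rules_derived.json
uveaclass evaluate --cases cases.csv --model model.json --out report.json
uveaclass run      --config config.json --out-dir artifacts/     # full pipeline
```

A pipeline config names either a simulation recipe or a case file:

```json
{
  "seed": 1,
  "simulate": {
    "diseases": [{"ruleset": "spa_hla_b27"}, {"ruleset": "fuchs_uveitis"}],
    "n_cases": 600, "train_fraction": 0.7,
    "flip_noise": 0.0, "missing_rate": 0.0
  },
  "boruta": {"n_iter": 30, "n_estimators": 50},
  "lasso": {"lambda": "cv"}
}
```

`uveaclass run` executes simulate → split → recode → select → fit →
validate → distill and writes `cases.csv`, `model_<stratum>.json`,
`rules_derived_<stratum>.json`, per-split confusion matrices and
`report.json` (accuracy per stratum and misclassification rate per
disease, each with Wilson 95% CIs). Reruns with the same config are
byte-identical.

## Notes

* Defaults for selection (500 trees, 100 iterations) and the
  cross-validation design (stratified 5-fold, 20-point log-spaced λ grid,
  one-standard-error rule) are documented conventions — the source
  publications do not specify them.
* The synthetic generator's distributions are a testing device and are
  deliberately not calibrated to any patient population.
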