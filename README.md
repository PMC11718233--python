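# keeperllm

Phenotype-algorithm validation on OMOP CDM data via standardized
patient-profile extraction and LLM-based case adjudication.

Observational studies on claims and EHR data depend on *phenotype
algorithms* — code-plus-logic definitions of who has a condition.
Validating them classically requires manual chart review, which is
expensive, unportable, and usually yields only the positive predictive
value. This package implements the alternative workflow: extract a
standardized, clinically organized profile of each candidate case from
structured data (the KEEPER approach — symptoms, disease history,
diagnostics, differentials, treatments per disease-specific concept
sets and time windows anchored at the index date), have a
text-completion backend adjudicate "did this patient truly have the
disease?", and use the resulting large-scale *silver standard* to
estimate both PPV and sensitivity of any phenotype algorithm:

- PPV = tp / n_flagged,  sensitivity = tp / n_silver_pos, with exact
  Clopper–Pearson 95% intervals;
- for binary adjudicators, AUC = (sensitivity + specificity) / 2;
- gold standards from leave-one-out majority votes over complete
  reviewer blocks.

It is aimed at observational-health researchers (OHDSI-style pipelines)
who want to quantify outcome misclassification without per-case manual
review. Real patient-level sources cannot be shared, so the package
includes a seeded synthetic-data generator that plants known
case/non-case structure in a toy OMOP vocabulary; a deterministic
rule-based mock backend makes the whole pipeline runnable and testable
offline, and HTTP/replay backends connect it to real models.

## Worked example

The `keeperllm` command chains the stages; every stage writes an
artifact plus a manifest, and reruns at a fixed seed are
byte-identical.

```bash
keeperllm simulate --disease ra --n-persons 2000 --prevalence 0.1 --seed 1 --out sim
# simulated 2000 persons, 204 true cases (10.2%)

keeperllm cohort --cdm sim/cdm --concept-set sim/concept_set_diagnoses.json --out cohort.csv
# diagnoses: 280 persons

keeperllm extract --cdm sim/cdm --cohort cohort.csv --config sim/keeper_config.yaml --out profiles.jsonl
# extracted 280 profiles

keeperllm adjudicate --profiles profiles.jsonl --config sim/keeper_config.yaml \
    --backend mock --out verdicts.jsonl
# adjudicated 280 profiles: 203 yes, 0 failures

keeperllm evaluate --verdicts verdicts.jsonl --reference sim/truth.csv --out report.csv
#    label   n  n_pos  n_neg sensitivity specificity  auc sensitivity_ci specificity_ci
# verdicts 280    204     76       99.5%      100.0% 1.00   97.3%-100.0%   95.3%-100.0%

keeperllm characterize --silver verdicts.jsonl --flags cohort.csv --out oc.json
# PPV 72.5% (66.9-77.6%), sensitivity 100.0% (98.2-100.0%)
```

Reading the numbers: 280 persons carry a qualifying diagnosis code, of
whom 204 are planted true cases. Against planted truth the mock
adjudicator reaches 99.5% sensitivity and 100.0% specificity (it
demands corroborating evidence beyond the diagnosis code, which planted
cases have and spurious codes lack). Treating its verdicts as a silver
standard, the first-occurrence diagnosis algorithm shows PPV 72.5% —
the planted spurious-code rate drags it below 1 — while its sensitivity
is 100.0% because every silver-positive person necessarily carries a
diagnosis code. The same `adjudicate` stage drives a real model by
swapping `--backend http --endpoint … --api-key-env MY_KEY` (or
`--backend replay --transcript …` for recorded regression runs);
long runs checkpoint to the output JSONL and `--resume` skips persons
already adjudicated.

The library mirrors the CLI one-to-one (`simulate_population`,
`first_occurrence_cohort`, `high_sensitivity_cohort`,
`extract_profiles`, `build_messages`, `adjudicate_cohort`, `metrics`,
`operating_characteristics`, …); see `docs/methods.md` for the
modelling conventions and design choices.

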