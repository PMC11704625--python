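# cogdiag

Digital-phenotyping markers and rule-based cognitive diagnosis, end to end:

1. **Synthetic cohort** (`cogdiag.cohort`) — seeded generator of raw
   participant streams (daily acceleration totals, location readings, EMA
   responses on a 1–5 Likert scale at 4 prompts/day, daily shape-test
   accuracies, journal entries, interview ratings) with configurable
   class-conditional structure. The default configuration emulates a study
   population of 124 older adults (75 healthy / 49 MCI, 89 female, age
   70.48 ± 8.72, ≥14 sensor days, 14% missing days).
2. **Marker extraction** (`cogdiag.markers`) — per-day home detection (modal
   10 m grid cell of the first 300 readings), activity/distance aggregates
   over non-missing days, EMA mean/variance/compliance, shape-test learning
   rate (OLS slope of the first 6 scores) plus score mean/SD, and min-max
   rescaling of real-valued markers to a 0–10 integer axis fit on a
   reference cohort.
3. **Text markers** (`cogdiag.textmarkers`) — deterministic journal features
   (vocabulary, sentence length, bundled emotion lexicons) and the eleven
   built-in text rules evaluated as computable predicates against
   cohort-relative thresholds.
4. **Rule induction** (`cogdiag.induction`) — CART-style Gini tree on the
   scaled marker table, converted to conjunctive if-then rules (one per path
   prefix) annotated with support (`pa`) and confidence (`pr`), filtered by
   `pa >= ceil(0.10 * n_train)` and `pr > 70`, with measured inversions of
   retained single-condition stump rules. Rules serialize to a plain-text
   DSL: `if <marker> <= <t> [and ...] then more likely <class>`.
5. **Inference engine** (`cogdiag.engine`) — builds the classification
   prompt (system message, numbered rule block, participant information,
   answer-format instruction), parses `Diagnosis: ...` responses by regex,
   and ships a pure deterministic backend (rule application + confidence-
   weighted voting, healthy tie-break) honoring the same prompt/response
   contract as any external text-generation backend.
6. **Selection & evaluation** (`cogdiag.evaluation`) — reference/training/
   test split (balanced 24+24 test, balanced 25+25 training from the
   reference set), accuracy / MCI precision / MCI recall / MCC, greedy
   wrapper selection over the six marker-family rule groups scored by
   internal stratified 5-fold cross-validation, and repeated-run mean ± SD
   reports.

## CLI

```bash
cogdiag simulate --seed 1 --out cohort.json
cogdiag markers  --cohort cohort.json --scaled --out markers.csv
cogdiag induce   --markers markers.csv --out rules.txt --max-depth 2 --seed 1
cogdiag classify --cohort cohort.json --rules rules.txt --out diagnoses.json \
                 --emit-prompts prompts/
cogdiag select   --cohort cohort.json --seed 1 --out selected.json
cogdiag evaluate --cohort cohort.json --runs 1 --seed 1 --out report.json
cogdiag query    --cohort cohort.json --group healthy \
                 --marker shape_score_sd --stat mean
```

`simulate` accepts `--config cohort.yaml` overriding any `CohortConfig`
field, including per-class generator effects. `evaluate` writes one report
row per marker family plus all-family fusion and wrapper selection (eight
rows). All commands are deterministic given `--seed` and write atomically.

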