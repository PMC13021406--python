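# lesionmatch

Feedback computation for diabetic-retinopathy (DR) annotation training.

Junior ophthalmologists learn to read fundus photographs by marking the
lesions that characterize DR — microaneurysms, hemorrhages, soft exudates and
hard exudates — and comparing their markings against a reference set of
detections. `lesionmatch` implements the computational core of such a
training loop:

1. **Lesion geometry** — drawn contours are rasterized in the pixel space of
   the image, dilated and morphologically closed so freehand gaps seal, holes
   are filled, and connected components become filled `Lesion` pixel sets
   ("the complete lesion, not just its outline").
2. **Greedy IOU matching** — for each pathology class independently, every
   reference lesion is compared against the still-unassigned learner-marked
   lesions by intersection over union, IOU(A, B) = |A ∩ B| / |A ∪ B|. The
   highest-scoring marked lesion is assigned and removed from the pool when
   its IOU reaches the threshold (**0.5, inclusive**, by default). Matched
   pairs are *correct*; unmatched marked lesions are *falsely input*;
   unmatched reference lesions are *missed*.
3. **Feedback reports** — per-pathology counts and the percentage of
   reference lesions found (100 · n_correct / n_reference), with categorized
   lesion lists ("All" / "Correct" / "Missed" / "False") color-tagged
   green / red / yellow.
4. **Severity grading** — an ordered, configurable rule table maps lesion
   counts to the five DR severity grades 0–4 (no DR → proliferative),
   ICDR-inspired but a documented stand-in, not a clinical instrument.
5. **Synthetic cases** — a seeded generator stands in for both the ML
   detector and the human learner, producing reference lesions plus perturbed
   markings (copy / small shift / relocate / drop / spurious) whose
   correct/false/missed outcomes are guaranteed by construction.
6. **Study metrics** — scoring for the usability and cognitive-load
   questionnaires used to evaluate such tools (SUS 0–100, 9-point Paas
   mental-effort, Naiive intrinsic/extraneous subscales).

## Worked example

```python
import lesionmatch as lm

case = lm.generate_case(lm.SyntheticCaseSpec(seed=42), lm.PerturbationSpec(seed=42))
result = lm.match_all(case.reference, case.marked)
report = lm.build_report(result, case.reference, case.marked)
for p in lm.PathologyClass:
    fb = report.pathologies[p]
    print(f"{p.value:>13}: {fb.n_correct}/{fb.n_reference} correct "
          f"({fb.percent_found:.1f}%), {fb.n_false} false, {fb.n_missed} missed")
sev = lm.grade_severity(case.reference)
print(f"severity grade: {sev.grade} ({sev.label}), rule: {sev.matched_rule}")
```

prints

```
microaneurysm: 0/2 correct (0.0%), 2 false, 2 missed
   hemorrhage: 1/4 correct (25.0%), 2 false, 3 missed
 soft_exudate: 0/2 correct (0.0%), 1 false, 2 missed
 hard_exudate: 2/3 correct (66.7%), 3 false, 1 missed
severity grade: 3 (severe), rule: soft_exudates_with_hemorrhages
```

Seed 42 emulates a fairly unlucky learner: of the four hemorrhages the
synthetic learner kept one copy in place (correct), relocated or mismarked
two (counted as *false*, with their originals *missed*), and dropped one.
The reference annotation itself carries hemorrhages together with soft
exudates, which the default rule table grades as severe (3). The expected
labels are part of the generated case (`case.expected`), so every number
above is checkable against the generator's bookkeeping.

The same flow is available from the shell:

```sh
lesionmatch simulate --seed 42 --out case42
lesionmatch evaluate case42/reference.json case42/marked.json --out reports
lesionmatch grade case42/reference.json
```

`simulate` writes reference/marked annotation JSON (with one mask PNG per
pathology) plus the expected outcomes; `evaluate` writes the report JSON and
a flat per-pathology CSV; exit codes are 0 (ok), 2 (input error),
3 (config error), 4 (internal error).

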