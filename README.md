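# docoutcome

Outcome prediction for disorders of consciousness (DOC) in the acute phase
after severe brain injury.

Patients surviving coma pass through Unresponsive Wakefulness Syndrome
(UWS) and the Minimally Conscious State (MCS) before emerging from DOC.
The standard bedside instrument, the JFK Coma Recovery Scale–Revised
(CRS-R), scores six behavioural subscales but applies stringent response
criteria, so subtle intentional behaviour — especially under cognitive
motor dissociation, where awareness is masked by blocked motor output —
is quoted at the reflexive level and the first assessment carries little
prognostic information.  This package implements an analysis pipeline in
which a 10-item binary Motor Behaviour Tool (MBT; items 1–5 positive motor
signs, 6–7 masking conditions, 8–10 pathological reflexes) complements the
CRS-R and turns the acute-phase assessment into an outcome predictor.

The pipeline has three statistical steps, applied to two primary outcome
classes (emerged from DOC versus remaining in DOC) and six
initial-diagnosis × outcome subclasses across nine planned comparisons:

1. **Nonparametric prediction from first assessments.**  Mann–Whitney U
   tests (exact by full permutation enumeration for n₁+n₂ ≤ 12, midrank
   ties; tie- and continuity-corrected normal approximation otherwise)
   compare first CRS-R subscores and MBT items between outcome groups,
   with Holm–Bonferroni family-wise error control.  Significant binary
   predictors are characterised by sensitivity, specificity and Yule's
   Q = (ad − bc)/(ad + bc).
2. **MBT-weighted CRS-R subscores.**  A subscale quoted exactly at its
   reflex level (auditory 1, visual 1, motor 2, oromotor 1, communication
   0) is raised by an increment δ ∈ {0.1, …, 0.9} whenever a mapped
   positive MBT item is present (items 1, 3, 5 raise all five subscales;
   item 2 the auditory/visual pair; item 4 the motor/oromotor pair).  An
   increment sweep re-tests every comparison at each δ and reports the
   critical increment — the smallest δ at which the Holm-corrected p falls
   below α.
3. **Longitudinal trajectory modelling.**  Each patient's subscale series
   is regressed on orthonormal polynomials of degree 0–3 (least squares on
   a canonical basis shared across patients), coefficients are screened
   with a Monte-Carlo Lilliefors normality check and tested within and
   between groups; group mean ± SEM curves yield the *discrimination time*
   (earliest day from which the outcome groups' bands stay disjoint) and
   the *cutoff-attainment time* (day the mean curve reaches the emergence
   cutoffs: motor 6 = functional object use, communication 2 = functional
   communication).

A transcription of the study cohort's per-patient demographics (33
patients: 20 UWS, 13 MCS) ships as a packaged fixture, and a seeded
synthetic-cohort generator emulates the longitudinal structure the paper
does not publish, so every stage is testable end to end.

## Worked example

```python
import numpy as np
from docoutcome import (load_fixture_cohort, patients_from_tables,
                        descriptive_comparison, enumerate_comparisons,
                        increment_sweep, critical_deltas,
                        generate, reference_scenarios)

# Step 0: the study cohort fixture
patients = patients_from_tables(load_fixture_cohort())
tables = descriptive_comparison(patients)
sub = dict(zip(tables["subclasses"].subclass, tables["subclasses"].n))
print(f"emerged (class 1): {sub['class1']}   remaining (class 2): {sub['class2']}")

# Steps 1-2 on a synthetic cohort with reflex-level first assessments
cohort = generate(reference_scenarios()["strong-separation"], seed=1)
comp = [c for c in enumerate_comparisons(cohort) if c.label == "class1_vs_class2"]
sweep = increment_sweep(cohort, comparisons=comp, deltas=[0.1, 0.5, 0.9])
print(critical_deltas(sweep).set_index("subscale").critical_delta)
```

prints

```
emerged (class 1): 21   remaining (class 2): 12
subscale
auditory         NaN
visual           0.1
motor            0.1
oromotor         0.1
communication    0.1
Name: critical_delta, dtype: float64
```

All 21 versus 12 patients match the published class split; the remaining
group's mean age recomputes to 39.83 (15.5) years.  In the synthetic
cohort both groups start at indistinguishable reflex-level CRS-R profiles
(the raw Holm-corrected p-values are 1.0 for every subscale), yet four of
the five MBT-weighted subscales discriminate the eventual outcome already
at the smallest increment — the weighted scores only reorder the groups
when positive MBT signs differ, which is precisely the information the
raw scale discards.  On the same cohort the fitted motor trajectories'
mean ± SEM bands separate from day 19, and the emerger group's mean curve
reaches the functional-object-use cutoff on day 43.

The same analyses are scriptable from the shell:

```
docoutcome simulate --scenario paper-like --seed 1 --out data/
docoutcome report --input data/ --seed 1 --out results/
```

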