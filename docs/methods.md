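# Methods

This note records the models, conventions and numerical choices behind
`docoutcome`, in the order the pipeline applies them, together with what
the synthetic-data tests do and do not establish.

## Diagnosis and outcome taxonomy

A CRS-R assessment is reduced to the five diagnostic subscales (auditory
0–4, visual 0–5, motor 0–6, oromotor 0–3, communication 0–2); the arousal
subscale is stored when present but excluded from every analysis, because
the UWS/MCS criteria and the emergence rule rest on the first five
subscales only.  Emergence from DOC is motor = 6 (functional object use)
or communication = 2 (functional communication).  Below emergence, a
profile is MCS when any subscale reaches its MCS threshold — auditory ≥ 3,
visual ≥ 2, motor ≥ 3, oromotor = 3, communication ≥ 1, the standard
CRS-R convention, shipped as an overridable table — and UWS otherwise.
Coma is outside the type system: study inclusion required UWS or MCS at
entry, and profiles below every threshold are labelled UWS.

Patients are cross-classified by initial diagnosis and discharge outcome
into subclasses (a) UWS→non-DOC, (b) MCS→non-DOC, (c) UWS→UWS,
(d) UWS→MCS, (e) MCS→UWS, (f) MCS→MCS; class 1 (emerged) = {a, b},
class 2 (remaining) = {c, d, e, f}.  The nine-comparison plan (class 1 vs
class 2; a vs c, a vs d, c vs d, a vs c∪d; b vs e, b vs f, e vs f,
b vs e∪f) is enumerated explicitly; comparisons with an empty side are
returned flagged as degenerate rather than dropped, so downstream tables
always have the same shape.  The discharge outcome is taken from the
recorded field; an optional validation mode cross-checks it against the
last assessment.

## The cohort fixture

`data/table3_cohort.csv` transcribes the study's per-patient demographics
verbatim (33 rows).  One aetiology cell carries a printing typo
("TBI (PO"); the normalised column corrects it to "TBI (Op)" and the raw
column preserves the original, since analyses use only the aetiology
category.  Aetiology strings map to tally categories through an editable
packaged lookup (`aetiology_map.csv`); the combined strings ("TBI, IS",
"IS, IVH") cannot be tallied unambiguously, so the lookup is a stated
convention, with parenthesised ruptured aneurysms counted under that
category.  Lesion strings parse into (region, laterality) pairs; the
tally category "Midbrain" covers both the mesencephalic and pontine
tokens, which is the only grouping that reproduces the published group
tallies.  "NA" encodes missing secondary endpoints and is excluded
pairwise from endpoint tables.

## Statistical primitives

**Mann–Whitney U.**  U is computed from midranks (ties get half credit).
For n₁+n₂ ≤ 12 (configurable) the two-sided p-value is exact: all
C(n₁+n₂, n₁) group reassignments are enumerated and p is the null
probability of a U at least as far from n₁n₂/2 as observed.  This
enumeration is valid under ties, which is why the exact path is
implemented here rather than delegated to library routines whose exact
method requires tie-free data; the suite cross-checks it against an
independent pairwise-counting brute-force oracle and, on tie-free data,
against the standard library implementation.  Larger samples use the
normal approximation with the tie-corrected variance and a 0.5 continuity
correction; an all-tied sample returns p = 1.

**Holm–Bonferroni.**  Step-down adjusted p-values, clipped at 1, with
monotonicity enforced along the sorted order; output in input order.
Families are always defined explicitly: the five subscales within one
comparison at one increment, the ten MBT items within one comparison, the
five subscales per (regressor subset, degree) in the longitudinal tests,
the tested variables of the descriptive table.  The increment sweep
itself is a search and is not corrected across increments.

**Binary predictor metrics.**  For a 2×2 table (rows: predictor
present/absent, columns: outcome positive/negative): sensitivity
a/(a+c), specificity d/(b+d), Yule's Q = (ad − bc)/(ad + bc).  A zero
denominator yields an undefined flag, never a substituted number.
Orientation: for MBT items 1–7 a present sign predicts emergence; for the
reflex items 8–10 a present sign predicts remaining in DOC (reflex
behaviour indicates deeper impairment); the orientation is configurable
per item.  Metrics are reported only where the Holm-corrected p-value is
below α, mirroring the dash convention of the published table.
Mann–Whitney is retained for binary items (a rank test on two Bernoulli
samples) for fidelity to the original analysis, rather than replaced by a
2×2 exact test; the descriptive table's categorical endpoints use
Fisher's exact test (small cells; the original does not name its test).

## MBT weighting and the increment sweep

Weighting fires only when a subscale sits exactly at its reflex level
(auditory 1, visual 1, motor 2, oromotor 1, communication 0) *and* at
least one mapped positive item is present; the subscale then scores
`level + δ` with δ ∈ (0, 1), so the weighted score approaches but never
reaches the next ordinal level, and the integer floor — hence the
behavioural diagnosis — is unchanged.  Scores below the reflex level are
never weighted, and negative/reflex items never enter weighting.  The
confirmatory MBT administered two days after the first is combined by
item-wise OR by default (a sign observed at either sitting counts),
configurable to first-only; the combination rule is a package convention.

A structural property worth stating: because weighted values stay strictly
inside an integer gap, the rank ordering of the pooled weighted scores is
identical at every δ in the grid, so the Mann–Whitney p-value is constant
along the sweep and the critical increment, when it exists, is the
smallest grid point.  The sweep is nevertheless reported per δ, as the
search procedure defines it; the constancy is asserted by tests.

## Longitudinal model

"GLM" here is ordinary least squares with identity link — a polynomial
regression in time.  The four monomials (degree 0–3) are orthonormalised
by QR decomposition on a uniform 101-point reference grid over the
canonical interval [−1, 1], an affine image of the analysis window
(default [0, 100] days); the orthonormality certificate max|GᵀG − I| must
be ≤ 1e−8.  Every patient's design matrix evaluates these same canonical
polynomials at the patient's assessment days, which makes coefficients
comparable across patients — orthonormalising per patient would not.
Rank-deficient designs (fewer assessments than regressors) get the
minimum-norm solution with a flag.

The combinatorial subset exploration covers all 15 non-empty subsets of
degrees {0, 1, 2, 3}.  Per (subset, subscale, degree) the pooled
coefficients are checked for normality with a Lilliefors test whose null
distribution is simulated (10,000 seeded replicates by default; the
add-one p-value estimator); each group's coefficients are tested against
zero with one-sample two-tailed t-tests, and the groups are compared with
a Welch t-test.  Both one-sample and two-sample results are reported side
by side: the original description is ambiguous about which carries the
between-class claim, so neither is silently preferred.

**Curves and timings.**  Group curves are pointwise means of per-patient
fitted curves with a standard-error band (ddof = 1; a single-patient
group gets a zero band), evaluated only over the observed day span —
polynomial fits are not trusted outside it.  Discrimination time uses a
persistence rule: the earliest grid day from which the two groups'
mean ± SEM bands are disjoint at every later grid day (default step
1 day); curves still overlapping at the window end return none.
Cutoff-attainment time is the earliest grid day the mean curve reaches
the emergence cutoff (motor 6, communication 2).  Discrimination curves
use the quadratic subset {0, 1, 2}: cubic fits of three-visit patients
are rank-deficient and oscillate at the window edges, producing spurious
band overlap, while straight lines diverge immediately and trivialise the
read-out.  Cutoff curves use the full cubic subset, because saturation at
the top of the scale needs curvature.  Ordinal scores are treated as
numeric throughout, as the source analysis does; no ordinal link is
attempted.

## Synthetic cohorts

No per-patient trajectories are published, so the generator is calibrated
to the summary statistics the study reports, and to nothing else.  Each
patient carries a latent recovery process L(t) = 1/(1 + exp(−(t − t50)/τ))
shared across subscales, with (t50, τ) drawn per (initial class, outcome)
cell; subscale k scores round(L·max_k), plus three outcome-independent
heterogeneity components: a per-patient reflex-level floor (probability
0.6 per motor-band subscale — persistent reflexive behaviour), a
per-patient vertical latent offset (SD 0.12, clipped to [0, 1] — stable
individual differences in behavioural level), and ±1 ordinal noise per
visit (probability 0.12), clipped to range.  Schedules emulate the
weekly plan: first assessment 11.2 ± 6 days post-insult truncated to the
28-day inclusion window, intervals 7.5 ± 2.9 days (≥ 2), follow-up
52 ± 15 days, at least three visits.  MBT items are one outcome-
conditional Bernoulli draw per patient, with default rates shaped by the
reported per-item sensitivity/specificity pattern.  Rejection sampling
(cap 1,000 attempts) enforces the structural constraints: the first
assessment diagnoses the intended class, emergers satisfy the emergence
rule at the last assessment, non-emergers never do; non-emergers'
discharge outcome is read off their last assessment.  Emerger trajectory
midpoints were chosen so that, within each initial-diagnosis class,
emergers and non-emergers are indistinguishable at the first assessment —
the study's central negative finding — and the outcome groups' curves
separate in the third week, matching the reported discrimination window.

Three reference scenarios ship: **paper-like** (sizes 20/13; the realized
emergence composition 11/20 UWS and 10/13 MCS is pinned, as in a cohort
with known outcome counts), **null** (identical trajectory and MBT
parameters for both outcome groups, constraints off, outcome labels
assigned independently — the exchangeable configuration for type-I-error
calibration), and **strong-separation** (an all-UWS cohort whose groups
share reflex-level first assessments but differ sharply in MBT profile
and recovery dynamics, with the vertical offset disabled so recovery
ground truths stay crisp).

**Ground truths for recovery checks** are defined as population
quantities of the generator, not as re-runs of the estimator: the
*separation day* is the first day the outcome groups' expected score
trajectories (class-mixture weighted, marginal over midpoints, floors and
noise) differ by half an ordinal point — the resolution of the scale;
the *cutoff crossing* is the crossing day of the population projection of
the expected emerger trajectory onto the basis, averaged over the
schedule distribution (projection commutes with the trajectory marginals
because the schedule is independent of the latent, so this is exactly the
estimand of the group mean curve; the schedule average uses a fixed-seed
draw of 500 designs).  The first-crossing read-out of a single replicate
is late-skewed because the fitted curve is nearly flat at the cutoff, so
the recovery tests compare the *median* discrimination day and the
crossing of the *replicate-averaged* curve against these truths.

**What the synthetic tests do not show.**  The generator reproduces
summary statistics (composition, schedules, emergence rates, item rates,
separation timing), not the distribution of real CRS-R trajectories:
real recovery is not logistic, subscales decouple (notably oromotor and
communication), measurement error is not ±1-uniform, and visit timing
correlates with clinical state.  Passing calibration and recovery tests
therefore establishes that the pipeline measures what it claims under a
plausible data-generating process — not that the clinical effect sizes
are as simulated.

## Numerical conventions

Result tables serialize with fixed formatting: 2 decimal places for means
and SDs, 3 for p-values, round-half-even, so re-runs are byte-identical.
Sample SDs use the n−1 denominator.  All Monte-Carlo procedures take
explicit seeds; the command-line interface requires one.  Alpha defaults
to 0.05 everywhere and is configurable.  The command-line interface never
overwrites outputs without `--force` and logs its configuration to
stderr.

## Known limitations

Ordinal scores are modelled as numeric at every stage, as in the source
analysis; a cumulative-link alternative is out of scope.  The published
correlation between the number of evaluations and care duration is not
reproducible from the demographics table alone (the referent column is
ambiguous), so the correlation helper exposes the column and method as
arguments and no specific value is asserted.  The published emerged-group
mean number of assessments (4.71) is inconsistent with the table it
summarises (102/21 = 4.86); tests assert only the remaining-group value.
Sensitivity values printed as "<1" in the source are reported here as
exact fractions.
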