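# Methods

## Outcome classification and the cutoff parameter

Patients are labeled by vital status: alive cases are *positive*
(treatment success), dead cases *negative*. A survival cutoff c > 0 (in
years) reclassifies dead patients who survived strictly longer than c
into the positive group; alive patients always stay positive, regardless
of how short their follow-up is — the reclassification is deliberately
one-directional (dead → positive), because a short follow-up is not
evidence of failure the way an early death is. c = 0 is the default and
disables reclassification. Times are carried in years; metadata given in
days (`days_to_death` / `days_to_last_followup`) is divided by 365.25.
For dead patients the time is survival-in-years, for alive patients
years-to-last-follow-up.

## Case-set combinatorics

For each cancer project a case set is built per sex present plus a
combined set when both sexes occur (a single-sex project contributes
exactly one set). With more than one project, pooled basket sets
(female / male / both) are added whenever the corresponding patients
exist — a single-sex project does contribute its patients to the pooled
sets of the opposite-sex selector's complement (its cases appear under
its own sex and under "both"). The collection is crossed with every
cutoff, and the default cutoff 0 is always included. For two projects,
one female-only, this yields 7 sets at the default cutoff and 21 with
two extra cutoffs.

## Treatment partition

A patient is *treated* when their harmonized drug set equals one of the
requested drug combinations exactly; each combination is an atomic unit,
so `carboplatin` and `carboplatin, paclitaxel` are different therapies.
A subset-match mode (`subset_match=True`) is available for exploratory
use. Drug names are harmonized by trimming, lower-casing and an optional
user-supplied synonym map (YAML); the packaged default map covers common
platinum-drug spelling variants.

## Differential features

The differential stage compares the positive and negative outcome groups
of the **treated** members of a case set (the untreated members enter
only at the validation stage). Two built-in scorers honor the feature
contract:

* genes — counts are normalized to log₂(CPM + 1); each gene gets a
  two-sided Wilcoxon rank-sum p-value and the effect
  log₂((mean⁺+1)/(mean⁻+1)) on the normalized scale;
* DMRs — CpG positions whose group-mean beta difference reaches
  `min_delta` (default 0.1) seed regions; consecutive seeds on one
  chromosome at most `max_gap` bp apart (default 500) merge, regions
  with at least `min_cpgs` seeds (default 5) are scored by a rank-sum
  test on per-patient region means; the effect is the mean methylation
  difference (mmd). Region coordinates are 0-based half-open
  internally.

Both scorers apply Benjamini–Hochberg adjustment; selection keeps
features with adjusted p < 0.05, at most 60 per direction, ordered by
adjusted p with ties broken by |effect| (descending) then feature id —
the tie-break is our deterministic choice; any rule would do.
Results from external backends (e.g. a negative-binomial GLM tool or a
segmentation-based region caller) can be ingested from a TSV with the
same columns and flow through the identical downstream machinery.

## Mean-of-medians stratification

For a feature's per-patient values the pivot is
`mom = (median(values⁺) + median(values⁻)) / 2`. Unlike the overall
median, the pivot is not dragged toward the larger outcome group. With
threshold 0, values strictly above the pivot are UP and values ≤ mom are
DOWN (ties at the pivot go DOWN; the choice is arbitrary but fixed). A
threshold t > 0 defines the band `[mom − w, mom + w]`, `w = |mom|·t/100`,
inclusive on both bounds; patients inside are excluded from the survival
comparison. Thresholds above 20 trigger a warning: the shrinking sample
usually costs more significance than the cleaner separation gains.
Stratification values are log₂(CPM+1) for genes and the per-position
beta value for methylation.

## Survival analysis

Kaplan–Meier curves use the product-limit estimator over distinct event
times. The Cox model is a purpose-built single-covariate fitter: Efron
handling of tied event times, Newton iteration (max 50 steps, tolerance
1e-9 on the coefficient, step-halving when the partial likelihood
decreases), two-sided Wald p-value. When the likelihood is monotone
(e.g. complete separation of event times) the fit is flagged
non-converged and the p-value falls back to the score test at β = 0,
which for a binary covariate without ties is exactly the log-rank test.
Censored observations remain at risk at their own time. Observations
with non-positive times cannot enter a risk set and are dropped with a
warning. The test suite cross-checks coefficients and p-values against
lifelines (the fits agree to ~1e-4; the residual difference is the other
library's looser stopping rule) and the score statistic against a
hand-coded log-rank oracle to 1e-8.

## Base and validation plots, filtering and ranking

For each candidate and each threshold, the **base plot** stratifies the
treated patients (pivot from the treated outcome groups) and Cox-tests
UP vs DOWN; the threshold with the smallest p is kept. The base label is
the stratum whose members survive longer (the sign of the UP-vs-DOWN
coefficient). The **validation plots** recompute the pivot on the full
cohort — the classification is intentionally applied to a different
patient set — and, within each stratum, Cox-test treated vs untreated,
again keeping each plot's best threshold. A validation plot for stratum
S is labeled S when the treated arm outlives the untreated arm, and with
the opposite label otherwise; so "UP validation labeled UP" and "DOWN
validation labeled DOWN" both mean "the treatment helps within the
stratum the base plot points to".

The consistency filter passes (base, UP-val, DOWN-val) label triples of
the form (UP, UP, \*) and (DOWN, \*, DOWN) — 4 of the 8 combinations.
The vp-product multiplies the base p with the direction-matching
validation p; a candidate is valid when it passes the filter **and** the
product is strictly below 0.0025 = 0.05². The product deliberately lets
a very strong plot compensate a weak partner. No multiplicity correction
is applied across candidates at this stage — the limit is a fixed
design constant, not an FDR.

For DMRs, every CpG position of a region is Cox-tested at every
threshold; for each threshold the best-performing position is recorded,
and validation then evaluates each recorded position as its own
candidate row.

Valid candidates are ranked globally by ascending vp-product; per case
set the geometric mean of the members' vp-products and the member count
are reported, ordered by member count.

## Pipeline orchestration

The driver materializes every case set, runs the requested analysis
types, and caches each (case set, analysis) result as a TSV under
`out/sets/`. Existing files are reused, never overwritten, so a re-run
with an added cutoff computes only the new sets and is byte-identical to
a fresh run with the union of the cutoffs. All stages are deterministic
given the inputs; the worker-count flag affects scheduling only (the
current implementation is serial). The HTML report is assembled with
plain string templating and `DataFrame.to_html`; it contains the patient
overview (treatment × sex × vital-status × project counts), the
survival/turnover listing that supports choosing a data-based cutoff,
age distributions per set, the candidate tables and the configuration /
version log. KM curves are exported as TSV data files rather than
images, so the report does not depend on a plotting backend.

## Synthetic cohorts

The generator emulates the structure of a pan-cancer treatment cohort:

* two projects (one female-only, one mixed-sex), 440 patients by
  default; ages ~ N(62, 10) clipped to [25, 90];
* ~65 % of patients treated with one of three platinum-based drug
  combinations; metadata drug spellings are corrupted at rate 0.15 with
  case changes, stray whitespace and historical synonyms
  ("cisplatinum", "taxol", …), all recoverable through the packaged
  synonym map — this exercises the harmonization path end to end;
* gene counts ~ negative binomial with log-uniform means in [20, 2000]
  and dispersions in [0.05, 0.5]; CpG beta values ~ Beta with
  concentration 10 on two synthetic chromosomes with strictly
  increasing coordinates;
* survival ~ exponential with per-patient hazard
  `baseline · Π stratum_effect^[high] · Π interaction^[high & treated]`
  over the planted markers (baseline 0.09/year), censoring by an
  independent exponential (0.08/year), giving roughly half the cohort
  censored under mature follow-up;
* planted markers: each has a Bernoulli(0.5) high/low indicator per
  patient that drives both the molecular value (8-fold count shift, or
  +0.4 beta shift over an 8-CpG region) and the hazard. Treatment-
  specific markers use an interaction hazard ratio of 8 (only when high
  **and** treated), universal markers a prognostic hazard ratio of 2
  (regardless of treatment), null markers nothing. Effect directions
  alternate so no aggregate arm-level survival difference exists, and
  every marker's log-hazard contribution is centered so the population
  hazard stays at baseline no matter how many markers are planted.

Two deliberate consequences of this design are worth knowing. First,
features are generated independently (no co-expression), because the
pipeline operates feature by feature. Second, planting ~24 hazard-active
markers in one cohort creates a shared frailty (log-hazard SD ≈ 2) that
attenuates every single marker's marginal association — exactly the
regime of real cohorts, where most true markers are *not* recovered at
n ≈ 400. Tests of end-to-end recovery therefore assert the *ordering*
(treatment-specific markers become valid candidates more often than
universal ones, most universal markers are rejected), pooled over fixed
seeds, rather than high absolute sensitivity. Passing these tests shows
the machinery discriminates mechanisms as designed; it does not promise
any particular sensitivity on real data, where effect sizes, censoring
patterns, batch structure and correlated features differ.

## Problem sizes used in the checks

The default synthetic conditions are 440 patients, 220 genes (10
treatment-specific + 10 universal + 200 null) and 400 CpGs with 2 + 2
planted regions. Null calibration uses a marker-free cohort with 2 000
genes; Cox parameter recovery uses 200 replicates of 100 patients per
arm; discrimination pools three seeded cohorts. These sizes were chosen
as the smallest that give stable verdicts for the seeded checks.

## Known limitations

* The built-in differential scorers are deliberately simple stand-ins
  honoring the backend contract; they are not a negative-binomial GLM
  with shrinkage, nor a binary-segmentation region caller with a 2-D
  Kolmogorov–Smirnov test. For production analyses, run the external
  backend of your choice and ingest its result TSV.
* Only a single binary covariate is supported in the Cox model — no
  multivariate adjustment, stratified baselines or proportionality
  diagnostics.
* The untreated comparison arm is "everyone else", which may include
  therapies molecularly similar to the one under study.
* The generator does not simulate batch effects, tumor purity,
  array-probe artifacts or co-expression modules.
* Feature ids are taken as given; no probe-to-gene annotation is
  performed.
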