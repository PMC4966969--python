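# Methods

## Problem setting

EHR phenotyping selects the patients who truly have a condition from a
pool flagged by billing codes. For ASD, an ICD-9 screen (include
299.0/299.80/299.9; exclude codes for Rett syndrome, childhood
disintegrative disorder, schizophrenia, tuberous sclerosis, fragile X,
and severe intellectual disability) yields a cohort with many false
positives. The package refines that cohort two ways — a DSM-IV
rule engine and a supervised two-stage classifier — and then studies
the comorbidity structure of the selected patients.

Inputs are pre-extracted: each patient is a set of dotted ICD-9 strings
plus an ordered list of concept mentions (CUI-style codes) carrying the
three attributes a clinical NLP stack emits (polarity, uncertainty,
subject). Raw note text, terminology services, and the licensed
glossary/phecode tables are out of scope; mapping tables are two-column
CSVs supplied by the user, with small synthetic stand-ins bundled for
tests and simulation.

## Rule engine

Symptom evidence is the number of *unique* glossary codes per DSM-IV
domain: repeated mentions of one concept count once. The default
mention filter drops negated and non-patient-subject mentions but keeps
uncertain ones — hedged language ("possible social withdrawal") is
exactly how milder presentations surface in notes, and the PDD-NOS
fallback is meant to catch them. The three criteria run in fixed order
(Autistic Disorder, Asperger's, PDD-NOS; first match wins). The
Asperger's and PDD-NOS thresholds (≥2 social + ≥1 behavior; ≥1 social +
≥1 other) are the DSM-IV-derived defaults and are config-exposed, as is
everything else (screen codes, criteria thresholds, attribute policy).

Useful consequence of the defaults: the union of the three criteria
simplifies to *social ≥ 1 and (communication + behavior) ≥ 1*, which
gives the synthetic generator a closed-form designed case rate (below).

## Two-stage classifier

Chart review uses four labels: `yes`, `maybe`, `no`, `unknown`
(an absent label means unreviewed and is distinct from `unknown`).
Stage 1 learns {yes, maybe} vs {no, unknown}; stage 2 learns yes vs
maybe on stage-1 positives only. Design choices where the method left
room:

- **Linear kernel.** Chi-square selection already prunes to ≤250
  features; a linear maximum-margin model is reproducible, fast, and
  serializes to a plain weight vector (JSON).
- **Chi-square on binarized presence, no continuity correction**;
  the margin model then sees raw mention counts of the selected
  columns. Ties in the ranking break lexicographically by code so the
  ranking is deterministic.
- **Grid search** maximizes development-set PPV (the metric that
  matters when the cohort feeds genomic studies: purity over
  completeness), over costs 2⁻¹⁰..2¹⁰ and a feature ladder
  10,20,…,250. Ties prefer fewer features, then smaller cost. Cells
  with no predicted positives have undefined PPV and are recorded as
  such, never treated as zero.
- **Split**: stratified 60/20/20 by floor allocation with the
  remainder to train, seeded.

## Evaluation conventions

PPV = TP/(TP+FP), recall = TP/(TP+FN), F1 = harmonic mean. The
rule-based output is scored with gold {yes, maybe} positive; the final
two-stage "yes" output with yes-only positive. Metrics with empty
denominators surface as explicit `None` — a degenerate cohort must not
silently score 0 or 1. AUC is the rank-sum formulation (ties ½). The
ICD-9-only baseline treats every screened patient as a predicted case,
so its PPV is the gold-positive fraction and its recall is undefined by
construction (patients outside the screen are never observed).
Inter-annotator agreement is the pairwise F-measure per label category,
2|A∩B| / (|A|+|B|), symmetric in the annotators. For ROC over the
discrete rule output, labels are ordinalized autistic=3, aspergers=2,
pdd_nos=1, non_case=0; this is an assumption, documented, not a claim
about any particular published AUC.

## Comorbidity clustering

Binary presence (not counts) of PheWAS categories per patient,
Euclidean k-means (10 seeded restarts per k, best inertia kept),
k = 2..20 selected by mean silhouette with ties to smaller k.
The prevalence filter keeps categories with prevalence ≥ 0.005
(strictly-below-threshold categories are excluded). Relative prevalence
of a code in a cluster is the ratio prevalence(code | cluster) /
prevalence(code | cohort); a comorbidity group's relative prevalence is
the unweighted mean over its member categories. DBSCAN and
agglomerative clustering run on the same matrix for comparison; a
single-cluster DBSCAN outcome is reported (silhouette `None`), not an
error. t-SNE (PCA init, perplexity min(30, (n−1)/3), seeded) provides
the 2-D visualization.

## Synthetic cohorts

**Phenotyping generator.** Gold labels drawn from the mix 44% yes /
10% no / 36% maybe / 10% unknown. Per label and DSM domain, the number
of unique symptom codes is Poisson (defaults: yes 4.0/2.5/3.5 for
social/communication/behavior, maybe 1.2/0.6/0.8, no 0.2/0.1/0.15,
unknown 0.3/0.2/0.2 — strong, moderate, and trace signal respectively),
truncated at the glossary category size; each symptom is mentioned
1 + Poisson(1) times. Background concepts: Poisson(344) mentions drawn
from a 2000-code vocabulary with Zipf(1.2) weights, mimicking
clinical-vocabulary skew; attribute noise (10% negated, 10% uncertain,
5% other-subject) applies to background mentions only, so the designed
case rate stays analytic: with the default criteria the flag
probability per label is (1−e^{−λ_S})(1−e^{−(λ_C+λ_B)}), and the
designed case rate is its mix-weighted sum, 63.3% under the defaults.
Every patient gets an include ICD-9 code; 5% additionally get an
exclusion code (independent of label, so screening does not bias the
case rate). The Poisson/Zipf forms are modeling conveniences chosen for
tractability, not empirical claims.

**Comorbidity generator.** Latent cluster mix 10% psychiatric / 10%
developmental / 10% seizures / 70% diffuse background; each ICD-9 code
in the bundled 60-code table is drawn at 0.45 if its comorbidity group
matches the patient's latent cluster, at 0.05 otherwise (equality of
the two rates is allowed so a no-signal null cohort can be generated).
The table gives each planted group 7–8 categories of mostly two codes —
the multi-code shape real phecode groups have — so within-group
category presence is ≈0.70 against ≈0.10 elsewhere. The latent
assignment is returned for recovery scoring.

What the generators do *not* emulate: longitudinal encounter structure,
correlated comorbidities within a patient, site-specific coding habits,
vocabulary drift, and symptom evidence that co-varies with record
length. Passing tests therefore demonstrate algorithmic correctness and
recoverability of planted structure, not clinical performance on real
records.

## Numerical choices and degenerate inputs

- Chi-square with a degenerate margin (feature always/never present)
  scores 0 rather than NaN.
- Single-class training sets, empty cohorts, and all-removed
  prevalence filters raise immediately with diagnostic messages.
- k values with n ≤ k, or where k-means degenerates to one cluster,
  are skipped with a warning rather than failing the sweep.
- LinearSVC uses max_iter 5000; at extreme costs on near-separable
  data the optimizer may still stop early, which only perturbs
  grid cells that are never selected.
- All randomness flows from explicit integer seeds (numpy
  `default_rng`, sklearn `random_state`); generators are pure functions
  of (config, seed).

## Known limitations

- Silhouette-based k selection on the planted cohort is marginal: the
  mean silhouettes of k=2 (one minority vs rest) and k=4 (full
  structure) differ by <0.01, so the selected k can flip with the
  generator draw even though k-means at k=4 recovers the plant well
  (ARI ≈ 0.8) whenever it is chosen. This mirrors the general weakness
  of silhouette selection when one diffuse cluster dominates the
  cohort; the per-k silhouette curve is always retained so users can
  inspect the margin.
- The two-stage model's development-set PPV is optimistically biased
  (it is the tuning objective); only test-set numbers should be
  reported.
- The rule engine's PDD-NOS fallback is deliberately permissive
  (1 social + 1 other symptom); on cohorts with weak attribute
  filtering it will over-flag, which is visible in the synthetic
  recall/PPV trade-off.
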