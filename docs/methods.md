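# Methods

`emrqtl` implements a quantitative-trait GWAS pipeline whose phenotypes
come from electronic medical records rather than a research protocol:
repeated red-blood-cell (RBC) trait measurements are mined from lab
tables, cleaned of values confounded by hospitalization, comorbidity,
medication or blood loss, collapsed to one phenotype per patient, and
tested for additive single-SNP association. This note records the
models, the defaults and why they were chosen, the numerical decisions,
and what the synthetic validation does and does not demonstrate.

## The phenotyping model

EMR lab values are opportunistic measurements: a complete blood count
drawn during chemotherapy, immediately after hip surgery, or on an
inpatient ward does not estimate the patient's habitual trait level.
The pipeline therefore removes values in three layers:

1. **Inpatient rule.** A value with admit ≤ sample date ≤ discharge for
   any hospitalization episode of the same patient is excluded — unless
   every value of that (patient, trait) pair is inpatient, in which case
   the values are retained as the only information available. The
   rescue scope is configurable (`patient-trait`, the default and the
   conservative reading, or `patient`). Dates are compared at day
   resolution; both boundaries are inclusive.
2. **Coded events.** A registry maps ICD-9-CM, procedural ICD-9 and
   CPT-4 codes (exact or prefix form, e.g. `282*`) to one of four
   categories — chronic condition (malignancy, cirrhosis, hereditary
   anemia, malabsorption), transplant, medication administration,
   surgery with major blood loss — and each category to a window
   policy. An event opens the interval
   `[event − lookback, event + duration]`, closed on both finite ends;
   chronic policies have no right end. Shipped defaults: chronic =
   unbounded with a 30-day lookback (work-up usually precedes coding);
   medication and surgery = 90 days forward, no lookback. These window
   lengths are site policy, not empirical constants; every length is a
   configuration value.
3. **Medication mentions in notes.** Marrow-suppressing and
   immunosuppressive drugs are frequently documented only in free text.
   A lexicon of generic and brand names is matched case-insensitively
   on word boundaries (multi-word brands as phrases). By default there
   is no negation handling — the filter is deliberately
   sensitivity-oriented, since a false exclusion costs one lab value
   while a false inclusion contaminates a phenotype; a basic
   "no/denies/without + term in the same sentence" suppressor is
   available behind a flag. Mentions open the medication window dated
   by the note.

A value is excluded iff its date lies in at least one window of its
patient; every covering category and every triggering event id is
recorded, so the audit log alone reconstructs the kept set. Patients
with no remaining value for any trait are dropped from the cohort.

The bundled registry and lexicon are **illustrative**: a small,
documented set of representative codes and drugs per category. Any real
deployment replaces them with a site's curated tables (CSV + YAML); the
algorithm is indifferent to the content.

## Aggregation

Repeated measurements collapse to the per-patient **median** per trait
(even counts: mean of the two central order statistics). Quantiles in
the cohort summary use linear interpolation between order statistics —
stated explicitly so the printed numbers are bit-reproducible. Group
comparisons use Welch's unequal-variance t-test for continuous
variables and the chi-square test for proportions; with an empty group
the summary is produced without P values and flagged.

## Genotype QC

Dosage matrices (0/1/2 minor-allele counts, −1 missing) pass a fixed,
logged funnel: (1) external sample-exclusion list — ancestry outliers,
relatedness, label errors are upstream concerns consumed as a list;
(2) sample call rate > 0.98; (3) marker call rate > 0.98;
(4) MAF > 0.05; (5) HWE exact P > 0.001. Samples precede markers so a
bad sample cannot drag markers down with it; the order matters for the
counts and is therefore pinned. Comparisons are strict in the stated
direction. Kept + dropped reconcile at every step.

The HWE test is the Levene–Haldane exact test: conditional on allele
counts, the probability of each heterozygote count is computed by the
stable ratio recurrence from the lowest-parity value and the two-sided
P sums all outcomes whose probability does not exceed the observed
one's (with a 1 + 1e−12 tie guard). Being discrete, the test is
conservative: at n = 3000 its measured size is ≈ 0.046 at nominal 0.05
and 0.0007–0.001 at nominal 0.001. Tests assert exhaustive agreement
(≤ 1e−12) with an independent log-factorial enumeration for every
table with total ≤ 50.

## Association model

For each marker and trait, ordinary least squares of the phenotype on
`[1, g, age, sex, PAD]` with minor-allele dosage g; missing genotypes
are handled complete-case per marker (no imputation by default). The
two-sided P comes from the t distribution at residual df, and the
SNP's variance explained is the **partial R²** — the incremental R²
over the covariate-only model, identically t²/(t² + df). The genome
scan uses a Frisch–Waugh residualization fast path (vectorized over
markers in chunks) that is exactly equivalent to the per-marker fit;
markers with missing data fall back to the single-marker path. Markers
constant after complete-case removal are flagged, never silently
dropped.

Genomic control: λ_GC = median(χ²₁)/0.4549364; adjusted P recomputes
the χ²₁ survival function at χ²/λ. λ < 1 is never applied (no
deflation). The genome-wide threshold is fixed at P < 5×10⁻⁸; no FDR
machinery.

Power for a QTL explaining variance fraction r² at sample size n and
level α is `P(X > q)` for X noncentral χ²₁ with noncentrality
`n·r²/(1−r²)` and q the (1−α) quantile of χ²₁. A simulation route
(genotype at a given MAF, trait at variance fraction r², the same OLS
fit) is provided and agrees with the closed form within Monte-Carlo
error. At n = 3000, r² = 1.5 %, α = 5×10⁻⁸ the analytic power is
**0.90**; the routes cross-check each other in the acceptance suite.

Replication comparison harmonizes effect alleles before comparing
directions: if the catalog reports the other allele of the marker, its
β sign is flipped; A/T and C/G markers are flagged strand-ambiguous
(unresolvable without frequency matching); unmatched markers and
allele mismatches produce flagged rows, not errors. The package
bundles a 25-row catalog of published RBC-trait QTL summary statistics
(HBS1L/MYB, TMPRSS6, HFE, SLC17A1 loci) used for internal-consistency
checks and as a worked replication example.

## The synthetic-data generator

The generator is first-class, tested code: it emulates the joint
structure the pipeline consumes and labels every simulated lab value
with ground truth computed by a direct, standalone evaluation of the
window policies — deliberately not by calling the production filter,
so filter and oracle can disagree if either is wrong.

**Trait model.** Hemoglobin, hematocrit and RBC count are the primary
quantities; the erythrocyte indices are derived per draw through the
exact identities MCV = 10·Hct/RBC, MCH = 10·Hgb/RBC,
MCHC = 100·Hgb/Hct, then rounded to analyzer reporting precision.
Defaults: Hgb 14.1 ± 1.3 g/dL, Hct 41.0 ± 3.6 %, RBC 4.5 ± 0.4
×10¹²/L, MCV 90.5 ± 4.2 fL, MCH 31.1 ± 1.6 pg, MCHC 34.3 ± 0.5 % in a
cohort of mean age 63.2 ± 9.5, 62 % male, 49 % PAD cases. The six
(mean, SD) targets are over-determined given the identities: the ratio
of the primary means pins the derived means (10·41.0/4.5 = 91.1, not
90.5). The generator resolves this by matching the primary means/SDs
exactly and solving the three pairwise correlations of the primaries
(delta method, closed form, with a nearest-correlation-matrix repair
if infeasible) so the derived indices hit their target SDs; the
derived means then land within 1 % of target, which is the guarantee
the tests assert. Repeated draws share the patient's latent mean with
intraclass correlation 0.7 (configurable; within-patient correlation
of repeats is rarely reported, and 0.7 reflects that these traits are
stable over time relative to assay noise).

**Covariates.** Age/sex/PAD enter the latent primary means linearly
(centered, so population means are unchanged). PAD coefficients mirror
observed case-control gaps (−0.5 g/dL Hgb, −1.1 % Hct, −0.1 ×10¹²/L
RBC); age and sex effects are near-proportional across the primaries
so the derived indices are only weakly covariate-dependent — as seen
in real cohorts, where MCH barely differs by disease status.

**Confounders.** Each category occurs in a patient with its configured
probability; events are anchored within ±30 days of an actual draw
(clinically, CBCs cluster around the encounters that generate codes —
uniform placement over 15 years would leave 90-day windows empty and
the filter untested). Codes are drawn from the same registry the
filter uses; medication-NLP confounding is planted as note text
containing a lexicon term. Benign decoy codes and mention-free decoy
notes are interleaved and must not trigger exclusions.
Hospitalizations are short episodes admitted just before a random
draw. Under the defaults roughly 6 % of values are inpatient and 10 %
window-excluded.

**Genotypes.** Independent markers with MAF ~ U(0.05, 0.5), genotypes
as two Bernoulli allele draws (HWE by construction), optional
missingness, deterministic marker metadata. No LD, no sex chromosomes,
no longitudinal drift — by design (see Limitations).

**Planted effects.** A causal spec (marker, trait, r²) adds
β·(g − 2p̄) to the latent trait mean with
β = √(r²·σ²/(2p(1−p))) at the realized allele frequency p; dosage is
centered so the population mean is preserved. For primary traits the
between-patient deviation is rescaled so total variance stays at σ²;
for derived traits the shift rides on top of the identity-derived
value and total variance grows by the (small) planted fraction.
Effects planted on a primary propagate into the indices through the
identities — deliberate, since real RBC loci are pleiotropic across
the panel.

**Determinism.** Every stage draws from a generator seeded by
(config seed, stage tag), so outputs are byte-identical for a fixed
config regardless of call order.

## What the validation experiments show — and what they do not

- *Null calibration*: with no causal effects, per-trait λ_GC at 10,000
  markers lies in [0.95, 1.05] and 5 % of P values fall below 0.05.
  Note λ̂'s sampling SD at 10,000 markers is ≈ 0.024, so this band is
  a ≈ ±2σ check per trait: an occasional excursion at an unlucky seed
  is expected behaviour, not inflation.
- *Recovery*: a QTL planted at r² = 2 % in 3,000 patients is detected
  at P < 5×10⁻⁸ at the analytically predicted rate (≈ 0.99), β is
  within 2 SE of truth in ≈ 95 % of replicates, and the mean fitted
  partial R² equals the planted fraction. The recovery harness uses
  one draw per patient and zero covariate effects so the planted r² is
  exactly the estimand; with repeated draws the median's variance is
  smaller than σ² (by icc + (1−icc)·c_k, c_k the median's variance
  factor), so fitted R² would exceed the planted fraction — an
  attenuation-in-reverse worth remembering when interpreting real
  EMR R² values.
- *Filter oracle*: across 50 random fixtures, the filter's decisions
  equal the independent truth labels for 100 % of values, with exact
  count reconciliation — the synthetic analogue of a manual chart
  review finding no discrepancies.

Passing these establishes internal correctness under the generator's
assumptions. It does **not** establish performance on real EMR data:
the generator has no coding errors or missed codes (truth and filter
share the registry configuration), no NLP ambiguity beyond word
boundaries, no LD (so no distinction between causal and tagging
variants), no population structure (so λ exercises only the null
case), and no informative-visit bias (draw counts are independent of
health state).

## Numerical choices

- Quantiles: numpy linear interpolation; median of even counts = mean
  of central pair.
- OLS via least squares with explicit (XᵀX)⁻¹ for the SE; validated
  against the normal-equations oracle and statsmodels to 1e−10.
- Exact-fit degenerate case (zero residual): P floors at 5e−324,
  partial R² = 1.
- HWE tie guard: outcomes with probability ≤ p_obs·(1 + 1e−12) are
  summed; P capped at 1.
- λ_GC from fewer than 100 markers warns; an empty table errors.
- PED/MAP round trips re-identify the counted allele as the rarer
  observed allele (ties broken lexicographically), so a roundtrip may
  flip dosage coding at allele-balanced markers — MAF and association
  results are invariant under the flip.

## Problem sizes

The shipped experiments run at 3,000 patients × 10,000 markers for
null calibration, 200 replicates × 3,000 patients for recovery, 2,000
Monte-Carlo replicates for power, 50 fixtures for the filter oracle,
and a 2,000 × 2,000 end-to-end demonstration with three planted QTL at
r² = 1.5–2.2 % — sizes at which every statistical property under test
is measurable with comfortable margins.

## Known limitations

Single-site, single-ancestry model (no mixed models or kinship);
no imputation or strand alignment against a reference; no
longitudinal modelling of repeated measures (the median discards
within-patient trajectories); the replication module matches by marker
id, not position or proxy LD; registry/lexicon content is
illustrative, not clinically curated.
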