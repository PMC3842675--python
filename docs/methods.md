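# Methods

## Cohort construction

The unit of analysis is an admission (a "case"); repeat admissions of one
person are distinct cases. MRDx categories are ranked by in-hospital
death count and the shortest prefix covering a configurable share
(default 80%) of all deaths is retained; the category that crosses the
threshold is included (≥, not >), and ties are broken by category id so
the ranking is order-invariant. Exclusion criteria are applied in a fixed
order — implausible age (≤ 28 days or ≥ 120 years, compared in days with
120·365 as the bound), stay > 365 days, transfer in or out, and
clinically heterogeneous or malignancy MRDx categories — with first-match
logging so the exclusion log partitions the removed records.

## Comorbidity coding

ICD-10 codes are normalized (uppercase, dots stripped) and matched
against prefix tables; the longest matching prefix wins, and same-length
ties map to every tied condition. The shipped tables transcribe the
published ICD-10 prefix lists for the 17 Charlson and 31 Elixhauser
conditions. Two transcription caveats: a handful of codes legitimately
belong to two conditions in the published lists (e.g. I42.6 to both
congestive heart failure and alcohol abuse) and are handled by the
same-length-tie rule, but where a *longer* prefix for one condition
shadows a shorter prefix of another (K70.0 alcohol abuse vs K70 liver
disease) the more specific entry wins and the shadowed assignment is
lost. Engine correctness is tested against small fixture tables, so the
mapping machinery does not depend on the fidelity of the shipped
transcription.

Severity hierarchies (complicated diabetes over uncomplicated,
moderate/severe liver disease over mild, metastatic over solid tumour,
complicated over uncomplicated hypertension) are applied after mapping
and re-applied after any set union, so mutually exclusive levels never
co-occur. Membership for the hierarchy is evaluated against the input
set, which collapses chains in a single application.

Two POA screens are implemented. The prior-year rule (Charlson): a
condition is kept if flagged chronic, or if mapped from claims of the
year preceding the admission. The shipped chronic flags mark all 17
conditions chronic except myocardial infarction — the published flag list
is not available, so this conservative default is a documented,
resource-overridable assumption. DRG screening (Elixhauser claim sets and
all drug-inferred sets): conditions listed for the admission's MRDx
category in an explicit exclusion map are removed. No computable
definition of "same disease category as the MRDx" exists, so the map is a
resource; the shipped fixture covers the 12 study categories with
clinically obvious pairs (a CHF admission screens out the CHF
comorbidity, a chronic-renal-failure admission screens out renal
disease, and so on). The MRDx itself is never counted as a comorbidity:
only secondary diagnoses are mapped.

## Drug-based inference

A drug is eligible as comorbidity evidence only when it maps to exactly
one condition and is not multi-indication, not an antineoplastic, not
plausibly used for mild conditions (including topicals), and not
parenteral; drugs mapping into severity-split families the prescription
cannot disambiguate (hypertension, diabetes) are excluded as well. The
eligibility flags are curator-supplied columns, not derived from an
indications database, because that curation is expert work. One
prescription event during the stay suffices; matching is exact after
case-folding. The shipped `drug_map.csv` is a synthetic fixture (the
study-scale national formulary curation is not public): one plausible
oral single-indication generic per inferable condition, plus rows that
exercise each exclusion rule. Inferred sets are DRG-screened before being
unioned with the claim-derived sets; provenance (claim / drug / both) is
tracked per condition.

The overlap report computes, per condition, the number of cases detected
by claims (A), by prescriptions (B) and by both, and the fraction of
additional comorbidities (|A∪B|−|A|)/|A∪B|. Fractions are kept at full
precision internally and rendered as one-decimal percentages.

## Mortality models

Per MRDx category, logistic regression of in-hospital death on age
(years, continuous — no functional form is imposed), sex, insurance
status, emergency admission, operative status, and either the Charlson
score (original or enhanced) or the Elixhauser indicators (claim or
enhanced set). Elixhauser indicators enter as main effects only;
interaction with the MRDx is realized by per-category stratification, not
product terms. Fitting is binomial IRLS (statsmodels GLM; at most 100
iterations, tolerance 1e-8); a fit is rejected as separated when any
coefficient exceeds 15 in magnitude on the logit scale. Any 0/1 column —
an Elixhauser indicator or a binary base covariate — is dropped with
logging when it has zero variance or a zero cell against the outcome (no
deaths among carriers, or no survivors among carriers); these are the two
directions of quasi-complete separation, and removing them keeps
small-stratum fits defined without penalization. Strata with fewer than
10 deaths (configurable) are refused.

The c-statistic is all-pairs concordance with the 0.5 tie convention,
computed via mid-ranks (exactly equivalent, O(n log n)). Its 95% CI is a
percentile bootstrap that resamples admissions with replacement and
*refits* the model per replicate; failed replicates are redrawn up to
10·B draws and more than 10% failures aborts. The Hosmer-Lemeshow test
uses g = 10 probability-ordered groups (quantile-based, so tied
probabilities stay together and the group count shrinks if ties force
it); degenerate groups (expected deaths 0 or n_g) are merged into a
neighbour; degrees of freedom are groups − 2, with the p undefined below
3 groups. The Wilcoxon signed-rank test drops zero differences,
mid-ranks ties, and uses the exact null for ≤ 25 untied nonzero pairs,
otherwise the continuity-corrected normal approximation. No
multiple-testing correction is applied across categories.

## Synthetic data generator

Each case draws covariates (age ~ Normal(61, 16) years clipped to
[1, 110]; male 59.1%; Medical Aid 6%; emergency 45%; operated 30%), an
MRDx category from configured weights, and independent latent
comorbidities from per-disease prevalences. Each latent disease carries
one ICD-10 code and at most one mapped drug. Emission channels, all
independent Bernoulli: the code reaches the secondary diagnoses with
probability 1 − m (m = missingness), the prior-year claims with
probability q (default 0.3; applied to every latent condition — for
chronic conditions the prior-year rule makes it irrelevant), and the drug
with probability s (sensitivity, default 0.8). Mapped drugs also appear
spuriously with probability 0.002 per drug per case: the drug map is
restricted to exclusively-indicated drugs, so prescriptions without the
condition must be rare, and larger values would simulate exactly the
multi-indication noise the eligibility rules exist to remove. Death is
Bernoulli with logit = category intercept + 0.030·(age − 60) + 0.10·male
+ 0.30·MedicalAid + 0.50·emergency − 0.30·operated + 0.35·(true Charlson
score). Because mortality depends on the *true* conditions, coding
missingness attenuates the fitted comorbidity coefficient — the mechanism
by which medication-inferred conditions can restore discrimination.

The 12 default categories use admission shares that follow the relative
ordering of a large national inpatient cohort, with the smallest strata
floored at ~4% so that every stratum supports a stable per-category fit
at the default study size of 20,000 admissions; intercepts are set so
category death rates span roughly 0.5–15%. Transfers (1% each way),
implausible ages (0.2%) and year-plus stays (0.1%) are injected so the
exclusion rules have real work in end-to-end runs.

Presets: `no_missingness` (m = 0, no spurious drugs — enhancement is
provably a no-op, used as an identity check), `paper_like` (m = 0.4,
within the 33–48% range chart audits report), and `drug_dominant`
(m = 0.8, s = 0.95 — conditions detected almost exclusively through
drugs). Output is deterministic per configuration, including the seed.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: comorbidity correlation structure (conditions
are sampled independently), many-to-one code/drug mappings (one code and
one drug per condition in the default panel; many-to-one matching is
exercised in unit tests), dose/duration/route detail, realistic
formularies or fee schedules, and within-hospital clustering. Calibration
to published cohort figures is order-of-magnitude only.

## Problem sizes and numerical choices

Validation runs use n = 20,000 admissions (single replicate for the
identity check; 20 seeded replicates for the enhancement property) and
bootstrap B = 200 in the reproduction script (B is configurable;
uncertainty statements in the package default to B = 1000). Convergence,
tie-breaking and degenerate-input behaviour are as described above;
rounding happens only at render time.

## Known limitations

- The shipped ICD-prefix and chronic-flag tables are transcriptions with
  the documented caveats; site-specific tables can be swapped in via
  `MappingResources.from_dir`.
- The drug map is a fixture; real deployments must supply a curated
  formulary mapping, and results are only as good as that curation.
- DRG screening is as strong as its exclusion map; unmapped MRDx
  categories screen nothing.
- Enhancement improvements measured on synthetic data quantify the
  mechanism, not the magnitude to expect on any particular real cohort.
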