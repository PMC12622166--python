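# Methods

## Problem setting

In NF1, benign plexiform neurofibromas (PN) can transform into malignant
peripheral nerve sheath tumors (MPNST), and the two are hard to separate
clinically or radiologically. Tumor-derived DNA fragments circulate in
plasma in proportion to the tumor fraction (TF) of cell-free DNA, so a
targeted sequencing panel over recurrently altered loci can, in
principle, detect transformation noninvasively. This package implements
the analysis layer of such an assay: everything downstream of variant
calling and bin-ratio estimation, up to a cross-validated malignancy
score and longitudinal MRD calls.

## The clonal mixture model

All effect sizes derive from one model. If a fraction TF of cfDNA
fragments originate from tumor cells:

- a clonal heterozygous point mutation is expected at allele fraction
  AF = TF/2, and the observed alternate-read count at depth *d* is
  Binomial(*d*, AF);
- a single-copy deletion shifts the expected coverage log2 ratio of the
  affected region by log2(1 − TF/2); a single-copy gain by
  log2(1 + TF/2); a homozygous deletion by log2(1 − TF).

At TF = 0.5 a single-copy loss therefore sits at log2(0.75) ≈ −0.415;
against a healthy panel with per-gene SD ≈ 0.1 that is a z-score of
roughly −4. These identities are used three times: by the generator to
plant lesions, by tests as analytic oracles, and in documentation to
reason about detectability limits.

## Pipeline stages and their parameters

### SNV/indel filtering

| parameter | default | notes |
|---|---|---|
| plasma AF threshold | > 0.0005 (strict) | boundary excluded; configurable to ≥ |
| tumor AF threshold | > 0.05 (strict) | tumor calls also drop on contamination/germline/normal-artifact flags |
| min alternate depth | 8 reads | both materials |
| panel removal fraction | > 0.10 | with a 12-sample panel: removal at ≥ 2 carriers |
| population AF cutoff | > 0.001 rejects | applied only when an annotation is present |

Filters accumulate reason codes rather than short-circuiting, so the
decisions TSV lists every failure per variant, and retained/rejected sets
always partition the input. The confidence-tier concept is reduced to a
binary gate (≥ 2 callers, or 1 caller with alternate depth ≥ 15),
off by default; the full tiering rubric used upstream is not public, so
this gate is an explicit stand-in. Noncoding variants are retained with
`is_coding=False`, excluded from features but present in audit output.

Severity encoding is ordinal, 6 → 0: loss-of-function (frameshift,
stop-gained, start-lost), protein-disrupting missense (PolyPhen damaging
AND SIFT deleterious), splice-altering (donor/acceptor/region subtypes
recorded but collapsed to one rank), VUS (discordant or missing
predictions), non-disrupting missense (both tools benign), synonymous,
other. Unrecognized Sequence Ontology terms map to *other* with a logged
warning, never an exception. CDKN2A and CDKN2B share one SNV/SV summary
locus (their coding events are rarely distinguishable at the feature
level) while keeping separate copy-number features.

### Copy-number profiling

Bins flagged for low depth (< 30 reads) or extreme ratios (|log2| > 3)
never contribute. Each sample's usable bins are median-recentered
(configurable off) to absorb global technical shifts, then aggregated per
gene with a symmetric trimmed mean (default 10% per tail; falls back to
the median if trimming would consume every bin). Two normalizations are
emitted deliberately: the healthy-panel z-score (mean/SD over
background-panel samples, sample SD with ddof = 1, floored at 0.01) and a
cohort-scaled value (log2 divided by the per-gene SD across case
samples); both enter the feature matrix because they answer different
questions (distance from technical noise vs relative magnitude within
the cohort). A gene with zero usable bins is *missing*, not zero;
missing values are imputed copy-neutral (0) at feature assembly with a
logged count. The chr8q composite is the unweighted mean over available
candidate-oncogene profiles.

### SV consensus

Single-linkage clustering joins same-type calls whose breakpoints both
lie within 100 bp; the representative breakpoint is the member median
(ties toward the lower position — merge tools differ here and the choice
is documented rather than load-bearing). Consensus events require ≥ 2
distinct callers and ≥ 200 bp (translocations exempt from the size rule
and from per-gene features). Plasma events additionally need split reads
≥ 2 AND discordant pairs ≥ 2 (the exact upstream depth minima are not
published; these defaults are configurable and flagged as stand-ins);
tumor events bypass the depth requirement. Control polishing removes any
event matching a control-set event at the same 100 bp tolerance —
a deliberate simplification standing in for re-genotyping every event
across controls. Blacklist regions are excluded. The processing order is
merge → caller filter → evidence filter → control removal.

### Feature integration and classification

The fixed feature vector per plasma sample: 3 continuous CNA columns
(log2, cohort-scaled, z) × 6 units (CDKN2A, CDKN2B, TP53, SUZ12, EED,
chr8q), SNV rank and multi-hit per tumor-suppressor locus (CDKN2A/B
merged, TP53, SUZ12, EED), SV category (0/1/2) for TP53/SUZ12/EED, and
the chr8-duplication flag — 30 columns. Ordinal encodings enter as
integers (a one-hot variant exists behind config); continuous CNA columns
are standardized with training-fold means/SDs only.

The classifier is scikit-learn logistic regression (L2, C = 1.0, lbfgs):
with ~30 features and ~100 samples some shrinkage is necessary, and the
regularization strength is deliberately unremarkable. Evaluation is
leave-one-out: for each sample, scaling parameters and coefficients are
fit on the other n − 1 rows, and the held-out probability is recorded.
Per-fold scaling parameters are retained on the results object so leakage
is testable, not just asserted. The AUC is the trapezoidal area under the
empirical ROC (identical to the Mann–Whitney concordance probability —
the test suite holds the two routes equal to 1e-12); its 95% CI is a
stratified bootstrap percentile interval (default 2000 replicates;
within-class resampling guarantees both classes in every replicate). The
operating point maximizes Youden's J with ties broken toward higher
specificity, matching the screening context where false positives
trigger invasive workup. Group separation uses the Wilcoxon rank-sum
test (exact enumeration when both groups ≤ 10 and tie-free, else normal
approximation with tie correction) and Welch's t.

The comparator arm is a genome-wide CNA burden score: mean |z| of
off-target bin log2 ratios against the per-bin panel reference. It is
intentionally the weaker, untargeted summary a tumor-fraction estimator
would approximate, and the synthetic benchmark asks only that the
integrated classifier beat it.

### MRD tracking

The tracked set is tumor-confirmed variants (tagged by whether they were
also detectable in pretreatment plasma) or, without tumor tissue,
retained pretreatment plasma variants. "Detected" at a timepoint means
passing the full plasma filter chain in that sample; raw caller output
never counts, because clearance claims are only as strong as the calls
behind them. Tracked SVs match by consensus breakpoints within 100 bp at
both ends. Status logic over post-treatment draws (day > 0): all
negative → clearance; a negative followed by any detection → molecular
relapse (first positive recorded); never negative → persistent; no
tracked variants or no post-treatment draws → indeterminate. Lead time is
the earliest clinical recurrence at or after the first positive draw
minus the first-positive day; detection after diagnosis yields none.

## The synthetic cohort generator

The generator's defaults encode the study conditions the pipeline is
designed for: 12 healthy + 44 PN + 26 MPNST patients contributing 44
plasma samples (serial draws included) + 19 matched tumors, a 12-sample
background panel, mean deduplicated plasma depth 1000×, tumor purity 0.6,
MPNST tumor fraction ~ Uniform(0.05, 0.5), bin noise SD 0.08 in log2
units. Each MPNST patient's tumor genome — lesion set, SNV coordinates,
SV breakpoints — is drawn once and shared by serial draws and matched
tumor, so plasma recapitulates tissue. Lesion probabilities reflect the
recurrent MPNST lesion spectrum (CDKN2A/B loss 0.7 with a 50/50
single/two-copy mixture at the 9p21 locus, TP53 loss/SNV 0.5, SUZ12 loss
0.55, EED loss 0.4, chr8q gain 0.6, NF1/MTAP loss 0.5, arm-level
instability 0.5); a patient drawing no lesions is assigned the
characteristic 9p21 loss so every tumor genome is non-empty. PN samples
carry a low-AF NF1 second hit with probability 0.2 — visible in audit
output but outside the feature gene set, as in benign precursors.

Three artifact channels are class-independent by construction, so they
test specificity rather than inflate it: ~30 shared low-AF SNV artifact
sites (prevalence 2–25%, AF 0.001–0.02) sprinkled across all samples
including the panel, which makes the > 10% panel rule load-bearing;
CHIP-gene variants (15% of samples, AF up to 0.05) removed by gene
masking; and recurrent artifact SVs present in both cases and controls,
removed by control matching. SV callers are simulated as three
pseudo-callers that each observe a true event with probability 0.85 and
≤ 50 bp breakpoint jitter, generating realistic single-caller orphans for
the ≥ 2-caller rule; split/discordant counts scale with TF, so
low-burden events genuinely drop out at the evidence filter.

Two scripted patients give the MRD logic deterministic ground truth:
MP01 (TP53 deletion present at resection, absent day 10, redetected day
100, clinical recurrence day 180 → lead time exactly 80 days) and MP02
(three tumor-informed variants — TERT, COA3, NCOA2 — cleared from every
post-operative draw). Scripted events are emitted by all three
pseudo-callers with fixed read support so their recovery tests the
pipeline, not caller-dropout luck.

What the generator does **not** emulate: read-level data (no FASTQ/BAM —
the pipeline starts at caller/bin outputs, so simulation does too),
sequencing-error substitution spectra, fragmentomics, methylation, GC and
mappability bias (assumed corrected upstream), subclonal architecture
beyond a single clonal population, and inter-patient germline variation.
Passing tests on synthetic cohorts therefore demonstrates the
correctness and internal consistency of the analysis logic under the
stated generative model — not clinical performance on real plasma.

## Numerical and degenerate-input choices

Coordinates are 0-based half-open internally; VCF positions convert at
the reader boundary. Chromosome names normalize to one dialect per run;
unplaced/alt contigs are rejected with reason codes. Panel SDs are
floored at 0.01 before division. Zero-variance feature columns scale to 0
with a warning rather than NaN. An empty background panel is a
configuration error, never a silent pass-through. A sample present in
the manifest but absent from every input is a hard error to prevent
feature/label misalignment. All stochastic components (generator,
bootstrap, solver) are driven by explicit seeds; identical seeds produce
byte-identical cohort trees and identical results.

## Problem sizes

The default test and acceptance runs use the full study-shaped cohort
(131 samples, ~430 bins/sample, LOOCV over 100 samples, 2000 bootstrap
replicates), which completes in seconds; repeated-simulation tests use a
scaled-down cohort (~40 samples) to keep the suite fast.

## Known limitations

- The severity-tier and SV depth-support rubrics of the upstream caller
  ensemble are not public; the implemented gates are documented
  approximations, configurable and off/conservative by default.
- Control-event removal replaces per-event re-genotyping; events at the
  edge of the 100 bp tolerance can survive polishing.
- The CNA-burden comparator is a deliberate simplification of HMM-based
  tumor-fraction estimation; its absolute AUC on synthetic data is not
  comparable to published tumor-fraction AUCs, only its ordering against
  the integrated model.
- "Multiclass" refers to the integration of multiple feature classes
  (SNV/CNA/SV) into one malignant-vs-non-malignant model; a 3-class
  softmax variant is exploratory and ROC evaluation always pools PN with
  healthy.
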