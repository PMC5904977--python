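# Methods

## The problem

Clinical laboratories running capture-based targeted NGS panels historically
confirm every reported variant with Sanger sequencing. Most NGS calls are
unambiguous; a small minority — low allele fraction, extreme GC, homopolymer
neighbourhoods, duplicated regions — are not. `vartriage` models the
probability that a call would be confirmed by an orthogonal assay and splits
calls into HIGH confidence (report without confirmation) and LOW confidence
(send to Sanger). The asymmetry of costs is absolute: a false positive — a
call released as HIGH that an orthogonal assay would have refuted — is a
wrong clinical result, while a false negative merely costs one unnecessary
Sanger reaction. The decision threshold is therefore calibrated to eliminate
false positives on the calibration data rather than to balance error rates.

## Features

Fourteen features per call, in fixed schema order:

| feature | definition | source |
|---|---|---|
| DP | read depth at the position | FORMAT |
| AD | reads supporting the alt allele | FORMAT (alt component) |
| AF | AD / DP | derived |
| GC@5/20/50 | G+C fraction in a 5/20/50-base window around the anchor | reference |
| MQ | RMS mapping quality | INFO |
| GQ | genotype quality | FORMAT |
| WHR | weighted homopolymer rate: sum of squared run lengths / number of runs, 20-base window | reference |
| HPL-D | distance to the longest homopolymer (length >= 2) within 20 bases | reference |
| HPL-L | length of that homopolymer | reference |
| QUAL | caller quality score | column 6 |
| QD | QUAL / DP (recomputed, never trusted from INFO) | derived |
| FS | Phred-scaled Fisher strand-bias score | INFO |

Window semantics: "a window of *n* bases" is *n* bases total, centered —
`n // 2` left of the anchor (the first REF base of the left-aligned record),
the anchor, and the remainder right. A per-side interpretation is available
through `ContextConfig(window_mode="per_side")` since the defining phrase is
ambiguous; the total reading keeps *n* the literal number of bases and
matches the published GC and WHR medians on random-composition checks
(uniform random sequence gives median WHR 2.0, inside the published 1.6–4.3
band). Runs of length 1 count toward WHR — the published WHR median of 2.4
on typical sequence is only attainable when they do — while HPL-D/HPL-L
consider only runs of length >= 2, a length-1 "homopolymer" being vacuous.

Coordinates are 1-based on the surface (VCF convention), 0-based half-open
internally. Windows clip at contig ends and fractions use actual base
counts. N bases are excluded from GC numerator and denominator and break
homopolymer runs; a window that is more than half N leaves the feature
undefined.

## Missing data and fail-safety

Absent MQ, GQ or FS are imputed with training-set medians and recorded in a
mask; absent QUAL, DP or AD (or DP = 0, or undefined context) put the call in
a fail-safe state that forces LOW confidence regardless of the model score.
The principle throughout is that uncertainty about the inputs must never
increase the chance of skipping confirmation.

## Model

L2-penalized logistic regression of the binary confirmation outcome on the
14 features, standardized by training-split mean and standard deviation
(dev/test are transformed with training parameters; no leakage). The penalty
(`l2_strength`, default 1.0 relative to the summed log-likelihood) is small
enough to be statistically negligible at cohort sizes but keeps the optimum
finite on separable data and the fit deterministic. lbfgs with tolerance
1e-10; an iteration-cap hit raises rather than returning a half-converged
model. Class imbalance is deliberately not reweighted: the asymmetry of
costs is handled entirely by the threshold.

### Threshold calibration

`tau` is the smallest threshold with zero false positives on the calibration
set: the midpoint between the highest unconfirmed score and the lowest
confirmed score above it (one ulp above the highest unconfirmed score when
no confirmed score lies above). Classification is HIGH iff
`predict_proba >= tau`. Applied to unseen data this construction guarantees
nothing by itself, which is why the conservative fail-safe states and the
override rules exist.

### Evaluation

* 70/15/15 train/dev/test split (stratified, largest-remainder rounding);
  the model is fitted on train, `tau` calibrated on dev, metrics reported on
  test.
* Stratified 10-fold cross-validation with per-fold refitting **and**
  per-fold recalibration of `tau` on each fold's training portion; reported
  confusion counts are out-of-fold. A single global `tau` is available
  (`per_fold_tau=False`) since the alternative protocol is equally
  defensible. When the minority class has fewer members than folds the split
  falls back to unstratified k-fold with a warning, which also covers
  leave-one-out.
* ROC/AUC by trapezoidal integration (equals the Mann–Whitney concordance;
  asserted against an O(n²) oracle in the tests).
* Accuracy with a symmetric normal-approximation binomial interval by
  default; Wilson by option.

## Override policy

Independently of the model score, the deployment policy always routes to
confirmation: homozygous calls (by GT, never inferred from AF), low-fraction
calls (AF in [0.1, 0.3]), and calls intersecting a user-supplied processed-
pseudogene BED. Segmental-duplication and repeat flags are carried for
stratification and can be promoted to overrides by policy. Overrides are
monotone toward LOW; with all rules disabled the final class equals the
model class for every call. Reasons are a closed enumeration
(`below_threshold`, `undefined_feature`, `low_fraction`, `homozygous`,
`pseudogene`, `segdup`, `repeat`). Pseudogene detection "in the same sample"
is beyond a VCF-only tool; a user-supplied pseudogene BED preserves the
rule's effect without BAM-level analysis.

## Synthetic cohort generator

The generator emulates a confirmation cohort of a 30-gene hereditary-cancer
panel: 7179 calls, 7.1% unconfirmed, ~18.8% indels (<= 25 bp), per-feature
marginals matched to published 5th/50th/95th percentile triples (DP
78/222/433, AF 0.13/0.49/0.56, QD 1.6/11.3/16.9, and so on). Identities hold
by construction: AD ~ Binomial(DP, target AF) so AF = AD/DP exactly, and
QUAL = QD x DP so QD = QUAL/DP exactly.

Truth is drawn first, the way artifacts actually arise:

* **Clean-site calls** (~92.3%) are genuinely present. Their features are
  truncated at the cohort's published 5th/95th percentile region (DP >= 80,
  het AF >= 0.33 after binomial sampling, QD >= 5.5, GQ >= 50, MQ >= 59,
  FS <= 9.2): a genuine variant at a clean site does not present with
  artifact-grade evidence. About 2% are homozygous (AF ~ 0.94–1.0).
* **Difficult-site calls** (~7.7%) carry degraded evidence: QD in
  [0.5, 3.3], AF below heterozygous balance along a deficiency frontier
  (the better the normalized quality, the lower the supporting fraction),
  12% low coverage (20–30 reads), 25% depressed mapping quality (38–55),
  30% strand bias (FS 8–35), and site profiles of 30% long homopolymers
  (length 10–15 within 3 bases, WHR 8–22) and 35% extreme GC (< 0.25 or
  > 0.75). About 7.9% of difficult-site calls are genuinely present — the
  future false negatives — and the rest are artifacts.
* **Artifacts recur.** Each artifact belongs to a recurrent site observed in
  ~8 carriers with an identical evidence vector (read-depth jitter aside in
  the VCF realization, annotations are copied exactly). This reflects how a
  single panel run across thousands of samples produces the *same*
  systematic miscall at the same difficult site, and it is the property that
  makes a zero-false-positive operating point transfer across resamples: any
  sizeable training subset contains every artifact site, so a threshold
  placed immediately above the worst-scoring artifact in training is above
  every artifact in held-out data as well. Difficult-but-true calls are
  unique (individual carriers) and drawn from the same evidence distribution
  as artifacts — the outcome of a difficult-site call is not readable from
  its features, which is why such calls need confirmation at all.

With these defaults, 10-fold cross-validation classifies 91–93% of calls
HIGH with zero false positives in every fold, a false-negative rate of
0.4–0.9% of confirmed calls, and AUC 0.996–0.999.

A second label mode (`generative_coefficients`) draws features from the
marginal families only and labels from Bernoulli(sigmoid(beta ·
x_standardized + b)), with the intercept solved by root-finding to hit the
target prevalence. It exists for parameter-recovery checks of the fitting
code; `feature_coupling=False` additionally breaks the AD = Binomial(DP, AF)
coupling because near-collinear features make individual coefficients
unidentifiable at any realistic sample size.

`simulate_vcf` realizes a cohort as files: the contig is built so that
difficult sites genuinely carry their planted homopolymers and GC-extreme
segments (and every copy of a recurrent artifact site shares one pasted
121-base context template), site features are then *computed* from that
sequence, and call features are embedded in the VCF annotation fields.
Re-extracting features from the written FASTA+VCF reproduces the stored
table to 32-bit float precision (htslib stores QUAL and INFO floats in 32
bits).

### What the generator does not emulate

Real read-level noise (no FASTQ/BAM), pseudogene sequence homology, the
joint feature distribution beyond the marginals and arithmetic identities,
and two details of the published low-confidence stratification: here all
unconfirmed calls have AF < 0.30 (the published table lists 8 of 513 with
AF >= 30%), and exact per-criterion cell counts are not targeted. Passing
tests therefore demonstrate the correctness and calibration behaviour of the
*method*, not that any particular laboratory's cohort is separable; on real
data the margin between artifact and genuine evidence must be established
empirically before relying on the threshold.

## Numerical and design choices

* Determinism: a single integer seed governs simulation, splitting and fold
  assignment; repeated runs produce byte-identical model JSON, VCF/FASTA and
  report files. Model serialization is lossless JSON.
* Ties in the longest-homopolymer selection break to the run nearest the
  anchor, then leftmost.
* Multi-allelic records are split per alt allele with the matching AD
  component; symbolic alleles and variants over 25 bp are skip-flagged and
  reported, never silently dropped.
* QD is recomputed as QUAL/DP (its definition), with a warning when an INFO
  QD disagrees by more than 10%.
* BED intervals are 0-based half-open; a flag fires iff the REF span
  intersects.
* Problem sizes in the test suite: oracle comparisons use 60-mers and sets
  of <= 200 points where brute force is exact and instant; cohort-level
  checks run the full n = 7179 across 10 seeds, and file-based round-trips
  use 300–1500 calls, which exercise every code path at a fraction of the
  cost.

## Known limitations

* The zero-FP guarantee is a property of the calibration set; transfer to
  unseen data relies on the recurrence/margin structure discussed above.
* The model is linear in the features; interactions (e.g. AF x DP) are not
  modelled, matching the method being implemented rather than improving it.
* Only het and hom-alt genotypes are scored; hom-alt is additionally always
  confirmed by the default override policy.
* VCFs are taken as left-aligned; no realignment or normalization beyond
  anchor selection is attempted.
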