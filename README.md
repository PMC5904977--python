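# vartriage

Confidence triage for clinical NGS variant calls: decide which calls can be
reported directly and which need orthogonal (Sanger) confirmation.

Clinical labs running capture-based targeted panels traditionally
Sanger-confirm every reported variant. Most NGS calls are unambiguous, but a
small subset — low allele fraction, extreme GC content, homopolymer
neighbourhoods, duplicated regions — genuinely needs a second assay.
`vartriage` fits a deterministic logistic-regression model of the
orthogonal-confirmation outcome on 14 site- and call-level features, then
calibrates its decision threshold to **eliminate false positives**: no call
classified HIGH confidence on the calibration data is one that Sanger found
not present. A conservative override policy additionally always confirms
homozygous calls, low-fraction calls (AF 0.1–0.3) and calls in flagged
pseudogene regions.

## The model

For a call with feature vector x (DP, AD, AF, GC@5/20/50, MQ, GQ, WHR,
HPL-D, HPL-L, QUAL, QD, FS; standardized by training mean/sd):

    P(confirmed | x) = sigmoid(beta . x + b)

fitted by L2-penalized maximum likelihood. The threshold tau is the smallest
value with zero false positives on the calibration set — the midpoint
between the highest-scoring unconfirmed call and the next confirmed score
above it — and the rule is HIGH iff P >= tau. Site features come from the
reference sequence: GC fraction in 5/20/50-base windows, the weighted
homopolymer rate (sum of squared homopolymer run lengths over the number of
runs in a 20-base window), and the distance to / length of the longest
homopolymer within 20 bases. See `docs/methods.md` for definitions,
conventions and the synthetic-cohort generator.

## Worked example

Everything is runnable without external data via the built-in cohort
simulator:

```sh
vartriage simulate --out-dir demo --n 2000 --seed 7
vartriage extract demo/calls.vcf --reference demo/reference.fa --out demo/extracted.tsv
python - <<'PY'
import pandas as pd
ext = pd.read_csv("demo/extracted.tsv", sep="\t")
lab = pd.read_csv("demo/labels.tsv", sep="\t")
ext.merge(lab, on=["chrom", "pos", "ref", "alt"]).to_csv(
    "demo/dataset.tsv", sep="\t", index=False, na_rep="NA")
PY
vartriage evaluate --features demo/dataset.tsv --k 10 --seed 7
```

The evaluation prints (abridged):

```json
{
 "accuracy": 0.9945,
 "auc_full_fit": 0.99791,
 "confusion": {"fn": 11, "fp": 0, "tn": 140, "tp": 1849}
}
```

Reading: of 2000 calls, 1849 + 0 = 1849 (92.5%) were classified HIGH
confidence out-of-fold and every one of them was confirmed (fp = 0 — the
error the threshold is built to eliminate); 151 calls were routed to Sanger,
of which 140 were indeed not present and 11 (0.6% of confirmed calls) were
genuine variants that cost one confirmatory reaction each. Training and
classification:

```sh
vartriage train --features demo/dataset.tsv --out-model demo/model.json --seed 7
vartriage classify demo/calls.vcf --reference demo/reference.fa \
    --model demo/model.json --out demo/triage
```

which writes `demo/triage.report.tsv` (one decision per call with
probability, class and machine-readable reason codes) and
`demo/triage.summary.json`. BED files with segmental-duplication, repeat or
pseudogene intervals plug in via `--bed-segdup`, `--bed-repeat`,
`--bed-pseudogene`.

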