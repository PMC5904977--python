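"""End-to-end triage of a VCF: score, apply clinical overrides, report.

Model output alone does not decide the worklist. A conservative deployment
policy always sends certain calls to confirmation regardless of the model's
probability: homozygous calls, low-fraction calls (AF in [0.1, 0.3]), and
calls in regions where a processed pseudogene is flagged. Segmental
duplication and repeat flags (from user-supplied BED files) are carried for
stratification and can optionally be promoted to overrides. Overrides are
monotone: they can demote HIGH to LOW, never the reverse.

Reason codes form a closed enumeration (:data:`REASON_CODES`) so downstream
systems can consume the report mechanically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .callsignals import (
    FEATURE_NAMES,
    CallFeatures,
    FeatureVector,
    VariantCall,
    assemble_feature_vector,
    call_features,
    parse_vcf,
)
from .confidence_model import HIGH, LOW, ConfidenceModel, classify
from .errors import BEDParseError, InputError
from .refcontext import ContextConfig, context_features

REASON_CODES = (
    "below_threshold",
    "undefined_feature",
    "low_fraction",
    "homozygous",
    "pseudogene",
    "segdup",
    "repeat",
)


@dataclass(frozen=True)
class IntervalFlagSet:
    """Per-call region flags derived solely from user-supplied BED files."""

    segdup: bool = False
    repeat: bool = False
    pseudogene: bool = False

    def as_dict(self) -> dict[str, bool]:
        return {"segdup": self.segdup, "repeat": self.repeat, "pseudogene": self.pseudogene}


@dataclass(frozen=True)
class OverridePolicy:
    """Which override rules are active; all toggles config-exposed."""

    confirm_homozygous: bool = True
    confirm_low_fraction: bool = True
    low_fraction_range: tuple[float, float] = (0.1, 0.3)
    confirm_pseudogene: bool = True
    confirm_segdup: bool = False
    confirm_repeat: bool = False


@dataclass
class TriageDecision:
    """Final routing of one call, with machine-readable reasons."""

    call: VariantCall
    vector: FeatureVector
    flags: IntervalFlagSet
    probability: float
    model_class: str
    final_class: str
    reasons: tuple[str, ...]


# ---------------------------------------------------------------------------
# Interval flags


def load_bed(path: str | Path) -> dict[str, IntervalTree]:
    """Parse a BED file (0-based half-open) into per-contig interval trees."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BEDParseError(f"{path}:{lineno}: expected at least 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BEDParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or end <= start:
                raise BEDParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            trees.setdefault(parts[0], IntervalTree()).addi(start, end)
    return trees


def _hits(trees: Mapping[str, IntervalTree] | None, call: VariantCall) -> bool:
    if not trees:
        return False
    tree = trees.get(call.chrom)
    if tree is None:
        return False
    start, end = call.ref_span
    return bool(tree.overlap(start, end))


def annotate_intervals(
    calls: Sequence[VariantCall],
    segdup: Mapping[str, IntervalTree] | str | Path | None = None,
    repeat: Mapping[str, IntervalTree] | str | Path | None = None,
    pseudogene: Mapping[str, IntervalTree] | str | Path | None = None,
) -> list[IntervalFlagSet]:
    """One flag set per call; a flag fires iff the REF span intersects an
    interval of the corresponding file. Absent file -> flag is false."""

    def as_trees(source):
        if source is None or isinstance(source, Mapping):
            return source
        return load_bed(source)

    seg_t, rep_t, pseudo_t = as_trees(segdup), as_trees(repeat), as_trees(pseudogene)
    return [
        IntervalFlagSet(
            segdup=_hits(seg_t, c), repeat=_hits(rep_t, c), pseudogene=_hits(pseudo_t, c)
        )
        for c in calls
    ]


# ---------------------------------------------------------------------------
# Override rules


def apply_overrides(
    call: VariantCall,
    vector: FeatureVector,
    probability: float,
    model_class: str,
    flags: IntervalFlagSet = IntervalFlagSet(),
    policy: OverridePolicy = OverridePolicy(),
    model_reason: str | None = None,
) -> TriageDecision:
    """Force LOW for the conservative clinical cases; never promote to HIGH."""
    reasons: list[str] = []
    if model_class == LOW and model_reason in ("undefined_feature", "below_threshold"):
        reasons.append(model_reason)
    af = vector.values[list(vector.schema).index("af")]
    if policy.confirm_homozygous and call.genotype == "hom_alt":
        reasons.append("homozygous")
    lo, hi = policy.low_fraction_range
    if policy.confirm_low_fraction and not math.isnan(af) and lo <= af <= hi:
        reasons.append("low_fraction")
    if policy.confirm_pseudogene and flags.pseudogene:
        reasons.append("pseudogene")
    if policy.confirm_segdup and flags.segdup:
        reasons.append("segdup")
    if policy.confirm_repeat and flags.repeat:
        reasons.append("repeat")
    final = LOW if reasons else model_class
    return TriageDecision(
        call=call,
        vector=vector,
        flags=flags,
        probability=probability,
        model_class=model_class,
        final_class=final,
        reasons=tuple(reasons),
    )


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class TriageReport:
    """Decisions for scoreable calls, skip-flagged calls, and a summary."""

    decisions: list[TriageDecision]
    skipped: list[VariantCall]
    summary: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.decisions:
            row = {
                "chrom": d.call.chrom,
                "pos": d.call.pos,
                "ref": d.call.ref,
                "alt": d.call.alt,
                "sample": d.call.sample_id,
                "genotype": d.call.genotype,
            }
            row.update(dict(zip(d.vector.schema, d.vector.values)))
            row.update(
                {
                    "probability": d.probability,
                    "model_class": d.model_class,
                    "final_class": d.final_class,
                    "reasons": ";".join(d.reasons),
                    "segdup": int(d.flags.segdup),
                    "repeat": int(d.flags.repeat),
                    "pseudogene": int(d.flags.pseudogene),
                }
            )
            rows.append(row)
        columns = [
            "chrom", "pos", "ref", "alt", "sample", "genotype",
            *FEATURE_NAMES,
            "probability", "model_class", "final_class", "reasons",
            "segdup", "repeat", "pseudogene",
        ]
        return pd.DataFrame(rows, columns=columns)

    def write(self, out_prefix: str | Path) -> dict[str, Path]:
        """Deterministic TSV report + JSON summary under ``<prefix>.*``."""
        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        report_path = out_prefix.with_suffix(".report.tsv")
        summary_path = out_prefix.with_suffix(".summary.json")
        frame = self.to_frame()
        frame.to_csv(report_path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
        summary_path.write_text(json.dumps(self.summary, sort_keys=True, indent=1) + "\n")
        return {"report": report_path, "summary": summary_path}


def run_pipeline(
    vcf: str | Path,
    reference: Mapping[str, object] | str | Path,
    model: ConfidenceModel | str | Path,
    sample: str | None = None,
    bed_segdup: str | Path | None = None,
    bed_repeat: str | Path | None = None,
    bed_pseudogene: str | Path | None = None,
    policy: OverridePolicy = OverridePolicy(),
    context_config: ContextConfig = ContextConfig(),
) -> TriageReport:
    """Classify every scoreable call of ``vcf``; see module docstring.

    ``reference`` may be a path to an indexed FASTA or a contig mapping.
    Skip-flagged calls (symbolic alleles, variants over 25 bp) are listed
    separately, never silently dropped. Reruns with identical inputs produce
    identical reports.
    """
    if not isinstance(model, ConfidenceModel):
        model = ConfidenceModel.load(model)
    if isinstance(reference, (str, Path)):
        import pyfaidx

        reference = pyfaidx.Fasta(str(reference))

    soft_impute = {
        name: float(model.impute[list(model.schema).index(name)])
        for name in ("mq", "gq", "fs")
        if name in model.schema
    }
    beds = {
        "segdup": load_bed(bed_segdup) if bed_segdup else None,
        "repeat": load_bed(bed_repeat) if bed_repeat else None,
        "pseudogene": load_bed(bed_pseudogene) if bed_pseudogene else None,
    }

    decisions: list[TriageDecision] = []
    skipped: list[VariantCall] = []
    for call in parse_vcf(vcf, sample=sample):
        if call.skip:
            skipped.append(call)
            continue
        ctx = context_features(reference, call.chrom, call.pos, context_config)
        feats = call_features(call, impute=soft_impute)
        vector = assemble_feature_vector(feats, ctx, schema=model.schema)
        model_class, model_reason = classify(model, vector)
        probability = float(model.predict_proba(vector)[0])
        flags = IntervalFlagSet(
            segdup=_hits(beds["segdup"], call),
            repeat=_hits(beds["repeat"], call),
            pseudogene=_hits(beds["pseudogene"], call),
        )
        decisions.append(
            apply_overrides(
                call, vector, probability, model_class,
                flags=flags, policy=policy, model_reason=model_reason,
            )
        )

    reason_histogram: dict[str, int] = {}
    for d in decisions:
        for r in d.reasons:
            reason_histogram[r] = reason_histogram.get(r, 0) + 1
    n_high = sum(1 for d in decisions if d.final_class == HIGH)
    summary = {
        "n_parsed": len(decisions) + len(skipped),
        "n_scored": len(decisions),
        "n_skipped": len(skipped),
        "n_high": n_high,
        "n_low": len(decisions) - n_high,
        "high_fraction": (n_high / len(decisions)) if decisions else 0.0,
        "reason_histogram": dict(sorted(reason_histogram.items())),
        "tau": model.tau,
    }
    return TriageReport(decisions=decisions, skipped=skipped, summary=summary)


# ---------------------------------------------------------------------------
# Stratification of LOW-confidence calls


STRATIFICATION_CRITERIA = (
    "low_coverage_20_30",
    "gc20_below_0.25",
    "gc50_below_0.25",
    "gc20_above_0.75",
    "gc50_above_0.75",
    "homopolymer_ge10_within_20bp",
    "segdup",
    "pseudogene",
    "repeat",
    "other",
)


def _criterion_masks(values: pd.DataFrame, flags: pd.DataFrame) -> dict[str, np.ndarray]:
    masks = {
        "low_coverage_20_30": (values["dp"] >= 20) & (values["dp"] <= 30),
        "gc20_below_0.25": values["gc20"] < 0.25,
        "gc50_below_0.25": values["gc50"] < 0.25,
        "gc20_above_0.75": values["gc20"] > 0.75,
        "gc50_above_0.75": values["gc50"] > 0.75,
        "homopolymer_ge10_within_20bp": values["hpl_l"] >= 10,
        "segdup": flags["segdup"].astype(bool),
        "pseudogene": flags["pseudogene"].astype(bool),
        "repeat": flags["repeat"].astype(bool),
    }
    any_mask = np.zeros(len(values), dtype=bool)
    for m in masks.values():
        any_mask |= np.asarray(m).astype(bool)
    masks["other"] = ~any_mask
    return {k: np.asarray(v).astype(bool) for k, v in masks.items()}


def stratify_low_confidence(
    decisions: Sequence[TriageDecision],
    labels: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Counts of LOW-confidence calls per difficulty criterion.

    Columns split by allele fraction (AF < 30% vs >= 30%) and, when Sanger
    outcomes are supplied, by confirmed ("present") vs not. Criteria are not
    mutually exclusive: a call matching several rows is counted in each.
    """
    low = [d for d in decisions if d.final_class == LOW]
    low_labels = None
    if labels is not None:
        if len(labels) != len(decisions):
            raise InputError("labels must align with decisions")
        low_labels = np.array(
            [int(l) for d, l in zip(decisions, labels) if d.final_class == LOW]
        )
    if not low:
        columns = ["present_af_lt_30", "present_af_ge_30", "not_present_af_lt_30",
                   "not_present_af_ge_30"] if labels is not None else ["af_lt_30", "af_ge_30"]
        return pd.DataFrame(0, index=list(STRATIFICATION_CRITERIA), columns=columns)

    values = pd.DataFrame(
        [dict(zip(d.vector.schema, d.vector.values)) for d in low]
    )
    flags = pd.DataFrame([d.flags.as_dict() for d in low])
    af_lt = np.asarray(values["af"] < 0.30)
    masks = _criterion_masks(values, flags)

    out: dict[str, list[int]] = {}
    if low_labels is None:
        out["af_lt_30"] = [int((masks[c] & af_lt).sum()) for c in STRATIFICATION_CRITERIA]
        out["af_ge_30"] = [int((masks[c] & ~af_lt).sum()) for c in STRATIFICATION_CRITERIA]
    else:
        present = low_labels.astype(bool)
        out["present_af_lt_30"] = [
            int((masks[c] & af_lt & present).sum()) for c in STRATIFICATION_CRITERIA
        ]
        out["present_af_ge_30"] = [
            int((masks[c] & ~af_lt & present).sum()) for c in STRATIFICATION_CRITERIA
        ]
        out["not_present_af_lt_30"] = [
            int((masks[c] & af_lt & ~present).sum()) for c in STRATIFICATION_CRITERIA
        ]
        out["not_present_af_ge_30"] = [
            int((masks[c] & ~af_lt & ~present).sum()) for c in STRATIFICATION_CRITERIA
        ]
    return pd.DataFrame(out, index=list(STRATIFICATION_CRITERIA))
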