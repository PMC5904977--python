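"""Call-dependent features parsed from VCF records.

One :class:`VariantCall` is the unit of analysis: a single alt allele of a
single sample. Multi-allelic records are split, taking the matching component
of the FORMAT ``AD`` field. Calls longer than 25 bp or with symbolic alleles
are emitted with a skip flag rather than silently dropped, so the caller can
report them separately.

The eight call-level features are the GATK-HaplotypeCaller-style annotations:

===== =============================================================
DP    read depth at the position (FORMAT)
AD    reads supporting the alt allele (FORMAT, alt component)
AF    allele fraction, AD / DP
MQ    root-mean-square mapping quality (INFO)
GQ    genotype quality (FORMAT)
QUAL  caller quality score (column 6)
QD    QUAL normalized by DP — recomputed as QUAL/DP, with a warning if an
      INFO QD is present and disagrees by more than 10%
FS    Phred-scaled Fisher's-exact strand-bias score (INFO)
===== =============================================================

Missing-value policy is fail-safe: absent QUAL/DP/AD leave the core features
undefined and the call is routed to LOW confidence downstream; absent
MQ/GQ/FS are imputed with training-set medians and recorded in the mask.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import InputError, SchemaError, VCFParseError
from .refcontext import ContextFeatures

#: Fixed feature order of the model schema.
FEATURE_NAMES: tuple[str, ...] = (
    "dp",
    "ad",
    "af",
    "gc5",
    "gc20",
    "gc50",
    "mq",
    "gq",
    "whr",
    "hpl_d",
    "hpl_l",
    "qual",
    "qd",
    "fs",
)

#: Features whose absence is tolerated via median imputation (everything else
#: missing puts the call in the fail-safe LOW route).
SOFT_MISSING: frozenset[str] = frozenset({"mq", "gq", "fs"})

#: Largest variant length (max allele length - 1) the model scores.
MAX_VARIANT_LENGTH = 25

_BASES = frozenset("ACGTN")


@dataclass
class VariantCall:
    """One normalized VCF record for a single sample/alt allele."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    sample_id: str
    genotype: str  # "het" | "hom_alt" | "other"
    qual: float | None = None
    dp: int | None = None
    ad: int | None = None
    gq: float | None = None
    mq: float | None = None
    fs: float | None = None
    qd_info: float | None = None
    skip: bool = False
    skip_reason: str | None = None

    @property
    def variant_length(self) -> int:
        """Inserted/deleted bases (0 for SNVs): max allele length - 1."""
        return max(len(self.ref), len(self.alt)) - 1

    @property
    def ref_span(self) -> tuple[int, int]:
        """0-based half-open interval covered by the REF allele."""
        return self.pos - 1, self.pos - 1 + len(self.ref)


@dataclass(frozen=True)
class CallFeatures:
    """The eight call-dependent features; undefined values are ``nan``."""

    dp: float
    ad: float
    af: float
    mq: float
    gq: float
    qual: float
    qd: float
    fs: float
    mask: frozenset[str] = frozenset()

    def as_dict(self) -> dict[str, float]:
        return {
            k: getattr(self, k) for k in ("dp", "ad", "af", "mq", "gq", "qual", "qd", "fs")
        }


@dataclass(frozen=True)
class FeatureVector:
    """Fixed-order feature values plus a missing-value mask."""

    values: np.ndarray
    mask: frozenset[str]
    schema: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.schema),):
            raise SchemaError(
                f"vector of length {self.values.shape} does not match schema "
                f"of {len(self.schema)} features"
            )

    @property
    def hard_missing(self) -> frozenset[str]:
        """Masked features that trigger the fail-safe LOW route."""
        return self.mask - SOFT_MISSING


def _genotype_class(gt: tuple | None, alt_index: int) -> str:
    if gt is None or any(a is None for a in gt):
        return "other"
    alleles = set(gt)
    if alleles == {alt_index}:
        return "hom_alt"
    if alleles == {0, alt_index} and list(gt).count(alt_index) == 1:
        return "het"
    return "other"


def _scalar(value) -> float | None:
    """INFO fields declared Number=1 arrive as scalars, others as tuples."""
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        value = value[0] if value else None
    return None if value is None else float(value)


def _info_get(rec, key: str) -> float | None:
    """INFO lookup tolerating keys absent from the header (pysam raises)."""
    try:
        return _scalar(rec.info.get(key))
    except (KeyError, ValueError):
        return None


def parse_vcf(path: str | Path, sample: str | None = None) -> Iterator[VariantCall]:
    """Yield one :class:`VariantCall` per alt allele of each record.

    ``sample`` selects the sample column; by default the first sample is
    used. Records with symbolic alleles or variants longer than 25 bp are
    yielded with ``skip=True`` and a reason, never silently dropped.
    """
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VCFParseError(f"{path}: {exc}") from exc

    samples = list(vcf.header.samples)
    if sample is not None:
        if sample not in samples:
            raise InputError(f"sample {sample!r} not found in {path} (has {samples})")
        sample_id = sample
    else:
        sample_id = samples[0] if samples else ""

    for rec in vcf:
        fmt = rec.samples[sample_id] if sample_id else None
        gt = fmt.get("GT") if fmt is not None else None
        ad_values = fmt.get("AD") if fmt is not None else None
        dp = fmt.get("DP") if fmt is not None else None
        gq = fmt.get("GQ") if fmt is not None else None
        mq = _info_get(rec, "MQ")
        fs = _info_get(rec, "FS")
        qd_info = _info_get(rec, "QD")

        for i, alt in enumerate(rec.alts or ()):
            alt_index = i + 1
            ad = None
            if ad_values is not None and len(ad_values) > alt_index:
                ad = ad_values[alt_index]
            call = VariantCall(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref.upper(),
                alt=str(alt).upper(),
                sample_id=sample_id,
                genotype=_genotype_class(gt, alt_index),
                qual=None if rec.qual is None else float(rec.qual),
                dp=None if dp is None else int(dp),
                ad=None if ad is None else int(ad),
                gq=None if gq is None else float(gq),
                mq=mq,
                fs=fs,
                qd_info=qd_info,
            )
            if set(call.alt) - _BASES or set(call.ref) - _BASES:
                call.skip, call.skip_reason = True, "symbolic_allele"
            elif call.ref == call.alt:
                call.skip, call.skip_reason = True, "ref_equals_alt"
            elif call.variant_length > MAX_VARIANT_LENGTH:
                call.skip, call.skip_reason = True, "variant_too_long"
            yield call


def call_features(
    call: VariantCall, impute: Mapping[str, float] | None = None
) -> CallFeatures:
    """Derive AF, QD and the raw annotations; apply the missing-value policy.

    ``impute`` maps soft-missing feature names (``mq``/``gq``/``fs``) to the
    training-set medians used to keep the logistic inputs finite; imputed
    features are recorded in the mask either way.
    """
    mask: set[str] = set()
    dp = math.nan if call.dp is None else float(call.dp)
    ad = math.nan if call.ad is None else float(call.ad)
    qual = math.nan if call.qual is None else float(call.qual)

    if call.dp is None or call.dp <= 0:
        mask.update({"dp", "af", "qd"})
        if call.dp is not None and call.dp <= 0:
            dp = float(call.dp)
        af = qd = math.nan
    else:
        if call.ad is None:
            mask.update({"ad", "af"})
            af = math.nan
        else:
            af = ad / dp
        if call.qual is None:
            mask.update({"qual", "qd"})
            qd = math.nan
        else:
            qd = qual / dp
            if call.qd_info is not None and call.qd_info > 0:
                if abs(qd - call.qd_info) > 0.10 * max(qd, call.qd_info):
                    warnings.warn(
                        f"{call.chrom}:{call.pos} INFO QD {call.qd_info:.2f} disagrees "
                        f"with QUAL/DP {qd:.2f} by >10%; using QUAL/DP",
                        stacklevel=2,
                    )
    if call.ad is None:
        mask.add("ad")
    if call.qual is None:
        mask.add("qual")

    soft: dict[str, float] = {}
    for name, raw in (("mq", call.mq), ("gq", call.gq), ("fs", call.fs)):
        if raw is None:
            mask.add(name)
            soft[name] = float(impute[name]) if impute and name in impute else math.nan
        else:
            soft[name] = float(raw)

    return CallFeatures(
        dp=dp,
        ad=ad,
        af=af,
        mq=soft["mq"],
        gq=soft["gq"],
        qual=qual,
        qd=qd,
        fs=soft["fs"],
        mask=frozenset(mask),
    )


def assemble_feature_vector(
    call_feats: CallFeatures,
    ctx_feats: ContextFeatures,
    schema: Sequence[str] = FEATURE_NAMES,
) -> FeatureVector:
    """Merge call- and site-dependent features into the fixed-order vector."""
    schema = tuple(schema)
    pool = {**call_feats.as_dict(), **ctx_feats.as_dict()}
    unknown = set(schema) - set(pool)
    if unknown:
        raise SchemaError(f"schema requests unknown features: {sorted(unknown)}")
    values = np.array([pool[name] for name in schema], dtype=float)
    mask = set(call_feats.mask) | set(ctx_feats.undefined())
    return FeatureVector(values=values, mask=frozenset(mask & set(schema)), schema=schema)


# ---------------------------------------------------------------------------
# Tabular I/O


def feature_frame(
    calls: Sequence[VariantCall], vectors: Sequence[FeatureVector]
) -> pd.DataFrame:
    """Site identifiers plus the 14 feature columns, one row per call."""
    if len(calls) != len(vectors):
        raise InputError("calls and vectors must have equal length")
    rows = []
    for call, vec in zip(calls, vectors):
        row = {"chrom": call.chrom, "pos": call.pos, "ref": call.ref, "alt": call.alt}
        row.update(dict(zip(vec.schema, vec.values)))
        rows.append(row)
    columns = ["chrom", "pos", "ref", "alt", *FEATURE_NAMES]
    return pd.DataFrame(rows, columns=columns)


def write_feature_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    """TSV with header; missing values encoded as ``NA``."""
    frame.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_feature_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)
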