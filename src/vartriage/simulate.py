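"""Synthetic references, VCFs and labelled cohorts for end-to-end testing.

The default ("cohort") generator emulates a clinical targeted-panel
confirmation cohort: ~7179 calls of which ~7.1% are not confirmed by Sanger,
with per-feature marginals matched to the published 5th/50th/95th percentile
triples (:data:`TABLE_MARGINALS`).

Truth is drawn first, the way artifacts actually arise: most calls sit at
clean sites and are genuine; a small difficult-site subpopulation (low allele
fraction, extreme GC, long homopolymers, low mapping quality) contains both
sequencing artifacts (~92% of it) and genuinely present variants that are
simply hard to sequence (~8% — the calls a conservative pipeline sends to
Sanger and confirms). Artifact call-quality evidence is bounded away from the
clean-site cluster (artifacts with pristine annotations do not occur), which
reproduces the empirical near-separability of such cohorts — the property
that makes a zero-false-positive operating point attainable at all. The
dataset-level identities AD ~ Binomial(DP, AF), AF = AD/DP and QD = QUAL/DP
hold by construction.

A second label mode is selected by supplying ``generative_coefficients``:
features are drawn from the marginal families only and the confirmation
outcome is Bernoulli(sigmoid(beta . x_standardized + b)), with the intercept
solved so the unconfirmed prevalence hits its target. This mode has no
hard class structure; it exists for parameter-recovery checks of the fitting
code against a known coefficient vector.

``simulate_vcf`` additionally realizes a cohort as (FASTA, VCF): the
reference contig is built so that difficult sites really carry planted
homopolymers / GC-extreme context, site features are then *computed* from
that sequence (so re-extraction round-trips exactly), and call features are
embedded in the VCF annotation fields.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .callsignals import FEATURE_NAMES
from .errors import InputError
from .refcontext import ContextConfig, context_features

#: Published per-feature (5th percentile, median, 95th percentile) triples
#: that the generator's marginals are matched to.
TABLE_MARGINALS: dict[str, tuple[float, float, float]] = {
    "dp": (78, 222, 433),
    "ad": (25, 110, 393),
    "af": (0.13, 0.49, 0.56),
    "gc5": (0.18, 0.45, 0.73),
    "gc20": (0.29, 0.44, 0.69),
    "gc50": (0.30, 0.42, 0.68),
    "mq": (59.3, 60.0, 60.0),
    "gq": (50, 99, 99),
    "whr": (1.6, 2.4, 4.3),
    "hpl_d": (0, 5, 15),
    "hpl_l": (2, 4, 6),
    "qual": (142, 2564, 5448),
    "qd": (1.6, 11.3, 16.9),
    "fs": (0, 1.7, 9.2),
}

#: Default coefficient vector (schema order) for the logistic label mode.
DEFAULT_LOGISTIC_COEF: tuple[float, ...] = (
    0.60,   # dp
    -0.45,  # ad
    1.10,   # af
    -0.40,  # gc5
    0.50,   # gc20
    -0.50,  # gc50
    0.45,   # mq
    0.70,   # gq
    -0.80,  # whr
    0.40,   # hpl_d
    -0.60,  # hpl_l
    0.90,   # qual
    1.00,   # qd
    -0.70,  # fs
)


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic cohort.

    Defaults reproduce the published cohort's composition: 7179 calls, 7.1%
    unconfirmed, with ~7.9% of difficult-site calls nonetheless confirmed
    (the future false negatives), ~18.8% indels, and marginals from
    :data:`TABLE_MARGINALS`.
    """

    n_calls: int = 7179
    unconfirmed_prevalence: float = 0.071
    difficult_confirm_rate: float = 0.079
    artifact_site_copies: int = 8
    hom_alt_fraction: float = 0.02
    indel_fraction: float = 0.188
    seed: int = 0
    feature_marginals: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(TABLE_MARGINALS)
    )
    # logistic label mode (None -> cohort mode)
    generative_coefficients: Sequence[float] | None = None
    generative_intercept: float | None = None
    feature_coupling: bool = True
    # reference / VCF realization
    contig_name: str = "sim1"
    contig_length: int | None = None
    gc_target: float = 0.45
    homopolymer_spec: tuple[tuple[int, int], ...] = ()
    call_spacing: int = 150
    sample_id: str = "SAMPLE1"

    def __post_init__(self) -> None:
        if not 0 < self.unconfirmed_prevalence < 1:
            raise InputError("unconfirmed_prevalence must be in (0, 1)")
        if not 0 <= self.difficult_confirm_rate < 1:
            raise InputError("difficult_confirm_rate must be in [0, 1)")
        for name, (p5, p50, p95) in self.feature_marginals.items():
            if not p5 <= p50 <= p95:
                raise InputError(f"marginals for {name!r} must satisfy p5 <= p50 <= p95")

    @property
    def difficult_rate(self) -> float:
        """Share of calls at difficult sites implied by the prevalence."""
        return self.unconfirmed_prevalence / (1.0 - self.difficult_confirm_rate)


# ---------------------------------------------------------------------------
# Low-level sequence helpers


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    at, gcp = (1.0 - gc) / 2.0, gc / 2.0
    return rng.choice(np.array(list("ACGT")), size=n, p=[at, gcp, gcp, at])


def simulate_reference(
    config: SimulationConfig,
) -> tuple[str, list[tuple[int, int]]]:
    """Random contig at ``gc_target`` with the requested homopolymers planted.

    Returns the sequence and the recorded (0-based start, length) of each
    planted run. Reproducible by seed.
    """
    length = config.contig_length or 10_000
    if length <= 0:
        raise InputError("contig_length must be positive")
    total_hp = sum(l * c for l, c in config.homopolymer_spec)
    if total_hp >= length:
        raise InputError("planted homopolymers exceed contig length")
    rng = np.random.default_rng(config.seed)
    seq = _random_seq(rng, length, config.gc_target)
    planted: list[tuple[int, int]] = []
    for run_length, count in config.homopolymer_spec:
        for _ in range(count):
            start = int(rng.integers(0, length - run_length))
            base = str(rng.choice(list("ACGT")))
            seq[start : start + run_length] = base
            planted.append((start, run_length))
    return "".join(seq), planted


# ---------------------------------------------------------------------------
# Call-feature sampling (shared by table and VCF modes)


def _truncnorm(rng, mean, sd, lo, hi, size) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_good_calls(rng: np.random.Generator, m: int, cfg: SimulationConfig) -> dict:
    """Call-level features of clean-site, genuinely present variants.

    Ranges are truncated at the cohort's published 5th/95th percentile
    region: a clean-site genuine call does not present with artifact-grade
    evidence, so its features have hard floors (depth, allele balance,
    normalized quality, genotype quality, mapping quality) and strand-bias
    stays bounded. That compactness is what leaves the score band between
    artifact evidence and clean evidence empty.
    """
    dp = np.clip(rng.lognormal(math.log(222.0), 0.45, m), 80, 1500).astype(int)
    hom = rng.random(m) < cfg.hom_alt_fraction
    af_target = np.where(
        hom,
        rng.uniform(0.94, 1.0, m),
        _truncnorm(rng, 0.49, 0.07, 0.36, 0.62, m),
    )
    ad = rng.binomial(dp, af_target)
    het_floor = np.rint(0.33 * dp).astype(int)  # true het allele balance floor
    ad = np.where(hom, ad, np.maximum(ad, het_floor))
    qd = _truncnorm(rng, 11.5, 3.2, 5.5, 26.0, m)
    qual = np.round(qd * dp, 2)
    mq = np.round(np.clip(60.0 - rng.exponential(0.25, m), 59.0, 60.0), 2)
    gq = np.clip(np.rint(rng.normal(115.0, 40.0, m)), 50, 99)
    fs = np.round(np.clip(rng.exponential(2.7, m), 0.0, 9.2), 3)
    return {
        "dp": dp,
        "ad": ad,
        "qual": qual,
        "mq": mq,
        "gq": gq,
        "fs": fs,
        "genotype": np.where(hom, "hom_alt", "het"),
    }


def _draw_difficult_calls(rng: np.random.Generator, m: int, cfg: SimulationConfig) -> dict:
    """Call-level features of scattered difficult-site calls.

    These are drawn from one distribution regardless of the eventual Sanger
    outcome: whether a difficult-site call turns out to be a sequencing
    artifact or a genuinely present variant is not readable from its
    evidence, which is exactly why such calls need orthogonal confirmation.
    Normalized call quality stays below the clean-site floor, and the
    supporting-read fraction is bounded below heterozygous balance along a
    deficiency frontier (the better the normalized quality, the lower the
    fraction).
    """
    low_cov = rng.random(m) < 0.12
    dp = np.where(
        low_cov,
        rng.integers(20, 31, m),
        np.clip(rng.lognormal(math.log(180.0), 0.5, m), 31, 1500).astype(int),
    ).astype(int)
    qd = rng.uniform(0.5, 3.3, m)
    frontier = 0.30 - 0.04 * qd  # upper AF bound, decreasing in QD
    af_target = rng.uniform(0.08, frontier - 0.01, m)
    ad = np.maximum(rng.binomial(dp, af_target), 1)
    ad = np.minimum(ad, np.maximum(np.rint(frontier * dp).astype(int), 1))
    qual = np.round(qd * dp, 2)
    mq = np.where(
        rng.random(m) < 0.25,
        rng.uniform(38.0, 55.0, m),
        np.clip(60.0 - rng.exponential(0.25, m), 40.0, 60.0),
    )
    mq = np.round(mq, 2)
    gq = np.clip(np.rint(rng.normal(62.0, 15.0, m)), 2, 92)
    fs = np.where(
        rng.random(m) < 0.30,
        rng.uniform(8.0, 35.0, m),
        rng.exponential(2.7, m),
    )
    fs = np.round(np.clip(fs, 0.0, 60.0), 3)
    return {
        "dp": dp,
        "ad": ad,
        "qual": qual,
        "mq": mq,
        "gq": gq,
        "fs": fs,
        "genotype": np.full(m, "het", dtype=object),
        "hp_profile": rng.random(m) < 0.30,
        "gc_profile": rng.random(m) < 0.35,
        "gc_high": rng.random(m) < 0.5,
    }


def _artifact_site_assignment(n_artifacts: int, copies: int) -> tuple[int, np.ndarray]:
    """Allocate artifact calls to recurrent sites, ~``copies`` calls each.

    Artifacts in a capture-based panel are systematic: the same
    difficult-site miscall recurs across carriers with the same evidence.
    Every site gets at least ``copies`` members (round-robin allocation), so
    any sizeable subsample of the cohort contains every artifact site.
    """
    n_sites = max(1, n_artifacts // copies)
    return n_sites, np.arange(n_artifacts) % n_sites


def _draw_good_sites(rng: np.random.Generator, m: int) -> dict:
    """Site features of clean contexts, drawn (table mode only)."""
    g = rng.normal(0.44, 0.115, m)
    gc50 = np.round(np.clip(g + rng.normal(0, 0.035, m), 0.02, 0.98), 3)
    gc20 = np.rint(np.clip(g + rng.normal(0, 0.06, m), 0.0, 1.0) * 20) / 20
    gc5 = np.rint(np.clip(g + rng.normal(0, 0.16, m), 0.0, 1.0) * 5) / 5
    whr = np.round(np.clip(rng.lognormal(math.log(2.4), 0.33, m), 1.0, 5.5), 3)
    hpl_l = rng.choice([2, 3, 4, 5, 6, 7], size=m, p=[0.18, 0.22, 0.26, 0.18, 0.11, 0.05])
    hpl_d = np.clip(np.rint(np.abs(rng.normal(0, 7.0, m))), 0, 20)
    return {
        "gc5": gc5,
        "gc20": gc20,
        "gc50": gc50,
        "whr": whr,
        "hpl_d": hpl_d.astype(float),
        "hpl_l": hpl_l.astype(float),
    }


def _draw_difficult_sites(rng: np.random.Generator, d: dict) -> dict:
    """Site features of difficult contexts, drawn (table mode only)."""
    m = len(d["dp"])
    site = _draw_good_sites(rng, m)
    hp = d["hp_profile"]
    site["whr"] = np.where(hp, np.round(rng.uniform(8.0, 22.0, m), 3), site["whr"])
    site["hpl_l"] = np.where(hp, rng.integers(10, 16, m).astype(float), site["hpl_l"])
    site["hpl_d"] = np.where(hp, rng.integers(0, 4, m).astype(float), site["hpl_d"])
    gcx = d["gc_profile"]
    g_extreme = np.where(
        d["gc_high"], rng.uniform(0.78, 0.92, m), rng.uniform(0.04, 0.20, m)
    )
    site["gc50"] = np.where(gcx, np.round(np.clip(g_extreme + rng.normal(0, 0.02, m), 0, 1), 3), site["gc50"])
    site["gc20"] = np.where(gcx, np.rint(np.clip(g_extreme + rng.normal(0, 0.05, m), 0, 1) * 20) / 20, site["gc20"])
    site["gc5"] = np.where(gcx, np.rint(np.clip(g_extreme + rng.normal(0, 0.12, m), 0, 1) * 5) / 5, site["gc5"])
    return site


def _finalize_frame(parts: dict) -> pd.DataFrame:
    frame = pd.DataFrame(parts)
    frame["af"] = frame["ad"] / frame["dp"]
    frame["qd"] = frame["qual"] / frame["dp"]
    return frame[list(FEATURE_NAMES)].astype(float)


# ---------------------------------------------------------------------------
# Feature-table simulation


def simulate_feature_table(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Draw a labelled 14-feature table; see the module docstring for modes.

    Returns ``(features, confirmed, truth)`` where ``confirmed`` is the
    binary Sanger outcome (1 = present) and ``truth`` records the generative
    parameters (and per-call difficult-site membership in cohort mode).
    """
    if config.generative_coefficients is not None:
        return _logistic_table(config)
    return _cohort_table(config)


def _assign_classes(
    rng: np.random.Generator, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Per-call class: 0 good, 1 difficult-but-true, 2 artifact.

    Artifacts (class 2, never confirmed) and difficult-but-true calls
    (class 1, confirmed by Sanger) share one evidence distribution — the
    outcome of a difficult-site call is not readable from its features,
    which is why it needs confirmation at all.
    """
    n = config.n_calls
    prev = config.unconfirmed_prevalence
    p_true = prev * config.difficult_confirm_rate / (1.0 - config.difficult_confirm_rate)
    u = rng.random(n)
    cls = np.zeros(n, dtype=int)
    cls[u < prev + p_true] = 1
    cls[u < prev] = 2
    confirmed = (cls != 2).astype(int)
    return cls, confirmed


def _cohort_table(config: SimulationConfig):
    rng = np.random.default_rng(config.seed)
    n = config.n_calls
    cls, confirmed = _assign_classes(rng, config)
    good_m, true_m, art_m = (int((cls == c).sum()) for c in (0, 1, 2))

    good = _draw_good_calls(rng, good_m, config)
    good.update(_draw_good_sites(rng, good_m))
    diff_true = _draw_difficult_calls(rng, true_m, config)
    diff_true.update(_draw_difficult_sites(rng, diff_true))
    # artifacts recur: draw one evidence vector per site, copy it exactly
    n_sites, site_of_copy = _artifact_site_assignment(art_m, config.artifact_site_copies)
    art_sites = _draw_difficult_calls(rng, n_sites, config)
    art_sites.update(_draw_difficult_sites(rng, art_sites))
    art = {k: np.asarray(v)[site_of_copy] for k, v in art_sites.items()}

    parts: dict[str, np.ndarray] = {}
    for name in ("dp", "ad", "qual", "mq", "gq", "fs", "gc5", "gc20", "gc50", "whr", "hpl_d", "hpl_l"):
        col = np.empty(n, dtype=float)
        col[cls == 0] = good[name]
        col[cls == 1] = diff_true[name]
        col[cls == 2] = art[name]
        parts[name] = col
    genotype = np.empty(n, dtype=object)
    genotype[cls == 0] = good["genotype"]
    genotype[cls == 1] = diff_true["genotype"]
    genotype[cls == 2] = art["genotype"]

    frame = _finalize_frame(parts)
    truth = {
        "mode": "cohort",
        "difficult_site": cls > 0,
        "artifact": cls == 2,
        "genotype": genotype,
        "params": {
            "n_calls": n,
            "unconfirmed_prevalence": config.unconfirmed_prevalence,
            "difficult_confirm_rate": config.difficult_confirm_rate,
            "artifact_site_copies": config.artifact_site_copies,
            "n_artifact_sites": n_sites,
            "difficult_rate": config.difficult_rate,
            "seed": config.seed,
        },
    }
    return frame, confirmed, truth


def _logistic_table(config: SimulationConfig):
    beta = np.asarray(config.generative_coefficients, dtype=float)
    if beta.shape != (len(FEATURE_NAMES),):
        raise InputError(
            f"generative_coefficients must have length {len(FEATURE_NAMES)}"
        )
    rng = np.random.default_rng(config.seed)
    n = config.n_calls

    dp = np.clip(rng.lognormal(math.log(222.0), 0.41, n), 20, 3000).astype(int)
    low_af = rng.random(n) < 0.10
    af_target = np.where(
        low_af, rng.uniform(0.08, 0.35, n), _truncnorm(rng, 0.49, 0.06, 0.05, 0.99, n)
    )
    if config.feature_coupling:
        ad = np.maximum(rng.binomial(dp, af_target), 1)
        qual = np.round(np.clip(rng.lognormal(math.log(2564.0), 0.46, n), 10, 60000), 2)
        qd = qual / dp
    else:
        ad = np.clip(rng.lognormal(math.log(110.0), 0.5, n), 5, 3000).astype(int)
        qual = np.round(np.clip(rng.lognormal(math.log(2564.0), 0.46, n), 10, 60000), 2)
        qd = _truncnorm(rng, 11.3, 4.5, 0.3, 30.0, n)
    site = _draw_good_sites(rng, n)
    mq = np.round(np.clip(60.0 - rng.exponential(0.25, n), 40.0, 60.0), 2)
    gq = np.clip(np.rint(rng.normal(115.0, 40.0, n)), 2, 99)
    fs = np.round(np.clip(rng.exponential(2.7, n), 0.0, 60.0), 3)

    parts = {
        "dp": dp.astype(float),
        "ad": ad.astype(float),
        "qual": qual,
        "mq": mq,
        "gq": gq,
        "fs": fs,
        **site,
    }
    frame = pd.DataFrame(parts)
    if config.feature_coupling:
        frame["af"] = frame["ad"] / frame["dp"]
        frame["qd"] = frame["qual"] / frame["dp"]
    else:
        frame["af"] = np.clip(af_target, 0.0, 1.0)
        frame["qd"] = qd
    frame = frame[list(FEATURE_NAMES)].astype(float)

    Z = (frame.values - frame.values.mean(axis=0)) / frame.values.std(axis=0)
    eta0 = Z @ beta
    target = 1.0 - config.unconfirmed_prevalence
    if config.generative_intercept is not None:
        intercept = float(config.generative_intercept)
    else:
        def gap(b: float) -> float:
            return float(expit(eta0 + b).mean() - target)

        lo, hi = -30.0, 30.0
        if gap(lo) > 0 or gap(hi) < 0:
            raise InputError(
                "target prevalence unattainable for the given coefficients: "
                f"mean sigmoid ranges ({expit(eta0 + lo).mean():.4f}, "
                f"{expit(eta0 + hi).mean():.4f})"
            )
        intercept = float(brentq(gap, lo, hi, xtol=1e-10))
    confirmed = (rng.random(n) < expit(eta0 + intercept)).astype(int)
    truth = {
        "mode": "logistic",
        "beta": beta,
        "intercept": intercept,
        "standardize_center": frame.values.mean(axis=0),
        "standardize_scale": frame.values.std(axis=0),
        "params": {
            "n_calls": n,
            "unconfirmed_prevalence": config.unconfirmed_prevalence,
            "seed": config.seed,
            "feature_coupling": config.feature_coupling,
        },
    }
    return frame, confirmed, truth


# ---------------------------------------------------------------------------
# VCF realization


def _format_fasta(name: str, seq: str, width: int = 60) -> str:
    lines = [f">{name}"]
    lines += [seq[i : i + width] for i in range(0, len(seq), width)]
    return "\n".join(lines) + "\n"


_VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID={contig},length={length}>
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS Mapping Quality">
##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled p-value using Fisher's exact test to detect strand bias">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Approximate read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def simulate_vcf(
    config: SimulationConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Write a matched (FASTA, VCF, features, labels, truth) file set.

    Variant positions are spaced ``call_spacing`` bases apart. Difficult
    sites with a homopolymer profile get a 10-15 base run planted 0-3 bases
    from the position; GC-profile sites sit in a locally rewritten
    GC-extreme segment. Site features are computed from the realized contig
    with :func:`vartriage.refcontext.context_features`, so re-extracting
    features from the output reproduces the stored table. Same seed, same
    bytes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.generative_coefficients is not None:
        raise InputError("simulate_vcf requires the cohort label mode")
    rng = np.random.default_rng(config.seed)
    n = config.n_calls
    spacing = config.call_spacing
    if spacing < 60:
        raise InputError("call_spacing must be at least 60 bases")
    margin = 200
    length = n * spacing + 2 * margin
    if config.contig_length is not None and config.contig_length < length:
        raise InputError(
            f"contig_length {config.contig_length} too short for {n} calls "
            f"at spacing {spacing} (need >= {length})"
        )
    length = max(length, config.contig_length or 0)

    cls, confirmed = _assign_classes(rng, config)
    good_m, true_m, art_m = (int((cls == c).sum()) for c in (0, 1, 2))
    good = _draw_good_calls(rng, good_m, config)
    diff_true = _draw_difficult_calls(rng, true_m, config)
    n_sites, site_of_copy = _artifact_site_assignment(art_m, config.artifact_site_copies)
    art_sites = _draw_difficult_calls(rng, n_sites, config)
    art = {k: np.asarray(v)[site_of_copy] for k, v in art_sites.items()}

    calls: dict[str, np.ndarray] = {}
    for name in ("dp", "ad", "qual", "mq", "gq", "fs", "genotype"):
        col = np.empty(n, dtype=object)
        col[cls == 0] = good[name]
        col[cls == 1] = diff_true[name]
        col[cls == 2] = art[name]
        calls[name] = col
    hp_profile = np.zeros(n, dtype=bool)
    hp_profile[cls == 1] = diff_true["hp_profile"]
    gc_profile = np.zeros(n, dtype=bool)
    gc_profile[cls == 1] = diff_true["gc_profile"]
    gc_high = np.zeros(n, dtype=bool)
    gc_high[cls == 1] = diff_true["gc_high"]

    seq = _random_seq(rng, length, config.gc_target)
    positions = margin + spacing * np.arange(n) + rng.integers(0, spacing // 3, n)

    # rewrite difficult-but-true contexts: GC-extreme segment / planted run
    for i in np.flatnonzero(gc_profile):
        p0 = int(positions[i]) - 1
        gc = 0.85 if gc_high[i] else 0.12
        seq[p0 - 60 : p0 + 61] = _random_seq(rng, 121, gc)
    for i in np.flatnonzero(hp_profile):
        p0 = int(positions[i]) - 1
        run_length = int(rng.integers(10, 16))
        gap = int(rng.integers(1, 4))
        start = p0 + gap if rng.random() < 0.5 else p0 - gap - run_length
        base = str(rng.choice(list("ACGT")))
        seq[start : start + run_length] = base
        # keep the call base itself distinct from the run
        if seq[p0] == base:
            seq[p0] = {"A": "C", "C": "A", "G": "T", "T": "G"}[base]

    # every copy of a recurrent artifact site shares one pasted context,
    # built with that site's own difficulty profile
    templates: list[np.ndarray] = []
    for s in range(n_sites):
        gc = (0.85 if art_sites["gc_high"][s] else 0.12) if art_sites["gc_profile"][s] else config.gc_target
        tpl = _random_seq(rng, 121, gc)
        if art_sites["hp_profile"][s]:
            run_length = int(rng.integers(10, 16))
            gap = int(rng.integers(1, 4))
            start = 60 + gap if rng.random() < 0.5 else 60 - gap - run_length
            base = str(rng.choice(list("ACGT")))
            tpl[start : start + run_length] = base
            if tpl[60] == base:
                tpl[60] = {"A": "C", "C": "A", "G": "T", "T": "G"}[base]
        templates.append(tpl)
    for i, site in zip(np.flatnonzero(cls == 2), site_of_copy):
        p0 = int(positions[i]) - 1
        seq[p0 - 60 : p0 + 61] = templates[site]

    contig = "".join(seq)
    reference = {config.contig_name: contig}
    ctx_cfg = ContextConfig()

    # alleles; copies of an artifact site share their alt base (SNVs)
    is_indel = (rng.random(n) < config.indel_fraction) & (cls != 2)
    art_alt_choice = rng.integers(0, 3, n_sites)
    refs: list[str] = []
    alts: list[str] = []
    others = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
    art_iter = iter(site_of_copy)
    for i in range(n):
        p0 = int(positions[i]) - 1
        anchor = contig[p0]
        if cls[i] == 2:
            site = next(art_iter)
            refs.append(anchor)
            alts.append(others[anchor][art_alt_choice[site]])
            continue
        if not is_indel[i]:
            refs.append(anchor)
            alts.append(str(rng.choice(list(others.get(anchor, "ACGT")))))
            continue
        ilen = int(min(25, 1 + rng.geometric(0.35)))
        if rng.random() < 0.5:  # insertion
            refs.append(anchor)
            alts.append(anchor + "".join(_random_seq(rng, ilen, 0.5)))
        else:  # deletion
            refs.append(contig[p0 : p0 + ilen + 1])
            alts.append(anchor)

    # site features computed from the realized reference
    ctx_rows = [
        context_features(reference, config.contig_name, int(p), ctx_cfg).as_dict()
        for p in positions
    ]
    ctx_frame = pd.DataFrame(ctx_rows)

    parts = {name: calls[name].astype(float) for name in ("dp", "ad", "qual", "mq", "gq", "fs")}
    parts.update({c: ctx_frame[c].to_numpy() for c in ctx_frame.columns})
    features = _finalize_frame(parts)

    # write outputs
    fasta_path = out_dir / "reference.fa"
    fasta_path.write_text(_format_fasta(config.contig_name, contig))
    import pyfaidx

    pyfaidx.Faidx(str(fasta_path))  # writes reference.fa.fai

    vcf_path = out_dir / "calls.vcf"
    with open(vcf_path, "w") as fh:
        fh.write(
            _VCF_HEADER.format(
                contig=config.contig_name, length=length, sample=config.sample_id
            )
        )
        for i in range(n):
            dp = int(calls["dp"][i])
            ad = int(calls["ad"][i])
            gt = "1/1" if calls["genotype"][i] == "hom_alt" else "0/1"
            fh.write(
                f"{config.contig_name}\t{int(positions[i])}\t.\t{refs[i]}\t{alts[i]}\t"
                f"{float(calls['qual'][i]):.2f}\t.\t"
                f"MQ={float(calls['mq'][i]):.2f};FS={float(calls['fs'][i]):.3f}\t"
                f"GT:AD:DP:GQ\t{gt}:{max(dp - ad, 0)},{ad}:{dp}:{int(calls['gq'][i])}\n"
            )

    table = pd.DataFrame(
        {
            "chrom": config.contig_name,
            "pos": positions.astype(int),
            "ref": refs,
            "alt": alts,
        }
    )
    table = pd.concat([table, features.reset_index(drop=True)], axis=1)
    table["genotype"] = calls["genotype"]
    table["confirmed"] = confirmed
    features_path = out_dir / "features.tsv"
    table.to_csv(features_path, sep="\t", index=False, na_rep="NA")

    labels_path = out_dir / "labels.tsv"
    table[["chrom", "pos", "ref", "alt", "confirmed"]].to_csv(
        labels_path, sep="\t", index=False
    )

    truth_path = out_dir / "truth.json"
    truth = {
        "mode": "cohort_vcf",
        "params": {
            "n_calls": n,
            "unconfirmed_prevalence": config.unconfirmed_prevalence,
            "difficult_confirm_rate": config.difficult_confirm_rate,
            "artifact_site_copies": config.artifact_site_copies,
            "n_artifact_sites": n_sites,
            "difficult_rate": config.difficult_rate,
            "indel_fraction": config.indel_fraction,
            "seed": config.seed,
            "contig_length": length,
        },
        "difficult_site": (cls > 0).astype(int).tolist(),
        "artifact": (cls == 2).astype(int).tolist(),
    }
    truth_path.write_text(json.dumps(truth, sort_keys=True, indent=1) + "\n")

    return {
        "fasta": fasta_path,
        "vcf": vcf_path,
        "features": features_path,
        "labels": labels_path,
        "truth": truth_path,
    }
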