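"""Site-dependent sequence-context features around a variant position.

A variant call is anchored at the 1-based position of the first REF base of
the (left-aligned) VCF record. Around that anchor this module computes six
signals of local sequence difficulty from the reference FASTA:

* ``gc5`` / ``gc20`` / ``gc50`` — fraction of G/C in a window of 5, 20 and 50
  bases around the anchor. A window of *n* bases is read as *n* bases total,
  centered: ``n // 2`` bases left of the anchor, the anchor itself, and the
  remainder to the right (configurable to *n* per side).
* ``whr`` — weighted homopolymer rate: the sum of squared homopolymer run
  lengths divided by the number of runs, over a 20-base window around the
  anchor. Every maximal run counts, including runs of length 1, and runs are
  truncated at the window boundary.
* ``hpl_d`` / ``hpl_l`` — distance to, and length of, the longest
  homopolymer (run length >= 2) within 20 bases of the anchor.

Homopolymer-rich and GC-extreme contexts are exactly where capture-based NGS
produces unreliable calls, which is why these features carry much of the
signal in the downstream confidence model.

Coordinates: the public surface is 1-based (VCF convention); internal
arithmetic is 0-based half-open. Windows are clipped at contig ends and
fractions use the actual base counts. ``N`` bases are excluded from GC
numerator and denominator and break homopolymer runs; when more than
``max_n_fraction`` of a window is N the feature is undefined (``nan``), which
downstream routes the call to LOW confidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Mapping

from .errors import InputError

_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class ReferenceWindow:
    """A slice of reference sequence with a marked anchor base.

    Attributes
    ----------
    chrom : contig name.
    center : 1-based reference coordinate of the anchor (the variant's first
        REF base).
    sequence : uppercase A/C/G/T/N string of the window.
    offset : 0-based index of the anchor within ``sequence``.
    """

    chrom: str
    center: int
    sequence: str
    offset: int

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError("reference window must be non-empty")
        if not 0 <= self.offset < len(self.sequence):
            raise InputError(
                f"offset {self.offset} outside window of length {len(self.sequence)}"
            )
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise InputError(f"window contains non-ACGTN characters: {sorted(bad)!r}")


@dataclass(frozen=True)
class HomopolymerRun:
    """A maximal single-nucleotide run within a window (0-based start)."""

    base: str
    start: int
    length: int

    @property
    def end(self) -> int:
        """Exclusive end index."""
        return self.start + self.length


@dataclass(frozen=True)
class ContextFeatures:
    """The six site-dependent features; undefined values are ``nan``."""

    gc5: float
    gc20: float
    gc50: float
    whr: float
    hpl_d: float
    hpl_l: float

    def undefined(self) -> tuple[str, ...]:
        """Names of features in the undefined (fail-safe) state."""
        return tuple(f.name for f in fields(self) if math.isnan(getattr(self, f.name)))

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class ContextConfig:
    """Tunables for context extraction.

    ``window_mode`` selects how an *n*-base window is interpreted: ``"total"``
    (n bases overall, anchor included) or ``"per_side"`` (n each side, 2n+1
    overall). ``hpl_min_length`` is the minimum run length that counts as a
    homopolymer for HPL-D/HPL-L; runs of length 1 always count toward WHR.
    """

    flank: int = 50
    gc_windows: tuple[int, int, int] = (5, 20, 50)
    whr_window: int = 20
    hpl_radius: int = 20
    hpl_min_length: int = 2
    window_mode: str = "total"  # or "per_side"
    max_n_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.window_mode not in ("total", "per_side"):
            raise InputError(f"unknown window_mode {self.window_mode!r}")
        if self.hpl_radius <= 0:
            raise InputError("hpl_radius must be positive")


def _contig_len(reference: Mapping[str, object], chrom: str) -> int:
    try:
        contig = reference[chrom]
    except KeyError:
        raise InputError(f"unknown contig {chrom!r}") from None
    return len(contig)


def _fetch(reference: Mapping[str, object], chrom: str, start0: int, end0: int) -> str:
    seg = reference[chrom][start0:end0]
    seq = getattr(seg, "seq", seg)  # pyfaidx Sequence or plain str
    return str(seq).upper()


def extract_window(
    reference: Mapping[str, object], chrom: str, pos: int, flank: int
) -> ReferenceWindow:
    """Return the window [pos-flank, pos+flank] (1-based, inclusive), clipped.

    ``reference`` may be a ``pyfaidx.Fasta`` or any mapping from contig name
    to string-like sequence. Unknown contig or out-of-range ``pos`` raise
    :class:`InputError`.
    """
    if flank < 0:
        raise InputError("flank must be >= 0")
    length = _contig_len(reference, chrom)
    if not 1 <= pos <= length:
        raise InputError(f"position {pos} outside contig {chrom!r} (length {length})")
    start0 = max(0, pos - 1 - flank)
    end0 = min(length, pos + flank)
    return ReferenceWindow(
        chrom=chrom,
        center=pos,
        sequence=_fetch(reference, chrom, start0, end0),
        offset=pos - 1 - start0,
    )


def _centered_span(window: ReferenceWindow, n: int, mode: str) -> str:
    """Sub-sequence of ``n`` bases (mode 'total') or 2n+1 ('per_side')."""
    if mode == "per_side":
        start = window.offset - n
        stop = window.offset + n + 1
    else:
        start = window.offset - n // 2
        stop = start + n
    return window.sequence[max(0, start) : max(0, stop)]


def gc_fraction(
    window: ReferenceWindow,
    n: int,
    *,
    window_mode: str = "total",
    max_n_fraction: float = 0.5,
) -> float:
    """GC fraction of the n-base subwindow centered on the anchor.

    Returns ``nan`` when more than ``max_n_fraction`` of the subwindow is N
    (and always when no non-N base remains).
    """
    if n <= 0:
        raise InputError("gc window size must be positive")
    sub = _centered_span(window, n, window_mode)
    if not sub:
        return math.nan
    n_count = sub.count("N")
    usable = len(sub) - n_count
    if usable == 0 or n_count / len(sub) > max_n_fraction:
        return math.nan
    return (sub.count("G") + sub.count("C")) / usable


def homopolymer_runs(sequence: str) -> tuple[HomopolymerRun, ...]:
    """Run-length encode ``sequence`` into maximal single-base runs.

    Runs tile the sequence exactly and appear left to right. N bases form
    their own runs; callers exclude them from WHR/HPL statistics.
    """
    if not sequence:
        raise InputError("cannot compute homopolymer runs of an empty sequence")
    runs: list[HomopolymerRun] = []
    start = 0
    for i in range(1, len(sequence) + 1):
        if i == len(sequence) or sequence[i] != sequence[start]:
            runs.append(HomopolymerRun(sequence[start], start, i - start))
            start = i
    return tuple(runs)


def weighted_homopolymer_rate(runs: tuple[HomopolymerRun, ...]) -> float:
    """Sum of squared run lengths over the number of runs (N runs excluded).

    Every maximal run counts, including runs of length 1, so the minimum
    value is 1.0 (fully alternating sequence) and the maximum for a window of
    length L is L**2 (a single run). Returns ``nan`` when no non-N run exists.
    """
    usable = [r for r in runs if r.base != "N"]
    if not usable:
        return math.nan
    return sum(r.length**2 for r in usable) / len(usable)


def longest_homopolymer(
    runs: tuple[HomopolymerRun, ...],
    offset: int,
    radius: int = 20,
    min_length: int = 2,
) -> tuple[float, float]:
    """(distance, length) of the longest homopolymer within ``radius`` bases.

    Candidate runs are non-N runs of length >= ``min_length`` whose span
    intersects [offset - radius, offset + radius]. The longest wins; ties go
    to the run nearest the anchor, then to the leftmost. Distance is 0 when
    the anchor lies inside the run, else the gap in bases from the anchor to
    the run's nearest edge. Returns ``(nan, nan)`` when no run qualifies.
    """
    if radius <= 0:
        raise InputError("radius must be positive")
    lo, hi = offset - radius, offset + radius
    best: tuple[int, int, int] | None = None  # (-length, distance, start)
    for run in runs:
        if run.base == "N" or run.length < min_length:
            continue
        last = run.end - 1
        if last < lo or run.start > hi:
            continue
        if run.start <= offset <= last:
            dist = 0
        elif run.start > offset:
            dist = run.start - offset
        else:
            dist = offset - last
        key = (-run.length, dist, run.start)
        if best is None or key < best:
            best = key
    if best is None:
        return math.nan, math.nan
    return float(best[1]), float(-best[0])


def _n_heavy(sub: str, max_n_fraction: float) -> bool:
    return not sub or sub.count("N") / len(sub) > max_n_fraction


def context_features(
    reference: Mapping[str, object],
    chrom: str,
    pos: int,
    config: ContextConfig = ContextConfig(),
) -> ContextFeatures:
    """All six site-dependent features from one window (``flank`` per side)."""
    window = extract_window(reference, chrom, pos, config.flank)

    gc = [
        gc_fraction(
            window,
            n,
            window_mode=config.window_mode,
            max_n_fraction=config.max_n_fraction,
        )
        for n in config.gc_windows
    ]

    whr_sub = _centered_span(window, config.whr_window, config.window_mode)
    if _n_heavy(whr_sub, config.max_n_fraction):
        whr = math.nan
    else:
        whr = weighted_homopolymer_rate(homopolymer_runs(whr_sub))

    hpl_d, hpl_l = longest_homopolymer(
        homopolymer_runs(window.sequence),
        window.offset,
        radius=config.hpl_radius,
        min_length=config.hpl_min_length,
    )

    return ContextFeatures(gc[0], gc[1], gc[2], whr, hpl_d, hpl_l)
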