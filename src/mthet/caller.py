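"""Heteroplasmy calling on quality-filtered pileup columns.

Three criteria decide a call at a position, applied to the filtered read
set (see :mod:`mthet.pileup`):

1. **depth** — at least ``min_depth`` reads (default 20) survive filtering;
2. **minor fraction** — the second-most-frequent allele accounts for at
   least ``min_minor_fraction`` (default 15 %) of the filtered depth;
3. **strand** — the minor allele is seen on at least
   ``min_minor_per_strand`` reads (default 2) on *each* strand.

The strand rule is the specificity workhorse: location-specific sequencing
errors are overwhelmingly strand-asymmetric, and requiring independent
support on both strands rejects them without any error-model fitting.

Fraction comparisons use exact rational arithmetic
(``minor * denom >= numer * depth``) so that boundary columns such as
15/100 are decided exactly, never by floating-point rounding.

Positions never yield more than two alleles here by construction: reads
carrying any base other than major and minor are tallied as
``third_count`` but a third allele is never promoted to a call.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np

from .io_formats import AlignedRead, CallTable, MtReference
from .pileup import (
    BASES,
    FilteredColumn,
    FilterParams,
    column_from_counts,
    genome_strand_counts,
)

CRIT_DEPTH = "depth"
CRIT_FRACTION = "minor_fraction"
CRIT_STRAND = "strand"


@dataclass(frozen=True)
class CallParams:
    """Thresholds for the three calling criteria."""

    min_depth: int = 20
    min_minor_fraction: float = 0.15
    min_minor_per_strand: int = 2

    def __post_init__(self):
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0 < self.min_minor_fraction <= 0.5:
            raise ValueError("min_minor_fraction must be in (0, 0.5]")
        if self.min_minor_per_strand < 0:
            raise ValueError("min_minor_per_strand must be >= 0")

    @property
    def fraction_exact(self) -> Fraction:
        # Fraction(str(x)) keeps decimal thresholds like 0.15 exact.
        return Fraction(str(self.min_minor_fraction))


@dataclass
class HeteroplasmyCall:
    """A called heteroplasmic position."""

    position: int
    ref_allele: str
    major_allele: str
    minor_allele: str
    depth: int
    minor_fwd: int
    minor_rev: int
    major_fwd: int
    major_rev: int
    third_count: int  # reads carrying any base other than major/minor
    minor_tie: bool = False  # two second-place alleles had equal counts

    @property
    def minor_count(self) -> int:
        return self.minor_fwd + self.minor_rev

    @property
    def major_count(self) -> int:
        return self.major_fwd + self.major_rev

    @property
    def minor_fraction(self) -> float:
        return self.minor_count / self.depth


@dataclass
class NoCall:
    """Machine-readable explanation of why a position was not called."""

    position: int
    depth: int
    failed: List[str]  # subset of {CRIT_DEPTH, CRIT_FRACTION, CRIT_STRAND}
    minor_allele: Optional[str] = None
    minor_fraction: float = 0.0
    minor_fwd: int = 0
    minor_rev: int = 0

    def __bool__(self) -> bool:  # a NoCall is falsy; a call is truthy
        return False


def _rank_alleles(fcol: FilteredColumn, ref_base: Optional[str]) -> List[str]:
    """Alleles present, ordered by count descending; ties broken by
    preferring the reference allele, then alphabetically."""

    def sort_key(b: str):
        pref = 0 if (ref_base is not None and b == ref_base) else 1
        return (-fcol.count(b), pref, b)

    return sorted((b for b in BASES if fcol.count(b) > 0), key=sort_key)


def call_position(
    fcol: FilteredColumn,
    params: CallParams = CallParams(),
    ref_base: Optional[str] = None,
) -> Union[HeteroplasmyCall, NoCall]:
    """Apply the three calling criteria to one filtered column.

    Returns a :class:`HeteroplasmyCall`, or a :class:`NoCall` carrying the
    list of failed criteria. When two alleles tie for second place, the one
    passing the strand criterion is evaluated; if both pass, the
    alphabetically smaller is taken and the tie recorded on the call.
    """
    depth = fcol.depth
    failed: List[str] = []
    if depth < params.min_depth:
        failed.append(CRIT_DEPTH)

    ranked = _rank_alleles(fcol, ref_base)
    if len(ranked) < 2:
        # No minor allele exists: fraction criterion cannot be met.
        return NoCall(
            position=fcol.position,
            depth=depth,
            failed=failed + [CRIT_FRACTION],
        )
    major = ranked[0]
    second_count = fcol.count(ranked[1])

    def passes_strand(b: str) -> bool:
        f, r = fcol.counts.get(b, (0, 0))
        return f >= params.min_minor_per_strand and r >= params.min_minor_per_strand

    candidates = [b for b in ranked[1:] if fcol.count(b) == second_count]
    tie = len(candidates) > 1
    passing = [b for b in candidates if passes_strand(b)]
    minor = min(passing) if passing else min(candidates)

    frac_ok = Fraction(second_count, depth) >= params.fraction_exact if depth else False
    if not frac_ok:
        failed.append(CRIT_FRACTION)
    if not passes_strand(minor):
        failed.append(CRIT_STRAND)

    mf, mr = fcol.counts.get(minor, (0, 0))
    if failed:
        return NoCall(
            position=fcol.position,
            depth=depth,
            failed=failed,
            minor_allele=minor,
            minor_fraction=second_count / depth if depth else 0.0,
            minor_fwd=mf,
            minor_rev=mr,
        )
    Mf, Mr = fcol.counts.get(major, (0, 0))
    return HeteroplasmyCall(
        position=fcol.position,
        ref_allele=ref_base if ref_base is not None else "N",
        major_allele=major,
        minor_allele=minor,
        depth=depth,
        minor_fwd=mf,
        minor_rev=mr,
        major_fwd=Mf,
        major_rev=Mr,
        third_count=depth - fcol.count(major) - second_count,
        minor_tie=tie,
    )


def explain_no_call(
    fcol: FilteredColumn,
    params: CallParams = CallParams(),
    ref_base: Optional[str] = None,
) -> NoCall:
    """Failure report for a column: depth, best minor fraction, strand
    counts, and the criteria that failed. For a column that would be
    called, returns a NoCall with an empty ``failed`` list."""
    result = call_position(fcol, params, ref_base)
    if isinstance(result, NoCall):
        return result
    return NoCall(
        position=result.position,
        depth=result.depth,
        failed=[],
        minor_allele=result.minor_allele,
        minor_fraction=result.minor_fraction,
        minor_fwd=result.minor_fwd,
        minor_rev=result.minor_rev,
    )


@dataclass
class ScanResult:
    """Calls plus per-position bookkeeping from a genome scan."""

    calls: List[HeteroplasmyCall]
    filtered_depth: np.ndarray  # post-filter depth at every position
    strand_counts: np.ndarray  # (ref_length, 4, 2) filtered allele counts

    def no_calls(self, params: CallParams = CallParams(), ref: Optional[MtReference] = None):
        """Failure reports for every uncalled position (lazy)."""
        called = {c.position for c in self.calls}
        for pos in range(1, self.strand_counts.shape[0] + 1):
            if pos in called:
                continue
            fcol = column_from_counts(pos, self.strand_counts[pos - 1])
            yield explain_no_call(fcol, params, ref.base(pos) if ref else None)


def scan_genome(
    reads: Iterable[AlignedRead],
    ref: MtReference,
    fparams: FilterParams = FilterParams(),
    cparams: CallParams = CallParams(),
    individual: str = "NA",
    species: str = "NA",
) -> CallTable:
    """Scan every reference position and emit the heteroplasmy call table.

    One vectorised pileup pass over positions 1..len(ref); the decision at
    each position is exactly :func:`call_position` on the filtered column.
    An empty read set yields an empty table.
    """
    result = scan_genome_detailed(reads, ref, fparams, cparams)
    table = CallTable.from_calls(result.calls, individual=individual, species=species)
    return table


def scan_genome_detailed(
    reads: Iterable[AlignedRead],
    ref: MtReference,
    fparams: FilterParams = FilterParams(),
    cparams: CallParams = CallParams(),
) -> ScanResult:
    """Like :func:`scan_genome` but returning per-position bookkeeping."""
    reads = list(reads)
    counts, depth = genome_strand_counts(reads, len(ref), fparams)
    calls: List[HeteroplasmyCall] = []
    # Only positions that can possibly pass are evaluated in Python.
    candidates = np.nonzero(depth >= cparams.min_depth)[0]
    for p0 in candidates:
        fcol = column_from_counts(int(p0) + 1, counts[p0])
        res = call_position(fcol, cparams, ref_base=ref.base(int(p0) + 1))
        if isinstance(res, HeteroplasmyCall):
            calls.append(res)
    return ScanResult(calls=calls, filtered_depth=depth, strand_counts=counts)
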