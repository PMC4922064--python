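"""Per-position pileup construction and read-level quality filtering.

For every mtDNA position the engine collects the read bases covering it and
applies two filters before any allele counting:

1. the base itself must have Phred quality >= ``min_base_quality``
   (default 23; reads with a lower score at the position are discarded);
2. every read base within ``neighbor_window`` positions on either side
   (default 5, in read coordinates) must have Phred quality
   >= ``min_neighbor_quality`` (default 15).

The neighbourhood rule rejects bases sitting in locally noisy stretches of a
read, the typical signature of a sequencing artifact. At read ends only the
neighbours that exist are evaluated — a missing neighbour is not a
low-quality neighbour. 'N' bases are dropped at this stage, never earlier.

Two code paths produce identical results: :func:`build_column` /
:func:`filter_column` work position-by-position on explicit entry lists
(the reference semantics), while :func:`genome_strand_counts` computes
filtered per-allele, per-strand counts for every position in one vectorised
pass and is what the genome scanner uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .io_formats import FORWARD, REVERSE, AlignedRead

BASES = "ACGT"
_BASE_CODE = np.full(256, 4, dtype=np.int8)  # everything not ACGT counts as N
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

_QPAD = np.int16(999)  # sentinel quality for absent neighbours; never filters


@dataclass(frozen=True)
class FilterParams:
    """Thresholds for the two read-level quality filters."""

    min_base_quality: int = 23
    neighbor_window: int = 5
    min_neighbor_quality: int = 15

    def __post_init__(self):
        if min(self.min_base_quality, self.neighbor_window, self.min_neighbor_quality) < 0:
            raise ValueError("filter parameters must be non-negative")


@dataclass(frozen=True)
class PileupEntry:
    """One read base over one reference position."""

    read_id: str
    strand: str
    base: str
    base_quality: int
    left_qualities: Tuple[int, ...]  # up to `window` read bases left, nearest last
    right_qualities: Tuple[int, ...]  # up to `window` read bases right, nearest first

    @property
    def neighbor_qualities(self) -> Tuple[int, ...]:
        return self.left_qualities + self.right_qualities


@dataclass
class PileupColumn:
    """All read bases covering one reference position, pre-filter."""

    position: int  # 1-based
    entries: List[PileupEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class FilteredColumn:
    """Surviving entries and per-strand allele counts after quality filtering.

    ``counts`` maps base -> (forward count, reverse count). ``entries`` is
    ``None`` when the column was produced by the vectorised genome pass,
    which tabulates counts without materialising entry objects.
    """

    position: int
    counts: Dict[str, Tuple[int, int]]
    depth: int
    entries: Optional[List[PileupEntry]] = None

    def count(self, base: str) -> int:
        f, r = self.counts.get(base, (0, 0))
        return f + r


def build_column(
    reads: Iterable[AlignedRead],
    position: int,
    neighbor_window: int = 5,
    ref_length: Optional[int] = None,
) -> PileupColumn:
    """Collect the read bases aligned over a 1-based reference position.

    Reads with a deletion at the position contribute no entry; insertions
    never create entries (they have no reference coordinate). Neighbour
    qualities are taken from the read's own quality string, truncated at
    read ends.
    """
    if position < 1 or (ref_length is not None and position > ref_length):
        raise IndexError(f"position {position} outside reference")
    col = PileupColumn(position=position)
    for read in reads:
        if not (read.start <= position <= read.end):
            continue
        qpos = None
        for q, r in read.aligned_pairs:
            if r == position:
                qpos = q
                break
        if qpos is None:  # deletion in this read at the position
            continue
        quals = read.base_qualities
        left = tuple(int(x) for x in quals[max(0, qpos - neighbor_window):qpos])
        right = tuple(int(x) for x in quals[qpos + 1:qpos + 1 + neighbor_window])
        col.entries.append(
            PileupEntry(
                read_id=read.read_id,
                strand=read.strand,
                base=read.sequence[qpos].upper(),
                base_quality=int(quals[qpos]),
                left_qualities=left,
                right_qualities=right,
            )
        )
    return col


def entry_passes(entry: PileupEntry, params: FilterParams) -> bool:
    """Apply both quality criteria to a single entry."""
    if entry.base not in BASES:
        return False
    if entry.base_quality < params.min_base_quality:
        return False
    for q in entry.neighbor_qualities:
        if q < params.min_neighbor_quality:
            return False
    return True


def filter_column(col: PileupColumn, params: FilterParams = FilterParams()) -> FilteredColumn:
    """Apply the two filters; tabulate surviving alleles split by strand."""
    survivors = [e for e in col.entries if entry_passes(e, params)]
    counts: Dict[str, List[int]] = {}
    for e in survivors:
        fr = counts.setdefault(e.base, [0, 0])
        fr[0 if e.strand == FORWARD else 1] += 1
    return FilteredColumn(
        position=col.position,
        counts={b: (f, r) for b, (f, r) in counts.items()},
        depth=len(survivors),
        entries=survivors,
    )


# --- vectorised whole-genome pass -------------------------------------------


def _flatten_reads(reads: Sequence[AlignedRead], window: int):
    """Concatenate read qualities with sentinel padding and precompute, for
    every sequenced base, the minimum quality among its in-read neighbours."""
    lengths = [len(r.sequence) for r in reads]
    total = sum(lengths) + window * (len(reads) + 1)
    bigq = np.full(total, _QPAD, dtype=np.int16)
    offsets = np.empty(len(reads), dtype=np.int64)
    off = window
    for i, r in enumerate(reads):
        offsets[i] = off
        bigq[off:off + lengths[i]] = r.base_qualities
        off += lengths[i] + window
    if window > 0:
        shifted = [np.roll(bigq, s) for s in range(1, window + 1)]
        shifted += [np.roll(bigq, -s) for s in range(1, window + 1)]
        minnbr = np.minimum.reduce(shifted)
    else:
        minnbr = np.full_like(bigq, _QPAD)
    return bigq, minnbr, offsets


def genome_strand_counts(
    reads: Sequence[AlignedRead],
    ref_length: int,
    params: FilterParams = FilterParams(),
) -> Tuple[np.ndarray, np.ndarray]:
    """Filtered per-strand allele counts for every reference position.

    Returns ``(counts, depth)`` where ``counts`` has shape
    ``(ref_length, 4, 2)`` indexed by (0-based position, base A/C/G/T,
    strand fwd/rev) and ``depth = counts.sum(axis=(1, 2))``. Equivalent to
    running :func:`build_column` + :func:`filter_column` at every position.
    """
    if ref_length <= 0:
        raise ValueError("ref_length must be positive")
    reads = list(reads)
    counts = np.zeros((ref_length, 4, 2), dtype=np.int64)
    if not reads:
        return counts, counts.sum(axis=(1, 2))
    bigq, minnbr, offsets = _flatten_reads(reads, params.neighbor_window)

    pos_parts, base_parts, qual_parts, nbr_parts, strand_parts = [], [], [], [], []
    for i, r in enumerate(reads):
        pairs = np.asarray(r.aligned_pairs, dtype=np.int64)
        if pairs.size == 0:
            continue
        qpos, rpos = pairs[:, 0], pairs[:, 1]
        codes = _BASE_CODE[np.frombuffer(r.sequence.encode("ascii"), dtype=np.uint8)]
        idx = offsets[i] + qpos
        pos_parts.append(rpos)
        base_parts.append(codes[qpos])
        qual_parts.append(bigq[idx])
        nbr_parts.append(minnbr[idx])
        strand_parts.append(
            np.full(len(qpos), 1 if r.strand == REVERSE else 0, dtype=np.int8)
        )
    if not pos_parts:
        return counts, counts.sum(axis=(1, 2))
    pos = np.concatenate(pos_parts)
    base = np.concatenate(base_parts)
    qual = np.concatenate(qual_parts)
    nbr = np.concatenate(nbr_parts)
    strand = np.concatenate(strand_parts)

    keep = (
        (base < 4)
        & (qual >= params.min_base_quality)
        & (nbr >= params.min_neighbor_quality)
        & (pos >= 1)
        & (pos <= ref_length)
    )
    key = (pos[keep] - 1) * 8 + base[keep].astype(np.int64) * 2 + strand[keep]
    flat = np.bincount(key, minlength=ref_length * 8)
    counts[:] = flat.reshape(ref_length, 4, 2)
    return counts, counts.sum(axis=(1, 2))


def column_from_counts(position: int, strand_counts: np.ndarray) -> FilteredColumn:
    """Build a :class:`FilteredColumn` from one row of the vectorised counts."""
    counts = {}
    for b_idx, b in enumerate(BASES):
        f, r = int(strand_counts[b_idx, 0]), int(strand_counts[b_idx, 1])
        if f or r:
            counts[b] = (f, r)
    depth = int(strand_counts.sum())
    return FilteredColumn(position=position, counts=counts, depth=depth, entries=None)
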