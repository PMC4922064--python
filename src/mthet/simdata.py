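"""Synthetic single-end mtDNA alignments with known ground truth.

The generator emulates the mtDNA fraction of a ChIP-seq experiment after
alignment: uniformly placed fixed-length single-end reads on a linear
~16.5 kb reference at 20-100x depth, Gaussian Phred quality profiles, PCR
duplicates, true heteroplasmies planted at configured minor-allele
fractions with configurable strand balance, independent per-base
sequencing errors, location-specific one-strand error sites, and
cross-species contaminant reads drawn from a diverged reference.

Planting is generative: each read covering a heteroplasmic position carries
the minor allele with the configured probability (Bernoulli per read), so
realised minor counts are binomial around the target fraction — the same
sampling noise a sequencer would produce. Errors are injected after
variant planting. All randomness flows from the mandatory seed; identical
configurations give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .caller import CallParams
from .io_formats import FORWARD, REVERSE, AlignedRead, MtReference

_BASES = "ACGTN"
_CODE = {b: i for i, b in enumerate(_BASES)}


@dataclass
class PlantedVariant:
    """A true heteroplasmy to plant.

    ``strand_balance`` is the expected share of minor-allele reads on the
    forward strand (0.5 = balanced). With equal strand sampling the
    per-read minor probability is ``2*f*b`` on forward and ``2*f*(1-b)``
    on reverse reads, which preserves the overall fraction ``f``.
    """

    position: int
    minor_allele: str
    minor_fraction: float
    strand_balance: float = 0.5


@dataclass
class StrandErrorSite:
    """A location-specific error afflicting only one strand."""

    position: int
    strand: str  # FORWARD or REVERSE
    rate: float  # per covering read of that strand
    base: str


@dataclass
class SimConfig:
    """Generator configuration; ``seed`` is mandatory for reproducibility."""

    seed: int
    ref_length: int = 16500
    read_length: int = 50
    mean_depth: float = 60.0
    variants: List[PlantedVariant] = field(default_factory=list)
    error_rate: float = 0.001
    strand_error_sites: List[StrandErrorSite] = field(default_factory=list)
    duplicate_rate: float = 0.0
    bq_mean: float = 35.0
    bq_sd: float = 3.0
    bq_floor: int = 10
    mapq: int = 60

    def __post_init__(self):
        for v in self.variants:
            if not 0 <= v.minor_fraction <= 1 or not 0 <= v.strand_balance <= 1:
                raise ValueError(f"variant at {v.position}: fractions must be in [0,1]")
            if not 1 <= v.position <= self.ref_length:
                raise ValueError(f"variant position {v.position} outside reference")
        if not 0 <= self.duplicate_rate <= 1 or not 0 <= self.error_rate <= 1:
            raise ValueError("rates must be in [0,1]")
        if self.read_length > self.ref_length:
            raise ValueError("read_length exceeds reference length")


@dataclass
class TruthEntry:
    variant: PlantedVariant
    expected_depth: float
    expected_callable: bool
    reason: str  # 'callable' or the first failing criterion
    warning: Optional[str] = None


@dataclass
class TruthSet:
    """Planted variants with their expected call/no-call labels."""

    entries: List[TruthEntry]
    warnings: List[str] = field(default_factory=list)

    def expected_positions(self) -> List[int]:
        return [e.variant.position for e in self.entries if e.expected_callable]


def random_reference(
    length: int = 16500, seed: int = 0, name: str = "chrM"
) -> MtReference:
    """Uniform-composition random mtDNA-sized reference."""
    rng = np.random.default_rng(seed)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
    return MtReference(name=name, sequence=seq, circular=True)


def diverged_reference(
    ref: MtReference, divergence: float = 0.10, seed: int = 1, name: Optional[str] = None
) -> MtReference:
    """Substitute a fraction of positions to emulate a related species."""
    rng = np.random.default_rng(seed)
    codes = np.frombuffer(ref.sequence.encode("ascii"), dtype=np.uint8)
    code4 = np.full(256, 4, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        code4[ord(b)] = i
    c = code4[codes]
    mask = (rng.random(len(c)) < divergence) & (c < 4)
    shift = rng.integers(1, 4, mask.sum())
    c[mask] = (c[mask] + shift) % 4
    seq = "".join(_BASES[i] for i in c)
    return MtReference(name=name or f"{ref.name}_diverged", sequence=seq, circular=ref.circular)


def expected_depth(cfg: SimConfig, position: int) -> float:
    """Expected read depth at a position under uniform linear placement
    (lower near the reference ends where fewer start sites cover it)."""
    n_reads = int(round(cfg.ref_length * cfg.mean_depth / cfg.read_length))
    n_starts = cfg.ref_length - cfg.read_length + 1
    lo = max(1, position - cfg.read_length + 1)
    hi = min(position, n_starts)
    covering = max(0, hi - lo + 1)
    return n_reads * covering / n_starts


def label_truth(cfg: SimConfig, cparams: CallParams = CallParams()) -> TruthSet:
    """Expected call/no-call label per planted variant from expectations.

    A variant is expected callable when its expected depth, fraction and
    expected per-strand minor counts clear the calling thresholds.
    Configurations whose expectations sit so low that the strand rule can
    never be satisfied are flagged with a warning rather than rejected.
    """
    entries = []
    warnings = []
    for v in cfg.variants:
        d = expected_depth(cfg, v.position)
        exp_minor = v.minor_fraction * d
        exp_fwd = exp_minor * v.strand_balance
        exp_rev = exp_minor * (1 - v.strand_balance)
        if d < cparams.min_depth:
            label, reason = False, "depth"
        elif Fraction(str(v.minor_fraction)) < cparams.fraction_exact:
            label, reason = False, "minor_fraction"
        elif min(exp_fwd, exp_rev) < cparams.min_minor_per_strand:
            label, reason = False, "strand"
        else:
            label, reason = True, "callable"
        warning = None
        if v.minor_fraction > 0 and exp_minor < 2 * cparams.min_minor_per_strand:
            warning = (
                f"variant at {v.position}: expected minor count {exp_minor:.1f} "
                f"too low to ever satisfy the strand rule"
            )
            warnings.append(warning)
        entries.append(
            TruthEntry(
                variant=v,
                expected_depth=d,
                expected_callable=label,
                reason=reason,
                warning=warning,
            )
        )
    return TruthSet(entries=entries, warnings=warnings)


def simulate_reads(
    ref: MtReference, cfg: SimConfig, cparams: CallParams = CallParams()
) -> Tuple[List[AlignedRead], TruthSet]:
    """Generate aligned reads with planted truth.

    Reads are emitted pre-aligned (coordinate-sorted, ungapped, MAPQ from
    the config) because the detection method consumes alignments.
    """
    if len(ref) != cfg.ref_length:
        raise ValueError(
            f"config ref_length {cfg.ref_length} != reference length {len(ref)}"
        )
    rng = np.random.default_rng(cfg.seed)
    L, rl = cfg.ref_length, cfg.read_length
    n = int(round(L * cfg.mean_depth / rl))
    code = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        code[ord(b)] = i
    refc = code[np.frombuffer(ref.sequence.encode("ascii"), dtype=np.uint8)]

    starts = rng.integers(1, L - rl + 2, n)
    reverse = rng.random(n) < 0.5
    idx = starts[:, None] + np.arange(rl)[None, :] - 1
    seqs = refc[idx].copy()  # (n, rl) base codes

    # Plant heteroplasmies (before error injection).
    for v in cfg.variants:
        covers = (starts <= v.position) & (v.position <= starts + rl - 1)
        p = np.where(
            reverse,
            2 * v.minor_fraction * (1 - v.strand_balance),
            2 * v.minor_fraction * v.strand_balance,
        ).clip(0, 1)
        hit = covers & (rng.random(n) < p)
        seqs[hit, v.position - starts[hit]] = _CODE[v.minor_allele]

    # Independent per-base sequencing errors (uniform among the other 3 bases).
    if cfg.error_rate > 0:
        err = (rng.random((n, rl)) < cfg.error_rate) & (seqs < 4)
        shift = rng.integers(1, 4, err.sum())
        seqs[err] = (seqs[err] + shift) % 4

    # Location-specific one-strand error sites.
    for site in cfg.strand_error_sites:
        on_strand = reverse if site.strand == REVERSE else ~reverse
        covers = (starts <= site.position) & (site.position <= starts + rl - 1)
        hit = on_strand & covers & (rng.random(n) < site.rate)
        seqs[hit, site.position - starts[hit]] = _CODE[site.base]

    quals = np.clip(
        np.rint(rng.normal(cfg.bq_mean, cfg.bq_sd, (n, rl))), cfg.bq_floor, 41
    ).astype(np.int16)

    dup = rng.random(n) < cfg.duplicate_rate
    dup_quals = np.clip(
        np.rint(rng.normal(cfg.bq_mean, cfg.bq_sd, (int(dup.sum()), rl))),
        cfg.bq_floor,
        41,
    ).astype(np.int16)

    reads: List[AlignedRead] = []
    lut = np.frombuffer(_BASES.encode("ascii"), dtype=np.uint8)
    d_i = 0
    for i in range(n):
        seq = lut[seqs[i]].tobytes().decode("ascii")
        strand = REVERSE if reverse[i] else FORWARD
        reads.append(
            AlignedRead(
                read_id=f"r{i:06d}",
                contig=ref.name,
                start=int(starts[i]),
                strand=strand,
                sequence=seq,
                base_qualities=quals[i],
                mapq=cfg.mapq,
            )
        )
        if dup[i]:
            # PCR duplicate: same molecule coordinates and bases, fresh
            # quality draw (an independent sequencing of the same fragment).
            reads.append(
                AlignedRead(
                    read_id=f"r{i:06d}.dup",
                    contig=ref.name,
                    start=int(starts[i]),
                    strand=strand,
                    sequence=seq,
                    base_qualities=dup_quals[d_i],
                    mapq=cfg.mapq,
                )
            )
            d_i += 1
    reads.sort(key=lambda r: (r.start, r.read_id))
    truth = label_truth(cfg, cparams)
    for e in truth.entries:
        # A plant identical to the reference base is a degenerate config:
        # the column stays unanimous and nothing is detectable there.
        if ref.base(e.variant.position) == e.variant.minor_allele:
            e.expected_callable = False
            e.reason = "minor_equals_reference"
            e.warning = (
                f"variant at {e.variant.position}: minor allele equals the "
                f"reference base; nothing to detect"
            )
            truth.warnings.append(e.warning)
    return reads, truth


def simulate_contaminant_reads(
    contaminant_ref: MtReference,
    n_reads: int,
    primary_contig: str,
    read_length: int = 50,
    mapq: int = 10,
    high_mapq_fraction: float = 0.0,
    high_mapq: int = 60,
    bq_mean: float = 35.0,
    bq_sd: float = 3.0,
    bq_floor: int = 10,
    seed: int = 0,
) -> List[AlignedRead]:
    """Reads from a diverged genome as they would appear after cross-species
    mapping onto the primary contig: coordinates on the primary reference,
    sequence from the contaminant, MAPQ low by default (an aligner places
    diverged reads with little confidence), optionally a sub-fraction
    mapped confidently to stress the caller."""
    rng = np.random.default_rng(seed)
    L = len(contaminant_ref)
    starts = rng.integers(1, L - read_length + 2, n_reads)
    reverse = rng.random(n_reads) < 0.5
    quals = np.clip(
        np.rint(rng.normal(bq_mean, bq_sd, (n_reads, read_length))), bq_floor, 41
    ).astype(np.int16)
    high = rng.random(n_reads) < high_mapq_fraction
    reads = []
    for i in range(n_reads):
        s = int(starts[i])
        reads.append(
            AlignedRead(
                read_id=f"c{i:06d}",
                contig=primary_contig,
                start=s,
                strand=REVERSE if reverse[i] else FORWARD,
                sequence=contaminant_ref.sequence[s - 1:s - 1 + read_length],
                base_qualities=quals[i],
                mapq=high_mapq if high[i] else mapq,
            )
        )
    return reads


def mix_contamination(
    primary: Sequence[AlignedRead],
    contaminant_ref: MtReference,
    fraction: float,
    seed: int,
    mapq: int = 10,
    high_mapq_fraction: float = 0.0,
    high_mapq: int = 60,
) -> List[AlignedRead]:
    """Add ``round(fraction * len(primary))`` contaminant reads to a sample.

    The count is exact by construction. Contaminant reads are drawn from
    ``contaminant_ref`` (e.g. :func:`diverged_reference`); their MAPQ
    defaults below the MAPQ-20 extraction threshold, mirroring how
    cross-species reads map.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0,1]")
    primary = list(primary)
    n_contam = int(round(fraction * len(primary)))
    if n_contam == 0:
        return sorted(primary, key=lambda r: (r.start, r.read_id))
    read_length = len(primary[0].sequence) if primary else 50
    contam = simulate_contaminant_reads(
        contaminant_ref,
        n_contam,
        primary_contig=primary[0].contig if primary else contaminant_ref.name,
        read_length=read_length,
        mapq=mapq,
        high_mapq_fraction=high_mapq_fraction,
        high_mapq=high_mapq,
        seed=seed,
    )
    out = primary + contam
    out.sort(key=lambda r: (r.start, r.read_id))
    return out
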