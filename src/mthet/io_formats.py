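"""Readers and writers for the standard formats the pipeline touches.

All positions exposed by this package are 1-based inclusive, following the
convention of the human mtDNA annotation databases (MITOMAP, rCRS numbering).
Internally, read offsets within a query sequence are 0-based.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import AlignIO, SeqIO

FORWARD = "forward"
REVERSE = "reverse"

#: Closed set of genomic context classes.
FEATURE_CLASSES = ("protein_coding", "rRNA", "tRNA", "D_loop", "other_intergenic")

#: Columns of the tab-separated call table, in order.
CALL_COLUMNS = [
    "individual",
    "species",
    "position",
    "ref",
    "major",
    "minor",
    "depth",
    "minor_fraction",
    "minor_fwd",
    "minor_rev",
    "context",
]


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass
class AlignedRead:
    """One single-end read mapped to the mitochondrial contig.

    ``aligned_pairs`` holds ``(query_offset, reference_position)`` tuples for
    aligned (match/mismatch) bases only: insertions in the read are excluded
    and deletions yield no pair, so reference positions are strictly
    increasing. ``query_offset`` is 0-based within ``sequence``;
    ``reference_position`` is 1-based.
    """

    read_id: str
    contig: str
    start: int  # 1-based leftmost aligned reference position
    strand: str  # FORWARD or REVERSE
    sequence: str
    base_qualities: np.ndarray  # Phred scores, one per sequenced base
    mapq: int
    aligned_pairs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.base_qualities = np.asarray(self.base_qualities, dtype=np.int16)
        if len(self.sequence) != len(self.base_qualities):
            raise FormatError(
                f"read {self.read_id}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.base_qualities)}"
            )
        if self.mapq < 0:
            raise FormatError(f"read {self.read_id}: negative MAPQ")
        if not self.aligned_pairs:
            # Ungapped default: read aligned end-to-end from `start`.
            self.aligned_pairs = [
                (i, self.start + i) for i in range(len(self.sequence))
            ]

    @property
    def end(self) -> int:
        """Rightmost aligned reference position (1-based inclusive)."""
        return self.aligned_pairs[-1][1]

    @property
    def is_reverse(self) -> bool:
        return self.strand == REVERSE


@dataclass
class MtReference:
    """A mitochondrial reference sequence.

    mtDNA is circular in vivo; ``circular`` records that fact but the
    pipeline consumes alignments to the linearised sequence (reads spanning
    the origin junction are outside scope).
    """

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise FormatError("empty reference sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise FormatError(f"reference contains non-ACGTN characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Reference base at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(f"position {position} outside reference (1..{len(self)})")
        return self.sequence[position - 1]


@dataclass
class MtFeature:
    """One annotated feature on the mitochondrial genome."""

    name: str
    feature_class: str  # one of FEATURE_CLASSES
    start: int  # 1-based inclusive
    end: int
    strand: str = FORWARD
    frame: Optional[int] = None  # phase for protein_coding features

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise FormatError(f"unknown feature class {self.feature_class!r}")
        if not 1 <= self.start <= self.end:
            raise FormatError(f"feature {self.name}: bad interval {self.start}-{self.end}")
        if self.feature_class == "protein_coding" and self.frame is None:
            self.frame = 0

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class MtAnnotation:
    """Feature list covering a mitochondrial reference."""

    features: list

    def overlapping(self, position: int) -> list:
        return [f for f in self.features if f.contains(position)]


def read_reference(path: str, name: Optional[str] = None, circular: bool = True) -> MtReference:
    """Read a mitochondrial reference from a FASTA file.

    With ``name`` given, that record is selected; otherwise the file must
    contain a single record.
    """
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    if name is None:
        if len(records) > 1:
            raise FormatError(f"{path} has {len(records)} records; pass a name")
        rec = records[0]
    else:
        matches = [r for r in records if r.id == name]
        if not matches:
            raise FormatError(f"record {name!r} not found in {path}")
        rec = matches[0]
    return MtReference(name=rec.id, sequence=str(rec.seq), circular=circular)


def read_alignments(path: str, contig: str) -> Iterator[AlignedRead]:
    """Stream mapped reads on ``contig`` from a SAM/BAM file.

    Unmapped, secondary and supplementary records are excluded. Mate fields
    are ignored: the source data are single-end. Qualities are the Phred
    scores as stored in the file.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with pysam.AlignmentFile(path, check_sq=False) as af:
        if contig not in af.references:
            raise FormatError(f"contig {contig!r} absent from header of {path}")
        for i, rec in enumerate(af):
            try:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                if rec.reference_name != contig:
                    continue
                pairs = [
                    (q, r + 1)
                    for q, r in rec.get_aligned_pairs(matches_only=True)
                ]
                yield AlignedRead(
                    read_id=rec.query_name,
                    contig=contig,
                    start=rec.reference_start + 1,
                    strand=REVERSE if rec.is_reverse else FORWARD,
                    sequence=rec.query_sequence,
                    base_qualities=np.array(rec.query_qualities, dtype=np.int16),
                    mapq=rec.mapping_quality,
                    aligned_pairs=pairs,
                )
            except (ValueError, TypeError) as exc:
                raise FormatError(f"malformed record #{i + 1} in {path}: {exc}") from exc


def write_sam(reads: Iterable[AlignedRead], ref: MtReference, path: str) -> None:
    """Write reads as a coordinate-sorted SAM file against ``ref``."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": ref.name, "LN": len(ref)}],
    }
    reads = sorted(reads, key=lambda r: (r.start, r.read_id))
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.query_sequence = r.sequence
            a.flag = 16 if r.is_reverse else 0
            a.reference_id = 0
            a.reference_start = r.start - 1
            a.mapping_quality = r.mapq
            a.cigarstring = f"{len(r.sequence)}M"
            a.query_qualities = [int(q) for q in r.base_qualities]
            out.write(a)


class CallTable:
    """Tabular container for heteroplasmy calls across individuals.

    One row per (individual, position). Wraps a pandas DataFrame with the
    columns in :data:`CALL_COLUMNS` (extra columns from annotation are
    carried along).
    """

    def __init__(self, df: Optional[pd.DataFrame] = None):
        if df is None:
            df = pd.DataFrame(columns=CALL_COLUMNS)
        missing = [c for c in CALL_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"call table missing columns: {missing}")
        df = df.copy()
        df["position"] = df["position"].astype(int)
        dup = df.duplicated(subset=["individual", "position"])
        if dup.any():
            raise FormatError("duplicate (individual, position) rows in call table")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CallTable):
            return NotImplemented
        a = self.df[CALL_COLUMNS].fillna("")
        b = other.df[CALL_COLUMNS].fillna("")
        if len(a) != len(b):
            return False
        if len(a) == 0:
            return True
        close = np.allclose(a["minor_fraction"].astype(float), b["minor_fraction"].astype(float))
        rest = [c for c in CALL_COLUMNS if c != "minor_fraction"]
        return close and a[rest].reset_index(drop=True).equals(b[rest].reset_index(drop=True))

    @classmethod
    def from_calls(cls, calls: Sequence, individual: str, species: str) -> "CallTable":
        """Build from :class:`~mthet.caller.HeteroplasmyCall` objects."""
        rows = []
        for c in calls:
            rows.append(
                {
                    "individual": individual,
                    "species": species,
                    "position": c.position,
                    "ref": c.ref_allele,
                    "major": c.major_allele,
                    "minor": c.minor_allele,
                    "depth": c.depth,
                    "minor_fraction": c.minor_fraction,
                    "minor_fwd": c.minor_fwd,
                    "minor_rev": c.minor_rev,
                    "context": "",
                }
            )
        return cls(pd.DataFrame(rows, columns=CALL_COLUMNS))

    def concat(self, other: "CallTable") -> "CallTable":
        return CallTable(pd.concat([self.df, other.df], ignore_index=True))


def write_calls(calls: CallTable, path: str, format: str = "tsv", header_comment: Optional[str] = None) -> None:
    """Write a call table as TSV (round-trippable) or minimal VCF."""
    if format == "tsv":
        with open(path, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            calls.df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    elif format == "vcf":
        _write_vcf(calls, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _write_vcf(calls: CallTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Minor allele fraction">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Filtered depth">\n')
        fh.write('##INFO=<ID=IND,Number=1,Type=String,Description="Individual">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, row in calls.df.iterrows():
            chrom = row["species"] or "chrM"
            alt = row["minor"] if row["minor"] != row["ref"] else row["major"]
            fh.write(
                f"{chrom}\t{row['position']}\t.\t{row['ref']}\t{alt}\t.\tPASS\t"
                f"AF={row['minor_fraction']:.6g};DP={row['depth']};IND={row['individual']}\n"
            )


def read_calls(path: str) -> CallTable:
    """Read a TSV call table written by :func:`write_calls`."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype={"individual": str, "species": str, "context": str},
        keep_default_na=False,
    )
    if len(df):
        df["minor_fraction"] = df["minor_fraction"].astype(float)
    return CallTable(df)


def read_msa(path: str):
    """Read an aligned-FASTA multiple sequence alignment.

    Returns a ``Bio.Align.MultipleSeqAlignment``; records must be of equal
    length and ids must be unique. Gap character is '-'.
    """
    try:
        msa = AlignIO.read(path, "fasta")
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    ids = [rec.id for rec in msa]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate record ids")
    return msa


# --- annotation readers ------------------------------------------------------

_GFF_CLASS_MAP = {
    "CDS": "protein_coding",
    "mRNA": "protein_coding",
    "protein_coding": "protein_coding",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "D_loop": "D_loop",
    "D-loop": "D_loop",
}


def read_annotation_gff3(path: str) -> MtAnnotation:
    """Read mitochondrial features from GFF3.

    Feature types are mapped onto the closed class set: CDS/mRNA ->
    protein_coding (CDS phase retained as the reading frame), tRNA, rRNA,
    D_loop/D-loop; anything else is ignored (it will classify as
    other_intergenic by absence).
    """
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    features = []
    for f in db.all_features():
        cls = _GFF_CLASS_MAP.get(f.featuretype)
        if cls is None:
            continue
        name = f.attributes.get("Name", f.attributes.get("ID", [f.id]))[0]
        frame = None
        if cls == "protein_coding":
            frame = int(f.frame) if f.frame not in (None, ".") else 0
        features.append(
            MtFeature(
                name=name,
                feature_class=cls,
                start=f.start,
                end=f.end,
                strand=REVERSE if f.strand == "-" else FORWARD,
                frame=frame,
            )
        )
    return MtAnnotation(features=features)


def read_annotation_table(path: str) -> MtAnnotation:
    """Read features from a TSV with columns name, class, start, end[, strand, frame].

    BED-style half-open 0-based input is not assumed: coordinates here are
    1-based inclusive, matching every other interface in the package.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    features = []
    for _, row in df.iterrows():
        features.append(
            MtFeature(
                name=str(row["name"]),
                feature_class=str(row["class"]),
                start=int(row["start"]),
                end=int(row["end"]),
                strand=str(row.get("strand", FORWARD)) if "strand" in df.columns else FORWARD,
                frame=int(row["frame"]) if "frame" in df.columns and not pd.isna(row["frame"]) else None,
            )
        )
    return MtAnnotation(features=features)


def read_annotation(path: str) -> MtAnnotation:
    """Dispatch on extension: .gff/.gff3 via GFF3 parser, else TSV."""
    if path.endswith((".gff", ".gff3")):
        return read_annotation_gff3(path)
    return read_annotation_table(path)
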