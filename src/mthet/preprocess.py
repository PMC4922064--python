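"""Read preprocessing: per-individual merge, duplicate removal, MAPQ extraction.

The pipeline order is merge -> dedup -> extract. Duplicate removal keeps,
per coordinate group, the copy with the highest mapping quality — the
classical single-end PCR-duplicate rule. A coordinate group is
(contig, start, strand) plus, by default, the aligned reference span, so
reads of different aligned length are not collapsed.
"""

from __future__ import annotations

from typing import Iterable, Iterator, List

from .io_formats import AlignedRead


class MixedContigError(ValueError):
    pass


def merge_individual(read_streams: Iterable[Iterable[AlignedRead]]) -> List[AlignedRead]:
    """Multiset union of per-experiment read streams, coordinate-sorted.

    All streams must be mapped to the same contig; the ChIP-seq use case is
    pooling signal and input experiments from one individual as technical
    replicates of the mtDNA fraction.
    """
    merged: List[AlignedRead] = []
    contig = None
    for k, stream in enumerate(read_streams):
        for read in stream:
            if contig is None:
                contig = read.contig
            elif read.contig != contig:
                raise MixedContigError(
                    f"stream #{k + 1} is mapped to {read.contig!r}, expected {contig!r}"
                )
            merged.append(read)
    merged.sort(key=lambda r: (r.start, r.end, r.read_id))
    return merged


def remove_duplicates(
    reads: Iterable[AlignedRead], use_span: bool = True
) -> List[AlignedRead]:
    """Keep one read per coordinate group: the one with the highest MAPQ.

    Ties on MAPQ keep the first read in input order (deterministic). With
    ``use_span=False`` the group key drops the aligned span, collapsing
    reads that share only (contig, start, strand).
    """
    best: dict = {}
    order: list = []
    for read in reads:
        key = (read.contig, read.start, read.strand, read.end if use_span else None)
        cur = best.get(key)
        if cur is None:
            best[key] = read
            order.append(key)
        elif read.mapq > cur.mapq:
            best[key] = read
    out = [best[k] for k in order]
    out.sort(key=lambda r: (r.start, r.end, r.read_id))
    return out


def extract_mtdna(
    reads: Iterable[AlignedRead], min_mapq: int = 20
) -> Iterator[AlignedRead]:
    """Retain reads with mapping quality >= ``min_mapq`` ("at least 20")."""
    for read in reads:
        if read.mapq >= min_mapq:
            yield read


def preprocess(
    read_streams: Iterable[Iterable[AlignedRead]],
    min_mapq: int = 20,
    use_span: bool = True,
) -> List[AlignedRead]:
    """Full preprocessing contract: merge, dedup, extract high-MAPQ reads."""
    merged = merge_individual(read_streams)
    deduped = remove_duplicates(merged, use_span=use_span)
    return list(extract_mtdna(deduped, min_mapq=min_mapq))
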