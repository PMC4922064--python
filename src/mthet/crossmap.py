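"""Cross-species position mapping through a mitochondrial multiple alignment.

A multiple sequence alignment of mtDNA genomes induces, per species, a
bijection between ungapped sequence positions and alignment columns.
Composing source->column->target maps any position to its orthologous
coordinate in another species, or reports it unmappable when the target
record has a gap in that column — never a nearest-position guess.

Also provides inclusive-interval region counting, with the five classical
human mtDNA low-complexity regions as a ready-made region set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

GAP = "-"

#: The five low-complexity (homopolymer/repeat) regions of the human mtDNA,
#: 1-based inclusive rCRS coordinates.
HUMAN_LOW_COMPLEXITY = [
    ("LC1", 66, 71),
    ("LC2", 303, 309),
    ("LC3", 514, 523),
    ("LC4", 12418, 12425),
    ("LC5", 16184, 16193),
]


@dataclass
class RegionSet:
    """Named 1-based inclusive intervals on one reference."""

    regions: List[Tuple[str, int, int]]

    def __post_init__(self):
        for name, start, end in self.regions:
            if start > end or start < 1:
                raise ValueError(f"bad region {name}: {start}-{end}")

    @classmethod
    def human_low_complexity(cls) -> "RegionSet":
        return cls(list(HUMAN_LOW_COMPLEXITY))

    @classmethod
    def from_tsv(cls, path: str) -> "RegionSet":
        """TSV columns: name, start, end (1-based inclusive)."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t", comment="#")
        return cls([(str(r["name"]), int(r["start"]), int(r["end"])) for _, r in df.iterrows()])

    @classmethod
    def from_bed(cls, path: str) -> "RegionSet":
        """BED (0-based half-open) converted to 1-based inclusive."""
        regions = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.rstrip("\n").split("\t")
                name = parts[3] if len(parts) > 3 else f"{parts[0]}:{parts[1]}-{parts[2]}"
                regions.append((name, int(parts[1]) + 1, int(parts[2])))
        return cls(regions)


class MsaPositionMap:
    """Bidirectional sequence-position <-> alignment-column tables.

    For every species, column ``i`` corresponds to the count of non-gap
    characters up to and including ``i``; ambiguity characters count as
    non-gap. Both directions are 1-based. The per-species map is an
    injective, strictly monotone function of the ungapped positions.
    """

    def __init__(self, seq_to_col: Dict[str, np.ndarray], col_to_seq: Dict[str, np.ndarray]):
        self._seq_to_col = seq_to_col
        self._col_to_seq = col_to_seq

    @property
    def species(self) -> List[str]:
        return list(self._seq_to_col)

    def ungapped_length(self, species: str) -> int:
        return len(self._seq_to_col[self._check(species)])

    def _check(self, species: str) -> str:
        if species not in self._seq_to_col:
            raise KeyError(f"unknown species {species!r}")
        return species

    def to_column(self, species: str, position: int) -> int:
        """Alignment column (1-based) of an ungapped sequence position."""
        s2c = self._seq_to_col[self._check(species)]
        if not 1 <= position <= len(s2c):
            raise IndexError(
                f"{species}: position {position} outside 1..{len(s2c)}"
            )
        return int(s2c[position - 1])

    def to_position(self, species: str, column: int) -> Optional[int]:
        """Ungapped position at a column, or None where the record is gapped."""
        c2s = self._col_to_seq[self._check(species)]
        if not 1 <= column <= len(c2s):
            raise IndexError(f"column {column} outside alignment width {len(c2s)}")
        val = int(c2s[column - 1])
        return val if val > 0 else None


def build_position_map(msa) -> MsaPositionMap:
    """Build per-species coordinate tables from an aligned-FASTA MSA
    (a ``Bio.Align.MultipleSeqAlignment`` or any iterable of records with
    ``.id`` and ``.seq``)."""
    records = list(msa)
    if not records:
        raise ValueError("empty alignment")
    seq_to_col: Dict[str, np.ndarray] = {}
    col_to_seq: Dict[str, np.ndarray] = {}
    for rec in records:
        s = str(rec.seq)
        arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
        nongap = arr != ord(GAP)
        cum = np.cumsum(nongap)
        cols = np.nonzero(nongap)[0] + 1  # 1-based columns of ungapped positions
        seq_to_col[rec.id] = cols.astype(np.int64)
        c2s = np.where(nongap, cum, 0).astype(np.int64)
        col_to_seq[rec.id] = c2s
    return MsaPositionMap(seq_to_col, col_to_seq)


@dataclass
class GapReport:
    """A source position whose orthologous column is gapped in the target."""

    source_species: str
    source_position: int
    column: int
    target_species: str

    def __bool__(self) -> bool:
        return False


def to_orthologous(
    position: int,
    source_species: str,
    target_species: str,
    position_map: MsaPositionMap,
):
    """Map a 1-based position between species via the alignment.

    Returns the target position (int), or a :class:`GapReport` (falsy) when
    the target record is gapped at the orthologous column.
    """
    col = position_map.to_column(source_species, position)
    target = position_map.to_position(target_species, col)
    if target is None:
        return GapReport(
            source_species=source_species,
            source_position=position,
            column=col,
            target_species=target_species,
        )
    return target


def count_in_regions(
    positions: Iterable[int], regions: RegionSet
) -> Tuple[Dict[str, int], int]:
    """Count positions falling in each named region (1-based inclusive).

    Returns (per-region counts, total). A position inside several
    overlapping regions increments each region's count but contributes
    once to the total.
    """
    per_region = {name: 0 for name, _, _ in regions.regions}
    total = 0
    for pos in positions:
        inside = False
        for name, start, end in regions.regions:
            if start <= pos <= end:
                per_region[name] += 1
                inside = True
        if inside:
            total += 1
    return per_region, total
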