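"""Genomic context and coding consequence annotation for heteroplasmy calls.

Context classes follow the mtDNA gene economy: protein-coding genes, rRNA
and tRNA genes, the D-loop (control region), and other intergenic sequence.
Coding consequences are computed under the vertebrate mitochondrial genetic
code (NCBI translation table 2: TGA=Trp, ATA=Met, AGA/AGG=stop) for single
nucleotide substitutions within a single CDS — a minimal consequence
predictor sufficient for the synonymous/nonsynonymous dichotomy.

mtDNA quirks such as incomplete stop codons completed by polyadenylation
are ignored: codons are translated from genomic sequence as annotated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq
from scipy import stats as sps

from .io_formats import FORWARD, REVERSE, MtAnnotation, MtFeature, MtReference
from .caller import HeteroplasmyCall

#: Precedence when features overlap: a coding interpretation wins over
#: structural RNA, which wins over control-region/intergenic labels.
CLASS_PRECEDENCE = ["protein_coding", "tRNA", "rRNA", "D_loop", "other_intergenic"]

VERTEBRATE_MITO_TABLE = 2


@dataclass
class GenomicContext:
    """Context class of a position, with codon detail for coding positions."""

    feature_class: str
    feature_name: Optional[str] = None
    codon_index: Optional[int] = None  # 0-based codon number within the CDS
    ref_codon: Optional[str] = None
    alt_codon: Optional[str] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    consequence: Optional[str] = None  # 'synonymous' | 'nonsynonymous'


def classify_position(position: int, annotation: MtAnnotation, ref_length: Optional[int] = None) -> str:
    """Context class of a 1-based position under the precedence rule.

    Positions overlapped by no feature are ``other_intergenic``.
    """
    if position < 1 or (ref_length is not None and position > ref_length):
        raise IndexError(f"position {position} out of range")
    classes = {f.feature_class for f in annotation.overlapping(position)}
    for cls in CLASS_PRECEDENCE:
        if cls in classes:
            return cls
    return "other_intergenic"


def _codon_table(table_id: int):
    return CodonTable.unambiguous_dna_by_id[table_id]


def _translate(codon: str, table_id: int) -> str:
    table = _codon_table(table_id)
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


def coding_consequence(
    call: HeteroplasmyCall,
    cds: MtFeature,
    ref: MtReference,
    table_id: int = VERTEBRATE_MITO_TABLE,
) -> GenomicContext:
    """Codon-level consequence of substituting the minor allele into a CDS.

    The codon is located from the CDS start, strand and frame; for
    reverse-strand genes the CDS is read off the reverse complement and the
    substituted base is complemented accordingly. The amino-acid comparison
    classifies the change as synonymous or nonsynonymous.
    """
    pos = call.position
    if not cds.contains(pos):
        raise ValueError(f"position {pos} outside CDS {cds.name} ({cds.start}-{cds.end})")
    if ref.base(pos) != call.ref_allele:
        raise ValueError(
            f"reference mismatch at {pos}: call says {call.ref_allele}, "
            f"sequence has {ref.base(pos)}"
        )
    frame = cds.frame or 0
    genomic = ref.sequence[cds.start - 1:cds.end]
    if cds.strand == REVERSE:
        coding = str(Seq(genomic).reverse_complement())
        offset = (cds.end - pos) - frame
        sub_base = str(Seq(call.minor_allele).complement())
    else:
        coding = genomic
        offset = (pos - cds.start) - frame
        sub_base = call.minor_allele
    if offset < 0:
        raise ValueError(f"position {pos} falls before the reading frame of {cds.name}")
    codon_index = offset // 3
    within = offset % 3
    codon_start = codon_index * 3
    ref_codon = coding[codon_start:codon_start + 3]
    if len(ref_codon) < 3:
        raise ValueError(f"position {pos} lies in an incomplete terminal codon of {cds.name}")
    alt_codon = ref_codon[:within] + sub_base + ref_codon[within + 1:]
    ref_aa = _translate(ref_codon, table_id)
    alt_aa = _translate(alt_codon, table_id)
    return GenomicContext(
        feature_class="protein_coding",
        feature_name=cds.name,
        codon_index=codon_index,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        consequence="synonymous" if ref_aa == alt_aa else "nonsynonymous",
    )


def annotate_call(
    call: HeteroplasmyCall,
    annotation: MtAnnotation,
    ref: MtReference,
    table_id: int = VERTEBRATE_MITO_TABLE,
) -> GenomicContext:
    """Full context for one call: class, plus codon detail when coding."""
    cls = classify_position(call.position, annotation, ref_length=len(ref))
    if cls != "protein_coding":
        feats = [f for f in annotation.overlapping(call.position) if f.feature_class == cls]
        return GenomicContext(feature_class=cls, feature_name=feats[0].name if feats else None)
    cds = [
        f
        for f in annotation.overlapping(call.position)
        if f.feature_class == "protein_coding"
    ][0]
    return coding_consequence(call, cds, ref, table_id)


# --- disease-association lookup ---------------------------------------------


@dataclass
class DiseaseTable:
    """Positional disease-association records on the human mtDNA."""

    records: Dict[int, List[dict]]  # position -> [{'allele':..., 'phenotype':...}]

    @classmethod
    def from_tsv(cls, path: str) -> "DiseaseTable":
        """Columns: position, allele, phenotype (tab-separated)."""
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"phenotype": str})
        records: Dict[int, List[dict]] = {}
        for _, row in df.iterrows():
            records.setdefault(int(row["position"]), []).append(
                {"allele": str(row["allele"]), "phenotype": str(row["phenotype"])}
            )
        return cls(records=records)


def disease_lookup(human_position: int, table: DiseaseTable) -> List[dict]:
    """Exact-position association records; empty when none are known."""
    return list(table.records.get(human_position, []))


def association_enrichment(
    observed_hits: int, observed_total: int, baseline_hits: int, baseline_total: int
) -> float:
    """Two-sided Fisher's exact test comparing an observed hit rate against a
    baseline rate, e.g. disease-associated fraction of calls vs database-wide."""
    if min(observed_hits, observed_total, baseline_hits, baseline_total) < 0:
        raise ValueError("counts must be non-negative")
    if observed_hits > observed_total or baseline_hits > baseline_total:
        raise ValueError("hits exceed totals")
    if observed_total + baseline_total == 0:
        raise ValueError("degenerate all-zero table")
    table = [
        [observed_hits, observed_total - observed_hits],
        [baseline_hits, baseline_total - baseline_hits],
    ]
    return float(sps.fisher_exact(table, alternative="two-sided")[1])
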