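"""Coverage statistics, mutation spectrum, Ts/Tv and comparison tests.

Coverage here is the *pre-quality-filter* depth of the preprocessed reads
(the quantity a depth utility reports on the merged, deduplicated,
MAPQ-filtered alignment); the caller's post-filter depth is a different
number and is reported separately by the scanner — the two are never mixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .io_formats import AlignedRead, CallTable

#: The 12 directional substitution classes, keyed major>minor on the
#: reference-forward strand. Complementary pairs are not collapsed.
SUBSTITUTIONS = [
    f"{a}>{b}" for a in "ACGT" for b in "ACGT" if a != b
]

#: Transitions among the directional classes (purine<->purine, py<->py).
TRANSITIONS = frozenset({"A>G", "G>A", "C>T", "T>C"})


@dataclass
class CoverageProfile:
    """Per-position read depth of a preprocessed alignment."""

    depth: np.ndarray  # length == reference length, zero-depth positions included
    ratio_threshold: int = 20

    @property
    def mean(self) -> float:
        return float(self.depth.mean())

    @property
    def sd(self) -> float:
        """Sample standard deviation (n-1 denominator)."""
        return float(self.depth.std(ddof=1)) if len(self.depth) > 1 else 0.0

    @property
    def coverage_ratio(self) -> float:
        """Fraction of positions covered by at least ``ratio_threshold`` reads."""
        return float((self.depth >= self.ratio_threshold).mean())


def coverage_profile(
    reads: Iterable[AlignedRead], ref_length: int, ratio_threshold: int = 20
) -> CoverageProfile:
    """Depth vector over all reference positions, plus mean/SD/ratio.

    Depth counts reads whose alignment covers a position (deletions
    excluded, via aligned pairs); mean and SD are over *all* positions,
    including uncovered ones.
    """
    if ref_length <= 0:
        raise ValueError("ref_length must be positive")
    depth = np.zeros(ref_length, dtype=np.int64)
    for read in reads:
        rpos = np.asarray([r for _, r in read.aligned_pairs], dtype=np.int64)
        rpos = rpos[(rpos >= 1) & (rpos <= ref_length)]
        np.add.at(depth, rpos - 1, 1)
    return CoverageProfile(depth=depth, ratio_threshold=ratio_threshold)


@dataclass
class MutationSpectrum:
    """Counts of the 12 directional substitution classes of a call set."""

    counts: Dict[str, int]

    @property
    def ts(self) -> int:
        return sum(c for s, c in self.counts.items() if s in TRANSITIONS)

    @property
    def tv(self) -> int:
        return sum(c for s, c in self.counts.items() if s not in TRANSITIONS)

    @property
    def total(self) -> int:
        return self.ts + self.tv

    @property
    def ts_tv_ratio(self) -> Optional[float]:
        """Ts/Tv, or None (undefined) when no transversions are present."""
        if self.tv == 0:
            return None
        return self.ts / self.tv

    def as_vector(self) -> np.ndarray:
        return np.array([self.counts.get(s, 0) for s in SUBSTITUTIONS], dtype=np.int64)


def mutation_spectrum(calls: CallTable) -> MutationSpectrum:
    """Tabulate each call's major>minor substitution."""
    counts = {s: 0 for s in SUBSTITUTIONS}
    for _, row in calls.df.iterrows():
        key = f"{row['major']}>{row['minor']}"
        if key in counts:
            counts[key] += 1
        else:
            raise ValueError(f"call with undefined alleles: {key}")
    return MutationSpectrum(counts=counts)


def compare_ts_tv(
    spectrum: MutationSpectrum, reference_ts: int, reference_tv: int
) -> float:
    """Two-sided Fisher's exact test of the 2x2 table [[Ts,Tv],[refTs,refTv]].

    Used to compare an observed transition/transversion balance against a
    reference spectrum (e.g. a database snapshot supplied as counts).
    """
    table = [[spectrum.ts, spectrum.tv], [reference_ts, reference_tv]]
    if sum(table[0]) + sum(table[1]) == 0:
        raise ValueError("all-zero table")
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


def compare_spectrum(
    spectrum: MutationSpectrum, reference_counts: Sequence[int]
) -> Tuple[float, float, int]:
    """Pearson chi-square of the observed 12-class spectrum against expected
    proportions from reference counts, scaled to the observed total.

    Cells with zero reference count (zero expectation) are dropped; the
    observed count must be zero there too. Returns (statistic, p-value,
    degrees of freedom = retained cells - 1).
    """
    obs = spectrum.as_vector().astype(float)
    ref = np.asarray(reference_counts, dtype=float)
    if ref.shape != obs.shape:
        raise ValueError(f"reference must have {len(obs)} cells")
    keep = ref > 0
    if (obs[~keep] > 0).any():
        raise ValueError("observed counts in cells with zero expectation")
    obs, ref = obs[keep], ref[keep]
    if len(obs) < 2:
        raise ValueError("fewer than 2 retained cells")
    expected = ref / ref.sum() * obs.sum()
    stat, p = sps.chisquare(obs, f_exp=expected)
    return float(stat), float(p), len(obs) - 1


def coverage_het_correlation(
    individuals: Sequence[Tuple[float, int]], min_coverage: Optional[float] = None
) -> Optional[float]:
    """Pearson correlation between mean coverage and heteroplasmy count.

    ``min_coverage`` restricts to individuals above that mean coverage
    (e.g. >40 to check the high-coverage subset). Returns None when the
    correlation is undefined (constant input or < 3 points).
    """
    pairs = [(c, n) for c, n in individuals if min_coverage is None or c > min_coverage]
    if len(pairs) < 3:
        return None
    x = np.array([c for c, _ in pairs], dtype=float)
    y = np.array([n for _, n in pairs], dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return None
    return float(sps.pearsonr(x, y)[0])


@dataclass
class CallSetSummary:
    """Headline per-cohort numbers for a multi-individual call set."""

    n_positions: int
    n_positive_individuals: int
    n_individuals: int
    mean_calls_per_positive: float
    pct_individuals_positive: float


def summarize_calls(calls: CallTable, total_individuals: int) -> CallSetSummary:
    """Cohort summary: how many positions, how prevalent, how many per carrier.

    ``total_individuals`` is the number of individuals screened (the table
    only contains positives).
    """
    n_pos = len(calls)
    positive = calls.df["individual"].nunique() if n_pos else 0
    if total_individuals < positive:
        raise ValueError("total_individuals smaller than individuals in table")
    return CallSetSummary(
        n_positions=n_pos,
        n_positive_individuals=positive,
        n_individuals=total_individuals,
        mean_calls_per_positive=n_pos / positive if positive else float("nan"),
        pct_individuals_positive=100.0 * positive / total_individuals
        if total_individuals
        else float("nan"),
    )
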