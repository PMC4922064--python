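"""Naive, independent re-implementations used as test oracles.

Everything here is written for obviousness, not speed, and deliberately
avoids the vectorised code paths and decision functions of the package.
"""

from fractions import Fraction
from math import comb

from mthet.io_formats import FORWARD


def naive_columns(reads, ref_length, window=5):
    """O(reads x length) pileup: per position, a list of entry dicts."""
    cols = {p: [] for p in range(1, ref_length + 1)}
    for read in reads:
        quals = list(read.base_qualities)
        for qpos, rpos in read.aligned_pairs:
            if not 1 <= rpos <= ref_length:
                continue
            neighbors = (
                quals[max(0, qpos - window):qpos] + quals[qpos + 1:qpos + 1 + window]
            )
            cols[rpos].append(
                {
                    "base": read.sequence[qpos].upper(),
                    "qual": quals[qpos],
                    "neighbors": neighbors,
                    "strand": read.strand,
                }
            )
    return cols


def naive_filter(entries, min_bq=23, min_nbq=15):
    """The two read-level filters, re-applied entry by entry."""
    out = []
    for e in entries:
        if e["base"] not in "ACGT":
            continue
        if e["qual"] < min_bq:
            continue
        if any(q < min_nbq for q in e["neighbors"]):
            continue
        out.append(e)
    return out


def naive_decide(entries, ref_base, min_depth=20, min_frac=Fraction(15, 100), min_strand=2):
    """The three calling criteria on a filtered entry list.

    Returns None (no call) or a dict with major/minor and counts, using the
    documented tie conventions (ref allele, then alphabetical, wins the
    major tie; the strand-passing then alphabetically smaller candidate is
    the minor).
    """
    depth = len(entries)
    counts = {}
    for e in entries:
        key = (e["base"], e["strand"])
        counts[key] = counts.get(key, 0) + 1
    totals = {}
    for (b, _s), c in counts.items():
        totals[b] = totals.get(b, 0) + c
    if depth < min_depth or len(totals) < 2:
        return None
    top = max(totals.values())
    top_alleles = sorted(
        [b for b, c in totals.items() if c == top],
        key=lambda b: (b != ref_base, b),
    )
    major = top_alleles[0]
    rest = {b: c for b, c in totals.items() if b != major}
    second = max(rest.values())
    if Fraction(second, depth) < min_frac:
        return None

    def strands(b):
        return (counts.get((b, FORWARD), 0), sum(c for (bb, s), c in counts.items() if bb == b and s != FORWARD))

    candidates = sorted(b for b, c in rest.items() if c == second)
    passing = [b for b in candidates if min(strands(b)) >= min_strand]
    if not passing:
        return None
    minor = passing[0]
    f, r = strands(minor)
    return {
        "major": major,
        "minor": minor,
        "depth": depth,
        "minor_count": second,
        "minor_fwd": f,
        "minor_rev": r,
    }


def naive_scan(reads, ref, min_bq=23, min_nbq=15, window=5, min_depth=20,
               min_frac=Fraction(15, 100), min_strand=2):
    """Whole-genome brute force: position -> decision dict (called only)."""
    cols = naive_columns(reads, len(ref), window=window)
    calls = {}
    for pos, entries in cols.items():
        surviving = naive_filter(entries, min_bq=min_bq, min_nbq=min_nbq)
        res = naive_decide(
            surviving, ref.base(pos), min_depth=min_depth,
            min_frac=min_frac, min_strand=min_strand,
        )
        if res is not None:
            calls[pos] = res
    return calls


def fisher_exact_two_sided(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))
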