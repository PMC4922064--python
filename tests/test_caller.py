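from fractions import Fraction

import numpy as np
import pytest

from mthet.caller import (
    CRIT_DEPTH,
    CRIT_FRACTION,
    CRIT_STRAND,
    CallParams,
    HeteroplasmyCall,
    NoCall,
    call_position,
    explain_no_call,
    scan_genome,
    scan_genome_detailed,
)
from mthet.io_formats import CallTable
from mthet.pileup import FilteredColumn
from mthet.simdata import PlantedVariant, SimConfig, StrandErrorSite, random_reference, simulate_reads

from oracles import naive_decide, naive_scan


def fcol(position=100, **counts):
    """FilteredColumn from base -> (fwd, rev) counts."""
    counts = {b: tuple(v) for b, v in counts.items()}
    depth = sum(f + r for f, r in counts.values())
    return FilteredColumn(position=position, counts=counts, depth=depth, entries=None)


# --- the three criteria at their boundaries ---------------------------------


def test_strand_criterion_rejects_one_sided_minor():
    # 3/20 = 15 % passes the fraction rule but reverse support is 1 < 2
    col = fcol(A=(9, 8), G=(2, 1))
    res = call_position(col, ref_base="A")
    assert isinstance(res, NoCall)
    assert res.failed == [CRIT_STRAND]


def test_call_at_exact_boundaries():
    # depth 20, minor 4 (2 fwd / 2 rev): every criterion exactly at threshold
    col = fcol(A=(8, 8), G=(2, 2))
    res = call_position(col, ref_base="A")
    assert isinstance(res, HeteroplasmyCall)
    assert res.minor_fraction == pytest.approx(0.20)
    assert (res.major_allele, res.minor_allele) == ("A", "G")
    assert res.third_count == 0


def test_depth_19_fails_depth_criterion():
    col = fcol(A=(8, 7), G=(2, 2))
    assert col.depth == 19
    res = call_position(col, ref_base="A")
    assert isinstance(res, NoCall)
    assert res.failed == [CRIT_DEPTH]


def test_depth_20_vs_19_flips_decision():
    called = call_position(fcol(A=(8, 8), G=(2, 2)), ref_base="A")
    not_called = call_position(fcol(A=(8, 7), G=(2, 2)), ref_base="A")
    assert isinstance(called, HeteroplasmyCall) and isinstance(not_called, NoCall)


def test_fraction_14_of_100_fails_15_passes():
    low = call_position(fcol(A=(43, 43), G=(7, 7)), ref_base="A")
    assert isinstance(low, NoCall)
    assert low.failed == [CRIT_FRACTION]
    ok = call_position(fcol(A=(43, 42), G=(8, 7)), ref_base="A")
    assert isinstance(ok, HeteroplasmyCall)
    assert ok.minor_fraction == pytest.approx(0.15)


def test_strand_1_vs_2_flips_decision():
    no = call_position(fcol(A=(20, 19), G=(20, 1)), ref_base="A")
    assert isinstance(no, NoCall) and CRIT_STRAND in no.failed
    yes = call_position(fcol(A=(20, 18), G=(20, 2)), ref_base="A")
    assert isinstance(yes, HeteroplasmyCall)


def test_fraction_uses_filtered_depth_not_major_plus_minor():
    # depth 40: A=30, G=5, T=5 -> G fraction 5/40 = 0.125 < 0.15 even though
    # 5/35 of major+minor would pass
    res = call_position(fcol(A=(15, 15), G=(3, 2), T=(2, 3)), ref_base="A")
    assert isinstance(res, NoCall)
    assert CRIT_FRACTION in res.failed


def test_exact_rational_boundary_no_float_artifacts():
    # 3/20 must be treated as exactly 0.15
    res = call_position(fcol(A=(9, 8), G=(2, 1)), ref_base="A")
    assert CRIT_FRACTION not in res.failed


def test_third_allele_counted_never_promoted():
    res = call_position(fcol(A=(20, 20), G=(5, 5), T=(1, 0)), ref_base="A")
    assert isinstance(res, HeteroplasmyCall)
    assert res.minor_allele == "G"
    assert res.third_count == 1


def test_major_tie_prefers_reference_then_alphabet():
    res = call_position(fcol(A=(10, 10), G=(10, 10)), ref_base="G")
    assert isinstance(res, HeteroplasmyCall)
    assert res.major_allele == "G" and res.minor_allele == "A"
    res2 = call_position(fcol(C=(10, 10), G=(10, 10)), ref_base="A")
    assert res2.major_allele == "C" and res2.minor_allele == "G"


def test_minor_tie_prefers_strand_passing_candidate():
    # G and T tie for second; only T has both-strand support
    res = call_position(fcol(A=(14, 14), G=(6, 0), T=(3, 3)), ref_base="A")
    assert isinstance(res, HeteroplasmyCall)
    assert res.minor_allele == "T"
    # both pass: alphabetically smaller wins and the tie is recorded
    res2 = call_position(fcol(A=(14, 14), G=(3, 3), T=(3, 3)), ref_base="A")
    assert res2.minor_allele == "G" and res2.minor_tie


def test_unanimous_column_is_fraction_nocall():
    res = call_position(fcol(A=(15, 15)), ref_base="A")
    assert isinstance(res, NoCall)
    assert res.failed == [CRIT_FRACTION]


# --- randomized equivalence with the brute-force criterion checker ----------


def test_randomized_decisions_match_bruteforce():
    rng = np.random.default_rng(1234)
    params = CallParams()
    for _ in range(10_000):
        counts = {}
        for b in "ACGT":
            if rng.random() < 0.6:
                counts[b] = (int(rng.integers(0, 30)), int(rng.integers(0, 30)))
        counts = {b: c for b, c in counts.items() if sum(c)}
        col = fcol(**counts)
        ref_base = str(rng.choice(list("ACGT")))
        entries = [
            {"base": b, "strand": s, "qual": 40, "neighbors": []}
            for b, (f, r) in counts.items()
            for s, k in (("forward", f), ("reverse", r))
            for _ in range(k)
        ]
        expected = naive_decide(entries, ref_base)
        got = call_position(col, params, ref_base=ref_base)
        if expected is None:
            assert isinstance(got, NoCall)
        else:
            assert isinstance(got, HeteroplasmyCall)
            assert got.major_allele == expected["major"]
            assert got.minor_allele == expected["minor"]
            assert (got.minor_fwd, got.minor_rev) == (
                expected["minor_fwd"], expected["minor_rev"],
            )


# --- explain_no_call ---------------------------------------------------------


def test_explain_lists_only_fraction_for_14_percent():
    rep = explain_no_call(fcol(A=(43, 43), G=(7, 7)), ref_base="A")
    assert rep.failed == [CRIT_FRACTION]
    assert rep.minor_fraction == pytest.approx(0.14)
    assert (rep.minor_fwd, rep.minor_rev) == (7, 7)


def test_explain_lists_depth_for_shallow_column():
    rep = explain_no_call(fcol(A=(4, 4), G=(1, 1)), ref_base="A")
    assert CRIT_DEPTH in rep.failed
    assert rep.depth == 10


def test_every_uncalled_position_has_a_failed_criterion(simulated_sample, mid_ref):
    reads, _, _ = simulated_sample
    result = scan_genome_detailed(reads, mid_ref)
    called = {c.position for c in result.calls}
    n_checked = 0
    for rep in result.no_calls(ref=mid_ref):
        assert rep.position not in called
        assert len(rep.failed) >= 1
        n_checked += 1
    assert n_checked == 1500 - len(called)


# --- genome scanning ---------------------------------------------------------


def test_scan_recovers_planted_variants_exactly(simulated_sample, mid_ref):
    reads, truth, _ = simulated_sample
    table = scan_genome(reads, mid_ref, individual="i1", species="test")
    assert sorted(table.df["position"]) == sorted(truth.expected_positions()) == [300, 700, 1100]
    planted = {v.position: v for v in (e.variant for e in truth.entries)}
    for _, row in table.df.iterrows():
        assert row["minor"] == planted[row["position"]].minor_allele
        assert row["ref"] == mid_ref.base(row["position"])


def test_scan_error_only_genome_yields_no_calls(mid_ref):
    cfg = SimConfig(seed=77, ref_length=1500, read_length=50, mean_depth=60, error_rate=0.005)
    reads, _ = simulate_reads(mid_ref, cfg)
    assert len(scan_genome(reads, mid_ref)) == 0


def test_scan_empty_input_gives_empty_table(mid_ref):
    table = scan_genome([], mid_ref)
    assert isinstance(table, CallTable) and len(table) == 0


def test_scan_is_deterministic(simulated_sample, mid_ref):
    reads, _, _ = simulated_sample
    t1 = scan_genome(reads, mid_ref)
    t2 = scan_genome(reads, mid_ref)
    assert t1 == t2


def test_scan_monotone_in_thresholds(simulated_sample, mid_ref):
    reads, _, _ = simulated_sample
    base = scan_genome(reads, mid_ref, cparams=CallParams())
    stricter_frac = scan_genome(reads, mid_ref, cparams=CallParams(min_minor_fraction=0.25))
    stricter_depth = scan_genome(reads, mid_ref, cparams=CallParams(min_depth=40))
    assert set(stricter_frac.df["position"]).issubset(set(base.df["position"]))
    assert set(stricter_depth.df["position"]).issubset(set(base.df["position"]))


def test_scan_matches_naive_oracle_with_errors(mid_ref):
    cfg = SimConfig(
        seed=55, ref_length=1500, read_length=50, mean_depth=45,
        variants=[PlantedVariant(400, "A" if mid_ref.base(400) != "A" else "C", 0.3),
                  PlantedVariant(900, "T" if mid_ref.base(900) != "T" else "G", 0.18)],
        error_rate=0.01, bq_mean=26, bq_sd=5, bq_floor=2,
    )
    reads, _ = simulate_reads(mid_ref, cfg)
    table = scan_genome(reads, mid_ref)
    oracle = naive_scan(reads, mid_ref)
    assert sorted(table.df["position"]) == sorted(oracle)
    for _, row in table.df.iterrows():
        exp = oracle[row["position"]]
        assert row["major"] == exp["major"] and row["minor"] == exp["minor"]
        assert row["depth"] == exp["depth"]


def test_one_strand_errors_never_called(mid_ref):
    """Location-specific errors confined to one strand are rejected by the
    strand rule even at 30 % of that strand's reads."""
    for seed in range(5):
        sites = [
            StrandErrorSite(250, "forward", 0.30, "A" if mid_ref.base(250) != "A" else "C"),
            StrandErrorSite(800, "reverse", 0.30, "G" if mid_ref.base(800) != "G" else "T"),
        ]
        cfg = SimConfig(seed=seed, ref_length=1500, read_length=50, mean_depth=60,
                        strand_error_sites=sites, error_rate=0.001)
        reads, _ = simulate_reads(mid_ref, cfg)
        table = scan_genome(reads, mid_ref)
        assert not set(table.df["position"]) & {250, 800}
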