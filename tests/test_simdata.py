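import numpy as np
import pytest

from mthet.caller import CallParams
from mthet.io_formats import FORWARD, REVERSE, write_sam
from mthet.pileup import build_column
from mthet.simdata import (
    PlantedVariant,
    SimConfig,
    StrandErrorSite,
    diverged_reference,
    expected_depth,
    label_truth,
    mix_contamination,
    random_reference,
    simulate_reads,
)


def test_error_free_genome_is_unanimous(small_ref):
    cfg = SimConfig(seed=2, ref_length=300, read_length=30, mean_depth=60, error_rate=0.0)
    reads, _ = simulate_reads(small_ref, cfg)
    for pos in (1, 50, 150, 299):
        col = build_column(reads, pos)
        bases = {e.base for e in col.entries}
        assert bases == {small_ref.base(pos)}


def test_same_seed_byte_identical(small_ref, tmp_path):
    cfg = SimConfig(seed=5, ref_length=300, read_length=30, mean_depth=40,
                    variants=[PlantedVariant(150, "A" if small_ref.base(150) != "A" else "C", 0.3)])
    p1, p2 = tmp_path / "a.sam", tmp_path / "b.sam"
    write_sam(simulate_reads(small_ref, cfg)[0], small_ref, str(p1))
    write_sam(simulate_reads(small_ref, cfg)[0], small_ref, str(p2))
    assert p1.read_bytes() == p2.read_bytes()


def test_different_seeds_differ(small_ref):
    r1, _ = simulate_reads(small_ref, SimConfig(seed=1, ref_length=300, read_length=30))
    r2, _ = simulate_reads(small_ref, SimConfig(seed=2, ref_length=300, read_length=30))
    assert [r.start for r in r1] != [r.start for r in r2]


def test_planted_fraction_binomial(mid_ref):
    """Empirical minor fraction across ~10^3 replicate columns stays within
    3 binomial standard errors of the planted 0.30."""
    minor_total = 0
    depth_total = 0
    n_cols = 0
    for seed in range(25):
        positions = list(range(100, 1401, 33))
        variants = [
            PlantedVariant(p, "A" if mid_ref.base(p) != "A" else "G", 0.30)
            for p in positions
        ]
        cfg = SimConfig(seed=seed, ref_length=1500, read_length=50, mean_depth=60,
                        variants=variants, error_rate=0.0)
        reads, _ = simulate_reads(mid_ref, cfg)
        for v in variants:
            col = build_column(reads, v.position)
            minor_total += sum(e.base == v.minor_allele for e in col.entries)
            depth_total += len(col)
            n_cols += 1
    assert n_cols >= 1000
    frac = minor_total / depth_total
    se = np.sqrt(0.3 * 0.7 / depth_total)
    assert abs(frac - 0.30) < 3 * se


def test_strand_balance_biases_minor_reads(mid_ref):
    v = PlantedVariant(700, "A" if mid_ref.base(700) != "A" else "G", 0.3, strand_balance=1.0)
    cfg = SimConfig(seed=3, ref_length=1500, read_length=50, mean_depth=80,
                    variants=[v], error_rate=0.0)
    reads, _ = simulate_reads(mid_ref, cfg)
    col = build_column(reads, 700)
    minor = [e for e in col.entries if e.base == v.minor_allele]
    assert len(minor) > 5
    assert all(e.strand == FORWARD for e in minor)


def test_strand_error_site_only_hits_one_strand(mid_ref):
    site = StrandErrorSite(400, REVERSE, 0.5, "A" if mid_ref.base(400) != "A" else "C")
    cfg = SimConfig(seed=6, ref_length=1500, read_length=50, mean_depth=80,
                    strand_error_sites=[site], error_rate=0.0)
    reads, _ = simulate_reads(mid_ref, cfg)
    col = build_column(reads, 400)
    err = [e for e in col.entries if e.base == site.base]
    assert len(err) > 5
    assert all(e.strand == REVERSE for e in err)


def test_quality_profile_respected(small_ref):
    cfg = SimConfig(seed=7, ref_length=300, read_length=30, mean_depth=40,
                    bq_mean=35, bq_sd=3, bq_floor=20)
    reads, _ = simulate_reads(small_ref, cfg)
    quals = np.concatenate([r.base_qualities for r in reads])
    assert quals.min() >= 20 and quals.max() <= 41
    assert abs(quals.mean() - 35) < 1


def test_reads_respect_linear_bounds(small_ref):
    cfg = SimConfig(seed=8, ref_length=300, read_length=30, mean_depth=50)
    reads, _ = simulate_reads(small_ref, cfg)
    assert all(1 <= r.start and r.end <= 300 for r in reads)
    assert all(len(r.sequence) == 30 for r in reads)


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(seed=1, ref_length=100, read_length=200)
    with pytest.raises(ValueError):
        SimConfig(seed=1, variants=[PlantedVariant(5, "A", 1.5)])
    with pytest.raises(ValueError):
        SimConfig(seed=1, variants=[PlantedVariant(20000, "A", 0.3)])


def test_expected_depth_edges():
    cfg = SimConfig(seed=1, ref_length=1000, read_length=50, mean_depth=60)
    # interior positions sit slightly above the genome-wide mean because no
    # read can start within read_length-1 bases of the right end
    assert expected_depth(cfg, 500) == pytest.approx(1200 * 50 / 951)
    assert expected_depth(cfg, 1) == pytest.approx(
        expected_depth(cfg, 500) / 50, rel=0.1
    )


def test_label_truth_examples():
    cfg = SimConfig(
        seed=1, ref_length=1500, read_length=50, mean_depth=60,
        variants=[
            PlantedVariant(500, "A", 0.30),
            PlantedVariant(700, "A", 0.10),
            PlantedVariant(900, "A", 0.20, strand_balance=1.0),
        ],
    )
    truth = label_truth(cfg, CallParams())
    by_pos = {e.variant.position: e for e in truth.entries}
    assert by_pos[500].expected_callable and by_pos[500].reason == "callable"
    assert not by_pos[700].expected_callable and by_pos[700].reason == "minor_fraction"
    assert not by_pos[900].expected_callable and by_pos[900].reason == "strand"


def test_infeasible_config_warns_in_truth():
    cfg = SimConfig(
        seed=1, ref_length=1500, read_length=50, mean_depth=21,
        variants=[PlantedVariant(750, "A", 0.16)],
    )
    truth = label_truth(cfg, CallParams())
    assert truth.warnings  # expected minor count ~3.4 < 4 can never pass 2+2


def test_truth_labels_agree_with_empirical_calls(mid_ref):
    """Clear-margin configurations: the expected-callable label predicts the
    actual call in > 90 % of seeds."""
    from mthet.caller import scan_genome

    v_yes = PlantedVariant(600, "A" if mid_ref.base(600) != "A" else "G", 0.40)
    v_no = PlantedVariant(1000, "T" if mid_ref.base(1000) != "T" else "C", 0.05)
    agree = 0
    n_seeds = 30
    for seed in range(n_seeds):
        cfg = SimConfig(seed=seed, ref_length=1500, read_length=50, mean_depth=60,
                        variants=[v_yes, v_no], error_rate=0.001)
        reads, truth = simulate_reads(mid_ref, cfg)
        called = set(scan_genome(reads, mid_ref).df["position"])
        labels = {e.variant.position: e.expected_callable for e in truth.entries}
        if (600 in called) == labels[600] and (1000 in called) == labels[1000]:
            agree += 1
    assert agree / n_seeds > 0.9


# --- contamination -----------------------------------------------------------


def test_mix_fraction_zero_is_identity(small_ref):
    cfg = SimConfig(seed=4, ref_length=300, read_length=30, mean_depth=40)
    reads, _ = simulate_reads(small_ref, cfg)
    cref = diverged_reference(small_ref, 0.1, seed=5)
    mixed = mix_contamination(reads, cref, 0.0, seed=6)
    assert mixed == sorted(reads, key=lambda r: (r.start, r.read_id))


def test_mix_exact_contaminant_count(mid_ref):
    cfg = SimConfig(seed=4, ref_length=1500, read_length=50, mean_depth=60)
    reads, _ = simulate_reads(mid_ref, cfg)
    cref = diverged_reference(mid_ref, 0.1, seed=5)
    mixed = mix_contamination(reads, cref, 0.10, seed=6)
    contam = [r for r in mixed if r.read_id.startswith("c")]
    assert len(contam) == round(0.10 * len(reads))
    assert all(r.mapq < 20 for r in contam)


def test_diverged_reference_divergence_rate(mid_ref):
    cref = diverged_reference(mid_ref, 0.10, seed=9)
    diffs = sum(a != b for a, b in zip(mid_ref.sequence, cref.sequence))
    assert diffs / len(mid_ref) == pytest.approx(0.10, abs=0.025)


def test_contaminated_pipeline_yields_no_calls(mid_ref):
    """End-to-end: 10 % diverged contaminant reads at default MAPQ produce
    zero heteroplasmy calls after preprocessing."""
    from mthet.caller import scan_genome
    from mthet.preprocess import preprocess

    cfg = SimConfig(seed=10, ref_length=1500, read_length=50, mean_depth=60)
    reads, _ = simulate_reads(mid_ref, cfg)
    cref = diverged_reference(mid_ref, 0.10, seed=11)
    mixed = mix_contamination(reads, cref, 0.10, seed=12)
    final = preprocess([mixed])
    assert len(scan_genome(final, mid_ref)) == 0
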