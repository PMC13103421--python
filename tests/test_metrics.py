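"""Coverage profiles, downsampling, background partition, conversion QC,
and replicate concordance."""

import math

import numpy as np
import pandas as pd
import pytest

from bsfusion.metrics import (
    background_scan,
    conversion_rate,
    cpg_retention,
    depth_profile,
    downsample_pairs,
    replicate_concordance,
)
from bsfusion.samio import Alignment, Region, parse_cigar
from bsfusion.simgen import SimConfig, simulate_dataset


def aln(qname="q", contig="chrA", pos=100, cigar="100M", **kw):
    return Alignment(qname=qname, contig=contig, pos=pos, mapq=60,
                     cigar=parse_cigar(cigar), **kw)


# ---------------------------------------------------------------------------
# Depth profiles
# ---------------------------------------------------------------------------

def test_empty_profile_is_zero():
    region = Region("R", "chrA", 1, 10_000)
    prof = depth_profile([], region, bin_size=1_000)
    assert prof.depths.shape == (10,)
    assert np.all(prof.depths == 0)


def test_single_read_bin_mean():
    region = Region("R", "chrA", 1, 1_000)
    prof = depth_profile([aln(pos=101, cigar="100M")], region, bin_size=1_000)
    assert prof.depths[0] == pytest.approx(100 / 1_000)


def test_clipped_bases_contribute_no_depth():
    region = Region("R", "chrA", 1, 1_000)
    prof = depth_profile([aln(pos=101, cigar="50S100M50S")], region, bin_size=1_000)
    assert prof.depths[0] == pytest.approx(100 / 1_000)


def test_depth_conservation(sim_full, toy_genome):
    """sum(bin depth x bin width) equals total aligned bases in region."""
    region = toy_genome.gene_a.as_region()
    alns = sim_full.alignments()
    prof = depth_profile(alns, region, bin_size=700)  # non-divisor bin size
    expected = 0
    for a in alns:
        if not a.is_primary or a.contig != region.contig:
            continue
        ref = a.pos
        for op, n in a.cigar:
            if op in "M=X":
                lo, hi = max(ref, region.start), min(ref + n - 1, region.end)
                expected += max(0, hi - lo + 1)
                ref += n
            elif op in "DN":
                ref += n
    assert prof.total_aligned_bases() == pytest.approx(expected)


def test_coverage_drops_at_planted_junction(sim_full, toy_genome, allele):
    """Reads crossing the junction align split, so aligned-base coverage
    collapses on the far side of the breakpoint within gene A."""
    region = toy_genome.gene_a.as_region()
    prof = depth_profile(sim_full.alignments(), region, bin_size=500)
    j_bin = (allele.pos_a - region.start) // 500
    median = float(np.median(prof.depths))
    assert prof.depths[j_bin + 1] < median
    assert prof.depths[j_bin + 2] < 0.1 * median


def test_region_outside_contig_rejected(toy_genome):
    lengths = {k: len(v) for k, v in toy_genome.contigs.items()}
    with pytest.raises(ValueError):
        depth_profile([], Region("R", "chrA", 1, 10**7), 1_000,
                      contig_lengths=lengths)


# ---------------------------------------------------------------------------
# Downsampling
# ---------------------------------------------------------------------------

def test_downsample_full_fraction_is_identity(sim_full):
    alns = sim_full.alignments()
    assert downsample_pairs(alns, 1.0, seed=0) == alns


def test_downsample_binomial_calibration():
    alns = [aln(qname=f"q{i}") for i in range(10_000)]
    kept = downsample_pairs(alns, 0.5, seed=1)
    sd = math.sqrt(10_000 * 0.25)
    assert abs(len(kept) - 5_000) <= 3 * sd


def test_downsample_deterministic_and_mate_consistent(sim_full):
    alns = sim_full.alignments()
    k1 = downsample_pairs(alns, 0.4, seed=2)
    k2 = downsample_pairs(alns, 0.4, seed=2)
    assert k1 == k2
    kept_qnames = {a.qname for a in k1}
    # all records of a kept template survive together
    for q in kept_qnames:
        assert sum(a.qname == q for a in alns) == sum(a.qname == q for a in k1)


def test_downsample_subsets_nested(sim_full):
    alns = sim_full.alignments()
    small = {a.qname for a in downsample_pairs(alns, 0.2, seed=3)}
    large = {a.qname for a in downsample_pairs(alns, 0.6, seed=3)}
    assert small <= large


def test_downsample_fraction_zero_rejected(sim_full):
    with pytest.raises(ValueError):
        downsample_pairs(sim_full.alignments(), 0.0)


# ---------------------------------------------------------------------------
# Background partition
# ---------------------------------------------------------------------------

def test_fusion_free_background_is_zero(sim_negative, target):
    counts = background_scan(sim_negative.alignments(), target)
    assert counts.inside_target == 0
    assert counts.outside_target == 0


def test_injected_chimeric_pairs_counted_outside(toy_genome, target):
    cfg = SimConfig(fraction=0.0, depth=5, seed=16, n_chimeric_noise=40)
    res = simulate_dataset(toy_genome, None, cfg)
    counts = background_scan(res.alignments(), target)
    assert counts.inside_target == 0
    assert counts.outside_target == 40


def test_background_partition_exact(toy_genome, allele, target):
    """inside + outside equals the total number of chimeric pairs."""
    cfg = SimConfig(fraction=0.5, depth=8, seed=17, n_chimeric_noise=15)
    res = simulate_dataset(toy_genome, allele, cfg)
    counts = background_scan(res.alignments(), target)
    assert counts.outside_target == 15
    assert counts.inside_target > 0
    # target fusion pairs are inter-contig, hence all chimeric
    from bsfusion.caller import call_fusion
    call = call_fusion(res.alignments(), target, mode="lenient")
    assert counts.inside_target == call.total_count


def test_background_monotone_under_downsampling(toy_genome, target):
    cfg = SimConfig(fraction=0.0, depth=5, seed=18, n_chimeric_noise=50)
    alns = simulate_dataset(toy_genome, None, cfg).alignments()
    prev = 0
    for f in (0.25, 0.5, 0.75, 1.0):
        c = background_scan(downsample_pairs(alns, f, seed=4), target)
        assert c.outside_target >= prev
        prev = c.outside_target


# ---------------------------------------------------------------------------
# Conversion-rate QC
# ---------------------------------------------------------------------------

def test_complete_conversion_rate_is_one(toy_genome):
    cfg = SimConfig(fraction=0.0, depth=3, seed=19, conversion_rate=1.0,
                    meth_cpg=0, meth_chg=0, meth_chh=0, seq_error=0.0)
    res = simulate_dataset(toy_genome, None, cfg)
    reports = conversion_rate(res.alignments(), toy_genome.contigs)
    for ctx in ("CpG", "CHG", "CHH", "all"):
        assert reports[ctx].rate == pytest.approx(1.0)


def test_conversion_rate_binomial_recovery(toy_genome):
    cfg = SimConfig(fraction=0.0, depth=5, seed=20, conversion_rate=0.99,
                    meth_cpg=0, meth_chg=0, meth_chh=0, seq_error=0.0)
    res = simulate_dataset(toy_genome, None, cfg)
    rep = conversion_rate(res.alignments(), toy_genome.contigs)["all"]
    assert rep.total >= 10_000
    sd = math.sqrt(rep.total * 0.99 * 0.01)
    assert abs(rep.converted - 0.99 * rep.total) <= 3 * sd


def test_methylated_cpg_retention(toy_genome):
    cfg = SimConfig(fraction=0.0, depth=3, seed=21, conversion_rate=1.0,
                    meth_cpg=1.0, meth_chg=0, meth_chh=0, seq_error=0.0)
    res = simulate_dataset(toy_genome, None, cfg)
    reports = conversion_rate(res.alignments(), toy_genome.contigs)
    assert cpg_retention(reports) == pytest.approx(1.0)
    assert reports["CHH"].rate == pytest.approx(1.0)


def test_contig_filter_restricts_assessment(toy_genome, sim_negative):
    rep_a = conversion_rate(sim_negative.alignments(), toy_genome.contigs,
                            contigs=["chrA"])
    rep_all = conversion_rate(sim_negative.alignments(), toy_genome.contigs)
    assert 0 < rep_a["all"].total < rep_all["all"].total


def test_missing_reference_contig_rejected(sim_negative, toy_genome):
    with pytest.raises(ValueError):
        conversion_rate(sim_negative.alignments(), toy_genome.contigs,
                        contigs=["lambda"])


# ---------------------------------------------------------------------------
# Replicate concordance
# ---------------------------------------------------------------------------

def _table(counts):
    rows = []
    for i, (s, d) in enumerate(counts):
        rows.append({"target": f"T{i}", "split": s, "discordant": d,
                     "total": s + d})
    return pd.DataFrame(rows)


def test_identical_tables_give_r_one():
    t = _table([(5, 2), (50, 20), (500, 200)])
    r = replicate_concordance([t, t.copy()])
    for v in r.values():
        assert v == pytest.approx(1.0)


def test_constant_table_is_error():
    t1 = _table([(5, 2), (50, 20)])
    t2 = _table([(7, 7), (7, 7)])
    with pytest.raises(ValueError, match="variance"):
        replicate_concordance([t1, t2])


def test_single_table_rejected():
    with pytest.raises(ValueError):
        replicate_concordance([_table([(1, 1), (2, 2)])])


def test_mismatched_target_lists_rejected():
    t1 = _table([(5, 2), (50, 20)])
    t2 = _table([(5, 2), (50, 20)])
    t2["target"] = ["T0", "T9"]
    with pytest.raises(ValueError, match="target"):
        replicate_concordance([t1, t2])
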