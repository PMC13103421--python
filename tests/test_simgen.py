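"""Toy-genome construction, fusion planting, fragment simulation,
bisulfite conversion, and oracle FASTQ/SAM emission."""

import filecmp
import math

import numpy as np
import pysam
import pytest

from bsfusion.simgen import (
    SimConfig,
    _place_read,
    bisulfite_convert,
    make_toy_reference,
    plant_fusion,
    revcomp,
    simulate_dataset,
    simulate_fragments,
)


# ---------------------------------------------------------------------------
# Toy reference
# ---------------------------------------------------------------------------

def test_reference_deterministic():
    g1 = make_toy_reference(lengths=(50_000, 50_000), seed=1)
    g2 = make_toy_reference(lengths=(50_000, 50_000), seed=1)
    assert g1.contigs == g2.contigs
    assert g1.genes == g2.genes


def test_gc_fraction_matches_binomial_expectation():
    L = 50_000
    g = make_toy_reference(lengths=(L, L), gc=0.5, seed=2)
    seq = g.contigs["chrA"]
    observed = seq.count("G") + seq.count("C")
    sd = math.sqrt(L * 0.5 * 0.5)
    assert abs(observed - 0.5 * L) <= 3 * sd


def test_gc_one_yields_only_gc():
    g = make_toy_reference(lengths=(2_000, 2_000), gc=1.0, seed=3)
    assert set(g.contigs["chrA"]) <= {"G", "C"}


def test_too_small_contig_rejected():
    with pytest.raises(ValueError):
        make_toy_reference(lengths=(500, 50_000), read_length=150)


# ---------------------------------------------------------------------------
# Fusion planting
# ---------------------------------------------------------------------------

def test_fused_length_is_sum_of_retained_sides(toy_genome):
    al = plant_fusion(toy_genome, 10_000, 9_000)
    la = 10_000
    lb = len(toy_genome.contigs["chrB"]) - 9_000 + 1
    assert len(al.sequence) == la + lb
    assert al.junction_offset == la


def test_fused_prefix_matches_gene_a_slice(toy_genome):
    al = plant_fusion(toy_genome, 10_000, 9_000)
    assert al.sequence[:10_000] == toy_genome.contigs["chrA"][:10_000]
    assert al.sequence[10_000:] == toy_genome.contigs["chrB"][8_999:]


def test_opposite_orientation_reverse_complements_gene_b(toy_genome):
    al = plant_fusion(toy_genome, 10_000, 9_000, orientation="opposite")
    assert al.sequence[10_000:] == revcomp(toy_genome.contigs["chrB"][:9_000])


def test_positions_outside_gene_rejected(toy_genome):
    with pytest.raises(ValueError):
        plant_fusion(toy_genome, 100, 9_000)  # upstream of gene A
    with pytest.raises(ValueError):
        plant_fusion(toy_genome, 10_000, 19_999)  # downstream of gene B


# ---------------------------------------------------------------------------
# Fragment simulation
# ---------------------------------------------------------------------------

def test_fraction_zero_has_no_fusion_fragments(toy_genome, allele):
    cfg = SimConfig(fraction=0.0, depth=5, seed=4)
    frags = simulate_fragments(toy_genome, allele, cfg)
    assert all(f.origin == "wildtype" for f in frags)


def test_fraction_calibration(toy_genome, allele):
    cfg = SimConfig(fraction=0.3, depth=5, seed=5)
    frags = simulate_fragments(toy_genome, allele, cfg, n_fragments=5_000)
    k = sum(f.origin == "fusion" for f in frags)
    sd = math.sqrt(5_000 * 0.3 * 0.7)
    assert abs(k - 1_500) <= 3 * sd


def test_spanning_count_matches_enumeration_oracle(toy_genome, allele):
    """With a fixed fragment length, enumerate every start position on
    the fused contig and count those covering the junction; the
    simulated spanning fraction must match to binomial precision."""
    flen = 300
    cfg = SimConfig(fraction=1.0, depth=5, seed=6, fragment_mean=flen,
                    fragment_sd=0.0)
    n = 10_000
    frags = simulate_fragments(toy_genome, allele, cfg, n_fragments=n)
    L = len(allele.sequence)
    J = allele.junction_offset
    spanning_starts = sum(
        1 for s in range(1, L - flen + 2) if s <= J <= s + flen - 2
    )
    p = spanning_starts / (L - flen + 1)
    observed = sum(f.spans_junction for f in frags)
    sd = math.sqrt(n * p * (1 - p))
    assert abs(observed - n * p) <= 3 * sd


def test_fragments_deterministic(toy_genome, allele):
    cfg = SimConfig(fraction=0.5, depth=5, seed=12)
    assert simulate_fragments(toy_genome, allele, cfg) == simulate_fragments(
        toy_genome, allele, cfg
    )


# ---------------------------------------------------------------------------
# Bisulfite conversion
# ---------------------------------------------------------------------------

def _random_fragment(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), n))


def test_complete_conversion_removes_all_cytosines():
    frag = _random_fragment(600, 1)
    cfg = SimConfig(conversion_rate=1.0, meth_cpg=0, meth_chg=0, meth_chh=0,
                    seq_error=0.0, read_length=150)
    (r1, _), (r2, _) = bisulfite_convert(frag, "top", cfg, rng=0)
    assert "C" not in r1       # converted strand: every C now reads T
    assert "G" not in r2       # complement shows the G->A pattern


def test_zero_conversion_is_identity():
    frag = _random_fragment(600, 2)
    cfg = SimConfig(conversion_rate=0.0, seq_error=0.0, read_length=150)
    (r1, _), (r2, _) = bisulfite_convert(frag, "top", cfg, rng=0)
    assert r1 == frag[:150]
    assert r2 == revcomp(frag[-150:])


def test_bottom_strand_shows_g_to_a_on_source():
    frag = _random_fragment(600, 3)
    cfg = SimConfig(conversion_rate=1.0, meth_cpg=0, meth_chg=0, meth_chh=0,
                    seq_error=0.0, read_length=150)
    (r1, _), _ = bisulfite_convert(frag, "bottom", cfg, rng=0)
    # read 1 is sequenced off the converted bottom strand: no C remains
    assert "C" not in r1
    assert r1 == revcomp(frag[-150:]).replace("C", "T")


def test_conversion_rate_binomial_calibration():
    frag = _random_fragment(48_000, 4)
    n_c = frag.count("C")
    assert n_c >= 10_000
    cfg = SimConfig(conversion_rate=0.99, meth_cpg=0, meth_chg=0, meth_chh=0,
                    seq_error=0.0, read_length=48_000, fragment_mean=48_000)
    (r1, _), _ = bisulfite_convert(frag, "top", cfg, rng=0)
    converted = sum(
        1 for a, b in zip(frag, r1) if a == "C" and b == "T"
    )
    sd = math.sqrt(n_c * 0.99 * 0.01)
    assert abs(converted - 0.99 * n_c) <= 3 * sd


# ---------------------------------------------------------------------------
# Oracle placement and emission
# ---------------------------------------------------------------------------

def test_split_read_placement_and_reciprocal_clips(toy_genome, allele):
    """A 100 bp read crossing the junction 60/40 yields a 60M40S primary
    in gene A and a reciprocally clipped 40 M segment in gene B."""
    J = allele.junction_offset
    segs = _place_read(allele, J - 59, J + 40, forward_on_source=True,
                       read_length=100, min_clip=20)
    assert len(segs) == 2
    primary, supp = segs
    assert primary.cigar() == (("M", 60), ("S", 40))
    assert primary.contig == "chrA" and primary.pos == J - 59
    assert supp.cigar("H") == (("H", 60), ("M", 40))
    assert supp.contig == "chrB" and supp.pos == allele.pos_b


def test_short_junction_side_absorbed_into_clip(toy_genome, allele):
    J = allele.junction_offset
    segs = _place_read(allele, J - 94, J + 5, forward_on_source=True,
                       read_length=100, min_clip=20)
    assert len(segs) == 1
    assert segs[0].cigar() == (("M", 95), ("S", 5))


def test_non_spanning_pairs_carry_no_sa_tag(sim_negative):
    assert all(not a.sa_entries for a in sim_negative.alignments())


def test_oracle_sa_consistency(sim_full):
    """Every truth row flagged as a split read corresponds to exactly one
    SA-tagged primary/supplementary record pair in the output."""
    by_qname = {}
    for a in sim_full.alignments():
        by_qname.setdefault((a.qname, a.is_read1), []).append(a)
    for t in sim_full.truth:
        for is_r1, flagged in ((True, t.r1_split), (False, t.r2_split)):
            records = by_qname[(t.fid, is_r1)]
            n_primary = sum(r.is_primary for r in records)
            assert n_primary == 1
            if flagged:
                assert len(records) == 2
                assert all(len(r.sa_entries) == 1 for r in records)
                prim = next(r for r in records if r.is_primary)
                supp = next(r for r in records if not r.is_primary)
                assert prim.sa_entries[0].pos == supp.pos
                assert supp.sa_entries[0].pos == prim.pos
            else:
                assert len(records) == 1


def test_fastq_emission_round_trip(tmp_path, toy_genome, allele):
    cfg = SimConfig(fraction=1.0, depth=1, seed=9)
    res = simulate_dataset(toy_genome, allele, cfg, n_fragments=3)
    p1, p2 = tmp_path / "r1.fq", tmp_path / "r2.fq"
    res.write_fastq(p1, p2)
    lines1 = p1.read_text().splitlines()
    lines2 = p2.read_text().splitlines()
    assert len(lines1) == len(lines2) == 12
    for i in range(3):
        assert lines1[4 * i].rsplit("/", 1)[0] == lines2[4 * i].rsplit("/", 1)[0]
        assert lines1[4 * i + 1] == res.pairs[i].r1.seq
        assert lines2[4 * i + 1] == res.pairs[i].r2.seq


def test_outputs_byte_identical_across_reruns(tmp_path, toy_genome, allele):
    cfg = SimConfig(fraction=0.5, depth=3, seed=10)
    for tag in ("x", "y"):
        res = simulate_dataset(toy_genome, allele, cfg)
        res.write_sam(tmp_path / f"{tag}.sam")
        res.write_fastq(tmp_path / f"{tag}_1.fq", tmp_path / f"{tag}_2.fq")
        res.write_truth(tmp_path / f"{tag}.tsv")
    for suffix in (".sam", "_1.fq", "_2.fq", ".tsv"):
        assert filecmp.cmp(tmp_path / f"x{suffix}", tmp_path / f"y{suffix}",
                           shallow=False)


def test_oracle_sam_is_valid_and_coordinate_sorted(tmp_path, sim_full):
    path = tmp_path / "oracle.sam"
    sim_full.write_sam(path)
    with pysam.AlignmentFile(str(path)) as fh:
        assert fh.header["HD"]["SO"] == "coordinate"
        last = {}
        n = 0
        for rec in fh:
            n += 1
            key = rec.reference_name
            assert rec.reference_start >= last.get(key, 0)
            last[key] = rec.reference_start
            # query-consuming CIGAR length matches stored sequence
            assert rec.infer_query_length() == len(rec.query_sequence)
    assert n == len(sim_full.alignments())


def test_duplicate_pairs_flagged(toy_genome, allele):
    cfg = SimConfig(fraction=0.5, depth=5, seed=13, dup_rate=0.2)
    res = simulate_dataset(toy_genome, allele, cfg)
    dups = [p for p in res.pairs if p.is_duplicate]
    assert dups, "expected some duplicate pairs at dup_rate=0.2"
    for p in dups[:5]:
        recs = [a for a in res.alignments() if a.qname == p.qname]
        assert all(a.is_duplicate for a in recs)
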