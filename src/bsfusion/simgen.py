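"""Synthetic bisulfite fusion-read generator with oracle alignments.

Real validation of a fusion caller needs a dilution series of
fusion-positive DNA in fusion-negative DNA, sequenced with a directional
bisulfite protocol and aligned with a split-capable bisulfite-aware
aligner.  This module emulates exactly that, desk-scale: a two-contig toy
genome with one gene per contig, a fusion allele planted at known
coordinates, paired-end fragments drawn from fusion and wildtype alleles
at a configurable mixing fraction, directional bisulfite conversion with
per-context methylation levels, and *oracle* alignments — SAM records
placed at the true origin of every read, with split reads represented the
way aligners represent them (soft-clipped primary + hard-clipped
supplementary + reciprocal SA:Z tags).

Because placement is by construction rather than by alignment, the truth
table emitted alongside is exact: every record can be traced back to its
fragment, allele of origin, and (for junction-spanning reads) the planted
breakpoint pair.  That makes the generator the ground-truth oracle for
the caller's acceptance tests.

Coordinates are 1-based inclusive throughout, matching SAM.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .samio import Alignment, Region, SAEntry, cigar_to_text

logger = logging.getLogger(__name__)

__all__ = [
    "Gene",
    "ToyGenome",
    "FusionAllele",
    "SimConfig",
    "SimTruth",
    "SimResult",
    "make_toy_reference",
    "plant_fusion",
    "simulate_fragments",
    "bisulfite_convert",
    "simulate_dataset",
    "emit_fastq",
    "emit_oracle_sam",
]

_COMP = bytes.maketrans(b"ACGTN", b"TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Toy genome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gene:
    name: str
    contig: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"

    def as_region(self) -> Region:
        return Region(self.name, self.contig, self.start, self.end)


@dataclass
class ToyGenome:
    """Two uppercase A/C/G/T contigs, one annotated gene interval each.

    The two genes must lie on distinct contigs (or, if ever on one, be
    separated by at least ``min_separation`` bases) so that ordinary
    concordant pairs can never look like fusion evidence.
    """

    contigs: dict[str, str]
    genes: tuple[Gene, Gene]
    min_separation: int = 1_000_000

    def __post_init__(self):
        for name, seq in self.contigs.items():
            if not set(seq) <= set("ACGT"):
                raise ValueError(f"contig {name}: sequence must be A/C/G/T only")
        for g in self.genes:
            if g.contig not in self.contigs:
                raise ValueError(f"gene {g.name}: unknown contig {g.contig}")
            if not (1 <= g.start <= g.end <= len(self.contigs[g.contig])):
                raise ValueError(f"gene {g.name}: interval outside contig bounds")
        a, b = self.genes
        if a.contig == b.contig:
            gap = max(a.start, b.start) - min(a.end, b.end)
            if gap < self.min_separation:
                raise ValueError(
                    "genes on one contig must be separated by "
                    f">= {self.min_separation} bases (gap {gap})"
                )

    @property
    def gene_a(self) -> Gene:
        return self.genes[0]

    @property
    def gene_b(self) -> Gene:
        return self.genes[1]

    def write_fasta(self, path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_genes_bed(self, path) -> None:
        with open(path, "w") as fh:
            for g in self.genes:
                fh.write(f"{g.contig}\t{g.start - 1}\t{g.end}\t{g.name}\n")


def make_toy_reference(
    lengths: tuple[int, int] = (50_000, 50_000),
    gc: float = 0.45,
    seed: int = 0,
    read_length: int = 150,
    contig_names: tuple[str, str] = ("chrA", "chrB"),
    gene_names: tuple[str, str] = ("GENEA", "GENEB"),
) -> ToyGenome:
    """Random two-contig genome with one gene interval per contig.

    Each gene spans the central 60 % of its contig, leaving flanks for
    off-target background.  ``gc`` is the per-base probability of G or C
    (G and C equiprobable, likewise A and T).
    """
    if not 0.0 < gc <= 1.0:
        raise ValueError(f"gc must be in (0, 1], got {gc}")
    for L in lengths:
        if L < 10 * read_length:
            raise ValueError(
                f"contig length {L} too small: need >= 10 x read_length ({read_length})"
            )
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    contigs: dict[str, str] = {}
    genes: list[Gene] = []
    for name, gname, L in zip(contig_names, gene_names, lengths):
        idx = rng.choice(4, size=L, p=p)
        contigs[name] = bytes(np.frombuffer(b"ACGT", np.uint8)[idx]).decode()
        start = int(0.2 * L) + 1
        end = int(0.8 * L)
        genes.append(Gene(gname, name, start, end))
    return ToyGenome(contigs=contigs, genes=(genes[0], genes[1]))


# ---------------------------------------------------------------------------
# Fusion allele
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FusionAllele:
    """A fused contig joining a retained side of gene A to one of gene B.

    ``orientation='same'`` keeps both segments on their reference
    strands: the fused sequence is chrA[1..posA] + chrB[posB..end].
    ``orientation='opposite'`` joins chrA[1..posA] to the reverse
    complement of chrB[1..posB] (gene B retained side is then *left* and
    its bases read along the minus strand).  ``junction_offset`` is the
    1-based position of the last gene-A base inside the fused contig.
    """

    sequence: str
    contig_a: str
    pos_a: int
    contig_b: str
    pos_b: int
    orientation: Literal["same", "opposite"]
    junction_offset: int
    retained_a: str = "left"
    retained_b: str = "right"  # 'right' for same, 'left' for opposite
    name: str = "fusion"

    @property
    def breakpoint(self) -> tuple[int, int]:
        """The planted (gene A coordinate, gene B coordinate) pair."""
        return (self.pos_a, self.pos_b)

    def to_wildtype(self, p: int) -> tuple[str, int, int]:
        """Map a fused-contig position to (contig, position, strand_sign).

        strand_sign is +1 where the fused base equals the reference base
        and -1 where it is the reference complement (opposite-orientation
        gene-B side).
        """
        if p <= self.junction_offset:
            return self.contig_a, p, +1
        off = p - self.junction_offset - 1
        if self.orientation == "same":
            return self.contig_b, self.pos_b + off, +1
        return self.contig_b, self.pos_b - off, -1


def plant_fusion(
    genome: ToyGenome,
    pos_a: int,
    pos_b: int,
    orientation: Literal["same", "opposite"] = "same",
) -> FusionAllele:
    """Create the fusion allele joining gene A at ``pos_a`` to gene B at
    ``pos_b`` (both 1-based, both inside their gene intervals)."""
    ga, gb = genome.gene_a, genome.gene_b
    if not ga.start <= pos_a <= ga.end:
        raise ValueError(f"pos_a {pos_a} outside gene {ga.name} [{ga.start},{ga.end}]")
    if not gb.start <= pos_b <= gb.end:
        raise ValueError(f"pos_b {pos_b} outside gene {gb.name} [{gb.start},{gb.end}]")
    seq_a = genome.contigs[ga.contig][:pos_a]
    if orientation == "same":
        seq_b = genome.contigs[gb.contig][pos_b - 1 :]
        retained_b = "right"
    elif orientation == "opposite":
        seq_b = revcomp(genome.contigs[gb.contig][:pos_b])
        retained_b = "left"
    else:
        raise ValueError(f"orientation must be 'same' or 'opposite', got {orientation!r}")
    return FusionAllele(
        sequence=seq_a + seq_b,
        contig_a=ga.contig,
        pos_a=pos_a,
        contig_b=gb.contig,
        pos_b=pos_b,
        orientation=orientation,
        junction_offset=pos_a,
        retained_b=retained_b,
    )


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions for one simulated library.

    Defaults model the dilution-series design: directional (OT/OB)
    EM-seq-style libraries, 2x150 bp reads, ~300 bp inserts (bisulfite
    treatment fragments DNA, so inserts are short), near-complete
    conversion of unmethylated cytosines (0.995), mammalian-like CpG
    methylation (0.75) with negligible CHG/CHH methylation (0.01), and a
    63x target depth matching the sequencing depth used for the dilution
    series.
    """

    fraction: float = 1.0          # proportion of fragments from the fusion allele
    depth: float = 63.0            # target mean coverage over the toy genome (x)
    read_length: int = 150
    fragment_mean: float = 300.0
    fragment_sd: float = 60.0
    conversion_rate: float = 0.995  # P(unmethylated C reads as T)
    meth_cpg: float = 0.75
    meth_chg: float = 0.01
    meth_chh: float = 0.01
    seq_error: float = 0.001
    seed: int = 0
    mapq: int = 60                 # oracle MAPQ for unique placements
    min_clip: int = 20             # shortest junction segment reported as split
    dup_rate: float = 0.0          # extra duplicate-flagged copies per pair
    low_mapq_rate: float = 0.0     # fraction of pairs assigned low_mapq
    low_mapq: int = 5
    n_chimeric_noise: int = 0      # injected off-target chimeric pairs
    base_quality: int = 37

    def __post_init__(self):
        probs = {
            "fraction": self.fraction,
            "conversion_rate": self.conversion_rate,
            "meth_cpg": self.meth_cpg,
            "meth_chg": self.meth_chg,
            "meth_chh": self.meth_chh,
            "seq_error": self.seq_error,
            "dup_rate": self.dup_rate,
            "low_mapq_rate": self.low_mapq_rate,
        }
        for k, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{k} must be in [0, 1], got {v}")
        if self.read_length < 1 or self.depth <= 0:
            raise ValueError("read_length and depth must be positive")
        if self.read_length > self.fragment_mean:
            warnings.warn(
                f"read_length {self.read_length} exceeds fragment_mean "
                f"{self.fragment_mean}; fragments are truncated at read_length",
                stacklevel=2,
            )


# ---------------------------------------------------------------------------
# Fragments and truth
# ---------------------------------------------------------------------------

@dataclass
class Fragment:
    fid: str
    origin: Literal["fusion", "wildtype"]
    source: str         # contig name, or the fusion allele name
    start: int          # 1-based on the source sequence
    length: int
    strand: Literal["top", "bottom"]
    spans_junction: bool


@dataclass
class SimTruth:
    """Ground truth for one simulated fragment."""

    fid: str
    origin: str
    spans_junction: bool
    bp_a: int | None
    bp_b: int | None
    strand: str
    r1_split: bool = False  # read 1 crosses the junction with both segments >= min_clip
    r2_split: bool = False

    def __post_init__(self):
        if self.spans_junction and self.origin != "fusion":
            raise ValueError("spans_junction implies fusion origin")
        if self.spans_junction != (self.bp_a is not None):
            raise ValueError("breakpoint pair present iff spans_junction")


def simulate_fragments(
    genome: ToyGenome,
    allele: FusionAllele | None,
    config: SimConfig,
    n_fragments: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[Fragment]:
    """Draw paired-end fragments from the fusion/wildtype allele mixture.

    The fragment count is chosen so that expected read coverage over the
    toy genome (hence over the gene intervals, sampling being uniform)
    approximates ``config.depth``; override with ``n_fragments``.  Each
    fragment is drawn from the fusion allele with probability
    ``config.fraction``.  Fragment lengths are Normal(fragment_mean,
    fragment_sd) rounded and truncated below at read_length.  The
    original-strand label (bisulfite top/bottom) is uniform per fragment
    (directional protocol).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.fraction > 0 and allele is None:
        raise ValueError("fraction > 0 requires a fusion allele")

    wt_names = list(genome.contigs)
    wt_lens = np.array([len(genome.contigs[c]) for c in wt_names], float)
    total_wt = wt_lens.sum()
    if n_fragments is None:
        n_fragments = int(round(config.depth * total_wt / (2 * config.read_length)))

    is_fusion = rng.random(n_fragments) < config.fraction
    lengths = np.rint(
        rng.normal(config.fragment_mean, config.fragment_sd, n_fragments)
    ).astype(int)
    lengths = np.maximum(lengths, config.read_length)
    strands = np.where(rng.random(n_fragments) < 0.5, "top", "bottom")
    # contig choice for wildtype fragments, weighted by length
    wt_choice = rng.choice(len(wt_names), size=n_fragments, p=wt_lens / total_wt)
    u_start = rng.random(n_fragments)

    fragments: list[Fragment] = []
    J = allele.junction_offset if allele is not None else -1
    fused_len = len(allele.sequence) if allele is not None else 0
    for i in range(n_fragments):
        flen = int(lengths[i])
        if is_fusion[i]:
            src = allele.name
            L = fused_len
        else:
            src = wt_names[int(wt_choice[i])]
            L = int(wt_lens[int(wt_choice[i])])
        if flen > L:
            flen = L
        start = 1 + int(u_start[i] * (L - flen + 1))
        spans = bool(is_fusion[i]) and start <= J <= start + flen - 2
        fragments.append(
            Fragment(
                fid=f"frag{i:07d}",
                origin="fusion" if is_fusion[i] else "wildtype",
                source=src,
                start=start,
                length=flen,
                strand=str(strands[i]),
                spans_junction=spans,
            )
        )
    return fragments


# ---------------------------------------------------------------------------
# Bisulfite conversion
# ---------------------------------------------------------------------------

_A, _C, _G, _T = 65, 67, 71, 84


def _context_classes_top(arr: np.ndarray) -> np.ndarray:
    """Per-position methylation context class for top-strand cytosines.

    0 = CpG, 1 = CHG, 2 = CHH; -1 where the base is not C.  The last two
    positions lack full context and default to CHH when they are C.
    """
    n = arr.size
    cls = np.full(n, -1, np.int8)
    is_c = arr == _C
    cls[is_c] = 2
    nxt1 = np.roll(arr, -1)
    nxt2 = np.roll(arr, -2)
    if n >= 1:
        nxt1[-1] = 0
    if n >= 2:
        nxt2[-2:] = 0
    cls[is_c & (nxt1 == _G)] = 0
    cls[is_c & (nxt1 != _G) & (nxt2 == _G)] = 1
    return cls


def _context_classes_bottom(arr: np.ndarray) -> np.ndarray:
    """Context classes for bottom-strand cytosines (genome G positions),
    reading leftward along the complement: 0 = CpG, 1 = CHG, 2 = CHH."""
    n = arr.size
    cls = np.full(n, -1, np.int8)
    is_g = arr == _G
    cls[is_g] = 2
    prv1 = np.roll(arr, 1)
    prv2 = np.roll(arr, 2)
    if n >= 1:
        prv1[0] = 0
    if n >= 2:
        prv2[:2] = 0
    cls[is_g & (prv1 == _C)] = 0
    cls[is_g & (prv1 != _C) & (prv2 == _C)] = 1
    return cls


def _convert_arr(
    arr: np.ndarray,
    cls: np.ndarray,
    strand: str,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply bisulfite conversion in place on a copy of ``arr`` (source-
    forward representation).  Top strand: C->T at converted positions;
    bottom strand: G->A (the bottom-strand C, seen from the forward
    reference)."""
    out = arr.copy()
    meth = np.array([config.meth_cpg, config.meth_chg, config.meth_chh])
    pos = np.nonzero(cls >= 0)[0]
    if pos.size:
        p_convert = (1.0 - meth[cls[pos]]) * config.conversion_rate
        hit = rng.random(pos.size) < p_convert
        out[pos[hit]] = _T if strand == "top" else _A
    return out


def _apply_seq_error(read: np.ndarray, config: SimConfig, rng: np.random.Generator) -> None:
    if config.seq_error <= 0:
        return
    err = np.nonzero(rng.random(read.size) < config.seq_error)[0]
    if err.size:
        # substitute with a uniformly chosen *different* base
        bases = np.frombuffer(b"ACGT", np.uint8)
        shift = rng.integers(1, 4, err.size)
        cur = np.searchsorted(bases, read[err])  # reads are ACGT-only here
        read[err] = bases[(cur + shift) % 4]


def bisulfite_convert(
    fragment: str,
    strand: Literal["top", "bottom"],
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
    context: np.ndarray | None = None,
) -> tuple[tuple[str, str], tuple[str, str]]:
    """Directionally convert one fragment and cut the read pair from it.

    Read 1 is sequenced from the converted strand (C->T pattern on top,
    G->A when the original strand is bottom); read 2 is its complement.
    Returns ``((seq1, qual1), (seq2, qual2))``.  Methylation context is
    derived from the fragment sequence itself unless a precomputed
    context-class array is supplied (positions lacking rightward/leftward
    context default to CHH).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng if rng is not None else config.seed)
    arr = np.frombuffer(fragment.encode(), np.uint8)
    if context is None:
        context = (
            _context_classes_top(arr) if strand == "top" else _context_classes_bottom(arr)
        )
    conv = _convert_arr(arr, context, strand, config, rng)
    # molecule as sequenced: top reads source-forward, bottom reads revcomp
    if strand == "top":
        molecule = conv
    else:
        molecule = conv[::-1].copy()
        molecule = np.frombuffer(
            bytes(molecule).translate(_COMP), np.uint8
        ).copy()
    rl = min(config.read_length, molecule.size)
    r1 = molecule[:rl].copy()
    r2_src = molecule[molecule.size - rl :]
    r2 = np.frombuffer(bytes(r2_src[::-1]).translate(_COMP), np.uint8).copy()
    _apply_seq_error(r1, config, rng)
    _apply_seq_error(r2, config, rng)
    qual = chr(config.base_quality + 33) * rl
    return (bytes(r1).decode(), qual), (bytes(r2).decode(), qual)


# ---------------------------------------------------------------------------
# Read placement (the oracle "aligner")
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    """One aligned segment of a read on the wildtype reference."""

    contig: str
    pos: int                 # 1-based leftmost
    strand: str              # '+' / '-'
    match_len: int
    lead_clip: int           # clips in reference orientation
    trail_clip: int

    def cigar(self, clip_op: str = "S") -> tuple[tuple[str, int], ...]:
        ops = []
        if self.lead_clip:
            ops.append((clip_op, self.lead_clip))
        ops.append(("M", self.match_len))
        if self.trail_clip:
            ops.append((clip_op, self.trail_clip))
        return tuple(ops)


@dataclass
class SimRead:
    seq: str
    qual: str
    segments: list[Segment]   # primary first; optional supplementary second
    is_read1: bool


@dataclass
class SimPair:
    qname: str
    r1: SimRead
    r2: SimRead
    mapq: int
    is_duplicate: bool = False


def _place_read(
    allele_or_src: FusionAllele | str,
    src_start: int,
    src_end: int,
    forward_on_source: bool,
    read_length: int,
    min_clip: int,
) -> list[Segment]:
    """Map a read's source interval to 1-2 reference segments.

    For wildtype sources (plain contig name) this is a single full-match
    segment.  For the fusion allele the interval may straddle the
    junction, producing two segments; a junction-side segment shorter
    than ``min_clip`` is absorbed into the clip of the other segment.
    """
    if isinstance(allele_or_src, str):
        return [
            Segment(
                contig=allele_or_src,
                pos=src_start,
                strand="+" if forward_on_source else "-",
                match_len=read_length,
                lead_clip=0,
                trail_clip=0,
            )
        ]
    allele = allele_or_src
    J = allele.junction_offset
    pieces: list[tuple[int, int]] = []  # source-coordinate sub-intervals
    if src_start <= J:
        pieces.append((src_start, min(src_end, J)))
    if src_end > J:
        pieces.append((max(src_start, J + 1), src_end))

    segments: list[Segment] = []
    for a, b in pieces:
        m = b - a + 1
        # read-coordinate interval (1-based within the read as sequenced)
        if forward_on_source:
            r0, r1 = a - src_start + 1, b - src_start + 1
        else:
            r0, r1 = src_end - b + 1, src_end - a + 1
        contig, ref_a, sign_a = allele.to_wildtype(a)
        _, ref_b, _ = allele.to_wildtype(b)
        if sign_a > 0:
            strand = "+" if forward_on_source else "-"
            pos = ref_a
        else:
            strand = "-" if forward_on_source else "+"
            pos = ref_b  # reversed mapping: b maps to the leftmost base
        lead_read, trail_read = r0 - 1, read_length - r1
        if strand == "+":
            lead, trail = lead_read, trail_read
        else:
            lead, trail = trail_read, lead_read
        segments.append(
            Segment(contig=contig, pos=pos, strand=strand,
                    match_len=m, lead_clip=lead, trail_clip=trail)
        )
    if len(segments) == 2:
        # primary = longer aligned segment; drop a sub-min_clip mate segment
        segments.sort(key=lambda s: -s.match_len)
        if segments[1].match_len < min_clip:
            segments = segments[:1]
    return segments


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    genome: ToyGenome
    allele: FusionAllele | None
    config: SimConfig
    pairs: list[SimPair]
    truth: list[SimTruth]

    def alignments(self) -> list[Alignment]:
        """The oracle alignments as in-memory primary/supplementary
        records, equivalent to parsing the emitted SAM."""
        out: list[Alignment] = []
        for pair in self.pairs:
            out.extend(_pair_records(pair))
        return out

    def write_fastq(self, path1, path2) -> None:
        emit_fastq(self.pairs, path1, path2)

    def write_sam(self, path) -> None:
        emit_oracle_sam(self.pairs, self.genome, path)

    def write_truth(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("fragment_id\torigin\tspans_junction\tbp_a\tbp_b\tstrand\t"
                     "r1_split\tr2_split\n")
            for t in self.truth:
                fh.write(
                    f"{t.fid}\t{t.origin}\t{int(t.spans_junction)}\t"
                    f"{t.bp_a if t.bp_a is not None else '.'}\t"
                    f"{t.bp_b if t.bp_b is not None else '.'}\t{t.strand}\t"
                    f"{int(t.r1_split)}\t{int(t.r2_split)}\n"
                )


def _sim_read(
    fragment: Fragment,
    seq: str,
    qual: str,
    is_read1: bool,
    allele: FusionAllele | None,
    config: SimConfig,
) -> SimRead:
    """Place one read of a pair.  Read placement depends only on the
    fragment's coordinates and original strand, not on the converted
    sequence."""
    s, e = fragment.start, fragment.start + fragment.length - 1
    rl = min(config.read_length, fragment.length)
    # Directional protocol: on a top-strand fragment read 1 is sequenced off
    # the 5' end reading forward and read 2 off the 3' end reading reverse;
    # a bottom-strand fragment swaps both ends and orientations.
    five_prime = (fragment.strand == "top") == is_read1
    if five_prime:
        src_start, src_end = s, s + rl - 1
    else:
        src_start, src_end = e - rl + 1, e
    forward_on_source = is_read1 if fragment.strand == "top" else not is_read1
    src = fragment.source if fragment.origin == "wildtype" else allele
    segments = _place_read(src, src_start, src_end, forward_on_source, rl, config.min_clip)
    return SimRead(seq=seq, qual=qual, segments=segments, is_read1=is_read1)


def simulate_dataset(
    genome: ToyGenome,
    allele: FusionAllele | None,
    config: SimConfig,
    n_fragments: int | None = None,
) -> SimResult:
    """Run the full generator: fragments -> conversion -> oracle placement.

    Deterministic for a given (genome, allele, config): the same seed
    yields byte-identical FASTQ/SAM/truth outputs.
    """
    rng = np.random.default_rng(config.seed)
    fragments = simulate_fragments(genome, allele, config, n_fragments, rng)

    # precompute source byte arrays and context classes once per source
    sources: dict[str, np.ndarray] = {
        name: np.frombuffer(seq.encode(), np.uint8)
        for name, seq in genome.contigs.items()
    }
    if allele is not None:
        sources[allele.name] = np.frombuffer(allele.sequence.encode(), np.uint8)
    ctx_top = {k: _context_classes_top(v) for k, v in sources.items()}
    ctx_bot = {k: _context_classes_bottom(v) for k, v in sources.items()}

    pairs: list[SimPair] = []
    truth: list[SimTruth] = []
    qual_full = chr(config.base_quality + 33) * config.read_length
    for frag in fragments:
        s0 = frag.start - 1
        arr = sources[frag.source][s0 : s0 + frag.length]
        ctx = (ctx_top if frag.strand == "top" else ctx_bot)[frag.source][
            s0 : s0 + frag.length
        ]
        conv = _convert_arr(arr, ctx, frag.strand, config, rng)
        if frag.strand == "top":
            molecule = conv
        else:
            molecule = np.frombuffer(bytes(conv[::-1]).translate(_COMP), np.uint8).copy()
        rl = min(config.read_length, frag.length)
        r1_arr = molecule[:rl].copy()
        r2_arr = np.frombuffer(
            bytes(molecule[molecule.size - rl :][::-1]).translate(_COMP), np.uint8
        ).copy()
        _apply_seq_error(r1_arr, config, rng)
        _apply_seq_error(r2_arr, config, rng)
        qual = qual_full if rl == config.read_length else chr(config.base_quality + 33) * rl

        r1 = _sim_read(frag, bytes(r1_arr).decode(), qual, True, allele, config)
        r2 = _sim_read(frag, bytes(r2_arr).decode(), qual, False, allele, config)
        mapq = config.mapq
        if config.low_mapq_rate > 0 and rng.random() < config.low_mapq_rate:
            mapq = config.low_mapq
        pairs.append(SimPair(qname=frag.fid, r1=r1, r2=r2, mapq=mapq))

        bp = allele.breakpoint if frag.spans_junction else (None, None)
        truth.append(
            SimTruth(
                fid=frag.fid,
                origin=frag.origin,
                spans_junction=frag.spans_junction,
                bp_a=bp[0],
                bp_b=bp[1],
                strand=frag.strand,
                r1_split=len(r1.segments) == 2,
                r2_split=len(r2.segments) == 2,
            )
        )
        if config.dup_rate > 0 and rng.random() < config.dup_rate:
            pairs.append(
                SimPair(qname=frag.fid + "_dup", r1=r1, r2=r2, mapq=mapq,
                        is_duplicate=True)
            )

    pairs.extend(_chimeric_noise(genome, config, rng))
    return SimResult(genome=genome, allele=allele, config=config, pairs=pairs,
                     truth=truth)


def _chimeric_noise(
    genome: ToyGenome, config: SimConfig, rng: np.random.Generator
) -> list[SimPair]:
    """Random inter-contig read pairs placed *outside* both gene
    intervals: genome-wide chimeric background with zero target signal."""
    out: list[SimPair] = []
    if config.n_chimeric_noise <= 0:
        return out
    rl = config.read_length
    names = list(genome.contigs)
    qual = chr(config.base_quality + 33) * rl

    def off_target_pos(contig: str) -> int:
        L = len(genome.contigs[contig])
        gene = next(g for g in genome.genes if g.contig == contig)
        # flanks outside the gene with room for a read
        windows = []
        if gene.start - rl >= 1:
            windows.append((1, gene.start - rl))
        if gene.end + 1 <= L - rl + 1:
            windows.append((gene.end + 1, L - rl + 1))
        lo, hi = windows[int(rng.integers(len(windows)))]
        return int(rng.integers(lo, hi + 1))

    for i in range(config.n_chimeric_noise):
        c1, c2 = names[0], names[1]
        p1, p2 = off_target_pos(c1), off_target_pos(c2)
        seq1 = genome.contigs[c1][p1 - 1 : p1 - 1 + rl]
        seq2 = revcomp(genome.contigs[c2][p2 - 1 : p2 - 1 + rl])
        r1 = SimRead(seq1, qual, [Segment(c1, p1, "+", rl, 0, 0)], True)
        r2 = SimRead(seq2, qual, [Segment(c2, p2, "-", rl, 0, 0)], False)
        out.append(SimPair(qname=f"noise{i:05d}", r1=r1, r2=r2, mapq=config.mapq))
    return out


# ---------------------------------------------------------------------------
# Emission: FASTQ, SAM, in-memory Alignment records
# ---------------------------------------------------------------------------

def emit_fastq(pairs: Sequence[SimPair], path1, path2) -> None:
    """Standard 4-line FASTQ, mate files record-synchronized; read names
    carry the fragment id."""
    if not pairs:
        raise ValueError("no read pairs to write")
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.qname}/1\n{p.r1.seq}\n+\n{p.r1.qual}\n")
            f2.write(f"@{p.qname}/2\n{p.r2.seq}\n+\n{p.r2.qual}\n")


def _record_seq_qual(read: SimRead, seg: Segment, is_supp: bool) -> tuple[str, str]:
    """SEQ/QUAL as stored in the SAM record: reference-oriented, and for
    hard-clipped supplementaries restricted to the aligned slice."""
    seq, qual = read.seq, read.qual
    if seg.strand == "-":
        seq, qual = revcomp(seq), qual[::-1]
    if is_supp:
        seq = seq[seg.lead_clip : seg.lead_clip + seg.match_len]
        qual = qual[seg.lead_clip : seg.lead_clip + seg.match_len]
    return seq, qual


def _pair_records(pair: SimPair) -> list[Alignment]:
    """Expand one simulated pair into primary (+ supplementary) records."""
    out = []
    for read, mate in ((pair.r1, pair.r2), (pair.r2, pair.r1)):
        mate_primary = mate.segments[0]
        for k, seg in enumerate(read.segments):
            is_supp = k > 0
            clip_op = "H" if is_supp else "S"
            sa = ()
            if len(read.segments) == 2:
                other = read.segments[1 - k]
                sa = (
                    SAEntry(
                        contig=other.contig,
                        pos=other.pos,
                        strand=other.strand,
                        cigar=other.cigar("S" if k else "H"),
                        mapq=pair.mapq,
                        nm=0,
                    ),
                )
            seq, _ = _record_seq_qual(read, seg, is_supp)
            out.append(
                Alignment(
                    qname=pair.qname,
                    contig=seg.contig,
                    pos=seg.pos,
                    mapq=pair.mapq,
                    cigar=seg.cigar(clip_op),
                    is_read1=read.is_read1,
                    is_read2=not read.is_read1,
                    is_reverse=seg.strand == "-",
                    is_primary=not is_supp,
                    is_duplicate=pair.is_duplicate,
                    is_unmapped=False,
                    mate_unmapped=False,
                    sa_entries=sa,
                    mate_contig=mate_primary.contig,
                    mate_pos=mate_primary.pos,
                    seq=seq,
                )
            )
    return out


def _sam_flag(aln: Alignment, mate_reverse: bool) -> int:
    flag = 0x1 | 0x2 * 0  # paired
    flag |= 0x40 if aln.is_read1 else 0x80
    if aln.is_reverse:
        flag |= 0x10
    if mate_reverse:
        flag |= 0x20
    if not aln.is_primary:
        flag |= 0x800
    if aln.is_duplicate:
        flag |= 0x400
    return flag


def emit_oracle_sam(pairs: Sequence[SimPair], genome: ToyGenome, path) -> None:
    """Write coordinate-sorted SAM against the wildtype reference.

    Junction-spanning reads get a soft-clipped primary plus a
    hard-clipped supplementary with reciprocal SA:Z tags; everything else
    gets a single full-match primary.  Fragments shorter than the read
    length are skipped with a warning (their reads would run off the
    molecule).
    """
    rows: list[tuple[int, int, str]] = []  # (contig rank, pos, line)
    order = {name: i for i, name in enumerate(genome.contigs)}
    for pair in pairs:
        mate_rev = {True: pair.r2.segments[0].strand == "-",
                    False: pair.r1.segments[0].strand == "-"}
        quals = iter(_expand_quals(pair))
        for aln in _pair_records(pair):
            flag = _sam_flag(aln, mate_rev[aln.is_read1])
            qual = next(quals)
            rnext = "=" if aln.mate_contig == aln.contig else aln.mate_contig
            tlen = 0
            if aln.mate_contig == aln.contig and aln.is_primary:
                tlen = aln.mate_pos - aln.pos
            tags = f"\tSA:Z:{''.join(e.to_text() for e in aln.sa_entries)}" \
                if aln.sa_entries else ""
            line = (
                f"{aln.qname}\t{flag}\t{aln.contig}\t{aln.pos}\t{aln.mapq}\t"
                f"{cigar_to_text(aln.cigar)}\t{rnext}\t{aln.mate_pos}\t{tlen}\t"
                f"{aln.seq}\t{qual}\tNM:i:0{tags}"
            )
            rows.append((order[aln.contig], aln.pos, line))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name, seq in genome.contigs.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        fh.write("@PG\tID:bsfusion-simgen\tPN:bsfusion\n")
        for _, _, line in rows:
            fh.write(line + "\n")


def _expand_quals(pair: SimPair) -> list[str]:
    """QUAL strings per emitted record, parallel to :func:`_pair_records`."""
    out = []
    for read in (pair.r1, pair.r2):
        for k, seg in enumerate(read.segments):
            out.append(_record_seq_qual(read, seg, k > 0)[1])
    return out
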