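"""Coverage, downsampling, genome-wide background, conversion-rate QC,
and replicate concordance.

These are the quality-control and characterization measurements that
surround a targeted fusion call: the local coverage drop that a real
junction produces (reads crossing it align split rather than
contiguously, and the partner locus receives none of their bases), the
linear growth of fusion evidence with sequencing depth probed by
seeded read-pair downsampling, the genome-wide chimeric background that
motivates restricting the analysis to target regions, the bisulfite
conversion-rate checks (all-context spike-in style, CpG retention,
genome-wide CHH), and the between-replicate concordance of per-target
counts.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .samio import Alignment, Region, fetch_pairs
from .caller import TargetPair, pass_filters

__all__ = [
    "DepthProfile",
    "ConversionReport",
    "BackgroundCounts",
    "depth_profile",
    "downsample_pairs",
    "background_scan",
    "conversion_rate",
    "cpg_retention",
    "replicate_concordance",
]


# ---------------------------------------------------------------------------
# Coverage profiling
# ---------------------------------------------------------------------------

@dataclass
class DepthProfile:
    region: Region
    bin_size: int
    depths: np.ndarray  # per-bin mean aligned-base coverage

    @property
    def bin_starts(self) -> np.ndarray:
        return self.region.start + self.bin_size * np.arange(self.depths.size)

    def total_aligned_bases(self) -> float:
        widths = np.minimum(
            self.bin_starts + self.bin_size - 1, self.region.end
        ) - self.bin_starts + 1
        return float(np.sum(self.depths * widths))


def _aligned_blocks(aln: Alignment) -> Iterable[tuple[int, int]]:
    """1-based inclusive reference intervals of aligned *bases* (M/=/X);
    deletions and skips shift the cursor but contribute no depth."""
    ref = aln.pos
    for op, n in aln.cigar:
        if op in "M=X":
            yield ref, ref + n - 1
            ref += n
        elif op in "DN":
            ref += n


def depth_profile(
    alignments: Iterable[Alignment] | str,
    region: Region,
    bin_size: int = 1000,
    contig_lengths: Mapping[str, int] | None = None,
) -> DepthProfile:
    """Per-bin mean coverage from aligned bases of primary, non-duplicate
    records.  Clipped bases contribute nothing — this is what makes a
    fusion junction show up as a local coverage drop."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if contig_lengths is not None:
        L = contig_lengths.get(region.contig)
        if L is None or region.end > L or region.start < 1:
            raise ValueError(
                f"region {region.name} outside contig {region.contig} bounds"
            )
    from .samio import read_alignments

    if isinstance(alignments, str):
        alignments = read_alignments(alignments)

    span = len(region)
    cov = np.zeros(span + 1, dtype=np.int64)  # diff array over the region
    for aln in alignments:
        if not aln.is_primary or aln.is_unmapped or aln.is_duplicate:
            continue
        if aln.contig != region.contig:
            continue
        for a, b in _aligned_blocks(aln):
            lo = max(a, region.start) - region.start
            hi = min(b, region.end) - region.start
            if lo > hi + 0:
                continue
            if hi < 0 or lo >= span:
                continue
            cov[lo] += 1
            cov[hi + 1] -= 1
    per_base = np.cumsum(cov[:-1])

    n_bins = math.ceil(span / bin_size)
    depths = np.zeros(n_bins)
    for i in range(n_bins):
        chunk = per_base[i * bin_size : (i + 1) * bin_size]
        depths[i] = chunk.sum() / chunk.size
    return DepthProfile(region=region, bin_size=bin_size, depths=depths)


# ---------------------------------------------------------------------------
# Downsampling
# ---------------------------------------------------------------------------

def _qname_keep(qname: str, fraction: float, seed: int) -> bool:
    h = hashlib.blake2b(
        qname.encode(), digest_size=8, key=str(seed).encode()[:16]
    ).digest()
    return int.from_bytes(h, "big") / 2**64 < fraction


def downsample_pairs(
    alignments: Iterable[Alignment],
    fraction: float,
    seed: int = 0,
) -> list[Alignment]:
    """Keep each qname — both mates and any supplementaries — with
    probability ``fraction`` via a seeded hash of the qname.

    Hashing (rather than per-record sampling) keeps mates and
    supplementary records of one template together, and makes subsets
    nested across fractions for a fixed seed: the 20 % subset is
    contained in the 50 % subset, which mirrors sub-sampling one library
    to increasing depths.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1.0:
        return list(alignments)
    return [a for a in alignments if _qname_keep(a.qname, fraction, seed)]


# ---------------------------------------------------------------------------
# Genome-wide background
# ---------------------------------------------------------------------------

@dataclass
class BackgroundCounts:
    inside_target: int
    outside_target: int

    @property
    def total(self) -> int:
        return self.inside_target + self.outside_target


def _is_chimeric(pair: tuple[Alignment, Alignment], min_distance: int) -> bool:
    r1, r2 = pair
    if r1.contig != r2.contig:
        return True
    if abs(r1.pos - r2.pos) > min_distance:
        return True
    for r in pair:
        for e in r.sa_entries:
            if e.contig != r.contig or abs(e.pos - r.pos) > min_distance:
                return True
    return False


def background_scan(
    alignments: Iterable[Alignment] | str,
    target: TargetPair,
    min_mapq: int = 20,
    min_distance: int = 1_000_000,
) -> BackgroundCounts:
    """Count fusion-like read pairs genome-wide vs within the target.

    A filtered primary pair is fusion-like (chimeric) when its mates map
    to different contigs, or to the same contig separated by more than
    ``min_distance``, or when either mate carries an SA entry across
    such a distance.  Chimeric pairs whose two mates both fall inside
    the target gene regions count as inside-target; every other chimeric
    pair is genome-wide background.  The partition is exact: inside +
    outside = total chimeric pairs.
    """
    if min_distance < 0:
        raise ValueError("min_distance must be >= 0")
    pairs = fetch_pairs(alignments, regions=None)
    inside = outside = 0
    regions = (target.gene_a, target.gene_b)
    for pair in pairs:
        if not pass_filters(pair, min_mapq):
            continue
        if not _is_chimeric(pair, min_distance):
            continue
        if all(any(m.overlaps(r) for r in regions) for m in pair):
            inside += 1
        else:
            outside += 1
    return BackgroundCounts(inside_target=inside, outside_target=outside)


# ---------------------------------------------------------------------------
# Bisulfite conversion-rate QC
# ---------------------------------------------------------------------------

@dataclass
class ConversionReport:
    context: str  # CpG | CHG | CHH | all
    converted: int
    total: int

    @property
    def rate(self) -> float:
        return self.converted / self.total if self.total else float("nan")


_CTX_NAMES = ("CpG", "CHG", "CHH")


def conversion_rate(
    alignments: Iterable[Alignment] | str,
    reference: Mapping[str, str],
    contigs: Sequence[str] | None = None,
    context: str = "all",
) -> dict[str, ConversionReport]:
    """Strand-aware conversion rates per cytosine context.

    For every reference cytosine covered by an aligned base (directional
    protocol: read 1 forward / read 2 reverse report the top strand via
    C→T; read 1 reverse / read 2 forward report the bottom strand via
    G→A), counts converted (T / A) vs retained (C / G) observations, with
    the context taken from the reference trinucleotide on the cytosine's
    strand.  ``contigs`` restricts the assessment, e.g. to an
    unmethylated lambda-like spike-in contig.  Returns reports keyed by
    context plus an ``"all"`` aggregate; a pUC19-style CpG-retention
    figure is ``1 - rate`` of the CpG report (see :func:`cpg_retention`).
    """
    from .samio import read_alignments

    if isinstance(alignments, str):
        alignments = read_alignments(alignments)
    refs = {
        name: np.frombuffer(str(seq).upper().encode(), np.uint8)
        for name, seq in reference.items()
        if contigs is None or name in contigs
    }
    if contigs is not None:
        missing = set(contigs) - set(refs)
        if missing:
            raise ValueError(f"reference sequence missing for contig(s) {sorted(missing)}")
    if not refs:
        raise ValueError("no reference sequences available")

    C, G, T, A = 67, 71, 84, 65
    conv = np.zeros(3, np.int64)
    tot = np.zeros(3, np.int64)

    # precompute per-contig context classes for both strands (simgen's
    # classifiers are reused: they encode the same trinucleotide rule)
    from .simgen import _context_classes_bottom, _context_classes_top

    ctx_top = {k: _context_classes_top(v) for k, v in refs.items()}
    ctx_bot = {k: _context_classes_bottom(v) for k, v in refs.items()}

    for aln in alignments:
        if not aln.is_primary or aln.is_unmapped or aln.is_duplicate:
            continue
        if aln.contig not in refs:
            continue
        ref = refs[aln.contig]
        if aln.seq is None:
            raise ValueError(
                f"alignment {aln.qname} lacks SEQ; conversion QC needs read bases"
            )
        seq = np.frombuffer(aln.seq.upper().encode(), np.uint8)
        top = aln.is_read1 != aln.is_reverse  # r1 fwd or r2 rev -> top strand
        ctx = ctx_top[aln.contig] if top else ctx_bot[aln.contig]
        # walk aligned blocks; SEQ is reference-oriented, so query offsets
        # advance in step with the reference regardless of strand
        q = 0
        r = aln.pos - 1  # 0-based
        for op, n in aln.cigar:
            if op in "M=X":
                rr = np.arange(r, min(r + n, ref.size))
                qq = np.arange(q, q + rr.size)
                cls = ctx[rr]
                site = cls >= 0
                if site.any():
                    bases = seq[qq[site]]
                    k = cls[site]
                    if top:
                        is_conv = bases == T
                        is_ret = bases == C
                    else:
                        is_conv = bases == A
                        is_ret = bases == G
                    informative = is_conv | is_ret
                    np.add.at(conv, k[informative], is_conv[informative].astype(np.int64))
                    np.add.at(tot, k[informative], 1)
                q += n
                r += n
            elif op in "IS":
                q += n
            elif op in "DN":
                r += n

    reports = {
        name: ConversionReport(name, int(conv[i]), int(tot[i]))
        for i, name in enumerate(_CTX_NAMES)
    }
    reports["all"] = ConversionReport("all", int(conv.sum()), int(tot.sum()))
    if context != "all" and context in reports:
        return {context: reports[context], "all": reports["all"]}
    return reports


def cpg_retention(reports: Mapping[str, ConversionReport]) -> float:
    """pUC19-style check: fraction of CpG cytosines retained as C."""
    return 1.0 - reports["CpG"].rate


# ---------------------------------------------------------------------------
# Replicate concordance
# ---------------------------------------------------------------------------

def replicate_concordance(
    tables: Sequence[pd.DataFrame],
    metrics: Sequence[str] = ("total", "split", "discordant"),
) -> dict[str, float]:
    """Pearson correlation of per-target counts between two replicate
    call tables (columns: target, split, discordant, total).

    With more than two tables the minimum pairwise correlation is
    reported per metric (the conservative summary).  Raises on fewer
    than two targets or on a zero-variance column.
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 call tables")
    aligned = [t.set_index("target").sort_index() for t in tables]
    idx = aligned[0].index
    for t in aligned[1:]:
        if not t.index.equals(idx):
            raise ValueError("call tables cover different target lists")
    if len(idx) < 2:
        raise ValueError("correlation undefined for < 2 targets")

    out: dict[str, float] = {}
    for metric in metrics:
        rs = []
        for i in range(len(aligned)):
            for j in range(i + 1, len(aligned)):
                x = aligned[i][metric].to_numpy(float)
                y = aligned[j][metric].to_numpy(float)
                if np.std(x) == 0 or np.std(y) == 0:
                    raise ValueError(
                        f"zero variance in metric {metric!r}; correlation undefined"
                    )
                rs.append(stats.pearsonr(x, y).statistic)
        out[metric] = float(min(rs))
    return out
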