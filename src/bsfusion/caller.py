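"""Targeted fusion calling from split and discordant read pairs.

The method asks one question of an aligned bisulfite library: how many
read pairs connect two named gene loci?  Two kinds of evidence count.  A
*split read pair* has one read whose alignment is divided across the
junction — a primary alignment in one gene carrying an SA:Z entry into
the other gene — with its mate mapping to that other gene.  A
*discordant read pair* has its two mates' primary alignments in the two
different genes with no qualifying split alignment.  Pairs are filtered
first (both mates mapped and primary, neither a duplicate, both
MAPQ >= 20), each qname is counted at most once, and the fusion read
pair count is the sum of the two classes.

For split reads the breakpoint is localized from clip boundaries: on
each of the two alignments (primary CIGAR and the SA entry's CIGAR,
each already expressed in its own reference orientation) the boundary
aligned base on the clipped side is the junction coordinate — the
leftmost aligned base when the leading clip dominates, the rightmost
when the trailing clip does.  Unique (gene A, gene B) coordinate pairs
are tallied with their supporting read counts.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .samio import (
    Alignment,
    DegenerateAlignmentError,
    Region,
    SAEntry,
    cigar_ref_span,
    clip_lengths,
    fetch_pairs,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TargetPair",
    "FusionEvidence",
    "FusionCall",
    "NoJunctionError",
    "pass_filters",
    "classify_pair",
    "locate_breakpoint",
    "call_fusion",
]


class NoJunctionError(ValueError):
    """Raised when breakpoint localization is attempted on an alignment
    with no clipped side (not a split alignment)."""


@dataclass(frozen=True)
class TargetPair:
    """The fusion hypothesis: two named, disjoint gene intervals."""

    gene_a: Region
    gene_b: Region

    def __post_init__(self):
        if self.gene_a.name == self.gene_b.name:
            raise ValueError("target genes must have distinct names")
        if self.gene_a.overlaps_interval(
            self.gene_b.contig, self.gene_b.start, self.gene_b.end
        ):
            raise ValueError("target gene regions must be disjoint")

    @property
    def name(self) -> str:
        return f"{self.gene_a.name}-{self.gene_b.name}"

    def swapped(self) -> "TargetPair":
        return TargetPair(self.gene_b, self.gene_a)


@dataclass
class FusionEvidence:
    """One classified read pair supporting the target fusion."""

    qname: str
    pair_class: Literal["split", "discordant"]
    split_read: Literal["read1", "read2", "none"] = "none"
    breakpoint: tuple[int, int] | None = None  # (pos in gene A, pos in gene B)


@dataclass
class FusionCall:
    """Aggregate fusion call for one target gene pair."""

    target: TargetPair
    split_count: int = 0
    discordant_count: int = 0
    breakpoints: Counter = field(default_factory=Counter)  # (posA, posB) -> support
    evidence: list[FusionEvidence] = field(default_factory=list)
    mode: str = "strict"
    detection_min: int = 1

    @property
    def total_count(self) -> int:
        return self.split_count + self.discordant_count

    @property
    def detected(self) -> bool:
        return self.total_count >= self.detection_min

    @property
    def modal_breakpoint(self) -> tuple[int, int] | None:
        if not self.breakpoints:
            return None
        return max(self.breakpoints.items(), key=lambda kv: (kv[1], kv[0]))[0]

    def summary(self) -> dict:
        return {
            "target": self.target.name,
            "gene_a": self.target.gene_a.name,
            "gene_b": self.target.gene_b.name,
            "split": self.split_count,
            "discordant": self.discordant_count,
            "total": self.total_count,
            "unique_breakpoints": len(self.breakpoints),
            "detected": self.detected,
            "mode": self.mode,
        }


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def pass_filters(pair: tuple[Alignment, Alignment], min_mapq: int = 20) -> bool:
    """Both mates mapped, neither flagged duplicate, both MAPQ >= min_mapq."""
    r1, r2 = pair
    for r in (r1, r2):
        if r.is_unmapped or r.mate_unmapped:
            return False
        if r.is_duplicate:
            return False
        if r.mapq < min_mapq:
            return False
    return True


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _sa_overlaps(entry: SAEntry, region: Region) -> bool:
    return region.overlaps_interval(entry.contig, entry.ref_start, entry.ref_end)


def _has_clip(aln: Alignment) -> bool:
    try:
        lead, trail = clip_lengths(aln.cigar)
    except DegenerateAlignmentError:
        return False
    return lead > 0 or trail > 0


def _qualifying_sa(aln: Alignment, other_gene: Region, min_mapq: int) -> SAEntry | None:
    """Best SA entry of ``aln`` landing in the partner gene.

    The entry must reach MAPQ >= min_mapq (symmetric filtering), and the
    primary must actually be clipped — a split alignment implies a clip.
    Several candidates are resolved by highest SA MAPQ, then lowest NM,
    then leftmost position.
    """
    if not aln.sa_entries or not _has_clip(aln):
        return None
    candidates = [
        e for e in aln.sa_entries
        if _sa_overlaps(e, other_gene) and e.mapq >= min_mapq
    ]
    if not candidates:
        return None
    return min(candidates, key=lambda e: (-e.mapq, e.nm, e.pos))


def classify_pair(
    pair: tuple[Alignment, Alignment],
    target: TargetPair,
    mode: Literal["strict", "lenient"] = "strict",
    min_mapq: int = 20,
) -> tuple[str, Alignment | None, SAEntry | None]:
    """Classify a filtered pair as split, discordant, or none.

    Split: one mate's primary alignment lies in one target gene and
    carries an SA entry into the other, while its mate maps to that
    other gene (``strict``) or to either gene (``lenient``).  Discordant:
    the mates' primaries lie in different target genes and neither
    carries a qualifying SA entry.  A split pair is never also counted
    discordant.  Returns ``(class, split_read_alignment, sa_entry)``.
    """
    r1, r2 = pair
    ga, gb = target.gene_a, target.gene_b

    def in_a(aln):
        return aln.overlaps(ga)

    def in_b(aln):
        return aln.overlaps(gb)

    split_candidates: list[tuple[Alignment, SAEntry]] = []
    for read, mate in ((r1, r2), (r2, r1)):
        for home, away in ((ga, gb), (gb, ga)):
            if not read.overlaps(home):
                continue
            entry = _qualifying_sa(read, away, min_mapq)
            if entry is None:
                continue
            if mode == "strict":
                mate_ok = mate.overlaps(away)
            else:
                mate_ok = mate.overlaps(away) or mate.overlaps(home)
            if mate_ok:
                split_candidates.append((read, entry))
                break  # one home gene per read

    if split_candidates:
        if len(split_candidates) > 1:
            logger.info(
                "qname %s: both mates carry qualifying SA entries; "
                "counted as one split pair", r1.qname,
            )
        read, entry = split_candidates[0]
        return "split", read, entry

    if (in_a(r1) and in_b(r2)) or (in_b(r1) and in_a(r2)):
        return "discordant", None, None
    return "none", None, None


# ---------------------------------------------------------------------------
# Breakpoint localization
# ---------------------------------------------------------------------------

def _boundary(pos: int, cigar) -> int:
    """Boundary aligned base on the clipped side of one alignment.

    Leading clip >= trailing clip: the junction abuts the first aligned
    base (``pos``); otherwise it abuts the last (``pos + ref_span - 1``).
    Since each alignment's CIGAR is expressed in its own reference
    orientation, this rule is strand-correct as-is.
    """
    lead, trail = clip_lengths(cigar)  # raises on all-clip CIGAR
    if lead == 0 and trail == 0:
        raise NoJunctionError("alignment has no clipped side; not a split alignment")
    if lead >= trail:
        return pos
    return pos + cigar_ref_span(cigar) - 1


def locate_breakpoint(
    split_read: Alignment,
    sa_entry: SAEntry,
    target: TargetPair,
) -> tuple[int, int]:
    """(gene A coordinate, gene B coordinate) of the junction.

    Applies the clip-boundary rule independently to the primary CIGAR
    and the SA entry's CIGAR, then orders the two coordinates by which
    alignment lies in gene A.
    """
    primary_bp = _boundary(split_read.pos, split_read.cigar)
    sa_bp = _boundary(sa_entry.pos, sa_entry.cigar)
    if split_read.overlaps(target.gene_a):
        return primary_bp, sa_bp
    return sa_bp, primary_bp


# ---------------------------------------------------------------------------
# Aggregate call
# ---------------------------------------------------------------------------

def call_fusion(
    alignments: Iterable[Alignment] | str,
    target: TargetPair,
    min_mapq: int = 20,
    mode: Literal["strict", "lenient"] = "strict",
    detection_min: int = 1,
    keep_evidence: bool = False,
) -> FusionCall:
    """Run the full fusion call for one target gene pair.

    Pipeline: fetch mated primary pairs touching either gene ->
    MAPQ/duplicate/mapped filters -> split/discordant classification ->
    breakpoint localization -> per-qname counting with unique-breakpoint
    support tallies.  An empty alignment source yields a zero-count
    call.
    """
    call = FusionCall(target=target, mode=mode, detection_min=detection_min)
    pairs = fetch_pairs(alignments, [target.gene_a, target.gene_b])
    for pair in pairs:
        if not pass_filters(pair, min_mapq):
            continue
        cls, split_read, sa_entry = classify_pair(pair, target, mode, min_mapq)
        if cls == "none":
            continue
        ev = FusionEvidence(qname=pair[0].qname, pair_class=cls)
        if cls == "split":
            ev.split_read = "read1" if split_read.is_read1 else "read2"
            ev.breakpoint = locate_breakpoint(split_read, sa_entry, target)
            call.split_count += 1
            call.breakpoints[ev.breakpoint] += 1
        else:
            call.discordant_count += 1
        if keep_evidence:
            call.evidence.append(ev)
    return call
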