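"""SAM/BAM ingestion and structural parsing of alignment records.

Fusion evidence lives in three places of a SAM record: the CIGAR string
(where does the aligned segment stop and the soft clip begin), the SA:Z
auxiliary tag (where did the clipped-off part of a chimeric read align),
and the mate fields (where did the other read of the pair go).  This
module turns those into plain Python structures with SAM-native
coordinates: 1-based, inclusive, leftmost-aligned.  BED intervals
(0-based, half-open) are converted at the boundary and never appear
internally.

File access goes through :mod:`pysam`; everything downstream of the file
boundary operates on :class:`Alignment` objects, so callers and tests can
also feed in-memory records produced by :mod:`bsfusion.simgen`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pysam

__all__ = [
    "SamFormatError",
    "DegenerateAlignmentError",
    "PairingError",
    "SAEntry",
    "Region",
    "Alignment",
    "parse_cigar",
    "cigar_to_text",
    "cigar_ref_span",
    "cigar_query_len",
    "clip_lengths",
    "parse_sa_tag",
    "sa_tag_text",
    "read_alignments",
    "read_regions_bed",
    "fetch_pairs",
]

# CIGAR op classes per the SAM specification.
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
REF_OPS = frozenset("MDN=X")      # consume reference
QUERY_OPS = frozenset("MIS=X")    # consume query (stored sequence)
CLIP_OPS = frozenset("SH")


class SamFormatError(ValueError):
    """Malformed CIGAR or SA:Z content."""


class DegenerateAlignmentError(ValueError):
    """An alignment with no aligned reference bases (all-clip CIGAR)."""


class PairingError(ValueError):
    """Input integrity violation while mating reads (e.g. two primary
    read-1 records under one query name)."""


# ---------------------------------------------------------------------------
# CIGAR
# ---------------------------------------------------------------------------

def parse_cigar(text: str) -> tuple[tuple[str, int], ...]:
    """Parse a CIGAR string into ``((op, length), ...)``.

    Raises :class:`SamFormatError` on unknown op codes or if the text is
    not fully consumed by ``<int><op>`` tokens.
    """
    if not text or text == "*":
        raise SamFormatError(f"empty or undefined CIGAR: {text!r}")
    ops = []
    end = 0
    for m in _CIGAR_RE.finditer(text):
        if m.start() != end:
            raise SamFormatError(f"invalid CIGAR {text!r}")
        ops.append((m.group(2), int(m.group(1))))
        end = m.end()
    if end != len(text):
        raise SamFormatError(f"invalid CIGAR {text!r}")
    return tuple(ops)


def cigar_to_text(cigar: Sequence[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)


def _as_ops(cigar) -> tuple[tuple[str, int], ...]:
    if isinstance(cigar, str):
        return parse_cigar(cigar)
    return tuple(cigar)


def cigar_ref_span(cigar) -> int:
    """Reference bases consumed by an alignment (ops M, D, N, =, X)."""
    ops = _as_ops(cigar)
    bad = [op for op, _ in ops if op not in REF_OPS | QUERY_OPS | CLIP_OPS | {"P"}]
    if bad:
        raise SamFormatError(f"unknown CIGAR op(s) {bad}")
    return sum(n for op, n in ops if op in REF_OPS)


def cigar_query_len(cigar) -> int:
    """Query bases implied by the CIGAR, counting soft *and* hard clips
    (i.e. the length of the original read)."""
    ops = _as_ops(cigar)
    return sum(n for op, n in ops if op in QUERY_OPS or op == "H")


def clip_lengths(cigar) -> tuple[int, int]:
    """(leading, trailing) clipped bases, soft and hard clips combined.

    Soft and hard clips are treated alike for side determination because
    aligners typically soft-clip the primary record of a chimeric read and
    hard-clip its supplementary.  An all-clip CIGAR raises
    :class:`DegenerateAlignmentError`.
    """
    ops = _as_ops(cigar)
    i = 0
    lead = 0
    while i < len(ops) and ops[i][0] in CLIP_OPS:
        lead += ops[i][1]
        i += 1
    j = len(ops)
    trail = 0
    while j > i and ops[j - 1][0] in CLIP_OPS:
        trail += ops[j - 1][1]
        j -= 1
    if i == j:
        raise DegenerateAlignmentError(f"all-clip CIGAR {cigar_to_text(ops)}")
    return lead, trail


# ---------------------------------------------------------------------------
# SA:Z tag
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SAEntry:
    """One entry of an SA:Z tag: ``rname,pos,strand,CIGAR,mapQ,NM;``.

    ``pos`` is 1-based leftmost; ``cigar`` is stored parsed but
    serializes back byte-for-byte via :meth:`to_text`.
    """

    contig: str
    pos: int
    strand: str  # '+' or '-'
    cigar: tuple[tuple[str, int], ...]
    mapq: int
    nm: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise SamFormatError(f"SA strand must be +/-, got {self.strand!r}")

    @property
    def ref_start(self) -> int:
        return self.pos

    @property
    def ref_end(self) -> int:
        return self.pos + cigar_ref_span(self.cigar) - 1

    def to_text(self) -> str:
        return (
            f"{self.contig},{self.pos},{self.strand},"
            f"{cigar_to_text(self.cigar)},{self.mapq},{self.nm};"
        )


def parse_sa_tag(text: str) -> list[SAEntry]:
    """Parse an SA:Z tag value into a list of :class:`SAEntry`, order
    preserved.  Each entry must have six comma-separated fields and be
    semicolon-terminated."""
    entries: list[SAEntry] = []
    for raw in text.split(";"):
        if raw == "":
            continue
        fields = raw.split(",")
        if len(fields) != 6:
            raise SamFormatError(
                f"SA entry {raw!r}: expected 6 fields, got {len(fields)}"
            )
        contig, pos_s, strand, cigar_s, mapq_s, nm_s = fields
        try:
            pos, mapq, nm = int(pos_s), int(mapq_s), int(nm_s)
        except ValueError as e:
            raise SamFormatError(f"SA entry {raw!r}: non-numeric field ({e})") from None
        entries.append(SAEntry(contig, pos, strand, parse_cigar(cigar_s), mapq, nm))
    if not text.endswith(";"):
        raise SamFormatError(f"SA tag {text!r} not semicolon-terminated")
    return entries


def sa_tag_text(entries: Iterable[SAEntry]) -> str:
    return "".join(e.to_text() for e in entries)


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Region:
    """A named genomic interval, 1-based inclusive on both ends."""

    name: str
    contig: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"region {self.name}: start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, contig: str, pos: int) -> bool:
        return contig == self.contig and self.start <= pos <= self.end

    def overlaps_interval(self, contig: str, start: int, end: int) -> bool:
        return contig == self.contig and start <= self.end and end >= self.start

    @classmethod
    def from_bed_fields(cls, fields: Sequence[str]) -> "Region":
        """BED line (0-based half-open) -> 1-based inclusive Region.
        Requires >= 4 columns (the name column)."""
        if len(fields) < 4:
            raise ValueError("BED targets need >= 4 columns (chrom start end name)")
        return cls(name=fields[3], contig=fields[0],
                   start=int(fields[1]) + 1, end=int(fields[2]))


def read_regions_bed(path) -> list[Region]:
    regions = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        regions.append(Region.from_bed_fields(line.split("\t")))
    return regions


def parse_region_spec(spec: str) -> Region:
    """Parse ``contig:start-end:NAME`` (1-based inclusive) from the CLI."""
    parts = spec.split(":")
    if len(parts) != 3:
        raise ValueError(f"region spec {spec!r}: want contig:start-end:NAME")
    contig, span, name = parts
    start_s, _, end_s = span.partition("-")
    return Region(name=name, contig=contig, start=int(start_s), end=int(end_s))


# ---------------------------------------------------------------------------
# Alignment records
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """Semantic content of one SAM record.

    ``pos`` is the 1-based leftmost aligned coordinate.  ``is_primary``
    means neither the secondary (0x100) nor the supplementary (0x800)
    flag is set.  Supplementary records of chimeric reads reach the
    caller only through the ``sa_entries`` of the primary.
    """

    qname: str
    contig: str | None
    pos: int
    mapq: int
    cigar: tuple[tuple[str, int], ...]
    is_read1: bool = True
    is_read2: bool = False
    is_reverse: bool = False
    is_primary: bool = True
    is_duplicate: bool = False
    is_unmapped: bool = False
    mate_unmapped: bool = False
    sa_entries: tuple[SAEntry, ...] = ()
    mate_contig: str | None = None
    mate_pos: int = 0
    seq: str | None = None  # SAM SEQ column (reference-oriented); optional

    @property
    def ref_start(self) -> int:
        return self.pos

    @property
    def ref_end(self) -> int:
        return self.pos + cigar_ref_span(self.cigar) - 1

    def overlaps(self, region: Region, padding: int = 0) -> bool:
        """True if any *aligned* reference base (clips excluded) lies in
        the region (optionally padded)."""
        if self.is_unmapped or self.contig is None:
            return False
        return region.overlaps_interval(
            self.contig, self.ref_start - padding, self.ref_end + padding
        )


def _from_pysam(rec: pysam.AlignedSegment) -> Alignment:
    sa = ()
    if rec.has_tag("SA"):
        sa = tuple(parse_sa_tag(rec.get_tag("SA")))
    return Alignment(
        qname=rec.query_name,
        contig=rec.reference_name,
        pos=(rec.reference_start or 0) + 1 if not rec.is_unmapped else 0,
        mapq=rec.mapping_quality,
        cigar=parse_cigar(rec.cigarstring) if rec.cigarstring else (),
        is_read1=rec.is_read1 or not rec.is_paired,
        is_read2=rec.is_read2,
        is_reverse=rec.is_reverse,
        is_primary=not (rec.is_secondary or rec.is_supplementary),
        is_duplicate=rec.is_duplicate,
        is_unmapped=rec.is_unmapped,
        mate_unmapped=rec.mate_is_unmapped if rec.is_paired else True,
        sa_entries=sa,
        mate_contig=rec.next_reference_name,
        mate_pos=(rec.next_reference_start or 0) + 1,
        seq=rec.query_sequence,
    )


def read_alignments(path) -> Iterator[Alignment]:
    """Stream Alignment records from a SAM/BAM file (pysam-backed)."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            yield _from_pysam(rec)


# ---------------------------------------------------------------------------
# Mate pairing within target regions
# ---------------------------------------------------------------------------

def fetch_pairs(
    alignments: Iterable[Alignment] | str | Path,
    regions: Sequence[Region] | None,
    padding: int = 0,
    return_unpaired: bool = False,
):
    """Mate primary records, keeping pairs where >= 1 mate overlaps a region.

    ``regions=None`` keeps every primary pair (used by the genome-wide
    background scan).  Secondary and supplementary records never become
    pair members.  Each qname yields at most one pair; a qname with two
    primary read-1 (or read-2) records raises :class:`PairingError`.
    Singletons whose mate record is absent are excluded from the pairing
    output (returned separately when ``return_unpaired``).
    """
    if isinstance(alignments, (str, Path)):
        alignments = read_alignments(alignments)

    by_qname: dict[str, list[Alignment | None]] = {}
    for aln in alignments:
        if not aln.is_primary or aln.is_unmapped:
            continue
        slot = 1 if aln.is_read2 else 0
        mates = by_qname.setdefault(aln.qname, [None, None])
        if mates[slot] is not None:
            which = "read-2" if slot else "read-1"
            raise PairingError(f"qname {aln.qname!r}: two primary {which} records")
        mates[slot] = aln

    pairs: list[tuple[Alignment, Alignment]] = []
    unpaired: list[Alignment] = []
    for qname in by_qname:
        r1, r2 = by_qname[qname]
        if r1 is None or r2 is None:
            single = r1 if r2 is None else r2
            if regions is None or any(single.overlaps(r, padding) for r in regions):
                unpaired.append(single)
            continue
        if regions is None or any(
            m.overlaps(r, padding) for m in (r1, r2) for r in regions
        ):
            pairs.append((r1, r2))
    # deterministic output irrespective of input record order
    pairs.sort(key=lambda p: (p[0].contig or "", p[0].pos, p[0].qname))
    if return_unpaired:
        unpaired.sort(key=lambda a: (a.contig or "", a.pos, a.qname))
        return pairs, unpaired
    return pairs
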