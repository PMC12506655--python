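"""Lightweight containers for aligned reads and per-site base observations.

The flip-remap machinery and the genotype-likelihood code operate on these
plain records; adapters convert from ``pysam.AlignedSegment`` so the same
code path serves both real BAM input and in-memory simulated reads.
Sequences are stored in reference (forward-genome) orientation, matching
``pysam``'s ``query_sequence``; reverse-complementing for FASTQ export of
reverse-strand reads happens only at serialization time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignedRead:
    """A (gaplessly stored) aligned read.

    ``start`` is the 1-based leftmost reference position.  ``seq`` and
    ``quals`` are in forward-genome orientation.  Reads converted from BAM
    records with indels are handled through ``ref_to_query``, an explicit
    reference-position → query-offset map; when it is ``None`` the alignment
    is taken to be an ungapped end-to-end match (the case for all simulated
    reads).
    """

    name: str
    chrom: str
    start: int
    seq: str
    quals: tuple[int, ...]
    mapq: int
    is_reverse: bool = False
    is_duplicate: bool = False
    ref_to_query: Optional[dict[int, int]] = None

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError("sequence and quality lengths differ")
        if self.start < 1:
            raise ValueError("alignment start must be >= 1")

    @property
    def end(self) -> int:
        """1-based inclusive rightmost reference position covered."""
        if self.ref_to_query is not None:
            return max(self.ref_to_query)
        return self.start + len(self.seq) - 1

    def covers(self, chrom: str, pos: int) -> bool:
        if chrom != self.chrom:
            return False
        if self.ref_to_query is not None:
            return pos in self.ref_to_query
        return self.start <= pos <= self.end

    def query_offset(self, pos: int) -> Optional[int]:
        """0-based offset into ``seq`` of reference position ``pos``.

        ``None`` when the position falls in a deletion / reference skip or
        outside the alignment.
        """
        if self.ref_to_query is not None:
            return self.ref_to_query.get(pos)
        if self.start <= pos <= self.end:
            return pos - self.start
        return None

    def base_at(self, pos: int) -> Optional[str]:
        off = self.query_offset(pos)
        return None if off is None else self.seq[off]

    def qual_at(self, pos: int) -> Optional[int]:
        off = self.query_offset(pos)
        return None if off is None else self.quals[off]

    def with_base(self, pos: int, base: str) -> "AlignedRead":
        off = self.query_offset(pos)
        if off is None:
            raise ValueError(f"position {pos} is not aligned in read {self.name}")
        seq = self.seq[:off] + base + self.seq[off + 1 :]
        return replace(self, seq=seq)


def from_pysam(seg) -> Optional[AlignedRead]:
    """Convert a ``pysam.AlignedSegment`` to an :class:`AlignedRead`.

    Returns ``None`` for unmapped or sequence-less records.  Indel-containing
    alignments get an explicit reference→query offset map.
    """
    if seg.is_unmapped or seg.query_sequence is None:
        return None
    quals = seg.query_qualities
    if quals is None:
        quals = [0] * len(seg.query_sequence)
    ref_to_query = None
    if seg.cigartuples is not None and any(op != 0 for op, _ in seg.cigartuples):
        ref_to_query = {
            rpos + 1: qpos
            for qpos, rpos in seg.get_aligned_pairs(matches_only=True)
        }
    return AlignedRead(
        name=seg.query_name,
        chrom=seg.reference_name,
        start=seg.reference_start + 1,
        seq=seg.query_sequence.upper(),
        quals=tuple(quals),
        mapq=seg.mapping_quality,
        is_reverse=seg.is_reverse,
        is_duplicate=seg.is_duplicate,
        ref_to_query=ref_to_query,
    )


@dataclass(frozen=True)
class ReadObservation:
    """One aligned base at a SNP site.

    ``base_quality`` is the phred-scaled quality Q of the observed base, so
    the sequencing-error probability is ``10**(-Q/10)``.  ``is_modified``
    distinguishes allele-flipped copies from original reads.
    """

    read_id: str
    base: str
    base_quality: int
    mapping_quality: int
    is_modified: bool = False
    mapped_pos: Optional[tuple[str, int]] = None

    def __post_init__(self) -> None:
        if self.base not in "ACGTN":
            raise ValueError(f"base must be one of A/C/G/T/N, got {self.base!r}")
        if self.base_quality < 0:
            raise ValueError("base quality must be >= 0")


# Separator used to tag flipped reads with their source site; chosen to be
# illegal in common read-name alphabets so collisions are detectable.
FLIP_TAG_SEP = "|flip|"


@dataclass(frozen=True)
class FlippedRead:
    """An allele-flipped copy of a read, ready for remapping.

    The copy is identical to its source read except for the single base at
    the tagged SNP, swapped ref↔alt.  ``origin_chrom``/``origin_pos`` record
    the site the flip targets so remapped reads can be re-associated without
    auxiliary state.
    """

    source: AlignedRead
    origin_chrom: str
    origin_pos: int
    flipped_to: str  # the allele the copy now carries at the site

    @property
    def name(self) -> str:
        return (
            f"{self.source.name}{FLIP_TAG_SEP}"
            f"{self.origin_chrom}|{self.origin_pos}|{self.flipped_to}"
        )

    def base_at_site(self) -> str:
        base = self.source.base_at(self.origin_pos)
        assert base is not None
        return base

    def to_fastq(self) -> str:
        """FASTQ record in sequencing (read) orientation."""
        seq = self.source.seq
        quals = self.source.quals
        if self.source.is_reverse:
            seq = reverse_complement(seq)
            quals = quals[::-1]
        qual_str = "".join(chr(min(q, 93) + 33) for q in quals)
        return f"@{self.name}\n{seq}\n+\n{qual_str}\n"
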